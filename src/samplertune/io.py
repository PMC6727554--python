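"""Readers and writers for the pipeline's tabular artifacts.

TSV is the native interchange format.  All readers validate and reject
malformed input (naming the offending row) rather than coercing it; all
writers are deterministic given identical inputs.

Artifacts
---------
hit table           gene_id, hit_id, ec (may be empty), lineage
                    (semicolon-separated, root → leaf); extra columns such
                    as identity/evalue are tolerated and ignored
annotation table    gene_id, alpha, ec, score — one row per gene × α
standard of truth   gene_id, curated_ec (comma-separated EC set or the
                    literal ``NONE``)
curation worksheet  gene_id, proposed_ec, score, curated_ec (blank — for
                    the curator to fill in)
grid export         threshold rows × α columns, cells ``CA/IA/IR/CR``
report              per-α TSV + JSON summary of the recommendation
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .assessment import ConfusionMatrixGrid, DEFAULT_THRESHOLDS, IR
from .ec import NOT_ENZYME_LITERAL, is_valid_ec, parse_truth_label
from .scoring import DEFAULT_ALPHA_GRID, NO_EC
from .selection import Recommendation

__all__ = [
    "ValidationError",
    "read_hit_table",
    "write_hit_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_standard_of_truth",
    "write_standard_of_truth",
    "write_curation_worksheet",
    "write_grid",
    "write_report",
    "read_recommendation_json",
    "hit_table_from_blast",
    "WorkbookLayout",
    "read_supplementary_workbook",
    "write_supplementary_workbook",
    "RunConfig",
]

PathLike = Union[str, Path]


class ValidationError(ValueError):
    """Malformed or inconsistent input data."""


def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if frame.empty:
        raise ValidationError(f"{path}: no data rows")
    return frame


def read_hit_table(path: PathLike) -> pd.DataFrame:
    """Read and validate a homology hit table."""
    frame = _read_tsv(path, ["gene_id", "hit_id", "ec", "lineage"])
    bad = [
        i + 2  # 1-based, plus header line
        for i, ec in enumerate(frame["ec"])
        if ec and not is_valid_ec(ec)
    ]
    if bad:
        raise ValidationError(f"{path}: malformed EC number in row(s) {bad}")
    empty_lineage = [i + 2 for i, lin in enumerate(frame["lineage"]) if not lin.strip()]
    if empty_lineage:
        raise ValidationError(f"{path}: empty lineage in row(s) {empty_lineage}")
    dup = frame.duplicated(subset=["gene_id", "hit_id"])
    if dup.any():
        rows = [i + 2 for i in frame.index[dup]]
        raise ValidationError(f"{path}: duplicate (gene_id, hit_id) in row(s) {rows}")
    return frame[["gene_id", "hit_id", "ec", "lineage"]]


def write_hit_table(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_annotation_table(path: PathLike) -> pd.DataFrame:
    frame = _read_tsv(path, ["gene_id", "alpha", "ec", "score"])
    try:
        frame = frame.assign(
            alpha=frame["alpha"].astype(float), score=frame["score"].astype(float)
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric alpha/score: {exc}") from None
    bad_score = frame.index[(frame["score"] < 0) | (frame["score"] > 1)]
    if len(bad_score):
        raise ValidationError(f"{path}: score outside [0,1] in row(s) {[i + 2 for i in bad_score]}")
    bad_ec = [
        i + 2
        for i, ec in enumerate(frame["ec"])
        if ec != NO_EC and not is_valid_ec(ec)
    ]
    if bad_ec:
        raise ValidationError(f"{path}: malformed EC number in row(s) {bad_ec}")
    return frame


def write_annotation_table(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_standard_of_truth(path: PathLike) -> pd.DataFrame:
    """Read a curated-label table; labels stay as raw strings, validated."""
    frame = _read_tsv(path, ["gene_id", "curated_ec"])
    for i, raw in enumerate(frame["curated_ec"]):
        try:
            parse_truth_label(raw)
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from None
    if frame["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene_id in standard of truth")
    return frame[["gene_id", "curated_ec"]]


def write_standard_of_truth(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_curation_worksheet(
    annotations: pd.DataFrame, sample_ids: Sequence[str], path: PathLike
) -> None:
    """Worksheet for the curator: sampled genes with an empty curated_ec."""
    sub = annotations[annotations["gene_id"].isin(list(sample_ids))]
    sheet = sub[["gene_id", "ec", "score"]].rename(columns={"ec": "proposed_ec"}).copy()
    sheet["curated_ec"] = ""
    sheet.to_csv(path, sep="\t", index=False)


def write_grid(grid: ConfusionMatrixGrid, path: PathLike) -> None:
    grid.to_frame().to_csv(path, sep="\t")


def write_report(
    recommendation: Recommendation,
    per_alpha: pd.DataFrame,
    tsv_path: PathLike,
    json_path: Optional[PathLike] = None,
) -> None:
    """Per-α report TSV (+ optional JSON summary of the recommendation)."""
    if per_alpha.empty:
        raise ValidationError("empty per-alpha report")
    cols = [
        "alpha",
        "mean_accuracy",
        "upper_threshold",
        "lower_threshold",
        "n_accepted",
        "n_rejected",
        "n_curate",
        "pct_curation",
        "curation_ratio",
        "selected",
    ]
    per_alpha[cols].to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(recommendation.to_dict(), indent=2, sort_keys=True) + "\n"
        )


def read_recommendation_json(path: PathLike) -> Recommendation:
    data = json.loads(Path(path).read_text())
    if data.get("curation_ratio") == "inf":
        data["curation_ratio"] = float("inf")
    return Recommendation(**data)


def hit_table_from_blast(
    blast_path: PathLike,
    ec_map: Mapping[str, str],
    lineage_map: Mapping[str, str],
) -> pd.DataFrame:
    """Build a hit table from BLAST tabular output (outfmt-6-like).

    Only the first two columns (query id, subject id) are used; ``ec_map``
    maps subject id → EC (missing / empty = no EC) and ``lineage_map``
    maps subject id → semicolon-separated lineage.  Subjects without a
    lineage are rejected.
    """
    raw = pd.read_csv(blast_path, sep="\t", header=None, dtype=str, comment="#")
    if raw.shape[1] < 2:
        raise ValidationError(f"{blast_path}: expected >=2 tab-separated columns")
    rows = []
    for i, (q, s) in enumerate(zip(raw[0], raw[1])):
        if s not in lineage_map:
            raise ValidationError(f"{blast_path}: row {i + 1}: no lineage for subject {s!r}")
        rows.append((q, s, ec_map.get(s, ""), lineage_map[s]))
    frame = pd.DataFrame(rows, columns=["gene_id", "hit_id", "ec", "lineage"])
    return frame.drop_duplicates(subset=["gene_id", "hit_id"], keep="first")


@dataclasses.dataclass(frozen=True)
class WorkbookLayout:
    """Column layout of a supplementary results workbook.

    Gene rows with one curated column and one (ec, score) column pair per
    α value; the α is encoded in the column name suffix, e.g.
    ``ec_0.1`` / ``score_0.1``.
    """

    gene_column: str = "gene"
    curated_column: str = "curated_ec"
    ec_prefix: str = "ec_"
    score_prefix: str = "score_"


def read_supplementary_workbook(
    path: PathLike, sheet: Union[str, int] = 0, layout: WorkbookLayout = WorkbookLayout()
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read a results workbook sheet into (standard of truth, annotations).

    The sheet must follow :class:`WorkbookLayout`; unrecognised layouts
    raise with the sheet's columns listed for diagnosis.
    """
    book = pd.read_excel(path, sheet_name=sheet, dtype=str)
    cols = list(book.columns)
    if layout.gene_column not in cols or layout.curated_column not in cols:
        raise ValidationError(
            f"{path}[{sheet}]: unrecognised layout; expected columns "
            f"{layout.gene_column!r} and {layout.curated_column!r}, found {cols}"
        )
    alphas = []
    for c in cols:
        if c.startswith(layout.ec_prefix):
            suffix = c[len(layout.ec_prefix):]
            if f"{layout.score_prefix}{suffix}" not in cols:
                raise ValidationError(
                    f"{path}[{sheet}]: EC column {c!r} without matching score column"
                )
            alphas.append(suffix)
    if not alphas:
        raise ValidationError(
            f"{path}[{sheet}]: no per-alpha '{layout.ec_prefix}*' columns found in {cols}"
        )
    truth = book[[layout.gene_column, layout.curated_column]].rename(
        columns={layout.gene_column: "gene_id", layout.curated_column: "curated_ec"}
    )
    rows = []
    for suffix in alphas:
        a = float(suffix)
        for gene, ec, score in zip(
            book[layout.gene_column],
            book[f"{layout.ec_prefix}{suffix}"],
            book[f"{layout.score_prefix}{suffix}"],
        ):
            rows.append((gene, a, ec if ec else NO_EC, float(score)))
    annotations = pd.DataFrame(rows, columns=["gene_id", "alpha", "ec", "score"])
    return truth, annotations


def write_supplementary_workbook(
    truth: pd.DataFrame,
    annotations: pd.DataFrame,
    path: PathLike,
    layout: WorkbookLayout = WorkbookLayout(),
) -> None:
    """Inverse of :func:`read_supplementary_workbook` (one sheet)."""
    wide = truth.rename(
        columns={"gene_id": layout.gene_column, "curated_ec": layout.curated_column}
    ).copy()
    for a in sorted(annotations["alpha"].astype(float).unique()):
        sub = annotations[annotations["alpha"].astype(float) == a].set_index("gene_id")
        suffix = f"{a:g}"
        wide[f"{layout.ec_prefix}{suffix}"] = (
            wide[layout.gene_column].map(sub["ec"]).fillna(NO_EC)
        )
        wide[f"{layout.score_prefix}{suffix}"] = (
            wide[layout.gene_column].map(sub["score"]).fillna(0.0)
        )
    wide.to_excel(path, index=False)


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration (YAML-loadable)."""

    alpha_grid: Tuple[float, ...] = DEFAULT_ALPHA_GRID
    thresholds: Tuple[float, ...] = DEFAULT_THRESHOLDS
    precision_target: float = 1.0
    npv_target: float = 1.0
    sampling_fraction: float = 0.05
    bin_width: float = 0.1
    initial_alpha: float = 0.5
    seed: int = 0
    wrong_below: str = IR

    def __post_init__(self) -> None:
        self.alpha_grid = tuple(float(a) for a in self.alpha_grid)
        self.thresholds = tuple(float(t) for t in self.thresholds)
        for name in ("alpha_grid", "thresholds"):
            vals = getattr(self, name)
            if list(vals) != sorted(set(vals)):
                raise ValidationError(f"{name} must be sorted and unique")
        for name in ("precision_target", "npv_target"):
            v = getattr(self, name)
            if not 0.75 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0.75, 1.0]")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)
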