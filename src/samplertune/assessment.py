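"""Confusion-matrix grids: standard of truth vs per-α annotations.

Each curated sample gene is compared with its automatic annotation at
every α and classified at every score threshold t into one of four cells:

* **CA** — correct annotation, accepted (score ≥ t),
* **IA** — incorrect annotation, accepted,
* **IR** — incorrect rejection (a correct annotation below t; by default
  also a wrong annotation below t),
* **CR** — correct rejection (a "not an enzyme" gene whose proposal falls
  below t).

Acceptance is at score ≥ t (equality accepted).  The published
classification scheme is ambiguous for a *wrong* EC proposal below the
threshold: the flow-chart reading files it under IR (the gene is enzymatic
and went unannotated), while the worked-example reading files it under CR
(a wrong proposal was suppressed).  ``wrong_below`` selects the reading;
the default is the flow-chart reading (``"IR"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .ec import NO_EC, NOT_ENZYME, NotEnzyme, TruthLabel, parse_truth_label

__all__ = [
    "CA",
    "IA",
    "IR",
    "CR",
    "ConfusionMatrix",
    "ConfusionMatrixGrid",
    "DEFAULT_THRESHOLDS",
    "classify_entry",
    "confusion_matrix",
    "build_grid",
    "truth_from_frame",
]

CA, IA, IR, CR = "CA", "IA", "IR", "CR"

#: Score thresholds 0.0–1.0 in steps of 0.1 (the score range is [0, 1]).
DEFAULT_THRESHOLDS: Tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))

_WRONG_BELOW_CHOICES = (IR, CR)


@dataclass(frozen=True)
class ConfusionMatrix:
    ca: int = 0
    ia: int = 0
    ir: int = 0
    cr: int = 0

    def __post_init__(self) -> None:
        if min(self.ca, self.ia, self.ir, self.cr) < 0:
            raise ValueError("negative confusion-matrix count")

    @property
    def total(self) -> int:
        return self.ca + self.ia + self.ir + self.cr

    def as_dict(self) -> Dict[str, int]:
        return {CA: self.ca, IA: self.ia, IR: self.ir, CR: self.cr}

    def __str__(self) -> str:
        return f"{self.ca}/{self.ia}/{self.ir}/{self.cr}"


def _proposal_correct(manual: TruthLabel, auto_ec: str) -> bool:
    """A proposal is correct if its EC is among the curated ECs, or if it
    proposes nothing for a gene curated as not an enzyme."""
    if isinstance(manual, NotEnzyme):
        return auto_ec == NO_EC
    return auto_ec in manual


def classify_entry(
    manual: TruthLabel,
    auto_ec: str,
    score: float,
    t: float,
    wrong_below: str = IR,
) -> str:
    """Classify one (curated label, proposal, threshold) triple.

    Accept region is score ≥ t.  Correct & accepted → CA; correct &
    rejected → IR; incorrect & accepted → IA; incorrect & rejected → CR
    when the gene is curated as not an enzyme, otherwise ``wrong_below``
    (IR by default, CR under the alternative reading).
    """
    if wrong_below not in _WRONG_BELOW_CHOICES:
        raise ValueError(f"wrong_below must be one of {_WRONG_BELOW_CHOICES}")
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score={score} outside [0, 1]")
    if not isinstance(manual, NotEnzyme) and (not manual or NO_EC in manual):
        raise ValueError("curated EC set must be non-empty valid ECs or NOT_ENZYME")
    accepted = score >= t
    correct = _proposal_correct(manual, auto_ec)
    if correct:
        return CA if accepted else IR
    if accepted:
        return IA
    return CR if isinstance(manual, NotEnzyme) else wrong_below


def truth_from_frame(frame: pd.DataFrame) -> Dict[str, TruthLabel]:
    """Parse a standard-of-truth DataFrame (``gene_id, curated_ec``)."""
    labels: Dict[str, TruthLabel] = {}
    for row in frame.itertuples(index=False):
        gid = str(row.gene_id)
        if gid in labels:
            raise ValueError(f"duplicate gene in standard of truth: {gid}")
        raw = row.curated_ec
        labels[gid] = raw if isinstance(raw, (NotEnzyme, frozenset)) else parse_truth_label(str(raw))
    if not labels:
        raise ValueError("empty standard of truth")
    return labels


def _annotations_at_alpha(annotations: pd.DataFrame, alpha: float) -> Dict[str, Tuple[str, float]]:
    sub = annotations[annotations["alpha"].astype(float).round(9) == round(float(alpha), 9)]
    return {
        str(r.gene_id): (str(r.ec), float(r.score)) for r in sub.itertuples(index=False)
    }


def confusion_matrix(
    truth: Mapping[str, TruthLabel] | pd.DataFrame,
    annotations: Mapping[str, Tuple[str, float]],
    t: float,
    wrong_below: str = IR,
) -> ConfusionMatrix:
    """Tally classify_entry over every gene of the standard of truth.

    ``annotations`` maps gene_id → (proposed ec, score) at one α.  A truth
    gene without an annotation is an error (the α grid must cover the
    sample).
    """
    if isinstance(truth, pd.DataFrame):
        truth = truth_from_frame(truth)
    if not truth:
        raise ValueError("empty standard of truth")
    counts = {CA: 0, IA: 0, IR: 0, CR: 0}
    for gene_id, manual in truth.items():
        if gene_id not in annotations:
            raise KeyError(f"no automatic annotation for sample gene {gene_id!r}")
        ec, score = annotations[gene_id]
        counts[classify_entry(manual, ec, score, t, wrong_below)] += 1
    return ConfusionMatrix(counts[CA], counts[IA], counts[IR], counts[CR])


@dataclass(frozen=True)
class ConfusionMatrixGrid:
    """One confusion matrix per (threshold, α) pair."""

    thresholds: Tuple[float, ...]
    alphas: Tuple[float, ...]
    cells: Mapping[Tuple[float, float], ConfusionMatrix]

    def cell(self, t: float, alpha: float) -> ConfusionMatrix:
        return self.cells[(round(float(t), 9), round(float(alpha), 9))]

    def column(self, alpha: float) -> List[ConfusionMatrix]:
        return [self.cell(t, alpha) for t in self.thresholds]

    @property
    def sample_size(self) -> int:
        return next(iter(self.cells.values())).total

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: threshold rows, α columns, 'CA/IA/IR/CR' cells."""
        data = {
            f"alpha={a:g}": [str(self.cell(t, a)) for t in self.thresholds]
            for a in self.alphas
        }
        return pd.DataFrame(data, index=pd.Index(self.thresholds, name="t"))


def build_grid(
    truth: Mapping[str, TruthLabel] | pd.DataFrame,
    annotation_table: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    wrong_below: str = IR,
) -> ConfusionMatrixGrid:
    """Confusion matrix for every (t, α) pair of the assessment array."""
    if isinstance(truth, pd.DataFrame):
        truth = truth_from_frame(truth)
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise ValueError("empty threshold list")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    alphas = sorted(annotation_table["alpha"].astype(float).unique())
    if not alphas:
        raise ValueError("annotation table holds no alpha values")
    cells: Dict[Tuple[float, float], ConfusionMatrix] = {}
    for a in alphas:
        ann = _annotations_at_alpha(annotation_table, a)
        for t in thresholds:
            cells[(round(t, 9), round(a, 9))] = confusion_matrix(truth, ann, t, wrong_below)
    return ConfusionMatrixGrid(tuple(thresholds), tuple(alphas), cells)
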