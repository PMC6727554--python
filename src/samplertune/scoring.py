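"""α-weighted enzyme-annotation scorer.

For each gene, homology hits (BLAST/HMMER-style) carry an optional EC
number and the taxonomic lineage of the source organism.  Every candidate
EC among a gene's hits receives

* a **frequency score** — the fraction of the gene's EC-bearing hits that
  carry the candidate EC, and
* a **taxonomy score** — the mean, over hits carrying the candidate EC, of
  the root-anchored lineage-prefix overlap with the query organism,
  normalised by the query lineage depth,

combined as ``alpha * freq + (1 - alpha) * tax``.  The gene is annotated
with the highest-scoring EC; genes with no EC-bearing hit are "potentially
non-metabolic" and annotated ``none`` with score 0.

This scorer follows the published contract of merlin-style frequency +
taxonomy annotation (scores in [0, 1], trade-off weight α) with the two
component scores defined explicitly as above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ec import NO_EC, is_valid_ec

__all__ = [
    "HomologyHit",
    "CandidateScore",
    "AutoAnnotation",
    "NonMetabolicGene",
    "DEFAULT_ALPHA_GRID",
    "shared_prefix_depth",
    "frequency_score",
    "taxonomy_score",
    "combined_score",
    "score_candidates",
    "annotate_gene",
    "annotate_genome",
    "hits_from_frame",
    "potentially_metabolic_ids",
]

#: Nine α values 0.1–0.9; the extremes 0.0 and 1.0 are excluded by default
#: because either would silence one score component entirely.
DEFAULT_ALPHA_GRID: Tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))


class NonMetabolicGene(ValueError):
    """Raised when an operation requires EC-bearing hits and none exist."""


@dataclass(frozen=True)
class HomologyHit:
    """One homology hit for a query gene.

    ``lineage`` is ordered root → leaf (e.g. superkingdom … species) and
    must be non-empty; ``ec`` is ``None`` for hits without an EC label.
    """

    gene_id: str
    hit_id: str
    ec: Optional[str]
    lineage: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.lineage) == 0:
            raise ValueError(f"hit {self.hit_id}: empty lineage")
        if self.ec is not None and not is_valid_ec(self.ec):
            raise ValueError(f"hit {self.hit_id}: malformed EC {self.ec!r}")


@dataclass(frozen=True)
class CandidateScore:
    ec: str
    freq: float
    tax: float
    combined: float


@dataclass(frozen=True)
class AutoAnnotation:
    """Proposed annotation of one gene at one α."""

    gene_id: str
    alpha: float
    ec: str  # an EC number, or NO_EC
    score: float


def shared_prefix_depth(a: Sequence[str], b: Sequence[str]) -> int:
    """Length of the common root-anchored prefix of two lineages."""
    depth = 0
    for x, y in zip(a, b):
        if x != y:
            break
        depth += 1
    return depth


def _ec_hits(hits: Iterable[HomologyHit]) -> List[HomologyHit]:
    return [h for h in hits if h.ec is not None]


def frequency_score(hits: Sequence[HomologyHit], ec: str) -> float:
    """Cardinality of ``ec`` among the gene's EC-bearing hits.

    Raises :class:`NonMetabolicGene` when no hit carries any EC number —
    such a gene has no evidence of being enzymatic.
    """
    labelled = _ec_hits(hits)
    if not labelled:
        raise NonMetabolicGene("no EC-bearing hits: potentially non-metabolic gene")
    return sum(h.ec == ec for h in labelled) / len(labelled)


def taxonomy_score(
    query_lineage: Sequence[str], hits: Sequence[HomologyHit], ec: str
) -> float:
    """Mean normalised lineage overlap of the hits carrying ``ec``.

    Each hit contributes shared_prefix_depth(query, hit) / len(query);
    identical lineages score 1, lineages sharing no taxon score 0.
    """
    if len(query_lineage) == 0:
        raise ValueError("empty query lineage")
    carriers = [h for h in hits if h.ec == ec]
    if not carriers:
        raise ValueError(f"no hit labelled {ec!r}")
    depth = len(query_lineage)
    return float(
        np.mean([shared_prefix_depth(query_lineage, h.lineage) / depth for h in carriers])
    )


def combined_score(freq: float, tax: float, alpha: float) -> float:
    """``alpha * freq + (1 - alpha) * tax``; all arguments in [0, 1]."""
    for name, v in (("freq", freq), ("tax", tax), ("alpha", alpha)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return alpha * freq + (1.0 - alpha) * tax


def score_candidates(
    hits: Sequence[HomologyHit], query_lineage: Sequence[str], alpha: float
) -> List[CandidateScore]:
    """Score every distinct candidate EC among a gene's hits."""
    out = []
    for ec in sorted({h.ec for h in _ec_hits(hits)}):
        f = frequency_score(hits, ec)
        t = taxonomy_score(query_lineage, hits, ec)
        out.append(CandidateScore(ec, f, t, combined_score(f, t, alpha)))
    return out


def annotate_gene(
    hits: Sequence[HomologyHit], query_lineage: Sequence[str], alpha: float
) -> AutoAnnotation:
    """Pick the candidate EC with the maximal combined score.

    Ties break to the lexicographically smallest EC string.  A gene whose
    hits carry no EC (or with no hits at all) is annotated ``none`` with
    score 0 rather than dropped, so downstream sampling can still expose
    it.
    """
    gene_id = hits[0].gene_id if hits else ""
    if any(h.gene_id != gene_id for h in hits):
        raise ValueError("hits span multiple gene_ids")
    candidates = score_candidates(hits, query_lineage, alpha) if _ec_hits(hits) else []
    if not candidates:
        return AutoAnnotation(gene_id, alpha, NO_EC, 0.0)
    # max on (score, reversed-lex) implemented as min on (-score, ec)
    best = min(candidates, key=lambda c: (-c.combined, c.ec))
    return AutoAnnotation(gene_id, alpha, best.ec, best.combined)


def hits_from_frame(frame: pd.DataFrame) -> Dict[str, List[HomologyHit]]:
    """Group a hit-table DataFrame into per-gene :class:`HomologyHit` lists.

    Expects columns ``gene_id, hit_id, ec, lineage`` with lineage either a
    semicolon-separated string (root→leaf) or a sequence of taxon names,
    and ec empty/NaN for unlabelled hits.
    """
    by_gene: Dict[str, List[HomologyHit]] = {}
    for row in frame.itertuples(index=False):
        ec = getattr(row, "ec")
        if ec is None or (isinstance(ec, float) and np.isnan(ec)) or ec == "":
            ec = None
        lineage = getattr(row, "lineage")
        if isinstance(lineage, str):
            lineage = tuple(part.strip() for part in lineage.split(";") if part.strip())
        else:
            lineage = tuple(lineage)
        hit = HomologyHit(str(row.gene_id), str(row.hit_id), ec, lineage)
        by_gene.setdefault(hit.gene_id, []).append(hit)
    return by_gene


def potentially_metabolic_ids(frame: pd.DataFrame) -> List[str]:
    """Genes with at least one EC-bearing hit, in first-seen order."""
    labelled = frame[frame["ec"].notna() & (frame["ec"] != "")]
    return list(dict.fromkeys(labelled["gene_id"].astype(str)))


def annotate_genome(
    hit_table: pd.DataFrame,
    query_lineage: Sequence[str],
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    *,
    allow_extreme_alpha: bool = False,
) -> pd.DataFrame:
    """Annotate every gene at every α of the grid.

    Returns a DataFrame with columns ``gene_id, alpha, ec, score`` (one row
    per gene × α).  Genes without EC-bearing hits appear with ec ``none``
    and score 0 (flagged non-metabolic; they do not count as potentially
    metabolic).  By default α must lie strictly inside (0, 1): either
    extreme erases one score component and should only be used
    deliberately (``allow_extreme_alpha=True``).
    """
    alphas = [float(a) for a in alpha_grid]
    if not alphas:
        raise ValueError("empty alpha grid")
    for a in alphas:
        lo_ok = 0.0 < a < 1.0 or (allow_extreme_alpha and 0.0 <= a <= 1.0)
        if not lo_ok:
            raise ValueError(
                f"alpha={a} outside (0, 1); pass allow_extreme_alpha=True to permit 0 or 1"
            )
    if hit_table.empty:
        warnings.warn("empty hit table: no annotations produced", stacklevel=2)
        return pd.DataFrame(columns=["gene_id", "alpha", "ec", "score"])

    rows = []
    for gene_id, hits in hits_from_frame(hit_table).items():
        if not _ec_hits(hits):
            for a in alphas:
                rows.append((gene_id, a, NO_EC, 0.0))
            continue
        # freq/tax per candidate EC are α-independent: compute once.
        per_ec = []
        for ec in sorted({h.ec for h in _ec_hits(hits)}):
            per_ec.append(
                (ec, frequency_score(hits, ec), taxonomy_score(query_lineage, hits, ec))
            )
        for a in alphas:
            best = min(
                ((ec, combined_score(f, t, a)) for ec, f, t in per_ec),
                key=lambda item: (-item[1], item[0]),
            )
            rows.append((gene_id, a, best[0], best[1]))
    return pd.DataFrame(rows, columns=["gene_id", "alpha", "ec", "score"])
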