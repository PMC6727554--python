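"""Score-stratified random sampling of genes for manual curation.

The curator's standard of truth is built from a random sample of 5–10% of
the potentially metabolic genes, drawn so that every occupied score
interval is represented and the intervals contribute near-equal numbers of
genes.  Stratification uses the annotation scores at one reference α (the
"initial sensible value" the annotation run started from).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .ec import NO_EC

__all__ = ["SamplePlan", "stratified_sample", "score_bin"]

DEFAULT_FRACTION = 0.05
DEFAULT_BIN_WIDTH = 0.1
DEFAULT_INITIAL_ALPHA = 0.5


@dataclass(frozen=True)
class SamplePlan:
    """A realised curation sample.

    ``sample_ids`` are the selected gene identifiers; ``bin_counts`` maps
    each score-bin index to the number of genes drawn from it.
    """

    fraction: float
    bin_width: float
    seed: int
    alpha: float
    sample_ids: Tuple[str, ...]
    bin_counts: Dict[int, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.sample_ids)


def score_bin(score: float, bin_width: float) -> int:
    """Index of the score interval [k·w, (k+1)·w); the top bin is closed."""
    n_bins = int(round(1.0 / bin_width))
    return min(int(score / bin_width), n_bins - 1)


def _allocate(target: int, occupancy: Dict[int, int]) -> Dict[int, int]:
    """Split ``target`` as evenly as possible across occupied bins.

    Even base quota with the remainder handed round-robin in bin order;
    quotas are capped at bin occupancy and any deficit is re-assigned to
    the bins with the most remaining capacity (ties to the lower bin).
    """
    bins = sorted(occupancy)
    k = len(bins)
    base, rem = divmod(target, k)
    quota = {b: base + (1 if i < rem else 0) for i, b in enumerate(bins)}
    # cap at occupancy, redistribute the deficit to the fullest bins
    deficit = 0
    for b in bins:
        if quota[b] > occupancy[b]:
            deficit += quota[b] - occupancy[b]
            quota[b] = occupancy[b]
    while deficit > 0:
        spare = [(occupancy[b] - quota[b], b) for b in bins if occupancy[b] > quota[b]]
        if not spare:
            break  # target exceeds population; caller guards against this
        _, b = max(spare, key=lambda item: (item[0], -item[1]))
        quota[b] += 1
        deficit -= 1
    return quota


def stratified_sample(
    annotations: pd.DataFrame,
    fraction: float = DEFAULT_FRACTION,
    bin_width: float = DEFAULT_BIN_WIDTH,
    seed: int = 0,
    alpha: float | None = None,
) -> SamplePlan:
    """Draw the curation sample, stratified by annotation score.

    ``annotations`` is an α-annotation table (``gene_id, alpha, ec,
    score``); rows at the reference α (the single α present, unless
    ``alpha`` is given) are used.  Genes annotated ``none`` (no EC-bearing
    hit) are not potentially metabolic and are excluded.  Selection within
    a bin is uniform without replacement under ``seed``.

    If the target sample is smaller than the number of occupied bins a
    warning is issued and one gene per bin is taken (fullest bins first)
    up to the budget.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction={fraction} outside (0, 1]")
    if not 0.0 < bin_width <= 1.0 or round(1.0 / bin_width) != 1.0 / bin_width:
        raise ValueError(f"bin_width={bin_width} must divide 1 evenly")

    sub = annotations
    if alpha is not None:
        sub = sub[np.isclose(sub["alpha"].astype(float), alpha)]
        if sub.empty:
            raise ValueError(f"no annotations at alpha={alpha}")
    else:
        alphas = sub["alpha"].unique()
        if len(alphas) != 1:
            raise ValueError(
                "annotation table holds several alphas; pass the reference alpha"
            )
        alpha = float(alphas[0])
    sub = sub[sub["ec"] != NO_EC]
    if sub.empty:
        raise ValueError("no potentially metabolic genes to sample")

    genes = sub["gene_id"].astype(str).tolist()
    scores = sub["score"].astype(float).tolist()
    n = len(genes)
    target = max(1, round(fraction * n))

    members: Dict[int, List[str]] = {}
    for g, s in sorted(zip(genes, scores)):
        members.setdefault(score_bin(s, bin_width), []).append(g)
    occupancy = {b: len(v) for b, v in members.items()}

    if target < len(occupancy):
        warnings.warn(
            f"sample target {target} smaller than the {len(occupancy)} occupied "
            "score bins; taking one gene per bin up to budget",
            stacklevel=2,
        )
        ordered = sorted(occupancy, key=lambda b: (-occupancy[b], b))[:target]
        quota = {b: 1 for b in ordered}
    else:
        quota = _allocate(min(target, n), occupancy)

    rng = np.random.default_rng(seed)
    chosen: List[str] = []
    bin_counts: Dict[int, int] = {}
    for b in sorted(quota):
        q = quota[b]
        if q == 0:
            continue
        pool = members[b]
        picks = rng.choice(len(pool), size=q, replace=False)
        chosen.extend(pool[i] for i in sorted(picks))
        bin_counts[b] = q
    return SamplePlan(fraction, bin_width, seed, alpha, tuple(chosen), bin_counts)
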