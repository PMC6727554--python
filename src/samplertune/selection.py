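"""Metrics, threshold selection and the α recommendation.

From the confusion-matrix grid, each α column yields

* ``accuracy = (CA + CR) / x1`` per threshold row, and its column mean,
* ``precision = CA / (CA + IA)`` — how often accepted annotations are
  correct — undefined (vacuous) when nothing is accepted,
* ``NPV = CR / (CR + IR)`` — how often rejections are correct — vacuous
  when nothing is rejected.

The upper threshold is the lowest t whose precision reaches the precision
target (annotations scoring ≥ t are auto-accepted); the lower threshold is
the highest t whose NPV reaches the NPV target (scores < t are
auto-rejected).  Genes scoring in between are queued for manual curation.
Targets may be relaxed from 1.0 down to 0.75 to trade accepted error for
curation effort.  The recommended α maximises the curation ratio score

    curation_ratio = mean accuracy / (fraction of potentially metabolic
                                      genes left to curate)

with the curation fraction counted on the *full-genome* annotation at the
candidate α, not on the sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assessment import ConfusionMatrix, ConfusionMatrixGrid
from .ec import NO_EC

__all__ = [
    "VACUOUS",
    "accuracy",
    "precision",
    "npv",
    "mean_accuracy",
    "ThresholdChoice",
    "select_thresholds",
    "curation_ratio",
    "Recommendation",
    "recommend",
    "rank_alpha_candidates",
    "DEFAULT_RELAXATION_GRID",
]

#: Sentinel for a metric whose denominator is zero (nothing accepted /
#: nothing rejected); it satisfies any target.
VACUOUS = None

#: Conventional relaxation ladder for precision/NPV targets.
DEFAULT_RELAXATION_GRID: Tuple[float, ...] = (1.00, 0.95, 0.85, 0.75)

MIN_TARGET = 0.75


def accuracy(cm: ConfusionMatrix) -> float:
    """(CA + CR) / (CA + CR + IA + IR)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.ca + cm.cr) / cm.total


def precision(cm: ConfusionMatrix) -> Optional[float]:
    """CA / (CA + IA); VACUOUS (None) when nothing is accepted."""
    denom = cm.ca + cm.ia
    return VACUOUS if denom == 0 else cm.ca / denom


def npv(cm: ConfusionMatrix) -> Optional[float]:
    """CR / (CR + IR); VACUOUS (None) when nothing is rejected."""
    denom = cm.cr + cm.ir
    return VACUOUS if denom == 0 else cm.cr / denom


def mean_accuracy(column: Sequence[ConfusionMatrix]) -> float:
    """Arithmetic mean of accuracy over all threshold rows of one α."""
    if not column:
        raise ValueError("empty grid column")
    return float(np.mean([accuracy(cm) for cm in column]))


def _satisfies(metric: Optional[float], target: float) -> bool:
    return metric is VACUOUS or metric >= target


def _check_target(name: str, value: float) -> None:
    if not MIN_TARGET <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [{MIN_TARGET}, 1.0]")


@dataclass(frozen=True)
class ThresholdChoice:
    """Upper/lower thresholds for one α column.

    ``upper_reachable`` / ``lower_reachable`` record whether any row met
    the target; an unreachable precision target yields an accept-nothing
    upper threshold (max t + step) and an unreachable NPV target a
    reject-nothing lower threshold (0).  ``crossed`` flags t_L > t_U; the
    pair is reported as-is, never silently reordered.
    """

    upper: float
    lower: float
    upper_reachable: bool = True
    lower_reachable: bool = True

    @property
    def crossed(self) -> bool:
        return self.lower > self.upper


def select_thresholds(
    thresholds: Sequence[float],
    column: Sequence[ConfusionMatrix],
    precision_target: float = 1.0,
    npv_target: float = 1.0,
) -> ThresholdChoice:
    """Pick (t_upper, t_lower) for one α column at the given targets."""
    _check_target("precision_target", precision_target)
    _check_target("npv_target", npv_target)
    if len(thresholds) != len(column) or not column:
        raise ValueError("thresholds and grid column must align and be non-empty")
    ts = [float(t) for t in thresholds]
    step = ts[1] - ts[0] if len(ts) > 1 else 0.1

    upper_ok = [t for t, cm in zip(ts, column) if _satisfies(precision(cm), precision_target)]
    lower_ok = [t for t, cm in zip(ts, column) if _satisfies(npv(cm), npv_target)]
    if upper_ok:
        t_u, u_reach = min(upper_ok), True
    else:
        t_u, u_reach = ts[-1] + step, False  # accept nothing
    if lower_ok:
        t_l, l_reach = max(lower_ok), True
    else:
        t_l, l_reach = 0.0, False  # reject nothing
    return ThresholdChoice(round(t_u, 9), round(t_l, 9), u_reach, l_reach)


def curation_ratio(mean_acc: float, n_curate: int, n_potentially_metabolic: int) -> float:
    """Mean accuracy divided by the fraction of genes left to curate.

    An empty curation band ranks best: +inf.
    """
    if n_potentially_metabolic <= 0:
        raise ValueError("n_potentially_metabolic must be positive")
    if n_curate == 0:
        return math.inf
    return mean_acc / (n_curate / n_potentially_metabolic)


@dataclass(frozen=True)
class Recommendation:
    alpha: float
    upper_threshold: float
    lower_threshold: float
    precision_target: float
    npv_target: float
    n_accepted: int
    n_rejected: int
    n_curate: int
    n_potentially_metabolic: int
    mean_accuracy: float
    curation_ratio: float
    thresholds_crossed: bool = False
    upper_reachable: bool = True
    lower_reachable: bool = True

    def __post_init__(self) -> None:
        if self.n_accepted + self.n_rejected + self.n_curate != self.n_potentially_metabolic:
            raise ValueError("accepted + rejected + curate must equal potentially metabolic")

    def to_dict(self) -> Dict[str, object]:
        d = dict(self.__dict__)
        if math.isinf(d["curation_ratio"]):
            d["curation_ratio"] = "inf"
        return d


def _band_counts(
    annotations: pd.DataFrame, alpha: float, choice: ThresholdChoice
) -> Tuple[int, int, int, int]:
    """(accepted, rejected, curate, potentially_metabolic) on the full genome."""
    sub = annotations[annotations["alpha"].astype(float).round(9) == round(float(alpha), 9)]
    sub = sub[sub["ec"] != NO_EC]
    scores = sub["score"].astype(float).to_numpy()
    n_pot = len(scores)
    n_acc = int((scores >= choice.upper).sum())
    # crossed thresholds (lower > upper): acceptance takes precedence in the
    # overlap, the curation band is empty, and the pair stays flagged
    n_rej = int((scores < min(choice.lower, choice.upper)).sum())
    n_cur = n_pot - n_acc - n_rej
    return n_acc, n_rej, n_cur, n_pot


def _rank_key(ratio: float, mean_acc: float, alpha: float):
    # maximise ratio, then mean accuracy, then prefer the LOWER α
    return (ratio, mean_acc, -alpha)


def recommend(
    grid: ConfusionMatrixGrid,
    annotations: pd.DataFrame,
    precision_target: float = 1.0,
    npv_target: float = 1.0,
) -> Tuple[Recommendation, pd.DataFrame]:
    """Choose α and thresholds that minimise curation at the error targets.

    ``annotations`` is the full-genome α-annotation table (same α grid as
    the confusion-matrix grid).  Returns the winning
    :class:`Recommendation` plus the per-α report table (one row per α:
    mean accuracy, thresholds, accepted/rejected/curate counts, curation
    fraction and ratio, selected flag).
    """
    if not grid.cells:
        raise ValueError("empty confusion-matrix grid")
    ann_alphas = set(np.round(annotations["alpha"].astype(float).unique(), 9))
    rows = []
    for a in grid.alphas:
        if round(a, 9) not in ann_alphas:
            raise ValueError(f"genome annotations missing alpha={a:g}")
        column = grid.column(a)
        m_acc = mean_accuracy(column)
        choice = select_thresholds(grid.thresholds, column, precision_target, npv_target)
        n_acc, n_rej, n_cur, n_pot = _band_counts(annotations, a, choice)
        ratio = curation_ratio(m_acc, n_cur, n_pot)
        rows.append(
            {
                "alpha": a,
                "mean_accuracy": m_acc,
                "upper_threshold": choice.upper,
                "lower_threshold": choice.lower,
                "n_accepted": n_acc,
                "n_rejected": n_rej,
                "n_curate": n_cur,
                "pct_curation": 100.0 * n_cur / n_pot,
                "curation_ratio": ratio,
                "crossed": choice.crossed,
                "upper_reachable": choice.upper_reachable,
                "lower_reachable": choice.lower_reachable,
            }
        )
    report = pd.DataFrame(rows)
    best_idx = max(
        range(len(rows)),
        key=lambda i: _rank_key(
            rows[i]["curation_ratio"], rows[i]["mean_accuracy"], rows[i]["alpha"]
        ),
    )
    report["selected"] = [i == best_idx for i in range(len(rows))]
    b = rows[best_idx]
    rec = Recommendation(
        alpha=b["alpha"],
        upper_threshold=b["upper_threshold"],
        lower_threshold=b["lower_threshold"],
        precision_target=precision_target,
        npv_target=npv_target,
        n_accepted=b["n_accepted"],
        n_rejected=b["n_rejected"],
        n_curate=b["n_curate"],
        n_potentially_metabolic=b["n_accepted"] + b["n_rejected"] + b["n_curate"],
        mean_accuracy=b["mean_accuracy"],
        curation_ratio=b["curation_ratio"],
        thresholds_crossed=b["crossed"],
        upper_reachable=b["upper_reachable"],
        lower_reachable=b["lower_reachable"],
    )
    return rec, report


def rank_alpha_candidates(
    candidates: Mapping[float, Tuple[float, float]],
) -> Tuple[float, Dict[float, float]]:
    """Rank α candidates given per-α (mean accuracy, curation fraction).

    Useful when only per-α summaries are available (e.g. a published
    report table) rather than the full grid.  Curation fractions are in
    (0, 1]; returns (winning α, α → curation ratio) under the same
    ranking rule as :func:`recommend`.
    """
    if not candidates:
        raise ValueError("no candidates")
    ratios: Dict[float, float] = {}
    for a, (m_acc, frac) in candidates.items():
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"curation fraction {frac} outside (0, 1]")
        ratios[a] = m_acc / frac
    best = max(candidates, key=lambda a: _rank_key(ratios[a], candidates[a][0], a))
    return best, ratios
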