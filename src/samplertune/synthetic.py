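"""Synthetic homology-hit benchmarks with controllable signal structure.

Real annotation projects differ in two ways that matter to the α
trade-off: how many taxonomically close, well-characterised organisms the
search database holds (taxonomy signal) and how concentrated the correct
EC is among the hits (frequency signal).  The generator emulates exactly
these: every enzymatic gene has a true EC, hits carry the true EC, a wrong
EC or no EC at configurable rates, and each hit's lineage shares a
root-anchored prefix of controllable depth with the query organism.

Because the scorer's taxonomy component is defined on shared-prefix depth,
the proximity knobs act directly on the taxonomy score: coupling correct
hits to deep prefixes (``taxonomy_informativeness`` → 1) makes taxonomy
diagnostic; concentrating wrong ECs on a per-gene confounder
(``frequency_informativeness`` → 0) makes frequency misleading.

The generator emits hit tables only — no sequences: the tuning procedure
never touches raw sequence data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ec import NOT_ENZYME_LITERAL

__all__ = ["SimulationConfig", "generate_dataset", "make_taxa_scenarios"]


def _default_profile() -> Tuple[float, ...]:
    # mildly favours intermediate relatedness
    return (0.05, 0.10, 0.15, 0.20, 0.20, 0.15, 0.10, 0.05)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic benchmark.

    ``proximity_profile`` is the base distribution over shared-prefix
    depths 0..lineage_depth (length lineage_depth + 1).
    ``misannotation_rate`` is the probability that an enzymatic gene's hit
    carries a wrong EC; ``no_ec_rate`` the probability it carries none;
    the rest carry the true EC.  ``taxonomy_informativeness`` couples
    correct hits to deep shared prefixes (and wrong hits to shallow ones);
    ``frequency_informativeness`` scatters wrong ECs across the pool
    (1.0) instead of concentrating them on a per-gene confounder (0.0).
    ``nonenzyme_decoy_rate`` is the fraction of non-enzymatic genes that
    still receive wrong-EC hits (and thus look potentially metabolic).
    """

    n_genes: int = 500
    frac_enzymatic: float = 0.55
    hits_per_gene: Tuple[int, int] = (3, 15)
    misannotation_rate: float = 0.2
    no_ec_rate: float = 0.1
    lineage_depth: int = 7
    proximity_profile: Tuple[float, ...] = field(default_factory=_default_profile)
    frequency_informativeness: float = 1.0
    taxonomy_informativeness: float = 0.5
    nonenzyme_decoy_rate: float = 0.35
    n_ec_pool: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.lineage_depth <= 0 or self.n_ec_pool < 2:
            raise ValueError("counts must be positive (and EC pool >= 2)")
        for name in (
            "frac_enzymatic",
            "misannotation_rate",
            "no_ec_rate",
            "frequency_informativeness",
            "taxonomy_informativeness",
            "nonenzyme_decoy_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.misannotation_rate + self.no_ec_rate > 1.0:
            raise ValueError("misannotation_rate + no_ec_rate exceeds 1")
        lo, hi = self.hits_per_gene
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid hits_per_gene range {self.hits_per_gene}")
        if self.frac_enzymatic > 0 and hi < 1:
            raise ValueError("enzymatic genes require at least one hit")
        prof = np.asarray(self.proximity_profile, dtype=float)
        if len(prof) != self.lineage_depth + 1 or prof.min() < 0 or prof.sum() <= 0:
            raise ValueError(
                "proximity_profile must be non-negative weights of length lineage_depth + 1"
            )


_LEVELS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
    "isolate",
    "clade",
)


def _query_lineage(depth: int) -> Tuple[str, ...]:
    return tuple(f"{_LEVELS[i % len(_LEVELS)]}_qry{i}" for i in range(depth))


def _ec_pool(n: int) -> List[str]:
    pool = []
    i = 0
    while len(pool) < n:
        a, rest = i % 6 + 1, i // 6
        b, rest = rest % 9 + 1, rest // 9
        c, d = rest % 9 + 1, rest // 81 + 1
        pool.append(f"{a}.{b}.{c}.{d}")
        i += 1
    return pool


def _profiles(cfg: SimulationConfig):
    depth = cfg.lineage_depth
    base = np.asarray(cfg.proximity_profile, dtype=float)
    base = base / base.sum()
    close = np.zeros(depth + 1)
    close[max(0, depth - 2) : depth + 1] = (0.2, 0.4, 0.4)[-min(3, depth + 1) :]
    close /= close.sum()
    far = np.zeros(depth + 1)
    far[: min(3, depth + 1)] = (0.5, 0.3, 0.2)[: min(3, depth + 1)]
    far /= far.sum()
    t = cfg.taxonomy_informativeness
    return t * close + (1 - t) * base, t * far + (1 - t) * base


def generate_dataset(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, Tuple[str, ...]]:
    """Generate (hit table, standard of truth for all genes, query lineage).

    Reproducible: identical config (incl. seed) gives identical tables.
    Truth labels are the intended EC for enzymatic genes and the
    "not an enzyme" literal otherwise.  Non-enzymatic genes either carry
    only EC-less hits (not potentially metabolic) or, for the decoy
    fraction, only misannotated hits.
    """
    rng = np.random.default_rng(config.seed)
    depth = config.lineage_depth
    query = _query_lineage(depth)
    pool = _ec_pool(config.n_ec_pool)
    correct_profile, wrong_profile = _profiles(config)
    depths = np.arange(depth + 1)
    lo, hi = config.hits_per_gene
    p_wrong, p_noec = config.misannotation_rate, config.no_ec_rate

    def lineage_at(d: int) -> str:
        if d >= depth:
            return ";".join(query)
        branch = rng.integers(0, 4)
        tail = (f"{_LEVELS[i % len(_LEVELS)]}_alt{branch}n{i}" for i in range(d, depth))
        return ";".join(list(query[:d]) + list(tail))

    def wrong_ec(true_ec: Optional[str], confounder: str) -> str:
        if rng.random() < config.frequency_informativeness:
            ec = pool[rng.integers(0, len(pool))]
            while ec == true_ec:
                ec = pool[rng.integers(0, len(pool))]
            return ec
        return confounder

    hit_rows = []
    truth_rows = []
    width = len(str(config.n_genes))
    for g in range(config.n_genes):
        gene_id = f"g{g:0{width}d}"
        enzymatic = rng.random() < config.frac_enzymatic
        true_ec = pool[rng.integers(0, len(pool))] if enzymatic else None
        confounder = pool[rng.integers(0, len(pool))]
        while confounder == true_ec:
            confounder = pool[rng.integers(0, len(pool))]
        decoy = (not enzymatic) and rng.random() < config.nonenzyme_decoy_rate
        n_hits = int(rng.integers(lo, hi + 1))
        for h in range(n_hits):
            if enzymatic:
                u = rng.random()
                if u < p_wrong:
                    ec = wrong_ec(true_ec, confounder)
                    d = int(rng.choice(depths, p=wrong_profile))
                elif u < p_wrong + p_noec:
                    ec = ""
                    d = int(rng.choice(depths, p=wrong_profile))
                else:
                    ec = true_ec
                    d = int(rng.choice(depths, p=correct_profile))
            elif decoy:
                ec = "" if rng.random() < p_noec else wrong_ec(None, confounder)
                d = int(rng.choice(depths, p=wrong_profile))
            else:
                ec = ""
                d = int(rng.choice(depths, p=wrong_profile))
            hit_rows.append((gene_id, f"{gene_id}_h{h:02d}", ec, lineage_at(d)))
        truth_rows.append((gene_id, true_ec if enzymatic else NOT_ENZYME_LITERAL))

    hits = pd.DataFrame(hit_rows, columns=["gene_id", "hit_id", "ec", "lineage"])
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "curated_ec"])
    return hits, truth, query


def make_taxa_scenarios(
    n_genes: int = 500, seed: int = 0
) -> Tuple[SimulationConfig, SimulationConfig]:
    """Configs for the two archetypal annotation projects.

    *taxa-rich* — many close, well-annotated relatives in the database:
    correct ECs dominate the hit lists (frequency is diagnostic) while
    nearly every organism, right or wrong, is a close relative (taxonomy
    is not).  *taxa-poor* — few close relatives, and those few are the
    reliable records: frequency is noisy (hit lists are short and wrong
    ECs pile on a confounder) while taxonomy separates right from wrong.
    Parameter recovery should favour a high α on the former and a low α on
    the latter.
    """
    rich = SimulationConfig(
        n_genes=n_genes,
        frac_enzymatic=0.55,
        hits_per_gene=(5, 25),
        misannotation_rate=0.20,
        no_ec_rate=0.10,
        proximity_profile=(0.02, 0.02, 0.04, 0.08, 0.14, 0.20, 0.25, 0.25),
        frequency_informativeness=1.0,
        taxonomy_informativeness=0.15,
        nonenzyme_decoy_rate=0.35,
        seed=seed,
    )
    poor = SimulationConfig(
        n_genes=n_genes,
        frac_enzymatic=0.55,
        hits_per_gene=(3, 10),
        misannotation_rate=0.45,
        no_ec_rate=0.05,
        proximity_profile=(0.30, 0.25, 0.20, 0.10, 0.06, 0.04, 0.03, 0.02),
        frequency_informativeness=0.0,
        taxonomy_informativeness=0.90,
        nonenzyme_decoy_rate=0.35,
        seed=seed,
    )
    return rich, poor
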