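import numpy as np
import pandas as pd
import pytest

from samplertune.ec import NOT_ENZYME
from samplertune.scoring import HomologyHit
from samplertune.worked_example import worked_example

QUERY = tuple(f"q{i}" for i in range(7))


def make_hit(gene, hit, ec, shared_depth, query=QUERY, tail="x"):
    """Hit whose lineage shares exactly ``shared_depth`` levels with query."""
    lineage = query[:shared_depth] + tuple(
        f"{tail}{i}" for i in range(shared_depth, len(query))
    )
    return HomologyHit(gene, hit, ec, lineage)


@pytest.fixture(scope="session")
def worked_example_tables():
    return worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_truth_and_annotations(rng, n_genes=50, alphas=(0.2, 0.5, 0.8)):
    """Random sample + annotations for oracle-equivalence checks."""
    ecs = ["1.1.1.1", "2.7.1.1", "3.5.1.2"]
    truth = {}
    rows = []
    for g in range(n_genes):
        gid = f"g{g:02d}"
        kind = rng.integers(0, 3)
        truth[gid] = NOT_ENZYME if kind == 0 else frozenset({ecs[kind]})
        for a in alphas:
            rows.append((gid, a, ecs[rng.integers(0, 3)], round(float(rng.random()), 3)))
    ann = pd.DataFrame(rows, columns=["gene_id", "alpha", "ec", "score"])
    return truth, ann
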