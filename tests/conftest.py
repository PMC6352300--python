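import numpy as np
import pandas as pd
import pytest

from drugsea.genesets import GeneSetDB
from drugsea.ranking import ExpressionCompendium


def brute_force_es(ranked_items, item_set):
    """Literal running-sum oracle in exact rational arithmetic."""
    from fractions import Fraction

    n = len(ranked_items)
    members = set(item_set) & set(ranked_items)
    k = len(members)
    assert 0 < k < n
    running = Fraction(0)
    best = Fraction(0)
    for item in ranked_items:
        running += Fraction(1, k) if item in members else -Fraction(1, n - k)
        if abs(running) > abs(best) or (
            abs(running) == abs(best) and running > best
        ):
            best = running
    return float(best)


def brute_force_bh(p):
    """Textbook step-up BH, written as an explicit loop."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_pos in range(m, 0, -1):
        i = order[rank_pos - 1]
        val = min(prev, p[i] * m / rank_pos)
        adj[i] = val
        prev = val
    return adj


@pytest.fixture
def tiny_compendium():
    """2 drugs x 6 genes, 2 control + 2 treatment samples each, one instance."""
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(6)]
    samples, meta = [], []
    for drug in ["dA", "dB"]:
        for arm, tag in [("control", "c"), ("treatment", "t")]:
            for r in range(2):
                samples.append(f"{drug}_{tag}{r}")
                meta.append((drug, arm, "i0"))
    expr = pd.DataFrame(
        rng.uniform(50, 150, size=(6, len(samples))), index=genes, columns=samples
    )
    samples_df = pd.DataFrame(
        meta, index=pd.Index(samples, name="sample_id"),
        columns=["drug", "arm", "instance"],
    )
    return ExpressionCompendium(expression=expr, samples=samples_df)


@pytest.fixture
def toy_db():
    return GeneSetDB(
        db_name="toy",
        pathways={
            "P1": ("first", frozenset({"g0", "g1"})),
            "P2": ("second", frozenset({"g2", "g3", "g4"})),
            "P3": ("third", frozenset({"g0", "g5"})),
        },
    )
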