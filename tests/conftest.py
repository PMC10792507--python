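"""Shared fixtures: tiny hand-built DEG sets, random fixture generators,
and brute-force set-enumeration oracles used across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from degcompare import DEGListSet, MasterTable


def make_degset(lists: dict[str, set[str]], alpha: float = 0.05) -> DEGListSet:
    return DEGListSet({k: frozenset(v) for k, v in lists.items()}, alpha)


def random_degset(
    rng: np.random.Generator, m: int | None = None, universe: int = 1000
) -> DEGListSet:
    """Random DEG lists over a bounded gene universe; every list non-empty."""
    if m is None:
        m = int(rng.integers(2, 21))
    genes = [f"g{i}" for i in range(universe)]
    lists = {}
    for i in range(m):
        size = int(rng.integers(1, max(2, universe // 2)))
        chosen = rng.choice(universe, size=size, replace=False)
        lists[f"e{i}"] = frozenset(genes[j] for j in chosen)
    return DEGListSet(lists, 0.05)


def master_from_logfc(logfc: dict[str, list[float]], genes: list[str],
                      padj: dict[str, list[float]] | None = None) -> MasterTable:
    """MasterTable from per-experiment logFC vectors (padj defaults to a
    significant value everywhere so all genes are DEGs)."""
    idx = pd.Index(genes, name="gene_id")
    lf = pd.DataFrame(logfc, index=idx, dtype=float)
    if padj is None:
        pj = pd.DataFrame(0.01, index=idx, columns=lf.columns)
        pj = pj.where(lf.notna())
    else:
        pj = pd.DataFrame(padj, index=idx, dtype=float)
    return MasterTable(lf, pj)


# ---------------------------------------------------------------------------
# brute-force oracles (deliberately naive; independent of the implementation)


def oracle_summary(lists: dict[str, frozenset[str]]) -> dict[str, dict]:
    union = set().union(*lists.values())
    out = {}
    for exp, genes in lists.items():
        others = set().union(*(g for e, g in lists.items() if e != exp))
        s = len([g for g in genes if g not in others])
        n = len(genes)
        delta = s / n
        share = n / len(union)
        out[exp] = {"n": n, "specific_n": s, "specific_fraction": delta,
                    "union_share": share, "R": delta / share}
    return out


def oracle_similarity(a: frozenset[str], b: frozenset[str]) -> float:
    c = len([g for g in a if g in b])
    only_a = len([g for g in a if g not in b])
    only_b = len([g for g in b if g not in a])
    return c / (c + min(only_a, only_b))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_degset():
    """Three overlapping lists: counts computable by hand."""
    return make_degset(
        {
            "e1": {"g1", "g2", "g3"},
            "e2": {"g2", "g3", "g4"},
            "e3": {"g5"},
        }
    )
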