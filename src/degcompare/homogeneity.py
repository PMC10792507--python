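"""Resampling test of DEG-composition homogeneity across experiments.

Given m DEG lists with joint list A (|A| = N), the test asks whether the
union size is stable when experiments are left out — i.e. whether the
lists sample one shared DEG pool (homogeneous) or carry list-specific
pools contributed by non-target factors (heterogeneous).

For each subsample size k from m-1 down to 1, each of ``iterations``
rounds draws two independent pseudo-samples with replacement from the m
lists — one of size k and one of size m — and records the difference of
their union sizes, d_j = N_mj - N_kj.  The empirical percentile interval
of the d distribution is taken at the requested coverage; if it excludes
zero at any tested k, the set of profiles is called heterogeneous.

Union sizes are computed on a compressed representation: genes sharing
the same membership pattern across lists are grouped, so each union size
is a masked sum over distinct patterns rather than a pass over all
genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Sequence

import numpy as np
import pandas as pd

from .profile_io import DEGListSet

__all__ = [
    "union_size",
    "resample_differences",
    "homogeneity_test",
    "HomogeneityResult",
    "KResult",
]


def union_size(lists: Iterable[AbstractSet[str]]) -> int:
    """Number of genes in at least one of the lists.  Duplicate selections
    of the same list (sampling with replacement) contribute once."""
    lists = list(lists)
    if not lists:
        raise ValueError("union_size requires at least one list")
    return len(frozenset().union(*lists))


@dataclass
class KResult:
    """Resampling outcome for one subsample size k."""

    k: int
    d_samples: np.ndarray  # integer differences, length = iterations
    ci: tuple[int, int]
    significant: bool

    @property
    def mean_d(self) -> float:
        return float(self.d_samples.mean())


@dataclass
class HomogeneityResult:
    """Full sweep over subsample sizes plus the overall verdict."""

    m: int
    iterations: int
    ci_level: float
    results: list[KResult]

    @property
    def heterogeneous(self) -> bool:
        return any(r.significant for r in self.results)

    @property
    def verdict(self) -> str:
        return "heterogeneous" if self.heterogeneous else "homogeneous"

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-k table: k, n_iterations, mean_d, ci bounds, flag."""
        return pd.DataFrame(
            [
                {
                    "k": r.k,
                    "n_iterations": len(r.d_samples),
                    "mean_d": r.mean_d,
                    "ci_lower": r.ci[0],
                    "ci_upper": r.ci[1],
                    "significant": r.significant,
                }
                for r in self.results
            ]
        )


# ---------------------------------------------------------------------------
# internals


def _pattern_compress(degset: DEGListSet) -> tuple[np.ndarray, np.ndarray, int]:
    """Group union genes by their membership pattern across the m lists.

    Returns (patterns, counts, m): a boolean array of distinct patterns
    (n_patterns x m) and the number of genes showing each pattern.
    """
    exps = degset.experiments
    genes = sorted(degset.union)
    member = np.zeros((len(genes), len(exps)), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, exp in enumerate(exps):
        for g in degset.lists[exp]:
            member[gene_pos[g], j] = True
    patterns, counts = np.unique(member, axis=0, return_counts=True)
    return patterns, counts, len(exps)


def _union_sizes_for_draws(
    patterns: np.ndarray, counts: np.ndarray, draws: np.ndarray
) -> np.ndarray:
    """Union size for each row of ``draws`` (list indices, drawn with
    replacement)."""
    n_iter = draws.shape[0]
    out = np.empty(n_iter, dtype=np.int64)
    chunk = 512
    for start in range(0, n_iter, chunk):
        block = draws[start : start + chunk]  # (b, k)
        # (b, n_patterns): does any chosen list contain the pattern?
        covered = patterns.T[block].any(axis=1)
        out[start : start + chunk] = covered @ counts
    return out


def _rng_for_k(seed: int | None, k: int) -> np.random.Generator:
    """Per-k substream so results at one k are independent of which other
    k values are tested."""
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))


def resample_differences(
    degset: DEGListSet, k: int, iterations: int, seed: int | None = None
) -> np.ndarray:
    """Vector of d_j = N_mj - N_kj over ``iterations`` resampling rounds.

    Per round, a k-sized and an m-sized pseudo-sample of lists are drawn
    uniformly with replacement, independently of one another.
    Reproducible for a fixed seed; the stream depends only on (seed, k).
    """
    m = degset.m
    if not 1 <= k < m:
        raise ValueError(f"k must satisfy 1 <= k < m={m}, got {k}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    patterns, counts, m = _pattern_compress(degset)
    rng = _rng_for_k(seed, k)
    draws_k = rng.integers(0, m, size=(iterations, k))
    draws_m = rng.integers(0, m, size=(iterations, m))
    n_k = _union_sizes_for_draws(patterns, counts, draws_k)
    n_m = _union_sizes_for_draws(patterns, counts, draws_m)
    return n_m - n_k


def _percentile_ci(d: np.ndarray, ci_level: float) -> tuple[int, int]:
    """Inclusive empirical percentile interval from the sorted order
    statistics (lower bound rounded down, upper rounded up in rank)."""
    tail = (1.0 - ci_level) / 2.0
    d_sorted = np.sort(d)
    n = len(d_sorted)
    lo = d_sorted[int(np.floor(tail * (n - 1)))]
    hi = d_sorted[int(np.ceil((1.0 - tail) * (n - 1)))]
    return int(lo), int(hi)


def homogeneity_test(
    degset: DEGListSet,
    iterations: int = 5000,
    ci_level: float = 0.95,
    seed: int | None = None,
    k_values: Sequence[int] | None = None,
) -> HomogeneityResult:
    """Run the resampling test over subsample sizes k = m-1 down to 1.

    At each k the percentile interval of the d distribution is formed at
    ``ci_level`` coverage; a k is significant when the interval excludes
    zero, and the verdict is heterogeneous if any tested k is
    significant.  ``k_values`` restricts the sweep (the verdict then
    refers only to those k).
    """
    m = degset.m
    if m < 2:
        raise ValueError("homogeneity_test requires at least 2 DEG lists")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    if k_values is None:
        k_values = range(m - 1, 0, -1)
    else:
        k_values = list(k_values)
        for k in k_values:
            if not 1 <= k < m:
                raise ValueError(f"k={k} outside [1, m-1]")

    results = []
    for k in k_values:
        d = resample_differences(degset, k, iterations, seed=seed)
        lo, hi = _percentile_ci(d, ci_level)
        results.append(KResult(k, d, (lo, hi), significant=not lo <= 0 <= hi))
    return HomogeneityResult(m, iterations, ci_level, results)
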