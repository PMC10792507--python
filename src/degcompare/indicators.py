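"""Per-profile descriptive indicators and pairwise DEG-list similarity.

For each DEG list i in a set of m lists with joint (union) list A of size
N, the indicators are

* ``n_i`` — number of DEGs in the list;
* ``s_i`` — number of DEGs specific to the list (DEGs in no other list);
* ``delta_i = s_i / n_i`` — the specific fraction;
* ``R_i = delta_i / (n_i / N)`` — the specific fraction relative to the
  list's share of the joint list.  R >> 1 flags a profile whose DEG
  composition is atypical for the set, e.g. one dominated by a non-target
  (batch) factor.

Pairwise similarity uses the overlap coefficient
``I = c / (c + min(a, b))``: the proportion of shared DEGs (c) in the
smaller of the two lists, where a and b count the DEGs private to each
list.  I is 0 for disjoint lists and 1 when one list nests in the other.

Note that s_i, delta_i and R_i are defined *relative to the current set
of lists*: adding or removing an experiment changes the specificity of
every other profile.
"""

from __future__ import annotations

from typing import AbstractSet

import pandas as pd

from .profile_io import DEGListSet

__all__ = ["summarize", "similarity_index", "similarity_matrix"]


def summarize(degset: DEGListSet) -> pd.DataFrame:
    """Per-experiment indicator table.

    Returns a DataFrame indexed by experiment_id with columns
    ``n`` (DEG count), ``specific_n`` (s_i), ``specific_fraction``
    (delta_i), ``union_share`` (n_i / N) and ``R``.

    Requires m >= 2: specificity is undefined for a single list.
    """
    if degset.m < 2:
        raise ValueError("summarize requires at least 2 DEG lists")
    counts = degset.membership_counts()
    N = degset.N
    rows = []
    for exp, genes in degset.lists.items():
        n = len(genes)
        s = sum(1 for g in genes if counts[g] == 1)
        delta = s / n
        share = n / N
        rows.append(
            {
                "experiment_id": exp,
                "n": n,
                "specific_n": s,
                "specific_fraction": delta,
                "union_share": share,
                "R": delta / share,
            }
        )
    return pd.DataFrame(rows).set_index("experiment_id")


def similarity_index(list_a: AbstractSet[str], list_b: AbstractSet[str]) -> float:
    """Overlap coefficient between two DEG lists.

    ``I = c / (c + min(a, b))`` with c the shared count and a, b the
    counts private to each list; equivalently the shared fraction of the
    smaller list.
    """
    if not list_a or not list_b:
        raise ValueError("similarity_index is undefined for empty DEG lists")
    c = len(list_a & list_b)
    a = len(list_a) - c
    b = len(list_b) - c
    return c / (c + min(a, b))


def similarity_matrix(degset: DEGListSet) -> pd.DataFrame:
    """Symmetric m x m matrix of pairwise similarity indices (diagonal 1),
    rows/columns in the experiment order of ``degset``."""
    if degset.m < 2:
        raise ValueError("similarity_matrix requires at least 2 DEG lists")
    exps = degset.experiments
    mat = pd.DataFrame(1.0, index=exps, columns=exps)
    for i, ea in enumerate(exps):
        for eb in exps[i + 1 :]:
            v = similarity_index(degset.lists[ea], degset.lists[eb])
            mat.loc[ea, eb] = v
            mat.loc[eb, ea] = v
    return mat
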