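"""Gene-set overrepresentation with the EASE-score Fisher variant.

The EASE score is a conservative one-tailed Fisher exact test in which one
gene is removed from the overlap cell before computing the hypergeometric
upper tail: p = P(X >= k - 1), X ~ Hypergeom(N, K, n).  It penalizes
categories supported by very few genes (k <= 1 gives p = 1) and is always at
least as large as the classical Fisher p for the same table.  Categories are
reported only when their significant-gene count lies within a size window
(default 3-50 genes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import GeneList, GeneSetCollection, ValidationError
from .differential import bh_fdr


def _check_table(k: int, n_list: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n_list, K)):
        raise ValidationError(f"inconsistent table: k={k}, n_list={n_list}, K={K}")
    if K > N or n_list > N:
        raise ValidationError(f"inconsistent table: K={K}, n_list={n_list}, N={N}")
    if N <= 0:
        raise ValidationError("background must be non-empty")


def ease_score(k: int, n_list: int, K: int, N: int) -> float:
    """EASE (overlap-decremented one-tailed Fisher) p-value.

    k genes of an n_list-gene query fall in a category of size K within a
    background of N genes.  k <= 1 returns 1 by construction.
    """
    _check_table(k, n_list, K, N)
    if k <= 1:
        return 1.0
    # P(X >= k-1) = hypergeom.sf(k-2)
    return float(scipy.stats.hypergeom.sf(k - 2, N, K, n_list))


def fisher_score(k: int, n_list: int, K: int, N: int) -> float:
    """Classical one-tailed Fisher exact p: P(X >= k)."""
    _check_table(k, n_list, K, N)
    if k == 0:
        return 1.0
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n_list))


def enrich(
    query: GeneList,
    sets: GeneSetCollection,
    background,
    min_size: int = 3,
    max_size: int = 50,
) -> pd.DataFrame:
    """EASE-score overrepresentation of ``query`` in each gene set.

    Sets are first restricted to the background; only sets whose overlap
    with the query (significant-gene count) lies in [min_size, max_size] are
    scored.  Rows are sorted by ascending EASE p; a BH q column is provided
    for convenience.
    """
    background = frozenset(background)
    if not background:
        raise ValidationError("background is empty")
    outside = query.symbols - background
    if outside:
        raise ValidationError(
            f"query member(s) outside background: {sorted(outside)[:5]}"
        )
    N = len(background)
    n_list = len(query)
    rows = []
    for name, members in sets:
        members_bg = frozenset(members) & background
        if not members_bg:
            continue
        k = len(query.symbols & members_bg)
        if not min_size <= k <= max_size:
            continue
        K = len(members_bg)
        rows.append(
            {
                "set_name": name,
                "description": sets.descriptions.get(name, ""),
                "k": k,
                "n_list": n_list,
                "K": K,
                "N": N,
                "ease_p": ease_score(k, n_list, K, N),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["set_name", "description", "k", "n_list", "K", "N", "ease_p"],
    )
    if len(table):
        table["q"] = bh_fdr(table["ease_p"].to_numpy()).q
        table = table.sort_values(
            ["ease_p", "set_name"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["q"] = np.nan
    return table
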