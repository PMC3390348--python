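"""Per-gene one-way ANOVA, BH false-discovery-rate summaries, effect sizes.

The test is the classic unbalanced fixed-effects one-way ANOVA computed on
unmasked cells only: F = MS_between / MS_within on (k-1, N-k) degrees of
freedom.  All per-gene statistics are vectorized across the gene axis.
Throughout the package, SD means the sample standard deviation (n-1
denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionStudy, ValidationError


def _dense_anova(X: np.ndarray, group_cols: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """F statistics and p-values per row for a complete (no-NaN) matrix.

    ``group_cols`` is a list of column-index arrays, one per group.  Used on
    the Monte Carlo fast path where no cells are masked.
    """
    k = len(group_cols)
    N = sum(len(c) for c in group_cols)
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for cols in group_cols:
        sub = X[:, cols]
        m = sub.mean(axis=1)
        ssb += len(cols) * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (N - k))
    p = scipy.stats.f.sf(F, k - 1, N - k)
    return F, p


def anova_per_gene(study: ExpressionStudy) -> pd.DataFrame:
    """One-way ANOVA across the study's ordered groups, per gene.

    Returns a DataFrame indexed by probe_id with columns ``symbol``,
    ``mean_<group>`` and ``n_<group>`` per group, ``F`` and ``p``.  Genes
    where any group has fewer than 2 unmasked values, or where all values are
    equal (zero total variance), carry NaN statistics and a reason in
    ``flag``; they are meant to be excluded from multiplicity correction.
    """
    group_cols = study.group_columns()
    if len(group_cols) < 2:
        raise ValidationError("ANOVA needs at least 2 groups with samples")
    X = study.values()
    k = len(group_cols)

    n_g, sum_g, ssw = {}, {}, np.zeros(study.n_genes)
    for g, cols in group_cols.items():
        sub = X[:, cols]
        n = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.nansum(sub, axis=1) / n
            ssw_g = np.nansum((sub - m[:, None]) ** 2, axis=1)
        n_g[g], sum_g[g] = n, m
        ssw += ssw_g

    n_total = sum(n_g.values())
    grand = sum(n_g[g] * sum_g[g] for g in group_cols) / n_total
    ssb = sum(n_g[g] * (sum_g[g] - grand) ** 2 for g in group_cols)

    low_n = np.zeros(study.n_genes, dtype=bool)
    for g in group_cols:
        low_n |= n_g[g] < 2
    sst = ssb + ssw
    constant = (sst <= 0) & ~low_n

    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (n_total - k))
    p = np.full(study.n_genes, np.nan)
    ok = ~low_n & ~constant
    # zero within-group variance with a real between-group difference: F=inf, p=0
    p[ok] = scipy.stats.f.sf(F[ok], k - 1, (n_total - k)[ok])
    F[~ok] = np.nan

    out = pd.DataFrame(index=study.probe_ids)
    out["symbol"] = study.genes["symbol"].to_numpy()
    for g in group_cols:
        out[f"mean_{g}"] = sum_g[g]
        out[f"n_{g}"] = n_g[g]
    out["F"] = F
    out["p"] = p
    flag = np.array([""] * study.n_genes, dtype=object)
    flag[low_n] = "low_n"
    flag[constant] = "constant"
    out["flag"] = flag
    return out


@dataclass(frozen=True)
class FDRResult:
    """BH step-up summary over a family of p-values.

    ``median_fdr`` is the median BH q-value among genes passing the
    significance gate (p <= alpha); ``expected_false_fraction`` is the
    alternative textbook reading alpha * m / n_significant.  Both are NaN
    when nothing passes the gate.
    """

    q: np.ndarray
    alpha: float
    n_significant: int
    median_fdr: float
    expected_false_fraction: float


def bh_fdr(p_values, alpha: float = 0.05) -> FDRResult:
    """Benjamini–Hochberg step-up q-values with a median-FDR summary.

    q-values are returned in input order and satisfy
    q_i = min_{j >= i} p_(j) * m / j over the sorted sequence.  The
    significance gate is on raw p (p <= alpha), matching a design in which
    FDR is reported alongside rather than used as the cutoff.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return FDRResult(np.array([]), alpha, 0, np.nan, np.nan)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    sig = p <= alpha
    n_sig = int(sig.sum())
    median_fdr = float(np.median(q[sig])) if n_sig else np.nan
    eff = alpha * len(p) / n_sig if n_sig else np.nan
    return FDRResult(q, alpha, n_sig, median_fdr, eff)


def effect_size(
    study: ExpressionStudy, group_a: str, group_b: str
) -> np.ndarray:
    """Per-gene standardized mean difference (mean_b - mean_a) / pooled SD.

    The pooled SD is the usual two-sample pooled within-group sample SD over
    unmasked values.  Genes with fewer than 2 values in either group or zero
    pooled SD get NaN.
    """
    cols = study.group_columns()
    for g in (group_a, group_b):
        if g not in cols:
            raise ValidationError(f"unknown group: {g!r}")
    X = study.values()

    def _stats(g):
        sub = X[:, cols[g]]
        n = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.nansum(sub, axis=1) / n
            ss = np.nansum((sub - m[:, None]) ** 2, axis=1)
        return n, m, ss

    na, ma, ssa = _stats(group_a)
    nb, mb, ssb = _stats(group_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.sqrt((ssa + ssb) / (na + nb - 2))
        d = (mb - ma) / pooled
    d[(na < 2) | (nb < 2) | (pooled <= 0)] = np.nan
    return d


def de_analysis(study: ExpressionStudy, alpha: float = 0.05) -> pd.DataFrame:
    """ANOVA + BH q-values in one table (q computed over valid genes only)."""
    table = anova_per_gene(study)
    valid = table["p"].notna()
    q = np.full(len(table), np.nan)
    if valid.any():
        fdr = bh_fdr(table.loc[valid, "p"].to_numpy(), alpha=alpha)
        q[valid.to_numpy()] = fdr.q
        table.attrs["n_significant"] = fdr.n_significant
        table.attrs["median_fdr"] = fdr.median_fdr
        table.attrs["expected_false_fraction"] = fdr.expected_false_fraction
    table["q"] = q
    table["significant"] = table["p"] <= alpha
    return table
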