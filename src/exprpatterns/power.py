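"""Discovery-power equalization by subsample resampling.

A larger study discovers more significant genes partly because it has more
arrays.  To compare its effect magnitude with a smaller study on equal
footing, subsets of arrays matching the smaller study's size are drawn
repeatedly, the per-subset significant-gene counts are histogrammed, a
Gaussian is least-squares fitted to the histogram, and the smaller study's
observed count is located on that fitted curve: the p-value is the
integrated area of the Gaussian below the comparison count divided by the
total area, i.e. Phi((count - mu) / sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats

from .datamodel import ExpressionStudy, ValidationError
from .differential import anova_per_gene


def subsample_significance_counts(
    study: ExpressionStudy,
    subset_size: int,
    iterations: int = 1000,
    alpha: float = 0.05,
    seed=None,
    stratified: bool = False,
) -> np.ndarray:
    """Significant-gene counts over random array subsets.

    Each iteration draws ``subset_size`` arrays without replacement (simple
    random by default; group-proportional when ``stratified``), redraws any
    subset leaving fewer than 2 arrays in some group, runs the per-gene
    ANOVA on the subset, and records the number of genes with p <= alpha.
    """
    group_cols = study.group_columns()
    n_groups = len(group_cols)
    if subset_size < 2 * n_groups:
        raise ValidationError(
            f"subset_size={subset_size} cannot leave 2 arrays in each of "
            f"{n_groups} groups"
        )
    if subset_size > study.n_samples:
        raise ValidationError("subset_size exceeds the number of samples")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    groups = study.samples["group"].to_numpy()

    if stratified:
        # per-group quota proportional to group size (largest remainder)
        sizes = {g: len(c) for g, c in group_cols.items()}
        exact = {g: subset_size * n / study.n_samples for g, n in sizes.items()}
        quota = {g: max(2, int(np.floor(x))) for g, x in exact.items()}
        rem = subset_size - sum(quota.values())
        for g in sorted(exact, key=lambda g: exact[g] - np.floor(exact[g]), reverse=True):
            if rem <= 0:
                break
            quota[g] += 1
            rem -= 1
        if sum(quota.values()) != subset_size:
            raise ValidationError("stratified quotas cannot match subset_size")

    counts = np.empty(iterations, dtype=int)
    for it in range(iterations):
        while True:
            if stratified:
                cols = np.concatenate(
                    [
                        rng.choice(group_cols[g], size=quota[g], replace=False)
                        for g in group_cols
                    ]
                )
            else:
                cols = rng.choice(study.n_samples, size=subset_size, replace=False)
            _, ok_counts = np.unique(groups[cols], return_counts=True)
            if len(ok_counts) == n_groups and (ok_counts >= 2).all():
                break
        sub = study.subset_samples(np.sort(cols))
        table = anova_per_gene(sub)
        counts[it] = int((table["p"] <= alpha).sum())
    return counts


@dataclass(frozen=True)
class GaussianFit:
    mu: float
    sigma: float
    amplitude: float
    r_squared: float


def fit_gaussian_to_histogram(counts, bin_width: float = 10.0) -> GaussianFit:
    """Least-squares Gaussian fit A exp(-(x-mu)^2 / (2 sigma^2)) to the
    frequency histogram of ``counts``.

    Bins of width ``bin_width`` span the data; the fit is initialized from
    the sample mean/SD and the modal bin height.  Requires at least 5
    non-empty bins.  ``r_squared`` is 1 - SS_resid/SS_total over the bins.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.std() == 0:
        raise ValidationError("degenerate histogram: all counts identical")
    lo = bin_width * np.floor(counts.min() / bin_width)
    hi = bin_width * np.ceil((counts.max() + 1) / bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    freq, _ = np.histogram(counts, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    if np.count_nonzero(freq) < 5:
        raise ValidationError(
            f"only {np.count_nonzero(freq)} non-empty bins; need >= 5 "
            f"(try a smaller bin_width)"
        )

    def gauss(x, a, mu, sigma):
        return a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))

    p0 = (float(freq.max()), float(counts.mean()), float(counts.std(ddof=1)))
    try:
        popt, _ = scipy.optimize.curve_fit(gauss, centers, freq, p0=p0, maxfev=10_000)
    except RuntimeError as err:
        raise ValidationError(f"Gaussian fit did not converge: {err}") from err
    a, mu, sigma = popt
    sigma = abs(float(sigma))
    resid = freq - gauss(centers, *popt)
    ss_tot = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return GaussianFit(mu=float(mu), sigma=sigma, amplitude=float(a), r_squared=r2)


def power_equalized_p(fit: GaussianFit, comparison_count: float) -> float:
    """Area of the fitted Gaussian below ``comparison_count`` / total area.

    Equals Phi((comparison_count - mu) / sigma): the probability, under the
    fitted subsample distribution, of a count at or below the smaller
    study's observation.
    """
    if fit.sigma <= 0:
        raise ValidationError("fit sigma must be positive")
    return float(scipy.stats.norm.cdf((comparison_count - fit.mu) / fit.sigma))


def empirical_quantile(counts, comparison_count: float) -> float:
    """Fraction of subsample counts at or below the comparison count."""
    counts = np.asarray(counts)
    return float(np.mean(counts <= comparison_count))
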