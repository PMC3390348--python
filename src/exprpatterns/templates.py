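"""Temporal expression-pattern classification by template matching.

Each ANOVA-significant gene's vector of group means (over the ordered
groups control -> 24 h -> 72 h) is Pearson-correlated with four artificial
temporal templates — sustained, transient, delayed, linear — and assigned to
the template with the largest |r|; the sign of r gives the direction of
change (positive = increased with deprivation).  A Monte Carlo simulation on
pure-noise matrices of the same dimensions calibrates how many genes each
template attracts by chance: the templates carve the space of mean profiles
into regions of different sizes, so the null counts are template-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import DOWN, UP, ValidationError

DEFAULT_TEMPLATE_ORDER = ("sustained", "transient", "delayed", "linear")

#: Numeric encodings of the four shapes over (control, 24 h, 72 h).
_PROFILES = {
    "sustained": (0.0, 1.0, 1.0),
    "transient": (0.0, 1.0, 0.0),
    "delayed": (0.0, 0.0, 1.0),
    "linear": (0.0, 0.5, 1.0),
}


@dataclass(frozen=True)
class Template:
    name: str
    profile: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "profile", np.asarray(self.profile, dtype=float))
        if np.ptp(self.profile) == 0:
            raise ValidationError(f"template {self.name!r} has a constant profile")


def default_templates(n_groups: int = 3) -> list[Template]:
    """The four canonical temporal templates for a 3-group design."""
    if n_groups != 3:
        raise ValidationError(
            "default templates are specific to the 3-group design "
            "(control, 24 h, 72 h)"
        )
    return [Template(name, _PROFILES[name]) for name in DEFAULT_TEMPLATE_ORDER]


def _correlations(means: np.ndarray, templates: list[Template]) -> np.ndarray:
    """Pearson r of each row of ``means`` with each template profile.

    Rows with zero variance produce NaN across all templates.
    """
    M = means - means.mean(axis=1, keepdims=True)
    m_norm = np.linalg.norm(M, axis=1)
    T = np.stack([t.profile for t in templates])
    T = T - T.mean(axis=1, keepdims=True)
    t_norm = np.linalg.norm(T, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (M @ T.T) / (m_norm[:, None] * t_norm[None, :])
    return r


def assign_templates(
    group_means, templates: list[Template] | None = None
) -> pd.DataFrame:
    """Assign each gene to the template with maximal |Pearson r|.

    ``group_means`` is an (n_genes, n_groups) array or DataFrame of group
    mean expression (one column per ordered group).  Ties in |r| are broken
    by template order; genes with constant means are left unassigned
    (template "", r NaN).

    Returns a DataFrame with columns ``template``, ``r``, ``direction``.
    """
    if templates is None:
        templates = default_templates()
    index = None
    if isinstance(group_means, pd.DataFrame):
        index = group_means.index
        group_means = group_means.to_numpy(dtype=float)
    means = np.atleast_2d(np.asarray(group_means, dtype=float))
    if means.shape[1] != len(templates[0].profile):
        raise ValidationError(
            f"group means have {means.shape[1]} entries, templates expect "
            f"{len(templates[0].profile)}"
        )
    r = _correlations(means, templates)
    valid = ~np.isnan(r).any(axis=1)
    # argmax on |r| keeps the first (template-order) winner on exact ties
    best = np.zeros(len(means), dtype=int)
    best_r = np.full(len(means), np.nan)
    if valid.any():
        best[valid] = np.argmax(np.abs(r[valid]), axis=1)
        best_r[valid] = r[valid, best[valid]]
    names = np.array([t.name for t in templates], dtype=object)
    out = pd.DataFrame(
        {
            "template": np.where(valid, names[best], ""),
            "r": best_r,
            "direction": np.where(
                valid, np.where(best_r > 0, UP, DOWN), ""
            ),
        },
        index=index,
    )
    return out


@dataclass
class NullTemplateCounts:
    """Per-iteration null counts of significant genes per (template, direction)."""

    counts: np.ndarray  # (iterations, n_templates, 2) — [:, :, 0]=up, [:, :, 1]=down
    template_names: tuple[str, ...]
    alpha: float
    n_genes: int

    @property
    def iterations(self) -> int:
        return self.counts.shape[0]

    @property
    def mean_count(self) -> pd.DataFrame:
        """Mean count per (template, direction) over iterations."""
        m = self.counts.mean(axis=0)
        return pd.DataFrame(m, index=list(self.template_names), columns=[UP, DOWN])

    @property
    def sd_count(self) -> pd.DataFrame:
        s = self.counts.std(axis=0, ddof=1)
        return pd.DataFrame(s, index=list(self.template_names), columns=[UP, DOWN])

    def per_direction_mean(self) -> pd.Series:
        """Per-template mean count per direction (up and down cells averaged)."""
        return self.mean_count.mean(axis=1)

    def summary(self) -> pd.DataFrame:
        rows = []
        mc, sd = self.mean_count, self.sd_count
        for t in self.template_names:
            for d in (UP, DOWN):
                rows.append((t, d, mc.loc[t, d], sd.loc[t, d]))
        return pd.DataFrame(rows, columns=["template", "direction", "mean_count", "mc_sd"])


def monte_carlo_template_null(
    n_genes: int,
    group_sizes,
    iterations: int = 1000,
    alpha: float = 0.05,
    seed=None,
    templates: list[Template] | None = None,
) -> NullTemplateCounts:
    """Null distribution of per-(template, direction) significant-gene counts.

    Each iteration draws an ``n_genes`` x ``sum(group_sizes)`` matrix of iid
    standard normal values, runs the one-way ANOVA per row, keeps rows with
    p <= alpha, assigns each to a template by max |r| on its group means, and
    tallies counts per (template, direction).  ANOVA p-values and the
    assignment geometry are location/scale invariant, so the standard normal
    draw is without loss of generality for any iid null.
    """
    from .differential import _dense_anova  # local import to avoid cycle at import time

    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    group_sizes = tuple(int(n) for n in group_sizes)
    if any(n < 2 for n in group_sizes):
        raise ValidationError("each group needs at least 2 samples")
    if templates is None:
        templates = default_templates(len(group_sizes))
    rng = np.random.default_rng(seed)
    n_samples = sum(group_sizes)
    edges = np.cumsum((0,) + group_sizes)
    group_cols = [np.arange(edges[i], edges[i + 1]) for i in range(len(group_sizes))]

    counts = np.zeros((iterations, len(templates), 2), dtype=int)
    names = tuple(t.name for t in templates)
    for it in range(iterations):
        X = rng.standard_normal((n_genes, n_samples))
        _, p = _dense_anova(X, group_cols)
        sig = p <= alpha
        if not sig.any():
            continue
        means = np.stack([X[sig][:, c].mean(axis=1) for c in group_cols], axis=1)
        assigned = assign_templates(means, templates)
        for ti, t in enumerate(names):
            in_t = assigned["template"] == t
            counts[it, ti, 0] = int((in_t & (assigned["direction"] == UP)).sum())
            counts[it, ti, 1] = int((in_t & (assigned["direction"] == DOWN)).sum())
    return NullTemplateCounts(
        counts=counts, template_names=names, alpha=alpha, n_genes=n_genes
    )


def template_count_test(observed_count: int, null_mean: float, n_genes: int) -> float:
    """Upper-tail exact binomial test of an observed template count.

    P(X >= observed), X ~ Binomial(n_genes, null_mean / n_genes), where
    ``null_mean`` is the Monte Carlo mean count for the template cell.
    """
    if observed_count < 0:
        raise ValidationError("observed_count must be >= 0")
    if not 0 < null_mean < n_genes:
        raise ValidationError("null_mean must lie in (0, n_genes)")
    return float(scipy.stats.binom.sf(observed_count - 1, n_genes, null_mean / n_genes))
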