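"""Synthetic study generation with recorded ground truth.

The generator emulates the structure of a two-cohort, three-group rodent
sleep-deprivation microarray study: a gene-by-array intensity matrix in which
most genes are null (pure within-group noise), a chosen fraction follow one of
the four temporal response templates (sustained / transient / delayed /
linear), cohort 2 arrays carry an additive background offset, and each cell
has a Bernoulli presence (detection) call.  Ground truth — which genes were
planted, with which template, direction and effect size — is recorded so that
every downstream stage of the pipeline can be tested without any external
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DOWN, UP, ExpressionStudy, ValidationError
from .templates import DEFAULT_TEMPLATE_ORDER, default_templates

#: Ordered treatment groups of the emulated design: home cage control, then
#: 24 h and 72 h of sleep deprivation.
DEFAULT_GROUPS = ("HC", "24SD", "72SD")
DEFAULT_GROUP_SIZES = (17, 16, 20)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study.

    Defaults reproduce the emulated study design: 2167 filtered genes on 53
    arrays in groups of 17/16/20, two cohorts splitting the arrays roughly
    37:32, a +0.5 noise-SD background offset on cohort 2, 200 genes planted
    per template at effect size 2 (in within-group SD units), unit noise SD,
    and 90% presence calls.
    """

    n_genes: int = 2167
    group_names: tuple[str, ...] = DEFAULT_GROUPS
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    cohort_split: float = 37 / 69
    cohort_offset: float = 0.5
    frac_per_template: dict[str, float] = field(
        default_factory=lambda: {t: 200 / 2167 for t in DEFAULT_TEMPLATE_ORDER}
    )
    effect_size: float = 2.0
    noise_sd: float = 1.0
    presence_rate: float = 0.9
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValidationError("each group needs at least 2 samples")
        if len(self.group_names) != len(self.group_sizes):
            raise ValidationError("group_names and group_sizes length mismatch")
        total = sum(self.frac_per_template.values())
        if total > 1 + 1e-12:
            raise ValidationError(
                f"template fractions sum to {total:.3f} > 1"
            )
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not 0 <= self.cohort_split <= 1:
            raise ValidationError("cohort_split must be in [0, 1]")


def generate_study(spec: SyntheticSpec) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Generate a study and its ground-truth table.

    Null genes are iid Normal(baseline, noise_sd) in every group.  A planted
    gene adds ``direction * effect_size * noise_sd * template_profile[group]``
    to its group means; directions are split 50/50 up/down.  Cohort 2 samples
    receive ``cohort_offset`` additively on all genes.  Presence calls are iid
    Bernoulli(presence_rate).

    Returns ``(study, truth)`` where ``truth`` is a DataFrame indexed by
    probe_id with columns status / template / direction / effect_size.
    """
    rng = np.random.default_rng(spec.seed)
    groups = np.repeat(spec.group_names, spec.group_sizes)
    n_samples = len(groups)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]

    # assign cohorts within each group so cohort is not confounded with group
    cohort = np.empty(n_samples, dtype=object)
    start = 0
    for size in spec.group_sizes:
        n1 = int(round(spec.cohort_split * size))
        cohort[start : start + n1] = "1"
        cohort[start + n1 : start + size] = "2"
        start += size

    templates = {t.name: t for t in default_templates(len(spec.group_names))}
    group_index = np.concatenate(
        [np.full(n, i) for i, n in enumerate(spec.group_sizes)]
    )

    # plant templates into leading genes, then shuffle gene order
    counts = {
        name: int(round(frac * spec.n_genes))
        for name, frac in spec.frac_per_template.items()
    }
    if sum(counts.values()) > spec.n_genes:
        raise ValidationError("planted gene counts exceed n_genes")
    status = np.array(["null"] * spec.n_genes, dtype=object)
    template_col = np.array([""] * spec.n_genes, dtype=object)
    direction = np.array([""] * spec.n_genes, dtype=object)
    shift = np.zeros((spec.n_genes, n_samples))
    row = 0
    for name, count in counts.items():
        profile = templates[name].profile[group_index]  # per-sample template value
        for j in range(count):
            sign = 1.0 if j % 2 == 0 else -1.0
            status[row] = "planted"
            template_col[row] = name
            direction[row] = UP if sign > 0 else DOWN
            shift[row] = sign * spec.effect_size * spec.noise_sd * profile
            row += 1
    order = rng.permutation(spec.n_genes)
    status, template_col, direction = status[order], template_col[order], direction[order]
    shift = shift[order]

    signal = (
        spec.baseline
        + shift
        + rng.normal(scale=spec.noise_sd, size=(spec.n_genes, n_samples))
    )
    signal = signal + np.where(cohort == "2", spec.cohort_offset, 0.0)[None, :]
    present = rng.random((spec.n_genes, n_samples)) < spec.presence_rate

    probe_ids = [f"probe_{i:05d}" for i in range(spec.n_genes)]
    genes = pd.DataFrame(
        {
            "symbol": [f"Gene{i:05d}" for i in range(spec.n_genes)],
            "grade": "A",
            "n_present": present.sum(axis=1),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    samples = pd.DataFrame(
        {"group": groups, "cohort": cohort},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    study = ExpressionStudy(
        genes=genes,
        samples=samples,
        signal=signal,
        present=present,
        mask=np.zeros_like(present, dtype=bool),
        group_order=spec.group_names,
    )
    truth = pd.DataFrame(
        {
            "symbol": genes["symbol"].to_numpy(),
            "status": status,
            "template": template_col,
            "direction": direction,
            "effect_size": np.where(status == "planted", spec.effect_size, 0.0),
        },
        index=genes.index,
    )
    return study, truth


def generate_null_matrix(
    n_genes: int,
    group_sizes,
    seed,
    group_names: tuple[str, ...] | None = None,
) -> ExpressionStudy:
    """A pure-noise study: iid standard normal, all present, one cohort.

    This is the random-data matrix used by the Monte Carlo calibration of the
    template-count null: same number of rows (genes) and columns (arrays) as
    the real design, signal replaced by randomly generated numbers.
    """
    group_sizes = tuple(int(n) for n in group_sizes)
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if any(n < 2 for n in group_sizes):
        raise ValidationError("each group needs at least 2 samples")
    if group_names is None:
        group_names = tuple(f"G{i}" for i in range(len(group_sizes)))
    rng = np.random.default_rng(seed)
    n_samples = sum(group_sizes)
    signal = rng.standard_normal((n_genes, n_samples))
    probe_ids = [f"null_{i:05d}" for i in range(n_genes)]
    genes = pd.DataFrame(
        {
            "symbol": [f"Null{i:05d}" for i in range(n_genes)],
            "grade": "A",
            "n_present": n_samples,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    samples = pd.DataFrame(
        {
            "group": np.repeat(group_names, group_sizes),
            "cohort": "1",
        },
        index=pd.Index([f"S{i:03d}" for i in range(n_samples)], name="sample_id"),
    )
    return ExpressionStudy(
        genes=genes,
        samples=samples,
        signal=signal,
        present=np.ones_like(signal, dtype=bool),
        mask=np.zeros_like(signal, dtype=bool),
        group_order=group_names,
    )


def truth_gene_list(truth: pd.DataFrame, template: str | None = None):
    """Signed symbol->direction mapping of planted genes (optionally one template)."""
    sel = truth["status"] == "planted"
    if template is not None:
        sel &= truth["template"] == template
    sub = truth[sel]
    return dict(zip(sub["symbol"], sub["direction"]))
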