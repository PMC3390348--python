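import numpy as np
import pandas as pd
import pytest

from exprpatterns import ExpressionStudy, SyntheticSpec, generate_study


def make_study(signal, groups, cohorts=None, present=None, symbols=None,
               grades=None, group_order=None):
    """Hand-build a small ExpressionStudy from explicit values."""
    signal = np.asarray(signal, dtype=float)
    n_genes, n_samples = signal.shape
    if cohorts is None:
        cohorts = ["1"] * n_samples
    if present is None:
        present = np.ones_like(signal, dtype=bool)
    if symbols is None:
        symbols = [f"Sym{i}" for i in range(n_genes)]
    if grades is None:
        grades = ["A"] * n_genes
    if group_order is None:
        group_order = tuple(pd.unique(pd.Series(groups)))
    genes = pd.DataFrame(
        {"symbol": symbols, "grade": grades,
         "n_present": np.asarray(present).sum(axis=1)},
        index=pd.Index([f"p{i}" for i in range(n_genes)], name="probe_id"),
    )
    samples = pd.DataFrame(
        {"group": list(groups), "cohort": list(cohorts)},
        index=pd.Index([f"s{i}" for i in range(n_samples)], name="sample_id"),
    )
    return ExpressionStudy(
        genes=genes, samples=samples, signal=signal,
        present=np.asarray(present, dtype=bool),
        mask=np.isnan(signal), group_order=group_order,
    )


@pytest.fixture
def tiny_study():
    """3 genes x 6 samples, two groups of 3, single cohort."""
    rng = np.random.default_rng(7)
    return make_study(rng.normal(size=(3, 6)), ["a"] * 3 + ["b"] * 3)


@pytest.fixture(scope="session")
def planted_study():
    """Small planted-signal study: 400 genes, 40 per template, effect 2."""
    spec = SyntheticSpec(
        n_genes=400,
        frac_per_template={t: 0.1 for t in
                           ("sustained", "transient", "delayed", "linear")},
        effect_size=2.0,
        noise_sd=1.0,
        seed=11,
    )
    return generate_study(spec)
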