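"""End-to-end pipeline orchestration.

Runs the stages in study order — simulate (or load), preprocess, per-gene
ANOVA + FDR, template assignment, Monte Carlo template null, overlap against
a reference list, subsample power equalization, and gene-set
overrepresentation — writing per-stage TSVs and a JSON manifest recording
seeds and headline counts.  The pipeline is a pure function of (inputs,
config, seeds).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import DOWN, UP, ExpressionStudy, GeneList, GeneSetCollection, ValidationError
from .differential import de_analysis
from .enrichment import enrich
from .io import (
    read_expression_study,
    read_gene_list,
    read_gene_sets,
    write_expression_study,
    write_gene_list,
    write_gene_sets,
    write_gene_table,
)
from .overlap import directional_agreement, overlap_test
from .power import (
    empirical_quantile,
    fit_gaussian_to_histogram,
    power_equalized_p,
    subsample_significance_counts,
)
from .preprocess import filter_probesets, mask_outliers, standardize_by_cohort
from .synthetic import SyntheticSpec, generate_study, truth_gene_list
from .templates import (
    assign_templates,
    default_templates,
    monte_carlo_template_null,
    template_count_test,
)

log = logging.getLogger("exprpatterns")


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    When ``matrix_path`` is unset, a synthetic study is generated from
    ``synthetic`` (a :class:`SyntheticSpec` field dict) and its planted truth
    doubles as the reference list for the overlap stage.
    """

    outdir: str = "pipeline_out"
    seed: int = 0
    alpha: float = 0.05
    min_present: int = 6
    k_sd: float = 2.0
    mc_iterations: int = 1000
    resample_iterations: int = 1000
    resample_subset_size: int = 21
    resample_bin_width: float = 10.0
    stratified_resampling: bool = False
    comparison_count: int | None = None
    enrich_min_size: int = 3
    enrich_max_size: int = 50
    # optional real-data inputs
    matrix_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    presence_path: str | None = None
    reference_list_path: str | None = None
    gene_sets_path: str | None = None
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        # distinct, reproducible substream per stochastic stage, kept < 2^31
        offsets = {"simulate": 1, "mcnull": 2, "resample": 3}
        return (self.seed * 7919 + offsets[stage]) % (2**31 - 1)


def _synthetic_gene_sets(
    truth: pd.DataFrame, background, rng, set_size: int = 30, n_random: int = 20
) -> GeneSetCollection:
    """A synthetic GMT: one set per planted (template, direction) plus
    random background sets, for exercising the enrichment stage."""
    sets: dict[str, frozenset] = {}
    desc: dict[str, str] = {}
    background = sorted(background)
    planted = truth[truth["status"] == "planted"]
    for (tmpl, direction), sub in planted.groupby(["template", "direction"]):
        symbols = sub["symbol"].tolist()
        take = rng.choice(len(symbols), size=min(set_size, len(symbols)), replace=False)
        name = f"planted_{tmpl}_{direction}"
        sets[name] = frozenset(symbols[i] for i in take)
        desc[name] = f"synthetic set drawn from planted {tmpl}/{direction} genes"
    for i in range(n_random):
        take = rng.choice(len(background), size=set_size, replace=False)
        name = f"random_{i:02d}"
        sets[name] = frozenset(background[j] for j in take)
        desc[name] = "synthetic random background set"
    return GeneSetCollection(sets=sets, descriptions=desc)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "ok", **info}
        log.info("stage=%s %s", stage, info)

    try:
        # -- simulate / load ------------------------------------------------
        truth = None
        if config.matrix_path is None:
            spec = SyntheticSpec(**{**config.synthetic, "seed": config.stage_seed("simulate")})
            study, truth = generate_study(spec)
            write_expression_study(study, outdir / "study")
            truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="probe_id")
            record("simulate", seed=spec.seed, n_genes=study.n_genes, n_samples=study.n_samples)
        else:
            study = read_expression_study(
                config.matrix_path,
                config.metadata_path,
                config.annotation_path,
                config.presence_path,
            )
            record("load", n_genes=study.n_genes, n_samples=study.n_samples)

        # -- preprocess -----------------------------------------------------
        study, report = filter_probesets(study, min_present=config.min_present)
        study = mask_outliers(study, k_sd=config.k_sd)
        study = standardize_by_cohort(study)
        report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        record(
            "preprocess",
            n_masked=int(study.mask.sum()),
            **{f"n_{s}": n for s, n in zip(report.to_frame()["stage"], report.to_frame()["n_genes"])},
        )

        # -- differential expression ---------------------------------------
        table = de_analysis(study, alpha=config.alpha)
        sig = table[table["significant"].fillna(False)]
        record(
            "de",
            n_tested=int(table["p"].notna().sum()),
            n_significant=len(sig),
            median_fdr=float(table.attrs.get("median_fdr", float("nan"))),
        )

        # -- template assignment -------------------------------------------
        mean_cols = [f"mean_{g}" for g in study.group_order]
        assignments = assign_templates(sig[mean_cols])
        de_out = sig.join(assignments).reset_index()
        write_gene_table(de_out, outdir / "significant_genes.tsv")
        n_up = int((assignments["direction"] == UP).sum())
        n_down = int((assignments["direction"] == DOWN).sum())
        record("templates", n_up=n_up, n_down=n_down)

        # -- Monte Carlo template null --------------------------------------
        group_sizes = [len(c) for c in study.group_columns().values()]
        null = monte_carlo_template_null(
            n_genes=study.n_genes,
            group_sizes=group_sizes,
            iterations=config.mc_iterations,
            alpha=config.alpha,
            seed=config.stage_seed("mcnull"),
        )
        summary = null.summary()
        obs_counts = (
            de_out.groupby(["template", "direction"]).size()
            if len(de_out)
            else pd.Series(dtype=int)
        )
        summary["observed"] = [
            int(obs_counts.get((t, d), 0))
            for t, d in zip(summary["template"], summary["direction"])
        ]
        summary["binomial_p"] = [
            template_count_test(o, m, study.n_genes) if m > 0 else float("nan")
            for o, m in zip(summary["observed"], summary["mean_count"])
        ]
        summary.to_csv(outdir / "template_null.tsv", sep="\t", index=False)
        record(
            "mcnull",
            seed=config.stage_seed("mcnull"),
            iterations=null.iterations,
            total_mean=float(null.counts.sum(axis=(1, 2)).mean()),
        )

        # -- overlap ---------------------------------------------------------
        background = set(study.genes["symbol"])
        discovered = GeneList(
            {
                s: d
                for s, d in zip(de_out["symbol"], de_out["direction"])
                if d in (UP, DOWN)
            },
            name="discovered",
        )
        if config.reference_list_path is not None:
            reference = read_gene_list(config.reference_list_path, name="reference")
        elif truth is not None:
            planted = {
                s: d
                for s, d in truth_gene_list(truth).items()
                if s in background
            }
            reference = GeneList(planted, name="planted")
        else:
            reference = None
        if reference is not None and len(reference) and len(discovered):
            ov = overlap_test(discovered, reference, background)
            n_agree, n_total, frac = (
                directional_agreement(discovered, reference)
                if discovered.is_signed and reference.is_signed
                else (None, None, None)
            )
            write_gene_list(discovered, outdir / "discovered_list.tsv")
            record(
                "overlap",
                observed=ov.observed,
                expected=ov.expected,
                p=ov.p,
                directional_agreement=frac,
            )
        else:
            record("overlap", skipped="no reference list or empty lists")

        # -- power equalization ----------------------------------------------
        counts = subsample_significance_counts(
            study,
            subset_size=config.resample_subset_size,
            iterations=config.resample_iterations,
            alpha=config.alpha,
            seed=config.stage_seed("resample"),
            stratified=config.stratified_resampling,
        )
        pd.DataFrame({"iteration": np.arange(len(counts)), "n_significant": counts}).to_csv(
            outdir / "resample_counts.tsv", sep="\t", index=False
        )
        comparison = (
            config.comparison_count
            if config.comparison_count is not None
            else len(sig)
        )
        try:
            fit = fit_gaussian_to_histogram(counts, bin_width=config.resample_bin_width)
            p_area = power_equalized_p(fit, comparison)
            record(
                "resample",
                seed=config.stage_seed("resample"),
                mean_count=float(counts.mean()),
                mu=fit.mu,
                sigma=fit.sigma,
                r_squared=fit.r_squared,
                comparison_count=comparison,
                p_area=p_area,
                empirical_quantile=empirical_quantile(counts, comparison),
            )
        except ValidationError as err:
            record("resample", mean_count=float(counts.mean()), fit_error=str(err))

        # -- enrichment -------------------------------------------------------
        if config.gene_sets_path is not None:
            gene_sets = read_gene_sets(config.gene_sets_path)
        elif truth is not None:
            rng = np.random.default_rng(config.stage_seed("simulate") + 1)
            gene_sets = _synthetic_gene_sets(truth, background, rng)
            write_gene_sets(gene_sets, outdir / "gene_sets.gmt")
        else:
            gene_sets = None
        if gene_sets is not None and len(discovered):
            enr = enrich(
                discovered,
                gene_sets,
                background,
                min_size=config.enrich_min_size,
                max_size=config.enrich_max_size,
            )
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            top = enr.iloc[0]["set_name"] if len(enr) else None
            record("enrich", n_sets_tested=len(enr), top_set=top)
        else:
            record("enrich", skipped="no gene sets or empty query")
    except Exception as err:
        stage = f"after {list(manifest['stages'])[-1]}" if manifest["stages"] else "start"
        raise RuntimeError(f"pipeline failed ({stage}): {err}") from err

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
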