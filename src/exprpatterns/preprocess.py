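"""Pre-statistical filtering, outlier masking, per-cohort standardization.

The filtering funnel keeps grade-'A' probe sets that map to exactly one
non-missing gene symbol and have a minimum number of presence (detection)
calls; when several probe sets share a symbol a single representative is
kept.  Outliers (cells beyond k SD of their treatment-group mean) are masked
as missing, and expression is then standardized to z-units separately within
each cohort, which removes additive per-cohort background shifts exactly
while retaining each cohort's variability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import ExpressionStudy, ValidationError


@dataclass(frozen=True)
class FilterReport:
    """Probe-set counts surviving each filtering stage, in order."""

    n_input: int
    n_grade_pass: int
    n_symbol_pass: int
    n_presence_pass: int

    def __post_init__(self) -> None:
        seq = (self.n_input, self.n_grade_pass, self.n_symbol_pass, self.n_presence_pass)
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise ValidationError(f"filter counts must be non-increasing: {seq}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "grade", "unique_symbol", "presence"],
                "n_genes": [
                    self.n_input,
                    self.n_grade_pass,
                    self.n_symbol_pass,
                    self.n_presence_pass,
                ],
            }
        )


def filter_probesets(
    study: ExpressionStudy,
    min_present: int = 6,
    presence_columns: np.ndarray | None = None,
) -> tuple[ExpressionStudy, FilterReport]:
    """Grade / unique-symbol / presence filtering funnel.

    Keeps genes that are grade 'A', carry a single non-missing symbol (when
    several probe sets share a symbol, the one with the most presence calls
    is kept, ties by higher mean signal then lexical probe_id), and have at
    least ``min_present`` presence calls.  ``presence_columns`` restricts the
    presence-call denominator to a subset of arrays (e.g. excluding
    stress-control chips); default is all samples.
    """
    n_cols = study.n_samples if presence_columns is None else len(presence_columns)
    if min_present > n_cols:
        raise ValidationError(
            f"min_present={min_present} exceeds the {n_cols} available samples"
        )
    genes = study.genes
    grade_ok = genes["grade"].astype(str) == "A"
    n_grade = int(grade_ok.sum())

    symbol = genes["symbol"]
    has_symbol = symbol.notna() & (symbol.astype(str).str.len() > 0)
    candidate = grade_ok & has_symbol

    n_present = study.n_present_per_gene(presence_columns)
    with np.errstate(invalid="ignore"):
        mean_signal = np.nanmean(study.values(), axis=1)

    # one representative probe set per symbol
    cand = pd.DataFrame(
        {
            "symbol": symbol[candidate],
            "n_present": n_present[candidate.to_numpy()],
            "mean_signal": mean_signal[candidate.to_numpy()],
        },
        index=genes.index[candidate],
    )
    # mergesort is stable, and the index is sorted lexically first so the
    # final tie-break is the lexically smallest probe_id
    cand = cand.loc[cand.index.sort_values()].sort_values(
        ["symbol", "n_present", "mean_signal"],
        ascending=[True, False, False],
        kind="mergesort",
    )
    representative = ~cand["symbol"].duplicated(keep="first")
    symbol_pass = pd.Index(cand.index[representative])
    n_symbol = len(symbol_pass)

    presence_ok = n_present >= min_present
    keep = symbol_pass[presence_ok[genes.index.get_indexer(symbol_pass)]]
    # preserve original gene order
    keep_mask = genes.index.isin(keep)
    filtered = study.subset_genes(np.flatnonzero(keep_mask))
    filtered.genes["n_present"] = n_present[keep_mask]
    report = FilterReport(
        n_input=study.n_genes,
        n_grade_pass=n_grade,
        n_symbol_pass=n_symbol,
        n_presence_pass=int(keep_mask.sum()),
    )
    return filtered, report


def mask_outliers(study: ExpressionStudy, k_sd: float = 2.0) -> ExpressionStudy:
    """Mask cells beyond ``k_sd`` sample SDs of their treatment-group mean.

    The group mean and SD include the candidate cell and the pass is not
    iterated.  Groups with zero SD mask nothing; genes left with fewer than
    2 unmasked values in some group are flagged ("low_n") on the returned
    study.
    """
    X = study.values()
    new_mask = study.mask.copy()
    for g, cols in study.group_columns().items():
        sub = X[:, cols]
        n = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.nansum(sub, axis=1) / n
            sd = np.sqrt(np.nansum((sub - m[:, None]) ** 2, axis=1) / (n - 1))
            outlier = np.abs(sub - m[:, None]) > k_sd * sd[:, None]
        outlier &= sd[:, None] > 0
        outlier &= ~np.isnan(sub)
        new_mask[:, cols] |= outlier
    out = replace(study, mask=new_mask, flags={k: set(v) for k, v in study.flags.items()})
    Xm = out.values()
    for g, cols in out.group_columns().items():
        n_ok = np.sum(~np.isnan(Xm[:, cols]), axis=1)
        for idx in np.flatnonzero(n_ok < 2):
            out.flag(str(out.probe_ids[idx]), "low_n")
    return out


def standardize_by_cohort(study: ExpressionStudy) -> ExpressionStudy:
    """Z-score each gene separately within each cohort, then recombine.

    Per gene and cohort, unmasked cells get (x - cohort mean) / cohort SD
    (sample SD over unmasked cells).  This removes any additive per-cohort,
    per-gene background shift exactly.  A gene with zero SD within a cohort
    has that cohort's cells set missing and is flagged ("zero_sd").
    """
    cohort_cols = study.cohort_columns()
    for c, cols in cohort_cols.items():
        if len(cols) < 2:
            raise ValidationError(f"cohort {c!r} has fewer than 2 samples")
    X = study.values()
    signal = study.signal.copy()
    new_mask = study.mask.copy()
    flagged = set()
    for c, cols in cohort_cols.items():
        sub = X[:, cols]
        n = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.nansum(sub, axis=1) / n
            sd = np.sqrt(np.nansum((sub - m[:, None]) ** 2, axis=1) / (n - 1))
            z = (sub - m[:, None]) / sd[:, None]
        degenerate = ~(sd > 0)
        z[degenerate] = np.nan
        flagged |= {str(p) for p in study.probe_ids[degenerate]}
        block = signal[:, cols]
        ok = ~np.isnan(z)
        block[ok] = z[ok]
        block[~ok] = np.nan
        signal[:, cols] = block
        new_mask[:, cols] |= ~ok
    out = replace(
        study,
        signal=signal,
        mask=new_mask,
        flags={k: set(v) for k, v in study.flags.items()},
    )
    for p in flagged:
        out.flag(p, "zero_sd")
    return out
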