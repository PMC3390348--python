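"""Core in-memory containers for grouped expression studies.

An :class:`ExpressionStudy` bundles a gene-by-sample signal matrix with
per-cell presence (detection) calls, a missing-value mask, gene annotations
and sample metadata (treatment group, cohort).  Downstream statistics consume
these objects only; file parsing lives in :mod:`exprpatterns.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

UP = "up"
DOWN = "down"
UNSIGNED = "unsigned"
DIRECTIONS = (UP, DOWN, UNSIGNED)


class ValidationError(ValueError):
    """A study, list or gene-set collection violates a structural invariant."""


@dataclass
class ExpressionStudy:
    """A gene x sample expression study.

    Parameters
    ----------
    genes
        DataFrame indexed by ``probe_id`` with at least columns ``symbol``
        (nullable string) and ``grade``; ``n_present`` is maintained from the
        presence matrix.
    samples
        DataFrame indexed by ``sample_id`` with columns ``group`` and
        ``cohort``.
    signal
        Float matrix, one row per gene, one column per sample.  Arbitrary
        intensity units, or z-units after cohort standardization.
    present
        Boolean matrix of detection ("presence") calls, same shape.
    mask
        Boolean matrix, True where a cell is treated as missing.
    group_order
        Ordered treatment groups as declared by the study design
        (e.g. home cage < 24 h deprivation < 72 h deprivation).
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    signal: np.ndarray
    present: np.ndarray
    mask: np.ndarray
    group_order: tuple[str, ...]
    flags: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.group_order = tuple(self.group_order)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def probe_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    def validate(self) -> None:
        shape = (self.n_genes, self.n_samples)
        for name in ("signal", "present", "mask"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValidationError(
                    f"{name} matrix has shape {arr.shape}, expected "
                    f"{shape} (genes x samples)"
                )
        if self.genes.index.has_duplicates:
            dup = self.genes.index[self.genes.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id: {dup!r}")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        unknown = set(self.samples["group"]) - set(self.group_order)
        if unknown:
            raise ValidationError(
                f"sample groups {sorted(unknown)} not in declared group "
                f"order {list(self.group_order)}"
            )
        if np.isnan(self.signal[~self.mask]).any():
            raise ValidationError("NaN signal in unmasked cells")

    # -- convenience -------------------------------------------------------

    def values(self) -> np.ndarray:
        """Signal with masked cells replaced by NaN (copy)."""
        out = self.signal.copy()
        out[self.mask] = np.nan
        return out

    def group_columns(self) -> dict[str, np.ndarray]:
        """Column indices per group, in declared group order."""
        groups = self.samples["group"].to_numpy()
        return {
            g: np.flatnonzero(groups == g)
            for g in self.group_order
            if (groups == g).any()
        }

    def cohort_columns(self) -> dict[str, np.ndarray]:
        cohorts = self.samples["cohort"].astype(str).to_numpy()
        return {c: np.flatnonzero(cohorts == c) for c in pd.unique(cohorts)}

    def n_present_per_gene(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Presence-call counts per gene over ``columns`` (default: all)."""
        pres = self.present if columns is None else self.present[:, columns]
        return pres.sum(axis=1)

    def subset_genes(self, keep: np.ndarray | pd.Index) -> "ExpressionStudy":
        if isinstance(keep, pd.Index):
            keep = self.genes.index.get_indexer(keep)
        return replace(
            self,
            genes=self.genes.iloc[keep].copy(),
            signal=self.signal[keep],
            present=self.present[keep],
            mask=self.mask[keep],
        )

    def subset_samples(self, cols: np.ndarray) -> "ExpressionStudy":
        cols = np.asarray(cols)
        return replace(
            self,
            samples=self.samples.iloc[cols].copy(),
            signal=self.signal[:, cols],
            present=self.present[:, cols],
            mask=self.mask[:, cols],
        )

    def flag(self, probe_id: str, reason: str) -> None:
        self.flags.setdefault(reason, set()).add(probe_id)


@dataclass(frozen=True)
class GeneList:
    """A set of gene symbols, each carrying a direction of change.

    ``entries`` maps symbol -> direction in {"up", "down", "unsigned"}.
    """

    entries: dict[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        bad = {d for d in self.entries.values() if d not in DIRECTIONS}
        if bad:
            raise ValidationError(f"invalid directions: {sorted(bad)}")

    @classmethod
    def from_symbols(cls, symbols, direction: str = UNSIGNED, name: str = "") -> "GeneList":
        return cls({s: direction for s in symbols}, name=name)

    @property
    def symbols(self) -> frozenset:
        return frozenset(self.entries)

    @property
    def is_signed(self) -> bool:
        return all(d != UNSIGNED for d in self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries

    def direction(self, symbol: str) -> str:
        return self.entries[symbol]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. functional categories) with descriptions."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValidationError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())
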