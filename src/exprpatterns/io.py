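"""Readers and writers for the study file set.

All interchange is plain TSV (UTF-8, '.' decimal): an expression matrix whose
first column is the probe id, a sample metadata table (sample_id, group,
cohort), a gene annotation table (probe_id, symbol, grade), an optional
presence matrix of P/A characters, signed gene lists, and GMT gene sets.
Missing signal values are serialized as empty cells; the mask is regenerated
on read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datamodel import ExpressionStudy, GeneList, GeneSetCollection, ValidationError


def read_expression_study(
    matrix_path,
    metadata_path,
    annotation_path,
    presence_path=None,
    group_order: tuple[str, ...] | None = None,
) -> ExpressionStudy:
    """Assemble a validated :class:`ExpressionStudy` from its TSV file set.

    ``group_order`` defaults to order of first appearance in the metadata.
    Raises :class:`ValidationError` naming the offending axis on any
    dimension or identifier mismatch.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata must have a sample_id column")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample_id in metadata: {dup!r}")
    meta = meta.set_index("sample_id")
    missing = [c for c in matrix.columns if c not in meta.index]
    if missing:
        raise ValidationError(
            f"matrix columns absent from metadata: {missing} (samples axis)"
        )
    extra = [s for s in meta.index if s not in matrix.columns]
    if extra:
        raise ValidationError(
            f"metadata samples absent from matrix: {extra} (samples axis)"
        )
    meta = meta.loc[list(matrix.columns)]

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str).set_index("probe_id")
    missing_g = [p for p in matrix.index if p not in ann.index]
    if missing_g:
        raise ValidationError(
            f"matrix probes absent from annotation: {missing_g[:5]} (genes axis)"
        )
    ann = ann.loc[list(matrix.index)]

    signal = matrix.to_numpy(dtype=float)
    mask = np.isnan(signal)

    if presence_path is not None and os.path.exists(str(presence_path)):
        pres_df = pd.read_csv(presence_path, sep="\t", index_col=0, dtype=str)
        if pres_df.shape != matrix.shape:
            raise ValidationError(
                f"presence matrix shape {pres_df.shape} != signal shape "
                f"{matrix.shape}"
            )
        present = pres_df.to_numpy() == "P"
    else:
        present = np.ones_like(mask, dtype=bool)

    ann = ann.copy()
    ann["n_present"] = present.sum(axis=1)
    if group_order is None:
        group_order = tuple(pd.unique(meta["group"]))
    return ExpressionStudy(
        genes=ann,
        samples=meta,
        signal=signal,
        present=present,
        mask=mask,
        group_order=group_order,
    )


def write_expression_study(study: ExpressionStudy, prefix) -> dict[str, str]:
    """Write the matrix/metadata/annotation/presence TSV set.

    Returns a dict of logical name -> path. Masked cells are written as empty
    fields.
    """
    prefix = str(prefix)
    paths = {
        "matrix": prefix + ".matrix.tsv",
        "metadata": prefix + ".samples.tsv",
        "annotation": prefix + ".genes.tsv",
        "presence": prefix + ".presence.tsv",
    }
    values = study.values()
    pd.DataFrame(values, index=study.probe_ids, columns=study.sample_ids).to_csv(
        paths["matrix"], sep="\t", index_label="probe_id"
    )
    study.samples.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    cols = [c for c in ("symbol", "grade") if c in study.genes.columns]
    study.genes[cols].to_csv(paths["annotation"], sep="\t", index_label="probe_id")
    pres = np.where(study.present, "P", "A")
    pd.DataFrame(pres, index=study.probe_ids, columns=study.sample_ids).to_csv(
        paths["presence"], sep="\t", index_label="probe_id"
    )
    return paths


def read_gene_sets(gmt_path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB member TAB member...``"""
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{gmt_path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *members = fields
            sets[name] = frozenset(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gene_list(path, name: str = "") -> GeneList:
    """Read a signed gene list TSV with columns symbol, direction."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "direction" not in df.columns:
        df["direction"] = "unsigned"
    return GeneList(dict(zip(df["symbol"], df["direction"])), name=name)


def write_gene_list(gene_list: GeneList, path) -> None:
    df = pd.DataFrame(
        sorted(gene_list.entries.items()), columns=["symbol", "direction"]
    )
    df.to_csv(path, sep="\t", index=False)


def write_gene_table(rows: pd.DataFrame, path) -> None:
    """Write a per-gene results table as TSV with a deterministic row order.

    Rows are ordered by ascending p-value, ties broken by symbol
    (alphabetical).  An empty frame yields a header-only file.
    """
    rows = rows.copy()
    sort_cols = [c for c in ("p", "symbol") if c in rows.columns]
    if sort_cols:
        rows = rows.sort_values(sort_cols, kind="mergesort")
    rows.to_csv(path, sep="\t", index=False)
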