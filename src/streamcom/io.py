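"""Readers and writers for the pipeline's external file formats.

All tabular formats are UTF-8 TSV with "." as the decimal separator; trees
are Newick with branch lengths. Count tables may be stored either samples x
taxa or taxa x samples — the orientation is declared at read time and
normalized to samples x taxa internally.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .containers import (
    AlignedBundle,
    CountTable,
    ParseError,
    Phylogeny,
    ValidationError,
    validate_metadata,
    validate_taxonomy,
)

logger = logging.getLogger("streamcom")

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_tree",
    "write_tree",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "align_inputs",
]


def read_count_table(path: str | Path, orientation: str = "samples") -> CountTable:
    """Read a TSV abundance matrix.

    Parameters
    ----------
    path : path-like
        TSV file whose first row and first column are identifiers.
    orientation : {"samples", "taxa"}
        What the *rows* of the file are. Taxa-as-rows input is transposed so
        the returned table is always samples x taxa.
    """
    if orientation not in ("samples", "taxa"):
        raise ValueError("orientation must be 'samples' or 'taxa'")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot read count table {path}: {exc}") from exc
    df.index = df.index.astype(str)
    # numeric coercion with located errors happens inside CountTable
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        rows, cols = bad.to_numpy().nonzero()
        r, c = rows[0], cols[0]
        raise ParseError(
            f"non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    if orientation == "taxa":
        numeric = numeric.T
    return CountTable(numeric)


def write_count_table(table: CountTable, path: str | Path, orientation: str = "samples") -> None:
    """Write a count table as TSV; full float precision so values round-trip."""
    if orientation not in ("samples", "taxa"):
        raise ValueError("orientation must be 'samples' or 'taxa'")
    df = table.data if orientation == "samples" else table.data.T
    if table.is_integer:
        df = df.astype("int64")
    df.to_csv(path, sep="\t", index_label="id")


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    text = Path(path).read_text()
    return Phylogeny.from_newick(text)


def write_tree(phylogeny: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phylogeny.to_newick())


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV (columns: taxon_id, domain...genus)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return validate_taxonomy(df)


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    tax.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV.

    Mandatory columns: sample_id, site_id, stream_type, season, year,
    latitude, longitude. Any further numeric column is carried along as an
    environmental variable.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def align_inputs(
    table: CountTable,
    tree: Phylogeny,
    tax: pd.DataFrame,
    meta: pd.DataFrame,
) -> AlignedBundle:
    """Restrict all inputs to their shared identifiers.

    Taxa are intersected with the tree's tips and the taxonomy table;
    samples are intersected with the metadata. Identifier matching is exact
    and case-sensitive. Dropped counts are recorded on the returned bundle
    and logged. Applying the operation twice is a no-op.
    """
    taxa_keep = [
        t for t in table.taxon_ids if t in set(tree.tip_names) and t in tax.index
    ]
    samples_keep = [s for s in table.sample_ids if s in meta.index]
    if not taxa_keep:
        raise ValidationError("no taxa shared between count table, tree, and taxonomy")
    if not samples_keep:
        raise ValidationError("no samples shared between count table and metadata")
    dropped_taxa = [t for t in table.taxon_ids if t not in set(taxa_keep)]
    dropped_samples = [s for s in table.sample_ids if s not in set(samples_keep)]
    aligned_table = table.select_samples(samples_keep).select_taxa(taxa_keep)
    aligned_tree = tree.shear(taxa_keep) if set(tree.tip_names) != set(taxa_keep) else tree
    bundle = AlignedBundle(
        table=aligned_table,
        tree=aligned_tree,
        taxonomy=tax.loc[taxa_keep],
        metadata=meta.loc[samples_keep],
        n_taxa_dropped=len(dropped_taxa),
        n_samples_dropped=len(dropped_samples),
        dropped_taxa=dropped_taxa,
        dropped_samples=dropped_samples,
    )
    if dropped_taxa or dropped_samples:
        logger.info(
            "align_inputs dropped %d taxa and %d samples",
            len(dropped_taxa),
            len(dropped_samples),
        )
    return bundle
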