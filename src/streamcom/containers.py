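"""Validated in-memory containers shared across the pipeline.

The pipeline moves three kinds of objects around: a samples x taxa count
table, a rooted phylogeny whose tips are taxon identifiers, and per-sample
metadata (site, stream type, season, coordinates, environmental variables).
Each container validates its invariants on construction so downstream
operations can assume well-formed input.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("streamcom")

#: Closed vocabulary of stream types in a river-lake network: headwater
#: tributaries, streams connecting cascading lakes, and the terminal outflow.
STREAM_TYPES = ("tributary", "interlake", "korana")

#: Sampling seasons covered by the study design.
SEASONS = ("spring", "summer", "winter")

#: Taxonomic ranks carried by a taxonomy table, coarsest first.
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Mandatory metadata columns; everything numeric beyond these is treated as
#: an environmental variable.
METADATA_REQUIRED = (
    "sample_id",
    "site_id",
    "stream_type",
    "season",
    "year",
    "latitude",
    "longitude",
)


class ValidationError(ValueError):
    """An input violates a container invariant."""


class ParseError(ValueError):
    """A file could not be parsed into a container."""


class VocabularyError(ValidationError):
    """A categorical field holds a token outside its closed vocabulary."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


class CountTable:
    """A samples x taxa abundance matrix with unique string identifiers.

    Counts may be raw integers (reads) or non-negative reals (e.g. after
    cumulative-sum-scaling normalization). Rows are always samples; readers
    transpose taxa-as-rows input at parse time so only one orientation exists
    internally.

    Parameters
    ----------
    data : pandas.DataFrame
        Abundances with sample identifiers as the index and taxon
        identifiers as the columns.
    """

    def __init__(self, data: pd.DataFrame, *, copy: bool = True):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("CountTable expects a pandas DataFrame")
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise ValidationError("count table must have at least one sample and one taxon")
        _check_unique([str(s) for s in data.index], "sample")
        _check_unique([str(t) for t in data.columns], "taxon")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            # locate the first offending cell for a useful message
            for j, col in enumerate(data.columns):
                coerced = pd.to_numeric(data.iloc[:, j], errors="coerce")
                bad = coerced.isna() & data.iloc[:, j].notna()
                if bad.any():
                    i = int(np.argmax(bad.to_numpy()))
                    raise ParseError(
                        f"non-numeric value {data.iat[i, j]!r} at sample "
                        f"{data.index[i]!r}, taxon {col!r}"
                    )
            raise ParseError("count table contains non-numeric values")
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ParseError(
                f"missing value at sample {data.index[i]!r}, taxon {data.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance {values[i, j]} at sample "
                f"{data.index[i]!r}, taxon {data.columns[j]!r}"
            )
        df = data.copy() if copy else data
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        self._df = df

    # -- basic accessors -------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        """The underlying samples x taxa DataFrame (do not mutate)."""
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    @property
    def is_integer(self) -> bool:
        """True when every cell is a whole number (raw read counts)."""
        v = self._df.to_numpy()
        return bool(np.all(np.equal(np.mod(v, 1), 0)))

    def sample_sums(self) -> pd.Series:
        return self._df.sum(axis=1)

    def taxon_sums(self) -> pd.Series:
        return self._df.sum(axis=0)

    def select_samples(self, ids: Iterable[str]) -> "CountTable":
        return CountTable(self._df.loc[list(ids)])

    def select_taxa(self, ids: Iterable[str]) -> "CountTable":
        return CountTable(self._df.loc[:, list(ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"<CountTable: {n} samples x {m} taxa>"


class Phylogeny:
    """A rooted tree with non-negative branch lengths and unique tip labels.

    Thin wrapper around :class:`skbio.TreeNode` that enforces the invariants
    phylogenetic operations rely on and caches the patristic (tip-to-tip
    path length) distance matrix.

    Branches lacking a length are assigned length 0 with a logged warning so
    patristic distances remain defined on permissively written Newick files.
    """

    def __init__(self, tree: TreeNode):
        tips = [t.name for t in tree.tips()]
        if len(tips) < 2:
            raise ValidationError("phylogeny must have at least two tips")
        if any(t is None for t in tips):
            raise ValidationError("phylogeny has unnamed tips")
        _check_unique(tips, "tip")
        n_missing = 0
        for node in tree.traverse(include_self=True):
            if node.length is None:
                node.length = 0.0
                n_missing += 1
            elif node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} at node {node.name!r}"
                )
        if n_missing:
            logger.warning("assigned length 0 to %d branches lacking lengths", n_missing)
        self._tree = tree
        self._patristic: pd.DataFrame | None = None

    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a Newick string (not a path; see :func:`streamcom.io.read_tree`)."""
        try:
            tree = TreeNode.read(_io.StringIO(source), format="newick")
        except Exception as exc:  # skbio raises several parser error types
            raise ParseError(f"unparseable Newick: {exc}") from exc
        return cls(tree)

    @property
    def tree(self) -> TreeNode:
        return self._tree

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self._tree.tips()]

    def patristic(self, taxa: Sequence[str] | None = None) -> pd.DataFrame:
        """Symmetric matrix of tip-to-tip path lengths.

        Parameters
        ----------
        taxa : sequence of str, optional
            Restrict (and order) the matrix to these tips.
        """
        if self._patristic is None:
            dm = self._tree.tip_tip_distances()
            self._patristic = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        if taxa is None:
            return self._patristic
        missing = set(taxa) - set(self._patristic.index)
        if missing:
            raise ValidationError(f"taxa absent from phylogeny: {sorted(missing)[:5]}")
        return self._patristic.loc[list(taxa), list(taxa)]

    def shear(self, taxa: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to the given tips (prunes internal structure)."""
        taxa = list(taxa)
        sheared = self._tree.copy().shear(taxa)
        return Phylogeny(sheared)

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self._tree.write(buf, format="newick")
        return buf.getvalue()

    def __repr__(self) -> str:
        return f"<Phylogeny: {len(self.tip_names)} tips>"


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame and return it indexed by sample_id.

    Checks the closed stream-type/season vocabularies, coordinate ranges,
    identifier uniqueness, and numeric environment columns.
    """
    df = df.copy()
    if df.index.name == "sample_id":
        df = df.reset_index()
    for col in METADATA_REQUIRED:
        if col not in df.columns:
            raise ValidationError(f"metadata missing required column {col!r}")
    _check_unique([str(s) for s in df["sample_id"]], "sample")
    bad_type = set(df["stream_type"]) - set(STREAM_TYPES)
    if bad_type:
        raise VocabularyError(
            f"unknown stream_type token(s) {sorted(bad_type)}; expected one of {STREAM_TYPES}"
        )
    bad_season = set(df["season"]) - set(SEASONS)
    if bad_season:
        raise VocabularyError(
            f"unknown season token(s) {sorted(bad_season)}; expected one of {SEASONS}"
        )
    for col in ("latitude", "longitude", "year"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-numeric value in metadata column {col!r}") from exc
    if (df["latitude"].abs() > 90).any():
        raise ValidationError("latitude outside [-90, 90]")
    if (df["longitude"].abs() > 180).any():
        raise ValidationError("longitude outside [-180, 180]")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    for col in environment_columns(df):
        df[col] = pd.to_numeric(df[col])
    return df


def environment_columns(meta: pd.DataFrame) -> list[str]:
    """Names of the environmental-variable columns of a metadata frame."""
    fixed = set(METADATA_REQUIRED) | {"sample_id"}
    return [
        c
        for c in meta.columns
        if c not in fixed and pd.api.types.is_numeric_dtype(pd.to_numeric(meta[c], errors="coerce"))
        and not pd.to_numeric(meta[c], errors="coerce").isna().all()
    ]


def validate_taxonomy(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a taxonomy table (taxon_id + ranked lineage) and index it."""
    df = df.copy()
    if df.index.name == "taxon_id":
        df = df.reset_index()
    if "taxon_id" not in df.columns:
        raise ValidationError("taxonomy missing required column 'taxon_id'")
    _check_unique([str(t) for t in df["taxon_id"]], "taxon")
    for rank in TAXONOMY_RANKS:
        if rank not in df.columns:
            df[rank] = ""
    df["taxon_id"] = df["taxon_id"].astype(str)
    df = df.set_index("taxon_id")
    df = df[list(TAXONOMY_RANKS)].fillna("").astype(str)
    return df


@dataclass
class AlignedBundle:
    """Inputs restricted to their common identifiers, plus a drop log."""

    table: CountTable
    tree: Phylogeny
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    n_taxa_dropped: int = 0
    n_samples_dropped: int = 0
    dropped_taxa: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)
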