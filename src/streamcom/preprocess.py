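"""Count-table preprocessing: taxonomy filters, rarity filters, rarefaction,
and cumulative sum scaling (CSS) normalization.

The intended order in the full pipeline is: taxonomy filter (drop organellar
and phylum-unassigned reads) -> global rarity filter (drop singleton and
doubleton taxa) -> low-depth sample filter -> then either (A) rarefaction to
a common depth for diversity and null-model work, or (B) CSS normalization
for distance-decay analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountTable, ValidationError

logger = logging.getLogger("streamcom")

#: Lineage terms whose presence anywhere in a taxon's ranked lineage marks it
#: as non-target for a 16S amplicon survey.
DEFAULT_EXCLUDE_TERMS = ("Eukaryota", "Mitochondria", "Chloroplast")


@dataclass
class FilterReport:
    """Accounting of what a filtering step removed and why."""

    step: str
    n_taxa_removed: int = 0
    n_samples_removed: int = 0
    removed_taxa: list[str] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [("taxon", t) for t in self.removed_taxa] + [
            ("sample", s) for s in self.removed_samples
        ]
        return pd.DataFrame(rows, columns=["kind", "identifier"]).assign(step=self.step)


def filter_by_taxonomy(
    table: CountTable,
    tax: pd.DataFrame,
    exclude_terms: tuple[str, ...] = DEFAULT_EXCLUDE_TERMS,
) -> tuple[CountTable, FilterReport]:
    """Remove taxa whose lineage matches an exclusion term or lacks a phylum.

    A taxon is removed when any rank of its lineage equals any of
    ``exclude_terms`` (exact, case-sensitive match on the rank value), or
    when its phylum rank is empty (unassigned at phylum level).
    """
    exclude = set(exclude_terms)
    removed: list[str] = []
    for taxon in table.taxon_ids:
        if taxon not in tax.index:
            continue
        lineage = tax.loc[taxon]
        if exclude & set(lineage.values) or lineage.get("phylum", "") == "":
            removed.append(taxon)
    keep = [t for t in table.taxon_ids if t not in set(removed)]
    report = FilterReport(
        step="taxonomy",
        n_taxa_removed=len(removed),
        removed_taxa=removed,
        thresholds={"exclude_terms": sorted(exclude)},
    )
    if not keep:
        logger.warning("taxonomy filter removed every taxon")
        # empty tables are invalid; signal via report but raise for clarity
        raise ValidationError("taxonomy filter removed all taxa")
    return table.select_taxa(keep), report


def filter_rare(table: CountTable, max_total: int = 2) -> tuple[CountTable, FilterReport]:
    """Remove globally rare taxa (summed count across all samples <= max_total).

    With the default threshold of 2 this removes singletons and doubletons,
    judged on the whole dataset rather than per sample. Requires raw integer
    counts — the rule is meaningless on normalized data.
    """
    if not table.is_integer:
        raise ValidationError("rarity filter is defined on raw integer counts")
    sums = table.taxon_sums()
    removed = [t for t in table.taxon_ids if sums[t] <= max_total]
    keep = [t for t in table.taxon_ids if sums[t] > max_total]
    if not keep:
        raise ValidationError("rarity filter removed all taxa")
    report = FilterReport(
        step="rare",
        n_taxa_removed=len(removed),
        removed_taxa=removed,
        thresholds={"max_total": max_total},
    )
    return table.select_taxa(keep), report


def filter_low_depth_samples(
    table: CountTable, min_reads: int = 1000
) -> tuple[CountTable, FilterReport]:
    """Remove samples whose library size (row sum) is below ``min_reads``."""
    sums = table.sample_sums()
    removed = [s for s in table.sample_ids if sums[s] < min_reads]
    keep = [s for s in table.sample_ids if sums[s] >= min_reads]
    if not keep:
        raise ValidationError(f"all samples fall below min_reads={min_reads}")
    report = FilterReport(
        step="depth",
        n_samples_removed=len(removed),
        removed_samples=removed,
        thresholds={"min_reads": min_reads},
    )
    return table.select_samples(keep), report


def rarefy(table: CountTable, depth: int | None = None, seed: int = 0) -> CountTable:
    """Subsample every sample to the same depth, without replacement.

    Each sample's reads are drawn without replacement (multivariate
    hypergeometric), so a sample already at the target depth is returned
    unchanged. Taxa that end up with all-zero columns are retained to keep
    dimensions stable; their ids are logged.

    Parameters
    ----------
    depth : int, optional
        Target library size. Defaults to the smallest library size in the
        table (rarefaction to the minimum).
    seed : int
        Seed for the subsampling RNG; fixed seed gives identical output.
    """
    if not table.is_integer:
        raise ValidationError("rarefaction is defined on raw integer counts")
    sums = table.sample_sums()
    if depth is None:
        depth = int(sums.min())
    depth = int(depth)
    too_small = sums[sums < depth]
    if len(too_small):
        raise ValidationError(
            f"depth {depth} exceeds library size of sample(s) "
            f"{list(too_small.index[:5])}"
        )
    rng = np.random.default_rng(seed)
    counts = table.values.astype(np.int64)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    result = pd.DataFrame(out, index=table.sample_ids, columns=table.taxon_ids)
    zero_cols = result.columns[(result.sum(axis=0) == 0)]
    if len(zero_cols):
        logger.info("rarefaction left %d taxa with zero total count", len(zero_cols))
    return CountTable(result)


def _lower_quantile(sorted_values: np.ndarray, q: float) -> float:
    """Empirical q-th quantile, lower (type-1) convention, on sorted input."""
    n = len(sorted_values)
    k = int(np.ceil(q * n)) - 1
    return float(sorted_values[max(k, 0)])


def css_normalize(
    table: CountTable, quantile: float = 0.5
) -> tuple[CountTable, pd.Series]:
    """Cumulative sum scaling normalization.

    For each sample j the scaling factor ``s_j`` is the sum of its counts
    over taxa whose nonzero count is <= the empirical q-th quantile (lower
    convention) of that sample's nonzero counts. Normalized values are
    ``c_ij / s_j * K`` with ``K`` the median of the scaling factors, so a
    typical sample keeps its scale. Zero counts stay zero.

    Returns the normalized table and the per-sample scaling factors.
    """
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    if not table.is_integer:
        raise ValidationError("CSS is defined on raw integer counts")
    counts = table.values.astype(float)
    factors = np.empty(counts.shape[0])
    for i, row in enumerate(counts):
        nz = np.sort(row[row > 0])
        if len(nz) == 0:
            raise ValidationError(f"sample {table.sample_ids[i]!r} has all-zero counts")
        qval = _lower_quantile(nz, quantile)
        factors[i] = row[(row > 0) & (row <= qval)].sum()
    scale = float(np.median(factors))
    normalized = counts / factors[:, None] * scale
    out = CountTable(
        pd.DataFrame(normalized, index=table.sample_ids, columns=table.taxon_ids)
    )
    return out, pd.Series(factors, index=table.sample_ids, name="css_factor")


def to_relative_abundance(table: CountTable) -> CountTable:
    """Scale each sample to sum to 1."""
    sums = table.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(f"zero-sum sample(s): {list(zero.index[:5])}")
    rel = table.data.div(sums, axis=0)
    return CountTable(rel)
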