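"""Distance-decay biogeography and abundance-occupancy core detection.

Geographic distances are geodesics on the WGS-84 ellipsoid computed with
Vincenty's inverse method, in meters. The distance-decay relationship (DDR)
is an ordinary least-squares fit of pairwise community similarity
(1 - Bray-Curtis, on CSS-normalized abundances) against pairwise geodesic
distance. Core-microbiome detection follows the abundance-occupancy
framing: a taxon's occupancy (fraction of samples where it is detected) is
plotted against the log10 of its mean relative abundance, and taxa with
occupancy 1 constitute the core.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CountTable, ValidationError
from .diversity import bray_curtis

__all__ = [
    "vincenty_distance",
    "geodesic_matrix",
    "ddr",
    "DdrFit",
    "abundance_occupancy",
    "core_coverage",
    "venn_partition",
]

# WGS-84 ellipsoid
_WGS84_A = 6378137.0
_WGS84_F = 1 / 298.257223563
_WGS84_B = _WGS84_A * (1 - _WGS84_F)


def vincenty_distance(
    lat1: float,
    lon1: float,
    lat2: float,
    lon2: float,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Geodesic distance in meters between two WGS-84 points (Vincenty inverse).

    Iterates the longitude-difference update to ``tol`` (radians). Raises for
    the nearly antipodal pairs where Vincenty's method fails to converge.
    """
    for lat in (lat1, lat2):
        if abs(lat) > 90:
            raise ValidationError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if abs(lon) > 180:
            raise ValidationError(f"longitude {lon} outside [-180, 180]")
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    u1 = math.atan((1 - _WGS84_F) * math.tan(math.radians(lat1)))
    u2 = math.atan((1 - _WGS84_F) * math.tan(math.radians(lat2)))
    big_l = math.radians(lon2 - lon1)
    sin_u1, cos_u1 = math.sin(u1), math.cos(u1)
    sin_u2, cos_u2 = math.sin(u2), math.cos(u2)

    lam = big_l
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cos_u2 * sin_lam, cos_u1 * sin_u2 - sin_u1 * cos_u2 * cos_lam
        )
        if sin_sigma == 0:
            return 0.0  # coincident points
        cos_sigma = sin_u1 * sin_u2 + cos_u1 * cos_u2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cos_u1 * cos_u2 * sin_lam / sin_sigma
        cos2_alpha = 1 - sin_alpha**2
        if cos2_alpha == 0:  # equatorial line
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2 * sin_u1 * sin_u2 / cos2_alpha
        c = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = big_l + (1 - c) * _WGS84_F * sin_alpha * (
            sigma
            + c
            * sin_sigma
            * (cos_2sigma_m + c * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        raise ValidationError(
            "Vincenty iteration failed to converge (nearly antipodal pair "
            f"({lat1}, {lon1}) - ({lat2}, {lon2}))"
        )

    u_sq = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    big_a = 1 + u_sq / 16384 * (4096 + u_sq * (-768 + u_sq * (320 - 175 * u_sq)))
    big_b = u_sq / 1024 * (256 + u_sq * (-128 + u_sq * (74 - 47 * u_sq)))
    delta_sigma = (
        big_b
        * sin_sigma
        * (
            cos_2sigma_m
            + big_b
            / 4
            * (
                cos_sigma * (-1 + 2 * cos_2sigma_m**2)
                - big_b
                / 6
                * cos_2sigma_m
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos_2sigma_m**2)
            )
        )
    )
    return _WGS84_B * big_a * (sigma - delta_sigma)


def geodesic_matrix(meta: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise geodesic distances (m) between samples."""
    ids = samples if samples is not None else list(meta.index)
    n = len(ids)
    out = np.zeros((n, n))
    coords = meta.loc[ids, ["latitude", "longitude"]].to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = vincenty_distance(*coords[i], *coords[j])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


@dataclass
class DdrFit:
    """OLS summary of a distance-decay regression (similarity per meter)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    subset: str


def ddr(
    table_css: CountTable,
    meta: pd.DataFrame,
    subset: list[str] | None = None,
    subset_label: str = "all",
) -> tuple[DdrFit, pd.DataFrame]:
    """Distance-decay regression of community similarity on geodesic distance.

    Parameters
    ----------
    table_css : CountTable
        CSS-normalized (or otherwise comparable) abundances.
    subset : list of sample ids, optional
        Restrict the regression to these samples (e.g. the longest-flow
        tributary plus all interlake and outflow samples). Default: all
        samples with metadata.

    Returns the fit and a per-pair frame (sample_a, sample_b, distance_m,
    similarity).
    """
    ids = subset if subset is not None else [s for s in table_css.sample_ids if s in meta.index]
    if len(ids) < 3:
        raise ValidationError("DDR needs at least 3 samples")
    sub = table_css.select_samples(ids)
    bc = bray_curtis(sub).data
    dist = geodesic_matrix(meta, ids)
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        rows.append(
            {
                "sample_a": ids[i],
                "sample_b": ids[j],
                "distance_m": dist.iat[i, j],
                "similarity": 1 - bc[i, j],
            }
        )
    pairs = pd.DataFrame(rows)
    if pairs["distance_m"].nunique() == 1:
        raise ValidationError("all pairwise distances identical; DDR regressor is degenerate")
    fit = sps.linregress(pairs["distance_m"], pairs["similarity"])
    return (
        DdrFit(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2),
            p_value=float(fit.pvalue),
            n_pairs=len(pairs),
            subset=subset_label,
        ),
        pairs,
    )


def abundance_occupancy(table_rel: CountTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon occupancy, log10 mean relative abundance, and membership class.

    Occupancy is the fraction of samples in which a taxon is detected
    (abundance > 0) — invariant under any positive rescaling of abundances.
    The abundance axis is log10 of the taxon's mean relative abundance over
    *all* samples (zeros included in the mean). Membership:

    - ``core``: occupancy exactly 1 (found in every sample);
    - ``unique_<type>``: detected in exactly one stream type;
    - ``shared_two`` / ``shared_three``: detected in two / all three stream
      types without reaching full occupancy.
    """
    if table_rel.shape[1] == 0:
        raise ValidationError("empty table")
    ids = [s for s in table_rel.sample_ids if s in meta.index]
    data = table_rel.data.loc[ids]
    present = data > 0
    occupancy = present.mean(axis=0)
    mean_ab = data.mean(axis=0)
    stream = meta.loc[ids, "stream_type"]
    rows = []
    for taxon in data.columns:
        types = sorted(set(stream[present[taxon]]))
        occ = float(occupancy[taxon])
        if occ == 1.0:
            membership = "core"
        elif len(types) == 1:
            membership = f"unique_{types[0]}"
        elif len(types) == 2:
            membership = "shared_two"
        elif len(types) == 3:
            membership = "shared_three"
        else:
            membership = "absent"
        with np.errstate(divide="ignore"):
            log_ab = float(np.log10(mean_ab[taxon])) if mean_ab[taxon] > 0 else -np.inf
        rows.append(
            {
                "taxon_id": taxon,
                "occupancy": occ,
                "log_mean_relative_abundance": log_ab,
                "membership": membership,
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def core_coverage(
    table_rel: CountTable,
    core_taxa: list[str],
    meta: pd.DataFrame,
    group_by: str = "stream_type",
) -> pd.Series:
    """Summed relative abundance of core taxa, averaged per group of samples."""
    ids = [s for s in table_rel.sample_ids if s in meta.index]
    core = [t for t in core_taxa if t in table_rel.data.columns]
    per_sample = (
        table_rel.data.loc[ids, core].sum(axis=1)
        if core
        else pd.Series(0.0, index=ids)
    )
    groups = meta.loc[ids, group_by]
    return per_sample.groupby(groups).mean().rename("core_coverage")


def venn_partition(
    table: CountTable, meta: pd.DataFrame, group_field: str = "stream_type"
) -> dict[str, int]:
    """Counts of taxa in the 7 regions of the three-group presence partition.

    Keys are sorted group names joined by "&" (e.g. ``"interlake&tributary"``
    for taxa found in exactly those two groups). Counts are disjoint and sum
    to the number of detected taxa.
    """
    ids = [s for s in table.sample_ids if s in meta.index]
    groups = meta.loc[ids, group_field]
    levels = sorted(set(groups))
    if len(levels) != 3:
        raise ValidationError(
            f"venn_partition needs exactly 3 groups, got {len(levels)}: {levels}"
        )
    present = table.data.loc[ids] > 0
    presence_by_group = {
        g: present.loc[groups[groups == g].index].any(axis=0) for g in levels
    }
    regions = {}
    for r in range(1, 4):
        for combo in itertools.combinations(levels, r):
            in_these = np.logical_and.reduce(
                [presence_by_group[g].to_numpy() for g in combo]
            )
            out_those = [presence_by_group[g].to_numpy() for g in levels if g not in combo]
            if out_those:
                in_these = in_these & ~np.logical_or.reduce(out_those)
            regions["&".join(combo)] = int(in_these.sum())
    return regions
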