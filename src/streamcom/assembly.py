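"""Phylogenetic and compositional null models for community assembly.

The inference chain: for every pair of communities compute the between-
sample mean nearest taxon distance (betaMNTD); standardize it against a
taxon-shuffle null to get the beta nearest taxon index (betaNTI); where
|betaNTI| <= 2 (no detectable selection), compare observed Bray-Curtis to a
stochastic-assembly null to get the abundance-based Raup-Crick index
(RC_bray); finally classify each pair into one of five assembly processes:

=====================  =============================
condition              process
=====================  =============================
betaNTI < -2           homogeneous selection
betaNTI > +2           variable selection
|betaNTI|<=2, RC>+.95  dispersal limitation
|betaNTI|<=2, RC<-.95  homogenizing dispersal
otherwise              undominated (drift alone)
=====================  =============================

betaMNTD(A, B) = 1/2 [ sum_i f_iA min_j d(i, j) + sum_j f_jB min_i d(j, i) ]

with i over taxa of A, j over taxa of B, d the patristic distance, and f
the within-sample relative abundances (weighted form) or 1/S (unweighted).
The betaNTI null shuffles the taxon-tip mapping among the taxa of the
analyzed table; betaNTI = (obs - mean_null) / sd_null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .containers import CountTable, Phylogeny, ValidationError

logger = logging.getLogger("streamcom")

PROCESSES = (
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def _pair_bmntd(
    fa: np.ndarray, fb: np.ndarray, d: np.ndarray, weighted: bool
) -> float:
    """betaMNTD from abundance vectors and a patristic matrix (same taxon order)."""
    ia = np.flatnonzero(fa)
    ib = np.flatnonzero(fb)
    if ia.size == 0 or ib.size == 0:
        raise ValidationError("betaMNTD undefined for an empty community")
    sub = d[np.ix_(ia, ib)]
    min_a = sub.min(axis=1)  # nearest taxon in B for each taxon of A
    min_b = sub.min(axis=0)
    if weighted:
        wa = fa[ia] / fa[ia].sum()
        wb = fb[ib] / fb[ib].sum()
    else:
        wa = np.full(ia.size, 1.0 / ia.size)
        wb = np.full(ib.size, 1.0 / ib.size)
    return float(0.5 * (wa @ min_a + wb @ min_b))


def beta_mntd(
    table: CountTable,
    tree: Phylogeny,
    pair: tuple[str, str],
    weighted: bool = True,
) -> float:
    """Between-sample mean nearest taxon distance for one sample pair.

    Taxa present in both samples contribute a nearest-taxon distance of 0
    (their nearest relative in the other sample is themselves).
    """
    a, b = pair
    taxa = [t for t in table.taxon_ids if t in set(tree.tip_names)]
    if not taxa:
        raise ValidationError("no table taxa found on the tree")
    d = tree.patristic(taxa).to_numpy()
    fa = table.data.loc[a, taxa].to_numpy(dtype=float)
    fb = table.data.loc[b, taxa].to_numpy(dtype=float)
    return _pair_bmntd(fa, fb, d, weighted)


def bnti(
    table: CountTable,
    tree: Phylogeny,
    pair: tuple[str, str],
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> tuple[float, float, float]:
    """beta nearest taxon index for one pair: (betaNTI, null mean, null sd).

    The null shuffles the taxon-tip mapping among all taxa of the table
    (equivalently, permutes rows and columns of the patristic matrix) and
    recomputes betaMNTD ``n_null`` times. Scale-invariant: multiplying all
    branch lengths by a constant cancels in the standardization.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99 for a usable null distribution")
    a, b = pair
    taxa = [t for t in table.taxon_ids if t in set(tree.tip_names)]
    d = tree.patristic(taxa).to_numpy()
    fa = table.data.loc[a, taxa].to_numpy(dtype=float)
    fb = table.data.loc[b, taxa].to_numpy(dtype=float)
    obs = _pair_bmntd(fa, fb, d, weighted)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_null)
    n = len(taxa)
    for k in range(n_null):
        perm = rng.permutation(n)
        nulls[k] = _pair_bmntd(fa, fb, d[np.ix_(perm, perm)], weighted)
    mean, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    if sd == 0:
        raise ValidationError("degenerate null: zero standard deviation")
    return (obs - mean) / sd, mean, sd


def raup_crick_bray(
    table: CountTable,
    pair: tuple[str, str],
    n_null: int = 999,
    seed: int = 0,
) -> float:
    """Abundance-based Raup-Crick index for one pair, in [-1, 1].

    Null communities preserve each sample's observed richness and library
    size: taxa are drawn without replacement with probability proportional
    to their occurrence frequency across the table, then reads are allocated
    multinomially with probability proportional to each drawn taxon's summed
    relative abundance across the table. RC compares observed Bray-Curtis to
    the null distribution with ties at half weight, rescaled to [-1, 1].
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    if not table.is_integer:
        raise ValidationError("Raup-Crick null is defined on integer counts")
    counts = table.values
    occ_freq = (counts > 0).sum(axis=0).astype(float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    regional_ab = rel.sum(axis=0)
    a, b = pair
    xa = table.data.loc[a].to_numpy(dtype=float)
    xb = table.data.loc[b].to_numpy(dtype=float)
    obs = braycurtis(xa, xb)
    rng = np.random.default_rng(seed)
    nulls = _null_bray_curtis(
        rng,
        n_null,
        occ_freq,
        regional_ab,
        richness=(int((xa > 0).sum()), int((xb > 0).sum())),
        libsize=(int(xa.sum()), int(xb.sum())),
    )
    below = int((nulls < obs - 1e-12).sum())
    ties = int((np.abs(nulls - obs) <= 1e-12).sum())
    rc = (below + 0.5 * ties) / n_null
    return float((rc - 0.5) * 2)


def _null_community(
    rng: np.random.Generator,
    occ_freq: np.ndarray,
    regional_ab: np.ndarray,
    richness: int,
    libsize: int,
) -> np.ndarray:
    """One null assemblage: occurrence-weighted membership, abundance-weighted reads."""
    n_pool = len(occ_freq)
    if richness > (occ_freq > 0).sum():
        raise ValidationError("observed richness exceeds the occupied taxon pool")
    members = rng.choice(
        n_pool, size=richness, replace=False, p=occ_freq / occ_freq.sum()
    )
    weights = regional_ab[members]
    if weights.sum() == 0:
        weights = np.ones(richness)
    community = np.zeros(n_pool)
    # every member gets >= 1 read; the remainder is allocated multinomially
    extra = libsize - richness
    alloc = rng.multinomial(extra, weights / weights.sum()) if extra > 0 else 0
    community[members] = 1 + alloc
    return community


def _null_bray_curtis(
    rng: np.random.Generator,
    n_null: int,
    occ_freq: np.ndarray,
    regional_ab: np.ndarray,
    richness: tuple[int, int],
    libsize: tuple[int, int],
) -> np.ndarray:
    out = np.empty(n_null)
    for k in range(n_null):
        na = _null_community(rng, occ_freq, regional_ab, richness[0], libsize[0])
        nb = _null_community(rng, occ_freq, regional_ab, richness[1], libsize[1])
        out[k] = braycurtis(na, nb)
    return out


def classify_process(bnti_value: float, rc_value: float) -> str:
    """Map a (betaNTI, RC) pair to its dominant assembly process."""
    if not -1 - 1e-12 <= rc_value <= 1 + 1e-12:
        raise ValueError("RC must lie in [-1, 1]")
    if bnti_value > BNTI_THRESHOLD:
        return "variable_selection"
    if bnti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_value < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


@dataclass
class AssemblyConfig:
    """Settings for a full null-model run."""

    n_null: int = 999
    seed: int = 0
    weighted: bool = True
    group_by: str = "season"


def partition_processes(pairs: pd.DataFrame, group_by: str = "group") -> pd.DataFrame:
    """Per-group fraction of pairs assigned to each of the five processes.

    ``pairs`` must hold one classified pair per row with columns ``process``
    and ``group_by``. Fractions within a group sum to 1.
    """
    if group_by not in pairs.columns:
        raise ValidationError(f"missing grouping column {group_by!r}")
    rows = []
    for group, sub in pairs.groupby(group_by, sort=True):
        if len(sub) == 0:
            raise ValidationError(f"empty group {group!r}")
        frac = sub["process"].value_counts(normalize=True)
        rows.append(
            {"group": group, **{p: float(frac.get(p, 0.0)) for p in PROCESSES}}
        )
    return pd.DataFrame(rows).set_index("group")


def _pairwise_bmntd_matrix(
    freqs: np.ndarray, d: np.ndarray, pairs_idx: list[tuple[int, int]], weighted: bool
) -> np.ndarray:
    return np.array([_pair_bmntd(freqs[i], freqs[j], d, weighted) for i, j in pairs_idx])


def assembly_pipeline(
    table: CountTable,
    tree: Phylogeny,
    meta: pd.DataFrame,
    config: AssemblyConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every within-group sample pair and aggregate process fractions.

    For efficiency one set of ``n_null`` taxon shuffles is shared by all
    pairs of the run (marginally identical to per-pair shuffles); Raup-Crick
    nulls are drawn per pair from a seed stream derived from ``config.seed``.

    Returns
    -------
    pairs : DataFrame
        One row per within-group pair: sample_a, sample_b, group, bmntd,
        bnti, rc, process.
    fractions : DataFrame
        Per-group fractions of the five processes.
    """
    config = config or AssemblyConfig()
    taxa = [t for t in table.taxon_ids if t in set(tree.tip_names)]
    if not taxa:
        raise ValidationError("no table taxa found on the tree")
    d = tree.patristic(taxa).to_numpy()
    sub = table.data[taxa]
    samples = [s for s in table.sample_ids if s in meta.index]
    groups = meta.loc[samples, config.group_by]
    freqs = sub.loc[samples].to_numpy(dtype=float)

    pairs_idx: list[tuple[int, int]] = []
    pair_groups: list = []
    index_of = {s: i for i, s in enumerate(samples)}
    for _, members in groups.groupby(groups, sort=True):
        ids = list(members.index)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs_idx.append((index_of[ids[i]], index_of[ids[j]]))
                pair_groups.append(members.iloc[0])

    rng = np.random.default_rng(config.seed)
    obs = _pairwise_bmntd_matrix(freqs, d, pairs_idx, config.weighted)
    n = len(taxa)
    nulls = np.empty((config.n_null, len(pairs_idx)))
    for k in range(config.n_null):
        perm = rng.permutation(n)
        dp = d[np.ix_(perm, perm)]
        nulls[k] = _pairwise_bmntd_matrix(freqs, dp, pairs_idx, config.weighted)
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    degenerate = null_sd == 0
    if degenerate.any():
        # identical-membership pairs: every shuffle reproduces the observed
        # value, so there is no deviation to standardize; score them 0
        logger.warning(
            "%d pair(s) had a degenerate betaMNTD null (identical membership); "
            "betaNTI set to 0",
            int(degenerate.sum()),
        )
        null_sd = np.where(degenerate, 1.0, null_sd)
    bnti_values = (obs - null_mean) / null_sd

    counts = sub.loc[samples].to_numpy()
    occ_freq = (counts > 0).sum(axis=0).astype(float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    regional_ab = rel.sum(axis=0)
    rc_values = np.empty(len(pairs_idx))
    rc_seeds = rng.integers(0, 2**31 - 1, size=len(pairs_idx))
    for p, (i, j) in enumerate(pairs_idx):
        xa, xb = counts[i].astype(float), counts[j].astype(float)
        obs_bc = braycurtis(xa, xb)
        prng = np.random.default_rng(int(rc_seeds[p]))
        null_bc = _null_bray_curtis(
            prng,
            config.n_null,
            occ_freq,
            regional_ab,
            richness=(int((xa > 0).sum()), int((xb > 0).sum())),
            libsize=(int(xa.sum()), int(xb.sum())),
        )
        below = int((null_bc < obs_bc - 1e-12).sum())
        ties = int((np.abs(null_bc - obs_bc) <= 1e-12).sum())
        rc_values[p] = ((below + 0.5 * ties) / config.n_null - 0.5) * 2

    rows = []
    for p, (i, j) in enumerate(pairs_idx):
        rows.append(
            {
                "sample_a": samples[i],
                "sample_b": samples[j],
                "group": pair_groups[p],
                "bmntd": obs[p],
                "bnti": bnti_values[p],
                "rc": rc_values[p],
                "process": classify_process(bnti_values[p], rc_values[p]),
            }
        )
    pairs_df = pd.DataFrame(rows)
    fractions = partition_processes(pairs_df, group_by="group")
    logger.info(
        "assembly run: %d pairs, n_null=%d, weighted=%s, seed=%d",
        len(pairs_df),
        config.n_null,
        config.weighted,
        config.seed,
    )
    return pairs_df, fractions
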