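"""Group-comparison statistics: PERMANOVA, one-way ANOVA, Tukey HSD, Pearson.

PERMANOVA is the one-factor form: sums of squares come from Gower-centered
squared distances, the pseudo-F statistic is ``(SS_b/df_b) / (SS_w/df_w)``,
and significance comes from permuting sample labels. ANOVA, Tukey's HSD
(Tukey-Kramer for unbalanced designs), and Pearson correlation delegate to
scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix

from .containers import ValidationError

__all__ = [
    "permanova",
    "PermanovaResult",
    "anova_oneway",
    "tukey_hsd",
    "TukeyResult",
    "pearson",
]


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        ss += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    return ss


def permanova(
    dm: DistanceMatrix | np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor permutational multivariate analysis of variance.

    Parameters
    ----------
    dm : skbio.DistanceMatrix or square ndarray
        Pairwise distances between samples.
    labels : sequence
        Group label per sample, aligned with ``dm``'s order.
    n_perm : int
        Number of label permutations; ``p = (#{F_perm >= F_obs} + 1)/(n_perm + 1)``.
    """
    d = np.asarray(dm.data if isinstance(dm, DistanceMatrix) else dm, dtype=float)
    labels = pd.Series(list(labels))
    if len(labels) != d.shape[0]:
        raise ValidationError("labels do not align with the distance matrix")
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    n = len(labels)
    if a < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValidationError("each group needs at least 2 samples")
    d2 = d**2
    ss_total = d2.sum() / (2 * n)
    ss_w = _ss_within(d2, codes, a)
    ss_b = ss_total - ss_w
    df_b, df_w = a - 1, n - a
    f_obs = (ss_b / df_b) / (ss_w / df_w)
    rng = np.random.default_rng(seed)
    # vectorized label permutations: one boolean indicator block per group
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    ss_w_perm = np.zeros(n_perm)
    for g in range(a):
        mask = (perms == g).astype(float)  # n_perm x n
        ss_w_perm += ((mask @ d2) * mask).sum(axis=1) / (2 * mask.sum(axis=1))
    f_perm = ((ss_total - ss_w_perm) / df_b) / (ss_w_perm / df_w)
    count = int((f_perm >= f_obs - 1e-12).sum())
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(ss_b / ss_total),
        p_value=float(p),
        n_permutations=n_perm,
        df_between=df_b,
        df_within=df_w,
    )


def _split_groups(values, labels) -> list[np.ndarray]:
    s = pd.Series(np.asarray(values, dtype=float), index=list(labels))
    groups = [g.to_numpy() for _, g in s.groupby(level=0, sort=True)]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("each group needs at least 2 values")
    return groups


def anova_oneway(values, labels) -> tuple[float, float]:
    """Classical one-way ANOVA F test; returns (F, p)."""
    groups = _split_groups(values, labels)
    if all(np.var(g) == 0 for g in groups):
        means = [g.mean() for g in groups]
        if np.allclose(means, means[0]):
            raise ValidationError("F undefined: zero variance everywhere, equal means")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


@dataclass
class TukeyResult:
    group_a: str
    group_b: str
    mean_difference: float
    p_adjusted: float


def tukey_hsd(values, labels, alpha: float = 0.05) -> list[TukeyResult]:
    """Tukey's honestly-significant-difference test for all group pairs.

    Uses the studentized range with the pooled ANOVA residual mean square;
    unbalanced designs use the Tukey-Kramer harmonic-mean correction (as
    implemented by :func:`scipy.stats.tukey_hsd`).
    """
    s = pd.Series(np.asarray(values, dtype=float), index=list(labels))
    names = sorted(s.index.unique())
    groups = [s.loc[[g]].to_numpy() for g in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("Tukey HSD needs >= 2 groups with >= 2 values each")
    res = sps.tukey_hsd(*groups)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out.append(
                TukeyResult(
                    group_a=str(names[i]),
                    group_b=str(names[j]),
                    mean_difference=float(groups[i].mean() - groups[j].mean()),
                    p_adjusted=float(res.pvalue[i, j]),
                )
            )
    return out


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValidationError("pearson needs aligned vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
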