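"""Alpha diversity, Bray-Curtis beta diversity, ordination, and
environment-vector fitting.

Alpha indices follow the classical definitions: bias-corrected Chao1
richness ``S_obs + F1(F1-1) / (2(F2+1))`` (F1/F2 = singleton/doubleton
counts), Shannon entropy in nats, and Pielou evenness ``H / ln(S_obs)``.
Ordinations are classical: PCoA by double-centering of the squared distance
matrix, and PCA of z-scored environmental variables via the correlation
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .containers import CountTable, ValidationError

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "pca_environment",
    "envfit",
    "Ordination",
    "EnvfitResult",
]


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample richness, Chao1, Shannon (nats), and Pielou evenness.

    Expects rarefied integer counts. Pielou is NaN for single-taxon samples
    (``ln S = 0``).
    """
    if not table.is_integer:
        raise ValidationError("alpha diversity expects (rarefied) integer counts")
    records = []
    for sample in table.sample_ids:
        counts = table.data.loc[sample].to_numpy()
        counts = counts[counts > 0]
        if counts.size == 0:
            raise ValidationError(f"sample {sample!r} is empty")
        s_obs = counts.size
        f1 = int((counts == 1).sum())
        f2 = int((counts == 2).sum())
        chao1 = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
        p = counts / counts.sum()
        shannon = float(-(p * np.log(p)).sum())
        pielou = shannon / np.log(s_obs) if s_obs > 1 else np.nan
        records.append(
            {
                "sample_id": sample,
                "richness_observed": s_obs,
                "chao1": chao1,
                "shannon": shannon,
                "pielou": pielou,
            }
        )
    return pd.DataFrame(records).set_index("sample_id")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = sum|a-b| / sum(a+b)."""
    sums = table.sample_sums()
    if (sums == 0).any():
        raise ValidationError("Bray-Curtis undefined for zero-sum samples")
    condensed = pdist(table.values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class Ordination:
    """Sample scores on orthogonal axes ordered by decreasing eigenvalue."""

    ids: list[str]
    scores: np.ndarray  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    loadings: pd.DataFrame | None = None  # PCA only: variables x axes

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"axis_{k + 1}" for k in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.ids, columns=cols)


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Principal coordinate analysis (classical metric scaling).

    The squared distance matrix is double-centered (Gower), eigendecomposed,
    and axes with eigenvalue <= 0 are dropped; proportions explained are
    computed over the positive eigenvalues only.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    d2 = np.asarray(dm.data) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12 * abs(eigval[0]), 0)
    eigval, eigvec = eigval[pos], eigvec[:, pos]
    scores = eigvec * np.sqrt(eigval)
    return Ordination(
        ids=list(dm.ids),
        scores=scores,
        eigenvalues=eigval,
        proportion_explained=eigval / eigval.sum(),
    )


def pca_environment(meta: pd.DataFrame, variables: list[str]) -> Ordination:
    """PCA of z-scored environmental variables (correlation matrix).

    Rows with any missing value among ``variables`` are dropped listwise.
    Eigenvalues sum to the number of variables; a zero-variance variable is
    rejected by name.
    """
    if len(variables) < 2:
        raise ValidationError("PCA needs at least 2 variables")
    x = meta[variables].apply(pd.to_numeric).dropna()
    if x.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 complete samples")
    sd = x.std(axis=0, ddof=1)
    dead = sd[sd == 0]
    if len(dead):
        raise ValidationError(f"zero-variance variable(s): {list(dead.index)}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0, None)
    scores = z.to_numpy() @ eigvec
    loadings = pd.DataFrame(
        eigvec,
        index=variables,
        columns=[f"axis_{k + 1}" for k in range(eigvec.shape[1])],
    )
    return Ordination(
        ids=list(x.index),
        scores=scores,
        eigenvalues=eigval,
        proportion_explained=eigval / eigval.sum(),
        loadings=loadings,
    )


@dataclass
class EnvfitResult:
    variable: str
    direction: np.ndarray  # unit vector in the ordination plane
    r_squared: float
    p_value: float
    n_permutations: int


def envfit(
    ordination: Ordination,
    meta: pd.DataFrame,
    variables: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> list[EnvfitResult]:
    """Fit environmental vectors onto the first two ordination axes.

    Each variable is regressed (with intercept) on the axis-1/axis-2 scores;
    R^2 is the squared multiple correlation and the direction is the unit
    vector of the regression coefficients. Significance comes from permuting
    the variable's values: ``p = (#{R2_perm >= R2_obs} + 1) / (n_perm + 1)``.
    """
    if ordination.scores.shape[1] < 2:
        raise ValidationError("envfit needs an ordination with >= 2 axes")
    rng = np.random.default_rng(seed)
    xy = ordination.scores[:, :2]
    x_design = np.column_stack([np.ones(len(xy)), xy])
    results = []
    for var in variables:
        y = pd.to_numeric(meta.loc[ordination.ids, var]).to_numpy(dtype=float)
        if np.std(y) == 0:
            raise ValidationError(f"constant variable {var!r}")
        coef, *_ = np.linalg.lstsq(x_design, y, rcond=None)
        fitted = x_design @ coef
        ss_res = ((y - fitted) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot
        direction = coef[1:]
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else direction
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            coef_p, *_ = np.linalg.lstsq(x_design, yp, rcond=None)
            ss_res_p = ((yp - x_design @ coef_p) ** 2).sum()
            r2_p = 1 - ss_res_p / ss_tot
            if r2_p >= r2:
                count += 1
        p = (count + 1) / (n_perm + 1)
        results.append(
            EnvfitResult(
                variable=var,
                direction=direction,
                r_squared=float(r2),
                p_value=float(p),
                n_permutations=n_perm,
            )
        )
    return results
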