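"""Phenotype-genotype association along the spawning gradient.

Trend regressions of standard length and gill-raker count against depth
and date, Mantel and partial Mantel tests of isolation-by-distance versus
isolation-by-adaptation, two-group phenotype tests, great-circle site
distances, and DAPC-style assignment of individuals to prior groups.

Mantel p-values are one-sided (observed or larger), computed by
simultaneous row/column permutation of the first matrix with the
(b + 1)/(m + 1) convention. The partial test uses the residual-permutation
variant: both matrices are residualized on the control matrix and the
permuted quantity is the residualized first matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .io import GenotypeTable
from .popgen_stats import _onehot

__all__ = [
    "MantelResult",
    "DapcResult",
    "linear_trend",
    "geographic_distance",
    "mantel",
    "partial_mantel",
    "group_membership_matrix",
    "dapc_assign",
    "two_group_tests",
    "phenotype_distance",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    controlled: str | None = None


@dataclass
class DapcResult:
    n_pcs: int
    rmse_by_pcs: dict[int, float]
    membership: pd.DataFrame  # individuals x groups posterior probabilities
    groups: list[str]

    def self_assignment(self, labels: np.ndarray) -> np.ndarray:
        """Posterior probability of each individual's own prior group."""
        return np.array(
            [self.membership.iloc[i][str(g)] for i, g in enumerate(labels)]
        )


def linear_trend(y: np.ndarray, x: np.ndarray) -> tuple[float, float, tuple[int, int], float]:
    """OLS slope of y on x with the F-test of the slope.

    Returns ``(slope, F, (df1, df2), p)``; F equals the squared t of the
    slope for simple regression.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    res = stats.linregress(x, y)
    f = res.rvalue**2 / (1 - res.rvalue**2) * (x.size - 2) if abs(res.rvalue) < 1 else np.inf
    return float(res.slope), float(f), (1, x.size - 2), float(res.pvalue)


def geographic_distance(sites: pd.DataFrame) -> pd.DataFrame:
    """Great-circle (haversine) distance matrix in km.

    ``sites`` needs columns ``site_lat``/``site_lon`` in decimal degrees;
    the index labels the sites.
    """
    lat = np.radians(sites["site_lat"].to_numpy(float))
    lon = np.radians(sites["site_lon"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=sites.index, columns=sites.index)


def _condensed(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def _check_square(*mats: np.ndarray) -> list[np.ndarray]:
    out = []
    n = None
    for M in mats:
        M = np.asarray(M, float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("distance matrices must be square")
        if not np.allclose(M, M.T, equal_nan=True):
            raise ValueError("distance matrices must be symmetric")
        if n is None:
            n = M.shape[0]
        elif M.shape[0] != n:
            raise ValueError("distance matrices must have the same order")
        out.append(M)
    return out


def mantel(
    D1: np.ndarray, D2: np.ndarray, permutations: int = 1000, seed: int = 0
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal elements; the null
    distribution permutes rows and columns of ``D1`` simultaneously.
    """
    D1, D2 = _check_square(D1, D2)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 111]))
    v2 = _condensed(D2)
    ok = np.isfinite(_condensed(D1)) & np.isfinite(v2)
    r_obs = float(np.corrcoef(_condensed(D1)[ok], v2[ok])[0, 1])
    n = D1.shape[0]
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        v1p = _condensed(D1[np.ix_(perm, perm)])
        r = np.corrcoef(v1p[ok], v2[ok])[0, 1]
        if r >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r_obs, (hits + 1) / (permutations + 1), permutations)


def _residualize(v: np.ndarray, c: np.ndarray) -> np.ndarray:
    beta = np.polyfit(c, v, 1)
    return v - np.polyval(beta, c)


def partial_mantel(
    D1: np.ndarray, D2: np.ndarray, C: np.ndarray,
    permutations: int = 1000, seed: int = 0, controlled: str = "C",
) -> MantelResult:
    """Partial Mantel correlation of D1 and D2 controlling for C.

    Off-diagonal vectors of D1 and D2 are each regressed on C's; r is the
    correlation of the residuals. The null permutes rows/columns of D1 and
    re-residualizes (residual-permutation variant).
    """
    D1, D2, C = _check_square(D1, D2, C)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 222]))
    vc = _condensed(C)
    r2 = _residualize(_condensed(D2), vc)
    r1 = _residualize(_condensed(D1), vc)
    r_obs = float(np.corrcoef(r1, r2)[0, 1])
    n = D1.shape[0]
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r1p = _residualize(_condensed(D1[np.ix_(perm, perm)]), vc)
        if np.corrcoef(r1p, r2)[0, 1] >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r_obs, (hits + 1) / (permutations + 1), permutations, controlled)


def group_membership_matrix(labels: np.ndarray) -> np.ndarray:
    """Binary distance: 0 for same-group pairs, 1 otherwise."""
    labels = np.asarray(labels)
    return (labels[:, None] != labels[None, :]).astype(float)


def phenotype_distance(values: np.ndarray) -> np.ndarray:
    """Pairwise absolute difference of a raw phenotype (SL, GR, depth...)."""
    values = np.asarray(values, float)
    return np.abs(values[:, None] - values[None, :])


def dapc_assign(
    genotypes: GenotypeTable,
    prior_groups: np.ndarray,
    cv_folds: int = 5,
    max_pcs: int = 50,
    seed: int = 0,
) -> DapcResult:
    """Discriminant analysis of principal components with CV-chosen PC count.

    The individual allele-count matrix is column-centered (missing calls
    imputed at the column mean), reduced by PCA, and a linear discriminant
    fitted on the retained PCs. The retained PC count minimizes the
    cross-validated root-mean-square of ``1 - P(correct group)`` over
    held-out fish. Returns per-individual posterior group membership.
    """
    labels = np.asarray(prior_groups).astype(str)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 prior groups")
    C, _, T, slices = _onehot(genotypes)
    X = C.copy()
    for l, sl in enumerate(slices):
        typed = T[:, l] > 0
        if typed.any():
            col_mean = X[typed][:, sl].mean(axis=0)
            X[~typed, sl] = col_mean
    X = X - X.mean(axis=0)
    n = X.shape[0]
    smallest = min(np.sum(labels == c) for c in classes)
    folds = cv_folds
    if smallest < cv_folds:
        folds = max(2, smallest)
        warnings.warn(f"smallest group has {smallest} fish; shrinking CV to {folds} folds",
                      stacklevel=2)
    rank = np.linalg.matrix_rank(X)
    grid_max = max(1, min(max_pcs, rank, n - folds))
    pca = PCA(n_components=grid_max, random_state=seed)
    scores = pca.fit_transform(X)
    rmse: dict[int, float] = {}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for k in range(1, grid_max + 1):
        errs = []
        for train, test in skf.split(scores, labels):
            lda = LinearDiscriminantAnalysis()
            lda.fit(scores[train, :k], labels[train])
            proba = lda.predict_proba(scores[test, :k])
            correct = [
                proba[i, list(lda.classes_).index(labels[test][i])]
                for i in range(len(test))
            ]
            errs.extend((1 - np.array(correct)) ** 2)
        rmse[k] = float(np.sqrt(np.mean(errs)))
    best_k = min(rmse, key=rmse.get)
    lda = LinearDiscriminantAnalysis().fit(scores[:, :best_k], labels)
    proba = lda.predict_proba(scores[:, :best_k])
    membership = pd.DataFrame(proba, columns=list(lda.classes_),
                              index=genotypes.individual_ids)
    return DapcResult(best_k, rmse, membership, list(lda.classes_))


def two_group_tests(
    values: np.ndarray, labels: np.ndarray
) -> dict[str, tuple[float, float] | tuple[float, int, float]]:
    """Two-sample t-test and Mann-Whitney U between exactly two groups."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    uniq = sorted(str(u) for u in pd.unique(labels) if not pd.isna(u))
    labels = labels.astype(str)
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    t = stats.ttest_ind(a, b)
    u = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "t": (float(t.statistic), int(len(a) + len(b) - 2), float(t.pvalue)),
        "u": (float(u.statistic), float(u.pvalue)),
    }
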