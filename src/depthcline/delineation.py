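"""Growth-cluster delineation from length-at-age data.

How many growth-rate clusters does a standard-length sample support?  The
module answers with three complementary tools used in sequence:

1. a Shapiro-Wilk normality test — a unimodal species predicts normal SL;
2. univariate Gaussian mixtures with 1..3 components compared by AICc
   (small-sample corrected Akaike criterion);
3. a dynamic tree-cut-style clustering of the average-linkage dendrogram
   that returns the cluster count without prespecifying it: preliminary
   clusters must exceed a minimum size (default 10% of N) and be separated
   by a genuine density valley; points left unassigned at that stage are
   attached to the nearest cluster medoid in a second pass.

Fish from other sampling sites are subsequently assigned to the nearest
existing cluster by SL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "MixtureFit",
    "ClusterSolution",
    "normality_test",
    "fit_gaussian_mixtures",
    "hybrid_tree_cut",
    "assign_to_clusters",
    "age_class_comparison",
]

SD_FLOOR = 1.0  # mm; EM components may not collapse below this
EM_RESTARTS = 10
AICC_TIE = 2.0  # models within this delta are "equally likely"
VALLEY_RATIO = 0.5  # split accepted when valley density < ratio * branch peak


@dataclass
class MixtureFit:
    """A fitted k-component univariate normal mixture."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    aicc: float
    n: int
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def n_params(self) -> int:
        return 3 * self.k - 1


@dataclass
class ClusterSolution:
    """Tree-cut clustering of SL values; label 0 = unassigned at stage 1."""

    labels: np.ndarray          # final labels, 1..k
    stage1_labels: np.ndarray   # 0 where attached only at stage 2
    medoids: np.ndarray         # per-cluster median SL (mm), ascending
    min_cluster_size: int

    @property
    def k(self) -> int:
        return len(self.medoids)


def normality_test(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for deviation from a normal distribution."""
    values = np.asarray(values, float)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("constant input has no defined normality test")
    w, p = stats.shapiro(values)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# Gaussian mixtures by EM with AICc model choice
# ---------------------------------------------------------------------------


def _kmeanspp_means(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    means = [values[rng.integers(values.size)]]
    for _ in range(k - 1):
        d2 = np.min([(values - m) ** 2 for m in means], axis=0)
        if d2.sum() == 0:
            means.append(values[rng.integers(values.size)])
        else:
            means.append(values[rng.choice(values.size, p=d2 / d2.sum())])
    return np.array(means)


def _em_once(
    values: np.ndarray, k: int, rng: np.random.Generator,
    max_iter: int = 200, tol: float = 1e-6,
) -> MixtureFit:
    n = values.size
    # initialize from a Lloyd-refined k-means partition: means, within-cluster
    # sds and proportions, the standard way to start mixture EM
    means = _kmeanspp_means(values, k, rng)
    for _ in range(25):
        assign = np.argmin(np.abs(values[:, None] - means[None, :]), axis=1)
        new_means = np.array([
            values[assign == j].mean() if (assign == j).any() else means[j]
            for j in range(k)
        ])
        if np.allclose(new_means, means):
            break
        means = new_means
    assign = np.argmin(np.abs(values[:, None] - means[None, :]), axis=1)
    sds = np.array([
        max(values[assign == j].std(), SD_FLOOR) if (assign == j).sum() > 1 else SD_FLOOR
        for j in range(k)
    ])
    weights = np.maximum(np.bincount(assign, minlength=k) / n, 1e-6)
    weights = weights / weights.sum()
    trace: list[float] = []
    loglik = -np.inf
    for _ in range(max_iter):
        logp = (
            np.log(weights)[None, :]
            + stats.norm.logpdf(values[:, None], means[None, :], sds[None, :])
        )
        lse = np.logaddexp.reduce(logp, axis=1)
        new_loglik = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * values[:, None]).sum(axis=0) / nk
        var = (resp * (values[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        # degenerate components restart at the sd floor rather than vanishing
        sds = np.maximum(np.sqrt(var), SD_FLOOR)
        trace.append(new_loglik)
        # stop on the mean per-observation log-likelihood change
        if new_loglik - loglik < tol * n and np.isfinite(loglik):
            break
        loglik = new_loglik
    p = 3 * k - 1
    aicc = -2 * trace[-1] + 2 * p + (2 * p * (p + 1) / (n - p - 1) if n > p + 1 else np.inf)
    order = np.argsort(means)
    return MixtureFit(k, means[order], sds[order], weights[order], trace[-1], aicc, n, trace)


def fit_gaussian_mixtures(
    values: np.ndarray, k_max: int = 3, seed: int = 0, restarts: int = EM_RESTARTS
) -> tuple[list[MixtureFit], int]:
    """EM fits for k = 1..k_max; the selected k minimizes AICc.

    Each k uses multiple seeded restarts with k-means++-style initial means
    and a 1 mm standard-deviation floor. AICc uses p = 3k - 1 free
    parameters. Fits within 2 AICc of the best are reported by
    :func:`equally_likely`.
    """
    values = np.asarray(values, float)
    if values.size <= 3 * k_max:
        raise ValueError(f"need n > {3 * k_max} observations for k_max={k_max}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    fits: list[MixtureFit] = []
    for k in range(1, k_max + 1):
        best = None
        for _ in range(restarts if k > 1 else 1):
            fit = _em_once(values, k, rng)
            if best is None or fit.log_likelihood > best.log_likelihood:
                best = fit
        fits.append(best)
    selected = int(np.argmin([f.aicc for f in fits])) + 1
    return fits, selected


def equally_likely(fits: list[MixtureFit]) -> list[int]:
    """Component counts whose AICc is within 2 of the minimum."""
    best = min(f.aicc for f in fits)
    return [f.k for f in fits if f.aicc - best < AICC_TIE]


# ---------------------------------------------------------------------------
# Dynamic tree-cut-style clustering
# ---------------------------------------------------------------------------


def _kde_valley_split(values: np.ndarray, left: np.ndarray, right: np.ndarray) -> bool:
    """Accept a dendrogram split only across a genuine density valley.

    The kernel density of the parent's values must dip, somewhere between
    the two branch medians, below ``VALLEY_RATIO`` times the lower of the
    two branch peak densities.
    """
    if np.ptp(values) < 1e-9:
        return False
    # bandwidth from the within-branch spread: the parent's pooled sd is
    # inflated by the very separation being tested and would oversmooth
    parent_sd = values.std(ddof=1)
    side_sds = [
        values[s].std(ddof=1) for s in (left, right) if s.sum() >= 2
    ]
    child_sd = max(min(side_sds, default=parent_sd), parent_sd / 20)
    factor = (child_sd / parent_sd) * values.size ** (-1 / 5)
    kde = stats.gaussian_kde(values, bw_method=factor)
    lo, hi = sorted([np.median(values[left]), np.median(values[right])])
    if hi - lo < 1e-9:
        return False
    between = kde(np.linspace(lo, hi, 64)).min()
    peaks = []
    for side in (left, right):
        sv = values[side]
        peaks.append(kde(np.linspace(sv.min(), sv.max(), 64)).max())
    return between < VALLEY_RATIO * min(peaks)


def hybrid_tree_cut(values: np.ndarray, min_frac: float = 0.10) -> ClusterSolution:
    """Detect-then-attach clustering of SL values on the average-linkage tree.

    Stage 1 descends the dendrogram: a branch is split when both of its
    children could form clusters separated by a density valley; children
    smaller than ``ceil(min_frac * n)`` are left unassigned (label 0)
    whenever their sibling continues as a cluster. Stage 2 attaches every
    unassigned point to the cluster with the nearest medoid. Clusters are
    relabelled 1..k in order of ascending medoid SL. The cluster count k is
    an output, never an input.
    """
    values = np.asarray(values, float)
    n = values.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    min_size = int(np.ceil(min_frac * n))
    if min_size < 2:
        raise ValueError("min_frac * n must be at least 2")
    z = hierarchy.linkage(values[:, None], method="average")
    root = hierarchy.to_tree(z)

    stage1 = np.zeros(n, dtype=int)
    next_label = [0]

    def leaves(node) -> np.ndarray:
        return np.array(node.pre_order(lambda x: x.id))

    def descend(node) -> None:
        idx = leaves(node)
        if node.is_leaf() or idx.size < 2 * 2:
            _finalize(idx)
            return
        li, ri = leaves(node.left), leaves(node.right)
        lmask = np.isin(idx, li)
        if not _kde_valley_split(values[idx], lmask, ~lmask):
            _finalize(idx)
            return
        small_l, small_r = li.size < min_size, ri.size < min_size
        if small_l and small_r:
            _finalize(idx)
        elif small_l:
            stage1[li] = 0
            descend(node.right)
        elif small_r:
            stage1[ri] = 0
            descend(node.left)
        else:
            descend(node.left)
            descend(node.right)

    def _finalize(idx: np.ndarray) -> None:
        if idx.size >= min_size:
            next_label[0] += 1
            stage1[idx] = next_label[0]
        else:
            stage1[idx] = 0

    descend(root)
    if next_label[0] == 0:  # everything undersized: one cluster of all points
        stage1[:] = 1
        next_label[0] = 1

    # order clusters by medoid SL and relabel 1..k
    raw_labels = [lb for lb in range(1, next_label[0] + 1)]
    medoids = np.array([np.median(values[stage1 == lb]) for lb in raw_labels])
    rank = np.argsort(medoids, kind="stable")
    relabel = {raw_labels[r]: i + 1 for i, r in enumerate(rank)}
    stage1_sorted = np.array([relabel.get(lb, 0) for lb in stage1])
    medoids = medoids[rank]

    # stage 2: nearest-medoid attachment (ties -> lower-SL cluster)
    final = stage1_sorted.copy()
    for i in np.flatnonzero(stage1_sorted == 0):
        final[i] = int(np.argmin(np.abs(medoids - values[i]))) + 1
    return ClusterSolution(final, stage1_sorted, medoids, min_size)


def assign_to_clusters(new_values: np.ndarray, solution: ClusterSolution) -> np.ndarray:
    """Assign new SL values to the nearest cluster medoid (ties -> lower SL)."""
    if solution.k == 0:
        raise ValueError("empty cluster solution")
    new_values = np.asarray(new_values, float)
    d = np.abs(solution.medoids[None, :] - new_values[:, None])
    return np.argmin(d, axis=1) + 1


def age_class_comparison(
    ages: np.ndarray, labels: np.ndarray
) -> dict[tuple[str, str], tuple[float, float]]:
    """Pairwise Mann-Whitney U comparison of age between SL classes.

    Returns ``{(class_a, class_b): (U, two-sided p)}`` for every class pair
    with at least 3 aged fish each.
    """
    ages = np.asarray(ages, float)
    labels = np.asarray(labels)
    ok = np.isfinite(ages)
    classes = sorted(str(c) for c in np.unique(labels[ok]))
    usable = [c for c in classes if (labels[ok].astype(str) == c).sum() >= 3]
    if len(usable) < 2:
        raise ValueError("need >= 2 classes with >= 3 aged fish")
    out = {}
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            xa = ages[ok][labels[ok].astype(str) == a]
            xb = ages[ok][labels[ok].astype(str) == b]
            # exact null enumeration for small classes, asymptotic otherwise
            method = "exact" if max(len(xa), len(xb)) <= 20 else "auto"
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            out[(a, b)] = (float(res.statistic), float(res.pvalue))
    return out
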