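"""Genotype-based statistics for microsatellite survey data.

Implements the population-genetic toolbox needed to compare putative
species groupings: observed/expected heterozygosity and Weir-Cockerham
F-statistics, exact and Markov-chain Hardy-Weinberg tests, linkage
disequilibrium G-tests, pairwise theta (F_ST) with permutation tests,
AMOVA variance components, ADZE-style rarefied (private) allelic richness,
Smouse-Peakall individual genetic distances, Cavalli-Sforza chord
distances, neighbour-joining trees with locus bootstrap, and
Benjamini-Hochberg FDR correction.

Missing data policy: per-locus pairwise deletion throughout; gene counts
are locus-specific. Permutation p-values use the (b + 1)/(m + 1)
convention so p is never zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj
from statsmodels.stats.multitest import multipletests

from .io import GenotypeTable

logger = logging.getLogger("depthcline")

__all__ = [
    "allele_counts",
    "allele_frequencies",
    "diversity_summary",
    "hwe_test",
    "ld_pairwise_tests",
    "weir_cockerham_theta",
    "pairwise_fst",
    "FstMatrix",
    "amova",
    "AmovaResult",
    "rarefied_richness",
    "RarefactionResult",
    "smouse_peakall_distance",
    "chord_distance",
    "nj_tree",
    "bh_fdr",
]


# ---------------------------------------------------------------------------
# Allele bookkeeping
# ---------------------------------------------------------------------------


def _group_indices(grouping: np.ndarray) -> dict[str, np.ndarray]:
    grouping = np.asarray(grouping)
    groups = {}
    for g in pd.unique(grouping):
        if pd.isna(g):
            continue
        groups[str(g)] = np.flatnonzero(grouping.astype(str) == str(g))
    if not groups:
        raise ValueError("grouping defines no non-empty groups")
    return groups


def allele_counts(
    genotypes: GenotypeTable, grouping: np.ndarray
) -> dict[str, list[dict[int, int]]]:
    """Per-group, per-locus allele count vectors (missing calls excluded).

    Gene counts per locus equal twice the number of typed individuals.
    Groups with zero typed individuals at a locus get an empty dict (and a
    log warning).
    """
    groups = _group_indices(grouping)
    out: dict[str, list[dict[int, int]]] = {}
    for name, idx in groups.items():
        per_locus = []
        for l in range(genotypes.n_loci):
            calls = genotypes.calls[idx, l, :].ravel()
            calls = calls[calls > 0]
            counts = dict(zip(*np.unique(calls, return_counts=True)))
            if not counts:
                logger.warning("group %s has no typed individuals at locus %s",
                               name, genotypes.locus_names[l])
            per_locus.append({int(a): int(c) for a, c in counts.items()})
        out[name] = per_locus
    return out


def allele_frequencies(
    genotypes: GenotypeTable, grouping: np.ndarray
) -> tuple[dict[str, list[np.ndarray]], list[list[int]]]:
    """Aligned per-group allele-frequency vectors.

    Returns ``(freqs, alleles)`` where ``alleles[l]`` is the sorted union of
    allele codes observed at locus ``l`` and ``freqs[group][l]`` is the
    frequency vector on that allele ordering (zeros where absent; NaN
    vector if the group is untyped at the locus).
    """
    counts = allele_counts(genotypes, grouping)
    alleles = [
        sorted(set().union(*[set(counts[g][l]) for g in counts]))
        for l in range(genotypes.n_loci)
    ]
    freqs: dict[str, list[np.ndarray]] = {}
    for g, per_locus in counts.items():
        vecs = []
        for l, cts in enumerate(per_locus):
            total = sum(cts.values())
            if total == 0:
                vecs.append(np.full(len(alleles[l]), np.nan))
            else:
                vecs.append(np.array([cts.get(a, 0) / total for a in alleles[l]]))
        freqs[g] = vecs
    return freqs, alleles


def _onehot(genotypes: GenotypeTable) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[slice]]:
    """Per-individual allele count/het-carrier matrices.

    Returns (C, H, T, locus_slices): C (n x A_total) allele copy counts,
    H (n x A_total) indicator of carrying exactly one copy, T (n x L)
    typed mask, and the column slice of each locus.
    """
    n, L = genotypes.n_individuals, genotypes.n_loci
    alleles = [
        np.unique(genotypes.calls[:, l, :][genotypes.calls[:, l, :] > 0])
        for l in range(L)
    ]
    offsets = np.concatenate([[0], np.cumsum([len(a) for a in alleles])])
    slices = [slice(offsets[l], offsets[l + 1]) for l in range(L)]
    A = offsets[-1]
    C = np.zeros((n, A))
    T = ~genotypes.missing
    for l in range(L):
        index = {a: i for i, a in enumerate(alleles[l])}
        for i in range(n):
            if T[i, l]:
                for a in genotypes.calls[i, l]:
                    C[i, offsets[l] + index[a]] += 1
    H = (C == 1).astype(float)
    return C, H, T.astype(float), slices


# ---------------------------------------------------------------------------
# Diversity summary
# ---------------------------------------------------------------------------


@dataclass
class DiversityTable:
    """Per group x locus diversity plus across-locus summaries."""

    per_locus: pd.DataFrame   # columns: group, locus, n_genes, ho, he, fis, a_n
    summary: pd.DataFrame     # per group: mean ho/he, multilocus fis, a_r at g
    g_std: int


def _ho_he(calls: np.ndarray) -> tuple[float, float, int]:
    """(H_O, unbiased H_E, gene count) for one locus sample of (n, 2) calls."""
    typed = calls[calls[:, 0] > 0]
    n = typed.shape[0]
    if n == 0:
        return np.nan, np.nan, 0
    ho = float(np.mean(typed[:, 0] != typed[:, 1]))
    _, cts = np.unique(typed.ravel(), return_counts=True)
    p = cts / (2 * n)
    he = (2 * n / (2 * n - 1)) * (1 - np.sum(p**2)) if n > 0 else np.nan
    return ho, float(he), 2 * n


def diversity_summary(
    genotypes: GenotypeTable, grouping: np.ndarray, g_std: int | None = None
) -> DiversityTable:
    """H_O, unbiased H_E, F_IS and allele counts per group and locus.

    F_IS per locus is ``1 - H_O/H_E`` with the unbiased H_E (undefined at
    monomorphic loci); the multilocus value is the ratio of sums over loci.
    ``g_std`` (genes) standardizes allelic richness by rarefaction; default
    is the smallest per-group gene count over loci.
    """
    groups = _group_indices(grouping)
    rows = []
    for name, idx in groups.items():
        for l, locus in enumerate(genotypes.locus_names):
            ho, he, ng = _ho_he(genotypes.calls[idx, l, :])
            a_n = len(np.unique(genotypes.calls[idx, l, :][genotypes.calls[idx, l, :] > 0]))
            fis = 1 - ho / he if he and he > 0 else np.nan
            rows.append({"group": name, "locus": locus, "n_genes": ng,
                         "ho": ho, "he": he, "fis": fis, "a_n": a_n})
    per_locus = pd.DataFrame(rows)
    min_genes = int(per_locus.groupby("group")["n_genes"].min().min())
    if g_std is None:
        g_std = min_genes
    elif g_std > min_genes:
        logger.warning("g_std=%d exceeds the smallest gene count %d; clipping",
                       g_std, min_genes)
        g_std = min_genes
    rar = rarefied_richness(genotypes, grouping, g_std)
    summary_rows = []
    for name in groups:
        sub = per_locus[per_locus["group"] == name]
        fis_ml = 1 - sub["ho"].sum() / sub["he"].sum() if sub["he"].sum() > 0 else np.nan
        summary_rows.append({
            "group": name,
            "n": len(groups[name]),
            "mean_ho": sub["ho"].mean(),
            "mean_he": sub["he"].mean(),
            "fis_multilocus": fis_ml,
            "a_r": rar.richness_means[name],
        })
    return DiversityTable(per_locus, pd.DataFrame(summary_rows), g_std)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact tests
# ---------------------------------------------------------------------------


def _log_table_prob(counts: dict[tuple[int, int], int], allele_counts_: dict[int, int]) -> float:
    """Log Levene probability of a genotype table given its allele counts."""
    n = sum(counts.values())
    het = sum(c for (a, b), c in counts.items() if a != b)
    lp = gammaln(n + 1) - sum(gammaln(c + 1) for c in counts.values())
    lp += het * math.log(2)
    lp += sum(gammaln(c + 1) for c in allele_counts_.values()) - gammaln(2 * n + 1)
    return float(lp)


def _enumerate_tables(allele_counts_: dict[int, int]):
    """Yield every genotype count table consistent with the allele counts."""
    alleles = sorted(allele_counts_)
    cats = [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]

    def rec(i, remaining, table):
        if i == len(cats):
            if all(v == 0 for v in remaining.values()):
                yield dict(table)
            return
        a, b = cats[i]
        if a == b:
            cap = remaining[a] // 2
        else:
            cap = min(remaining[a], remaining[b])
        for c in range(cap + 1):
            remaining[a] -= c * (2 if a == b else 1)
            if a != b:
                remaining[b] -= c
            table[(a, b)] = c
            yield from rec(i + 1, remaining, table)
            remaining[a] += c * (2 if a == b else 1)
            if a != b:
                remaining[b] += c
        table.pop(cats[i], None)

    yield from rec(0, dict(allele_counts_), {})


def _hwe_exact_enumerate(obs: dict[tuple[int, int], int]) -> float:
    allele_counts_: dict[int, int] = {}
    for (a, b), c in obs.items():
        allele_counts_[a] = allele_counts_.get(a, 0) + c * (2 if a == b else 1)
        if a != b:
            allele_counts_[b] = allele_counts_.get(b, 0) + c
    lp_obs = _log_table_prob(obs, allele_counts_)
    p = 0.0
    for table in _enumerate_tables(allele_counts_):
        lp = _log_table_prob(table, allele_counts_)
        if lp <= lp_obs + 1e-9:
            p += math.exp(lp)
    return min(p, 1.0)


def _hwe_mcmc(
    genos: list[tuple[int, int]], chain: int, demem: int, rng: np.random.Generator
) -> float:
    """Markov-chain exact HWE test (allele-switch proposals, Metropolis).

    The chain walks over labeled genotype lists: two individuals swap one
    gene each. Proposals are symmetric in list space, and each genotype
    table corresponds to n!/prod(m_g!) lists, so the list-level target
    density that makes the table marginal equal the Levene distribution is
    proportional to 2^het alone. The p-value is the visited fraction of
    tables whose Levene probability does not exceed the observed one.
    """
    genos = [tuple(sorted(g)) for g in genos]
    counts: dict[tuple[int, int], int] = {}
    for g in genos:
        counts[g] = counts.get(g, 0) + 1
    het = sum(1 for g in genos if g[0] != g[1])
    lfac = lambda c: float(gammaln(c + 1))
    # table log-probability up to the allele-count constant
    log_table = -sum(lfac(c) for c in counts.values()) + het * math.log(2)
    log_obs = log_table
    n = len(genos)
    hits = 0
    samples = 0
    pick = rng.integers(0, n, size=(chain + demem, 2))
    pos = rng.integers(0, 2, size=(chain + demem, 2))
    us = rng.uniform(size=chain + demem)
    log2 = math.log(2)
    for step in range(chain + demem):
        i, j = pick[step]
        if i != j:
            g1, g2 = genos[i], genos[j]
            x, y = g1[pos[step, 0]], g2[pos[step, 1]]
            if x != y:
                g1n = tuple(sorted((g1[1 - pos[step, 0]], y)))
                g2n = tuple(sorted((g2[1 - pos[step, 1]], x)))
                dhet = (
                    int(g1n[0] != g1n[1]) + int(g2n[0] != g2n[1])
                    - int(g1[0] != g1[1]) - int(g2[0] != g2[1])
                )
                # Hastings ratio on the list-level target 2^het with the
                # gene-pick correction: a homozygote offers its allele at
                # both positions, a heterozygote at one
                c1 = 2 if g1[0] == g1[1] else 1
                c2 = 2 if g2[0] == g2[1] else 1
                c1n = 2 if g1n[0] == g1n[1] else 1
                c2n = 2 if g2n[0] == g2n[1] else 1
                ratio = math.exp(dhet * log2) * (c1n * c2n) / (c1 * c2)
                if ratio >= 1 or us[step] < ratio:
                    affected = {}
                    for g in (g1, g2, g1n, g2n):
                        affected[g] = counts.get(g, 0)
                    new = dict(affected)
                    new[g1] -= 1
                    new[g2] -= 1
                    new[g1n] = new.get(g1n, 0) + 1
                    new[g2n] = new.get(g2n, 0) + 1
                    log_table += (
                        sum(lfac(affected[g]) for g in affected)
                        - sum(lfac(new[g]) for g in new)
                        + dhet * log2
                    )
                    genos[i], genos[j] = g1n, g2n
                    for g, c in new.items():
                        if c:
                            counts[g] = c
                        else:
                            counts.pop(g, None)
        if step >= demem:
            samples += 1
            if log_table <= log_obs + 1e-9:
                hits += 1
    return (hits + 1) / (samples + 1)


def hwe_test(
    genotypes: GenotypeTable,
    grouping: np.ndarray,
    chain: int = 100_000,
    dememorization: int = 1_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Exact Hardy-Weinberg test per locus within each group.

    Complete enumeration of genotype tables (Levene distribution) when the
    locus carries <= 3 alleles and few individuals; otherwise a
    Metropolis Markov chain over tables with the stated chain length and
    dememorization (burn-in). Monomorphic loci return p = 1.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    logger.info("HWE test: chain=%d demem=%d seed=%d", chain, dememorization, seed)
    groups = _group_indices(grouping)
    rows = []
    for name, idx in groups.items():
        for l, locus in enumerate(genotypes.locus_names):
            calls = genotypes.calls[idx, l, :]
            typed = calls[calls[:, 0] > 0]
            if typed.shape[0] < 5:
                rows.append({"group": name, "locus": locus, "p": np.nan,
                             "method": "insufficient"})
                continue
            alleles = np.unique(typed.ravel())
            if len(alleles) == 1:
                rows.append({"group": name, "locus": locus, "p": 1.0,
                             "method": "monomorphic"})
                continue
            genos = [tuple(sorted(g)) for g in typed]
            if len(alleles) <= 3 and typed.shape[0] <= 12:
                obs: dict[tuple[int, int], int] = {}
                for g in genos:
                    obs[g] = obs.get(g, 0) + 1
                p = _hwe_exact_enumerate(obs)
                method = "enumeration"
            else:
                p = _hwe_mcmc(genos, chain, dememorization, rng)
                method = "mcmc"
            rows.append({"group": name, "locus": locus, "p": p, "method": method})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_pairwise_tests(
    genotypes: GenotypeTable,
    grouping: np.ndarray,
    permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Permutation G-test of genotypic linkage disequilibrium per locus pair.

    Within each group, the two-locus genotype contingency table's
    G-statistic is compared against a null built by shuffling one locus'
    genotypes across individuals. Pairs with fewer than two genotype
    categories at either locus are skipped and counted as untested.
    """
    if genotypes.n_loci < 2:
        raise ValueError("need at least two loci")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    groups = _group_indices(grouping)

    def g_stat(ix: np.ndarray, iy: np.ndarray, nx: int, ny: int) -> float:
        tab = np.bincount(ix * ny + iy, minlength=nx * ny).reshape(nx, ny).astype(float)
        tot = tab.sum()
        exp = np.outer(tab.sum(1), tab.sum(0)) / tot
        nz = tab > 0
        return float(2 * np.sum(tab[nz] * np.log(tab[nz] / exp[nz])))

    def genotype_codes(calls: np.ndarray) -> tuple[np.ndarray, int]:
        lo = calls.min(axis=1)
        hi = calls.max(axis=1)
        _, codes = np.unique(lo * 10_000 + hi, return_inverse=True)
        return codes, int(codes.max()) + 1

    rows = []
    for name, idx in groups.items():
        for l1, l2 in itertools.combinations(range(genotypes.n_loci), 2):
            both = ~genotypes.missing[idx][:, l1] & ~genotypes.missing[idx][:, l2]
            sub = idx[both]
            x, nx = genotype_codes(genotypes.calls[sub, l1, :])
            y, ny = genotype_codes(genotypes.calls[sub, l2, :])
            if nx < 2 or ny < 2:
                rows.append({"group": name, "locus1": genotypes.locus_names[l1],
                             "locus2": genotypes.locus_names[l2], "g": np.nan,
                             "p": np.nan, "tested": False})
                continue
            g_obs = g_stat(x, y, nx, ny)
            hits = 0
            for _ in range(permutations):
                if g_stat(x, rng.permutation(y), nx, ny) >= g_obs - 1e-12:
                    hits += 1
            rows.append({"group": name, "locus1": genotypes.locus_names[l1],
                         "locus2": genotypes.locus_names[l2], "g": g_obs,
                         "p": (hits + 1) / (permutations + 1), "tested": True})
    df = pd.DataFrame(rows)
    tested = df[df["tested"]]
    n_sig = int((tested["p"] < alpha).sum())
    summary = {
        "n_comparisons": len(df),
        "n_tested": len(tested),
        "n_significant": n_sig,
        "pct_significant": 100 * n_sig / len(df) if len(df) else np.nan,
    }
    return df, summary


# ---------------------------------------------------------------------------
# Weir-Cockerham theta and pairwise F_ST
# ---------------------------------------------------------------------------


def _wc_components(
    C: np.ndarray, H: np.ndarray, T: np.ndarray, slices: list[slice],
    group_idx: list[np.ndarray],
) -> tuple[float, float, float]:
    """Summed Weir-Cockerham variance components (a, b, c) over loci and alleles."""
    sum_a = sum_b = sum_c = 0.0
    r_total = len(group_idx)
    for l, sl in enumerate(slices):
        n_i = np.array([T[idx, l].sum() for idx in group_idx])
        use = n_i > 0
        if use.sum() < 2:
            continue
        n_i = n_i[use]
        r = len(n_i)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
        if nc <= 0:
            continue
        Cg = np.stack([C[idx][:, sl].sum(axis=0) for k, idx in enumerate(group_idx) if use[k]])
        Hg = np.stack([H[idx][:, sl].sum(axis=0) for k, idx in enumerate(group_idx) if use[k]])
        p_i = Cg / (2 * n_i[:, None])
        h_i = Hg / n_i[:, None]
        pbar = (n_i[:, None] * p_i).sum(axis=0) / n_i.sum()
        s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i[:, None] * h_i).sum(axis=0) / n_i.sum()
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        sum_a += a.sum()
        sum_b += b.sum()
        sum_c += c.sum()
    return sum_a, sum_b, sum_c


def weir_cockerham_theta(genotypes: GenotypeTable, grouping: np.ndarray) -> float:
    """Multilocus Weir-Cockerham theta (ratio of sums over loci and alleles).

    Negative estimates are reported as computed, never truncated.
    """
    groups = _group_indices(grouping)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    C, H, T, slices = _onehot(genotypes)
    a, b, c = _wc_components(C, H, T, slices, list(groups.values()))
    denom = a + b + c
    return float(a / denom) if denom != 0 else np.nan


@dataclass
class FstMatrix:
    """Pairwise theta matrix with permutation p-values and FDR flags."""

    groups: list[str]
    theta: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame
    permutations: int

    def pairs(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.groups):
            for b in self.groups[i + 1:]:
                rows.append({"group1": a, "group2": b,
                             "theta": self.theta.loc[a, b],
                             "p": self.pvalues.loc[a, b],
                             "significant": bool(self.significant.loc[a, b])})
        return pd.DataFrame(rows)


def pairwise_fst(
    genotypes: GenotypeTable,
    grouping: np.ndarray,
    permutations: int = 10_000,
    seed: int = 0,
    fdr_q: float = 0.05,
) -> FstMatrix:
    """Pairwise multilocus theta with permutation tests and BH-FDR flags.

    For each group pair, individuals are permuted between the two groups;
    p = (number of permuted theta >= observed + 1)/(permutations + 1).
    """
    groups = _group_indices(grouping)
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    for g, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"group {g} has fewer than 2 individuals")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 707]))
    logger.info("pairwise F_ST: %d permutations, seed=%d", permutations, seed)
    C, H, T, slices = _onehot(genotypes)
    theta = pd.DataFrame(0.0, index=names, columns=names)
    pval = pd.DataFrame(np.nan, index=names, columns=names)
    raw_ps, pair_list = [], []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ia, ib = groups[a], groups[b]
            both = np.concatenate([ia, ib])
            n1 = len(ia)

            def theta_of(split_a, split_b):
                aa, bb, cc = _wc_components(C, H, T, slices, [split_a, split_b])
                d = aa + bb + cc
                return aa / d if d != 0 else np.nan

            obs = theta_of(ia, ib)
            hits = 0
            for _ in range(permutations):
                perm = rng.permutation(both)
                t = theta_of(perm[:n1], perm[n1:])
                if np.isnan(t) or t >= obs - 1e-12:
                    hits += 1
            p = (hits + 1) / (permutations + 1)
            theta.loc[a, b] = theta.loc[b, a] = obs
            pval.loc[a, b] = pval.loc[b, a] = p
            raw_ps.append(p)
            pair_list.append((a, b))
            if obs < 0:
                logger.info("negative theta for %s vs %s: %.4g (reported as computed)",
                            a, b, obs)
    reject, _ = bh_fdr(np.array(raw_ps), q=fdr_q)
    sig = pd.DataFrame(False, index=names, columns=names)
    for (a, b), flag in zip(pair_list, reject):
        sig.loc[a, b] = sig.loc[b, a] = bool(flag)
    return FstMatrix(names, theta, pval, sig, permutations)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Two-level AMOVA: among-group and within-group variance components."""

    grouping_name: str
    sigma_among: float
    sigma_within: float       # among-individual + within-individual components
    sigma_among_ind: float
    sigma_within_ind: float
    phi_st: float
    p: float
    permutations: int


def _amova_components(
    C: np.ndarray, T: np.ndarray, slices: list[slice], group_idx: list[np.ndarray],
    het: np.ndarray,
) -> tuple[float, float, float]:
    """AMOVA variance components (among groups, among ind., within ind.).

    Sums of squared deviations on per-gene allele indicator vectors
    (half squared Euclidean distances), locus by locus, summed over loci.
    """
    sa = sb = sc = 0.0
    for l, sl in enumerate(slices):
        n_i = np.array([T[idx, l].sum() for idx in group_idx])
        use = n_i > 0
        if use.sum() < 2:
            continue
        n_i = n_i[use]
        r = len(n_i)
        N = n_i.sum()
        if N <= r:
            continue
        nc = (N - (n_i**2).sum() / N) / (r - 1)
        Cg = np.stack([C[idx][:, sl].sum(axis=0)
                       for k, idx in enumerate(group_idx) if use[k]])
        gbar_pop = Cg / (2 * n_i[:, None])
        gbar = Cg.sum(axis=0) / (2 * N)
        ss_ap = float((n_i[:, None] * (gbar_pop - gbar) ** 2).sum())
        # among individuals within pops: sum_i ||gbar_i - gbar_pop||^2
        ss_ai = 0.0
        for k, idx in enumerate([g for q, g in enumerate(group_idx) if use[q]]):
            typed = idx[T[idx, l] > 0]
            gi = C[typed][:, sl] / 2
            ss_ai += float(((gi - gbar_pop[k]) ** 2).sum())
        ss_wi = float(het[:, l][np.concatenate(group_idx)].sum()) / 2
        ms_ap = ss_ap / (r - 1)
        ms_ai = ss_ai / (N - r)
        ms_wi = ss_wi / N
        sc += ms_wi
        sb += (ms_ai - ms_wi) / 2
        sa += (ms_ap - ms_ai) / (2 * nc)
    return sa, sb, sc


def amova(
    genotypes: GenotypeTable,
    grouping: np.ndarray,
    permutations: int = 10_000,
    seed: int = 0,
    grouping_name: str = "grouping",
) -> AmovaResult:
    """Analysis of molecular variance over the given individual grouping.

    Variance is partitioned among groups, among individuals within groups
    and within individuals from allele-based sums of squares; Phi_ST is the
    among-group fraction. Significance by permuting individuals among
    groups. Negative components are retained (not zeroed) and logged.
    """
    groups = _group_indices(grouping)
    if len(groups) < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 808]))
    C, H, T, slices = _onehot(genotypes)
    # het per locus: individual is heterozygous iff any allele carried once
    het_locus = np.zeros_like(T)
    for l, sl in enumerate(slices):
        het_locus[:, l] = (H[:, sl].sum(axis=1) > 0).astype(float)

    idx_list = list(groups.values())
    sa, sb, sc = _amova_components(C, T, slices, idx_list, het_locus)
    if sa < 0 or sb < 0:
        logger.info("negative AMOVA variance component retained: a=%.4g b=%.4g", sa, sb)
    total = sa + sb + sc
    phi = sa / total if total != 0 else np.nan

    sizes = [len(i) for i in idx_list]
    all_idx = np.concatenate(idx_list)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(all_idx)
        splits, off = [], 0
        for s in sizes:
            splits.append(perm[off:off + s])
            off += s
        pa, pb, pc = _amova_components(C, T, slices, splits, het_locus)
        ptot = pa + pb + pc
        pphi = pa / ptot if ptot != 0 else np.nan
        if np.isnan(pphi) or pphi >= phi - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return AmovaResult(grouping_name, sa, sb + sc, sb, sc, float(phi), p, permutations)


# ---------------------------------------------------------------------------
# Rarefied (private) allelic richness
# ---------------------------------------------------------------------------


@dataclass
class RarefactionResult:
    """ADZE-style rarefaction at standardized gene count g."""

    g: int
    richness: pd.DataFrame            # group x locus expected distinct alleles
    richness_means: dict[str, float]  # per group, mean over loci
    private: dict[str, float]         # per group, mean private alleles per locus
    generalized: dict[frozenset, float]  # per group subset, mean per locus


def _presence_prob(N: int, Ni: int, g: int) -> float:
    """P(allele with Ni copies out of N genes appears in a subsample of g)."""
    if Ni == 0:
        return 0.0
    if N - Ni < g:
        return 1.0
    return 1.0 - math.exp(
        gammaln(N - Ni + 1) - gammaln(N - Ni - g + 1) - gammaln(N + 1) + gammaln(N - g + 1)
    )


def rarefied_richness(
    genotypes: GenotypeTable,
    grouping: np.ndarray,
    g: int,
    subsets: str = "singletons",
) -> RarefactionResult:
    """Rarefied allelic richness and (generalized) private allelic richness.

    E[A] per locus is the sum over alleles of their presence probability in
    a hypergeometric subsample of ``g`` genes. Private richness of a group
    sums, per allele, the probability it appears in that group's subsample
    and in no other group's. ``subsets='all'`` additionally evaluates every
    group combination (allele present in every member, absent elsewhere).
    ``g`` larger than a group's gene count is clipped with a warning.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    counts = allele_counts(genotypes, grouping)
    names = list(counts)
    L = genotypes.n_loci
    union = [
        sorted(set().union(*[set(counts[gr][l]) for gr in names])) for l in range(L)
    ]
    # per-group per-locus clip of g
    richness = pd.DataFrame(index=names, columns=genotypes.locus_names, dtype=float)
    Q: dict[str, list[np.ndarray]] = {}
    for gr in names:
        qs = []
        for l in range(L):
            N = sum(counts[gr][l].values())
            g_eff = g
            if g > N:
                logger.warning("g=%d exceeds gene count %d for group %s locus %d; clipped",
                               g, N, gr, l)
                g_eff = N
            q = np.array([
                _presence_prob(N, counts[gr][l].get(a, 0), g_eff) if N else 0.0
                for a in union[l]
            ])
            qs.append(q)
            richness.loc[gr, genotypes.locus_names[l]] = q.sum()
        Q[gr] = qs
    richness_means = {gr: float(richness.loc[gr].mean()) for gr in names}

    def subset_private(members: frozenset) -> float:
        per_locus = []
        for l in range(L):
            inside = np.prod([Q[m][l] for m in members], axis=0)
            outside = np.prod([1 - Q[o][l] for o in names if o not in members], axis=0) \
                if len(members) < len(names) else 1.0
            per_locus.append(float((inside * outside).sum()))
        return float(np.mean(per_locus))

    private = {gr: subset_private(frozenset([gr])) for gr in names}
    generalized: dict[frozenset, float] = {}
    if subsets == "all":
        for size in range(1, len(names)):
            for combo in itertools.combinations(names, size):
                generalized[frozenset(combo)] = subset_private(frozenset(combo))
    else:
        generalized = {frozenset([gr]): v for gr, v in private.items()}
    return RarefactionResult(g, richness, richness_means, private, generalized)


# ---------------------------------------------------------------------------
# Genetic distances and trees
# ---------------------------------------------------------------------------


def smouse_peakall_distance(genotypes: GenotypeTable) -> np.ndarray:
    """Individual pairwise genetic distance on allele-count vectors.

    Per shared typed locus, half the squared Euclidean distance between the
    two individuals' allele-count vectors, summed over loci. Pairs with no
    shared typed locus get NaN (flagged in the log).
    """
    C, _, T, slices = _onehot(genotypes)
    n = genotypes.n_individuals
    D = np.zeros((n, n))
    shared = np.zeros((n, n))
    for l, sl in enumerate(slices):
        X = C[:, sl]
        t = T[:, l]
        ss = (X**2).sum(axis=1)
        sq = ss[:, None] + ss[None, :] - 2 * X @ X.T
        mask = np.outer(t, t)
        D += 0.5 * np.maximum(sq, 0) * mask
        shared += mask
    D[shared == 0] = np.nan
    if np.isnan(D).any():
        logger.warning("individual pairs with no shared typed locus: distance missing")
    np.fill_diagonal(D, 0.0)
    return D


def chord_distance(freqs: dict[str, list[np.ndarray]]) -> pd.DataFrame:
    """Cavalli-Sforza chord distance between populations.

    Per locus, ``cos(theta) = sum_i sqrt(p_i q_i)`` and the locus distance
    is ``sqrt(2 * (1 - cos(theta)))``; the population distance is the mean
    over loci shared (typed in both populations). Zero iff the frequency
    vectors are identical at every shared locus.
    """
    names = list(freqs)
    if len(names) < 2:
        raise ValueError("need >= 2 populations")
    D = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            per_locus = []
            for fa, fb in zip(freqs[a], freqs[b]):
                if np.isnan(fa).any() or np.isnan(fb).any():
                    logger.info("locus untyped in %s or %s; dropped for the pair", a, b)
                    continue
                cos_t = float(np.sqrt(fa * fb).sum())
                per_locus.append(math.sqrt(max(2 * (1 - min(cos_t, 1.0)), 0.0)))
            if not per_locus:
                raise ValueError(f"populations {a} and {b} share no typed locus")
            D.loc[a, b] = D.loc[b, a] = float(np.mean(per_locus))
    return D


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of an (arbitrarily rooted) tree.

    Each internal edge is encoded as the side of the split *not* containing
    the alphabetically first taxon, so rootings compare equal.
    """
    ref = min(taxa)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if len(side) >= 2 and len(taxa) - len(side) >= 2:
            parts.add(side)
    return parts


def nj_tree(
    distmatrix: pd.DataFrame,
    bootstrap_replicates: int = 1000,
    genotypes: GenotypeTable | None = None,
    grouping: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset, float], str]:
    """Saitou-Nei neighbour-joining tree with optional locus bootstrap.

    When ``genotypes`` (and ``grouping``) are given, bootstrap replicates
    resample loci with replacement, recompute chord distances and rebuild
    the tree; supports are majority percentages of replicates containing
    each bipartition of the reference tree. Returns the tree, the support
    map and a Newick string with supports as internal node labels.
    """
    names = list(distmatrix.index)
    if len(names) < 3:
        raise ValueError("need >= 3 populations for a tree")
    dm = DistanceMatrix(distmatrix.to_numpy(float), ids=names)
    tree = nj(dm)
    taxa = frozenset(names)
    supports: dict[frozenset, float] = {}
    if genotypes is not None and grouping is not None and bootstrap_replicates > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 909]))
        ref_parts = _bipartitions(tree, taxa)
        tally = {p: 0 for p in ref_parts}
        L = genotypes.n_loci
        for _ in range(bootstrap_replicates):
            pick = rng.integers(0, L, size=L)
            boot = GenotypeTable(
                list(genotypes.individual_ids),
                [f"L{i}" for i in range(L)],
                genotypes.calls[:, pick, :],
            )
            fr, _ = allele_frequencies(boot, grouping)
            bt = nj(DistanceMatrix(chord_distance(fr).to_numpy(float), ids=list(fr)))
            bparts = _bipartitions(bt, taxa)
            for part in ref_parts:
                if part in bparts:
                    tally[part] += 1
        supports = {p: 100 * c / bootstrap_replicates for p, c in tally.items()}
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if min(taxa) in side:
                side = taxa - side
            if side in supports:
                node.name = f"{supports[side]:.1f}"
    newick = str(tree).strip()
    return tree, supports, newick


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, monotone adjusted p)."""
    pvalues = np.asarray(pvalues, float)
    if ((pvalues < 0) | (pvalues > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject, adjusted
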