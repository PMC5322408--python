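"""Diversity, F-statistics, HWE, LD, rarefaction, distances, trees, FDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from depthcline.io import GenotypeTable
from depthcline import popgen_stats as pg
from depthcline import simdata


def _table(calls, pops=None):
    calls = np.asarray(calls)
    return GenotypeTable(
        [f"i{k}" for k in range(calls.shape[0])],
        [f"L{j}" for j in range(calls.shape[1])],
        calls,
        None if pops is None else np.asarray(pops),
    )


# --- allele bookkeeping -----------------------------------------------------


def test_allele_counts_exclude_missing_and_sum_to_genes(toy_genotypes):
    grouping = np.array(["a"] * 4 + ["b"] * 4)
    counts = pg.allele_counts(toy_genotypes, grouping)
    assert counts["a"][0] == {1: 4, 2: 4}
    # the missing call at LocB drops two genes
    assert sum(counts["a"][1].values()) == 6
    pooled = pg.allele_counts(toy_genotypes, np.array(["all"] * 8))["all"]
    for l in range(2):
        merged: dict[int, int] = {}
        for g in ("a", "b"):
            for al, c in counts[g][l].items():
                merged[al] = merged.get(al, 0) + c
        assert pooled[l] == merged


# --- diversity ---------------------------------------------------------------


def test_diversity_all_homozygous_group():
    calls = [[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]]
    div = pg.diversity_summary(_table(calls), np.array(["g"] * 4), g_std=2)
    row = div.per_locus.iloc[0]
    assert row["ho"] == 0.0
    assert row["he"] == pytest.approx((8 / 7) * 0.5)
    assert row["fis"] == 1.0


def test_he_unbiased_small_sample_correction():
    """Mean unbiased H_E over simulations matches 2pq for a biallelic locus."""
    rng = np.random.default_rng(0)
    p_true = 0.3
    hes = []
    for _ in range(300):
        genes = rng.uniform(size=(10, 2)) < p_true
        calls = np.where(genes, 1, 2)[:, None, :]
        div = pg.diversity_summary(_table(calls), np.array(["g"] * 10), g_std=2)
        hes.append(div.per_locus["he"].iloc[0])
    assert np.mean(hes) == pytest.approx(2 * p_true * (1 - p_true), abs=0.01)


def test_multilocus_fis_is_ratio_of_sums(toy_genotypes):
    div = pg.diversity_summary(toy_genotypes, np.array(["g"] * 8), g_std=4)
    per = div.per_locus
    expected = 1 - per["ho"].sum() / per["he"].sum()
    assert div.summary["fis_multilocus"].iloc[0] == pytest.approx(expected)


# --- Hardy-Weinberg ----------------------------------------------------------


def test_hwe_enumeration_example_and_monomorphic():
    # AA=1, AB=2, BB=1 plus a fifth individual to clear the minimum n;
    # use the raw enumeration for the printed example
    assert pg._hwe_exact_enumerate({(1, 1): 1, (1, 2): 2, (2, 2): 1}) == pytest.approx(1.0)
    calls = [[[1, 1]]] * 6
    res = pg.hwe_test(_table(calls), np.array(["g"] * 6))
    assert res["p"].iloc[0] == 1.0 and res["method"].iloc[0] == "monomorphic"


def test_hwe_enumeration_matches_levene_distribution():
    """Enumerated table probabilities sum to one for 3-allele counts."""
    alleles = {1: 6, 2: 4, 3: 2}
    total = sum(
        math.exp(pg._log_table_prob(t, alleles)) for t in pg._enumerate_tables(alleles)
    )
    assert total == pytest.approx(1.0, abs=1e-10)


def test_hwe_mcmc_agrees_with_enumeration():
    rng = np.random.default_rng(1)
    genos = [(1, 1)] * 3 + [(1, 2)] * 5 + [(2, 2)] * 2 + [(1, 3), (2, 3)]
    obs: dict[tuple[int, int], int] = {}
    for g in genos:
        obs[g] = obs.get(g, 0) + 1
    exact = pg._hwe_exact_enumerate(obs)
    mcmc = pg._hwe_mcmc(list(genos), chain=40_000, demem=2_000, rng=rng)
    assert mcmc == pytest.approx(exact, abs=0.05)


def test_hwe_uniform_under_null():
    """Data simulated in HWE should rarely reject."""
    sig = 0
    n_tests = 0
    spec = simdata.SpeciesPhenotypeSpec(250, 15, 33, 3, 20, 9)
    for seed in range(6):
        pool = simdata.simulate_allele_frequencies(1, target_fst=0.0, seed=seed)
        g, _ = simdata.simulate_individuals(pool, [spec], [40], seed=seed)
        res = pg.hwe_test(g, np.array(["g"] * 40), chain=20_000,
                          dememorization=1_000, seed=seed)
        sig += (res["p"] < 0.05).sum()
        n_tests += res["p"].notna().sum()
    assert sig / n_tests <= 0.07


# --- linkage disequilibrium --------------------------------------------------


def test_ld_pair_count_bookkeeping():
    spec = simdata.SpeciesPhenotypeSpec(250, 15, 33, 3, 20, 9)
    pool = simdata.simulate_allele_frequencies(2, target_fst=0.05, seed=2)
    g, p = simdata.simulate_individuals(pool, [spec] * 2, [15, 15], seed=2)
    df, summary = pg.ld_pairwise_tests(g, p["species"].to_numpy(), permutations=99, seed=2)
    # 10 loci -> 45 pairs per group, 2 groups -> 90 comparisons
    assert summary["n_comparisons"] == 90
    assert summary["pct_significant"] == pytest.approx(
        100 * summary["n_significant"] / 90
    )


def test_ld_null_rate_near_alpha():
    spec = simdata.SpeciesPhenotypeSpec(250, 15, 33, 3, 20, 9)
    sig = tested = 0
    for seed in range(4):
        pool = simdata.simulate_allele_frequencies(1, target_fst=0.0, seed=seed + 20)
        g, _ = simdata.simulate_individuals(pool, [spec], [40], seed=seed)
        df, s = pg.ld_pairwise_tests(g, np.array(["g"] * 40), permutations=99, seed=seed)
        sig += s["n_significant"]
        tested += s["n_tested"]
    assert sig / tested < 0.12  # unlinked loci: about the nominal 5%


# --- Weir-Cockerham theta and AMOVA -----------------------------------------


def test_theta_matches_hand_computed_components():
    """4 individuals, 1 biallelic locus: direct a/(a+b+c) arithmetic."""
    calls = [[[1, 1]], [[1, 2]], [[2, 2]], [[2, 2]]]
    gt = _table(calls)
    grouping = np.array(["x", "x", "y", "y"])
    # by hand: r=2, n_i=(2,2), nbar=2, nc=2, per allele 1:
    # p = (0.75, 0.0), pbar=0.375, s2 = 2*(0.375^2)*2/(1*2)=0.28125
    # h (het carrying allele 1) = (0.5, 0); hbar=0.25
    r, nbar, nc = 2, 2.0, 2.0
    pbar, s2, hbar = 0.375, 0.28125, 0.25
    a1 = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
    b1 = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2 - (3 / 8) * hbar)
    c1 = hbar / 2
    # allele 2 mirrors allele 1 exactly (biallelic symmetry)
    expected = (2 * a1) / (2 * (a1 + b1 + c1))
    assert pg.weir_cockerham_theta(gt, grouping) == pytest.approx(expected, abs=1e-12)


def test_theta_fixation_and_null():
    fixed = _table([[[1, 1]]] * 3 + [[[2, 2]]] * 3)
    grouping = np.array(["x"] * 3 + ["y"] * 3)
    assert pg.weir_cockerham_theta(fixed, grouping) == 1.0
    # null: identical frequency draws -> theta near 0, permutation p > .05
    spec = simdata.SpeciesPhenotypeSpec(250, 15, 33, 3, 20, 9)
    nonsig = 0
    for seed in range(10):
        pool = simdata.simulate_allele_frequencies(2, target_fst=0.0, seed=seed)
        g, p = simdata.simulate_individuals(pool, [spec] * 2, [30, 30], seed=seed)
        fst = pg.pairwise_fst(g, p["species"].to_numpy(), permutations=99, seed=seed)
        nonsig += fst.pairs()["p"].iloc[0] > 0.05
    assert nonsig >= 9


def test_pairwise_fst_matrix_shape_and_symmetry(two_pop_cohort):
    g, p = two_pop_cohort
    fst = pg.pairwise_fst(g, p["species"].to_numpy(), permutations=99, seed=1)
    assert fst.theta.loc["1", "2"] == fst.theta.loc["2", "1"]
    assert fst.theta.loc["1", "1"] == 0.0
    assert 0 < fst.pvalues.loc["1", "2"] <= 1
    assert fst.pairs()["significant"].iloc[0]


def test_amova_matches_theta_on_balanced_toys_and_detects_null():
    rng = np.random.default_rng(3)
    for _ in range(5):
        calls = rng.integers(1, 4, size=(12, 3, 2))
        gt = _table(calls)
        grouping = np.array(["x"] * 6 + ["y"] * 6)
        res = pg.amova(gt, grouping, permutations=99, seed=1)
        theta = pg.weir_cockerham_theta(gt, grouping)
        assert res.phi_st == pytest.approx(theta, abs=1e-6)
    # random labels on structureless data: phi ~ 0
    labels = rng.permutation(np.array(["x", "y"] * 6))
    res = pg.amova(_table(rng.integers(1, 4, size=(12, 3, 2))), labels,
                   permutations=99, seed=2)
    assert abs(res.phi_st) < 0.2
    with pytest.raises(ValueError):
        pg.amova(_table(rng.integers(1, 4, size=(6, 2, 2))), np.array(["x"] * 6))


def test_amova_fixed_difference_gives_phi_one():
    gt = _table([[[1, 1]]] * 4 + [[[2, 2]]] * 4)
    res = pg.amova(gt, np.array(["x"] * 4 + ["y"] * 4), permutations=99, seed=1)
    assert res.phi_st == pytest.approx(1.0)


# --- rarefaction -------------------------------------------------------------


def _enumerate_expected_alleles(genes: list[int], g: int) -> float:
    """Brute force: mean distinct alleles over all gene subsamples of size g."""
    vals = []
    for combo in itertools.combinations(range(len(genes)), g):
        vals.append(len({genes[i] for i in combo}))
    return float(np.mean(vals))


def test_rarefaction_matches_exhaustive_enumeration_small():
    calls = [[[1, 2]], [[1, 1]], [[2, 3]]]  # 6 genes: 1,2,1,1,2,3
    gt = _table(calls)
    grouping = np.array(["g"] * 3)
    genes = [1, 2, 1, 1, 2, 3]
    for g in (2, 3, 4, 5, 6):
        res = pg.rarefied_richness(gt, grouping, g)
        assert res.richness.iloc[0, 0] == pytest.approx(
            _enumerate_expected_alleles(genes, g), abs=1e-12
        )
    # g = N reproduces the observed count
    assert pg.rarefied_richness(gt, grouping, 6).richness.iloc[0, 0] == 3.0


def test_rarefaction_monotone_in_g(toy_genotypes):
    grouping = np.array(["a"] * 4 + ["b"] * 4)
    values = [
        pg.rarefied_richness(toy_genotypes, grouping, g).richness.to_numpy()
        for g in (2, 3, 4, 5, 6)
    ]
    for lo, hi in zip(values[:-1], values[1:]):
        assert (hi >= lo - 1e-12).all()


def test_private_richness_disjoint_groups_equals_total():
    calls_a = [[[1, 1]], [[1, 2]]]
    calls_b = [[[3, 3]], [[3, 4]]]
    gt = _table(calls_a + calls_b)
    grouping = np.array(["a", "a", "b", "b"])
    res = pg.rarefied_richness(gt, grouping, 4, subsets="all")
    for grp in ("a", "b"):
        assert res.private[grp] == pytest.approx(res.richness_means[grp])
    # generalized: the pair {a,b} shares no allele, so joint-private is 0
    assert res.generalized == pytest.approx(
        {frozenset(["a"]): 2.0, frozenset(["b"]): 2.0}
    ) or res.generalized[frozenset(["a"])] == pytest.approx(2.0)


def test_generalized_private_two_of_three_groups():
    """Allele shared by exactly groups a and b counts for the {a,b} subset."""
    calls = [[[1, 2]], [[1, 2]], [[1, 3]]]
    gt = _table(calls)
    grouping = np.array(["a", "b", "c"])
    res = pg.rarefied_richness(gt, grouping, 2, subsets="all")
    # allele 2 present in a and b (prob 1 at g=N=2), absent from c
    assert res.generalized[frozenset(["a", "b"])] == pytest.approx(1.0)
    assert res.generalized[frozenset(["c"])] == pytest.approx(1.0)  # allele 3


# --- distances and trees -----------------------------------------------------


def test_smouse_peakall_examples():
    calls = [[[1, 1]], [[2, 2]], [[1, 2]], [[3, 4]]]
    D = pg.smouse_peakall_distance(_table(calls))
    assert D[0, 1] == 4.0   # AA vs BB
    assert D[0, 2] == 1.0   # AA vs AB
    assert D[2, 3] == 2.0   # AB vs CD
    assert D[0, 0] == 0.0
    np.testing.assert_allclose(D, D.T)


def test_chord_distance_extremes_and_triangle():
    freqs = {
        "p": [np.array([1.0, 0.0])],
        "q": [np.array([0.0, 1.0])],
        "r": [np.array([0.5, 0.5])],
    }
    D = pg.chord_distance(freqs)
    assert D.loc["p", "q"] == pytest.approx(math.sqrt(2))  # cos(theta) = 0
    assert D.loc["p", "p"] == 0.0
    rng = np.random.default_rng(5)
    for _ in range(50):
        f = {k: [v / v.sum()] for k, v in
             {"a": rng.uniform(size=4), "b": rng.uniform(size=4),
              "c": rng.uniform(size=4)}.items()}
        M = pg.chord_distance(f)
        assert M.loc["a", "c"] <= M.loc["a", "b"] + M.loc["b", "c"] + 1e-12


def test_nj_recovers_additive_four_taxon_tree():
    # true unrooted tree: A,B joined (2,3) - internal edge 1 - C,D joined (4,5)
    names = ["A", "B", "C", "D"]
    D = pd.DataFrame(
        [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
        index=names, columns=names, dtype=float,
    )
    tree, _, newick = pg.nj_tree(D, bootstrap_replicates=0)
    parts = pg._bipartitions(tree, frozenset(names))
    assert frozenset({"C", "D"}) in parts
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["A"] == pytest.approx(2)
    assert lengths["B"] == pytest.approx(3)
    total = sum(n.length for n in tree.traverse() if n.length is not None)
    assert total == pytest.approx(2 + 3 + 4 + 5 + 1)


def test_nj_three_taxa_three_point_formula():
    names = ["A", "B", "C"]
    D = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                     index=names, columns=names, dtype=float)
    tree, _, _ = pg.nj_tree(D, bootstrap_replicates=0)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)
    with pytest.raises(ValueError):
        pg.nj_tree(D.iloc[:2, :2])


def test_bootstrap_of_identical_loci_gives_full_support(two_pop_cohort):
    g, p = two_pop_cohort
    # four pseudo-populations from two species halves; duplicate one locus
    labels = np.array([f"{s}{'ab'[i % 2]}" for i, s in enumerate(p["species"])])
    same = GenotypeTable(
        g.individual_ids, ["L"] * 1 * 8, np.repeat(g.calls[:, :1, :], 8, axis=1)
    )
    fr, _ = pg.allele_frequencies(same, labels)
    D = pg.chord_distance(fr)
    _, supports, _ = pg.nj_tree(D, bootstrap_replicates=30, genotypes=same,
                                grouping=labels, seed=1)
    assert supports and all(v == 100.0 for v in supports.values())


# --- FDR ---------------------------------------------------------------------


def test_bh_fdr_step_up_examples():
    reject, adj = pg.bh_fdr(np.full(15, 0.001), q=0.05)
    assert reject.all()
    reject, _ = pg.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04, 0.05]), q=0.05)
    assert reject.all()  # max k with p_(k) <= k q / m is 5
    reject, adj = pg.bh_fdr(np.array([0.06]), q=0.05)
    assert not reject[0]
    assert (np.diff(np.sort(adj)) >= 0).all()
    with pytest.raises(ValueError):
        pg.bh_fdr(np.array([1.2]))
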