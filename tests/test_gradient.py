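"""Trend regressions, Mantel machinery, geographic distance, DAPC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from depthcline import gradient_tests as gt
from depthcline import simdata


def test_linear_trend_exact_fit_and_f_equals_t_squared():
    x = np.arange(10, dtype=float)
    slope, f, df, p = gt.linear_trend(2 * x, x)
    assert slope == pytest.approx(2.0)
    assert p < 1e-10
    rng = np.random.default_rng(0)
    y = 3 * x + rng.normal(size=10)
    slope, f, (df1, df2), p = gt.linear_trend(y, x)
    from scipy import stats

    res = stats.linregress(x, y)
    t = res.slope / res.stderr
    assert f == pytest.approx(t**2, rel=1e-9)
    assert (df1, df2) == (1, 8)
    with pytest.raises(ValueError):
        gt.linear_trend(y, np.full(10, 2.0))


def test_geographic_distance_haversine():
    sites = pd.DataFrame(
        {"site_lat": [47.0, 48.0, 47.0], "site_lon": [8.0, 8.0, 8.0]},
        index=["a", "b", "c"],
    )
    D = gt.geographic_distance(sites)
    assert D.loc["a", "b"] == pytest.approx(111.2, abs=0.3)  # 1 deg latitude
    assert D.loc["a", "c"] == 0.0
    assert D.loc["b", "a"] == D.loc["a", "b"]


def test_mantel_identity_gives_r_one():
    rng = np.random.default_rng(1)
    x = rng.uniform(size=8)
    D = np.abs(x[:, None] - x[None, :])
    res = gt.mantel(D, D, permutations=99, seed=1)
    assert res.r == pytest.approx(1.0)
    assert res.p <= 0.05


def test_mantel_p_matches_exhaustive_enumeration_n5():
    rng = np.random.default_rng(2)
    x = rng.uniform(size=5)
    y = x + rng.normal(0, 0.2, size=5)
    D1 = np.abs(x[:, None] - x[None, :])
    D2 = np.abs(y[:, None] - y[None, :])
    iu = np.triu_indices(5, 1)
    r_obs = np.corrcoef(D1[iu], D2[iu])[0, 1]
    count = 0
    for perm in itertools.permutations(range(5)):
        Dp = D1[np.ix_(perm, perm)]
        if np.corrcoef(Dp[iu], D2[iu])[0, 1] >= r_obs - 1e-12:
            count += 1
    p_exact = count / 120
    res = gt.mantel(D1, D2, permutations=4999, seed=2)
    assert res.p == pytest.approx(p_exact, abs=0.03)


def test_mantel_cross_checked_against_skbio():
    from skbio.stats.distance import mantel as skbio_mantel, DistanceMatrix

    rng = np.random.default_rng(3)
    x = rng.uniform(size=12)
    y = x + rng.normal(0, 0.5, size=12)
    D1 = np.abs(x[:, None] - x[None, :])
    D2 = np.abs(y[:, None] - y[None, :])
    r_ref, p_ref, _ = skbio_mantel(
        DistanceMatrix(D1), DistanceMatrix(D2), permutations=999,
        alternative="greater",
    )
    res = gt.mantel(D1, D2, permutations=999, seed=3)
    assert res.r == pytest.approx(r_ref, abs=1e-12)
    assert res.p == pytest.approx(p_ref, abs=0.03)


def test_partial_mantel_full_control_kills_correlation():
    rng = np.random.default_rng(4)
    x = rng.uniform(size=15)
    C = np.abs(x[:, None] - x[None, :])
    noise = rng.uniform(size=15)
    D1 = C + 0.01 * np.abs(noise[:, None] - noise[None, :])
    res = gt.partial_mantel(D1, C.copy(), C, permutations=99, seed=4)
    assert abs(res.r) < 0.2  # D2 = C: nothing left after control
    assert -1 <= res.r <= 1


def test_partial_mantel_reduces_to_simple_when_control_uncorrelated():
    rng = np.random.default_rng(5)
    x = rng.uniform(size=25)
    y = x + rng.normal(0, 0.3, size=25)
    z = rng.uniform(size=25)  # unrelated control
    D1 = np.abs(x[:, None] - x[None, :])
    D2 = np.abs(y[:, None] - y[None, :])
    C = np.abs(z[:, None] - z[None, :])
    simple = gt.mantel(D1, D2, permutations=99, seed=5)
    partial = gt.partial_mantel(D1, D2, C, permutations=99, seed=5)
    assert partial.r == pytest.approx(simple.r, abs=0.1)


def test_group_membership_matrix_block_structure():
    labels = np.array(["a", "a", "b"])
    M = gt.group_membership_matrix(labels)
    np.testing.assert_array_equal(M, [[0, 0, 1], [0, 0, 1], [1, 1, 0]])
    assert (gt.group_membership_matrix(np.array(["x"] * 4)) == 0).all()


def test_dapc_self_assignment_monotone_in_divergence():
    spec = simdata.SpeciesPhenotypeSpec(250, 15, 33, 3, 20, 9)
    medians = []
    for fst in (0.0, 0.05, 0.15):
        pool = simdata.simulate_allele_frequencies(2, target_fst=fst, seed=6)
        g, p = simdata.simulate_individuals(pool, [spec] * 2, [60, 60], seed=6)
        res = gt.dapc_assign(g, p["species"].to_numpy(), cv_folds=4, seed=6)
        np.testing.assert_allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)
        medians.append(np.median(res.self_assignment(p["species"].to_numpy())))
    assert medians[0] < 0.75  # no signal: near 1/K
    assert medians[2] > 0.9
    assert medians == sorted(medians)


def test_dapc_shrinks_folds_for_small_groups():
    spec = simdata.SpeciesPhenotypeSpec(250, 15, 33, 3, 20, 9)
    pool = simdata.simulate_allele_frequencies(2, target_fst=0.1, seed=7)
    g, p = simdata.simulate_individuals(pool, [spec] * 2, [30, 3], seed=7)
    with pytest.warns(UserWarning, match="folds"):
        res = gt.dapc_assign(g, p["species"].to_numpy(), cv_folds=5, seed=7)
    assert res.n_pcs >= 1


def test_two_group_tests_effect_and_symmetry():
    rng = np.random.default_rng(8)
    gr = np.concatenate([rng.normal(37.8, 2.7, 50), rng.normal(27.7, 2.7, 36)])
    labels = np.array(["small"] * 50 + ["large"] * 36)
    res = gt.two_group_tests(gr, labels)
    t, df, p = res["t"]
    assert p < 0.001 and df == 84
    swapped = gt.two_group_tests(gr, np.where(labels == "small", "large", "small"))
    assert swapped["t"][0] == pytest.approx(-t)
    same = gt.two_group_tests(np.tile(gr[:10], 2), np.array(["a"] * 10 + ["b"] * 10))
    assert same["t"][2] == pytest.approx(1.0)
    assert same["u"][1] > 0.99
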