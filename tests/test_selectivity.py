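"""Skew-normal selectivity fitting, curve crossings and class assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from depthcline import selectivity


def _pheno(sl_by_mesh: dict[float, np.ndarray]) -> pd.DataFrame:
    rows = []
    for mesh, sls in sl_by_mesh.items():
        rows.extend({"sl": float(s), "mesh": mesh} for s in sls)
    return pd.DataFrame(rows)


def test_fit_recovers_symmetric_truth():
    """With alpha-truth 0 the fitted shape stays small and the mode is recovered.

    The skew-normal shape is weakly identified near zero (singular
    information), so individual samples can push the MLE of alpha up while
    the density barely moves; the typical fitted alpha stays small and the
    mode is always recovered.
    """
    alphas = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        sl = stats.skewnorm.rvs(0.0, loc=250, scale=20, size=500, random_state=rng)
        model = selectivity.fit_mesh_selectivity(_pheno({35.0: sl}), [35.0])
        _, _, alpha = model.params[35.0]
        alphas.append(alpha)
        assert alpha >= 0
        assert model.modes()[35.0] == pytest.approx(250, abs=5)
    # alpha never drifts to strong skew, and samples whose unconstrained MLE
    # is negative land on the alpha = 0 boundary
    assert max(alphas) < 2.0
    assert min(alphas) < 0.1


def test_fit_is_deterministic():
    rng = np.random.default_rng(1)
    sl = stats.skewnorm.rvs(2.0, loc=200, scale=30, size=200, random_state=rng)
    p = _pheno({25.0: sl})
    m1 = selectivity.fit_mesh_selectivity(p, [25.0])
    m2 = selectivity.fit_mesh_selectivity(p, [25.0])
    assert m1.params == m2.params


def test_small_mesh_flagged_unreliable_but_fitted():
    rng = np.random.default_rng(2)
    data = {25.0: rng.normal(200, 20, 100), 35.0: rng.normal(270, 20, 5)}
    with pytest.warns(UserWarning, match="unreliable"):
        model = selectivity.fit_mesh_selectivity(_pheno(data))
    assert 35.0 in model.unreliable and 35.0 in model.params


def test_modes_increase_with_mesh_on_preset_survey():
    from depthcline import simdata

    _, pheno, _ = simdata.simulate_preset("lucerne3", seed=4)
    model = selectivity.fit_mesh_selectivity(pheno)
    modes = model.modes()
    assert modes[25.0] < modes[35.0] < modes[45.0]


def test_boundary_between_shifted_identical_curves_is_midpoint():
    rng = np.random.default_rng(3)
    a = stats.skewnorm.rvs(0.0, loc=220, scale=20, size=2000, random_state=rng)
    b = a + 60  # identical shape shifted by delta
    model = selectivity.fit_mesh_selectivity(_pheno({25.0: a, 35.0: b}))
    part = selectivity.class_boundaries(model)
    modes = model.modes()
    midpoint = (modes[25.0] + modes[35.0]) / 2
    assert part.boundaries[0] == pytest.approx(midpoint, abs=1.0)


def test_three_meshes_give_two_increasing_boundaries_matching_brute_force():
    rng = np.random.default_rng(4)
    data = {
        25.0: stats.skewnorm.rvs(2, loc=180, scale=40, size=400, random_state=rng),
        35.0: stats.skewnorm.rvs(2, loc=255, scale=40, size=400, random_state=rng),
        45.0: stats.skewnorm.rvs(2, loc=330, scale=40, size=400, random_state=rng),
    }
    model = selectivity.fit_mesh_selectivity(_pheno(data))
    part = selectivity.class_boundaries(model)
    assert len(part.boundaries) == 2
    assert part.boundaries[0] < part.boundaries[1]
    # brute-force oracle: dense grid scan for the crossing of the analytic curves
    for (lo, hi), found in zip([(25.0, 35.0), (35.0, 45.0)], part.boundaries):
        grid = np.linspace(model.modes()[lo], model.modes()[hi], 200_001)
        diff = model.evaluate(lo, grid) - model.evaluate(hi, grid)
        crossing = grid[np.argmin(np.abs(diff))]
        assert found == pytest.approx(crossing, abs=0.5)


def test_no_crossing_raises_naming_the_pair():
    rng = np.random.default_rng(5)
    same = stats.skewnorm.rvs(1, loc=250, scale=30, size=500, random_state=rng)
    model = selectivity.fit_mesh_selectivity(_pheno({25.0: same, 35.0: same + 0.01}))
    with pytest.raises(ValueError, match="25.0|35.0"):
        selectivity.class_boundaries(model)


def test_class_assignment_tie_and_extremes():
    part = selectivity.SLClassPartition([245.0, 315.0], (150.0, 430.0))
    pheno = pd.DataFrame({"sl": [245.0, 244.9, 315.0, 140.0, 500.0, 250.0]})
    with pytest.warns(UserWarning, match="extreme"):
        out = selectivity.assign_selectivity_classes(pheno, part)
    # a fish exactly on a boundary joins the lower class
    assert list(out["sl_class"]) == ["C1", "C1", "C2", "C1", "C3", "C2"]
    shuffled = selectivity.assign_selectivity_classes(
        pheno.iloc[::-1].reset_index(drop=True), part
    )
    assert list(shuffled["sl_class"]) == ["C2", "C3", "C1", "C2", "C1", "C1"]


def test_total_selectivity_sums_components_and_dips_between_modes():
    rng = np.random.default_rng(6)
    far = {
        25.0: stats.skewnorm.rvs(0, loc=150, scale=15, size=400, random_state=rng),
        45.0: stats.skewnorm.rvs(0, loc=350, scale=15, size=400, random_state=rng),
    }
    model = selectivity.fit_mesh_selectivity(_pheno(far))
    grid = np.linspace(140, 360, 500)
    total = selectivity.total_selectivity(model, grid)
    for m in model.mesh_sizes:
        assert (total >= model.evaluate(m, grid) - 1e-12).all()
    modes = model.modes()
    between = (grid > modes[25.0]) & (grid < modes[45.0])
    # modes separated by >> 4 omega leave a detectable dip in the total curve
    assert total[between].min() < 0.5 * total.max()
    single = selectivity.fit_mesh_selectivity(_pheno({25.0: far[25.0]}), [25.0])
    np.testing.assert_allclose(
        selectivity.total_selectivity(single, grid), single.evaluate(25.0, grid)
    )
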