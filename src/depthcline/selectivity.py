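"""Gill-net mesh selectivity: skew-normal curves, total selectivity, SL classes.

Each mesh size retains fish with a length-dependent probability modelled as
a right-skewed normal curve of standard length (SL). Curves are fitted by
maximum likelihood to the catch-at-length of each mesh (panels fished in
series with equal intensity, so the catch is a sample from the retention
curve), rescaled to unit maximum, and summed to give total selectivity.
Boundaries between selectivity SL classes sit where the unit-scaled curves
of adjacent meshes cross, and every fish is assigned to a class by its SL
irrespective of the mesh it was actually caught in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SelectivityModel",
    "SLClassPartition",
    "fit_mesh_selectivity",
    "class_boundaries",
    "assign_selectivity_classes",
    "total_selectivity",
]

MIN_FISH_PER_MESH = 10
GRID_STEP = 1.0  # mm
GRID_PAD = 20.0  # mm


@dataclass
class SelectivityModel:
    """Fitted per-mesh skew-normal retention curves on a common SL grid."""

    mesh_sizes: list[float]
    params: dict[float, tuple[float, float, float]]  # mesh -> (xi, omega, alpha)
    grid: np.ndarray
    curves: dict[float, np.ndarray]  # unit-max scaled, on grid
    total_curve: np.ndarray
    unreliable: set[float]

    def modes(self) -> dict[float, float]:
        """Grid location of each curve's maximum (mm)."""
        return {m: float(self.grid[np.argmax(c)]) for m, c in self.curves.items()}

    def evaluate(self, mesh: float, sl: np.ndarray) -> np.ndarray:
        """Unit-max skew-normal retention of ``mesh`` at lengths ``sl``."""
        xi, omega, alpha = self.params[mesh]
        peak = stats.skewnorm.pdf(self.grid, alpha, loc=xi, scale=omega).max()
        return stats.skewnorm.pdf(np.asarray(sl, float), alpha, loc=xi, scale=omega) / peak

    def report(self) -> pd.DataFrame:
        modes = self.modes()
        return pd.DataFrame(
            [
                {"mesh": m, "xi": self.params[m][0], "omega": self.params[m][1],
                 "alpha": self.params[m][2], "mode": modes[m],
                 "reliable": m not in self.unreliable}
                for m in self.mesh_sizes
            ]
        )


@dataclass
class SLClassPartition:
    """Ordered class boundaries (mm) tiling the observed SL range."""

    boundaries: list[float]
    sl_range: tuple[float, float]

    def __post_init__(self) -> None:
        if sorted(self.boundaries) != list(self.boundaries):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.boundaries) + 1

    def labels(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_classes)]

    def ranges(self) -> list[tuple[float, float]]:
        edges = [self.sl_range[0], *self.boundaries, self.sl_range[1]]
        return list(zip(edges[:-1], edges[1:]))


def _skewnorm_mle(sl: np.ndarray) -> tuple[float, float, float]:
    """ML fit of a right-skewed normal (shape constrained >= 0).

    Method-of-moments starting values; shape started at 1. Deterministic:
    L-BFGS-B from a fixed start.
    """
    sl = np.asarray(sl, float)
    mu, sd = sl.mean(), sl.std(ddof=1)

    def nll(theta):
        xi, log_omega, alpha = theta
        ll = stats.skewnorm.logpdf(sl, alpha, loc=xi, scale=np.exp(log_omega))
        return -np.sum(ll)

    best = None
    for alpha0 in (1.0, 0.1, 3.0):
        res = optimize.minimize(
            nll,
            x0=[mu - 0.5 * sd * alpha0 / np.hypot(1, alpha0), np.log(sd), alpha0],
            method="L-BFGS-B",
            bounds=[(None, None), (np.log(sd * 0.05), np.log(sd * 10)), (0.0, 50.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    xi, log_omega, alpha = best.x
    return float(xi), float(np.exp(log_omega)), float(alpha)


def fit_mesh_selectivity(
    pheno: pd.DataFrame, mesh_sizes: list[float] | None = None
) -> SelectivityModel:
    """Fit a unit-max skew-normal selectivity curve per mesh size.

    Meshes with fewer than 10 measured fish are still fitted but flagged
    unreliable. The evaluation grid spans the observed SL range padded by
    20 mm at 1 mm resolution.
    """
    data = pheno.dropna(subset=["sl", "mesh"])
    if mesh_sizes is None:
        mesh_sizes = sorted(data["mesh"].unique())
    sl_all = data["sl"].to_numpy(float)
    if sl_all.size == 0:
        raise ValueError("no fish with SL and mesh recorded")
    grid = np.arange(sl_all.min() - GRID_PAD, sl_all.max() + GRID_PAD + GRID_STEP, GRID_STEP)
    params, curves, unreliable = {}, {}, set()
    for m in mesh_sizes:
        sl = data.loc[data["mesh"] == m, "sl"].to_numpy(float)
        if sl.size < MIN_FISH_PER_MESH:
            unreliable.add(m)
            warnings.warn(f"mesh {m}: only {sl.size} fish; curve flagged unreliable",
                          stacklevel=2)
        if sl.size < 3:
            raise ValueError(f"mesh {m}: cannot fit a curve to {sl.size} fish")
        xi, omega, alpha = _skewnorm_mle(sl)
        params[m] = (xi, omega, alpha)
        curve = stats.skewnorm.pdf(grid, alpha, loc=xi, scale=omega)
        curves[m] = curve / curve.max()
    total = np.sum([curves[m] for m in mesh_sizes], axis=0)
    return SelectivityModel(list(mesh_sizes), params, grid, curves, total, unreliable)


def class_boundaries(model: SelectivityModel) -> SLClassPartition:
    """Locate crossings of adjacent unit-scaled mesh curves between their modes.

    The crossing of each adjacent mesh pair is bracketed between the two
    modes and refined by bisection on the difference of the analytic
    curves; k meshes give k-1 boundaries and k classes.
    """
    if len(model.mesh_sizes) < 2:
        raise ValueError("need >= 2 fitted meshes to derive class boundaries")
    modes = model.modes()
    boundaries = []
    for lo_mesh, hi_mesh in zip(model.mesh_sizes[:-1], model.mesh_sizes[1:]):
        a, b = modes[lo_mesh], modes[hi_mesh]
        if a >= b:
            raise ValueError(
                f"modes of meshes {lo_mesh} and {hi_mesh} are not ordered; "
                "cannot locate a crossing"
            )

        def diff(x):
            return float(
                model.evaluate(lo_mesh, np.array([x]))[0]
                - model.evaluate(hi_mesh, np.array([x]))[0]
            )

        if diff(a) <= 0 or diff(b) >= 0:
            raise ValueError(
                f"no crossing between the modes of meshes {lo_mesh} and {hi_mesh} "
                "(degenerate overlap)"
            )
        boundaries.append(float(optimize.bisect(diff, a, b, xtol=1e-6)))
    if sorted(boundaries) != boundaries:
        raise ValueError("derived boundaries are not increasing")
    return SLClassPartition(boundaries, (float(model.grid[0]), float(model.grid[-1])))


def assign_selectivity_classes(
    pheno: pd.DataFrame, partition: SLClassPartition, column: str = "sl_class"
) -> pd.DataFrame:
    """Label every fish C1..Ck by SL interval (half-open: boundary -> lower class).

    Fish outside the observed SL range fall into the nearest extreme class
    (with a warning).
    """
    out = pheno.copy()
    sl = out["sl"].to_numpy(float)
    lo, hi = partition.sl_range
    if np.nanmin(sl) < lo or np.nanmax(sl) > hi:
        warnings.warn("SL outside the fitted range; using the nearest extreme class",
                      stacklevel=2)
    # half-open [lo, hi): a fish exactly on a boundary joins the lower class
    idx = np.searchsorted(np.asarray(partition.boundaries), sl, side="left")
    labels = partition.labels()
    out[column] = [labels[i] if np.isfinite(s) else None for i, s in zip(idx, sl)]
    return out


def total_selectivity(model: SelectivityModel, sl_grid: np.ndarray) -> np.ndarray:
    """Pointwise sum of the unit-scaled mesh curves at ``sl_grid``."""
    sl_grid = np.asarray(sl_grid, float)
    return np.sum([model.evaluate(m, sl_grid) for m in model.mesh_sizes], axis=0)
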