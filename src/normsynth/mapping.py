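"""Monotone normal-score maps between each original variable and a standard
normal, built from KDE-augmented quantiles.

Each map m_j solves P_j(x) = G_j(y), where P_j is the cumulative distribution
of the variable (estimated from the sample pooled with a large set of KDE
draws, which removes staircasing from ties and sparse tails) and G_j is the
cumulative distribution of a large standard-normal set.  The two empirical
quantile functions are matched on a common probability grid, giving paired
knot tables interpolated piecewise-linearly in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kde import KDEModel, kde_sample

DEFAULT_GRID = 4096  # interior probability grid points for quantile pairing
_DUP_TOL = 1e-12


def box_muller(u1, u2):
    """Exact transform of two uniforms into two independent standard normals.

    z1 = sqrt(-2 ln u1) cos(2 pi u2), z2 = sqrt(-2 ln u1) sin(2 pi u2),
    with u1 in (0, 1] (u1 = 0 is rejected) and u2 in [0, 1).
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if np.any(u1 <= 0.0) or np.any(u1 > 1.0):
        raise ValueError("u1 must lie in (0, 1]")
    r = np.sqrt(-2.0 * np.log(u1))
    theta = 2.0 * np.pi * u2
    z1, z2 = r * np.cos(theta), r * np.sin(theta)
    if z1.ndim == 0:
        return float(z1), float(z2)
    return z1, z2


def box_muller_normals(rng: np.random.Generator, size: int) -> np.ndarray:
    """size standard normals generated with the Box-Muller transform."""
    half = (size + 1) // 2
    u1 = 1.0 - rng.random(half)  # in (0, 1]
    u2 = rng.random(half)
    z1, z2 = box_muller(u1, u2)
    return np.concatenate([z1, z2])[:size]


@dataclass
class MarginalMap:
    """A tabulated monotone transform between one X variable and N(0,1).

    x_knots and y_knots are non-decreasing vectors of equal length (strictly
    increasing for a properly augmented map); forward/inverse evaluation
    interpolates linearly and clamps beyond the terminal knots.  Clamp events
    and the number of flat "staircase" runs are counted in ``meta``: flat runs
    arise from tied quantiles (integer-valued or sparse data without KDE
    augmentation) and distort the transform, because every tied observation is
    sent to one edge of its quantile run.
    """

    x_knots: np.ndarray
    y_knots: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_knots = np.asarray(self.x_knots, dtype=float).ravel()
        self.y_knots = np.asarray(self.y_knots, dtype=float).ravel()
        if self.x_knots.size != self.y_knots.size:
            raise ValueError("knot vectors must have equal length")
        if self.x_knots.size < 2:
            raise ValueError("need at least 2 knots")
        if np.any(np.diff(self.x_knots) < 0) or np.any(np.diff(self.y_knots) <= 0):
            raise ValueError("x knots must be non-decreasing, y knots strictly increasing")
        if self.x_knots[0] == self.x_knots[-1]:
            raise ValueError("x knots are constant")
        self.meta.setdefault("clamped_forward", 0)
        self.meta.setdefault("clamped_inverse", 0)

    @property
    def flat_runs(self) -> int:
        """Number of staircase segments (runs of tied x knots)."""
        scale = max(abs(self.x_knots[0]), abs(self.x_knots[-1]), 1.0)
        tied = np.diff(self.x_knots) <= _DUP_TOL * scale
        # count maximal runs of consecutive ties
        return int(np.count_nonzero(np.diff(np.concatenate([[0], tied.view(np.int8)])) == 1))

    @property
    def is_strict(self) -> bool:
        return bool(np.all(np.diff(self.x_knots) > 0))


def _dedupe_y(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse exact ties in the normal-side knots (averaging x partners).

    Ties in y are numerical accidents (the normal draws are continuous) but
    would break inversion; ties in x are kept — they are the staircase
    signature the map diagnostics report.
    """
    tied = np.diff(y) <= _DUP_TOL
    if not tied.any():
        return x, y
    group = np.concatenate([[0], np.cumsum(~tied)])
    n_groups = group[-1] + 1
    counts = np.bincount(group, minlength=n_groups)
    x = np.bincount(group, weights=x, minlength=n_groups) / counts
    y = np.bincount(group, weights=y, minlength=n_groups) / counts
    return x, y


def build_map(
    x: np.ndarray,
    kde: KDEModel,
    config,
    rng: np.random.Generator,
    grid: int = DEFAULT_GRID,
) -> MarginalMap:
    """Construct the normal-score map for one variable.

    The variable's observations are pooled with ``config.kde_augment_n`` KDE
    draws to estimate P_j; ``config.map_normal_n`` Box-Muller standard normals
    estimate G_j.  Empirical quantiles of both sets on an equal-probability
    grid of ``grid`` interior points become the paired knots.
    """
    x = np.asarray(x, dtype=float).ravel()
    if np.var(x) == 0 and config.kde_augment_n == 0:
        raise ValueError("constant variable: map undefined")
    if config.kde_augment_n > 0:
        pooled = np.concatenate([x, kde_sample(kde, config.kde_augment_n, rng)])
    else:
        pooled = x
    normals = box_muller_normals(rng, config.map_normal_n)
    q = np.arange(1, grid + 1) / (grid + 1)
    xk = np.quantile(pooled, q)
    yk = np.quantile(normals, q)
    xk, yk = _dedupe_y(xk, yk)
    mmap = MarginalMap(
        xk, yk,
        meta={
            "bandwidth": float(kde.bandwidth),
            "knots": int(xk.size),
            "augment_n": int(config.kde_augment_n),
        },
    )
    mmap.meta["flat_runs"] = mmap.flat_runs
    return mmap


def forward(mmap: MarginalMap, x: np.ndarray) -> np.ndarray:
    """Map X values to Y by piecewise-linear interpolation (clamped tails)."""
    x = np.asarray(x, dtype=float)
    out_of_range = int(np.count_nonzero((x < mmap.x_knots[0]) | (x > mmap.x_knots[-1])))
    mmap.meta["clamped_forward"] += out_of_range
    return np.interp(x, mmap.x_knots, mmap.y_knots)


def invert(mmap: MarginalMap, y: np.ndarray) -> np.ndarray:
    """Map Y values back to X (knot roles swapped, clamped tails)."""
    y = np.asarray(y, dtype=float)
    out_of_range = int(np.count_nonzero((y < mmap.y_knots[0]) | (y > mmap.y_knots[-1])))
    mmap.meta["clamped_inverse"] += out_of_range
    return np.interp(y, mmap.y_knots, mmap.x_knots)
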