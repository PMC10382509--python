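"""Univariate Gaussian KDE, KDE sampling, the two-sample KS statistic, and
differential-evolution bandwidth selection with a KS fitness.

The density estimate for one variable with observations x_i and bandwidth h is

    p(x) = (1/n) sum_i phi((x - x_i)/h) / h,

with phi the standard normal density.  The bandwidth is chosen per variable by
a stochastic search: a population of candidate h values evolves for a fixed
number of generations; in every pairwise competition each candidate draws a
fresh synthetic sample of the source size from its KDE and the candidate whose
sample sits closer to the source in two-sample KS distance survives.  The
returned bandwidth is the mean of the terminal population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import kolmogi

_SQRT_2PI = np.sqrt(2.0 * np.pi)

# classic DE/rand/1 control parameters (1-D genomes, so crossover is moot)
_DE_F = 0.5


@dataclass
class KDEModel:
    """A fitted univariate Gaussian kernel density: support points + bandwidth."""

    support: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float).ravel()
        if self.support.size < 1 or not np.all(np.isfinite(self.support)):
            raise ValueError("support must be nonempty and finite")
        if not self.bandwidth > 0:
            raise ValueError(f"bandwidth must be positive, got {self.bandwidth}")

    @property
    def norm_const(self) -> float:
        """Per-kernel normalization k = sqrt(2 pi) h implied by the Gaussian kernel."""
        return _SQRT_2PI * self.bandwidth


@dataclass
class DEResult:
    """Outcome of the bandwidth search for one variable."""

    bandwidth: float
    terminal_population: np.ndarray
    fitness_trace: list  # per-generation (best, mean) KS distance of survivors
    generations: int
    n_evaluations: int = 0


class KSResult(NamedTuple):
    statistic: float
    critical: float
    reject: bool


def kde_density(model: KDEModel, query: np.ndarray) -> np.ndarray:
    """Evaluate the KDE at the query points (vectorized over both axes)."""
    q = np.atleast_1d(np.asarray(query, dtype=float))
    h = model.bandwidth
    z = (q[:, None] - model.support[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (model.support.size * model.norm_const)
    return dens if np.ndim(query) else float(dens[0])


def kde_sample(model: KDEModel, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw m realizations: a uniformly chosen support point plus h * N(0,1)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    idx = rng.integers(0, model.support.size, size=m)
    return model.support[idx] + model.bandwidth * rng.standard_normal(m)


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Max absolute distance between the two empirical CDFs (pooled grid)."""
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def ks_critical_two_sample(n_a: int, n_b: int, alpha: float = 0.05) -> float:
    """Asymptotic two-sample critical distance c(alpha) * sqrt((na+nb)/(na*nb))."""
    return float(kolmogi(alpha)) * np.sqrt((n_a + n_b) / (n_a * n_b))


def ks_two_sample(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> KSResult:
    """Two-sample KS test with the asymptotic critical value; reject iff D >= critical."""
    d = ks_statistic(a, b)
    crit = ks_critical_two_sample(np.size(a), np.size(b), alpha)
    return KSResult(d, crit, bool(d >= crit))


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect candidates back into (lo, hi]; lo is an open bound (h > 0)."""
    v = np.asarray(v, dtype=float)
    span = hi - lo
    for _ in range(64):
        out_hi = v > hi
        out_lo = v <= lo
        if not (out_hi.any() or out_lo.any()):
            break
        v = np.where(out_hi, 2 * hi - v, v)
        v = np.where(out_lo, 2 * lo - v + 1e-12 * span, v)
    return np.clip(v, lo + 1e-15 * span, hi)


def de_optimize_bandwidth(
    x: np.ndarray,
    config,
    rng: np.random.Generator,
) -> DEResult:
    """Evolve a population of candidate bandwidths against a KS fitness.

    Initialization is uniform on (0, 4 * var(x)]; each generation pits every
    incumbent against a DE/rand/1 challenger, drawing one fresh synthetic
    sample of size len(x) per contender, so total work is exactly
    2 * pop_size * generations synthetic-sample comparisons.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 observations to optimize a bandwidth")
    var = float(np.var(x, ddof=1))
    if var <= 0:
        raise ValueError("zero-variance input: bandwidth undefined")
    pop_size, gens = config.de_pop_size, config.de_generations
    if pop_size < 4:
        raise ValueError("de_pop_size must be >= 4 for DE/rand/1 mutation")
    lo, hi = 0.0, 4.0 * var
    n = x.size
    x_sorted = np.sort(x)

    def fitness(h: float) -> float:
        draw = x[rng.integers(0, n, size=n)] + h * rng.standard_normal(n)
        draw.sort()
        grid = np.concatenate([x_sorted, draw])
        cdf_a = np.searchsorted(x_sorted, grid, side="right") / n
        cdf_b = np.searchsorted(draw, grid, side="right") / n
        return float(np.abs(cdf_a - cdf_b).max())

    pop = lo + (hi - lo) * (1.0 - rng.random(pop_size))  # uniform on (lo, hi]
    trace: list[tuple[float, float]] = []
    n_evals = 0
    for _ in range(gens):
        # DE/rand/1 challengers from three distinct rows of the previous generation
        r = np.empty((pop_size, 3), dtype=int)
        for i in range(pop_size):
            r[i] = rng.choice(pop_size, size=3, replace=False)
        challengers = _reflect(pop[r[:, 0]] + _DE_F * (pop[r[:, 1]] - pop[r[:, 2]]), lo, hi)
        survivors = np.empty_like(pop)
        fits = np.empty(pop_size)
        for i in range(pop_size):
            f_inc, f_ch = fitness(pop[i]), fitness(challengers[i])
            n_evals += 2
            if f_ch < f_inc:
                survivors[i], fits[i] = challengers[i], f_ch
            else:
                survivors[i], fits[i] = pop[i], f_inc
        pop = survivors
        trace.append((float(fits.min()), float(fits.mean())))
    return DEResult(
        bandwidth=float(pop.mean()),
        terminal_population=pop,
        fitness_trace=trace,
        generations=gens,
        n_evaluations=n_evals,
    )
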