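"""Covariance/PCA of the normalized sample, normal sampling in the
decorrelated representation, and the end-to-end synthetic population
generator.

With Y the marginally normalized sample, the model is

    C_y = P diag(sigma_j^2) P^T          (symmetric eigendecomposition)
    T   = (Y - mean) P                   (decorrelated scores)
    T_s ~ column-wise N(0, sigma_j^2)    (synthetic scores, independent)
    Y_s = T_s P^T + mean                 (covariance restored)
    X_s = m_j^{-1}(Y_s)                  (marginals restored)

so the whole joint distribution is encoded by d monotone maps plus the
covariance of Y — no multivariate density estimation is ever required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ModelArchive, RunConfig, Sample, rng_stream
from .kde import KDEModel, de_optimize_bandwidth
from .mapping import MarginalMap, box_muller_normals, build_map, forward, invert

_EIG_FLOOR_REL = 1e-12  # eigenvalues below this fraction of the trace are residue


@dataclass
class CovMatrix:
    """A symmetric covariance matrix tagged with its representation."""

    values: np.ndarray
    rep: str = "X"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(v, v.T, atol=1e-12 * max(1.0, np.abs(v).max())):
            raise ValueError("covariance must be symmetric")
        if np.any(np.diag(v) < 0):
            raise ValueError("negative variance on the diagonal")

    @property
    def d(self) -> int:
        return self.values.shape[0]


@dataclass
class PCAModel:
    """Eigenvectors (columns of P), descending eigenvalues, and column means."""

    P: np.ndarray
    eigenvalues: np.ndarray
    means: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        d = self.P.shape[0]
        if self.P.shape != (d, d) or self.eigenvalues.shape != (d,) or self.means.shape != (d,):
            raise ValueError("inconsistent PCA model shapes")
        if np.any(self.eigenvalues < 0) or np.any(np.diff(self.eigenvalues) > 0):
            raise ValueError("eigenvalues must be nonnegative and descending")

    @property
    def d(self) -> int:
        return self.P.shape[0]


def covariance(sample: Sample) -> CovMatrix:
    """Unbiased (n-1 denominator) covariance of the sample columns."""
    if sample.n < 2:
        raise ValueError("need n >= 2 for a covariance")
    c = np.cov(sample.values, rowvar=False, ddof=1).reshape(sample.d, sample.d)
    return CovMatrix(0.5 * (c + c.T), sample.rep)


def pca_fit(y: Sample) -> PCAModel:
    """Symmetric eigendecomposition of cov(Y), components in descending order.

    Signs are fixed so each eigenvector's largest-magnitude entry is positive;
    eigenvalues below 1e-12 of the trace are floored to zero (residue).
    """
    if y.rep != "Y":
        raise ValueError("PCA is fit in the Y representation")
    c = covariance(y).values
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite covariance")
    vals, vecs = np.linalg.eigh(c)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.where(vals < _EIG_FLOOR_REL * vals.sum(), 0.0, np.maximum(vals, 0.0))
    flip = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])])
    vecs = vecs * np.where(flip == 0, 1.0, flip)
    return PCAModel(P=vecs, eigenvalues=vals, means=y.values.mean(axis=0))


def pca_forward(y: Sample, model: PCAModel) -> Sample:
    """T = (Y - means) P."""
    if y.d != model.d:
        raise ValueError("dimension mismatch")
    t = (y.values - model.means) @ model.P
    return Sample(t, [f"t{j + 1}" for j in range(model.d)], "T")


def sample_t(
    model: PCAModel,
    N: int,
    rng: np.random.Generator,
    normal_source=box_muller_normals,
) -> Sample:
    """N x d scores, column j ~ N(0, sigma_j^2), columns independent.

    The normal source defaults to Box-Muller and is pluggable.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    z = normal_source(rng, N * model.d).reshape(N, model.d)
    t = z * np.sqrt(model.eigenvalues)[None, :]
    return Sample(t, [f"t{j + 1}" for j in range(model.d)], "T")


def inverse_pca(t: Sample, model: PCAModel) -> Sample:
    """Y_s = T_s P^T + means (exact inverse of pca_forward)."""
    if t.d != model.d:
        raise ValueError("dimension mismatch")
    y = t.values @ model.P.T + model.means
    return Sample(y, [f"y{j + 1}" for j in range(model.d)], "Y")


def mvn_logdensity(point: np.ndarray, cov: CovMatrix) -> float:
    """Zero-mean multivariate normal log-density at one point.

    log r = -(d/2) log(2 pi) - (1/2) log|C| - (1/2) point^T C^{-1} point
    """
    from scipy.linalg import cho_factor, cho_solve
    point = np.asarray(point, dtype=float).ravel()
    c = cov.values
    if point.size != c.shape[0]:
        raise ValueError("dimension mismatch")
    try:
        chol = cho_factor(c, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise ValueError("covariance not positive definite") from exc
    if not np.all(np.isfinite(chol[0])):
        raise ValueError("covariance not positive definite")
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    quad = float(point @ cho_solve(chol, point))
    d = point.size
    return float(-0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet - 0.5 * quad)


def variance_explained_pct(eigenvalues: np.ndarray, components) -> float:
    """Percent of total variance explained by the selected components.

    ``components`` is an index array/slice into the (descending) spectrum.
    When the normalized sample has unit-variance marginals the trace is ~d, so
    one eigenvalue of a d=10 problem contributes eigenvalue * 10 percent.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if np.any(eig < 0):
        raise ValueError("eigenvalues must be nonnegative")
    return float(100.0 * eig[components].sum() / eig.sum())


@dataclass
class SyntheticPopulation:
    """Row-linked synthetic realizations in all three representations."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if not (self.x.shape == self.y.shape == self.t.shape):
            raise ValueError("representations must share a shape")

    @property
    def size(self) -> int:
        return self.x.shape[0]

    @property
    def d(self) -> int:
        return self.x.shape[1]

    def matrix(self, rep: str) -> np.ndarray:
        return {"X": self.x, "Y": self.y, "T": self.t}[rep]


def generate_population(
    sample: Sample,
    config: RunConfig,
) -> tuple[ModelArchive, SyntheticPopulation]:
    """Run the whole pipeline: fit maps + PCA, then synthesize a population.

    Per variable: optimize the KDE bandwidth, build the KDE-augmented
    normal-score map, and map the sample to Y.  Fit PCA on Y, draw
    ``config.sp_size`` independent normal scores in T, and invert both
    transforms, producing row-linked X/Y/T synthetic populations.
    """
    archive = fit_model(sample, config)
    sp = synthesize(archive, config.sp_size)
    return archive, sp


def fit_model(sample: Sample, config: RunConfig) -> ModelArchive:
    """Steps 1-2: per-variable bandwidths and maps, then PCA of the mapped sample."""
    if sample.rep != "X":
        raise ValueError("fitting starts from the X representation")
    constant = [nm for j, nm in enumerate(sample.names) if np.var(sample.column(j)) == 0]
    if constant:
        raise ValueError(f"constant variable(s): {constant}")
    maps: list[MarginalMap] = []
    de_results = []
    y = np.empty_like(sample.values)
    for j in range(sample.d):
        x_j = sample.column(j)
        de = de_optimize_bandwidth(x_j, config, rng_stream(config.seed, f"de/{j}"))
        kde = KDEModel(support=x_j, bandwidth=de.bandwidth)
        mmap = build_map(x_j, kde, config, rng_stream(config.seed, f"map/{j}"))
        y[:, j] = forward(mmap, x_j)
        maps.append(mmap)
        de_results.append(de)
    y_sample = Sample(y, sample.names, "Y")
    model = pca_fit(y_sample)
    return ModelArchive(
        maps=maps, pca=model, config=config, names=list(sample.names),
        provenance=sample.digest(), de_results=de_results,
    )


def synthesize(archive: ModelArchive, N: int) -> SyntheticPopulation:
    """Steps 3-5: sample T_s, invert PCA to Y_s, invert the maps to X_s."""
    config = archive.config
    t_s = sample_t(archive.pca, N, rng_stream(config.seed, "t-sample"))
    y_s = inverse_pca(t_s, archive.pca)
    x_s = np.empty_like(y_s.values)
    for j, mmap in enumerate(archive.maps):
        x_s[:, j] = invert(mmap, y_s.values[:, j])
    return SyntheticPopulation(x=x_s, y=y_s.values, t=t_s.values, names=list(archive.names))


def draw_linked_samples(
    sp: SyntheticPopulation,
    n: int,
    rng: np.random.Generator,
) -> dict[str, Sample]:
    """One uniform row subset (without replacement) viewed in X, Y and T."""
    if n > sp.size:
        raise ValueError(f"requested {n} rows from a population of {sp.size}")
    idx = rng.choice(sp.size, size=n, replace=False)
    t_names = [f"t{j + 1}" for j in range(sp.d)]
    return {
        "X": Sample(sp.x[idx], sp.names, "X"),
        "Y": Sample(sp.y[idx], sp.names, "Y"),
        "T": Sample(sp.t[idx], t_names, "T"),
    }


def draw_synthetic_sample(
    sp: SyntheticPopulation,
    n: int,
    rng: np.random.Generator,
    rep: str = "X",
) -> Sample:
    """A synthetic sample of size n in one representation (rows stay linked
    across representations when drawn via :func:`draw_linked_samples`)."""
    return draw_linked_samples(sp, n, rng)[rep]
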