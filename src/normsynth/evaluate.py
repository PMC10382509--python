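"""Statistical comparisons between a sample and its synthetic populations.

The battery combines
  * per-variable two-sample KS comparisons against repeated synthetic draws,
  * an unbiased maximum-mean-discrepancy (MMD) two-sample test with a
    Gaussian kernel scaled by the median heuristic and the analytic
    distribution-free acceptance bound,
  * a random-projection multivariate-normality test (project onto many fixed
    random unit vectors, test each projection for univariate normality),
  * Mardia's multivariate skewness/kurtosis tests,
  * element-wise covariance confidence-interval coverage, and
  * eigenvalue comparisons of PCA transforms swapped between sample and
    synthetic data, judged with two-sided F-tests,

aggregated into a JSON-serializable report that includes a summary verdict on
whether the sample exhibits the latent normal characteristic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.special import kolmogi, ndtr
from scipy.stats import chi2, f as f_dist, norm

from .data import RunConfig, Sample
from .kde import ks_critical_two_sample, ks_statistic
from .pca import SyntheticPopulation, covariance, pca_fit, pca_forward


class KSNormalityResult(NamedTuple):
    statistic: float
    critical: float
    reject: bool


@dataclass
class MMDResult:
    mmd_u2: float
    mmd_c: float
    kernel_sigma: float
    accept: bool


@dataclass
class ProjectionBattery:
    projections: np.ndarray  # s x d unit vectors
    non_reject_pct: float

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.projections, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("projection vectors must have unit norm")
        if not 0.0 <= self.non_reject_pct <= 100.0:
            raise ValueError("non_reject_pct must lie in [0, 100]")


@dataclass
class MardiaResult:
    b1: float
    b2: float
    stat_skew: float
    stat_kurt: float
    p_skew: float
    p_kurt: float


@dataclass
class CovCoverageResult:
    coverage_pct: np.ndarray  # d x d, percent of repeats covered
    reps: int
    ci_level: float = 0.95


@dataclass
class EigCompareResult:
    condition: str  # "sample/syn" or "syn/sample"
    eigen_ref: np.ndarray
    eigen_test: np.ndarray
    p_values: np.ndarray


def _ks_normality_stats(z: np.ndarray) -> np.ndarray:
    """Column-wise one-sample KS distance from N(mean, sd) with estimated
    parameters; z has shape (n, s)."""
    n = z.shape[0]
    mu = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance projection")
    u = np.sort((z - mu) / sd, axis=0)
    cdf = ndtr(u)
    i = np.arange(1, n + 1)[:, None]
    d_plus = (i / n - cdf).max(axis=0)
    d_minus = (cdf - (i - 1) / n).max(axis=0)
    return np.maximum(d_plus, d_minus)


def ks_normality(z: np.ndarray, alpha: float = 0.05) -> KSNormalityResult:
    """One-sample KS test of z against a normal with estimated mean and sd.

    Uses the standard asymptotic critical value c(alpha)/sqrt(n) (no
    parameter-estimation correction), which is conservative.
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.size < 10:
        raise ValueError("need at least 10 observations")
    d = float(_ks_normality_stats(z[:, None])[0])
    crit = float(kolmogi(alpha)) / np.sqrt(z.size)
    return KSNormalityResult(d, crit, bool(d >= crit))


def median_heuristic(a: Sample | np.ndarray, b: Sample | np.ndarray) -> float:
    """Median pairwise Euclidean distance over the pooled rows (zeros excluded)."""
    av = a.values if isinstance(a, Sample) else np.atleast_2d(np.asarray(a, dtype=float))
    bv = b.values if isinstance(b, Sample) else np.atleast_2d(np.asarray(b, dtype=float))
    pooled = np.vstack([av, bv])
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 pooled rows")
    dists = pdist(pooled)
    dists = dists[dists > 0]
    if dists.size == 0:
        raise ValueError("all rows identical: kernel scale undefined")
    return float(np.median(dists))


def mmd_critical_value(m: int, alpha: float = 0.05, kernel_bound: float = 1.0) -> float:
    """Distribution-free acceptance threshold for the unbiased MMD^2 statistic.

    mmd_c = (4 K / sqrt(m)) sqrt(ln(1/alpha)) with K the kernel bound (1 for a
    Gaussian kernel) and m the smaller sample size.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    return float(4.0 * kernel_bound / np.sqrt(m) * np.sqrt(np.log(1.0 / alpha)))


def mmd_test(a: Sample, b: Sample, alpha: float = 0.05,
             sigma: float | None = None) -> MMDResult:
    """Unbiased Gaussian-kernel MMD^2 two-sample test.

    MMD_u^2 averages the within-sample kernel values (diagonal excluded) and
    subtracts twice the cross-sample average; the kernel is
    exp(-||u - v||^2 / (2 sigma^2)) with sigma from the median heuristic of
    the pooled samples unless given.  Accept (same distribution) iff
    MMD_u^2 < mmd_c.
    """
    if a.d != b.d:
        raise ValueError("dimension mismatch")
    if sigma is None:
        sigma = median_heuristic(a, b)
    ga = 2.0 * sigma * sigma
    kaa = np.exp(-cdist(a.values, a.values, "sqeuclidean") / ga)
    kbb = np.exp(-cdist(b.values, b.values, "sqeuclidean") / ga)
    kab = np.exp(-cdist(a.values, b.values, "sqeuclidean") / ga)
    m, n = a.n, b.n
    term_a = (kaa.sum() - np.trace(kaa)) / (m * (m - 1))
    term_b = (kbb.sum() - np.trace(kbb)) / (n * (n - 1))
    stat = float(term_a + term_b - 2.0 * kab.mean())
    crit = mmd_critical_value(min(m, n), alpha)
    return MMDResult(mmd_u2=stat, mmd_c=crit, kernel_sigma=float(sigma),
                     accept=bool(stat < crit))


def make_projections(d: int, n_projections: int, rng: np.random.Generator) -> np.ndarray:
    """n_projections random unit vectors (standard-normal components, normalized)."""
    u = rng.standard_normal((n_projections, d))
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def random_projection_test(
    w: Sample,
    alpha: float,
    config: RunConfig,
    rng: np.random.Generator | None = None,
    projections: np.ndarray | None = None,
) -> ProjectionBattery:
    """Percent of random 1-D projections that pass univariate KS normality.

    The projection series is fixed once generated, so the same vectors can
    probe a sample and many of its synthetic samples.
    """
    if w.n < 20:
        raise ValueError("need n >= 20")
    if projections is None:
        if rng is None:
            raise ValueError("either projections or rng must be given")
        projections = make_projections(w.d, config.n_projections, rng)
    if projections.shape[1] != w.d:
        raise ValueError("stored projections have a different dimension")
    z = w.values @ projections.T  # n x s
    stats = _ks_normality_stats(z)
    crit = float(kolmogi(alpha)) / np.sqrt(w.n)
    pct = 100.0 * float(np.mean(stats < crit))
    return ProjectionBattery(projections=projections, non_reject_pct=pct)


def mardia_test(w: Sample) -> MardiaResult:
    """Mardia's multivariate skewness and kurtosis tests.

    With g_ij the Mahalanobis inner products of centered rows (ML covariance,
    denominator n): b1 = mean(g_ij^3), b2 = mean(g_ii^2).  n b1 / 6 is
    asymptotically chi-square with d(d+1)(d+2)/6 df; (b2 - d(d+2)) /
    sqrt(8 d (d+2) / n) is asymptotically standard normal (two-sided).
    """
    n, d = w.n, w.d
    if n <= d:
        raise ValueError("need n > d")
    centered = w.values - w.values.mean(axis=0)
    s = centered.T @ centered / n
    try:
        s_inv = np.linalg.inv(s)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance") from exc
    # accumulate sum g_ij^3 in row blocks: the full n x n Mahalanobis matrix
    # is only a few MB at n ~ 667 but grows quadratically
    half = centered @ s_inv
    g_sum3 = 0.0
    diag = np.einsum("ij,ij->i", half, centered)
    block = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, block):
        g_block = half[start:start + block] @ centered.T
        g_sum3 += float((g_block ** 3).sum())
    b1 = g_sum3 / (n * n)
    b2 = float((diag ** 2).sum() / n)
    stat_skew = n * b1 / 6.0
    df_skew = d * (d + 1) * (d + 2) / 6.0
    stat_kurt = (b2 - d * (d + 2)) / np.sqrt(8.0 * d * (d + 2) / n)
    return MardiaResult(
        b1=b1, b2=b2, stat_skew=float(stat_skew), stat_kurt=float(stat_kurt),
        p_skew=float(chi2.sf(stat_skew, df_skew)),
        p_kurt=float(2.0 * norm.sf(abs(stat_kurt))),
    )


def covariance_ci_coverage(
    sample: Sample,
    sp: SyntheticPopulation,
    config: RunConfig,
    rng: np.random.Generator,
    reps: int | None = None,
) -> CovCoverageResult:
    """How often each source covariance element falls inside synthetic CIs.

    Per repeat: draw ``config.n_eval_reps`` synthetic samples of the source
    size, compute their covariance matrices, take element-wise empirical
    2.5/97.5 percentiles, and record whether the source element lies inside.
    Coverage is the percent of repeats inside, per element.
    """
    reps = config.n_eval_reps if reps is None else reps
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n, d = sample.n, sample.d
    if sp.size < n:
        raise ValueError("population smaller than the sample size")
    pop = sp.matrix(sample.rep)
    ref = covariance(sample).values
    inner = config.n_eval_reps
    inside = np.zeros((d, d))
    for _ in range(reps):
        idx = rng.integers(0, sp.size, size=(inner, n))
        draws = pop[idx]  # inner x n x d
        centered = draws - draws.mean(axis=1, keepdims=True)
        covs = np.einsum("rij,rik->rjk", centered, centered) / (n - 1)
        lo, hi = np.percentile(covs, [2.5, 97.5], axis=0)
        inside += (ref >= lo) & (ref <= hi)
    return CovCoverageResult(coverage_pct=100.0 * inside / reps, reps=reps)


def eigenvalue_compare(
    sample_y: Sample,
    syn_y: Sample,
    direction: str = "sample/syn",
) -> EigCompareResult:
    """Swap a PCA transform between sample and synthetic data and F-test the
    component variances against the donor's eigenvalues.

    ``sample/syn``: fit on the sample, transform the synthetic sample;
    ``syn/sample``: fit on the synthetic sample, transform the sample.
    Two-sided F-test with (n-1, n-1) degrees of freedom per component.
    """
    if sample_y.d != syn_y.d:
        raise ValueError("dimension mismatch")
    if direction == "sample/syn":
        donor, receiver = sample_y, syn_y
    elif direction == "syn/sample":
        donor, receiver = syn_y, sample_y
    else:
        raise ValueError("direction must be 'sample/syn' or 'syn/sample'")
    model = pca_fit(donor)
    t = pca_forward(receiver, model)
    test_var = t.values.var(axis=0, ddof=1)
    ref = model.eigenvalues
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ref > 0, test_var / np.where(ref > 0, ref, 1.0), np.nan)
    p = np.where(
        np.isfinite(ratio),
        2.0 * np.minimum(
            f_dist.cdf(ratio, receiver.n - 1, donor.n - 1),
            f_dist.sf(ratio, receiver.n - 1, donor.n - 1),
        ),
        np.where(test_var == 0, 1.0, 0.0),
    )
    return EigCompareResult(condition=direction, eigen_ref=ref,
                            eigen_test=test_var, p_values=np.minimum(p, 1.0))


def ks_battery(
    sample: Sample,
    sp: SyntheticPopulation,
    config: RunConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-variable percent of repeated two-sample KS tests not rejected.

    Each repeat compares the source column against a fresh synthetic draw of
    the source size; the critical distance is the asymptotic two-sample value
    at ``config.alpha``.
    """
    pop = sp.matrix(sample.rep)
    if sp.size < sample.n:
        raise ValueError("population smaller than the sample size")
    n = sample.n
    crit = ks_critical_two_sample(n, n, config.alpha)
    pct = np.empty(sample.d)
    for j in range(sample.d):
        src = np.sort(sample.column(j))
        col = pop[:, j]
        hits = 0
        for _ in range(config.n_eval_reps):
            draw = np.sort(col[rng.integers(0, sp.size, size=n)])
            grid = np.concatenate([src, draw])
            d_stat = np.abs(
                np.searchsorted(src, grid, side="right") / n
                - np.searchsorted(draw, grid, side="right") / n
            ).max()
            hits += d_stat < crit
        pct[j] = 100.0 * hits / config.n_eval_reps
    return pct


@dataclass
class EvaluationReport:
    """All test blocks for one sample/synthetic-population comparison."""

    config: dict
    blocks: dict
    latent_normal: bool

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {"config": self.config, "blocks": self.blocks,
             "latent_normal": self.latent_normal},
            default=_jsonify, indent=2,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        doc = json.loads(text)
        return cls(config=doc["config"], blocks=doc["blocks"],
                   latent_normal=doc["latent_normal"])


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def build_report(
    config: RunConfig,
    projection_floor: float = 90.0,
    **blocks,
) -> EvaluationReport:
    """Assemble test blocks into a report with a latent-normal verdict.

    The verdict is true when (a) the MMD battery in Y accepts in at least 95%
    of repeats and (b) the random-projection non-reject percentage of the
    mapped sample reaches ``projection_floor``.  Mardia results are reported
    but do not gate the verdict.
    """
    blocks = {k: v for k, v in blocks.items() if v is not None}
    if not blocks:
        raise ValueError("no results to report")
    mmd_ok = True
    if "mmd_y_accept_pct" in blocks:
        mmd_ok = blocks["mmd_y_accept_pct"] >= 95.0
    proj_ok = True
    if "projection_y_sample_pct" in blocks:
        proj_ok = blocks["projection_y_sample_pct"] >= projection_floor
    return EvaluationReport(config=config.to_dict(), blocks=blocks,
                            latent_normal=bool(mmd_ok and proj_ok))


def evaluate_sample(
    sample: Sample,
    archive,
    sp: SyntheticPopulation,
    config: RunConfig,
    n_projection_samples: int = 20,
) -> EvaluationReport:
    """Run the full battery for a sample against its synthetic population.

    The sample is mapped through the archive's transforms so comparisons run
    in all three representations; MMD and KS batteries repeat
    ``config.n_eval_reps`` times, projection batteries reuse one fixed vector
    series per representation across the sample and ``n_projection_samples``
    synthetic samples.
    """
    from .data import rng_stream
    from .mapping import forward

    y_vals = np.column_stack(
        [forward(m, sample.column(j)) for j, m in enumerate(archive.maps)]
    )
    sample_y = Sample(y_vals, sample.names, "Y")
    sample_t = pca_forward(sample_y, archive.pca)
    reps_by_rep = {"X": sample, "Y": sample_y, "T": sample_t}

    blocks: dict = {}
    # per-variable KS batteries
    for rep, s in reps_by_rep.items():
        rng = rng_stream(config.seed, f"eval/ks/{rep}")
        blocks[f"ks_{rep.lower()}_pct"] = ks_battery(s, sp, config, rng)

    # MMD batteries
    for rep, s in reps_by_rep.items():
        rng = rng_stream(config.seed, f"eval/mmd/{rep}")
        accepts, stats, crits = [], [], []
        pop = sp.matrix(rep)
        for _ in range(config.n_eval_reps):
            idx = rng.integers(0, sp.size, size=s.n)
            syn = Sample(pop[idx], s.names, rep)
            res = mmd_test(s, syn, config.alpha)
            accepts.append(res.accept)
            stats.append(res.mmd_u2)
            crits.append(res.mmd_c)
        blocks[f"mmd_{rep.lower()}_accept_pct"] = 100.0 * float(np.mean(accepts))
        blocks[f"mmd_{rep.lower()}_u2_mean"] = float(np.mean(stats))
        blocks[f"mmd_{rep.lower()}_c_mean"] = float(np.mean(crits))

    # random projection batteries (fixed series per representation)
    for rep, s in reps_by_rep.items():
        rng = rng_stream(config.seed, f"eval/proj/{rep}")
        u = make_projections(s.d, config.n_projections, rng)
        battery = random_projection_test(s, config.alpha, config, projections=u)
        blocks[f"projection_{rep.lower()}_sample_pct"] = battery.non_reject_pct
        pop = sp.matrix(rep)
        syn_pcts = []
        for _ in range(n_projection_samples):
            idx = rng.integers(0, sp.size, size=s.n)
            syn = Sample(pop[idx], s.names, rep)
            syn_pcts.append(
                random_projection_test(syn, config.alpha, config,
                                       projections=u).non_reject_pct
            )
        blocks[f"projection_{rep.lower()}_syn_pct"] = float(np.mean(syn_pcts))

    # Mardia tests on the sample and one synthetic sample per representation
    for rep, s in reps_by_rep.items():
        rng = rng_stream(config.seed, f"eval/mardia/{rep}")
        blocks[f"mardia_{rep.lower()}_sample"] = mardia_test(s)
        idx = rng.integers(0, sp.size, size=s.n)
        syn = Sample(sp.matrix(rep)[idx], s.names, rep)
        blocks[f"mardia_{rep.lower()}_syn"] = mardia_test(syn)

    # covariance CI coverage in X and Y
    for rep in ("X", "Y"):
        rng = rng_stream(config.seed, f"eval/cov/{rep}")
        cov_res = covariance_ci_coverage(reps_by_rep[rep], sp, config, rng)
        blocks[f"cov_coverage_{rep.lower()}_pct"] = cov_res.coverage_pct

    # eigenvalue comparisons, both directions
    rng = rng_stream(config.seed, "eval/eig")
    idx = rng.integers(0, sp.size, size=sample.n)
    syn_y = Sample(sp.y[idx], sample.names, "Y")
    for direction in ("sample/syn", "syn/sample"):
        res = eigenvalue_compare(sample_y, syn_y, direction)
        key = "eig_" + direction.replace("/", "_")
        blocks[key + "_p"] = res.p_values
        blocks[key + "_vars"] = res.eigen_test
    blocks["eigenvalues_sample"] = pca_fit(sample_y).eigenvalues

    return build_report(config, **blocks)
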