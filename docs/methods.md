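# Methods

## Model and assumptions

`normsynth` targets small samples (hundreds of observations) of d continuous,
correlated, arbitrarily distributed variables. The modeling assumption is a
**latent normal characteristic**: there exist monotone per-variable
transforms m_j such that Y = m(X) is approximately multivariate normal. Under
that assumption the joint law of X decomposes into

* d monotone marginal maps (estimated nonparametrically), and
* the covariance matrix C_y of the normalized sample (a parametric normal
  model),

so no multivariate density estimation is needed — the piece of the problem
that scales badly with dimension is replaced by a d × d covariance. The
assumption is *testable*: the package's batteries (random projections, MMD
in Y/T, Mardia) measure how well it holds, and the summary verdict refuses
samples whose copula is not Gaussian (mixture counterexamples drop the
projection battery from ~100% to ~65% non-rejection).

Each marginal is assumed continuous. Integer-captured variables (age,
BMI-like) are handled by the KDE augmentation, which interpolates the tied
atoms smoothly; they remain an approximation (see limitations).

## Pipeline details and numerical choices

**KDE and bandwidth search.** Univariate Gaussian KDE per variable. The
bandwidth is chosen by differential evolution with a stochastic fitness: a
candidate h draws one fresh synthetic sample of the source size n from its
KDE and is scored by the two-sample KS distance to the source. Control
parameters: population 1000 for 30 generations at full scale (2 × pop × gens
fitness draws in total), initialization uniform on (0, 4·var(x_j)],
challengers formed by DE/rand/1 (F = 0.5; with one-dimensional genomes
crossover is moot), out-of-range mutants reflected back into the interval,
and the returned bandwidth is the mean of the terminal population. The
fitness is deliberately re-drawn every competition (no caching), which keeps
selection honest under noise; the terminal population clusters tightly
(observed sd ≲ 2% of the initial bound width at full scale).

**Normal-score maps.** The pooled set (sample + `kde_augment_n` KDE draws,
default 10⁶) estimates P_j; `map_normal_n` Box–Muller standard normals
(default 10⁶) estimate G_j. Quantiles of both on an equal-probability grid
of 4096 interior points become paired knots; evaluation is piecewise-linear
in either direction. Numerical choices:

* *Tails*: values beyond the terminal knots are clamped (the knot range
  covers ≈ ±3.3σ on the normal side with the 4096-point grid); clamp events
  are counted in the map metadata. Extrapolating an empirical quantile
  function is unreliable, so clamping is preferred.
* *Ties*: exact ties on the normal side (numerical accidents) are collapsed
  by averaging their partners. Ties on the x side are **kept**: they are the
  staircase signature of tied/sparse data mapped without augmentation, and
  the map reports them (`flat_runs`, `is_strict`). A properly augmented map
  is strictly monotone; for that the augmentation must dominate the tied
  sample well beyond one grid spacing per atom (with n = 667 and the 4096
  grid, ≥ ~3·10⁵ draws; the 10⁶ default is comfortable).
* *Normal source*: Box–Muller is the default and is pluggable
  (`normal_source` argument of the samplers).

**PCA and synthesis.** Covariance uses the unbiased n−1 denominator
throughout. Y is centered by its (near-zero) empirical means before PCA and
the means are restored on inversion. Eigenvector signs are fixed by making
each column's largest-magnitude entry positive (reproducibility).
Eigenvalues below 10⁻¹² of the trace are floored to zero and their T columns
emitted as constant zero: such components are numerical residue, and
flooring prevents noise amplification through the inverse transform.
Synthetic scores are independent normals with the eigenvalue variances —
i.e. the sample's T marginals are *approximated* as normal even where a
normality test on the sample would reject; deviations are reported by the
battery, not corrected.

**Seeding.** A single master seed fans out into labeled substreams
(`de/{j}`, `map/{j}`, `t-sample`, `eval/...`), so every stage is
individually reproducible and the whole pipeline is bit-for-bit
deterministic given `RunConfig.seed`.

## Evaluation battery

* **Two-sample KS**: pooled-grid ECDF distance; asymptotic critical value
  c(α)·√((n_a+n_b)/(n_a n_b)), appropriate at n ≈ 667 (measured null
  rejection ~5.1% at α = 5%).
* **One-sample KS normality** (inside the projection battery): against a
  normal with mean/sd estimated from the data, using the plain asymptotic
  critical value c(α)/√n. With estimated parameters this is *conservative*
  (null rejection ≈ 0); the battery relies on that documented conservatism —
  it mirrors near-100% non-reject rates for truly normal synthetic samples.
* **MMD**: unbiased MMD² with Gaussian kernel exp(−‖u−v‖²/2σ²), σ = median
  pairwise Euclidean distance of the pooled rows (zero distances excluded).
  The acceptance threshold is the distribution-free bound
  MMD_c = (4K/√m)·√ln(1/α) with K = 1, which depends only on (m, α): at
  m = 667, α = 0.05 it is 0.2681. The bound is loose — measured MMD² under
  the null is ~10⁻³ — so acceptance is necessary, not sufficient; the
  discriminating information is carried by the statistic's magnitude and by
  the projection battery.
* **Random projections**: n_projections (default 1000) unit vectors with
  standard-normal components, generated once and reused across the sample
  and all its synthetic samples; each projection is KS-tested for
  normality; the score is the percent not rejected.
* **Mardia**: b1 and b2 from Mahalanobis inner products with the ML (1/n)
  covariance; n·b1/6 ~ χ² with d(d+1)(d+2)/6 df, (b2 − d(d+2))/√(8d(d+2)/n)
  ~ N(0,1) two-sided. Computed in row blocks so memory stays linear in n.
  Measured null rejection 4–6% at n = 667, d = 5.
* **Covariance CI coverage**: per repeat, `n_eval_reps` synthetic samples of
  size n give element-wise empirical 2.5/97.5 percentiles; coverage is the
  percent of repeats in which the source element falls inside.
* **Eigenvalue comparisons**: the PCA transform is swapped between sample
  and synthetic sample in both directions; receiver component variances are
  compared to the donor's eigenvalues with two-sided F-tests, df (n−1, n−1).
* **Verdict**: latent-normal is declared when the MMD battery in Y accepts
  in ≥ 95% of repeats *and* the mapped sample's projection battery reaches
  the floor (default 90%, motivated by mid-90s scores of real samples that
  are usefully treated as latent normal). Mardia is reported but does not
  gate: real samples of this size routinely fail Mardia yet synthesize well.

Repeated-draw batteries sample rows from the synthetic population with
replacement (the population stands in for an unlimited distribution);
`draw_linked_samples` provides without-replacement, row-linked X/Y/T draws
where linkage matters.

## Synthetic study conditions

The fixture generator draws latent MVN(0, R) data and distorts each marginal
monotonically. Defaults mirror the scale of the motivating study: n = 667,
d = 10, AR(1) latent correlation with ρ = 0.7 (strong but not degenerate
neighbor correlation), and a marginal mix of five right-skewed (exp), two
symmetric continuous (identity), one bounded (logistic) and two
integer-captured (round, ~60 distinct values, sd 10) variables — the
character of the positive-valued, right-skewed, partly integer-captured
measurements the method targets. A `cube` tag (z³) is available but not a
default: its marginal density is unbounded at 0, which no targeted
measurement exhibits and which univariate Gaussian KDE cannot represent.

The non-latent counterexample mixes MVN(0, R) and MVN(0, DRD) (R constant
correlation 0.9, D sign-alternating) with equal weights: every marginal is
exactly N(0,1) but the copula is non-Gaussian, so it isolates exactly the
failure the verdict must catch.

What the fixtures do **not** emulate: measurement error structure, outliers,
bounded-support pile-ups, multimodality, or the specific covariance spectra
of real instruments. Passing tests therefore demonstrate correctness of the
machinery and closure under the method's own assumptions, not performance on
any particular real dataset.

Desk-scale study conditions used by the test suite and the acceptance
script: synthetic populations of 10⁵, DE population 100 over 10 generations,
100 evaluation repetitions, 1000 projections. Full-scale defaults (10⁶
populations, DE 1000 × 30, 1000 repetitions) are the `RunConfig` defaults.

## Known limitations

* **KDE smoothing shrink.** The mapped sample's variances fall ~1–5% below 1
  (smoothing inflates the pooled spread by ≈ h²; peaked marginals lose the
  most), so the Y eigenvalue spectrum sums slightly below d. The exact
  identity Σλ = trace(C_y) always holds.
* **Support boundaries.** The Gaussian kernel smears mass across a support
  boundary (e.g. below 0 for a lognormal), biasing the extreme tail of the
  map: small in cumulative probability (≲ 0.03), but amplified by 1/φ(z)
  when read in normal-score units. No boundary correction is applied.
* **Quantile-map accuracy is sample-limited.** At n = 667 the ECDF's
  sampling noise alone puts ~0.2 normal-score error at the 0.5% quantile;
  map accuracy should be judged in cumulative-probability units.
* **Augmentation and marginal KS.** Without augmentation this package's map
  construction degenerates to the empirical normal-score transform, whose
  synthetic marginals are near-bootstrap copies of the sample — marginal KS
  comparisons do not degrade, only the structural pathologies (flat runs,
  no strict inverse, no tail extension, bootstrap-like discreteness of the
  synthetic values) appear. Augmentation buys strict monotonicity,
  continuous space-filling synthetic values and smooth tails, at the price
  of the smoothing shrink above.
* **Integer variables** are synthesized as continuous values interpolating
  the atoms; downstream users needing integers must re-round.
* **MMD bound looseness.** The distribution-free threshold cannot reject
  subtle copula violations at these sample sizes; use the projection
  battery for discrimination.
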