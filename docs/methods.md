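# Methods

This note records the model, the numerical choices, and what the synthetic
test conditions do and do not demonstrate.

## Model overview

The package predicts three performance outcomes (simple reaction time,
executive-function error rate, perceptuo-motor error rate) from three
physiological predictors (stress, sleep duration, physical exertion). Each
outcome gets its own 4-dimensional joint density p(y, x₁, x₂, x₃) — a main
effects model: the only cross-variable information supplied is the set of
pairwise predictor–outcome correlations, and no predictor–predictor or
outcome–outcome structure is imposed. Conditioning on the predictors is
closed-form because the joint is a finite mixture of isotropic Gaussians:
the conditional p(y|x) is again a univariate Gaussian mixture whose weights
are the component responsibilities at x.

## Marginal estimation

Per variable, observations from several sources in a common unit are pooled
as a mixture of per-source Gaussian KDEs with weights πₖ = nₖ/Σn. Executive
and perceptuo-motor error *rates* are derived from binary trial outcomes by
a moving average over windows of five successive trials.

Numerical choices (the data sources give no guidance on any of them):

* **Bandwidth**: Scott's rule per source (sd·n^(−1/5)) times a global
  multiplier `kde.bandwidth_scale` (default 1.0) — a reproducible stand-in
  for manual per-source tuning.
* **Grid**: 512 equally spaced points over the pooled data range padded by
  3 pooled bandwidths; the tabulated density is renormalized so its
  trapezoidal integral is exactly 1.
* **Axis normalization**: the joint fit works on [−1, 1] axes. The physical
  interval mapped onto [−1, 1] is bounded by the 0.001/0.999 quantiles of
  the estimated marginal by default, so unbounded tails do not dictate the
  map; densities are interpolated, Jacobian-scaled, and renormalized (the
  ≤0.2% clipped tail mass is redistributed proportionally).
* **Unit conversion** factors are supplied by configuration (e.g. cortisol
  µg/dL → nmol/L multiplies by 27.59), never hard-coded into the estimator.

## Latent stress fusion

Stress is observed through cortisol, alpha amylase, heart rate, and
subjective ratings. Each source i is an affine readout dᵢ = aᵢ·s + bᵢ of a
latent stress variable s with density p_S(s) = Σ_c α_c N(s; μ_c, σ_c²),
N_c = 6 components. All parameters are fitted jointly by maximum
likelihood; each datum contributes −log[(1/|aᵢ|)·p_S((d−bᵢ)/aᵢ)].

* **Initialization**: aᵢ = sample sd, bᵢ = sample mean of source i (so the
  initial latent mapping is each source's z-scores); mixture weights and
  sds 1/N_c; means linearly spaced over [−2, 4], μ_c = −2 + 6(c−1)/(N_c−1).
* **Identifiability**: the affine family leaves the latent scale defined
  only up to s → κs + δ. The scale is anchored by freezing source 1's
  (a, b) at their initialization, which makes the latent axis a generalized
  z-score of source 1 and makes parameter-recovery tests well-posed. The
  likelihood itself is invariant under the reparameterization (tested).
* **Optimization**: one deterministic bounded quasi-Newton (L-BFGS-B)
  descent; σ_c floored at 10⁻³ through a log parameterization (preventing
  component collapse onto single points), weights kept on the simplex by a
  softmax with the first logit pinned. Scale orientation follows source 1's
  raw scale (a > 0 throughout). If the optimizer fails to improve on the
  initialization the initialization is returned with a warning.
* **Model order** N_c = 6 is fixed; adaptive order selection is out of
  scope.

## Effect sizes

Correlation constraints come from published effect sizes. Conversions use
standard meta-analytic relations: r = d/√(d² + h) with
h = (n₁+n₂)²/(n₁n₂) (h = 4 under the equal-group assumption); Hedges' g is
treated as d on this scale. Studies of the same pair are pooled by
inverse-variance weighting (variance 1/(n−3)) on the Fisher-z scale, with
the pooled CI from the pooled z-variance. The packaged default matrix keeps
the nine predictor–outcome coefficients with 95% CIs; the canonical value
for the sleep/reaction-time cell is −0.278 (an alternative printing of
−0.276 exists for the same quantity; the matrix keeps −0.278).

## Joint density construction

**Basis.** N equally spaced lattice points per axis (N odd) on [−1, 1],
M = 7 widths σ ∈ {0.03, 0.05, 0.10, 0.15, 0.20, 0.30, 0.40}; basis index
i = m·N⁴ + n is width-major with the center index raveling axes
(y, x₁, x₂, x₃) in C order. Production default N = 21 (7·21⁴ ≈ 1.36 M
coefficients); the desk-scale test profile uses N = 9 (45,927
coefficients). Basis functions are *untruncated* ℝ⁴ Gaussians; reported
densities are divided by the mixture's closed-form box mass so that the
joint integrates to 1 over [−1, 1]⁴, while moment algebra (means, sds,
cross-moments, and the moment constraints themselves) uses the untruncated
mixture, for which the relations are exact: isotropic components have zero
within-component cross-covariance, so E[x_j·y] = Σᵢ αᵢ μ_{x_j,i} μ_{y,i}.

**Constraints.** Each axis marginal is evaluated at K = 41 equally spaced
points (blocks A₁..A₄); each predictor–outcome pair contributes one moment
row (block A₅) with target r·s_x·s_y + m_x·m_y scaled by 1/(s_x·s_y), where
the means and sds are those of the *supplied* normalized marginals. Block
weights default to w = (1, 1, 1, 1, 75): the moment block has only three
rows and is up-weighted so that fitting the correlations is not swamped by
the 164 marginal rows.

**Inner solver.** On the simplex the weighted L1 penalty λ‖diag(c)α‖₁
equals the linear form λ·cᵀα, so each inner problem is a smooth convex QP
over the simplex with a unique optimal value. It is solved by fully
corrective Frank–Wolfe (simplicial decomposition): the linear oracle over
the simplex is a coordinate argmin of the gradient; up to 8 new atoms are
admitted per major iteration; the active set is re-optimized on its small
Gram system by FISTA with adaptive restart and exact Euclidean simplex
projection; zero-weight atoms are dropped. The Frank–Wolfe duality gap
gradᵀα − minᵢ gradᵢ upper-bounds the objective suboptimality and is the
stopping criterion (default 10⁻⁹, with a bounded escalation of the
corrective budget when the gap stalls). Because the constraint stack has
only 4K + 3 ≈ 167 rows, the optimal support is small and the method reaches
certified optima in seconds where a generic projected-gradient iteration
needs tens of thousands of full-dimension passes. The same solver, via the
gap certificate, matches a generic SLSQP solve of the identical objective
to < 10⁻⁵ on the 162-coefficient oracle basis (tested).

**Adaptive reweighting.** c starts at 1; after each solve, cᵢ = 1/αᵢ where
αᵢ > t and cᵢ = 1/t where αᵢ ≤ t (the published description of the
else-branch is ambiguous; the 1/t cap keeps zeroed coefficients maximally
penalized). Coefficients at the 1/t cap are excluded from subsequent
solves: their penalty gradient λ/t = 10⁴ exceeds any attainable data-term
gradient, so they are provably zero at the optimum. Thresholded
coefficients (αᵢ ≤ t = 10⁻⁹) are set to zero and the survivors renormalized
to sum exactly to 1; iteration stops when at most N_z = 400 survive or
after `lasso.max_outer` = 50 rounds (then the best iterate is returned with
a warning flag).

**Recovered statistics.** The fidelity report compares supplied marginals
with the mixture-implied marginals (L1 and max discrepancies) and supplied
correlations with recovered ones. The recovered correlation uses the
effect-size relation exactly as the constraint does — fitted cross-moment
E[x_j·y], supplied means and sds. The fully model-implied correlation
(all moments from the mixture) is reported alongside as `model_r`; on the
reduced N = 9 lattice it differs from the supplied value by up to a few
hundredths because the coarse basis cannot reproduce the supplied marginals
below L1 ≈ 0.01–0.03, which biases the mixture's own means and sds — a
resolution property of the reduced lattice, not of the optimization.

## Conditional queries

Conditioning is closed-form: component weights ∝ αᵢ·N₃(x; μ_{x,i}, σᵢ²I),
computed in log-space with log-sum-exp; a conditioning point whose
predictor density falls below 10⁻³⁰⁰ raises an error. Physical-unit inputs
are mapped through the stored axis transforms; out-of-range inputs are
clamped to [−1, 1] with a warning (interactive sliders imply bounded
ranges). Summaries are computed by quadrature on the tabulated conditional:
mode = grid argmax refined by local quadratic interpolation (smallest mode
returned on ties, with a logged flag), median/percentiles by interpolated
inverse CDF, and the "95% interval" is the central 95% interval of the
conditional *predictive* density — the only interval computable from the
stated model (it is not a model-uncertainty interval). Kurtosis is reported
as excess kurtosis (Gaussian = 0). Location and scale statistics are mapped
to physical units; skew and kurtosis are affine-invariant and reported
as-is.

## Synthetic fixtures: what they emulate and what they do not

The original multi-study tables are not redistributable, so all tests run
on generated data:

* **Stress sources**: drawn from a known fusion model whose latent mixture
  is standardized (mean 0, variance 1), so the anchored scale recovered by
  the ML fit coincides with the generating scale up to sampling error, and
  recovery can be scored by L1 distance between latent densities.
* **Marginal suite**: six analytic densities with the qualitative shapes
  seen in practice — right-skewed shifted log-normal latency (shift 150 ms,
  scale e^5.3, σ = 0.2), beta error rates (2.5, 6) and (3, 6), a bimodal
  sleep mixture 0.6·N(7.5, 1.0²) + 0.4·N(4.7, 1.1²) h, a truncated normal
  on the Borg 6–20 scale (center 12, width 3), and a three-component stress
  mixture. Bounded variables map their exact support onto [−1, 1];
  unbounded ones use 10⁻⁵ quantiles. Shape parameters follow a resolution
  rule fixed at design time: every density's local feature scale on the
  normalized axis stays ≥ ~0.15 so that the reduced N = 9 lattice (spacing
  0.25) can represent the suite; the production N = 21 lattice resolves
  sharper structure than the suite contains. Consequences: passing tests
  demonstrate correctness of the construction and solver at desk scale,
  *not* that N = 9 suffices for arbitrary real marginals — sharper real
  densities need the full lattice.
* **Representable joint problems**: a known sparse α on well-separated
  interior components generates exact marginal and moment targets
  (construct-and-recover oracles).
* All generators take a single seed (NumPy PCG64 via
  `numpy.random.default_rng`) and are bit-reproducible.

## Problem sizes and profiles

Test and acceptance runs use the reduced profile — N = 9 lattice, K = 41,
suite marginals on 2001-point grids, fusion recovery on 4 sources × 2000
observations, Monte-Carlo oracles at 10⁵ draws — chosen so the full suite
completes in a few minutes on one CPU. The N = 21 production profile is
exercised by the same code paths (the solver's cost scales with the active
set, not the basis size, after the first gradient) but is not part of the
default test run.

## Known limitations

* Single-outcome joints: three separate 4-D fits, no outcome–outcome
  coupling; no predictor–predictor interaction constraints.
* Isotropic fixed-width, lattice-centered components can leave spherical
  artifacts in slices; free-center/anisotropic bases are out of scope.
* The affine readout gᵢ(s) = aᵢs + bᵢ is a simplification; nonlinear source
  maps are not modeled.
* KDE bandwidths are rule-based, not cross-validated; censored or truncated
  observations are not handled.
* The latent stress axis orientation is a convention (positively oriented
  with source 1's raw scale).
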