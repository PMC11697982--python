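# Methods

## Model

Given a micro-state time series {x_t} ⊂ ℝᵖ, the framework learns three
maps so that the effective information (EI) of the macro-level dynamics is
maximized subject to a micro-prediction constraint:

* a coarse-graining φ(x) = first q coordinates of ψ(x), where
  ψ: ℝᵖ → ℝᵖ is an exactly invertible network ("information discarding"
  is coordinate projection);
* an anti-coarse-graining φ†(y) = ψ⁻¹([y, ξ]), ξ ~ N(0, I_{p−q}), sharing
  every parameter with φ;
* forward and reversed macro-dynamics f, g: ℝᵠ → ℝᵠ.

Direct EI maximization is intractable, so training minimizes the surrogate

    L = Σ_t w(x_t) ‖y_t − g(y_{t+1})‖₁ + λ ‖x̂_{t+1} − x_{t+1}‖₁,

with y_t = φ(x_t), x̂_{t+1} = φ†(f(φ(x_t))), and inverse-probability
weights w ∝ 1/p̂(y_t) that re-target the empirical macro distribution to
the uniform one demanded by the do-intervention in the EI definition.
p̂ is a Gaussian KDE (Scott's rule by default), refreshed every
`reweight_every` epochs because φ drifts during training. Norms are L1 per
sample, averaged over the batch, consistent with MAE-based evaluation.

The degree of causal emergence at scale q is ΔJ = 𝒥(f_q) − 𝒥(f_p) in bits
per dimension, where the q = p model plays the role of the learned
micro-dynamics. A ΔJ verdict is reported as *valid* only when the macro
model's 10-step normalized MAE is at or below `error_threshold` (0.3):
above it, the macro model no longer simulates the data and its EI is
meaningless.

## Effective information of learned dynamics

For the learned continuous dynamics with additive Gaussian residual noise
(σ_i per dimension) and a uniform intervention over the anisotropic box
∏_i [−L_i, L_i],

    EI = E_y[ln |det J_f(y)|] + Σ_i ln(2L_i) − (q/2) ln(2πe) − Σ_i ln σ_i,

estimated by Monte Carlo (default 400–500 draws; analytic network
Jacobians; singular values floored at 1e−12 so degenerate maps yield
large-negative, never non-finite, EI). 𝒥 = EI/q is the dimension-averaged
EI used for cross-scale comparison; discrete-chain examples use raw EI in
bits, matching the usual presentation of the Markov worked example.

Two estimation choices matter:

* **Per-dimension intervention half-widths L_i** (the observed macro
  bounding box per dimension) rather than one global L. With a single L
  the q = p model can inflate 𝒥 arbitrarily by linearly shrinking its
  unpredictable coordinates — σ_i falls while L stays pinned to the widest
  dimension. With per-dimension L_i, 𝒥 is invariant to any per-coordinate
  linear rescaling, and noise dimensions contribute their true
  ln(range/noise) ≈ 0, which is what makes the micro scale score lower on
  noisy data.
* **Residual noise scales σ_i** are the per-dimension RMS one-step
  prediction residuals of f on a held-out split (floor 1e−6), so a
  near-deterministic fit cannot produce −∞.

The formula neglects the smoothing of the output density by the noise, an
O(σ/L) edge effect; the test suite checks it against numerically
integrated channel mutual information (2% at σ/L = 0.1).

## Architecture and optimization

* **Invertible network**: a fixed volume-preserving affine pre-layer
  (centering + orthogonal PCA rotation of the training inputs) followed by
  RealNVP-style affine coupling layers (default 3) with alternating
  even/odd masks; scale heads pass through 5·tanh(·), and both heads are
  zero-initialized so every layer starts as the identity. The PCA pre-layer
  is essential in practice: without it the identity-initialized encoder
  begins as coordinate truncation, and on data whose informative directions
  are not axis-aligned the reconstruction loss plateaus far above the noise
  floor.
* **Dynamics**: residual MLPs y + net(y) (tanh, zero-initialized output),
  so f and g start as the identity — the right prior for small time steps.
* **Optimization**: Adam (default 2e−3) with exponential decay to
  `lr_decay`×(initial rate) over the run; the L1 objectives keep gradient
  magnitudes O(1) near the optimum, so a fixed step cannot settle.
  The first `warmup_epochs` train the prediction term alone, stabilizing φ
  before density estimation and the inverse term switch on. Weights are
  clipped at `clip_max` (20) and self-normalized to mean 1 (clip and
  normalization iterated to their joint fixed point).
* **Everything is seeded**: initialization, batching, decode noise, EI
  sampling and data splits derive from the single `seed`, and repeated fits
  are bitwise identical.
* Autodiff is a ~300-line reverse-mode engine on numpy arrays, checked
  against finite differences in the test suite.

## Multi-step prediction

Rollouts iterate f in macro space from a single encode and decode each
step with its own deterministic noise stream; re-encoding decoded states
would inject decoder noise into the state itself. Rollouts exceeding an
overflow guard are truncated and flagged. Normalized MAE is
MAE / mean|truth − truth's per-dimension mean| — scale-free, equal to 1
for a predictor that always answers the mean.

## Synthetic benchmarks

* **Noisy SIR** (β = 1, γ = 0.5, dt = 0.01, RK4): initial conditions
  uniform on the simplex triangle (optionally restricted to S > 1/3 for
  out-of-distribution experiments); micro-state (S, S, I, I) + N(0, σ²I₄),
  isotropic noise being the simplest reading of the observation model.
  This emulates redundant, noisily observed sensors over a smooth
  low-dimensional dynamics; it does not emulate non-Gaussian noise,
  missing data, or observation maps that are not coordinate duplication.
* **Boids**: N = 16 (configurable) on a 300×300 toroidal canvas; Reynolds
  cohesion/alignment/separation within per-rule radii act inside each of
  two groups, each group turning by a constant ±angle per step; speed is
  held constant. Intrinsic noise adds per-boid heading perturbations
  uniform on α·[−π, π]; extrinsic noise N(0, δ_max) perturbs observations
  only (the clean series is returned alongside). Rule radii/weights and
  the toroidal boundary are package defaults, exposed in `BoidsConfig`.
* **Duplicated linear system**: stable random linear dynamics (spectral
  radius set to 0.95) in `dim_true` dimensions, embedded by coordinate
  duplication plus Gaussian noise — a fixture whose optimal macro
  dimension is known by construction.

Passing tests on these generators demonstrate the machinery —
denoising coarse-graining, EI maximization, scale selection — under
idealized conditions (Markovian dynamics, stationary noise, abundant
data); they do not establish performance on real observational data,
where non-Markovian structure and sampling limitations dominate.

## Ψ indicator

Ψ = I(V_t; V_{t+1}) − Σ_j I(x_t^{(j)}; V_{t+1}) for a scalar macro
variable V; Ψ > 0 is sufficient but not necessary for emergence. MI
estimators are pluggable: plug-in for discrete data, Gaussian
(−½ log₂(1−ρ²)) or binned for continuous; which estimator best matches
published Ψ values on continuous data is genuinely open, so the choice is
a parameter.

## Attribution

Integrated gradients along the straight path from a baseline (dataset mean
by convention here) with a trapezoidal rule (default 64 nodes; completeness
holds to well under 1%). Saliency aggregation takes the mean absolute map
over samples, zeroes designated columns (e.g. velocity coordinates), and
optionally max-abs-normalizes each macro row — the "enhance the maximum"
convention used for saliency displays.

## Problem sizes and limitations

Bundled tests and the acceptance script train scaled-down models (SIR:
60–100 trajectories × 80–100 steps, 120 epochs; scale scans: 30×60 linear
fixtures, 60 epochs) — sizes chosen so the full causal-emergence pipeline
is exercised end to end on one CPU. Known limitations: Markovian dynamics
are assumed; q must be chosen by scanning; coupling-layer expressiveness
bounds how much a decoder can suppress pad noise (ln-gain ≥ −5 per
traversed layer); EI estimates inherit KDE and Monte-Carlo error; and the
discrete worked example's printed 0.55 bits is 0.5436 at full precision
for the standard chain reconstruction.
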