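# nisplus

Learn emergent macro-dynamics from multivariate time series and quantify
the degree of causal emergence by maximizing effective information.

## The problem

Complex dynamical systems — epidemics, flocks, brains — are observed as
high-dimensional micro-state time series, yet their interesting behavior
often lives at a coarser scale. *Causal emergence* makes this precise: a
coarse-graining φ: ℝᵖ → ℝᵠ exhibits causal emergence when the macro-level
dynamics f_q has **stronger causal effect** than the micro-level dynamics,
measured by effective information (EI),

    𝒥 = I(Y_t ; Ŷ_{t+1} | do(Y_t ~ U(𝒴))),

the mutual information between successive states when the current state is
forced by intervention to be uniform. This package implements a neural
framework (NIS+, the *neural information squeezer*) that learns φ, the
forward macro-dynamics f_q and a reversed macro-dynamics g jointly, by
minimizing

    Σ_t w(x_t) ‖φ(x_t) − g(φ(x_{t+1}))‖ + λ ‖φ†(f_q(φ(x_t))) − x_{t+1}‖,

where φ† ≈ φ⁻¹ shares parameters with φ through an invertible
coupling-layer network, and the inverse-probability weights
w = p̃(y_t)/p(y_t) (kernel-density estimated) emulate the uniform
do-intervention. The degree of causal emergence at macro dimension q is

    Δ𝒥 = 𝒥(f_q) − 𝒥(f_p),

with q = p giving the learned micro-dynamics; a report is trusted only when
the 10-step normalized MAE stays at or below 0.3.

The package also ships exact discrete-Markov EI (with transition-matrix
coarse-graining), the Ψ synergy indicator for comparison, integrated-
gradients attribution of macro-dimensions to micro-coordinates, and
simulators for the benchmark systems (noisy SIR epidemic, two-group
boids flock, duplicated linear fixtures). There is no torch dependency:
networks and training run on a small numpy reverse-mode autodiff included
in the package.

## Worked example: causal emergence in a discrete Markov chain

An 8-state chain whose states 1–7 jump uniformly among themselves while
state 8 is absorbing; grouping {1..7} into one macro-state yields a
perfectly deterministic 2-state macro chain:

```python
import numpy as np
from nisplus import TransitionMatrix, Partition, ei_discrete, coarse_grain_tpm, delta_j

micro = np.zeros((8, 8)); micro[:7, :7] = 1/7; micro[7, 7] = 1.0
j_micro = ei_discrete(micro, log_base=2)          # 0.5436 bits
macro = coarse_grain_tpm(TransitionMatrix(micro), Partition([range(7), [7]]))
j_macro = ei_discrete(macro, log_base=2)          # 1.0 bit
print(j_micro, j_macro, delta_j(j_macro, j_micro))
# 0.5435644431995965 1.0 0.4564355568004035
```

Δ𝒥 ≈ 0.46 > 0: the macro scale is more informative about its own future
than the micro scale — causal emergence.

## Worked example: noisy SIR micro-data

The SIR epidemic (β = 1, γ = 0.5) evolves two degrees of freedom (S, I);
the micro-state duplicates them and adds Gaussian observation noise,
x_t = (S, S, I, I) + ξ, ξ ~ N(0, σ²I₄). Training at q = 2 versus q = p = 4:

```python
from nisplus import SIRConfig, TrainConfig, simulate_sir, quantify_ce

data = simulate_sir(SIRConfig(sigma=1e-3, n_traj=100, T=100, seed=1))
cfg = TrainConfig(q=2, epochs=120, learning_rate=2e-3, seed=1, warmup_epochs=10)
report = quantify_ce(list(data.micro), 2, cfg)
print(report)
# CEReport(q=2, j_macro=7.81.., j_micro=6.87.., delta_j=0.94..,
#          nmae=0.011.., valid=True, threshold=0.3)
```

Δ𝒥 ≈ +0.9 bits per dimension with a 10-step normalized MAE of ~0.01: the
learned 2-dimensional macro-dynamics denoises the duplicated observations
and has stronger causal effect than the learned micro-dynamics — exactly
the behavior expected at low observational noise.

The scikit-learn-style estimator is available directly
(`NISPlus(q=2).fit(trajectories)`, then `.transform`, `.predict`,
`.rollout`, `.effective_information()`), and a CLI covers the same ground:

```bash
nisplus simulate sir --sigma 1e-3 -n 100 -T 100 --seed 1 --out data/sir
nisplus ce --data data/sir --q 2 --q 4 --seed 1
nisplus ei discrete --tpm chain.csv --partition '[[0,1,2,3,4,5,6],[7]]'
```

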