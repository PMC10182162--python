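# channeltrend

**Screening how ion-channel conductances shape single-neuron stimulus
encoding, with trend-filtered point-process GLMs.**

A neuron's computational role — how it converts injected current into spike
trains — depends on which ion channels it expresses and how strongly.
`channeltrend` links the two model families that describe these levels
separately: a conductance-based (Hodgkin–Huxley-type) biophysical model,
whose maximal conductances `g_k` are mechanistic knobs, and a point-process
generalized linear model (PP-GLM), whose fitted filters describe stimulus
encoding. The package simulates a current-clamp experiment while one
channel's conductance is scaled over a grid, fits one PP-GLM per scaling
factor *jointly* with a trend-filtering penalty, and summarizes each
encoding feature's sensitivity to the channel with a single statistic, the
**sum of slopes**. The result is a screen: which channels modulate which
parts of the stimulus filter, the post-spike history filter, and the
baseline firing rate.

## The model

For conductance scaling factor `g_i`, the probability of a spike in 1 ms
bin `j` is a Bernoulli GLM with a logit link,

```
logit(p_j) = [k_i ⊗ s]_j + b_i + [h_i ⊗ y]_j
```

where `s` is the injected current, `y` the binary spike train, `k_i` the
stimulus filter and `h_i` the post-spike history filter, both expanded in
10 raised-cosine bases (narrow near lag 0, wide at long lags), plus a
baseline `b_i` — 21 coefficients `β(g_i)` per condition. The logit link is
used because bins are binary (multiple spikes per bin are clipped), where a
log-link Poisson model would be biased at high rates.

Fitting each condition separately gives noisy coefficient-versus-`g`
trajectories. The joint estimator solves

```
min_{β(g_1)…β(g_B)}  Σ_i −ℓ_i(β(g_i)) + λ Σ_i ‖β(g_i) − β(g_{i+1})‖₁ / (g_{i+1} − g_i)
```

— a weighted fused lasso ("trend filtering") across the ordered conductance
grid. The ℓ1 penalty on successive differences sets small,
noise-level changes exactly to zero while keeping real trends. λ is chosen
on a 23-point geometric grid `{λ_max·e⁻ʲ} ∪ {0}` by the largest-λ rule:
the largest penalty whose summed held-out log-likelihood (30% of trials)
is within ζ = log 1.0005 of the best over the grid. Each encoding feature
`q` is then scored by the sum of slopes

```
SS_q = Σ_j |β(g_j)_q − β(g_{j+1})_q| / (g_{j+1} − g_j),
```

the step-normalized total variation of its trajectory: zero for features
untouched by the channel, large for strongly modulated ones.

The solver is a proximal Newton method whose fused-lasso subproblems are
solved exactly through a box-constrained dual; its λ=0 and λ≥λ_max limits
provably coincide with independent per-condition and pooled logistic MLEs,
which the test suite verifies against independent solvers.

## Worked example

Simulate spike trains from a known family of PP-GLMs in which exactly two
coefficients vary with the conductance factor (stimulus coefficient 2 and
the baseline, both with step-normalized total variation ≈ 3.0), then refit
with trend filtering:

```python
import numpy as np
from channeltrend import ConductanceTrendGLM, make_cosine_basis
from channeltrend.glm import simulate_spikes_from_glm
from channeltrend.neuron import DEFAULT_FACTORS, SpikeTrainSet
from channeltrend.trend import ConductanceGrid
from channeltrend.verify import make_true_model_sequence

bK, bH = make_cosine_basis("stimulus"), make_cosine_basis("history")
grid = ConductanceGrid(np.array(DEFAULT_FACTORS))
base = np.zeros(21); base[:3] = [0.5, 0.3, 0.1]; base[10] = -3.0; base[11] = -4.0
truth = make_true_model_sequence(grid, base, varying_indices=[2, 10],
                                 amplitude=1.0, seed=0)

rng = np.random.Generator(np.random.PCG64(42))
stimulus = rng.standard_normal((30, 1000))
spike_trains = {
    float(g): SpikeTrainSet(
        simulate_spikes_from_glm(truth.params(i), bK, bH, stimulus, seed=rng),
        factor=float(g))
    for i, g in enumerate(grid.factors)}

model = ConductanceTrendGLM(spike_trains, stimulus, channel="ka")
results = model.fit(split_seed=0)
print(results.summary())
```

```
Conductance Trend-Filtered PP-GLM Results
=========================================================
channel:              ka
conditions (B):       10
grid:                 [0.01 0.05 0.2  0.5  0.8  1.   1.2  1.5  2.   3.  ]
coefficients/cond:    21 (10 stimulus + 1 baseline + 10 history)
trials (train/val):   21/9
lambda_max:           3370.84
lambda*:              8.35549
zeta:                 0.000499875
val loglik at lambda*:-20755.5963
solver converged:     True (3 outer iterations)
---------------------------------------------------------
sum of slopes at lambda* (logit spikes/bin per unit factor):
 coefficient    block  peak_lag_ms     ss
           0 stimulus       1.0000 0.3186
           1 stimulus       1.8568 0.0644
           2 stimulus       3.0806 2.3849
           3 stimulus       4.8286 0.2296
           4 stimulus       7.3255 0.0000
           ...
          10 baseline          NaN 1.8679
          11  history       1.0000 0.0000
           ...
          20  history      48.5031 0.2710
```

The two planted features (stimulus coefficient 2 with SS 2.38 and the
baseline with SS 1.87) stand out an order of magnitude above the planted
nulls, several of which are fused to exactly zero — the screen recovers
which encoding features the "channel" modulates. At λ = 0 the same SS
vector is dominated by noise (every coefficient scores high).

The same interface runs on the bundled conductance-based point neuron
(transient Na, delayed-rectifier K, A-type K, high-voltage-activated Ca)
driven by correlated pink-noise current, end to end:

```bash
channeltrend run -o demo_out          # stimulus -> simulate -> fit -> screen
channeltrend verify --repeats 10 --seed 1 -o verify_out
```

`demo_out/ss_screen.csv` tabulates SS per channel and coefficient;
`verify_out/recovery_summary.json` reports the planted-trend recovery
errors across the penalty path. Spike trains from external simulators
(e.g. full morphological NEURON models) can be imported through a plain
spike-time text format (`channeltrend.io.load_spike_trains`) and fitted
identically.

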