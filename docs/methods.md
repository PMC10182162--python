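# Methods

This note documents the models, algorithms, defaults and design choices in
`channeltrend`, and what the synthetic data used by the tests do and do not
establish about real recordings.

## 1. Stimulus generation

The simulated experiment injects, on every trial, the sum of a DC offset
and a broadband fluctuating current built by convolving Gaussian white
noise with an alpha kernel `α(t) = (t/τ)·exp(−t/τ)`, τ = 3 ms, sampled at
the integration step (0.025 ms) and normalized to unit peak. Filtering is
causal (`full`-mode convolution truncated to the trial length), so the
first few milliseconds contain the kernel ramp-in.

Trial-to-trial structure follows the frozen-noise design: each trial's
fluctuating part is `√c·parent + √(1−c)·unique`, with the parent signal
shared across trials and the unique component freshly drawn. Because both
components have unit variance, the expected inter-trial Pearson
correlation of the fluctuation is exactly `c`; the mixture is then scaled
to the target SD and added to the DC offset. Separate seeds control the
parent and the noise, and output is bit-reproducible.

Defaults (free parameters, chosen once and documented rather than derived):
`dc_offset = 3.5 µA/cm²`, `noise_sd = 2.0 µA/cm²`, `c = 0.8`. With the
default neuron these produce ≈ 20 Hz firing at control conductance,
3–30 Hz across the full 0.01–3.0 scaling grid, and spike-train
trial-to-trial correlations around 0.1 — a fluctuation-driven regime in
which every grid point remains active.

## 2. Conductance-based neuron and spike extraction

The bundled neuron is a single compartment with Hodgkin–Huxley-type
channels: transient Na (m³h, ḡ = 120 mS/cm²), delayed-rectifier K (n⁴,
ḡ = 36), an A-type K current (a³b, ḡ = 8) with Connor–Stevens-like
steady-state/time-constant gates, a high-voltage-activated Ca current (m²,
ḡ = 1.5), and leak (0.3 mS/cm², −54.4 mV); C = 1 µF/cm², rest near
−65 mV. All constants live in `ChannelSpec`/`NeuronModel` configuration
objects and can be replaced wholesale. A conductance screen scales one
channel's ḡ by each factor in {0.01, 0.05, 0.2, 0.5, 0.8, 1.0, 1.2, 1.5,
2.0, 3.0} while reusing the identical stimulus ensemble, so differences
between conditions are attributable to the scaled channel alone.

Integration is fixed-step at 40 kHz (0.025 ms): exponential Euler for the
gating variables (which therefore stay in [0, 1] unconditionally) and
forward Euler for the voltage. Halving the step changes spike times by
less than the 1 ms analysis bin. A voltage excursion beyond ±200 mV raises
an integration-failure error naming the step size.

Spikes are upward crossings of 0 mV; the spike time is the first sample at
or above threshold, and the trace must return below threshold before a new
crossing counts (no double-counting of plateaus). Interpolating the exact
crossing time would shift times by less than the integration step and is
not done. Times are binned into 1 ms half-open intervals `[k, k+1)` ms with
counts clipped to one — the binary point-process convention.

The single compartment reproduces the *statistical* phenomenology the
pipeline needs (conductance-dependent rates, refractoriness, trial
variability); it does not reproduce any particular cell type's dendritic
filtering or channel kinetics. Spike trains from morphologically detailed
simulators can be imported through the spike-time text format and fitted
identically.

## 3. The point-process GLM

Per condition, the spike probability in bin `j` is
`logit(p_j) = [k⊗s]_j + b + [h⊗y]_j`. Both filters are expanded in
raised-cosine bases: bumps equally spaced on the log-stretched axis
`ψ(t) = log(t + stretch)` with half-overlap, unit peak, 10 bases per
filter over a 100 ms span (defaults; stimulus-encoding effects typically
localize at 5–30 ms and history effects at 20–60 ms, well inside this
span). The default stretch of 1 ms gives first/last basis
widths of roughly 1.3 and 36 ms. The 40 kHz stimulus is averaged within
each 1 ms bin before convolution.

Two causality conventions are enforced: history covariates start at lag
1 bin (a bin's own spike cannot predict itself — including lag 0 would
make the regression degenerate), and convolution state resets at trial
boundaries. History columns are computed by exact kernel accumulation at
spike positions, so pre-spike entries are exactly zero and causality holds
to the bit, not merely to rounding.

The Bernoulli log-likelihood `ℓ(β) = Σ_j [y_j x_jᵀβ − log(1+exp(x_jᵀβ))]`
is evaluated with the `max(t,0) + log1p(exp(−|t|))` decomposition, stable
for arbitrary logits. Single-condition fits use damped Newton (gradient
∞-norm < 1e−6 or relative change < 1e−9); a coefficient norm above 1e4
raises a perfect-separation error suggesting the joint fit. GLM spike
simulation is sequential per bin — stimulus drive precomputed, history
drive accumulated from the spikes already drawn — vectorized across trials
and seeded.

Note on quasi-separation: a hard (deterministic) refractory period in the
data drives early history coefficients toward −∞ at λ = 0, because no
spike ever follows within those lags. This is the correct unpenalized MLE
limit, not a solver defect; the joint solver stops such drifts at |β| = 30
(per-bin logits beyond ±30 are numerically saturated) and flags the fit.

## 4. Joint estimation with trend filtering

The joint objective adds the weighted fused-ℓ1 penalty
`λ Σ_i w_i‖β(g_i) − β(g_{i+1})‖₁`, `w_i = 1/(g_{i+1}−g_i)`, to the summed
negative log-likelihoods. Conditions with zero spikes cannot be fitted and
are dropped with a warning before the grid is formed.

**Solver.** The problem is solved by proximal Newton. Each outer iteration
replaces every condition's likelihood by its exact second-order expansion
and solves the resulting fused-lasso quadratic program exactly through its
dual: with block-diagonal Hessian `H` and linearization point `c`, the
dual is `min_η ½(c − Dᵀη)ᵀH⁻¹(c − Dᵀη)` subject to `|η_iq| ≤ λ·w_i`, a
small box-constrained QP over the (B−1)×P difference multipliers, solved
by L-BFGS-B with Hessian applications through explicit block inverses.
Complementary slackness identifies exactly fused pairs (interior dual
coordinates), and a tolerance-level snap makes fused successive
coefficients bit-identical. An Armijo backtracking line search on the true
penalized objective guards each step; convergence is declared when the
quadratic model's decrease falls below 1e−12·(1+|objective|). Two to nine
outer iterations (a handful of data passes) suffice in practice, and the
λ = 0 / λ ≥ λ_max limits match independent per-condition and pooled
logistic MLEs to ~1e−6, verified in the tests against both an independent
logistic solver and a generic convex solver via an epigraph
reformulation. Operator-splitting (ADMM-style) variants of this solver
were evaluated and converge to the same solutions, but need orders of
magnitude more data passes for the same accuracy on realistic problem
sizes; the proximal Newton form is the package's choice.

**λ_max.** At the pooled MLE β̄, stationarity of the fused problem requires
cut-point subgradients `t_j = −Σ_{i≤j} ∇ℓ_i(β̄)` with `|t_j[q]| ≤ λ·w_j`,
so `λ_max = max_{j,q} |Σ_{i≤j} ∂(−ℓ_i)/∂β_q(β̄)| / w_j`. The tests confirm
this against a bisection search for the smallest collapsing penalty
(agreement within 1%) and its homogeneity in the weights.

**Path and selection.** λ runs over `{λ_max·e⁻ʲ, j = 0..21} ∪ {0}` (23
values), fitted largest-first with primal and dual warm starts; 70% of
trials train, 30% validate, with one seeded split shared by all
conditions. λ* is the largest λ whose summed validation log-likelihood is
within ζ of the grid maximum. ζ defaults to log 1.0005 interpreted as a
bound on the *total* validation likelihood ratio; a per-observation
scaling is available (`select_lambda(..., per_observation=True)`). The
total interpretation is deliberately strict: when the validation curve
rises monotonically all the way to λ = 0 — as it does for the bundled
neuron at small demo sizes, where deterministic refractoriness keeps
improving the fit as history coefficients grow — the rule honestly selects
λ = 0. In the GLM-based verification setting (section 6) the rule selects
interior λ* values and minimizes the recovery error there, the behavior
the method is designed for.

## 5. Sum of slopes and the channel screen

`SS_q = Σ_j w_j |β(g_j)_q − β(g_{j+1})_q|` is evaluated exactly from the
fitted trajectories. Units: the coefficients are logits per 1 ms bin, so
SS is reported in logit spikes/bin per unit scaling factor (a per-second
convention would multiply by 1000; axes are labeled per-bin to avoid the
ambiguity). Useful identities, all tested: SS is zero for fused
trajectories, invariant to adding a constant to a trajectory, and
absolutely homogeneous under coefficient scaling.

The screen table reports SS at each channel's own λ* (the λ = 0 column is
available for comparison), partitioned into stimulus/baseline/history
blocks with basis peak-lag labels, and ranks channels by total SS. No
cross-channel normalization is applied; a max-normalized view is for
plotting only.

## 6. Verification by planted recovery

The recovery harness builds a known coefficient sequence over the grid:
selected coefficients follow monotone linear (or sigmoid) trajectories of
specified amplitude, all others are exactly constant (planted nulls, true
SS = 0). Spike trains are simulated from these GLMs, the full pipeline
(split, path, selection, SS) is re-run, and the SS error against truth is
recorded at every λ, over repeats with a seeded seed-sequence; a repeat
with an all-silent condition is excluded with a log entry. The error
metric is mean absolute deviation per coefficient (RMSE available).

Scaled-down default protocol: the 10-point default grid, 30 trials of
1000 bins, 10 repeats. At these sizes the experiment reproduces the
expected qualitative behavior, and the acceptance checks assert it: SS
error at λ* far below the error at λ = 0, the mean-error minimum at (or
immediately below) λ*, and error growing again for λ > λ*.

What passing these tests shows: the estimator recovers conductance-driven
trends and suppresses noise *when the data are generated by the model
class itself* and trajectories are piecewise-smooth. What they do not
show: robustness to model misspecification (non-Bernoulli variability,
nonstationarity, unmodeled adaptation), to recording artifacts, or to
grids too coarse for the underlying biophysical nonlinearity — all of
which real experiments add.

## 7. Determinism and numerical conventions

All randomness flows from explicit seeds through `numpy` PCG64 generators
(seed sequences for per-repeat streams); the full pipeline writes a
resolved-config snapshot and is byte-reproducible for a fixed config. Ties
in the λ-selection cannot occur (the argmax is always feasible); the
degenerate λ_max = 0 case (identical conditions) yields an all-zero grid
and a trivially fused path. Half-open binning, first-sample spike timing,
lag-1 history onset and causal ramp-in are the conventions most likely to
matter when comparing against other implementations.
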