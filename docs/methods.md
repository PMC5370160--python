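# Methods

## Model

A neuron's intracellular calcium concentration `c` is modeled as a stable
autoregressive process of order `p` driven by the spike count `s_t ≥ 0` in
each imaging frame,

    c_t = Σ_{i=1..p} γ_i c_{t−i} + s_t ,

and the observed fluorescence is `y_t = c_t + b + ε_t` with i.i.d. Gaussian
noise `ε_t ~ N(0, σ²)` and constant baseline `b`. The fluorescence scale is
fixed at 1 (a unit spike causes a unit calcium jump), so `ŝ_t = 1`
corresponds to one action potential. Equivalently `c = s * h`, where `h` is
the impulse response of the AR process (`h_{1+t} = γ^t` for p = 1, the
(1,1) entry of the t-th power of the companion matrix in general), and
`s = G c` with `G` the banded lower-triangular deconvolution operator
carrying 1 on the diagonal and `−γ_i` on the i-th subdiagonal.

p = 1 describes indicators whose rise is fast relative to the frame
interval; p = 2 adds a finite rise time (e.g. GCaMP6s at high frame rates).

Deconvolution is the non-negative LASSO

    min_{c} ½‖c − y‖² + λ‖G c‖₁   s.t.  G c ≥ 0 ,                (soft)

or, avoiding the hand-picked λ, the noise-constrained problem

    min ‖s‖₁  s.t.  s = G c ≥ 0,  ‖c − y‖² ≤ σ²T ,        (constrained)

in which λ appears as the dual variable of the residual constraint. Two
non-convex variants trade the ℓ1 bias for sparsity: a minimum spike size
`s_min` (hard shrinkage), and an ℓ0 mode that minimizes the number of
spikes subject to the noise constraint.

## Solvers

**AR(1) online active set.** The constraint `c_{t+1} ≥ γ c_t` generalizes
the monotonicity constraint of isotonic regression; the solver generalizes
the pool-adjacent-violators algorithm. Frames between inferred spikes form
pools `(v, w, t, l)` — fitted first value, weight `w = Σ_τ γ^{2τ}`, start,
length — and a single forward sweep merges adjacent pools whenever
`v_{i+1} < γ^{l_i} v_i` (plus `s_min` in hard mode), each merge in O(1).
The sweep returns the exact global optimum of the soft problem in O(T) and
can be warm-started from an existing partition, in which case an iteration
costs O(z) for z pools. Two boundary details:

- The final frame's ℓ1 shift is λ (not λ(1−γ)) because the last column of
  `G` sums to 1.
- The constraint set implies `c ≥ 0` (first row of `G` gives `s_1 = c_1`).
  When the leading pool fits negative, it is frozen at zero with infinite
  weight, which makes the active-set solution exact rather than relying on
  a posteriori clipping; ties in the merge condition do not merge.
  Construction still clips any remaining negative pool value at zero
  (possible only transiently during tuning).

**Hyperparameter loop.** Starting from λ = 0, each iteration takes an
analytic step in λ (or in the total shift φ = b + λ(1−γ) when the baseline
is unknown, with `b̂ = ⟨y − ĉ⟩` recovered after each step): holding the
pool structure and the zero-clipping pattern fixed, the residual sum of
squares is a quadratic in the step, solved exactly for RSS = σ²T. Pools
already clipped at zero get zero sensitivity — without this the tuned
solution's true RSS stalls below the target and the constraint is never
tight. A warm-started sweep then re-enforces the decay constraints. The λ
sequence is non-decreasing in practice; convergence is declared when a
step triggers no merges and the relative RSS gap is below 1e−9 (tighter
than the 1e−4 contract), capped at 20 iterations.

**γ step.** The AR coefficient is optimized by coordinate descent on the
RSS over the current pool structure with the pool *values held at their
current fits* (bounded scalar search on [0, 1), tolerance 1e−6; jointly
with `b` by L-BFGS-B when the baseline is also optimized). Holding the
values fixed is an exact block-coordinate step of the joint objective in
(values, γ); the subsequent warm re-solve refits values and re-merges.
Re-fitting the values inside the γ search (per the closed-form pool value
at each candidate γ) was tested and rejected: the pool boundaries created
under a wrong γ select segments whose local decay matches that wrong γ, so
the refit landscape's minimum tracks the current value and the iteration
collapses downward instead of recovering the truth. With values held
fixed, initialization at 0.9 (or at the autocovariance estimate ≈ 0.97)
converges to ≈ 0.955 against a ground truth of 0.95. For speed the RSS may
be restricted to the pools with largest `max(0, v)·l` (large isolated
events); in that restricted mode `b` is kept at the global `⟨y − ĉ⟩`
estimate, since a handful of segments cannot identify a baseline.

**Decimation.** Hyperparameters can be tuned on k-fold block-averaged data
(k = 10 by default in the pipeline; p = 1 only, as the rescaling rule
γ → γ^k is specific to a single coefficient): σ scales by 1/√k and the
inverse transform rescales λ so the shrinkage μ = λ(1−γ) is invariant; the
incomplete tail block is dropped. The full-length solve is warm-started
with singleton pools on frames within `[k(t_i−1), k(t_i+1.5)]` of each
upsampled decimated spike time and long pools elsewhere.

**ℓ0 variant.** Starting from the spikeless single-pool fit, spikes are
added one at a time at the largest values of the ℓ1 noise-constrained
solution (ties to earlier frames; frames already holding a spike skipped;
neighbors not excluded), splitting the containing pool with closed-form
refits, until RSS ≤ σ²T. The smallest surviving spike is reported as the
achieved `s_min`.

**Limited-lag online mode.** The streaming estimator processes samples with
the full active-set update but commits the estimate for frame `t − τ` once
sample `t` is consumed (τ frames of lookahead); committed values never
change, while internal pools may keep merging across the boundary.
τ ≥ T reproduces the batch solution exactly (including the final-frame
shift correction applied at the end of the stream). Truncating the
backtracking itself was tested and is uniformly worse. In hard mode the
lag-dependent threshold `s_min(τ) = 0.5 + 0.175 e^{−τ}` is used.

**AR(p > 1) greedy solver.** Pools track their first value and last p−1
values (the boundary condition for the successor). The merge condition
compares the next pool's value with the dynamics extrapolated one step past
the current pool; updates hold the predecessor's tail fixed, making the
method greedy. A zero-floor freeze analogous to the AR(1) case pins a
negative leading pool at zero. The analytic λ step exploits that the
solution is linear in λ for fixed structure: RSS(λ) is recovered as an
exact quadratic from three evaluations of the refit chain (the clipped
construction makes it piecewise quadratic; the warm-started outer
iteration absorbs pattern changes, converging in 2–3 passes). A local
jitter pass moves each spike within ±1 frame, keeping the placement that
minimizes the RSS of the two flanking pools; the objective never
increases.

**ONNLS.** For arbitrary kernels the exact solution is found in the spike
domain: `min ½‖K s − (y − λK^{-T}1)‖², s ≥ 0`, with `K` the Toeplitz
convolution matrix. A warm-started Lawson–Hanson active-set solve is
applied on windows of 200 frames stepped by 100 (configurable down to
1-frame steps for streaming), with each block carrying the full kernel
column of its spikes and the activity outside the block peeled off its
data at full kernel length. One sweep is the online algorithm; sweeps
repeat (block coordinate descent on the convex objective) until
stationary, which reproduces batch NNLS to ~1e−13. Noise-constrained
tuning solves the exact RSS quadratic on the current active set and
re-runs warm-started; seeding with the greedy dual solution's λ and spikes
converges in 1–2 passes. Support restriction is implemented by masking the
entering set; the restriction radius around previously found spikes is ±1
frame, matching the ~1-bin spike-timing uncertainty at benchmark SNR — a
±2 window lets the least-squares fit split a spike's mass across distant
neighbors, measurably diluting spike-train correlation.

## Synthetic data

The generator reproduces the benchmark protocols: Poisson spike counts per
frame (homogeneous, or sinusoidal-rate for the hyperparameter study),
AR filtering, Gaussian noise, optional constant baseline. Standard
conditions are 100 s at 30 Hz (T = 3000), γ = 0.95 / σ = 0.3 for AR(1) and
γ = (1.7, −0.712) / σ = 1 for AR(2). Parameters the protocols leave open
were fixed once: mean firing rate 0.5 Hz (typical of this literature and
of the benchmark figures' spike density); sinusoidal rate mean 0.5 Hz,
amplitude 0.45 Hz, period 25 s; baseline b = 1 for the baseline-recovery
study. Spike-train accuracy is the Pearson correlation between the
deconvolved trace and the binned truth, optionally after smoothing both
with a 1-bin Gaussian.

What the generator does not emulate: indicator nonlinearity/saturation,
signal-dependent (photon) noise, baseline drift, and movement or demixing
artifacts of real recordings. Passing benchmarks therefore demonstrates
correctness of the optimization and self-tuning machinery under the
model's assumptions, not robustness to un-modeled physiology.

## Problem sizes and numerical choices

The benchmark harness uses 20 traces of T = 3000 per condition, matching
the published protocol; the long-recording check uses 5 traces of
T = 300,000 (per-trace scatter there is ~0.003, so a small repeat count
suffices). Merge statistics are collected over a grid of γ ∈ [0.9, 0.99]
and λ ∈ [0, 5] on 5 traces (300,000 observation steps). Noise σ is
estimated from the Welch periodogram over normalized frequencies
[0.25, 0.5] of the sampling rate, averaged in the log domain
(`exp(mean(log PSD))`, the field's standard convention; arithmetic mean
and median are available) and converted via `σ = √(PSD·fs/2)`. The
autocovariance initializer solves the lag recursions on lags p+1..p+5 by
least squares and clamps to stability (falling back to γ = 0.9 for p = 1
when degenerate); it is documented as a crude initializer that
overestimates γ under correlated spiking. Kernels are truncated at
|h| < 1e−9 or five decay times, whichever is first; ONNLS builds its
window-length kernel explicitly. Benchmark protocols pass the stated
simulation parameters (γ, σ) to the solvers as known inputs; the
hyperparameter-optimization scenario estimates everything from data.

## Known limitations

- The greedy AR(2) solution carries a ~1% objective gap to the exact
  primal solution (denoised traces agree to <1% RMS of the signal range;
  pointwise maxima at isolated one-frame spike-timing differences); the
  ONNLS refinement closes it.
- The s_min/ℓ0 modes are non-convex; solutions are good local minima, not
  certified global ones.
- The correlation differences among ℓ1/ℓ0/s_min variants on the AR(1)
  benchmark are about one standard error at 20 traces and their ordering
  can depend on the realization.
- Estimating hyperparameters on a short initial batch assumes stationary
  γ, σ and b over the recording.
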