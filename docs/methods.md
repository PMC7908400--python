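# Methods

This note documents the models implemented in `decompcast`, the numerical
choices behind them, what the synthetic generator does and does not
emulate, and the limitations a user should know before trusting a green
test suite.

## Variational mode decomposition

`vmd_decompose` solves the standard constrained variational problem: find
modes `u_k` and center frequencies `ω_k` minimizing the summed bandwidth of
the frequency-shifted analytic signals subject to `Σ u_k = f`, by ADMM in
the frequency domain. Per iteration each mode is updated by a Wiener
filter of the residual spectrum,

    û_k(ω) ← ( f̂(ω) − Σ_{j≠k} û_j(ω) + λ̂(ω)/2 ) / ( 1 + 2α (ω − ω_k)² ),

each center frequency by the power-weighted mean frequency of its mode, and
the dual variable λ ascends on the reconstruction gap (disabled at the
default `tau = 0`, which is the robust choice for noisy data).

Numerical choices:

- **Boundary handling.** The signal is mirror-extended by half its length
  on each side and cropped after decomposition; this suppresses edge
  artifacts and is fully deterministic.
- **Spectrum convention.** Updates operate on the one-sided spectrum; modes
  are reconstructed by Hermitian completion. The DC bin is its own
  conjugate pair and is *not* doubled (doing so corrupts the mode means).
- **Defaults.** `K = 3`, `alpha = 2000`, `tol = 1e−7`, `max_iter = 500`,
  evenly spaced initial center frequencies. `K = 3` feeds the three-band
  regrouping directly; for `K > 3`, `restructure_modes` partitions the
  frequency-sorted modes into contiguous near-equal bands (remainder to the
  low bands) and sums within bands.
- The residual is defined as input minus mode sum, so additive
  reconstruction is exact to round-off at every stage by construction.
- On a pure two-tone test signal the per-mode bandwidth is below one FFT
  bin, so bandwidth-versus-`alpha` behavior is only measurable after adding
  broadband noise; the tests do exactly that.

## The four learners

All four share one contract: train on a `SlidingWindowDataset` (4-lag
windows of one scaled component, one-step-ahead target), predict one value
per input row, fully seeded.

**BPNN.** One sigmoid hidden layer (9 units), linear output, incremental
(per-sample) gradient descent on the half-squared pattern error with
momentum: `Δw(t) = η·∂E/∂w + α·Δw(t−1)`, `w(t) = w(t−1) − Δw(t)`, with
`η = 0.01`, `α = 0.9`, at most 1000 epochs, goal MSE `4e−5` on scaled
targets. Two choices matter and were validated empirically:

- *Incremental, not batch.* Batch descent on the mean squared error at
  `η = 0.01` is an order of magnitude too slow to reach the `4e−5` goal
  within 1000 epochs even on a noiseless linear target; per-sample updates
  (the classic formulation of this learning rule) reach it in tens of
  epochs.
- *Seeded shuffling.* With patterns presented in chronological order, a
  slowly trending component makes the weights chase the drifting target
  within each epoch and training stalls (observed MSE plateau ≈ 0.03);
  reshuffling the presentation order each epoch from a seed-derived
  generator removes the effect while keeping runs bit-reproducible.

**ANFIS.** Five-layer Takagi–Sugeno system: Gaussian premises, product
t-norm firing, normalization, first-order linear consequents, weighted sum.
The grid variant uses 2 membership functions per input (16 rules for 4
inputs), centers at the ends of the scaled input range, spread 0.5.
Hybrid training solves the consequents exactly by `lstsq` on the
normalized-firing design matrix each epoch (ridge `1e−8` fallback if
rank-deficient), then takes one gradient step on premise centers and
spreads (spreads floored at `1e−4` to stay positive).

**ANFIS-FCM.** Fuzzy c-means (fuzziness `m = 2`) on the input rows seeds
one rule per cluster (default `c = 9`, mirroring the BPNN hidden-layer
width, since no canonical value exists); each rule's premise is centered at
the cluster center with spread `0.15 ×` the per-input data range, then the
same hybrid training runs. FCM itself follows the alternating membership /
center updates; a point coincident with a center receives crisp membership,
and the cost trace is non-increasing by alternating minimization.

**GMDH.** Layered polynomial network: every unordered pair of current
inputs spawns a candidate neuron `y = a₀ + a₁u + a₂v + a₃u² + a₄v² +
a₅uv`, fitted by least squares on the first 70 % of the training rows and
scored by RMSE on the held-out last 30 % (the external criterion; the split
is chronological so the criterion is a genuine forecast score). The best
`n_input` candidates survive per layer; growth stops when a layer's best
criterion fails to improve, so the returned criterion never deteriorates.

**Rolling forecasts** always feed the most recent *observed* values into
the lag window — predictions are never recycled — matching operational
one-day-ahead forecasting.

## Weight optimization (IWOA)

The whale optimization algorithm runs 30 agents for 500 iterations in the
`[−2, 2]^4` box: per agent and iteration, encircling
(`X ← X* − A·|C·X* − X|`), random search (same form around a random agent
when `|A| ≥ 1`), or logarithmic-spiral approach
(`X ← |X* − X|·e^{bl}·cos 2πl + X*`) chosen by a fair coin; `a` decays
linearly 2 → 0. Positions are clamped to the box.

The chaotic local search maps a position into unit coordinates, applies one
logistic-map step (`μ = 4`, the chaotic regime; coordinates landing exactly
on the map's fixed or absorbing points {0, ¼, ½, ¾, 1} are nudged by
`1e−6`), maps back, and accepts only strict improvements.

- **CLS scope (a deliberate design choice).** By default the chaotic probe
  starts from the best solution only (`cls_mode="best"`). Applying it to
  the whole population each iteration (`cls_mode="population"`, also
  implemented) was measured to *hurt* global convergence on 5-D Rastrigin
  restricted to the weight box (median over 20 seeds: 2.49 versus 0.0 for
  plain WOA): accepted long-range chaotic jumps disrupt the swarm's
  late-stage collapse onto the optimum. The best-only probe preserves the
  intended "local search close to the best solution" semantics and never
  degrades the incumbent.
- **Warm start.** `optimize_vm_weights` seeds the population with the four
  selector vectors (1 in one coordinate). Combined with elitism and greedy
  CLS this guarantees — not merely makes likely — that the fitted
  combination's RMSE on the fitting segment is ≤ every single member's.

## Ensemble semantics and the split

Weights are fitted per component (including the residual, treated as a
fourth weighted component) on a weight-optimization segment that follows
the training segment and precedes the test segment; reported metrics use
only the test segment. The shipped default split of a 763-point series is
572 / 95 / 96: ~75 % training, with the remaining 191 points divided
near-evenly so weight fitting and testing never share data. Weights are
boxed to [−2, 2] but *not* constrained to sum to 1; negative and super-unit
weights let the combination cancel correlated member errors.

One property deserves honesty: *the combined forecast is guaranteed to beat
every member only on the segment the weights were fitted on.* On the test
segment the claim holds when the series is stationary enough for the fitted
weights to transfer — and it can fail when a single member dominates every
component, because a one-model forecast benefits from cross-component error
cancellation that per-component weighting forgoes. The test suite therefore
checks out-of-sample dominance on a fixture whose components genuinely have
different best combinations (known true weights per component, small
noise), and checks the fitted-segment guarantee everywhere else.

## Synthetic data

`generate_series` emulates the structure the paradigm assumes: 763 daily
points, mean level 60 (a typical polluted-region daily PM2.5 concentration,
µg/m³), a slow ramp of amplitude 10, three sinusoids at {0.004, 0.03, 0.12}
cycles/sample (separated by more than an octave so narrowband decomposition
is well-posed) with amplitudes 18/9/5, and AR(1) noise (coefficient 0.6,
marginal sd 2) so that even the irregular part is partly lag-forecastable,
as real concentration noise is. The offset keeps the series strictly
positive, which MAPE requires.

What it does **not** emulate: missing days, detection limits, regime
changes, heavy-tailed pollution episodes, or calendar effects. A green
end-to-end test therefore establishes that the machinery is correct and
internally consistent — not that the method attains any particular accuracy
on real monitoring data.

`generate_weight_fixture` produces four smooth, well-conditioned
pseudo-member columns (Gram condition number checked < 1e6 at generation)
and an actual series that is a known boxed weighted sum plus optional
noise, giving the weight optimizer a closed-form least-squares oracle.

## Known limitations

- The whole series (including the test tail) is decomposed at once before
  splitting, mirroring the usual offline evaluation protocol of
  decomposition-ensemble studies; a strictly operational system would need
  rolling re-decomposition, which is out of scope.
- MAPE is undefined on series that touch zero; the metrics module rejects
  such inputs rather than silently clipping.
- GMDH's ridge fallback triggers on constant targets or duplicated neuron
  outputs; a warning is emitted and results remain finite.
- The optimizer treats the objective as a black box; no gradient or
  normal-equations shortcut is used inside `optimize_vm_weights`, so the
  closed-form optimum serves as an independent oracle in the tests.
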