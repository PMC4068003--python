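# Methods

This note documents the models, estimator conventions, default parameters,
and numerical choices behind `melange`, plus what the synthetic generators
do and do not emulate.

## Models

### Lattice model (sandpile-type)

`L x L` (default 50×50) non-leaky integrate-and-fire neurons on a square
lattice with open boundaries.  Time advances in synchronous 1 ms steps (one
effective synaptic delay); all units above threshold in a step spike
together, and charge arriving within a step accumulates before the next
threshold test.  A spike moves 4 units of potential out of the spiker; each
existing nearest neighbour receives `alpha`, so the bulk dissipates
`4(1 - alpha)` per spike and edge/corner spikes lose a further
`1-2 x alpha` over the boundary.  At `alpha = 1` the bulk is conservative
and the model is the classic sandpile; `alpha < 1` makes it sub-critical.
The threshold `Theta = 0` is a pure offset and does not affect dynamics.

**Drive.** External input *sets a unit above threshold*: `V <- Theta + eps`
(`eps = 1e-6`), so one forced spike results.  A unit already above threshold
is left unchanged (its spike counts as propagated; at the drive rates used
the case is negligible).  In STS mode input is applied to one uniformly
random unit only when the network is quiescent; in driven mode every unit
receives input independently with probability `h * 1 ms` per step, and
spikes carry an origin flag (input vs propagated).

An implication worth stating explicitly: because a drive event injects at
most 4 charge units (the potential always exceeds `Theta - 4`), charge
balance bounds the number of spikes sustained per input spike by
`4 / (4(1 - alpha))` in the bulk — about 100 at `alpha = 0.99`, and about
160–180 even at `alpha = 1`, where only the boundary dissipates.  The
measured spikes-per-input ratio at `alpha = 0.99`, `r = 5` Hz is ~23; claims
of substantially larger amplification (thousands) are outside what this
model class can produce under any drive convention.

**Initialization and transients.** Potentials start uniform on
`[Theta - 4, Theta)`.  Driven runs discard 10^5 steps; STS runs discard
10^4 avalanches (defaults) so statistics are taken in the self-organized
stationary state.

### Stochastic branching model

2500 units; an active unit draws `k = 4` targets uniformly with replacement
(self-targets and duplicates allowed — the simplest reading of random
re-assignment, and `k` barely matters) and activates each with probability
`p = alpha / k`; an activation is additionally lost with probability
`p_diss = 0.001` (projection "outside the grid").  A unit activated by
several sources is active once.  The model is critical at `alpha = 1` in the
infinite-size limit; `p_diss` and the finite population impose an effective
cutoff near `1/p_diss = 1000`.  The simulated size distribution matches the
exact total-progeny law of a branching process with Binomial(4, p(1-p_diss))
offspring (Dwass formula) — this closed form is the oracle used in tests.

### STS rasters

Under a separation of time scales, inter-avalanche pauses are arbitrarily
long; for binned statistics they only need to dominate every bin size and
avalanche duration, so `run_sts_raster` inserts a fixed 10 s gap between
cascades (bins go up to 0.5 s; cascades last well under 1 s).  With this
convention `sigma*` decays to zero at large bin sizes, as it must with STS,
while driven rasters give `sigma* -> 1`.

## Measures

* **Binning** pools all units into half-open bins `[j*bs, (j+1)*bs)` from
  t = 0 (no phase averaging; phase sensitivity is exercised in tests); the
  trailing partial bin is dropped.
* **Avalanches** are maximal runs of non-empty bins; size = spikes in the
  run.  Runs touching the record boundary are kept but flagged; at the run
  lengths used here including or excluding them changes statistics by <1%.
* **`f(s=1, bs)`** is normalized to 1 at `bs = 1 <IEI>`, with
  `<IEI> = 1/R` the mean inter-event interval of the pooled population.
  For Poisson activity it decays as `exp(-3 R bs)` (a spike in a bin
  flanked by two empty bins); for driven-critical activity it is a power
  law in `bs` regardless of the sampling geometry.
* **`sigma*`** averages `n_i / n_{i-1}` over bins with `n_{i-1} > 0`;
  an empty successor contributes 0.  For independent Poisson bins the
  closed form is `lam * E[1/n | n > 0]`, `n ~ Poisson(lam)` (series-summed
  in the tests).
* **Logarithmic binning** uses integer-aligned geometric edges (fractional
  bins at small integer sizes would distort densities); heights are
  per-unit-size densities at the geometric centre of the occupied integers.
  An exact power law survives the transform to better than 0.001 in slope.

## DFA

Order-1 (linear detrending), non-overlapping forward-tiled windows,
trailing partial window discarded, window widths 2^4..2^11 ms; `beta` is the
least-squares slope of `log2 F` vs `log2 w`.  On spectral surrogates of
known Hurst exponent the implementation recovers `beta = H` to ±0.05 across
16–2048 ms windows.  Below 16 ms the 1 ms sampling resolution interferes;
above ~2 s the scaling of the signals in scope breaks down.

## Distribution fitting

Sizes are integers, so all families are fitted as discrete distributions on
`s >= s_min` (default 1), optionally truncated at `s_max`.  Continuous
densities are discretized by their mass on `[s - 1/2, s + 1/2)`; the pure
power law uses the zeta form.  Normalization is analytic where possible
(zeta, geometric, Gaussian CDF) and otherwise a converging sum with an
incomplete-gamma tail beyond 10^7, accurate to ~1e-6 — without the tail
term, heavy-tailed members acquire a spurious likelihood advantage.
Likelihoods are compared per datum on identical support with a Vuong-style
normal approximation.  The untruncated support is the default; truncation
at the system size is available via `s_max`.

Two estimator conventions deserve note:

* The *graphical* exponent (least-squares slope of log-binned densities) is
  provided because exponents of the lattice model are conventionally read
  off plots; ML fitting remains authoritative for family comparison.  The
  lattice exponent is read over `s in [1, 300]`, below the cutoff.
* For the branching model the discrete-ML range is `s in [10, 300]`: the
  exact total-progeny law shows the `s^-3/2` asymptote is accurate only
  above `s ~ 10` (fitting from `s = 1` is biased low by ~0.1), and 300 stays
  below the dissipation cutoff.
* The finite-size cutoff scale is reported as `1/lambda` of the ML
  power-law-with-cutoff fit; a "departure point" reading (where the density
  falls 10× below the fitted power law) is also provided and, for an
  exponential cutoff, sits at `ln(10) ~ 2.3` cutoff scales.

## Drive calibration

`calibrate_drive` bisects on `log h` for a target single-unit rate.  Since
every input spike yields at least one spike, `r(h) >= h`, so `h = r_target`
brackets from above without simulation; the lower bracket is evaluated.
Rates are estimated from 200 s of post-transient activity (counted
in-kernel without storing spikes), tolerance 2% relative.  At `alpha = 0`
the exact identity `r = h` is returned.

## LFP event extraction

Zero-phase (forward–backward) 4th-order Butterworth low-pass at 40 Hz —
zero-phase because binning at millisecond scales is phase sensitive.
Positive lobes are delimited by linearly interpolated zero crossings and
scored by trapezoidal area; the per-channel threshold keeps exactly
`floor(r_target * T)` largest-area lobes (default 1/4 Hz), ties broken by
earliest occurrence, and the event time is the lobe maximum (lobe onset
available via a flag).  Interpolated-area terms are computed in
sample-local coordinates so that identical lobes tie exactly.

## Synthetic generators

All generators are seed-deterministic and carry regeneration metadata.

* `make_poisson_raster`: independent homogeneous Poisson units — the
  `alpha = 0` reference with closed-form avalanche statistics.
* `make_invivo_like_raster`: an explicit caricature of recorded spiking —
  independent avalanches with lognormal sizes (defaults mu = 0.89,
  sigma² = 1.2, population rate 320 Hz within the 37–1560 Hz envelope of
  typical multi-unit recordings, tens of units) placed on a `1 <IEI>` bin
  grid with geometric gaps tuned so the realized rate matches the target.
  It exists to test the statistics path (parameter recovery closes the
  loop); it has no network mechanism, no refractoriness, and no
  rate nonstationarity, so passing tests say nothing about cortex beyond
  the correctness of the measures.  Recovery must bin on the generator's
  own grid (`meta["iei_ms"]`): a bin width off by even 0.5% drifts across
  the construction grid and merges avalanches.
* `make_fractional_noise`: spectral synthesis with `S(f) ~ f^-(2H-1)`, so
  DFA recovers `beta = H` — the DFA calibration input.
* `make_lfp_surrogate`: low-frequency sinusoids with random phases plus
  white noise at 400 Hz — plumbing for the event-extraction path.

## Problem sizes and determinism

Defaults sized for a single CPU: 10^5 avalanches per STS sample, 10^6 ms
per driven cell (5×10^5 ms where only a rate is needed), 3 replicate seeds
per pipeline cell.  Fixed seeds give bit-identical rasters and tables; all
sub-seeds derive from one user seed via `SeedSequence`.

## Known limitations

* No leak, inhibition, heterogeneous weights, or learning; the lattice
  topology is nearest-neighbour only.  These are the classic minimal models,
  chosen because their critical behaviour is well characterized.
* At `alpha = 1`, `h = 0.02` Hz the driven lattice settles at
  `r ~ 3.6` Hz.  The stationary rate equals `h` times the mean cascade per
  input, which is sensitive at the ~10% level to how much charge a drive
  event injects (set-to-threshold injects 2 units on average); published
  descriptions of this operating point quote rates between ~3 and 5 Hz, and
  the set-to-threshold convention used here is the literal reading.
* The subsampled `sigma*` curve of the driven-critical *lattice* peaks at
  the expected bin size (~100 ms) but at ~1.9 rather than ~3; the driven
  critical *branching* model, analysed identically, peaks at ~3.1 at the
  same bin size.  The lattice's population activity is less bursty at the
  100 ms scale even though its DFA exponent (~1.06) shows the expected
  long-range correlations.
* Avalanche *duration* distributions and shape collapse are out of scope,
  as are spike sorting and any claims about specific recorded datasets.
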