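# Methods

`interbrain` measures how entrainment between two people's EEG signals
changes *over time*, rather than collapsing a whole recording to one coupling
number.  It distinguishes concurrent (zero-lag, undirected) from sequential
(lagged, directed) entrainment, and applies both to the amplitude, power and
phase of the signals.  This note documents the estimators, their assumptions,
the defaults that matter, and what the simulation generators do and do not
emulate.

## Data model

The unit of analysis is a dyad of epoched recordings: for each person, an
array of channels × trials × samples time-locked to a shared event (sample
`t0_index` is time zero; user-facing times are seconds, negative = pre-event).
Trials, sampling rate and event onsets must match across the dyad.  Non-finite
samples are rejected at ingestion: artifact repair is explicitly out of scope,
and silently imputing values would corrupt every downstream estimator.

Sliding windows are half-open `[start, end)` intervals in sample space,
left-aligned from sample 0 with a trailing partial window dropped; a window's
time stamp is its centre.  A "0.5 s window with 200 ms overlap" therefore
means step = 0.3 s.

## Time-frequency decomposition

All power and phase series come from convolution with complex Morlet wavelets
(Gaussian-windowed complex exponentials).  The wavelet is normalised so that a
unit-amplitude sinusoid at the centre frequency yields coefficients of
magnitude ≈ 1, making power values interpretable in units of squared signal
amplitude.  Edges are reflection-padded and a per-frequency validity mask
flags everything within 3 Gaussian SDs of each epoch edge; windowed metrics
should exclude masked samples.  Defaults: frequency grid 2–30 Hz in 1 Hz
steps; wavelet width log-spaced from 3 cycles at the lowest to 8 at the
highest analysed frequency.  Analyses that must track fast changes (chirps,
short bursts) use a fixed 3-cycle width instead — the temporal smoothing of a
wide wavelet can smear two bursts 300 ms apart into apparent overlap, which
defeats exactly the temporal-scale distinction this package exists to make.

The decomposition agrees with MNE-Python's Morlet implementation (phase to
< 0.05 rad at non-negligible amplitude; amplitude to a per-frequency
rescaling), which serves as an independent cross-check in the test suite.

Evoked vs induced activity is separated by subtracting the trial-averaged ERP
from every trial before decomposition.  This matters twice: induced power is
what background-oscillation entrainment mechanisms act on, and the
deterministic evoked component is the main source of within-epoch
nonstationarity for the autoregressive fits below.

## Concurrent metrics

* **Power correlations** — Spearman's rho across trials between the two
  persons' single-trial power, at each time-frequency point (rank-based for
  robustness to the heavy-tailed distribution of power).  Zero-variance
  points are reported as missing, never coerced to 0.  With a window scheme,
  power is moving-window averaged first: a deliberate loss of temporal
  precision that lets co-fluctuations offset in time (e.g. an infant's burst
  trailing the adult's by 300 ms) appear as concurrent correlation.
* **ITC** — within one person, the magnitude of the across-trial mean unit
  phasor.
* **Across-trial PLV** — `|1/N Σ_k exp(i(ϕ_{t,k} − ψ_{t,k}))|` per time
  point: resolves transient, event-locked locking at the full sampling rate.
* **Windowed PLV** — the same phasor mean taken over the T samples of a
  window within each trial, then averaged across trials (mean of single-trial
  PLVs, not PLV of pooled phases): detects stable coupling during a window.
  Choose windows of ≥ 3 cycles of the analysed frequency; shorter windows
  bias the estimate upward.
* **Cross-frequency m:n PLV** — locking between oscillations at `fm` and
  `fn` with `m·fn = n·fm` (e.g. infant 6 Hz vs adult 9 Hz, 2:3).  Two
  conventions ship: the default applies coefficients `(n+m)/2m` and
  `(m+n)/2n` to the two phases; `mode="classic"` uses the integer
  coefficients `n·ϕ − m·ψ`.  The default's non-integer coefficients make it
  sensitive to 2π wrapping, so it requires unwrapped phase input; the classic
  mode accepts principal values.  Both reduce to the plain PLV at 1:1.

## Sequential metrics

* **Lagged Spearman correlation** — rho at every integer-sample lag in
  `[−L, +L]`, overlapping segments only; positive lag means x leads y.
* **Granger causality** — `GC_{x→y} = ln(var(e_y|past y) / var(e_y|past y,
  past x))` from nested OLS fits on lag-stacked design matrices, pooling
  trials within a window (lag windows never straddle trial boundaries).
  Negative estimates are numerical noise in nested fits and are clipped to 0
  with a counter.  Model order via AIC/BIC over the bivariate fit
  (`n·ln det Σ + penalty·4p`); the temporal reach of an order is
  `order/srate` — 5 samples span 5 ms at 1000 Hz but 39 ms at 128 Hz, which
  is why `downsample_for_gc` (anti-aliased decimation to 128 Hz) is offered
  before fitting when low-frequency dynamics matter.
* **Spectral GC** — the Geweke decomposition: `A(f) = I − Σ_k A_k
  e^{−i2πfk/fs}`, `H = A⁻¹`, `S = HΣH*`, with the causal part of `S_yy`
  isolated through the partialled innovation variance.  Its band average
  recovers the time-domain value for a stable VAR once the univariate fit has
  converged (order ≥ ~5 for the ARMA structure induced by a driven channel);
  the test suite checks this integral identity to 5%.
* **PDC** — `|Ā_ij(f)|` column-normalised so `Σ_i PDC²_{i←j}(f) = 1`
  exactly.
* **Phase transfer entropy** — the entropy combination
  `H(y_t, y_{t′}) + H(y_{t′}, x_{t′}) − H(y_{t′}) − H(y_t, y_{t′}, x_{t′})`
  with `t′ = t − δ`, on phases binned into equal-width bins over (−π, π].
  The second term is implemented exactly as printed in the source definition
  (both arguments at `t′`); some transfer-entropy formulations use
  `H(y_t, x_{t′})` instead — noted, not silently corrected.  Defaults: δ =
  a quarter cycle of the analysed frequency; bin count by the
  Otnes–Enochson rule `round(exp(0.626 + 0.4·ln(N − δ − 1)))`.  Unlike PLV,
  observations may be pooled over time *and* trials, so PTE works in shorter
  windows.  Estimates are reported raw: the histogram estimator's bias can
  produce small negative values, and clipping them would hide a useful
  diagnostic of undersampling (a counter tracks them).

Every directed metric satisfies: swapping the channels exactly swaps the two
directions, and GC is invariant to positive rescaling of either channel.

## Inference

* **GC F-test** — nested-regression F with (p, n − 2p − 1) degrees of
  freedom.  Two calibration caveats discovered by simulation and worth
  knowing: (i) at the very large pooled n of trial-stacked fits, per-trial
  linear detrending introduces enough serial structure (order 1/window
  length) to inflate the F-test, so detrend only when the data actually
  carry trends; (ii) heteroscedastic innovations (e.g. an event-locked
  variance surge) also miscalibrate it.  The permutation route is immune to
  both.
* **Rayleigh test** — `p ≈ exp(√(1+4n+4(n²−R²)) − (1+2n))` for PLV/ITC, plus
  the closed-form critical value `√(−ln α / n)`.
* **Permutation nulls** — three schemes, all permuting person B only:
  segment order within trials (recommended for event-locked effects; segment
  length = the metric's own window), trial re-pairing, and per-trial circular
  time shifts.  The last is the guard against spurious locking between two
  oscillators that merely share a rhythm: for such pairs the scrambled and
  real PLV distributions coincide.  `p = (1 + #{null ≥ obs})/(n_perm + 1)`,
  never exactly 0; identical seeds give bit-identical nulls.  Default
  n_perm = 1000 (tests use 200 for speed).
* **Corrections** — Bonferroni for small planned sets; max-statistic (pixel)
  and cluster-mass permutation correction for maps.  Clusters use
  4-connectivity in (frequency, time) and the mass statistic (sum of
  suprathreshold values); pointwise thresholds are each pixel's own
  (1 − pixel_alpha) null quantile.  Tests are one-sided upper for the
  non-negative metrics, two-sided for correlations.

## Simulation generators

All generators share: 256 Hz, epoch −0.5…+1.5 s, 100 trials, one channel per
person, theta/alpha-band oscillations, unit oscillation amplitude.  Each
trial draws from its own RNG stream keyed by (seed, trial), so enlarging the
trial count never reshuffles earlier trials.  Scenario-specific parameters
(lags, reset times, noise levels, chirp endpoints, burst offset) are
documented in each generator's signature and recoverable by the matching
metric — that parameter-recovery loop is the package's primary verification
surface.

Two constructions deserve comment because the obvious alternatives are
subtly wrong:

* In both GC scenarios, y is generated from the *observed* past of x
  (`y_t = g(t)·x_{t−lag} + noise`).  If instead y is built from a shared
  clean source while x carries observation noise, y's past genuinely
  back-predicts x (y is the cleaner observer of the shared signal), and at
  the pooled n of trial-stacked fits the y→x F-test correctly rejects — the
  simulation would then not have the "no reverse influence" property it is
  supposed to demonstrate.  With y a function of x's own past plus
  independent noise, GC y→x is structurally zero.
* The gradual-GC scenario anneals the *transmission* noise into y while x is
  a clean AR(2) resonance (pole radius 0.85 at 5 Hz).  Annealing observation
  noise on x instead makes GC x→y fall, not rise, because that noise
  propagates into the bivariate residual.

What the generators do **not** emulate: 1/f background spectra, volume
conduction, artifacts, inter-channel correlation structure, or
non-sinusoidal waveform shape.  Passing tests therefore show that the
estimators recover planted coupling under controlled conditions — not that
real infant–adult EEG will be as clean.  In particular the phase-reset
scenarios plant far stronger locking (post-reset PLV ≈ 1) than real data
shows.

## Numerical choices

Windows are snapped to integer samples by rounding.  Phases are principal
values in (−π, π]; phase bins are equal-width with the upper edge clipped
into the last bin.  AR designs are checked for rank before solving; unstable
fits (companion spectral radius ≥ 1) are flagged and excluded from order
selection.  Spearman ties get average ranks.  CSV output uses 17 significant
digits so written values round-trip exactly.

## Problem sizes

The test suite runs the full pipelines at the study conditions (100 trials,
256 Hz, 2 s epochs), with 10–20 seeds for the ordering/trend assertions,
200 permutations for the cluster tests, and n = 10⁴–2·10⁴ samples for the
closed-form GC oracles; the whole suite completes in well under a minute of
CPU plus a few seconds for the acceptance script.

## Known limitations

Bivariate only — no conditional (multi-channel) GC; no state-space GC; the
F-test caveats above; binned PTE is biased at small sample counts (the bias
is direction-symmetric, which is why the ordering assertions survive it);
the printed cross-frequency mode's wrap sensitivity; EDF is the only
supported binary format.
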