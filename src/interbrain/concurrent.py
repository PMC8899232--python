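"""Concurrent (zero-lag) inter-brain entrainment metrics.

Concurrent coupling is undirected: "when A is high, B is high".  The metrics
here operate on the power or phase of the two persons' time-frequency
decompositions:

* :func:`power_correlation_map` — across-trial Spearman correlation of
  single-trial power at each time-frequency point (optionally after
  moving-window averaging, which trades temporal precision for sensitivity to
  lagged power co-fluctuations).
* :func:`itc` — inter-trial coherence, the across-trial phase consistency of
  a single channel/person.
* :func:`plv_over_trials` — across-trial phase-locking value between the two
  persons, one estimate per time point (sensitive to transient, event-locked
  locking).
* :func:`plv_over_time` — windowed within-trial phase locking (sensitive to
  stable coupling during a window).
* :func:`crossfreq_plv` — m:n phase locking between oscillations at different
  centre frequencies (e.g. infant 6 Hz vs adult 9 Hz).

All phase-consistency outputs lie in [0, 1]; correlations in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .signal_model import WindowScheme, moving_window_average
from .timefreq import AnalyticTFR


@dataclass
class EntrainmentMap:
    """Metric values indexed by (optionally direction,) frequency and time.

    ``values`` has shape (n_freqs, n_times) for undirected metrics and
    (n_directions, n_freqs, n_times) for directed ones, with ``directions``
    naming the leading axis (e.g. ``["a->b", "b->a"]``).  ``time_stamps`` are
    seconds relative to the event onset.  ``meta`` records the parameters that
    produced the map (window scheme, trial count, seeds, ...).
    """

    metric: str
    values: np.ndarray
    time_stamps: np.ndarray
    freqs_hz: np.ndarray
    directions: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_stamps = np.asarray(self.time_stamps, dtype=float)
        self.freqs_hz = np.atleast_1d(np.asarray(self.freqs_hz, dtype=float))
        expected_ndim = 2 if self.directions is None else 3
        if self.values.ndim != expected_ndim:
            raise ValueError(
                f"values must be {expected_ndim}-d for this metric; got {self.values.ndim}-d"
            )

    def select(self, direction: str) -> np.ndarray:
        if self.directions is None:
            raise ValueError(f"metric {self.metric!r} is undirected")
        return self.values[self.directions.index(direction)]


def _phases(x) -> np.ndarray:
    if isinstance(x, AnalyticTFR):
        return np.angle(x.coeffs)
    return np.asarray(x, dtype=float)


def spearman_over_axis0(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho between ``a`` and ``b`` along axis 0, elementwise over the
    remaining axes.  Ties receive average ranks; points where either input has
    zero variance are undefined and returned as NaN (never coerced to 0)."""
    ra = rankdata(a, axis=0)
    rb = rankdata(b, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    num = (ra * rb).sum(axis=0)
    den = np.sqrt((ra**2).sum(axis=0) * (rb**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return rho


def power_correlation_map(
    tfr_a: AnalyticTFR,
    tfr_b: AnalyticTFR,
    scheme: WindowScheme | None = None,
) -> EntrainmentMap:
    """Across-trial Spearman correlation of single-trial power at each
    time-frequency point.

    With a :class:`WindowScheme`, the single-trial power is first averaged in
    sliding windows and the correlation computed per window — the reduced
    temporal scale that reveals power co-fluctuations offset in time.
    """
    if tfr_a.n_trials != tfr_b.n_trials:
        raise ValueError("trial counts differ")
    if tfr_a.n_trials < 5:
        raise ValueError("need at least 5 trials for a meaningful rank correlation")
    pow_a = np.abs(tfr_a.coeffs) ** 2
    pow_b = np.abs(tfr_b.coeffs) ** 2
    if scheme is not None:
        pow_a, times = moving_window_average(pow_a, scheme, tfr_a.t0_index)
        pow_b, _ = moving_window_average(pow_b, scheme, tfr_b.t0_index)
    else:
        times = tfr_a.times
    rho = spearman_over_axis0(pow_a, pow_b)
    return EntrainmentMap(
        metric="power_spearman",
        values=rho,
        time_stamps=times,
        freqs_hz=tfr_a.freqs_hz,
        meta={
            "n_trials": tfr_a.n_trials,
            "windowed": scheme is not None,
            "window_length_s": None if scheme is None else scheme.length_s,
            "window_step_s": None if scheme is None else scheme.step_s,
        },
    )


def itc(tfr_or_phase) -> EntrainmentMap:
    """Inter-trial coherence: magnitude of the across-trial mean unit phasor
    of a single person's phase, per time-frequency point."""
    ph = _phases(tfr_or_phase)
    if ph.shape[0] < 2:
        raise ValueError("ITC requires at least 2 trials")
    vals = np.abs(np.exp(1j * ph).mean(axis=0))
    times = tfr_or_phase.times if isinstance(tfr_or_phase, AnalyticTFR) else np.arange(ph.shape[-1], dtype=float)
    freqs = tfr_or_phase.freqs_hz if isinstance(tfr_or_phase, AnalyticTFR) else np.arange(ph.shape[1], dtype=float)
    return EntrainmentMap(
        metric="itc", values=vals, time_stamps=times, freqs_hz=freqs,
        meta={"n_trials": ph.shape[0]},
    )


def plv_over_trials(phase_a, phase_b) -> EntrainmentMap:
    """Across-trial phase-locking value between two persons.

    At each time-frequency point, ``|1/N sum_k exp(i(phi_{t,k} - psi_{t,k}))|``
    over the N trials: 1 means the phase difference is identical on every
    trial, 0 means no locking.  One estimate per time point, so transient
    event-locked locking is resolved at the full sampling rate.
    """
    pa, pb = _phases(phase_a), _phases(phase_b)
    if pa.shape != pb.shape:
        raise ValueError(f"phase arrays differ in shape: {pa.shape} vs {pb.shape}")
    if pa.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    vals = np.abs(np.exp(1j * (pa - pb)).mean(axis=0))
    times = phase_a.times if isinstance(phase_a, AnalyticTFR) else np.arange(pa.shape[-1], dtype=float)
    freqs = phase_a.freqs_hz if isinstance(phase_a, AnalyticTFR) else np.arange(pa.shape[1], dtype=float)
    return EntrainmentMap(
        metric="plv_trials", values=vals, time_stamps=times, freqs_hz=freqs,
        meta={"n_trials": pa.shape[0]},
    )


def plv_over_time(phase_a, phase_b, scheme: WindowScheme) -> EntrainmentMap:
    """Windowed within-trial phase-locking value.

    Per window and trial, ``|1/T sum_n exp(i(phi_n - psi_n))|`` over the T
    samples inside the window.  The map holds the across-trial mean of the
    per-trial PLVs (the single-trial estimates, not the PLV of pooled
    phases); per-trial values are kept in ``meta["per_trial"]``.
    """
    pa, pb = _phases(phase_a), _phases(phase_b)
    if pa.shape != pb.shape:
        raise ValueError("phase arrays differ in shape")
    if scheme.length_samples < 2:
        raise ValueError("window must contain at least 2 samples")
    phasor = np.exp(1j * (pa - pb))
    per_trial = np.stack(
        [np.abs(phasor[..., s:e].mean(axis=-1)) for s, e in scheme.boundaries], axis=-1
    )  # trials x freqs x windows
    t0 = phase_a.t0_index if isinstance(phase_a, AnalyticTFR) else 0
    times = scheme.centres_s(t0)
    freqs = phase_a.freqs_hz if isinstance(phase_a, AnalyticTFR) else np.arange(pa.shape[1], dtype=float)
    return EntrainmentMap(
        metric="plv_time",
        values=per_trial.mean(axis=0),
        time_stamps=times,
        freqs_hz=freqs,
        meta={
            "n_trials": pa.shape[0],
            "window_length_s": scheme.length_s,
            "window_step_s": scheme.step_s,
            "per_trial": per_trial,
        },
    )


def crossfreq_plv(
    phase_a,
    phase_b,
    m: int,
    n: int,
    fm: float | None = None,
    fn: float | None = None,
    mode: str = "as_printed",
) -> EntrainmentMap:
    """m:n cross-frequency phase-locking value across trials.

    ``phase_a`` is the phase of person A at centre frequency ``fm`` and
    ``phase_b`` that of person B at ``fn``, with positive integers m, n
    satisfying ``m * fn == n * fm`` (so the two oscillations complete m and n
    cycles in the same interval).  Two conventions for the generalised phase
    difference are available:

    * ``mode="as_printed"`` (default):
      ``dphi = ((n + m) / (2 m)) phi - ((m + n) / (2 n)) psi``
    * ``mode="classic"``: ``dphi = n phi - m psi`` (the conventional n:m
      locking index; with ``m * fn == n * fm`` these are the smallest integer
      coefficients that cancel the carrier frequencies)

    Reduces exactly to :func:`plv_over_trials` when m == n == 1.

    .. note::
       The default mode's coefficients are non-integer for m != n, so its
       value changes under 2-pi wrapping of the input phases: feed it
       *unwrapped* phase series.  The classic integer mode is wrap-invariant
       and accepts principal-value phases.
    """
    if not (isinstance(m, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("m and n must be integers")
    if m < 1 or n < 1:
        raise ValueError("m and n must be positive")
    if fm is not None and fn is not None:
        if not np.isclose(m * fn, n * fm, rtol=1e-6):
            raise ValueError(
                f"integer ratio constraint violated: m*fn = {m * fn:g} != n*fm = {n * fm:g}"
            )
    pa, pb = _phases(phase_a), _phases(phase_b)
    if pa.shape != pb.shape:
        raise ValueError("phase arrays differ in shape")
    if mode == "as_printed":
        dphi = ((n + m) / (2.0 * m)) * pa - ((m + n) / (2.0 * n)) * pb
    elif mode == "classic":
        dphi = n * pa - m * pb
    else:
        raise ValueError("mode must be 'as_printed' or 'classic'")
    vals = np.abs(np.exp(1j * dphi).mean(axis=0))
    times = phase_a.times if isinstance(phase_a, AnalyticTFR) else np.arange(pa.shape[-1], dtype=float)
    freqs = phase_a.freqs_hz if isinstance(phase_a, AnalyticTFR) else np.arange(pa.shape[1], dtype=float)
    return EntrainmentMap(
        metric="crossfreq_plv", values=vals, time_stamps=times, freqs_hz=freqs,
        meta={"m": int(m), "n": int(n), "fm": fm, "fn": fn, "mode": mode,
              "n_trials": pa.shape[0]},
    )
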