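"""Seeded simulation generators for dual-EEG entrainment scenarios.

Each generator builds a :class:`~interbrain.signal_model.DyadEpochs` in which
a known coupling has been planted, so that the matching metric can recover
the planted parameter.  They double as test fixtures and as worked examples:

* :func:`sim_event_locked_gc` — an ERP-like transient in x; y is a delayed,
  scaled copy plus noise (lag 100 ms by default).  Detected by lagged
  correlation and time-varying GC (x->y only).
* :func:`sim_phase_reset_concurrent` — two partially phase-locked oscillators
  whose phases are reset to perfect locking 200 ms after the event.  Detected
  by across-trial PLV.
* :func:`sim_phase_reset_sequential` — as above, but y's reset trails x's by
  200 ms and y's post-reset phase is copied from x.  Detected by phase
  transfer entropy.
* :func:`sim_gradual_gc` — y receives a 25-ms-delayed copy of x's stochastic
  narrow-band oscillation through a channel whose noise anneals linearly,
  producing a gradual rise in GC x->y with y->x flat.
* :func:`sim_frequency_drift` — two chirps converging on a common frequency
  (x: 6->9 Hz, y: 12->9 Hz), producing a gradual rise in windowed PLV.
* :func:`sim_lagged_power_bursts` — oscillatory bursts with a shared
  trial-wise amplitude, y's burst peaking 300 ms after x's: invisible to
  per-sample power correlations, visible after moving-window averaging.

Defaults emulate an event-locked dual-EEG epoch: 256 Hz, -0.5..+1.5 s around
the event, 100 trials, theta/alpha-band oscillations.  Each trial draws from
its own deterministic RNG stream (derived from ``(seed, trial)``), so
enlarging ``n_trials`` never reshuffles earlier trials.  Amplitudes are in
arbitrary units of the oscillation amplitude (1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import DyadEpochs, Recording

DEFAULT_SRATE = 256.0
DEFAULT_EPOCH_S = 2.0
DEFAULT_T0_S = 0.5  # epoch runs -0.5 .. +1.5 s around the event
DEFAULT_N_TRIALS = 100


def _trial_rng(seed: int, trial: int, stream: int = 0) -> np.random.Generator:
    """Deterministic per-trial RNG stream."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(trial), int(stream))))


def _dyad(x: np.ndarray, y: np.ndarray, srate: float, t0_index: int) -> DyadEpochs:
    return DyadEpochs(
        a=Recording("a", ["ch"], x[np.newaxis], srate, t0_index),
        b=Recording("b", ["ch"], y[np.newaxis], srate, t0_index),
    )


@dataclass
class SimSpec:
    """Declarative description of a simulation run (used by the CLI).

    ``params`` holds scenario-specific keyword arguments passed through to
    the generator.  A seed is mandatory: every generator is fully
    reproducible from its spec.
    """

    scenario: str
    seed: int
    n_trials: int = DEFAULT_N_TRIALS
    epoch_s: float = DEFAULT_EPOCH_S
    srate: float = DEFAULT_SRATE
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {sorted(SCENARIOS)}"
            )

    def generate(self) -> DyadEpochs:
        return SCENARIOS[self.scenario](
            seed=self.seed, n_trials=self.n_trials, epoch_s=self.epoch_s,
            srate=self.srate, **self.params,
        )


# ---------------------------------------------------------------------------
# Event-locked transient with lagged copy (GC scenario)
# ---------------------------------------------------------------------------

def sim_event_locked_gc(
    seed: int,
    n_trials: int = DEFAULT_N_TRIALS,
    epoch_s: float = DEFAULT_EPOCH_S,
    srate: float = DEFAULT_SRATE,
    t0_s: float = DEFAULT_T0_S,
    lag_s: float = 0.1,
    gain: float = 1.0,
    coupling_width_s: float = 0.2,
    erp_freq_hz: float = 4.0,
    erp_centre_s: float = 0.35,
    erp_width_s: float = 0.12,
    noise_x: float = 0.3,
    noise_y: float = 0.3,
) -> DyadEpochs:
    """ERP-like transient in x; y receives x's past through an event-locked
    coupling.

    x carries a Gaussian-windowed low-frequency (4 Hz) wave centred
    ``erp_centre_s`` after the event, identical across trials, plus
    stationary white noise.  y is generated from the observed past of x
    through a coupling gain that switches on around the (delayed) transient:
    ``y_t = g(t) * x_{t-lag} + noise`` with ``g(t)`` a Gaussian bump of width
    ``coupling_width_s`` peaking ``lag_s`` after the transient centre.
    Because y is a function of x's own observed past plus independent noise,
    GC y->x is structurally zero, while GC x->y shows an event-locked
    increase where the coupling is active.  In the noise-free limit y is a
    delayed, scaled, envelope-weighted copy of x.
    """
    n = int(round(epoch_s * srate))
    t0_index = int(round(t0_s * srate))
    lag = int(round(lag_s * srate))
    if lag < 1:
        raise ValueError("lag must be at least one sample")
    t_ext = (np.arange(-lag, n) - t0_index) / srate  # extended axis for the shift
    t = t_ext[lag:]
    envelope = np.exp(-((t_ext - erp_centre_s) ** 2) / (2 * erp_width_s**2))
    erp = envelope * np.sin(2 * np.pi * erp_freq_hz * (t_ext - erp_centre_s))
    g_t = gain * np.exp(-((t - erp_centre_s - lag_s) ** 2) / (2 * coupling_width_s**2))
    x = np.empty((n_trials, n))
    y = np.empty((n_trials, n))
    for k in range(n_trials):
        rng = _trial_rng(seed, k)
        x_ext = erp + noise_x * rng.standard_normal(n + lag)
        x[k] = x_ext[lag:]
        y[k] = g_t * x_ext[:n] + noise_y * rng.standard_normal(n)
    return _dyad(x, y, srate, t0_index)


# ---------------------------------------------------------------------------
# Phase resets (concurrent and sequential)
# ---------------------------------------------------------------------------

def sim_phase_reset_sequential(
    seed: int,
    n_trials: int = DEFAULT_N_TRIALS,
    epoch_s: float = DEFAULT_EPOCH_S,
    srate: float = DEFAULT_SRATE,
    t0_s: float = DEFAULT_T0_S,
    f0_hz: float = 6.0,
    reset_x_s: float = 0.2,
    offset_s: float = 0.2,
    kappa: float = 3.0,
    reset_jitter_kappa: float = 10.0,
    diffusion_rad: float = 0.02,
    noise: float = 0.2,
) -> DyadEpochs:
    """Two oscillators; x's phase resets at ``reset_x_s`` after the event and
    y's resets ``offset_s`` later, to a phase copied from x.

    Before its reset each channel carries a trial-random phase (y's weakly
    coupled to x's with von Mises concentration ``kappa``) plus a small phase
    random walk (``diffusion_rad`` per sample).  At its reset, x jumps onto a
    common track with a small trial-wise jitter (von Mises,
    ``reset_jitter_kappa``); from ``reset_x_s + offset_s`` onward y's phase is
    x's phase delayed by ``offset_s``, so y entrains to x.  With
    ``offset_s=0`` both reset together and are perfectly locked thereafter
    (the concurrent scenario).
    """
    n = int(round(epoch_s * srate))
    t0_index = int(round(t0_s * srate))
    t = (np.arange(n) - t0_index) / srate
    i_rx = t0_index + int(round(reset_x_s * srate))
    i_ry = t0_index + int(round((reset_x_s + offset_s) * srate))
    if not (0 <= i_rx < n and 0 <= i_ry < n):
        raise ValueError("reset times must lie within the epoch")
    d = i_ry - i_rx
    x = np.empty((n_trials, n))
    y = np.empty((n_trials, n))
    for k in range(n_trials):
        rng = _trial_rng(seed, k)
        phi_x = rng.uniform(-np.pi, np.pi)
        phi_y = phi_x + rng.vonmises(0.0, kappa)
        eps = rng.vonmises(0.0, reset_jitter_kappa)
        walk_x = np.cumsum(diffusion_rad * rng.standard_normal(n))
        walk_y = np.cumsum(diffusion_rad * rng.standard_normal(n))
        theta_x = 2 * np.pi * f0_hz * t + phi_x + walk_x
        # reset: jump onto the common track, keep diffusing afterwards
        post = slice(i_rx, n)
        theta_x[post] = (
            2 * np.pi * f0_hz * (t[post] - t[i_rx]) + eps
            + (walk_x[post] - walk_x[i_rx])
        )
        theta_y = 2 * np.pi * f0_hz * t + phi_y + walk_y
        if i_ry < n:
            # y's phase is x's phase delayed by the reset offset
            theta_y[i_ry:] = theta_x[i_rx : i_rx + (n - i_ry)] if d > 0 else theta_x[i_ry:]
        x[k] = np.cos(theta_x) + noise * rng.standard_normal(n)
        y[k] = np.cos(theta_y) + noise * rng.standard_normal(n)
    return _dyad(x, y, srate, t0_index)


def sim_phase_reset_concurrent(
    seed: int,
    n_trials: int = DEFAULT_N_TRIALS,
    epoch_s: float = DEFAULT_EPOCH_S,
    srate: float = DEFAULT_SRATE,
    t0_s: float = DEFAULT_T0_S,
    f0_hz: float = 6.0,
    reset_time_s: float = 0.2,
    kappa: float = 3.0,
    diffusion_rad: float = 0.02,
    noise: float = 0.2,
) -> DyadEpochs:
    """Partially phase-locked oscillators with a concurrent phase reset
    ``reset_time_s`` after the event, after which they are purely phase
    locked.  Equivalent to :func:`sim_phase_reset_sequential` with zero
    offset."""
    return sim_phase_reset_sequential(
        seed=seed, n_trials=n_trials, epoch_s=epoch_s, srate=srate, t0_s=t0_s,
        f0_hz=f0_hz, reset_x_s=reset_time_s, offset_s=0.0, kappa=kappa,
        diffusion_rad=diffusion_rad, noise=noise,
    )


# ---------------------------------------------------------------------------
# Gradual GC via noise annealing
# ---------------------------------------------------------------------------

def sim_gradual_gc(
    seed: int,
    n_trials: int = DEFAULT_N_TRIALS,
    epoch_s: float = DEFAULT_EPOCH_S,
    srate: float = DEFAULT_SRATE,
    t0_s: float = DEFAULT_T0_S,
    lag_s: float = 0.025,
    gain: float = 1.0,
    osc_freq_hz: float = 5.0,
    osc_r: float = 0.85,
    noise_start: float = 1.2,
    noise_end: float = 0.1,
) -> DyadEpochs:
    """y receives x's past (25 ms lag) through a noisy channel whose noise
    anneals linearly over the epoch.

    x is a stochastic narrow-band oscillation — an AR(2) resonance at
    ``osc_freq_hz`` with pole radius ``osc_r`` (the standard model of a noisy
    neural rhythm) — so it carries fresh innovations every sample while its
    own past is a sufficient statistic for its future.  ``y_t = gain *
    x_{t-lag} + sigma(t) * w`` with sigma falling from ``noise_start`` to
    ``noise_end``: as the channel clears, x's past predicts y ever better
    and GC x->y rises gradually, while y's past carries nothing about x
    beyond x's own past, so GC y->x stays flat at zero.  Setting
    ``noise_end = noise_start`` gives the stationary control with a flat GC
    profile.
    """
    if noise_end > noise_start:
        raise ValueError("noise schedule must be non-increasing")
    n = int(round(epoch_s * srate))
    t0_index = int(round(t0_s * srate))
    lag = int(round(lag_s * srate))
    if lag < 1:
        raise ValueError("lag must be at least one sample")
    sigma = np.linspace(noise_start, noise_end, n)
    phi = 2 * np.pi * osc_freq_hz / srate
    a1, a2 = 2 * osc_r * np.cos(phi), -(osc_r**2)
    burn = int(2 * srate)  # settle the resonance away from the epoch
    x = np.empty((n_trials, n))
    y = np.empty((n_trials, n))
    for k in range(n_trials):
        rng = _trial_rng(seed, k)
        e = rng.standard_normal(n + lag + burn)
        s = np.empty(n + lag + burn)
        s[0], s[1] = e[0], e[1]
        for t in range(2, s.size):
            s[t] = a1 * s[t - 1] + a2 * s[t - 2] + e[t]
        s = s[burn:]
        s = s / s.std()
        x[k] = s[lag:]
        y[k] = gain * s[:n] + sigma * rng.standard_normal(n)
    return _dyad(x, y, srate, t0_index)


# ---------------------------------------------------------------------------
# Converging frequency chirps
# ---------------------------------------------------------------------------

def sim_frequency_drift(
    seed: int,
    n_trials: int = DEFAULT_N_TRIALS,
    epoch_s: float = DEFAULT_EPOCH_S,
    srate: float = DEFAULT_SRATE,
    t0_s: float = DEFAULT_T0_S,
    fx_hz: tuple = (6.0, 9.0),
    fy_hz: tuple = (12.0, 9.0),
    noise: float = 0.3,
) -> DyadEpochs:
    """Linear chirps converging on a common peak frequency.

    x sweeps ``fx_hz[0] -> fx_hz[1]`` and y ``fy_hz[0] -> fy_hz[1]`` over the
    epoch (defaults 6->9 and 12->9 Hz), each trial with an independent random
    initial phase.  As the instantaneous frequencies converge, the phase
    relation between x and y stabilises and windowed PLV rises.
    """
    nyq = srate / 2
    if max(*fx_hz, *fy_hz) >= nyq:
        raise ValueError("chirp endpoints must be below Nyquist")
    n = int(round(epoch_s * srate))
    t0_index = int(round(t0_s * srate))
    tau = np.arange(n) / srate  # time from epoch start
    T = epoch_s

    def chirp_phase(f0, f1):
        return 2 * np.pi * (f0 * tau + (f1 - f0) * tau**2 / (2 * T))

    px = chirp_phase(*fx_hz)
    py = chirp_phase(*fy_hz)
    x = np.empty((n_trials, n))
    y = np.empty((n_trials, n))
    for k in range(n_trials):
        rng = _trial_rng(seed, k)
        x[k] = np.cos(px + rng.uniform(-np.pi, np.pi)) + noise * rng.standard_normal(n)
        y[k] = np.cos(py + rng.uniform(-np.pi, np.pi)) + noise * rng.standard_normal(n)
    return _dyad(x, y, srate, t0_index)


# ---------------------------------------------------------------------------
# Lagged power bursts (temporal-scale caution)
# ---------------------------------------------------------------------------

def sim_lagged_power_bursts(
    seed: int,
    n_trials: int = DEFAULT_N_TRIALS,
    epoch_s: float = DEFAULT_EPOCH_S,
    srate: float = DEFAULT_SRATE,
    t0_s: float = DEFAULT_T0_S,
    carrier_hz: float = 10.0,
    burst_x_s: float = 0.2,
    offset_s: float = 0.3,
    burst_width_s: float = 0.06,
    amp_sd: float = 0.5,
    noise: float = 0.4,
) -> DyadEpochs:
    """Oscillatory bursts with a shared trial-wise amplitude; y's burst peaks
    ``offset_s`` (default 300 ms) after x's.

    The shared lognormal amplitude makes the two persons' single-trial burst
    powers rank-correlated across trials — but never at the same instant, so
    per-sample power correlations see nothing while window-averaged power
    (windows long enough to span both bursts) reveals the coupling.
    """
    if burst_x_s + offset_s + 3 * burst_width_s > epoch_s - t0_s:
        raise ValueError("bursts must fit inside the post-event epoch")
    n = int(round(epoch_s * srate))
    t0_index = int(round(t0_s * srate))
    t = (np.arange(n) - t0_index) / srate
    env_x = np.exp(-((t - burst_x_s) ** 2) / (2 * burst_width_s**2))
    env_y = np.exp(-((t - burst_x_s - offset_s) ** 2) / (2 * burst_width_s**2))
    x = np.empty((n_trials, n))
    y = np.empty((n_trials, n))
    for k in range(n_trials):
        rng = _trial_rng(seed, k)
        amp = rng.lognormal(0.0, amp_sd)  # shared burst amplitude
        x[k] = (
            amp * env_x * np.cos(2 * np.pi * carrier_hz * t + rng.uniform(-np.pi, np.pi))
            + noise * rng.standard_normal(n)
        )
        y[k] = (
            amp * env_y * np.cos(2 * np.pi * carrier_hz * t + rng.uniform(-np.pi, np.pi))
            + noise * rng.standard_normal(n)
        )
    return _dyad(x, y, srate, t0_index)


SCENARIOS = {
    "event_locked_gc": sim_event_locked_gc,
    "phase_reset_concurrent": sim_phase_reset_concurrent,
    "phase_reset_sequential": sim_phase_reset_sequential,
    "gradual_gc": sim_gradual_gc,
    "frequency_drift": sim_frequency_drift,
    "lagged_power_bursts": sim_lagged_power_bursts,
}
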