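"""Core data containers and stationarity preprocessing for epoched dual-EEG.

The containers here are deliberately minimal: a :class:`Recording` holds one
person's epoched voltage data (channels x trials x samples), a
:class:`DyadEpochs` pairs two aligned recordings, and a :class:`WindowScheme`
describes a sliding-window tiling of the epoch.  All entrainment metrics in
:mod:`interbrain.concurrent` and :mod:`interbrain.sequential` consume these.

Preprocessing is limited to what directed-coupling estimation needs for
approximate stationarity: polynomial detrending, subtraction of the
trial-averaged ERP (to separate induced from evoked activity), and
moving-window averaging (temporal-scale reduction).  Artifact handling is out
of scope; non-finite samples are rejected at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateWindowError(ValueError):
    """Raised when a window is too short for the requested operation."""


@dataclass
class Recording:
    """Epoched single-person EEG.

    Parameters
    ----------
    person_id : str
        Label for the person (e.g. ``"infant"``, ``"adult"``).
    channel_labels : list of str
        One label per channel.
    data : ndarray, shape (n_channels, n_trials, n_samples)
        Voltage in microvolts.
    srate : float
        Sampling rate in Hz.
    t0_index : int
        Sample index of the event onset (time zero) within the epoch.
    """

    person_id: str
    channel_labels: list
    data: np.ndarray
    srate: float
    t0_index: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (channels, trials, samples); got shape {self.data.shape}"
            )
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data.shape[0]")
        if not self.srate > 0:
            raise ValueError("srate must be positive")
        if not 0 <= self.t0_index < self.n_samples:
            raise ValueError("t0_index must lie within the epoch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(
                "non-finite samples in data; artifact repair is out of scope, "
                "clean the data before ingestion"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to event onset (negative = pre-event)."""
        return (np.arange(self.n_samples) - self.t0_index) / self.srate


@dataclass
class DyadEpochs:
    """Two aligned epoched recordings (one per person)."""

    a: Recording
    b: Recording

    def __post_init__(self):
        if self.a.srate != self.b.srate:
            raise ValueError("sampling rates differ between persons")
        if self.a.n_samples != self.b.n_samples:
            raise ValueError("epoch lengths differ between persons")
        if self.a.n_trials != self.b.n_trials:
            raise ValueError("trial counts differ between persons")
        if self.a.t0_index != self.b.t0_index:
            raise ValueError("event onsets are not aligned")

    @property
    def srate(self) -> float:
        return self.a.srate

    @property
    def n_trials(self) -> int:
        return self.a.n_trials

    @property
    def n_samples(self) -> int:
        return self.a.n_samples

    @property
    def t0_index(self) -> int:
        return self.a.t0_index

    @property
    def times(self) -> np.ndarray:
        return self.a.times

    def swapped(self) -> "DyadEpochs":
        """Return the dyad with person roles exchanged."""
        return DyadEpochs(a=self.b, b=self.a)


@dataclass
class WindowScheme:
    """Sliding-window tiling of an epoch.

    Windows are half-open ``[start, end)`` intervals in sample space,
    left-aligned from sample 0; a trailing partial window is dropped.  The
    overlap between successive windows is ``length_s - step_s``.
    """

    length_s: float
    step_s: float
    srate: float
    boundaries: list = field(default_factory=list)  # list of (start, end) sample pairs

    def __post_init__(self):
        if not 0 < self.step_s <= self.length_s:
            raise ValueError("require 0 < step_s <= length_s")

    @property
    def n_windows(self) -> int:
        return len(self.boundaries)

    @property
    def length_samples(self) -> int:
        return int(round(self.length_s * self.srate))

    def centres_s(self, t0_index: int = 0) -> np.ndarray:
        """Window centre times in seconds relative to the event onset."""
        c = np.array([(s + e) / 2.0 for s, e in self.boundaries])
        return (c - t0_index) / self.srate


def make_windows(epoch_samples: int, srate: float, length_s: float, step_s: float) -> WindowScheme:
    """Build the maximal set of half-open windows fitting inside the epoch.

    Starts advance by ``step_s`` from sample 0; the last window that would
    overrun the epoch is dropped.
    """
    if length_s <= 0 or step_s <= 0 or srate <= 0:
        raise ValueError("length_s, step_s and srate must be positive")
    length = int(round(length_s * srate))
    step = int(round(step_s * srate))
    if length < 2:
        raise ValueError("window must contain at least 2 samples")
    if step < 1:
        raise ValueError("step must be at least one sample")
    if length > epoch_samples:
        raise ValueError(
            f"window of {length} samples does not fit in epoch of {epoch_samples}"
        )
    boundaries = [(s, s + length) for s in range(0, epoch_samples - length + 1, step)]
    return WindowScheme(length_s=length_s, step_s=step_s, srate=srate, boundaries=boundaries)


def detrend_window(data: np.ndarray, order: int) -> np.ndarray:
    """Remove a least-squares polynomial of the given order along the last axis.

    ``order`` 0 removes the mean, 1 a linear trend, etc.  Applied independently
    per leading index (channel, trial, ...).
    """
    data = np.asarray(data, dtype=float)
    if order not in (0, 1, 2, 3):
        raise ValueError("order must be in {0, 1, 2, 3}")
    n = data.shape[-1]
    if n < order + 2:
        raise DegenerateWindowError(
            f"window of {n} samples too short for order-{order} detrending"
        )
    t = np.arange(n, dtype=float)
    # Vandermonde design; lstsq over the flattened leading axes.
    design = np.vander(t, order + 1, increasing=True)
    flat = data.reshape(-1, n).T  # samples x series
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ coef
    return resid.T.reshape(data.shape)


def subtract_erp(rec: Recording) -> Recording:
    """Subtract the across-trial mean waveform (ERP) from every trial.

    Removes the additive, phase-locked (evoked) component so that what remains
    is the induced/ongoing activity.  Refuses single-trial input, which would
    be zeroed entirely.
    """
    if rec.n_trials < 2:
        raise ValueError("subtract_erp requires at least 2 trials")
    erp = rec.data.mean(axis=1, keepdims=True)
    return Recording(
        person_id=rec.person_id,
        channel_labels=list(rec.channel_labels),
        data=rec.data - erp,
        srate=rec.srate,
        t0_index=rec.t0_index,
    )


def moving_window_average(
    data: np.ndarray, scheme: WindowScheme, t0_index: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Average the last axis over each window of ``scheme``.

    Returns ``(averaged, centre_times_s)`` where ``averaged`` has one value per
    window along the last axis and centre times are in seconds relative to the
    event onset.  This is the temporal-scale reduction used to trade temporal
    precision for sensitivity to lagged concurrent coupling.
    """
    data = np.asarray(data, dtype=float)
    if scheme.n_windows == 0:
        raise ValueError("window scheme is empty")
    if scheme.boundaries[-1][1] > data.shape[-1]:
        raise ValueError("window scheme does not fit the data")
    out = np.stack(
        [data[..., s:e].mean(axis=-1) for s, e in scheme.boundaries], axis=-1
    )
    return out, scheme.centres_s(t0_index)
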