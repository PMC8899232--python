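"""Complex Morlet wavelet time-frequency decomposition.

Every entrainment metric in this package consumes either the power or the
phase of a complex time-frequency representation.  The decomposition is a
convolution with complex Morlet wavelets (a Gaussian-windowed complex
exponential), amplitude-normalised so that a unit-amplitude sinusoid at a
wavelet's centre frequency yields ``|coeff| ~ 1`` in steady state.  Edges are
reflection-padded and a per-frequency validity mask flags the samples within
three Gaussian standard deviations of each epoch edge, where estimates are
contaminated by the padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .signal_model import Recording, subtract_erp


@dataclass
class AnalyticTFR:
    """Complex time-frequency coefficients for one channel.

    Attributes
    ----------
    coeffs : ndarray, complex, shape (n_trials, n_freqs, n_samples)
    freqs_hz : ndarray
        Strictly increasing analysis frequencies.
    srate : float
    cycles : ndarray
        Wavelet width (number of cycles) per frequency.
    valid_mask : ndarray, bool, shape (n_freqs, n_samples)
        False where the estimate overlaps the epoch edge (within 3 SD of the
        wavelet's Gaussian envelope).
    t0_index : int
        Sample index of the event onset.
    """

    coeffs: np.ndarray
    freqs_hz: np.ndarray
    srate: float
    cycles: np.ndarray
    valid_mask: np.ndarray
    t0_index: int = 0

    def __post_init__(self):
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.freqs_hz.ndim != 1 or np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs_hz must be strictly increasing")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite coefficients")

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[2]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.t0_index) / self.srate


def default_cycles(freqs_hz: np.ndarray, lo: float = 3.0, hi: float = 8.0) -> np.ndarray:
    """Log-spaced wavelet widths across the analysed band (3 cycles at the
    lowest frequency up to 8 at the highest; constant if only one frequency)."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if freqs_hz.size == 1:
        return np.array([lo])
    return np.logspace(np.log10(lo), np.log10(hi), freqs_hz.size)


def _morlet_kernel(freq: float, n_cycles: float, srate: float) -> np.ndarray:
    """Complex Morlet wavelet normalised so a unit real sinusoid at ``freq``
    yields unit-magnitude coefficients."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.0 * sigma_t * srate))
    t = np.arange(-half, half + 1) / srate
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = envelope * np.exp(2j * np.pi * freq * t)
    # Response of the convolution to cos(2*pi*f*t) has magnitude sum(envelope)/2.
    return kernel * (2.0 / envelope.sum())


def morlet_decompose(
    rec: Recording,
    freqs_hz,
    cycles=None,
    channel: int = 0,
) -> AnalyticTFR:
    """Decompose one channel of a recording into complex TF coefficients.

    Parameters
    ----------
    rec : Recording
    freqs_hz : array-like
        Analysis frequencies (Hz), strictly increasing, below Nyquist.
    cycles : float, array-like or None
        Wavelet width per frequency; default log-spaced 3..8 across the band.
    channel : int
        Channel index to decompose.
    """
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if np.any(freqs_hz >= rec.srate / 2):
        raise ValueError("analysis frequency at or above Nyquist")
    if np.any(freqs_hz <= 0):
        raise ValueError("analysis frequencies must be positive")
    if cycles is None:
        cycles = default_cycles(freqs_hz)
    cycles = np.broadcast_to(np.asarray(cycles, dtype=float), freqs_hz.shape).copy()
    if np.any(cycles < 2):
        raise ValueError("need at least 2 cycles per wavelet")

    x = rec.data[channel]  # trials x samples
    n_trials, n_samples = x.shape
    coeffs = np.empty((n_trials, freqs_hz.size, n_samples), dtype=complex)
    valid = np.ones((freqs_hz.size, n_samples), dtype=bool)

    for fi, (f, nc) in enumerate(zip(freqs_hz, cycles)):
        kernel = _morlet_kernel(f, nc, rec.srate)
        half = (len(kernel) - 1) // 2
        if len(kernel) > n_samples:
            raise ValueError(
                f"epoch of {n_samples} samples shorter than the {len(kernel)}-sample "
                f"wavelet at {f:g} Hz"
            )
        # Reflection padding keeps edge transients bounded; the mask still
        # flags everything within one wavelet half-length of the edges.
        padded = np.concatenate(
            [x[:, half:0:-1], x, x[:, -2 : -half - 2 : -1]], axis=1
        )
        conv = fftconvolve(padded, kernel[np.newaxis, :], mode="same", axes=1)
        coeffs[:, fi, :] = conv[:, half : half + n_samples]
        valid[fi, :half] = False
        if half > 0:
            valid[fi, -half:] = False

    return AnalyticTFR(
        coeffs=coeffs,
        freqs_hz=freqs_hz,
        srate=rec.srate,
        cycles=cycles,
        valid_mask=valid,
        t0_index=rec.t0_index,
    )


def power(tfr: AnalyticTFR) -> np.ndarray:
    """Squared magnitude of the coefficients (trials x freqs x samples)."""
    return np.abs(tfr.coeffs) ** 2


def phase(tfr: AnalyticTFR) -> np.ndarray:
    """Phase angle in (-pi, pi] (trials x freqs x samples)."""
    return np.angle(tfr.coeffs)


def induced_power(rec: Recording, freqs_hz, cycles=None, channel: int = 0) -> np.ndarray:
    """Power of the ERP-subtracted recording.

    Removing the trial-averaged waveform before decomposition strips the
    additive, phase-locked (evoked) component, leaving power changes of the
    ongoing background activity (induced responses).
    """
    return power(morlet_decompose(subtract_erp(rec), freqs_hz, cycles, channel))
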