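"""Sequential (directed, lagged) inter-brain entrainment metrics.

Directed coupling between two channels x (person A) and y (person B) is
estimated four ways:

* :func:`lagged_spearman` — rank correlation as one series is shifted against
  the other; the simplest lag detector.
* Granger causality (GC): the log-ratio of residual variances of the
  univariate vs bivariate autoregressive fits,
  ``GC_{x->y} = ln(var(e_y | past y) / var(e_y | past y, past x))``,
  computed per sliding window for time-varying estimates
  (:func:`gc_time_domain`, :func:`gc_time_varying`).
* Frequency-domain decompositions of the same VAR fit: Geweke spectral GC
  (:func:`gc_spectral`) and partially directed coherence (:func:`pdc`).
* Phase transfer entropy (:func:`phase_transfer_entropy`): an
  entropy-combination estimate of directed information flow between binned
  phase series, which unlike PLV can pool observations over time *and*
  trials.

AR models are fitted by ordinary least squares on lag-stacked design
matrices, pooling trials within a window (lag windows never straddle trial
boundaries).  Model order is chosen by AIC/BIC (:func:`select_model_order`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample_poly

from .concurrent import EntrainmentMap
from .signal_model import DyadEpochs, WindowScheme, detrend_window
from .timefreq import AnalyticTFR

DIRECTIONS = ["x->y", "y->x"]


# ---------------------------------------------------------------------------
# Lagged rank correlation
# ---------------------------------------------------------------------------

def lagged_spearman(x: np.ndarray, y: np.ndarray, max_lag_s: float, srate: float):
    """Spearman correlation at every integer-sample lag in [-max_lag, +max_lag].

    Positive lag means x leads y (x at time t is paired with y at t + lag).
    Only overlapping segments are correlated; no padding.  Returns
    ``(lags_s, rho)`` with lags in seconds.
    """
    from scipy.stats import spearmanr

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    max_lag = int(round(max_lag_s * srate))
    n = x.size
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below half the series length")
    lags = np.arange(-max_lag, max_lag + 1)
    rho = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
        rho[i] = spearmanr(xs, ys).statistic
    return lags / srate, rho


def model_order_duration_ms(order: int, srate: float) -> int:
    """Temporal reach of an AR model order in milliseconds at a sampling rate.

    E.g. 5 samples at 1000 Hz span 5 ms; the same order at 128 Hz spans 39 ms
    — the reason for downsampling before GC when low-frequency dynamics
    matter.
    """
    return int(round(order / srate * 1000.0))


# ---------------------------------------------------------------------------
# AR fitting
# ---------------------------------------------------------------------------

@dataclass
class ARFit:
    """Bivariate (and nested univariate) autoregressive fit for one window.

    ``coeffs[k]`` is the 2x2 matrix applied to the state ``[x, y]`` at lag
    k+1.  ``resid_cov_biv`` is the 2x2 residual covariance of the bivariate
    fit; ``resid_var_uni`` the residual variances of the two univariate
    (self-prediction) fits.  RSS fields support the nested-model F-test.
    """

    order: int
    coeffs: np.ndarray  # (order, 2, 2)
    resid_cov_biv: np.ndarray  # (2, 2)
    resid_var_uni: np.ndarray  # (2,) -> [var(e_x), var(e_y)]
    srate: float
    n_obs: int
    rss_uni: np.ndarray = field(default=None)  # (2,)
    rss_biv: np.ndarray = field(default=None)  # (2,)
    stable: bool = True
    window_id: int | None = None

    def companion_spectral_radius(self) -> float:
        p = self.order
        comp = np.zeros((2 * p, 2 * p))
        for k in range(p):
            comp[:2, 2 * k : 2 * k + 2] = self.coeffs[k]
        if p > 1:
            comp[2:, :-2] = np.eye(2 * (p - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())


def _lag_stack(series: np.ndarray, order: int):
    """Design matrix of lagged values pooled across trials.

    ``series`` is (n_series, n_trials, n_samples); returns
    ``(targets, design)`` where targets is (n_obs, n_series) and design is
    (n_obs, n_series * order) ordered lag-major: columns
    [s0@lag1, s1@lag1, s0@lag2, ...].  Lag windows never cross trial
    boundaries.
    """
    n_series, n_trials, n_samples = series.shape
    if n_samples <= order:
        raise ValueError("window shorter than the model order")
    rows_per_trial = n_samples - order
    targets = series[:, :, order:].reshape(n_series, -1).T
    design = np.empty((n_trials * rows_per_trial, n_series * order))
    for k in range(1, order + 1):
        block = series[:, :, order - k : n_samples - k].reshape(n_series, -1).T
        design[:, (k - 1) * n_series : k * n_series] = block
    return targets, design


def fit_var(x: np.ndarray, y: np.ndarray, order: int, srate: float,
            window_id: int | None = None) -> ARFit:
    """OLS fit of the bivariate VAR(order) and the two nested univariate AR
    fits, pooling trials.

    ``x`` and ``y`` are (n_trials, n_samples) (1-d accepted for single
    trials).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y must have matching shape")
    series = np.stack([x, y], axis=0)
    n_samples = x.shape[1]
    if n_samples <= 2 * order + 1:
        raise ValueError(
            f"{n_samples} samples cannot support a bivariate fit of order {order}"
        )
    targets, design = _lag_stack(series, order)
    n_obs = targets.shape[0]

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design matrix in window {window_id} "
            f"(rank {rank} < {design.shape[1]})"
        )
    coef_biv, _, _, _ = np.linalg.lstsq(design, targets, rcond=None)
    resid_biv = targets - design @ coef_biv
    rss_biv = (resid_biv**2).sum(axis=0)
    resid_cov = resid_biv.T @ resid_biv / n_obs

    rss_uni = np.empty(2)
    var_uni = np.empty(2)
    for ci in range(2):
        tgt, dsn = _lag_stack(series[ci : ci + 1], order)
        c, _, _, _ = np.linalg.lstsq(dsn, tgt, rcond=None)
        r = tgt - dsn @ c
        rss_uni[ci] = (r**2).sum()
        var_uni[ci] = rss_uni[ci] / n_obs

    # coef_biv rows are lag-major [x@1, y@1, x@2, ...]; columns are targets.
    coeffs = coef_biv.reshape(order, 2, 2).transpose(0, 2, 1)
    fit = ARFit(
        order=order,
        coeffs=coeffs,
        resid_cov_biv=resid_cov,
        resid_var_uni=var_uni,
        srate=srate,
        n_obs=n_obs,
        rss_uni=rss_uni,
        rss_biv=rss_biv,
        window_id=window_id,
    )
    fit.stable = fit.companion_spectral_radius() < 1.0
    return fit


def select_model_order(x, y, p_max: int, srate: float, criterion: str = "BIC"):
    """Model order minimising AIC or BIC over p = 1..p_max.

    The criterion is computed from the bivariate fit's residual covariance:
    ``n ln det(Sigma) + penalty * k`` with k = 4p free coefficients and
    penalty 2 (AIC) or ln n (BIC).  Returns ``(order, curve)`` with the full
    criterion curve (index 0 = order 1).
    """
    criterion = criterion.upper()
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    curve = np.full(p_max, np.nan)
    for p in range(1, p_max + 1):
        try:
            fit = fit_var(x, y, p, srate)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not fit.stable:
            continue
        sign, logdet = np.linalg.slogdet(fit.resid_cov_biv)
        if sign <= 0:
            continue
        k = 4 * p
        penalty = 2.0 if criterion == "AIC" else np.log(fit.n_obs)
        curve[p - 1] = fit.n_obs * logdet + penalty * k
    if np.all(np.isnan(curve)):
        raise ValueError("no stable AR fit at any order up to p_max")
    return int(np.nanargmin(curve)) + 1, curve


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

_NEGATIVE_GC_CLIPS = {"count": 0}


def gc_from_fit(fit: ARFit) -> np.ndarray:
    """Time-domain GC for both directions from a fitted ARFit.

    ``GC_{x->y} = ln(var(e_y)_uni / var(e_y)_biv)`` and symmetrically for
    y->x.  Small negative estimates (numerical noise in nested OLS fits) are
    clipped to 0 with a counter.
    """
    var_biv = np.diag(fit.resid_cov_biv)
    with np.errstate(divide="ignore"):
        gc_xy = float(np.log(fit.resid_var_uni[1] / var_biv[1]))
        gc_yx = float(np.log(fit.resid_var_uni[0] / var_biv[0]))
    out = np.array([gc_xy, gc_yx])
    if np.any(out < 0):
        _NEGATIVE_GC_CLIPS["count"] += int(np.sum(out < 0))
        warnings.warn("negative GC estimate clipped to 0", RuntimeWarning, stacklevel=2)
        out = np.clip(out, 0.0, None)
    return out


def gc_time_domain(x, y, order: int, srate: float = 1.0):
    """Time-domain GC in both directions on one window of (trials x samples)
    data.  Returns ``(gc_xy, gc_yx, fit)``."""
    fit = fit_var(x, y, order, srate)
    gc = gc_from_fit(fit)
    return gc[0], gc[1], fit


def gc_time_varying(
    dyad: DyadEpochs,
    scheme: WindowScheme,
    order: int,
    channel: int = 0,
    detrend_order: int | None = 1,
) -> EntrainmentMap:
    """GC per sliding window (direction x window).

    Trials are pooled within each window (lag-stacked, never straddling trial
    boundaries).  Each window is demeaned and linearly detrended per trial
    before fitting — the segment-wise stationarity treatment for slow drifts
    (``detrend_order=None`` skips it for data already free of trends).  Fits
    are kept in ``meta["fits"]``.
    """
    xa = dyad.a.data[channel]
    xb = dyad.b.data[channel]
    vals = np.full((2, scheme.n_windows), np.nan)
    fits = []
    for wi, (s, e) in enumerate(scheme.boundaries):
        if detrend_order is None:
            wx, wy = xa[:, s:e], xb[:, s:e]
        else:
            wx = detrend_window(xa[:, s:e], detrend_order)
            wy = detrend_window(xb[:, s:e], detrend_order)
        gcxy, gcyx, fit = gc_time_domain(wx, wy, order, dyad.srate)
        fit.window_id = wi
        vals[0, wi], vals[1, wi] = gcxy, gcyx
        fits.append(fit)
    return EntrainmentMap(
        metric="gc_time",
        values=vals[:, np.newaxis, :],
        time_stamps=scheme.centres_s(dyad.t0_index),
        freqs_hz=np.array([np.nan]),
        directions=list(DIRECTIONS),
        meta={"order": order, "fits": fits, "window_length_s": scheme.length_s,
              "window_step_s": scheme.step_s, "detrend_order": detrend_order},
    )


def _transfer_matrices(fit: ARFit, freqs_hz: np.ndarray):
    """A(f) = I - sum_k A_k exp(-i 2 pi f k / srate) and H(f) = A(f)^-1."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    k = np.arange(1, fit.order + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs_hz, k) / fit.srate)  # (F, p)
    A = np.eye(2)[np.newaxis] - np.einsum("fk,kij->fij", phase, fit.coeffs)
    det = np.linalg.det(A)
    if np.any(np.abs(det) < 1e-12):
        bad = freqs_hz[np.abs(det) < 1e-12]
        raise np.linalg.LinAlgError(f"A(f) singular at frequencies {bad}")
    H = np.linalg.inv(A)
    return A, H


def gc_spectral(fit: ARFit, freqs_hz) -> EntrainmentMap:
    """Geweke spectral GC per direction and frequency.

    The AR coefficients are projected onto complex sinusoids (the transfer
    function ``H(f) = A(f)^-1``); the spectral matrix ``S = H Sigma H*`` is
    then decomposed into intrinsic and causal parts, e.g.
    ``I_{x->y}(f) = ln( S_yy / (S_yy - (Sxx - Sxy^2/Syy_resid) |H_yx|^2) )``
    using the partialled input noise.  Integrates (averages) back to the
    time-domain GC for a stable VAR.
    """
    if not fit.stable:
        raise ValueError("spectral GC requires a stable AR fit")
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    _, H = _transfer_matrices(fit, freqs_hz)
    sigma = fit.resid_cov_biv
    S = np.einsum("fij,jk,flk->fil", H, sigma, H.conj())
    vals = np.empty((2, freqs_hz.size))
    # x -> y: remove from S_yy the part carried by x's partialled innovations.
    sxx_p = sigma[0, 0] - sigma[0, 1] ** 2 / sigma[1, 1]
    syy_p = sigma[1, 1] - sigma[0, 1] ** 2 / sigma[0, 0]
    syy = np.real(S[:, 1, 1])
    sxx = np.real(S[:, 0, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        vals[0] = np.log(syy / (syy - sxx_p * np.abs(H[:, 1, 0]) ** 2))
        vals[1] = np.log(sxx / (sxx - syy_p * np.abs(H[:, 0, 1]) ** 2))
    vals = np.clip(vals, 0.0, None)  # tiny negatives are numerical noise
    return EntrainmentMap(
        metric="gc_spectral",
        values=vals[:, :, np.newaxis],
        time_stamps=np.array([0.0]),
        freqs_hz=freqs_hz,
        directions=list(DIRECTIONS),
        meta={"order": fit.order},
    )


def pdc(fit: ARFit, freqs_hz) -> EntrainmentMap:
    """Partially directed coherence per direction and frequency.

    ``PDC_{i<-j}(f) = |A_ij(f)| / sqrt(sum_k |A_kj(f)|^2)`` with
    ``A(f) = I - sum A_k e^{-i2pifk/srate}``; column-normalised so
    ``sum_i PDC_{i<-j}^2 = 1`` at every frequency.  The map's directions are
    ``x->y`` (= PDC_{y<-x}) and ``y->x``.
    """
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    A, _ = _transfer_matrices(fit, freqs_hz)
    mag = np.abs(A)
    colnorm = np.sqrt((mag**2).sum(axis=1))  # (F, 2) per source column j
    with np.errstate(invalid="ignore", divide="ignore"):
        full = np.where(colnorm[:, np.newaxis, :] > 0,
                        mag / colnorm[:, np.newaxis, :], np.nan)
    vals = np.stack([full[:, 1, 0], full[:, 0, 1]])  # y<-x, x<-y
    return EntrainmentMap(
        metric="pdc",
        values=vals[:, :, np.newaxis],
        time_stamps=np.array([0.0]),
        freqs_hz=freqs_hz,
        directions=list(DIRECTIONS),
        meta={"order": fit.order, "full_matrix": full},
    )


def downsample_for_gc(data: np.ndarray, srate: float, target_hz: float = 128.0):
    """Anti-aliased decimation to a lower rate before AR fitting, so a given
    model order spans a longer past (e.g. order 5 at 128 Hz reaches 39 ms
    instead of 10 ms at 512 Hz).  Returns ``(data, new_srate)``."""
    if target_hz >= srate:
        return data, srate
    factor = int(round(srate / target_hz))
    out = resample_poly(data, 1, factor, axis=-1)
    return out, srate / factor


# ---------------------------------------------------------------------------
# Phase transfer entropy
# ---------------------------------------------------------------------------

@dataclass
class PTEConfig:
    """Parameters of the binned phase-transfer-entropy estimator.

    ``delta`` is the prediction lag in samples; ``n_bins`` the number of
    equal-width phase bins on (-pi, pi].  ``bin_rule`` records how ``n_bins``
    was chosen (``"fixed"`` or ``"otnes"``).
    """

    delta: int
    n_bins: int
    bin_rule: str = "fixed"

    def __post_init__(self):
        if self.delta < 1:
            raise ValueError("delta must be >= 1 sample")
        if self.n_bins < 2:
            raise ValueError("need at least 2 phase bins")


def otnes_bins(n_obs: int, delta: int) -> int:
    """Histogram bin count by the Otnes-Enochson rule,
    ``round(exp(0.626 + 0.4 ln(N - delta - 1)))``."""
    return int(round(np.exp(0.626 + 0.4 * np.log(max(n_obs - delta - 1, 2)))))


def default_pte_config(centre_freq_hz: float, srate: float, n_obs: int) -> PTEConfig:
    """Lag = a quarter cycle of the analysed frequency; bins by the
    Otnes-Enochson rule."""
    delta = max(1, int(round(srate / centre_freq_hz / 4.0)))
    return PTEConfig(delta=delta, n_bins=otnes_bins(n_obs, delta), bin_rule="otnes")


_NEGATIVE_PTE = {"count": 0}


def _bin_phases(ph: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin indices on (-pi, pi]."""
    idx = np.floor((ph + np.pi) / (2 * np.pi) * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def _entropy(*indices: np.ndarray, n_bins: int) -> float:
    """Shannon entropy (nats) of the empirical joint histogram of the given
    bin-index arrays."""
    joint = indices[0].astype(np.int64).copy()
    for ix in indices[1:]:
        joint = joint * n_bins + ix
    counts = np.bincount(joint.ravel())
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _pte_directional(src: np.ndarray, tgt: np.ndarray, cfg: PTEConfig) -> float:
    """PTE source->target for pooled observation arrays (obs,) at t and t'."""
    tgt_t, tgt_p, src_p = tgt[0], tgt[1], src[1]
    h_yy = _entropy(tgt_t, tgt_p, n_bins=cfg.n_bins)
    h_yx = _entropy(tgt_p, src_p, n_bins=cfg.n_bins)
    h_y = _entropy(tgt_p, n_bins=cfg.n_bins)
    h_yyx = _entropy(tgt_t, tgt_p, src_p, n_bins=cfg.n_bins)
    pte = h_yy + h_yx - h_y - h_yyx
    if pte < 0:
        _NEGATIVE_PTE["count"] += 1
    return pte


def phase_transfer_entropy(phase_x, phase_y, cfg: PTEConfig, pool: str = "both"):
    """Phase transfer entropy in both directions.

    Implements the entropy combination
    ``PTE_{x->y} = H(y_t, y_t') + H(y_t', x_t') - H(y_t') - H(y_t, y_t', x_t')``
    with ``t' = t - delta``, phases binned into ``cfg.n_bins`` equal-width
    bins.  Estimates are reported raw (negative values are possible from
    estimator bias and are counted, not clipped).

    ``pool`` controls which observations enter the joint histograms:

    * ``"both"`` — all (trial, time) pairs pooled: two scalars.
    * ``"over_time"`` — pooled over time within each trial: arrays (n_trials,).
    * ``"over_trials"`` — pooled over trials at each time point: arrays
      (n_valid_times,).

    Returns ``(pte_xy, pte_yx)``.
    """
    px = _phases_2d(phase_x)
    py = _phases_2d(phase_y)
    if px.shape != py.shape:
        raise ValueError("phase arrays differ in shape")
    n_trials, n_samples = px.shape
    if n_samples <= cfg.delta:
        raise ValueError("series shorter than the PTE lag")
    bx = _bin_phases(px, cfg.n_bins)
    by = _bin_phases(py, cfg.n_bins)
    d = cfg.delta

    def pair(b):  # (value at t, value at t') pairs
        return b[:, d:], b[:, :-d]

    xt, xp = pair(bx)
    yt, yp = pair(by)

    def check(n_eff):
        if n_eff < cfg.n_bins**2:
            raise ValueError(
                f"{n_eff} observations cannot fill {cfg.n_bins}^2 histogram cells"
            )
        if n_eff < 5 * cfg.n_bins**2:
            warnings.warn("few observations per histogram cell; PTE will be biased",
                          RuntimeWarning, stacklevel=3)

    if pool == "both":
        check(xt.size)
        return (
            _pte_directional((xt, xp), (yt, yp), cfg),
            _pte_directional((yt, yp), (xt, xp), cfg),
        )
    if pool == "over_time":
        check(xt.shape[1])
        out = np.array([
            [_pte_directional((xt[k], xp[k]), (yt[k], yp[k]), cfg),
             _pte_directional((yt[k], yp[k]), (xt[k], xp[k]), cfg)]
            for k in range(n_trials)
        ])
        return out[:, 0], out[:, 1]
    if pool == "over_trials":
        check(n_trials)
        out = np.array([
            [_pte_directional((xt[:, t], xp[:, t]), (yt[:, t], yp[:, t]), cfg),
             _pte_directional((yt[:, t], yp[:, t]), (xt[:, t], xp[:, t]), cfg)]
            for t in range(xt.shape[1])
        ])
        return out[:, 0], out[:, 1]
    raise ValueError("pool must be 'both', 'over_time' or 'over_trials'")


def _phases_2d(x) -> np.ndarray:
    """Accept an AnalyticTFR (single frequency) or a (trials, samples) array."""
    if isinstance(x, AnalyticTFR):
        if x.freqs_hz.size != 1:
            raise ValueError("pass a single-frequency TFR or a 2-d phase array")
        return np.angle(x.coeffs[:, 0, :])
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[np.newaxis, :]
    if x.ndim != 2:
        raise ValueError("phases must be (trials, samples)")
    return x


def pte_time_varying(
    phase_x, phase_y, scheme: WindowScheme, cfg: PTEConfig, t0_index: int = 0
) -> EntrainmentMap:
    """PTE per sliding window (direction x window), pooling time and trials
    within each window."""
    px = _phases_2d(phase_x)
    py = _phases_2d(phase_y)
    vals = np.full((2, scheme.n_windows), np.nan)
    for wi, (s, e) in enumerate(scheme.boundaries):
        xy, yx = phase_transfer_entropy(px[:, s:e], py[:, s:e], cfg, pool="both")
        vals[0, wi], vals[1, wi] = xy, yx
    if isinstance(phase_x, AnalyticTFR):
        t0_index = phase_x.t0_index
    return EntrainmentMap(
        metric="pte",
        values=vals[:, np.newaxis, :],
        time_stamps=scheme.centres_s(t0_index),
        freqs_hz=np.array([np.nan]),
        directions=list(DIRECTIONS),
        meta={"delta": cfg.delta, "n_bins": cfg.n_bins,
              "window_length_s": scheme.length_s, "window_step_s": scheme.step_s},
    )
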