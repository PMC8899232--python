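"""Directed metrics: lagged correlation, AR/GC machinery, PDC, PTE."""

import numpy as np
import pytest

from interbrain.sequential import (
    PTEConfig,
    downsample_for_gc,
    fit_var,
    gc_spectral,
    gc_time_domain,
    gc_time_varying,
    lagged_spearman,
    model_order_duration_ms,
    pdc,
    phase_transfer_entropy,
    pte_time_varying,
    select_model_order,
)
from interbrain.signal_model import DyadEpochs, Recording, make_windows


def simulate_var(coeffs, sigma, n, seed, burn=200):
    """Simulate a bivariate VAR given (p, 2, 2) lag matrices."""
    rng = np.random.default_rng(seed)
    p = coeffs.shape[0]
    chol = np.linalg.cholesky(sigma)
    z = np.zeros((n + burn, 2))
    eps = rng.standard_normal((n + burn, 2)) @ chol.T
    for t in range(p, n + burn):
        z[t] = eps[t]
        for k in range(p):
            z[t] += coeffs[k] @ z[t - k - 1]
    return z[burn:, 0], z[burn:, 1]


UNIDIR = np.array([[[0.7, 0.0], [0.5, 0.0]]])  # x autonomous AR(1) driving y


class TestLaggedSpearman:
    def test_recovers_pure_shift(self, rng):
        x = rng.standard_normal(500)
        y = np.roll(x, 10)
        y[:10] = rng.standard_normal(10)
        lags, rho = lagged_spearman(x, y, max_lag_s=0.2, srate=100.0)
        assert lags[np.argmax(rho)] == pytest.approx(0.10)
        assert rho.max() > 0.9

    def test_excessive_lag_rejected(self, rng):
        with pytest.raises(ValueError, match="half"):
            lagged_spearman(rng.standard_normal(50), rng.standard_normal(50), 0.3, 100.0)

    def test_swapping_series_mirrors_profile(self, rng):
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        _, fwd = lagged_spearman(x, y, 0.1, 100.0)
        _, rev = lagged_spearman(y, x, 0.1, 100.0)
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-12)


class TestModelOrder:
    def test_order_duration_worked_examples(self):
        # 5 samples span 5 ms at 1000 Hz but 39 ms at 128 Hz
        assert model_order_duration_ms(5, 1000.0) == 5
        assert model_order_duration_ms(5, 128.0) == 39
        assert model_order_duration_ms(15, 128.0) == 117

    def test_bic_recovers_known_var3_order(self):
        coeffs = np.zeros((3, 2, 2))
        coeffs[0] = [[0.4, 0.0], [0.3, 0.3]]
        coeffs[2] = [[-0.35, 0.0], [0.0, -0.35]]
        hits = 0
        for seed in range(20):
            x, y = simulate_var(coeffs, np.eye(2), 2000, seed)
            order, _ = select_model_order(x, y, p_max=6, srate=100.0)
            hits += order == 3
        assert hits >= 15

    def test_white_noise_prefers_smallest_order(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            order, _ = select_model_order(
                rng.standard_normal(1500), rng.standard_normal(1500),
                p_max=6, srate=100.0,
            )
            hits += order == 1
        assert hits >= 15

    def test_single_candidate(self, rng):
        order, curve = select_model_order(
            rng.standard_normal(500), rng.standard_normal(500), p_max=1, srate=100.0
        )
        assert order == 1 and curve.shape == (1,)


class TestFitVar:
    def test_matches_statsmodels_reference(self):
        from statsmodels.tsa.api import VAR as SmVAR

        x, y = simulate_var(UNIDIR, np.eye(2), 3000, seed=7)
        fit = fit_var(x, y, order=1, srate=100.0)
        sm = SmVAR(np.column_stack([x, y])).fit(maxlags=1, trend="n")
        np.testing.assert_allclose(fit.coeffs[0], sm.coefs[0], atol=1e-6)
        np.testing.assert_allclose(fit.resid_cov_biv, sm.sigma_u_mle, rtol=1e-3)

    def test_nested_variance_ordering_and_stability(self, rng):
        x, y = simulate_var(UNIDIR, np.eye(2), 1500, seed=3)
        fit = fit_var(x, y, order=2, srate=100.0)
        assert fit.stable
        assert (np.diag(fit.resid_cov_biv) <= fit.resid_var_uni + 1e-9).all()

    def test_rank_deficient_design_rejected(self):
        x = np.zeros(100)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_var(x, x, order=2, srate=100.0)


class TestGcTimeDomain:
    def test_matches_population_oracle_on_var1(self):
        # y_t = 0.5 x_{t-1} + e with x AR(1): population GC_{x->y} at order 1
        # follows from the Yule-Walker variance of the univariate fit
        x, y = simulate_var(UNIDIR, np.eye(2), 10_000, seed=1)
        gc_xy, gc_yx, _ = gc_time_domain(x, y, order=1, srate=100.0)
        vx = 1.0 / (1 - 0.49)
        vy = 0.25 * vx + 1.0
        c1 = 0.25 * 0.7 * vx
        population = np.log((vy - c1**2 / vy) / 1.0)
        assert gc_xy == pytest.approx(population, rel=0.10)
        assert gc_yx < 0.01

    def test_invariant_to_channel_rescaling(self):
        x, y = simulate_var(UNIDIR, np.eye(2), 3000, seed=5)
        base = gc_time_domain(x, y, 3, 100.0)[:2]
        scaled = gc_time_domain(17.0 * x, 0.04 * y, 3, 100.0)[:2]
        np.testing.assert_allclose(base, scaled, atol=1e-8)

    def test_swapping_channels_swaps_directions(self):
        x, y = simulate_var(UNIDIR, np.eye(2), 2000, seed=9)
        xy, yx, _ = gc_time_domain(x, y, 2, 100.0)
        xy2, yx2, _ = gc_time_domain(y, x, 2, 100.0)
        assert xy == pytest.approx(yx2, abs=1e-12)
        assert yx == pytest.approx(xy2, abs=1e-12)


class TestGcTimeVarying:
    def test_single_window_reduces_to_whole_epoch_fit(self, rng):
        data_a = rng.standard_normal((1, 5, 200))
        data_b = rng.standard_normal((1, 5, 200))
        dyad = DyadEpochs(
            a=Recording("a", ["c"], data_a, 100.0, 0),
            b=Recording("b", ["c"], data_b, 100.0, 0),
        )
        scheme = make_windows(200, 100.0, 2.0, 2.0)
        m = gc_time_varying(dyad, scheme, order=3, detrend_order=None)
        xy, yx, _ = gc_time_domain(data_a[0], data_b[0], 3, 100.0)
        assert m.values.shape == (2, 1, 1)
        assert m.values[0, 0, 0] == pytest.approx(xy, abs=1e-12)
        assert m.values[1, 0, 0] == pytest.approx(yx, abs=1e-12)

    def test_stationary_coupling_yields_flat_profile(self):
        from scipy.stats import spearmanr

        trends = []
        for seed in range(6):
            trials = [simulate_var(UNIDIR, np.eye(2), 600, seed=100 * seed + k)
                      for k in range(20)]
            xa = np.stack([t[0] for t in trials])[np.newaxis]
            xb = np.stack([t[1] for t in trials])[np.newaxis]
            dyad = DyadEpochs(
                a=Recording("a", ["c"], xa, 100.0, 0),
                b=Recording("b", ["c"], xb, 100.0, 0),
            )
            scheme = make_windows(600, 100.0, 1.0, 1.0)
            m = gc_time_varying(dyad, scheme, order=2)
            trends.append(
                spearmanr(np.arange(scheme.n_windows), m.values[0, 0]).statistic
            )
        # no systematic drift across windows for a time-invariant VAR
        assert abs(np.mean(trends)) < 0.5


class TestSpectral:
    def test_band_average_matches_time_domain(self):
        # Geweke integral property: the mean of spectral GC over the full
        # frequency axis recovers time-domain GC for a stable VAR
        x, y = simulate_var(UNIDIR, np.eye(2), 20_000, seed=2)
        gc_xy, _, fit = gc_time_domain(x, y, order=5, srate=100.0)
        freqs = np.linspace(0.0, 50.0, 1001)
        spec = gc_spectral(fit, freqs)
        band_avg = np.trapezoid(spec.values[0][:, 0], freqs) / 50.0
        assert band_avg == pytest.approx(gc_xy, rel=0.05)

    def test_narrowband_drive_peaks_in_band(self):
        # oscillatory source at ~10 Hz (AR(2) resonance) driving y
        r, f0, srate = 0.95, 10.0, 100.0
        phi = 2 * np.pi * f0 / srate
        coeffs = np.zeros((2, 2, 2))
        coeffs[0] = [[2 * r * np.cos(phi), 0.0], [0.8, 0.0]]
        coeffs[1, 0, 0] = -(r**2)
        x, y = simulate_var(coeffs, np.eye(2), 20_000, seed=4)
        _, _, fit = gc_time_domain(x, y, order=6, srate=srate)
        freqs = np.arange(1.0, 50.0)
        spec = gc_spectral(fit, freqs).values[0][:, 0]
        peak = freqs[np.argmax(spec)]
        assert 8.0 <= peak <= 12.0
        assert spec[freqs > 30].max() < 0.2 * spec.max()

    def test_independent_channels_near_zero_everywhere(self, rng):
        x = rng.standard_normal(8000)
        y = rng.standard_normal(8000)
        _, _, fit = gc_time_domain(x, y, order=3, srate=100.0)
        spec = gc_spectral(fit, np.arange(1.0, 50.0))
        assert spec.values.max() < 0.02

    def test_pdc_column_normalisation_and_diagonal_limit(self, rng):
        # identity on random stable fits; diagonal VAR puts all mass on the
        # diagonal
        x, y = simulate_var(UNIDIR, np.eye(2), 4000, seed=6)
        _, _, fit = gc_time_domain(x, y, order=4, srate=100.0)
        freqs = np.arange(1.0, 50.0, 2.0)
        full = pdc(fit, freqs).meta["full_matrix"]
        np.testing.assert_allclose((full**2).sum(axis=1), 1.0, atol=1e-12)

        diag = np.array([[[0.5, 0.0], [0.0, -0.4]]])
        x2, y2 = simulate_var(diag, np.eye(2), 50, seed=0)
        fit2 = fit_var(x2, y2, 1, 100.0)
        fit2.coeffs = diag  # exact diagonal coefficients
        m = pdc(fit2, freqs)
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_unidirectional_pdc_asymmetry(self):
        x, y = simulate_var(UNIDIR, np.eye(2), 10_000, seed=8)
        _, _, fit = gc_time_domain(x, y, order=3, srate=100.0)
        m = pdc(fit, np.arange(1.0, 40.0))
        assert m.values[0].max() > 0.3       # y <- x present
        assert m.values[1].max() < 0.1       # x <- y absent


class TestDownsample:
    def test_decimation_halves_rate_and_extends_reach(self, rng):
        data = rng.standard_normal((4, 1024))
        out, new_rate = downsample_for_gc(data, 512.0, target_hz=128.0)
        assert new_rate == pytest.approx(128.0)
        assert out.shape == (4, 256)
        assert model_order_duration_ms(5, new_rate) == 39


class TestPte:
    def test_deterministic_phase_map_is_strongly_directed(self, rng):
        px = rng.uniform(-np.pi, np.pi, (40, 400))
        py = np.empty_like(px)
        py[:, 1:] = px[:, :-1]
        py[:, 0] = rng.uniform(-np.pi, np.pi, 40)
        cfg = PTEConfig(delta=1, n_bins=8)
        xy, yx = phase_transfer_entropy(px, py, cfg, pool="both")
        assert xy > 10 * max(yx, 0.01)

    def test_independent_walks_are_symmetric(self):
        diffs = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            pa = np.angle(np.exp(1j * np.cumsum(0.3 * rng.standard_normal((20, 500)), axis=1)))
            pb = np.angle(np.exp(1j * np.cumsum(0.3 * rng.standard_normal((20, 500)), axis=1)))
            xy, yx = phase_transfer_entropy(pa, pb, PTEConfig(delta=5, n_bins=6), pool="both")
            diffs.append(xy - yx)
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 1e-3

    def test_swapping_channels_swaps_directions(self, rng):
        pa = rng.uniform(-np.pi, np.pi, (10, 200))
        pb = rng.uniform(-np.pi, np.pi, (10, 200))
        cfg = PTEConfig(delta=3, n_bins=4)
        xy, yx = phase_transfer_entropy(pa, pb, cfg, pool="both")
        xy2, yx2 = phase_transfer_entropy(pb, pa, cfg, pool="both")
        assert xy == pytest.approx(yx2, abs=1e-12)
        assert yx == pytest.approx(xy2, abs=1e-12)

    def test_pooling_modes_shapes(self, rng):
        pa = rng.uniform(-np.pi, np.pi, (15, 120))
        pb = rng.uniform(-np.pi, np.pi, (15, 120))
        cfg = PTEConfig(delta=2, n_bins=3)
        xy, yx = phase_transfer_entropy(pa, pb, cfg, pool="over_time")
        assert xy.shape == (15,)
        xy, yx = phase_transfer_entropy(pa, pb, cfg, pool="over_trials")
        assert xy.shape == (118,)

    def test_too_few_observations_rejected(self, rng):
        pa = rng.uniform(-np.pi, np.pi, (2, 10))
        with pytest.raises(ValueError, match="histogram"):
            phase_transfer_entropy(pa, pa, PTEConfig(delta=1, n_bins=8), pool="both")

    def test_gc_and_pte_asymmetry_signs_agree_on_linear_coupling(self):
        # for a linearly phase-coupled system the directed asymmetry seen by
        # GC (on the signals) and PTE (on the phases) must point the same way
        agree = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            drive = np.cumsum(0.25 * rng.standard_normal((12, 600)), axis=1)
            px = drive + 0.1 * rng.standard_normal((12, 600))
            py = np.empty_like(px)
            py[:, 4:] = drive[:, :-4]
            py[:, :4] = rng.uniform(-np.pi, np.pi, (12, 4))
            py += 0.1 * rng.standard_normal((12, 600))
            wx = np.angle(np.exp(1j * px))
            wy = np.angle(np.exp(1j * py))
            xy, yx = phase_transfer_entropy(wx, wy, PTEConfig(delta=4, n_bins=6), pool="both")
            gxy, gyx, _ = gc_time_domain(np.cos(px), np.cos(py), order=8, srate=100.0)
            agree += (xy > yx) == (gxy > gyx)
        assert agree >= int(0.95 * n_seeds)

    def test_time_varying_window_map(self, rng):
        pa = rng.uniform(-np.pi, np.pi, (20, 300))
        pb = rng.uniform(-np.pi, np.pi, (20, 300))
        scheme = make_windows(300, 100.0, 1.0, 0.5)
        m = pte_time_varying(pa, pb, scheme, PTEConfig(delta=2, n_bins=4))
        assert m.values.shape == (2, 1, scheme.n_windows)
        assert m.directions == ["x->y", "y->x"]
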