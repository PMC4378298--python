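"""VAR fitting, the parametric spectral matrix and the Geweke decomposition,
validated against closed forms, plug-in truth, the time-domain measure and an
independent library fit."""

import numpy as np
import pytest

from lfo_gcnet import (
    NetworkSpec,
    VarModel,
    default_freq_grid,
    fit_var,
    gc_spectra_from_model,
    integrate_gc,
    pairwise_gc,
    peak_frequency,
    select_order,
    simulate_var,
    spectral_matrix,
)
from lfo_gcnet.spectral import batch_fit_bivar, batch_pair_igc

TR = 2.0
FREQS = default_freq_grid(TR)


def _ar1_series(a=0.5, t_len=5000, seed=0):
    spec = NetworkSpec(region_names=("x",), edges=(), ar_self=a, tr_s=TR)
    return simulate_var(spec, t_len, seed=seed)


class TestSelectOrder:
    def test_recovers_var2(self):
        spec = NetworkSpec(
            region_names=("x", "y"),
            edges=(("x", "y", 0.5, 2), ("y", "x", -0.4, 2)),
            ar_self=0.3,
            tr_s=TR,
        )
        ts = simulate_var(spec, 2000, seed=31)
        assert select_order(ts, p_max=10).order_p == 2

    def test_white_noise_bic_picks_minimum(self):
        picks = []
        for rep in range(100):
            x = np.random.default_rng(rep).normal(size=(300, 2))
            picks.append(select_order(x, p_max=6, criterion="BIC").order_p)
        assert np.mean(np.asarray(picks) == 1) >= 0.95

    def test_infeasible_length_errors(self):
        x = np.zeros((15, 2))
        with pytest.raises(ValueError, match="p_max"):
            select_order(x, p_max=10)

    def test_trace_covers_all_orders(self):
        ts = _ar1_series(t_len=400)
        sel = select_order(ts, p_max=4)
        assert sorted(sel.trace) == [1, 2, 3, 4]


class TestFitVar:
    def test_ar1_consistency(self):
        ts = _ar1_series(a=0.5, t_len=5000, seed=12)
        model = fit_var(ts, 1)
        assert model.coeffs[0, 0, 0] == pytest.approx(0.5, abs=0.05)
        assert model.noise_cov[0, 0] == pytest.approx(1.0, abs=0.1)

    def test_independent_pair_coefficients_near_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(2000, 2))
        model = fit_var(x, 1)
        # standard error of a regression weight on white noise ~ 1/sqrt(T)
        se = 1.0 / np.sqrt(x.shape[0])
        assert abs(model.coeffs[0, 0, 1]) < 3 * se
        assert abs(model.coeffs[0, 1, 0]) < 3 * se

    def test_parametric_bootstrap_roundtrip(self, unidirectional_spec):
        ts = simulate_var(unidirectional_spec, 10_000, seed=3)
        fitted = fit_var(ts, 1)
        respec = NetworkSpec(
            region_names=("x", "y"),
            edges=(
                ("x", "y", float(fitted.coeffs[0, 1, 0]), 1),
                ("y", "x", float(fitted.coeffs[0, 0, 1]), 1),
            ),
            ar_self=tuple(np.diag(fitted.coeffs[0])),
            innovation_cov=fitted.noise_cov,
            tr_s=TR,
        )
        refit = fit_var(simulate_var(respec, 10_000, seed=4), 1)
        big = np.abs(fitted.coeffs[0]) > 0.1
        assert np.allclose(refit.coeffs[0][big], fitted.coeffs[0][big], rtol=0.05)

    def test_matches_statsmodels(self, long_unidirectional_series):
        sm_var = pytest.importorskip("statsmodels.tsa.api")
        ours = fit_var(long_unidirectional_series, 2)
        theirs = sm_var.VAR(long_unidirectional_series.data).fit(2, trend="n")
        theirs_coeffs = theirs.coefs  # (p, R, R)
        assert np.allclose(ours.coeffs, theirs_coeffs, atol=1e-8)
        assert np.allclose(ours.noise_cov, theirs.sigma_u, rtol=0.05)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="T = 5"):
            fit_var(np.zeros((5, 2)), 2)


class TestSpectralMatrix:
    def test_white_noise_flat_spectrum(self):
        model = VarModel(1, np.zeros((1, 2, 2)), np.eye(2))
        res = spectral_matrix(model, FREQS, TR)
        assert np.allclose(res.S, TR * np.eye(2), atol=1e-12)
        assert np.allclose(res.power, TR)

    def test_ar1_lowpass_shape(self):
        model = VarModel(1, np.full((1, 1, 1), 0.9), np.eye(1))
        power = spectral_matrix(model, FREQS, TR).power[:, 0]
        assert np.all(np.diff(power) < 0)

    def test_ar1_closed_form(self):
        a, f = 0.5, 0.05
        model = VarModel(1, np.full((1, 1, 1), a), np.eye(1))
        res = spectral_matrix(model, np.array([f]), TR)
        expected = TR / np.abs(1 - a * np.exp(-2j * np.pi * f * TR)) ** 2
        assert res.S[0, 0, 0].real == pytest.approx(expected, abs=1e-10)

    def test_hermitian_positive_semidefinite(self, long_unidirectional_series):
        model = fit_var(long_unidirectional_series, 3)
        res = spectral_matrix(model, FREQS[::16], TR)
        assert np.allclose(res.S, res.S.conj().swapaxes(1, 2))
        eig = np.linalg.eigvalsh(res.S)
        assert eig.min() > -1e-12
        assert np.all(res.power >= 0)


class TestPairwiseGc:
    def test_decoupled_null_is_small(self, decoupled_spec):
        ts = simulate_var(decoupled_spec, 5000, seed=21)
        gc = pairwise_gc(ts, ("x", "y"), order_p=1)
        assert gc.m_1_to_2.max() < 0.01
        assert gc.m_2_to_1.max() < 0.01
        assert np.abs(gc.m_inst).max() < 0.01

    def test_estimate_matches_plugin_truth(
        self, unidirectional_spec, long_unidirectional_series
    ):
        est = pairwise_gc(long_unidirectional_series, ("x", "y"), order_p=1)
        truth_model = VarModel(
            1, unidirectional_spec.coeff_matrices(), unidirectional_spec.sigma()
        )
        truth = gc_spectra_from_model(truth_model, FREQS, TR)
        rel = np.abs(est.m_1_to_2 - truth.m_1_to_2) / truth.m_1_to_2
        assert rel.max() < 0.10
        assert est.m_2_to_1.max() < 0.01

    def test_spectral_mean_equals_time_domain_measure(self, long_unidirectional_series):
        """Geweke equivalence: the average of M_x->y over (0, Nyquist] equals
        ln(var_restricted / var_full) from nested regressions."""
        x = long_unidirectional_series.data
        est = pairwise_gc(long_unidirectional_series, ("x", "y"), order_p=1)
        spectral_mean = integrate_gc(FREQS, est.m_1_to_2, FREQS[0], FREQS[-1])
        # independent oracle: restricted (own past only) vs full regression
        y = x[:, 1]
        beta_r = np.linalg.lstsq(y[:-1, None], y[1:], rcond=None)[0]
        var_r = np.var(y[1:] - y[:-1] * beta_r[0])
        z = x[:-1]
        beta_f = np.linalg.lstsq(z, y[1:], rcond=None)[0]
        var_f = np.var(y[1:] - z @ beta_f)
        time_domain = np.log(var_r / var_f)
        assert spectral_mean == pytest.approx(time_domain, rel=0.05)

    def test_decomposition_identity(self, long_unidirectional_series):
        gc = pairwise_gc(long_unidirectional_series, ("x", "y"), order_p=2)
        resid = gc.m_total - gc.m_1_to_2 - gc.m_2_to_1 - gc.m_inst
        assert np.abs(resid).max() < 1e-6

    def test_label_equivariance(self, long_unidirectional_series):
        fwd = pairwise_gc(long_unidirectional_series, ("x", "y"), order_p=2)
        rev = pairwise_gc(long_unidirectional_series, ("y", "x"), order_p=2)
        assert np.allclose(fwd.m_1_to_2, rev.m_2_to_1, atol=1e-12)
        assert np.allclose(fwd.m_2_to_1, rev.m_1_to_2, atol=1e-12)
        assert np.allclose(fwd.m_total, rev.m_total, atol=1e-12)
        assert np.allclose(fwd.m_inst, rev.m_inst, atol=1e-12)

    def test_density_convention_cancels(self, unidirectional_spec):
        """Scaling the innovation covariance (or equivalently the one-sided
        density constant) leaves every GC spectrum unchanged."""
        model = VarModel(
            1, unidirectional_spec.coeff_matrices(), unidirectional_spec.sigma()
        )
        scaled = VarModel(1, model.coeffs, 7.3 * model.noise_cov)
        a = gc_spectra_from_model(model, FREQS, TR)
        b = gc_spectra_from_model(scaled, FREQS, TR)
        assert np.allclose(a.m_1_to_2, b.m_1_to_2, atol=1e-12)
        assert np.allclose(a.m_total, b.m_total, atol=1e-12)

    def test_directed_measures_nonnegative(self, base_network):
        from lfo_gcnet import GroupScenario, detrend_bandpass, make_group_scenario

        ts = detrend_bandpass(
            make_group_scenario(GroupScenario("AB", 1, seed=13), base_network)[0]
        )
        for pair in (("LM1", "SMA"), ("RM1", "LPMC")):
            gc = pairwise_gc(ts, pair, order_p=3)
            assert gc.m_1_to_2.min() >= 0.0
            assert gc.m_2_to_1.min() >= 0.0


class TestIntegrateGc:
    def test_constant_spectrum_gives_band_average(self):
        assert integrate_gc(FREQS, np.full(FREQS.size, 0.37), 0.04, 0.1) == pytest.approx(0.37)
        assert integrate_gc(FREQS, np.zeros(FREQS.size), 0.04, 0.1) == 0.0

    def test_linear_ramp_gives_midpoint(self):
        f1, f2 = 0.04, 0.1
        ramp = np.clip((FREQS - f1) / (f2 - f1), 0, None)
        assert integrate_gc(FREQS, ramp, f1, f2) == pytest.approx(0.5, abs=0.01)

    def test_band_outside_grid_errors(self):
        with pytest.raises(ValueError, match="not covered"):
            integrate_gc(FREQS, np.ones(FREQS.size), 0.2, 0.3)
        with pytest.raises(ValueError, match="f1 < f2"):
            integrate_gc(FREQS, np.ones(FREQS.size), 0.1, 0.04)


class TestPeakFrequency:
    def test_single_maximum(self):
        power = np.exp(-((FREQS - 0.07) ** 2) / 1e-4)
        grid_peak = FREQS[np.argmin(np.abs(FREQS - 0.07))]
        assert peak_frequency(FREQS, power, band=(0.04, 0.1)) == grid_peak

    def test_flat_spectrum_ties_break_low(self):
        flat = np.ones(FREQS.size)
        peak = peak_frequency(FREQS, flat, band=(0.04, 0.1))
        in_band = FREQS[(FREQS >= 0.04) & (FREQS <= 0.1)]
        assert peak == in_band[0]

    def test_empty_band_errors(self):
        with pytest.raises(ValueError, match="band"):
            peak_frequency(FREQS, np.ones(FREQS.size), band=(0.3, 0.4))


class TestBatchEngine:
    def test_batch_matches_scalar_path(self, unidirectional_spec):
        series = [simulate_var(unidirectional_spec, 237, seed=s) for s in range(6)]
        x = np.stack([ts.data for ts in series])
        i12, i21 = batch_pair_igc(x, 3, TR)
        for b in (0, 3, 5):
            gc = pairwise_gc(series[b], ("x", "y"), order_p=3)
            assert integrate_gc(FREQS, gc.m_1_to_2, 0.04, 0.1) == pytest.approx(i12[b], rel=1e-9)
            assert integrate_gc(FREQS, gc.m_2_to_1, 0.04, 0.1) == pytest.approx(i21[b], rel=1e-9)

    def test_batch_fit_matches_scalar_fit(self, unidirectional_spec):
        series = [simulate_var(unidirectional_spec, 300, seed=s) for s in range(3)]
        coeffs, sigma = batch_fit_bivar(np.stack([t.data for t in series]), 2)
        for b, ts in enumerate(series):
            single = fit_var(ts, 2)
            assert np.allclose(coeffs[b], single.coeffs, atol=1e-10)
            assert np.allclose(sigma[b], single.noise_cov, atol=1e-10)
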