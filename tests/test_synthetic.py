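"""The VAR generator: stationarity gates, determinism, analytic covariance,
group scenarios, motion tables and behavior scores."""

import numpy as np
import pytest
from scipy import linalg, stats

from lfo_gcnet import (
    GROUND_TRUTH_EDGES,
    GroupScenario,
    NetworkSpec,
    make_group_scenario,
    motion_exclude,
    simulate_behavior,
    simulate_motion,
    simulate_var,
)
from lfo_gcnet.spectral import (
    batch_pair_igc,
    default_freq_grid,
    fit_var,
    gc_spectra_from_model,
    peak_frequency,
    select_order,
    spectral_matrix,
)
from lfo_gcnet.preprocess import detrend_bandpass
from lfo_gcnet.synthetic import companion_spectral_radius


class TestSimulateVar:
    def test_white_noise_case(self):
        spec = NetworkSpec(region_names=("a", "b", "c"), edges=(), ar_self=0.0)
        ts = simulate_var(spec, 4000, seed=5)
        x = ts.data
        assert abs(x.mean()) < 3 / np.sqrt(x.size)
        for col in x.T:
            lag1 = np.corrcoef(col[:-1], col[1:])[0, 1]
            assert abs(lag1) < 3 / np.sqrt(len(col))

    def test_seeded_determinism(self, unidirectional_spec):
        a = simulate_var(unidirectional_spec, 500, seed=7)
        b = simulate_var(unidirectional_spec, 500, seed=7)
        assert a.data.tobytes() == b.data.tobytes()
        c = simulate_var(unidirectional_spec, 500, seed=8)
        assert a.data.tobytes() != c.data.tobytes()

    def test_lag1_cross_covariance_matches_yule_walker(
        self, unidirectional_spec, long_unidirectional_series
    ):
        # oracle: stationary covariance of the companion process from the
        # discrete Lyapunov equation, independent of the simulator
        a1 = unidirectional_spec.coeff_matrices()[0]
        sigma = unidirectional_spec.sigma()
        gamma0 = linalg.solve_discrete_lyapunov(a1, sigma)
        gamma1 = a1 @ gamma0  # cov(x_t, x_{t-1})
        expected = gamma1[1, 0]  # cov(y_t, x_{t-1})
        x = long_unidirectional_series.data
        observed = np.mean(x[1:, 1] * x[:-1, 0])
        assert observed == pytest.approx(expected, rel=0.05)

    def test_nonstationary_spec_rejected_with_radius(self):
        spec = NetworkSpec(
            region_names=("x", "y"),
            edges=(("x", "y", 0.9, 1), ("y", "x", 0.9, 1)),
            ar_self=0.5,
        )
        radius = companion_spectral_radius(spec.coeff_matrices())
        assert radius >= 1.0
        with pytest.raises(ValueError, match=f"{radius:.4f}"):
            simulate_var(spec, 200, seed=0)

    def test_non_positive_definite_innovations_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        spec = NetworkSpec(region_names=("x", "y"), edges=(), ar_self=0.2, innovation_cov=bad)
        with pytest.raises(ValueError, match="positive definite"):
            simulate_var(spec, 200, seed=0)

    def test_short_series_and_short_burnin_rejected(self, unidirectional_spec):
        with pytest.raises(ValueError, match="n_samples"):
            simulate_var(unidirectional_spec, 30, seed=0)
        with pytest.raises(ValueError, match="burn_in"):
            simulate_var(unidirectional_spec, 100, burn_in=3, seed=0)


class TestGroupScenario:
    def test_decoupled_scenario_has_zero_ground_truth_gc(self, base_network):
        # with coupling_scale 0 the generating process is diagonal, so the
        # true directed GC of every bivariate sub-process is exactly 0
        scaled = base_network.scaled(0.0)
        coeffs = scaled.coeff_matrices()
        off_diag = coeffs - np.stack([np.diag(np.diag(c)) for c in coeffs])
        assert np.all(off_diag == 0.0)
        freqs = default_freq_grid(scaled.tr_s, 64)
        names = list(scaled.region_names)
        i, j = names.index("LM1"), names.index("SMA")
        from lfo_gcnet.spectral import VarModel

        sub = VarModel(
            order_p=coeffs.shape[0],
            coeffs=coeffs[:, [i, j]][:, :, [i, j]],
            noise_cov=scaled.sigma()[np.ix_([i, j], [i, j])],
        )
        gc = gc_spectra_from_model(sub, freqs, scaled.tr_s)
        assert np.max(gc.m_1_to_2) == 0.0
        assert np.max(gc.m_2_to_1) == 0.0

    def test_destabilizing_scale_rejected(self, base_network):
        with pytest.raises(ValueError, match="spectral radius"):
            make_group_scenario(GroupScenario("AB", 2, coupling_scale=2.0, seed=0), base_network)

    def test_scenario_determinism_and_labels(self, base_network):
        sc = GroupScenario("MP", 3, seed=42)
        a = make_group_scenario(sc, base_network)
        b = make_group_scenario(sc, base_network)
        assert all(x.data.tobytes() == y.data.tobytes() for x, y in zip(a, b))
        assert [x.group_label for x in a] == ["MP"] * 3
        assert a[0].n_samples == 130  # stroke session length
        assert a[0].data.tobytes() != a[1].data.tobytes()

    def test_ab_group_power_peaks_in_dominant_band(self, base_network):
        """Group-mean parametric power of SMA peaks inside 0.06-0.08 Hz, and
        the majority of regions peak there too (the weaker regions' spectra
        have a competing low-frequency lobe; see the methods note)."""
        subs = make_group_scenario(GroupScenario("AB", 13, seed=11), base_network)
        freqs = default_freq_grid(2.0)
        powers = []
        for ts in subs:
            filt = detrend_bandpass(ts)
            order = select_order(filt, p_max=6).order_p
            powers.append(spectral_matrix(fit_var(filt, order), freqs, 2.0).power)
        mean_power = np.mean(powers, axis=0)
        sma = list(base_network.region_names).index("SMA")
        peak = peak_frequency(freqs, mean_power[:, sma], band=(0.04, 0.1))
        assert 0.06 <= peak <= 0.08
        in_band = sum(
            0.06 <= peak_frequency(freqs, mean_power[:, r], band=(0.04, 0.1)) <= 0.08
            for r in range(mean_power.shape[1])
        )
        assert in_band >= 3

    def test_stronger_coupling_gives_larger_edge_gc(self, base_network):
        """Mean integrated GC over the true edges is larger at scale 0.8 than
        at 0.2 in >= 95% of replicate scenario pairs."""
        n_rep, n_sub, t_len = 100, 13, 237
        pairs_to_fit = sorted({tuple(sorted(e)) for e in GROUND_TRUTH_EDGES})
        wins = 0
        for rep in range(n_rep):
            means = {}
            for scale, label in ((0.2, "lo"), (0.8, "hi")):
                subs = make_group_scenario(
                    GroupScenario("SS", n_sub, coupling_scale=scale,
                                  n_samples=t_len, seed=9_000 + rep),
                    base_network,
                )
                filt = [detrend_bandpass(ts) for ts in subs]
                total = 0.0
                for p1, p2 in pairs_to_fit:
                    x = np.stack([ts.pair_data((p1, p2)) for ts in filt])
                    i12, i21 = batch_pair_igc(x, 3, 2.0)
                    for s, d in GROUND_TRUTH_EDGES:
                        if tuple(sorted((s, d))) == (p1, p2):
                            total += (i12 if s == p1 else i21).mean()
                means[label] = total / len(GROUND_TRUTH_EDGES)
            wins += means["hi"] > means["lo"]
        assert wins >= 95


class TestMotion:
    def test_no_violators_all_kept(self):
        records = simulate_motion(100, 10, violator_fraction=0.0, seed=1)
        assert all(motion_exclude(r).keep for r in records)

    def test_all_violators_none_kept(self):
        records = simulate_motion(100, 10, violator_fraction=1.0, seed=1)
        assert not any(motion_exclude(r).keep for r in records)

    def test_four_of_seventeen_excluded(self):
        """The able-bodied cohort: 4 of 17 exceed the motion limits."""
        records = simulate_motion(237, 17, violator_fraction=4 / 17, seed=3)
        kept = sum(motion_exclude(r).keep for r in records)
        assert kept == 13

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            simulate_motion(50, 5, violator_fraction=1.2, seed=0)


class TestBehavior:
    def test_noiseless_scores_are_collinear(self):
        dgc = [0.1, 0.2, 0.3]
        raw = simulate_behavior(dgc, slope=1.0, intercept=0.0, noise_sd=0.0,
                                seed=0, round_to_int=False)
        r, _ = stats.pearsonr(raw, dgc)
        assert r == pytest.approx(1.0)

    def test_scores_are_integer_rounded_half_away(self):
        out = simulate_behavior([0.05, -0.05], slope=10.0, intercept=0.0,
                                noise_sd=0.0, seed=0)
        assert out.tolist() == [1.0, -1.0]  # 0.5 -> 1, -0.5 -> -1

    def test_null_slope_gives_uniform_pvalues(self):
        rng = np.random.default_rng(17)
        pvals = []
        for rep in range(200):
            dgc = rng.normal(0, 0.1, size=20)
            dfma = simulate_behavior(dgc, slope=0.0, intercept=5.0, noise_sd=3.0,
                                     seed=rep, round_to_int=False)
            pvals.append(stats.pearsonr(dfma, dgc)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_of_correlation_at_stated_effect(self):
        """slope 40, noise 2, n = 50: the correlation rejects at alpha = 0.05
        in >= 95% of 500 replicates."""
        from lfo_gcnet import correlate_brain_behavior

        rng = np.random.default_rng(23)
        hits = 0
        for rep in range(500):
            dgc = rng.normal(0, 0.1, size=50)
            dfma = simulate_behavior(dgc, slope=40.0, intercept=2.0, noise_sd=2.0, seed=rep)
            _, p = correlate_brain_behavior(dfma, dgc)
            hits += p < 0.05
        assert hits >= 475

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_behavior([0.1], 1.0, 0.0, -1.0, seed=0)
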