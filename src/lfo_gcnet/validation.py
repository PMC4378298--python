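"""Study-level validation experiments with known ground truth.

These are the package's self-checks: estimator behavior under the exact
decoupled null (type-I calibration of the permutation threshold), agreement
with the plug-in truth for a known unidirectional system, recovery of the
four-group ordering and of the seven true connections in the synthetic
motor-network study, and the preprocessing contracts. Each experiment is
deterministic given its seed and sized to run on a single CPU in minutes.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from . import preprocess as pre
from . import spectral as spec
from . import stats as gs
from . import synthetic as syn

__all__ = [
    "type_i_error_calibration",
    "null_gc_ceiling",
    "plugin_oracle_errors",
    "eq1_identity_residual",
    "group_ordering_experiment",
    "edge_detection_experiment",
    "preprocessing_contracts",
    "printed_table_results",
]

TR = 2.0
BAND = pre.DEFAULT_BAND_HZ
ORDER = 3  # shared low order for band-limited data (see docs/methods.md)


def _decoupled_pair(ar_self: float = 0.5) -> syn.NetworkSpec:
    return syn.NetworkSpec(region_names=("x", "y"), edges=(), ar_self=ar_self, tr_s=TR)


def _unidirectional_pair(c: float = 0.4) -> syn.NetworkSpec:
    return syn.NetworkSpec(
        region_names=("x", "y"), edges=(("x", "y", c, 1),), ar_self=0.5, tr_s=TR
    )


def type_i_error_calibration(
    n_replicates: int = 200,
    n_subjects: int = 6,
    t_len: int = 237,
    n_perm: int = 1000,
    alpha: float = 0.01,
    order_p: int = ORDER,
    seed: int = 0,
) -> dict[str, Any]:
    """Empirical type-I error of the permutation threshold on the exact null.

    Per replicate: ``n_subjects`` independent decoupled pairs, the pooled
    permutation threshold, and the fraction of unpermuted directed iGC
    values above it. Returns the fraction pooled over all replicates
    (expected ~= alpha when the threshold is calibrated).
    """
    null = _decoupled_pair()
    root = np.random.SeedSequence(seed)
    exceed = 0
    total = 0
    for rep, child in enumerate(root.spawn(n_replicates)):
        arrays = [
            syn.simulate_var(null, t_len, seed=s).data
            for s in child.spawn(n_subjects)
        ]
        thr = gs.permutation_threshold(
            arrays, TR, n_perm=n_perm, alpha=alpha, seed=rep, order_p=order_p
        ).threshold
        i12, i21 = spec.batch_pair_igc(np.stack(arrays), order_p, TR, band=BAND)
        vals = np.concatenate([i12, i21])
        exceed += int((vals > thr).sum())
        total += vals.size
    return {"type_i_error": exceed / total, "alpha": alpha, "n_values": total}


def null_gc_ceiling(t_len: int = 10_000, seed: int = 0, order_p: int = ORDER) -> dict[str, float]:
    """Maximum of the directed GC spectra for a long decoupled simulation."""
    ts = syn.simulate_var(_decoupled_pair(), t_len, seed=seed)
    gc = spec.pairwise_gc(ts, ("x", "y"), order_p=order_p)
    return {
        "max_m_1_to_2": float(gc.m_1_to_2.max()),
        "max_m_2_to_1": float(gc.m_2_to_1.max()),
        "n_samples": t_len,
    }


def plugin_oracle_errors(t_len: int = 10_000, seed: int = 0) -> dict[str, float]:
    """Estimated GC spectra vs the plug-in truth for a unidirectional system.

    Also checks the Geweke spectral-temporal equivalence: the mean of the
    directed spectrum over (0, Nyquist] vs the time-domain log variance
    ratio from nested regressions.
    """
    model_spec = _unidirectional_pair()
    ts = syn.simulate_var(model_spec, t_len, seed=seed)
    freqs = spec.default_freq_grid(TR)
    est = spec.pairwise_gc(ts, ("x", "y"), order_p=1)
    truth = spec.gc_spectra_from_model(
        spec.VarModel(1, model_spec.coeff_matrices(), model_spec.sigma()), freqs, TR
    )
    rel = np.abs(est.m_1_to_2 - truth.m_1_to_2) / truth.m_1_to_2

    y, x = ts.data[:, 1], ts.data[:, 0]
    beta_r = np.linalg.lstsq(y[:-1, None], y[1:], rcond=None)[0]
    var_r = np.var(y[1:] - y[:-1] * beta_r[0])
    z = ts.data[:-1]
    beta_f = np.linalg.lstsq(z, y[1:], rcond=None)[0]
    var_f = np.var(y[1:] - z @ beta_f)
    time_domain = float(np.log(var_r / var_f))
    spectral_mean = float(spec.integrate_gc(freqs, est.m_1_to_2, freqs[0], freqs[-1]))
    return {
        "max_rel_err_vs_plugin": float(rel.max()),
        "max_reverse_gc": float(est.m_2_to_1.max()),
        "spectral_mean": spectral_mean,
        "time_domain_gc": time_domain,
        "spectral_temporal_rel_err": abs(spectral_mean - time_domain) / time_domain,
    }


def eq1_identity_residual(seed: int = 0, t_len: int = 237) -> dict[str, float]:
    """Max |M_total - M_1->2 - M_2->1 - M_inst| over all 10 pairs and all
    512 grid frequencies for one synthetic five-region subject."""
    from itertools import combinations

    base = syn.default_network()
    ts = pre.detrend_bandpass(
        syn.make_group_scenario(syn.GroupScenario("AB", 1, seed=seed), base)[0]
    )
    worst = 0.0
    for pair in combinations(ts.region_names, 2):
        gc = spec.pairwise_gc(ts, pair, order_p=ORDER)
        resid = np.abs(gc.m_total - gc.m_1_to_2 - gc.m_2_to_1 - gc.m_inst)
        worst = max(worst, float(resid.max()))
    return {"max_abs_residual": worst, "n_pairs": 10}


def _network_values(
    base: syn.NetworkSpec, scale: float, n_subjects: int, t_len: int, seed
) -> np.ndarray:
    """Per-subject network sums (the seven true connections) for one cohort."""
    subs = syn.make_group_scenario(
        syn.GroupScenario(
            "SS", n_subjects, coupling_scale=scale, n_samples=t_len,
            seed=seed if isinstance(seed, int) else int(seed.generate_state(1)[0]) % 2**31,
        ),
        base,
    )
    filt = [pre.detrend_bandpass(ts) for ts in subs]
    edges = list(syn.GROUND_TRUTH_EDGES)
    pairs = sorted({tuple(sorted(e)) for e in edges})
    vals = np.zeros(n_subjects)
    for p1, p2 in pairs:
        x = np.stack([ts.pair_data((p1, p2)) for ts in filt])
        i12, i21 = spec.batch_pair_igc(x, ORDER, TR, band=BAND)
        for s, d in edges:
            if tuple(sorted((s, d))) == (p1, p2):
                vals += i12 if s == p1 else i21
    return vals


def group_ordering_experiment(
    n_replicates: int = 100, t_len: int = 237, seed: int = 0
) -> dict[str, Any]:
    """Four-group synthetic study: does the network ordering of the clinical
    groups reproduce? Coupling scales AB 1.0, SS 0.2, MP 0.3, MP+PT 0.8;
    13/13/6/7 subjects; equal session lengths (see docs/methods.md)."""
    base = syn.default_network()
    root = np.random.SeedSequence([seed, 101])
    ab_ss_sig = 0
    mppt_gt_mp = 0
    diffs = []
    for child in root.spawn(n_replicates):
        s = child.spawn(4)
        ab = _network_values(base, 1.0, 13, t_len, s[0])
        ss = _network_values(base, 0.2, 13, t_len, s[1])
        mp = _network_values(base, 0.3, 6, t_len, s[2])
        mppt = _network_values(base, 0.8, 7, t_len, s[3])
        t, p = gs.network_ttest(ab, ss)
        ab_ss_sig += int(p < 0.05 and ab.mean() > ss.mean())
        mppt_gt_mp += int(mppt.mean() > mp.mean())
        diffs.append(mppt.mean() - mp.mean())
    return {
        "ab_gt_ss_significant_rate": ab_ss_sig / n_replicates,
        "mppt_gt_mp_rate": mppt_gt_mp / n_replicates,
        "mean_mppt_minus_mp": float(np.mean(diffs)),
        "n_replicates": n_replicates,
    }


def edge_detection_experiment(
    n_replicates: int = 6,
    n_perm: int = 1000,
    alpha: float = 0.01,
    t_len: int = 237,
    seed: int = 0,
) -> dict[str, Any]:
    """Fraction of the seven true connections whose able-bodied group-mean
    integrated GC exceeds the permutation threshold (pooled AB + SS, 26
    subjects, as in the reference analysis)."""
    base = syn.default_network()
    root = np.random.SeedSequence([seed, 202])
    hits = 0
    total = 0
    for rep, child in enumerate(root.spawn(n_replicates)):
        s = child.spawn(2)
        ab = [
            pre.detrend_bandpass(ts)
            for ts in syn.make_group_scenario(
                syn.GroupScenario("AB", 13, seed=int(s[0].generate_state(1)[0]) % 2**31),
                base,
            )
        ]
        ss = [
            pre.detrend_bandpass(ts)
            for ts in syn.make_group_scenario(
                syn.GroupScenario(
                    "SS", 13, n_samples=t_len,
                    seed=int(s[1].generate_state(1)[0]) % 2**31,
                ),
                base,
            )
        ]
        pool = ab + ss
        for src, dst in syn.GROUND_TRUTH_EDGES:
            thr = gs.permutation_threshold(
                [t.pair_data((src, dst)) for t in pool],
                TR,
                n_perm=n_perm,
                alpha=alpha,
                seed=1000 * rep + total,
                order_p=ORDER,
            ).threshold
            igc = spec.batch_pair_igc(
                np.stack([t.pair_data((src, dst)) for t in ab]), ORDER, TR, band=BAND
            )[0].mean()
            hits += int(igc > thr)
            total += 1
    return {
        "detection_rate": hits / total,
        "n_edge_tests": total,
        "pool_size": len(pool),
    }


def preprocessing_contracts(seed: int = 0) -> dict[str, float]:
    """The three desk-checkable preprocessing contracts."""
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    mask = pre.sphere_mask(
        pre.RoiDefinition("probe", (30.0, 30.0, 30.0), 6.0), affine, (30, 30, 30)
    )
    records = syn.simulate_motion(237, 17, violator_fraction=4 / 17, seed=seed)
    kept = sum(pre.motion_exclude(r).keep for r in records)

    t = np.arange(4000) * TR
    x = np.sin(2 * np.pi * 0.01 * t)[:, None]
    out = pre.detrend_bandpass(pre.RoiTimeSeries(x, TR, ["probe"])).data[:, 0]
    attenuation_pct = 100.0 * (1.0 - np.std(out) / np.std(x))
    return {
        "sphere_mask_voxels": int(mask.sum()),
        "subjects_kept_of_17": int(kept),
        "rms_attenuation_pct_at_0p01hz": float(attenuation_pct),
    }


def printed_table_results() -> dict[str, float]:
    """Reproductions from the packaged clinical tables."""
    records = gs.load_clinical_tables()
    mp = [r for r in records if r.intervention == "MP"]
    mppt = [r for r in records if r.intervention == "MPPT"]
    r, p = gs.correlate_brain_behavior(
        [x.delta_fma for x in mppt], [x.delta_gc["SMA->LPMC"] for x in mppt]
    )
    _, p_mppt = gs.paired_delta_ttest([x.delta_fma for x in mppt])
    _, p_mp = gs.paired_delta_ttest([x.delta_fma for x in mp])
    return {
        "pearson_r_mppt_sma_lpmc": float(r),
        "pearson_p_mppt_sma_lpmc": float(p),
        "paired_p_mppt_dfma": float(p_mppt),
        "paired_p_mp_dfma": float(p_mp),
        "mean_age_years": float(np.mean([x.age_years for x in records])),
        "max_post_stroke_months": max(x.post_stroke_months for x in records),
        "n_stroke_participants": len(records),
    }
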