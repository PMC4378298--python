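"""End-to-end study orchestration.

Composes the stages in acquisition order: generate (or load) ROI series ->
motion exclusion -> detrend + band-pass -> per-pair GC spectra and power ->
band integration -> permutation thresholds -> group comparisons (percent
difference / modulation, network t-tests) -> brain-behavior correlation.
Emits a JSON-serializable result bundle with provenance (config hash, seed)
plus TSV tables mirroring the figures' numeric content.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import preprocess as pre
from . import spectral as spec
from . import stats as gs
from . import synthetic as syn

__all__ = ["StudyConfig", "run_study", "report", "save_bundle"]

logger = logging.getLogger(__name__)

GROUPS = ("AB", "SS", "MP", "MPPT")


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    mode: str = "synthetic"  # synthetic | files
    seed: int = 0
    band_hz: tuple[float, float] = pre.DEFAULT_BAND_HZ
    alpha: float = 0.01
    n_perm: int = 1000
    # Band-passed series have no finite true order, so AIC saturates at
    # p_max; a low cap limits the filtering-induced bias of the GC estimate.
    p_max: int = 3
    # a 0.02 Hz-wide spectral bump needs ~6 poles to localize; >= 8 drives
    # the fitted roots onto the unit circle
    power_p_max: int = 6
    order_criterion: str = "AIC"
    n_freqs: int = spec.DEFAULT_N_FREQS
    # synthetic-mode cohort structure
    n_ab_recruited: int = 17
    n_ab_motion_violators: int = 4
    n_mp: int = 6
    n_mppt: int = 7
    coupling: float = 0.38
    # Equal session lengths across groups isolate coupling effects from the
    # T-dependent bias of GC on filtered data; set False for the clinical
    # acquisition lengths (AB 237, stroke 130).
    equal_session_length: bool = True
    coupling_scales: dict[str, float] = field(
        default_factory=lambda: dict(syn.GROUP_COUPLING_SCALES)
    )
    behavior_slope: float = 40.0
    behavior_intercept: float = 2.0
    behavior_noise_sd: float = 2.0
    behavior_connection: str = "SMA->LPMC"
    # files-mode inputs
    series_dir: str | None = None
    table1_path: str | None = None
    table2_path: str | None = None
    allow_unfiltered: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly inside (0, 1)")
        if self.band_hz[0] <= 0 or self.band_hz[0] >= self.band_hz[1]:
            raise ValueError("band must satisfy 0 < f1 < f2")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _connection_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}->{pair[1]}"


def _subject_igc(
    series: pre.RoiTimeSeries, cfg: StudyConfig
) -> tuple[dict[str, float], dict[str, int], np.ndarray]:
    """Integrated GC for all 20 ordered pairs plus parametric power spectra."""
    if not series.filtered and not cfg.allow_unfiltered:
        raise ValueError(
            f"subject {series.subject_id}: refusing to run GC on unfiltered "
            f"data (set allow_unfiltered to override)"
        )
    freqs = spec.default_freq_grid(series.tr_s, cfg.n_freqs)
    igc: dict[str, float] = {}
    orders: dict[str, int] = {}
    for r1, r2 in combinations(series.region_names, 2):
        g = spec.pairwise_gc(
            series, (r1, r2), freqs_hz=freqs, order_p="aic", p_max=cfg.p_max
        )
        igc[_connection_label((r1, r2))] = float(
            spec.integrate_gc(freqs, g.m_1_to_2, *cfg.band_hz)
        )
        igc[_connection_label((r2, r1))] = float(
            spec.integrate_gc(freqs, g.m_2_to_1, *cfg.band_hz)
        )
        orders[f"{r1}|{r2}"] = g.model.order_p
    # region power from the full R-dimensional fit
    sel = spec.select_order(series, p_max=cfg.power_p_max, criterion=cfg.order_criterion)
    model = spec.fit_var(series, sel.order_p)
    power = spec.spectral_matrix(model, freqs, series.tr_s).power
    return igc, orders, power


def _simulate_cohorts(cfg: StudyConfig) -> dict[str, Any]:
    """Generate the four cohorts; stroke subjects get pre and post sessions."""
    base = syn.default_network(coupling=cfg.coupling)
    rng_seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    t_stroke = syn.GROUP_N_SAMPLES["AB"] if cfg.equal_session_length else None

    ab_all = syn.make_group_scenario(
        syn.GroupScenario(
            "AB", cfg.n_ab_recruited, cfg.coupling_scales["AB"],
            seed=int(rng_seeds[0].generate_state(1)[0]) % 2**31,
        ),
        base,
    )
    motion = syn.simulate_motion(
        n_volumes=syn.GROUP_N_SAMPLES["AB"],
        n_subjects=cfg.n_ab_recruited,
        violator_fraction=cfg.n_ab_motion_violators / cfg.n_ab_recruited,
        seed=int(rng_seeds[1].generate_state(1)[0]) % 2**31,
    )
    excluded = []
    ab = []
    for ts, mo in zip(ab_all, motion):
        decision = pre.motion_exclude(mo, n_samples=ts.n_samples)
        if decision.keep:
            ab.append(ts)
        else:
            excluded.append(
                {
                    "subject_id": ts.subject_id,
                    "axis": decision.offending_axis,
                    "volume": decision.offending_volume,
                }
            )
    n_stroke = cfg.n_mp + cfg.n_mppt
    ss = syn.make_group_scenario(
        syn.GroupScenario(
            "SS", n_stroke, cfg.coupling_scales["SS"], n_samples=t_stroke,
            seed=int(rng_seeds[2].generate_state(1)[0]) % 2**31,
        ),
        base,
    )
    mp = syn.make_group_scenario(
        syn.GroupScenario(
            "MP", cfg.n_mp, cfg.coupling_scales["MP"], n_samples=t_stroke,
            seed=int(rng_seeds[3].generate_state(1)[0]) % 2**31,
        ),
        base,
    )
    mppt = syn.make_group_scenario(
        syn.GroupScenario(
            "MPPT", cfg.n_mppt, cfg.coupling_scales["MPPT"], n_samples=t_stroke,
            seed=int(rng_seeds[4].generate_state(1)[0]) % 2**31,
        ),
        base,
    )
    return {
        "AB": ab,
        "SS": ss,
        "MP": mp,
        "MPPT": mppt,
        "excluded": excluded,
        "behavior_seed": int(rng_seeds[5].generate_state(1)[0]) % 2**31,
        "true_edges": [
            _connection_label((s, t)) for s, t in syn.GROUND_TRUTH_EDGES
        ],
    }


def _load_cohorts(cfg: StudyConfig) -> dict[str, Any]:
    if cfg.series_dir is None:
        return {g: [] for g in GROUPS} | {"excluded": [], "true_edges": []}
    series = [
        pre.read_roi_timeseries(p)
        for p in sorted(Path(cfg.series_dir).glob("*.tsv"))
    ]
    out: dict[str, Any] = {g: [] for g in GROUPS}
    for ts in series:
        if ts.group_label not in GROUPS:
            raise ValueError(
                f"subject {ts.subject_id}: unknown group {ts.group_label!r}"
            )
        out[ts.group_label].append(ts)
    out["excluded"] = []
    out["true_edges"] = []
    return out


def run_study(config: StudyConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the result bundle."""
    cfg = config
    bundle: dict[str, Any] = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "warnings": [],
    }

    # --- stage: generate / load ------------------------------------------
    stage = "generate"
    try:
        cohorts = _simulate_cohorts(cfg) if cfg.mode == "synthetic" else _load_cohorts(cfg)
        bundle["excluded_subjects"] = cohorts["excluded"]
        bundle["true_edges"] = cohorts["true_edges"]

        # --- stage: preprocess -------------------------------------------
        stage = "preprocess"
        groups: dict[str, list[pre.RoiTimeSeries]] = {}
        for g in GROUPS:
            groups[g] = [
                ts if ts.filtered else pre.detrend_bandpass(ts, *cfg.band_hz)
                for ts in cohorts[g]
            ]

        # --- stage: spectra + integration --------------------------------
        stage = "gc"
        igc_tables: dict[str, pd.DataFrame] = {}
        power_mean: dict[str, np.ndarray] = {}
        freqs = None
        for g in GROUPS:
            rows, powers = [], []
            for ts in groups[g]:
                if freqs is None:
                    freqs = spec.default_freq_grid(ts.tr_s, cfg.n_freqs)
                igc, _orders, power = _subject_igc(ts, cfg)
                rows.append({"subject_id": ts.subject_id, **igc})
                powers.append(power)
            igc_tables[g] = pd.DataFrame(rows)
            if powers:
                power_mean[g] = np.mean(powers, axis=0)
        bundle["freqs_hz"] = freqs.tolist() if freqs is not None else []
        region_names = list(groups["AB"][0].region_names) if groups["AB"] else []
        bundle["region_names"] = region_names
        bundle["igc"] = {g: df.to_dict("records") for g, df in igc_tables.items()}
        bundle["power_peaks_hz"] = {
            g: {
                name: spec.peak_frequency(freqs, power_mean[g][:, i])
                for i, name in enumerate(region_names)
            }
            for g in power_mean
        }

        # --- stage: permutation thresholds --------------------------------
        stage = "thresholds"
        connections = bundle["true_edges"] or [
            _connection_label(p) for p in gs.SIGNIFICANT_CONNECTIONS
        ]
        pool = groups["AB"] + groups["SS"]
        thresholds: dict[str, float] = {}
        if pool:
            perm_root = np.random.SeedSequence([cfg.seed, 7]).generate_state(
                len(connections)
            )
            for conn, s in zip(connections, perm_root):
                src, dst = conn.split("->")
                res = gs.permutation_threshold(
                    pool,
                    pool[0].tr_s,
                    pair=(src, dst),
                    n_perm=cfg.n_perm,
                    alpha=cfg.alpha,
                    seed=int(s) % 2**31,
                    band=cfg.band_hz,
                    order_p=cfg.p_max,
                    n_freqs=cfg.n_freqs,
                )
                thresholds[conn] = res.threshold
        bundle["thresholds"] = thresholds
        bundle["pool_size"] = len(pool)

        # per-connection significance of the group-mean integrated flow
        significant: dict[str, dict[str, Any]] = {}
        for g in GROUPS:
            df = igc_tables[g]
            significant[g] = {}
            for conn, thr in thresholds.items():
                if df.empty or conn not in df:
                    continue
                mean_igc = float(df[conn].mean())
                significant[g][conn] = {
                    "igc": mean_igc,
                    "threshold": thr,
                    "significant": bool(mean_igc > thr),
                }
        bundle["group_igc"] = significant

        # --- stage: group comparisons -------------------------------------
        stage = "group"
        d_pct, m_mp, m_mppt = {}, {}, {}
        for conn in connections:
            have = all(not igc_tables[g].empty and conn in igc_tables[g] for g in GROUPS)
            if not have:
                continue
            ab_v = float(igc_tables["AB"][conn].mean())
            ss_v = float(igc_tables["SS"][conn].mean())
            mp_v = float(igc_tables["MP"][conn].mean())
            mppt_v = float(igc_tables["MPPT"][conn].mean())
            if ab_v > 0:
                d_pct[conn] = gs.percent_difference(ss_v, ab_v)
            if mp_v != 0:
                m_mp[conn] = gs.percent_modulation(mp_v, ss_v)
            if mppt_v != 0:
                m_mppt[conn] = gs.percent_modulation(mppt_v, ss_v)
        bundle["percent_difference"] = d_pct
        bundle["percent_modulation"] = {"MP": m_mp, "MPPT": m_mppt}

        def network_values(g: str) -> np.ndarray:
            df = igc_tables[g]
            cols = [c for c in connections if c in df]
            return df[cols].sum(axis=1).to_numpy() if not df.empty and cols else np.array([])

        net = {g: network_values(g) for g in GROUPS}
        net_tests = {}
        for a, b in (("AB", "SS"), ("SS", "MP"), ("SS", "MPPT"), ("MP", "MPPT")):
            if net[a].size >= 2 and net[b].size >= 2:
                t, p = gs.network_ttest(net[a], net[b])
                net_tests[f"{a}_vs_{b}"] = {"t": t, "p": p, "n": [int(net[a].size), int(net[b].size)]}
        bundle["network_ttests"] = net_tests

        # --- stage: brain-behavior -----------------------------------------
        stage = "behavior"
        if cfg.mode == "synthetic" and not igc_tables["SS"].empty:
            conn = cfg.behavior_connection
            n_stroke = cfg.n_mp + cfg.n_mppt
            pre_vals = igc_tables["SS"][conn].to_numpy()
            post_vals = np.concatenate(
                [igc_tables["MP"][conn].to_numpy(), igc_tables["MPPT"][conn].to_numpy()]
            )
            delta_gc = post_vals - pre_vals[:n_stroke]
            delta_fma = syn.simulate_behavior(
                delta_gc,
                cfg.behavior_slope,
                cfg.behavior_intercept,
                cfg.behavior_noise_sd,
                seed=cohorts["behavior_seed"],
            )
            mp_slice = slice(0, cfg.n_mp)
            mppt_slice = slice(cfg.n_mp, n_stroke)
            behavior = {"connection": conn}
            for label, sl in (("MP", mp_slice), ("MPPT", mppt_slice)):
                t, p = gs.paired_delta_ttest(delta_fma[sl])
                entry = {
                    "delta_fma": delta_fma[sl].tolist(),
                    "delta_gc": delta_gc[sl].tolist(),
                    "paired_t": t,
                    "paired_p": p,
                }
                if delta_fma[sl].size >= 3:  # Pearson needs n >= 3
                    r, rp = gs.correlate_brain_behavior(delta_fma[sl], delta_gc[sl])
                    entry["pearson_r"] = r
                    entry["pearson_p"] = rp
                behavior[label] = entry
            bundle["behavior"] = behavior
        else:
            bundle["behavior"] = clinical_behavior_block(
                cfg.table1_path, cfg.table2_path
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if cfg.out_dir:
        save_bundle(bundle, cfg.out_dir)
    return bundle


def clinical_behavior_block(
    table1_path: str | None = None, table2_path: str | None = None
) -> dict[str, Any]:
    """Paired tests and brain-behavior correlations from the clinical tables."""
    records = gs.load_clinical_tables(table1_path, table2_path)
    block: dict[str, Any] = {"connection": "SMA->LPMC", "n_participants": len(records)}
    for label in ("MP", "MPPT"):
        sub = [r for r in records if r.intervention == label]
        dfma = [r.delta_fma for r in sub]
        t, p = gs.paired_delta_ttest(dfma)
        entry: dict[str, Any] = {"delta_fma": dfma, "paired_t": t, "paired_p": p}
        for conn in sorted({k for r in sub for k in r.delta_gc}):
            dgc = [r.delta_gc[conn] for r in sub]
            r_, p_ = gs.correlate_brain_behavior(dfma, dgc)
            entry[f"pearson_{conn}"] = {"r": r_, "p": p_}
        block[label] = entry
    return block


def report(bundle: dict[str, Any], out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Render the bundle as human-readable tables (TSV when out_dir given).

    Tables mirror the figures' numeric content: integrated flow per
    connection per group with significance flags; percent difference and
    modulation; network t-tests; brain-behavior correlation.
    """
    required = ["group_igc", "percent_difference", "percent_modulation", "network_ttests"]
    missing = [k for k in required if k not in bundle]
    if missing:
        raise KeyError(f"bundle is missing stage outputs: {missing}")

    rows = []
    for g, conns in bundle["group_igc"].items():
        for conn, vals in conns.items():
            rows.append(
                {
                    "group": g,
                    "connection": conn,
                    "igc": vals["igc"],
                    "threshold": vals["threshold"],
                    "significant": "*" if vals["significant"] else "",
                }
            )
    flow = pd.DataFrame(rows)

    mod_rows = []
    for conn, d in bundle["percent_difference"].items():
        mod_rows.append({"connection": conn, "statistic": "D_SS_vs_AB", "percent": round(d)})
    for label, block in bundle["percent_modulation"].items():
        for conn, m in block.items():
            mod_rows.append(
                {"connection": conn, "statistic": f"M_{label}", "percent": round(m)}
            )
    modulation = pd.DataFrame(mod_rows)

    nets = pd.DataFrame(
        [
            {"comparison": k, "t": v["t"], "p": v["p"], "n_a": v["n"][0], "n_b": v["n"][1]}
            for k, v in bundle["network_ttests"].items()
        ]
    )

    beh_rows = []
    behavior = bundle.get("behavior", {})
    for label in ("MP", "MPPT"):
        entry = behavior.get(label)
        if not entry:
            continue
        row = {
            "group": label,
            "paired_t": entry["paired_t"],
            "paired_p": entry["paired_p"],
        }
        if "pearson_r" in entry:
            row["pearson_r"] = entry["pearson_r"]
            row["pearson_p"] = round(entry["pearson_p"], 2)
        for key, val in entry.items():
            if key.startswith("pearson_") and isinstance(val, dict):
                row[f"{key}_r"] = val["r"]
                row[f"{key}_p"] = round(val["p"], 2)
        beh_rows.append(row)
    behavior_df = pd.DataFrame(beh_rows)

    tables = {
        "integrated_flow": flow,
        "modulation": modulation,
        "network_ttests": nets,
        "behavior": behavior_df,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    return tables


def save_bundle(bundle: dict[str, Any], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "bundle.json"
    path.write_text(json.dumps(bundle, indent=1, default=float))
    return path
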