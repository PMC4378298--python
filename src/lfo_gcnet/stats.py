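"""Group-level inference on integrated causal flow and behavior.

Permutation null thresholds for directed GC, percent difference relative to
the able-bodied reference, percent modulation relative to the pre-treatment
state, network-level t-tests, paired tests on Fugl-Meyer change scores, and
the brain-behavior Pearson correlation. Also loads the packaged clinical
tables (demographics and per-participant dFMA / dGC values).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import DEFAULT_BAND_HZ, RoiTimeSeries
from .spectral import DEFAULT_N_FREQS, batch_pair_igc, select_order

__all__ = [
    "ClinicalRecord",
    "PermutationResult",
    "TestResult",
    "SIGNIFICANT_CONNECTIONS",
    "permutation_threshold",
    "percent_difference",
    "percent_modulation",
    "network_ttest",
    "paired_delta_ttest",
    "correlate_brain_behavior",
    "load_clinical_tables",
]

#: The seven connections with significant causal flow in able-bodied
#: participants: LM1<->SMA, RPMC<->SMA, RPMC->LM1, SMA->RM1, SMA->LPMC.
SIGNIFICANT_CONNECTIONS: tuple[tuple[str, str], ...] = (
    ("LM1", "SMA"),
    ("SMA", "LM1"),
    ("RPMC", "SMA"),
    ("SMA", "RPMC"),
    ("RPMC", "LM1"),
    ("SMA", "RM1"),
    ("SMA", "LPMC"),
)


class TestResult(NamedTuple):
    statistic: float
    pvalue: float


@dataclass(frozen=True)
class PermutationResult:
    threshold: float
    alpha: float
    n_perm: int
    n_null: int


@dataclass(frozen=True)
class ClinicalRecord:
    """One stroke survivor's printed clinical attributes."""

    participant_id: int
    age_years: int
    sex: str
    post_stroke_months: int
    mmse: int
    lesion_note: str
    intervention: str  # MP or MPPT
    delta_fma: int
    delta_gc: dict[str, float]

    def __post_init__(self) -> None:
        if not 0 <= self.mmse <= 30:
            raise ValueError(
                f"participant {self.participant_id}: MMSE {self.mmse} outside 0..30"
            )
        if self.intervention not in ("MP", "MPPT"):
            raise ValueError(
                f"participant {self.participant_id}: unknown intervention "
                f"{self.intervention!r}"
            )


def _pair_arrays(
    series_list: Sequence[RoiTimeSeries | np.ndarray],
    pair: tuple[str, str] | None,
) -> list[np.ndarray]:
    out = []
    for s in series_list:
        if isinstance(s, RoiTimeSeries):
            if pair is None:
                raise ValueError("pair is required with RoiTimeSeries inputs")
            out.append(s.pair_data(pair))
        else:
            arr = np.asarray(s, float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("array inputs must be T x 2")
            out.append(arr)
    return out


def permutation_threshold(
    series_list: Sequence[RoiTimeSeries | np.ndarray],
    tr_s: float,
    *,
    pair: tuple[str, str] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    order_p: int | None = None,
    n_freqs: int = DEFAULT_N_FREQS,
    perm_chunk: int = 256,
) -> PermutationResult:
    """Empirical significance threshold for integrated directed GC.

    For each permutation draw, the time indices of the second member of
    every subject's pair are randomly permuted — destroying the temporal
    (and hence causal) structure while preserving the amplitude
    distribution — the bivariate model is refitted and the band-integrated
    GC recomputed. Both directed values from each permuted fit enter the
    pooled null; the threshold is its empirical (1 - alpha) quantile.

    ``series_list`` pools the subjects of both groups under comparison (the
    reference analysis pools able-bodied and stroke participants, 26 series).
    The model order is fixed across permutations: ``order_p`` if given,
    otherwise each subject's AIC-selected order on the unpermuted pair.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm * alpha < 10:
        warnings.warn(
            f"n_perm * alpha = {n_perm * alpha:.1f} < 10: the empirical "
            f"quantile is unstable; increase n_perm",
            stacklevel=2,
        )
    arrays = _pair_arrays(series_list, pair)
    rng = np.random.default_rng(seed)

    # Group subjects by (length, order) so each group runs batched.
    keyed: dict[tuple[int, int], list[np.ndarray]] = {}
    for arr in arrays:
        p = order_p if order_p is not None else select_order(arr).order_p
        keyed.setdefault((arr.shape[0], p), []).append(arr)

    null_chunks: list[np.ndarray] = []
    for (t, p), group in keyed.items():
        stack = np.stack(group)  # (n_sub, T, 2)
        n_sub = stack.shape[0]
        done = 0
        while done < n_perm:
            chunk = min(perm_chunk, n_perm - done)
            # (chunk, n_sub, T, 2): x column kept, y column permuted per draw
            xs = np.broadcast_to(stack, (chunk, n_sub, t, 2)).copy()
            for c in range(chunk):
                for s in range(n_sub):
                    xs[c, s, :, 1] = stack[s, rng.permutation(t), 1]
            flat = xs.reshape(chunk * n_sub, t, 2)
            igc12, igc21 = batch_pair_igc(flat, p, tr_s, band=band, n_freqs=n_freqs)
            null_chunks.append(igc12)
            null_chunks.append(igc21)
            done += chunk
    null = np.concatenate(null_chunks)
    return PermutationResult(
        threshold=float(np.quantile(null, 1.0 - alpha)),
        alpha=alpha,
        n_perm=n_perm,
        n_null=int(null.size),
    )


def percent_difference(igc_ss: float, igc_ab: float) -> float:
    """Percent difference D = (iGC_SS - iGC_AB) / iGC_AB x 100%.

    The able-bodied value is the reference; a negative D means the stroke
    group's causal flow is weaker.
    """
    if igc_ab <= 0:
        raise ValueError(
            f"reference iGC_AB must be > 0 for a percent difference, got {igc_ab}"
        )
    return (igc_ss - igc_ab) / igc_ab * 100.0


def percent_modulation(igc_post: float, igc_ss: float) -> float:
    """Percent modulation M = (iGC_post - iGC_SS) / iGC_post x 100%.

    Note the asymmetry with :func:`percent_difference`: the denominator is
    the POST-treatment value, so M is bounded above by 100% but unbounded
    below.
    """
    if igc_post == 0:
        raise ValueError("post-treatment iGC must be nonzero for percent modulation")
    return (igc_post - igc_ss) / igc_post * 100.0


def network_ttest(
    igc_a: Sequence[float],
    igc_b: Sequence[float],
    paired: bool = False,
) -> TestResult:
    """t-test on per-subject network summaries (sum of the seven connections).

    Two-sample (unpaired, pooled variance) by default, matching the group
    comparisons; paired for pre/post contrasts on the same subjects.
    """
    a = np.asarray(igc_a, float)
    b = np.asarray(igc_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two subjects per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        return paired_delta_ttest(a - b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0)
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(t), float(p))


def paired_delta_ttest(deltas: Sequence[float]) -> TestResult:
    """One-sample t-test of difference scores against zero.

    t = mean / (sd / sqrt(n)), df = n - 1, two-tailed.
    """
    d = np.asarray(deltas, float)
    if d.size < 2:
        raise ValueError("need at least two difference scores")
    if d.std(ddof=1) == 0:
        warnings.warn("degenerate variance in difference scores", stacklevel=2)
        return TestResult(0.0, 1.0) if d.mean() == 0 else TestResult(np.inf, 0.0)
    t, p = sps.ttest_1samp(d, 0.0)
    return TestResult(float(t), float(p))


def correlate_brain_behavior(
    delta_fma: Sequence[float],
    delta_gc: Sequence[float],
) -> TestResult:
    """Pearson correlation between behavior change and connectivity change.

    Returns (r, two-tailed p) with p from t = r sqrt(n-2)/sqrt(1-r^2),
    df = n - 2.
    """
    x = np.asarray(delta_fma, float)
    y = np.asarray(delta_gc, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p))


_DGC_PREFIX = "dgc_"


def _packaged(name: str) -> Path:
    return Path(importlib.resources.files("lfo_gcnet").joinpath("data", name))


def load_clinical_tables(
    table1_path: str | Path | None = None,
    table2_path: str | Path | None = None,
) -> list[ClinicalRecord]:
    """Load the printed clinical tables (packaged TSV fixtures by default).

    Table 1 holds demographics (age, sex, months post-stroke, MMSE, lesion
    note); Table 2 holds per-participant dFMA and dGC for the connections
    LM1->SMA, SMA->LM1 and SMA->LPMC, split MP (6) / MP+PT (7).
    """
    t1 = pd.read_csv(table1_path or _packaged("table1_clinical.tsv"), sep="\t")
    t2 = pd.read_csv(table2_path or _packaged("table2_delta.tsv"), sep="\t")
    merged = t1.merge(t2, on="participant", validate="one_to_one")
    records = []
    for i, row in merged.iterrows():
        try:
            delta_gc = {
                col[len(_DGC_PREFIX):].replace("_to_", "->"): float(row[col])
                for col in merged.columns
                if col.startswith(_DGC_PREFIX)
            }
            records.append(
                ClinicalRecord(
                    participant_id=int(row["participant"]),
                    age_years=int(row["age_years"]),
                    sex=str(row["sex"]),
                    post_stroke_months=int(row["post_stroke_months"]),
                    mmse=int(row["mmse"]),
                    lesion_note=str(row["lesion_note"]),
                    intervention=str(row["intervention"]),
                    delta_fma=int(row["delta_fma"]),
                    delta_gc=delta_gc,
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"malformed clinical table row {i + 1}: {exc}") from exc
    allowed = {f"{s}->{t}" for s, t in SIGNIFICANT_CONNECTIONS}
    for rec in records:
        extra = set(rec.delta_gc) - allowed
        if extra:
            raise ValueError(
                f"participant {rec.participant_id}: dGC connections {extra} are "
                f"not among the seven significant connections"
            )
    return records
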