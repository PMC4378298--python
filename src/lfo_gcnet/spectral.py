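"""Parametric spectral Granger causality for low-frequency ROI time series.

The estimation chain is: ordinary-least-squares fit of a vector
autoregression (VAR) of order p, the parametric spectral matrix

    A(f) = I - sum_k A_k exp(-i 2 pi f k tr),   H(f) = A(f)^-1,
    S(f) = H(f) Sigma H(f)* . tr,

and, per region pair from a fresh bivariate fit, the Geweke decomposition of
total interdependence into two directed terms and an instantaneous term,

    M_total(f) = ln[ S11 S22 / det S(f) ]
    M_2->1(f)  = ln[ S11(f) / (Htilde11 Sigma11 Htilde11*) ],
                 Htilde11 = H11 + (Sigma12/Sigma11) H12
    M_1->2(f)  = ln[ S22(f) / (Htilde22 Sigma22 Htilde22*) ],
                 Htilde22 = H22 + (Sigma12/Sigma22) H21
    M_inst(f)  = ln[ (Htilde11 Sigma11 Htilde11*)(Htilde22 Sigma22 Htilde22*)
                     / det S(f) ]

which satisfy M_total = M_1->2 + M_2->1 + M_inst identically. Directed flow
is summarized by the band-normalized integral (trapezoidal) over the
analysis band, by default 0.04-0.1 Hz.

The one-sided x tr density convention cancels in every log-ratio; it only
affects absolute power values. A batched bivariate engine (`batch_pair_igc`)
vectorizes fit + integrated GC over many series at once; permutation nulls
and Monte-Carlo suites run through it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .preprocess import DEFAULT_BAND_HZ, RoiTimeSeries
from .synthetic import companion_spectral_radius

__all__ = [
    "VarModel",
    "SpectralResult",
    "PairGcSpectra",
    "IntegratedFlow",
    "OrderSelection",
    "default_freq_grid",
    "select_order",
    "fit_var",
    "spectral_matrix",
    "gc_spectra_from_model",
    "pairwise_gc",
    "integrate_gc",
    "peak_frequency",
    "batch_fit_bivar",
    "batch_pair_igc",
]

logger = logging.getLogger(__name__)

DEFAULT_N_FREQS = 512
DEFAULT_P_MAX = 10


@dataclass
class VarModel:
    """A fitted (or specified) vector autoregression."""

    order_p: int
    coeffs: np.ndarray  # (p, R, R)
    noise_cov: np.ndarray  # (R, R), symmetric positive definite
    n_samples_fit: int = 0
    criterion_trace: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, float)
        self.noise_cov = np.asarray(self.noise_cov, float)
        if self.coeffs.shape != (self.order_p, self.n_regions, self.n_regions):
            raise ValueError("coeffs must have shape (p, R, R)")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-8):
            raise ValueError("noise covariance must be symmetric")
        radius = companion_spectral_radius(self.coeffs)
        if radius >= 1.0:
            warnings.warn(
                f"fitted VAR is not stationary (companion spectral radius "
                f"{radius:.4f} >= 1)",
                stacklevel=2,
            )

    @property
    def n_regions(self) -> int:
        return self.coeffs.shape[1]

    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.coeffs)


@dataclass
class SpectralResult:
    """Frequency grid with spectral matrix, transfer function and power."""

    freqs_hz: np.ndarray  # (F,)
    S: np.ndarray  # (F, R, R) complex
    H: np.ndarray  # (F, R, R) complex
    power: np.ndarray  # (F, R) real, diag of S
    region_names: Sequence[str] | None = None


class PairGcSpectra(NamedTuple):
    """The four Geweke interdependence spectra for one region pair."""

    freqs_hz: np.ndarray
    m_total: np.ndarray
    m_1_to_2: np.ndarray
    m_2_to_1: np.ndarray
    m_inst: np.ndarray
    pair: tuple[str, str]
    model: VarModel


@dataclass(frozen=True)
class IntegratedFlow:
    """Band-integrated causal flow for one ordered pair."""

    pair: tuple[str, str]
    igc: float
    band: tuple[float, float]
    threshold: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if self.band[0] >= self.band[1]:
            raise ValueError("band must satisfy f1 < f2")
        if self.igc < 0:
            raise ValueError("integrated GC must be >= 0")


class OrderSelection(NamedTuple):
    order_p: int
    criterion: str
    trace: dict[int, float]


def default_freq_grid(tr_s: float, n_freqs: int = DEFAULT_N_FREQS) -> np.ndarray:
    """Evenly spaced grid of ``n_freqs`` points on (0, Nyquist]."""
    nyq = 0.5 / tr_s
    return np.linspace(0.0, nyq, n_freqs + 1)[1:]


def _as_array(series) -> np.ndarray:
    if isinstance(series, RoiTimeSeries):
        return series.data
    return np.asarray(series, float)


def _lagged_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack p lags: Y = rows p..T-1, Z columns ordered lag-1 .. lag-p."""
    t, r = x.shape
    z = np.concatenate([x[p - k : t - k] for k in range(1, p + 1)], axis=1)
    return x[p:], z


def fit_var(series, order_p: int) -> VarModel:
    """OLS fit of a VAR(p): each time point regressed on its p predecessors.

    No intercept is included — inputs are expected detrended/filtered and
    hence zero-mean. The noise covariance uses the unbiased denominator
    T - p - R*p.
    """
    x = _as_array(series)
    t, r = x.shape
    if order_p < 1:
        raise ValueError("order_p must be >= 1")
    if t <= r * order_p + 1:
        raise ValueError(
            f"T = {t} too short for R = {r}, p = {order_p}: need T > R*p + 1"
        )
    y, z = _lagged_design(x, order_p)
    gram = z.T @ z
    try:
        beta = np.linalg.solve(gram, z.T @ y)  # (R*p, R)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular regressor matrix; try a lower model order"
        ) from None
    resid = y - z @ beta
    dof = t - order_p - r * order_p
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom")
    sigma = resid.T @ resid / dof
    coeffs = beta.T.reshape(r, order_p, r).swapaxes(0, 1)
    return VarModel(
        order_p=order_p, coeffs=coeffs, noise_cov=sigma, n_samples_fit=t
    )


def select_order(
    series,
    p_max: int = DEFAULT_P_MAX,
    criterion: str = "AIC",
) -> OrderSelection:
    """Information-criterion order selection over 1..p_max.

    All candidate orders are scored on the common effective sample (rows
    p_max..T-1) so that likelihoods are comparable.
    """
    x = _as_array(series)
    t, r = x.shape
    if criterion.upper() not in ("AIC", "BIC"):
        raise ValueError("criterion must be AIC or BIC")
    if t <= r * p_max + 1:
        raise ValueError(
            f"T = {t} too short for p_max = {p_max} with R = {r}: "
            f"need T > R*p_max + 1"
        )
    t_eff = t - p_max
    y_full, z_full = _lagged_design(x, p_max)
    trace: dict[int, float] = {}
    for p in range(1, p_max + 1):
        z = z_full[:, : r * p]
        beta = np.linalg.lstsq(z, y_full, rcond=None)[0]
        resid = y_full - z @ beta
        sigma_ml = resid.T @ resid / t_eff
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            trace[p] = np.inf
            continue
        k = p * r * r
        penalty = 2.0 * k / t_eff if criterion.upper() == "AIC" else np.log(t_eff) * k / t_eff
        trace[p] = float(logdet + penalty)
    best = min(trace, key=trace.get)
    return OrderSelection(order_p=best, criterion=criterion.upper(), trace=trace)


def _transfer_function(
    coeffs: np.ndarray, freqs_hz: np.ndarray, tr_s: float
) -> np.ndarray:
    """H(f) = [I - sum_k A_k e^{-i 2 pi f k tr}]^{-1}, shape (F, R, R)."""
    p, r, _ = coeffs.shape
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs_hz * tr_s, k))  # (F, p)
    a = np.eye(r) - np.einsum("fk,kij->fij", phase, coeffs.astype(complex))
    det = np.linalg.det(a)
    bad = np.abs(det) < 1e-14
    if bad.any():
        f_bad = float(np.asarray(freqs_hz)[bad][0])
        raise np.linalg.LinAlgError(
            f"A(f) numerically singular at f = {f_bad:.6g} Hz"
        )
    return np.linalg.inv(a)


def spectral_matrix(
    model: VarModel, freqs_hz: np.ndarray, tr_s: float
) -> SpectralResult:
    """Parametric spectral matrix S(f) = H Sigma H* . tr (one-sided)."""
    freqs_hz = np.asarray(freqs_hz, float)
    h = _transfer_function(model.coeffs, freqs_hz, tr_s)
    s = tr_s * np.einsum("fij,jk,flk->fil", h, model.noise_cov.astype(complex), h.conj())
    s = 0.5 * (s + s.conj().swapaxes(1, 2))  # enforce Hermitian symmetry
    power = np.real(np.diagonal(s, axis1=1, axis2=2))
    return SpectralResult(freqs_hz=freqs_hz, S=s, H=h, power=power)


def _geweke_measures(
    h: np.ndarray, sigma: np.ndarray, tr_s: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Geweke spectra from a bivariate transfer function.

    h: (..., F, 2, 2) complex; sigma: (..., 2, 2). Returns
    (m_total, m_1_to_2, m_2_to_1, m_inst) of shape (..., F).
    """
    s11 = (
        np.abs(h[..., 0, 0]) ** 2 * sigma[..., 0, 0, None]
        + 2.0 * np.real(h[..., 0, 0] * h[..., 0, 1].conj()) * sigma[..., 0, 1, None]
        + np.abs(h[..., 0, 1]) ** 2 * sigma[..., 1, 1, None]
    ) * tr_s
    s22 = (
        np.abs(h[..., 1, 0]) ** 2 * sigma[..., 0, 0, None]
        + 2.0 * np.real(h[..., 1, 0] * h[..., 1, 1].conj()) * sigma[..., 0, 1, None]
        + np.abs(h[..., 1, 1]) ** 2 * sigma[..., 1, 1, None]
    ) * tr_s
    # det S(f) = |det H|^2 det Sigma . tr^2 (2x2)
    det_h = h[..., 0, 0] * h[..., 1, 1] - h[..., 0, 1] * h[..., 1, 0]
    det_sigma = (
        sigma[..., 0, 0] * sigma[..., 1, 1] - sigma[..., 0, 1] ** 2
    )
    det_s = np.abs(det_h) ** 2 * det_sigma[..., None] * tr_s**2

    h11t = h[..., 0, 0] + (sigma[..., 0, 1] / sigma[..., 0, 0])[..., None] * h[..., 0, 1]
    h22t = h[..., 1, 1] + (sigma[..., 0, 1] / sigma[..., 1, 1])[..., None] * h[..., 1, 0]
    intrinsic1 = np.abs(h11t) ** 2 * sigma[..., 0, 0, None] * tr_s
    intrinsic2 = np.abs(h22t) ** 2 * sigma[..., 1, 1, None] * tr_s

    m_total = np.log(s11 * s22 / det_s)
    m_2_to_1 = np.log(s11 / intrinsic1)
    m_1_to_2 = np.log(s22 / intrinsic2)
    m_inst = np.log(intrinsic1 * intrinsic2 / det_s)
    return m_total, m_1_to_2, m_2_to_1, m_inst


def _clamp_nonneg(values: np.ndarray, what: str) -> np.ndarray:
    low = float(values.min()) if values.size else 0.0
    if low < 0:
        if low < -1e-8:
            logger.warning("clamping %s: minimum %.3e < 0", what, low)
        values = np.maximum(values, 0.0)
    return values


def gc_spectra_from_model(
    model: VarModel,
    freqs_hz: np.ndarray,
    tr_s: float,
    pair: tuple[str, str] = ("1", "2"),
) -> PairGcSpectra:
    """Geweke spectra of a bivariate model (fitted or ground-truth)."""
    if model.n_regions != 2:
        raise ValueError("gc_spectra_from_model requires a bivariate model")
    freqs_hz = np.asarray(freqs_hz, float)
    h = _transfer_function(model.coeffs, freqs_hz, tr_s)
    m_total, m12, m21, m_inst = _geweke_measures(h, model.noise_cov, tr_s)
    m12 = _clamp_nonneg(m12, f"M {pair[0]}->{pair[1]}")
    m21 = _clamp_nonneg(m21, f"M {pair[1]}->{pair[0]}")
    return PairGcSpectra(
        freqs_hz=freqs_hz,
        m_total=m_total,
        m_1_to_2=m12,
        m_2_to_1=m21,
        m_inst=m_inst,
        pair=tuple(pair),
        model=model,
    )


def pairwise_gc(
    series: RoiTimeSeries,
    pair: tuple[str, str],
    freqs_hz: np.ndarray | None = None,
    order_p: int | str = "aic",
    p_max: int = DEFAULT_P_MAX,
) -> PairGcSpectra:
    """Bivariate spectral Granger causality between two regions.

    A fresh bivariate VAR is fitted on the two columns (order chosen by AIC
    up to ``p_max`` unless given); the four Geweke spectra are evaluated on
    ``freqs_hz`` (default: 512 points on (0, Nyquist]).
    """
    x = series.pair_data(pair)
    if freqs_hz is None:
        freqs_hz = default_freq_grid(series.tr_s)
    if isinstance(order_p, str):
        order_p = select_order(x, p_max=p_max, criterion=order_p.upper() if order_p.upper() in ("AIC", "BIC") else "AIC").order_p
    model = fit_var(x, order_p)
    return gc_spectra_from_model(model, freqs_hz, series.tr_s, pair=pair)


def integrate_gc(
    freqs_hz: np.ndarray,
    measure_spectrum: np.ndarray,
    f1: float = DEFAULT_BAND_HZ[0],
    f2: float = DEFAULT_BAND_HZ[1],
) -> float:
    """Band-normalized trapezoidal integral of a measure spectrum.

    Returns (1/(f_hi - f_lo)) * integral over the grid points inside
    [f1, f2]; equals the plain band average for a constant spectrum.
    """
    freqs_hz = np.asarray(freqs_hz, float)
    if f1 >= f2:
        raise ValueError("require f1 < f2")
    if f1 < freqs_hz[0] - 1e-12 or f2 > freqs_hz[-1] + 1e-12:
        raise ValueError(
            f"band [{f1}, {f2}] Hz not covered by the grid "
            f"[{freqs_hz[0]:.6g}, {freqs_hz[-1]:.6g}]"
        )
    sel = (freqs_hz >= f1 - 1e-12) & (freqs_hz <= f2 + 1e-12)
    f = freqs_hz[sel]
    if f.size < 2:
        raise ValueError("band contains fewer than two grid points")
    m = np.asarray(measure_spectrum, float)[..., sel]
    return np.trapezoid(m, f, axis=-1) / (f[-1] - f[0])


def peak_frequency(
    freqs_hz: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] | None = None,
) -> float:
    """Argmax frequency of a spectrum, optionally restricted to a band.

    Ties break toward the lower frequency.
    """
    freqs_hz = np.asarray(freqs_hz, float)
    power = np.asarray(power, float)
    if band is not None:
        sel = (freqs_hz >= band[0] - 1e-12) & (freqs_hz <= band[1] + 1e-12)
        if not sel.any():
            raise ValueError(f"no grid points inside band {band}")
        freqs_hz, power = freqs_hz[sel], power[sel]
    return float(freqs_hz[int(np.argmax(power))])


# ---------------------------------------------------------------------------
# Batched bivariate engine (permutation nulls, Monte-Carlo suites)

def batch_fit_bivar(x: np.ndarray, order_p: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS VAR(p) fit of a batch of bivariate series.

    x: (B, T, 2). Returns coeffs (B, p, 2, 2) and noise covariance
    (B, 2, 2) with the same unbiased denominator as :func:`fit_var`.
    """
    b, t, r = x.shape
    if r != 2:
        raise ValueError("batch engine is bivariate only")
    p = order_p
    y = x[:, p:, :]
    z = np.concatenate([x[:, p - k : t - k, :] for k in range(1, p + 1)], axis=2)
    gram = np.einsum("btk,btl->bkl", z, z)
    rhs = np.einsum("btk,btr->bkr", z, y)
    beta = np.linalg.solve(gram, rhs)  # (B, 2p, 2)
    resid = y - np.einsum("btk,bkr->btr", z, beta)
    dof = t - p - r * p
    sigma = np.einsum("bti,btj->bij", resid, resid) / dof
    coeffs = beta.swapaxes(1, 2).reshape(b, r, p, r).swapaxes(1, 2)
    return coeffs, sigma


def _batch_transfer(coeffs: np.ndarray, freqs_hz: np.ndarray, tr_s: float) -> np.ndarray:
    """Closed-form inverse of A(f) for 2x2 batches: (B, F, 2, 2)."""
    b, p, _, _ = coeffs.shape
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(np.asarray(freqs_hz) * tr_s, k))  # (F, p)
    a = np.eye(2) - np.einsum("fk,bkij->bfij", phase, coeffs.astype(complex))
    det = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    h = np.empty_like(a)
    h[..., 0, 0] = a[..., 1, 1] / det
    h[..., 1, 1] = a[..., 0, 0] / det
    h[..., 0, 1] = -a[..., 0, 1] / det
    h[..., 1, 0] = -a[..., 1, 0] / det
    return h


def batch_pair_igc(
    x: np.ndarray,
    order_p: int,
    tr_s: float,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    n_freqs: int = DEFAULT_N_FREQS,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrated directed GC for a batch of bivariate series.

    Returns (igc_1_to_2, igc_2_to_1), each (B,). Spectra are evaluated only
    on the grid points of the default (0, Nyquist] grid that fall inside the
    integration band; values are clamped at zero like the scalar path.
    """
    grid = default_freq_grid(tr_s, n_freqs)
    sel = (grid >= band[0] - 1e-12) & (grid <= band[1] + 1e-12)
    freqs = grid[sel]
    coeffs, sigma = batch_fit_bivar(x, order_p)
    h = _batch_transfer(coeffs, freqs, tr_s)
    _, m12, m21, _ = _geweke_measures(h, sigma, tr_s)
    m12 = np.maximum(m12, 0.0)
    m21 = np.maximum(m21, 0.0)
    span = freqs[-1] - freqs[0]
    return (
        np.trapezoid(m12, freqs, axis=-1) / span,
        np.trapezoid(m21, freqs, axis=-1) / span,
    )
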