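"""ROI extraction and temporal preprocessing of resting-state BOLD series.

Turns registered 4D volumes (or already-extracted multi-column series) into
analysis-ready region-of-interest (ROI) time series: voxel-mean extraction
over spherical ROIs defined in MNI millimeter space, linear detrending,
zero-phase band-pass filtering in the low-frequency band (default
0.04-0.1 Hz), and head-motion exclusion (more than 2 mm translation or more
than 1.5 degrees rotation on any axis, relative to the first volume).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RoiDefinition",
    "RoiTimeSeries",
    "MotionRecord",
    "MotionDecision",
    "DEFAULT_ROIS",
    "DEFAULT_BAND_HZ",
    "sphere_mask",
    "extract_roi_series",
    "detrend_bandpass",
    "motion_exclude",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "read_motion_tsv",
]

#: Analysis band of the low-frequency BOLD oscillations, Hz.
DEFAULT_BAND_HZ = (0.04, 0.1)


@dataclass(frozen=True)
class RoiDefinition:
    """A spherical region of interest in MNI millimeter space."""

    name: str
    center_mni_mm: tuple[float, float, float]
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"ROI {self.name}: radius_mm must be > 0")


#: The five core motor-execution regions: left/right primary motor cortex,
#: left/right premotor cortex and the supplementary motor area.
DEFAULT_ROIS: tuple[RoiDefinition, ...] = (
    RoiDefinition("LM1", (-33.0, -19.8, 52.1)),
    RoiDefinition("RM1", (35.7, -18.1, 52.0)),
    RoiDefinition("LPMC", (-34.3, -1.4, 55.8)),
    RoiDefinition("RPMC", (35.1, 0.1, 54.9)),
    RoiDefinition("SMA", (0.0, -4.2, 64.7)),
)

REGION_NAMES: tuple[str, ...] = tuple(r.name for r in DEFAULT_ROIS)


@dataclass
class RoiTimeSeries:
    """One subject's T x R matrix of region signals.

    data columns follow ``region_names``; ``tr_s`` is the sampling interval
    (fMRI repetition time) in seconds.
    """

    data: np.ndarray
    tr_s: float
    region_names: Sequence[str]
    subject_id: str = ""
    group_label: str | None = None
    filtered: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x R matrix")
        if self.data.shape[1] != len(self.region_names):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.region_names)} region names"
            )
        if len(set(self.region_names)) != len(list(self.region_names)):
            raise ValueError("region_names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, list(self.region_names).index(name)]

    def pair_data(self, pair: tuple[str, str]) -> np.ndarray:
        """T x 2 submatrix for an ordered region pair."""
        names = list(self.region_names)
        return self.data[:, [names.index(pair[0]), names.index(pair[1])]]


@dataclass
class MotionRecord:
    """Six rigid-body motion parameters per volume for one subject."""

    subject_id: str
    translations_mm: np.ndarray  # T x 3
    rotations_deg: np.ndarray  # T x 3

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, float))
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, float))
        if self.translations_mm.shape != self.rotations_deg.shape:
            raise ValueError("translations and rotations must have the same shape")
        if self.translations_mm.shape[1] != 3:
            raise ValueError("expected three translation and three rotation axes")

    @property
    def n_volumes(self) -> int:
        return self.translations_mm.shape[0]


@dataclass(frozen=True)
class MotionDecision:
    keep: bool
    offending_axis: str | None = None
    offending_volume: int | None = None
    max_translation_mm: float = 0.0
    max_rotation_deg: float = 0.0


def sphere_mask(
    roi: RoiDefinition,
    affine: np.ndarray,
    grid_shape: tuple[int, int, int],
) -> np.ndarray:
    """Boolean voxel mask of a closed ball around the ROI center.

    A voxel is included iff the Euclidean distance from its center (the
    affine image of its 0-based index) to ``center_mni_mm`` is at most
    ``radius_mm``.
    """
    affine = np.asarray(affine, float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 voxel-to-mm map")
    nx, ny, nz = (int(s) for s in grid_shape)
    if min(nx, ny, nz) <= 0:
        raise ValueError("grid_shape entries must be positive")

    center = np.asarray(roi.center_mni_mm, float)
    # Work near the ROI only: invert the affine to find the candidate box.
    ijk_center = np.linalg.solve(affine, np.append(center, 1.0))[:3]
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    halo = np.ceil(roi.radius_mm / spacing).astype(int) + 1

    lo = np.maximum(np.floor(ijk_center).astype(int) - halo, 0)
    hi = np.minimum(np.ceil(ijk_center).astype(int) + halo + 1, [nx, ny, nz])
    if np.any(lo >= hi):
        raise ValueError(
            f"ROI {roi.name!r}: center {tuple(center)} lies outside the image "
            f"grid by more than its radius"
        )

    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    inside = np.linalg.norm(world - center, axis=1) <= roi.radius_mm

    mask = np.zeros((nx, ny, nz), dtype=bool)
    mask[idx[inside, 0], idx[inside, 1], idx[inside, 2]] = True
    if not mask.any():
        raise ValueError(f"ROI {roi.name!r}: empty mask (center outside grid?)")
    return mask


def extract_roi_series(
    volume4d,
    rois: Sequence[RoiDefinition],
    *,
    tr_s: float | None = None,
    subject_id: str = "",
    group_label: str | None = None,
) -> RoiTimeSeries:
    """Voxel-mean time series per ROI from a registered 4D NIfTI image.

    ``volume4d`` may be a nibabel image or a path. Column order follows the
    input ROI list. ``tr_s`` defaults to the pixdim[4] stored in the header.
    """
    import nibabel as nib

    img = nib.load(str(volume4d)) if isinstance(volume4d, (str, Path)) else volume4d
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D volume")
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3])

    cols = []
    for roi in rois:
        mask = sphere_mask(roi, img.affine, data.shape[:3])
        block = data[mask, :]  # voxels x T
        n_bad = int(np.isnan(block).any(axis=1).sum())
        if n_bad:
            raise ValueError(
                f"ROI {roi.name!r}: {n_bad} voxels inside the mask contain NaN"
            )
        cols.append(block.mean(axis=0))
    return RoiTimeSeries(
        data=np.column_stack(cols),
        tr_s=float(tr_s),
        region_names=[r.name for r in rois],
        subject_id=subject_id,
        group_label=group_label,
    )


def _bandpass_sos(f_lo: float, f_hi: float, tr_s: float):
    return signal.butter(
        4, [f_lo, f_hi], btype="bandpass", fs=1.0 / tr_s, output="sos"
    )


def bandpass_filter(
    x: np.ndarray, f_lo: float, f_hi: float, tr_s: float
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along axis 0.

    Forward-backward application (no phase distortion, so directed lag
    structure is preserved), mirror padding at the edges.
    """
    nyq = 0.5 / tr_s
    if not (0.0 < f_lo < f_hi):
        raise ValueError("require 0 < f_lo < f_hi")
    if f_hi >= nyq:
        raise ValueError(
            f"f_hi = {f_hi} Hz is at or above the Nyquist frequency "
            f"{nyq} Hz for tr_s = {tr_s} s"
        )
    sos = _bandpass_sos(f_lo, f_hi, tr_s)
    return signal.sosfiltfilt(sos, np.asarray(x, float), axis=0, padtype="even")


def detrend_bandpass(
    series: RoiTimeSeries,
    f_lo: float = DEFAULT_BAND_HZ[0],
    f_hi: float = DEFAULT_BAND_HZ[1],
) -> RoiTimeSeries:
    """Least-squares linear detrend per column, then zero-phase band-pass."""
    detrended = signal.detrend(series.data, axis=0, type="linear")
    filtered = bandpass_filter(detrended, f_lo, f_hi, series.tr_s)
    return replace(series, data=filtered, filtered=True)


_AXES = ("x", "y", "z")


def motion_exclude(
    motion: MotionRecord,
    trans_limit_mm: float = 2.0,
    rot_limit_deg: float = 1.5,
    *,
    n_samples: int | None = None,
) -> MotionDecision:
    """Apply the head-motion exclusion rule.

    A subject is excluded iff any per-volume absolute displacement relative
    to the first (reference) volume strictly exceeds ``trans_limit_mm`` on
    any translation axis or ``rot_limit_deg`` on any rotation axis
    ("more than" is read as a strict inequality: boundary values are kept).
    """
    if trans_limit_mm <= 0 or rot_limit_deg <= 0:
        raise ValueError("limits must be positive")
    if n_samples is not None and motion.n_volumes != n_samples:
        raise ValueError(
            f"motion table has {motion.n_volumes} volumes but the series has "
            f"{n_samples} samples"
        )
    trans = np.abs(motion.translations_mm - motion.translations_mm[0])
    rot = np.abs(motion.rotations_deg - motion.rotations_deg[0])

    for block, limit, kind in ((trans, trans_limit_mm, "t"), (rot, rot_limit_deg, "r")):
        over = block > limit
        if over.any():
            vol, axis = np.argwhere(over)[0]
            return MotionDecision(
                keep=False,
                offending_axis=f"{kind}{_AXES[axis]}",
                offending_volume=int(vol),
                max_translation_mm=float(trans.max()),
                max_rotation_deg=float(rot.max()),
            )
    return MotionDecision(
        keep=True,
        max_translation_mm=float(trans.max()),
        max_rotation_deg=float(rot.max()),
    )


# ---------------------------------------------------------------------------
# File formats: TSV series + JSON sidecar; 6-column motion TSV (tx ty tz rx ry rz)

def write_roi_timeseries(series: RoiTimeSeries, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(series.data, columns=list(series.region_names))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "tr_s": series.tr_s,
        "subject_id": series.subject_id,
        "group_label": series.group_label,
        "filtered": series.filtered,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_roi_timeseries(path: str | Path) -> RoiTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    if "tr_s" not in meta:
        raise ValueError(f"missing sidecar with tr_s for {path}")
    return RoiTimeSeries(
        data=df.to_numpy(float),
        tr_s=float(meta["tr_s"]),
        region_names=list(df.columns),
        subject_id=str(meta.get("subject_id", path.stem)),
        group_label=meta.get("group_label"),
        filtered=bool(meta.get("filtered", False)),
    )


def read_motion_tsv(path: str | Path, subject_id: str | None = None) -> MotionRecord:
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got {arr.shape[1]}")
    return MotionRecord(
        subject_id=subject_id or Path(path).stem,
        translations_mm=arr[:, :3],
        rotations_deg=arr[:, 3:],
    )
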