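"""Signal preparation: drift removal, smoothing, ROI extraction, fALFF.

Drift removal is a projection onto a low-order slow polynomial basis
(Legendre), which removes scanner drift while leaving task-band content
essentially untouched; it is idempotent and zero-means every ROI. The
fALFF (fractional amplitude of low-frequency fluctuation) score — low-band
over high-band spectral power — flags components dominated by
high-frequency noise, which are discarded below a threshold of 1. The
subject-inclusion rule keeps subjects with enough slow trials to support
10-second connectivity windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy import ndimage, signal

from .core import RoiTimeSeriesSet

logger = logging.getLogger(__name__)

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def detrend_timeseries(series: RoiTimeSeriesSet, basis_order: int = 3) -> RoiTimeSeriesSet:
    """Remove slow polynomial trends (orders 0..basis_order) per ROI.

    The output has zero mean per ROI and variance no larger than the input;
    applying it twice equals applying it once (projection).
    """
    if basis_order < 0:
        raise ValueError("basis_order must be >= 0")
    if series.n_samples <= basis_order + 1:
        raise ValueError("series length must exceed basis_order + 1")
    x = np.linspace(-1.0, 1.0, series.n_samples)
    basis = legendre.legvander(x, basis_order)  # (n_samples, order+1)
    coef, _, _, _ = np.linalg.lstsq(basis, series.data.T, rcond=None)
    return series.with_data(series.data - (basis @ coef).T)


def smooth_volume(volume: np.ndarray, fwhm_mm: float, voxel_mm) -> np.ndarray:
    """Gaussian-smooth each frame of a 4-D volume (spatial axes only).

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis, converted to voxel units
    by the voxel size. ``fwhm_mm = 0`` is the identity.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, t)")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    voxel_mm = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    if np.any(voxel_mm <= 0):
        raise ValueError("voxel sizes must be positive")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA / voxel_mm
    return ndimage.gaussian_filter(volume, sigma=(*sigma_vox, 0.0), mode="nearest")


def extract_roi_timeseries(volume, atlas, roi_ids, tr: float | None = None,
                           subject_id: str = "sub-01") -> RoiTimeSeriesSet:
    """Mean time series over each atlas label.

    ``volume`` is a 4-D array or NIfTI image; ``atlas`` a 3-D integer label
    array or image on the same grid (no resampling is attempted — a grid
    mismatch is an error). Each requested ROI row is the unweighted mean
    over its voxels, per frame.
    """
    vol_data, vol_tr = _as_volume(volume)
    atlas_data, _ = _as_volume(atlas, allow_3d=True)
    if atlas_data.shape != vol_data.shape[:3]:
        raise ValueError(
            f"atlas grid {atlas_data.shape} does not match volume grid "
            f"{vol_data.shape[:3]}")
    if tr is None:
        tr = vol_tr
    if tr is None:
        raise ValueError("tr not recoverable from the volume; pass tr=")
    atlas_data = atlas_data.astype(int)
    missing = [r for r in roi_ids if not np.any(atlas_data == int(r))]
    if missing:
        raise ValueError(f"ROI ids absent from atlas: {missing}")
    rows = [vol_data[atlas_data == int(r)].mean(axis=0) for r in roi_ids]
    return RoiTimeSeriesSet(subject_id, tuple(roi_ids), np.vstack(rows), tr)


def _as_volume(obj, allow_3d: bool = False):
    """Accept an ndarray or a nibabel image; return (array, tr-or-None)."""
    if hasattr(obj, "get_fdata"):
        zooms = obj.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else None
        return np.asanyarray(obj.dataobj), tr
    arr = np.asarray(obj)
    if allow_3d and arr.ndim == 3:
        return arr, None
    return arr, None


@dataclass
class FalffReport:
    """Per-ROI fALFF scores and the keep decision at a threshold."""

    roi_ids: tuple
    falff: np.ndarray
    low_band: tuple
    high_band: tuple
    threshold: float

    @property
    def keep_mask(self) -> np.ndarray:
        return self.falff >= self.threshold

    @property
    def kept_roi_ids(self) -> tuple:
        return tuple(r for r, keep in zip(self.roi_ids, self.keep_mask) if keep)


def compute_falff(series: RoiTimeSeriesSet,
                  low_band=(0.01, 0.08), high_band=None,
                  threshold: float = 1.0,
                  detrend_order: int = 3) -> FalffReport:
    """Low-band over high-band spectral power ratio per ROI.

    Bands are in Hz; ``high_band`` defaults to (low_band[1], Nyquist]. The
    periodogram is a plain FFT power estimate of the detrended series
    (no taper). A ROI with zero high-band power gets fALFF = +inf and is
    kept (logged), since all its power is low-frequency by definition.
    """
    nyquist = 1.0 / (2.0 * series.tr)
    if high_band is None:
        high_band = (low_band[1], nyquist)
    for lo, hi in (low_band, high_band):
        if not (0 < lo < hi <= nyquist + 1e-12):
            raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist={nyquist:.3f}]")
    detrended = detrend_timeseries(series, detrend_order)
    freqs, power = signal.periodogram(detrended.data, fs=1.0 / series.tr, axis=1)
    low = (freqs >= low_band[0]) & (freqs <= low_band[1])
    high = (freqs > high_band[0]) & (freqs <= high_band[1])
    low_power = power[:, low].sum(axis=1)
    high_power = power[:, high].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        falff = np.where(high_power > 0, low_power / np.maximum(high_power, 1e-300),
                         np.inf)
    for roi, score in zip(series.roi_ids, falff):
        if not np.isfinite(score):
            logger.warning("ROI %s has zero high-band power; fALFF=inf, kept", roi)
    return FalffReport(series.roi_ids, falff, tuple(low_band), tuple(high_band),
                       threshold)


def select_subjects(trial_tables: dict, min_rt: float = 10.0,
                    min_trials: int = 13) -> list:
    """Subjects with at least ``min_trials`` trials slower than ``min_rt``.

    Implements the inclusion rule for fixed-length connectivity windows:
    a subject is analyzable only if most trials are long enough to hold a
    full window. Defaults: RT > 10 s for >= 13 trials.
    """
    included = []
    for sid, trials in trial_tables.items():
        if trials is None or len(trials) == 0:
            logger.warning("subject %s has an empty trial table; excluded", sid)
            continue
        if int((trials["duration"] > min_rt).sum()) >= min_trials:
            included.append(sid)
    return included
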