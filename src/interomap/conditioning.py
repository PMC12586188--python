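"""Per-subject BOLD signal conditioning.

Implements the desk-scale preprocessing chain applied before connectivity
analysis: nuisance regression against motion and tissue-signal confounds,
zero-phase band-pass filtering within runs, per-run linear detrending with
unit-variance normalization, 3D Gaussian spatial smoothing, and
framewise-displacement motion summaries. All operations preserve the frame
count and never introduce non-finite values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from interomap.cohort import MOTION_COLUMNS, SubjectTimeSeries, VoxelGrid

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class MotionSummary:
    """Framewise-displacement summary of one subject's motion trace.

    FD combines translation increments (mm) with rotation increments
    converted to arc length on a sphere of ``head_radius_mm``. The first
    frame's FD is defined as 0 and excluded from the summary statistics.
    ``frac_subvoxel`` is the fraction of frames moving less than one voxel.
    """

    fd_series: np.ndarray
    fd_mean: float
    fd_sd: float
    frac_subvoxel: float
    head_radius_mm: float
    voxel_size_mm: float

    def to_dict(self) -> dict:
        return {
            "fd_mean": self.fd_mean,
            "fd_sd": self.fd_sd,
            "frac_subvoxel": self.frac_subvoxel,
            "head_radius_mm": self.head_radius_mm,
            "voxel_size_mm": self.voxel_size_mm,
            "n_frames": int(self.fd_series.size),
        }


def _design_matrix(confounds: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack([confounds.to_numpy(dtype=float), np.ones(len(confounds))])
    names = list(confounds.columns) + ["intercept"]
    return X, names


def regress_nuisance(ts: SubjectTimeSeries, confounds: pd.DataFrame) -> SubjectTimeSeries:
    """Voxel-wise least-squares removal of confound regressors.

    The design is the confound table plus an intercept; residuals are exactly
    orthogonal to every design column. Raises on frame-count mismatch or a
    rank-deficient design (naming the offending columns).
    """
    if len(confounds) != ts.n_frames:
        raise ValueError(
            f"confound table has {len(confounds)} frames, data has {ts.n_frames}"
        )
    X, names = _design_matrix(confounds)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        zero = [n for n, col in zip(names, X.T) if np.allclose(col, 0)]
        # columns that do not increase rank when added incrementally
        collinear, cols = [], np.ones((X.shape[0], 1))
        for n, col in zip(names, X.T):
            cand = np.column_stack([cols, col])
            if np.linalg.matrix_rank(cand) == cols.shape[1]:
                collinear.append(n)
            else:
                cols = cand
        raise ValueError(
            f"rank-deficient confound design (rank {rank} < {X.shape[1]}); "
            f"zero columns: {zero or 'none'}; collinear columns: {collinear}"
        )
    beta, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    resid = ts.data - (X @ beta).T
    return ts.with_data(resid)


def temporal_filter(
    ts: SubjectTimeSeries,
    low_hz: float = 0.008,
    high_hz: float = 0.09,
    order: int = 2,
) -> SubjectTimeSeries:
    """Zero-phase Butterworth band-pass, applied independently within runs.

    A forward-backward (filtfilt) order-``order`` Butterworth filter; with
    ``low_hz`` = 0 a low-pass filter is used instead. Frequencies are in Hz
    against the subject's sampling rate 1/TR.
    """
    nyquist = 0.5 / ts.tr_s
    if not (0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist ({nyquist} Hz)")
    if low_hz > 0:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_s, output="sos")
    else:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=1.0 / ts.tr_s, output="sos")
    out = np.empty_like(ts.data)
    for sl in ts.run_slices():
        out[:, sl] = signal.sosfiltfilt(sos, ts.data[:, sl], axis=1)
    return ts.with_data(out)


def detrend_normalize(ts: SubjectTimeSeries) -> tuple[SubjectTimeSeries, np.ndarray]:
    """Per run and per voxel: remove the linear trend, then scale to unit
    sample variance.

    Returns the conditioned series and a boolean flag array marking voxels
    that were constant (zero variance) within at least one run; those voxels
    are mapped to all-zeros rather than treated as an error.
    """
    out = ts.data.copy()
    degenerate = np.zeros(ts.n_voxels, dtype=bool)
    for sl in ts.run_slices():
        seg = out[:, sl]
        if seg.shape[1] < 3:
            raise ValueError("each run needs >= 3 frames for detrending")
        seg = signal.detrend(seg, axis=1, type="linear")
        sd = seg.std(axis=1, ddof=1)
        zero = sd < 1e-12
        degenerate |= zero
        sd[zero] = 1.0
        seg /= sd[:, None]
        seg[zero] = 0.0
        out[:, sl] = seg
    return ts.with_data(out), degenerate


def spatial_smooth(
    volume_series: np.ndarray, fwhm_mm: float, grid: VoxelGrid
) -> np.ndarray:
    """Per-frame 3D Gaussian smoothing of a (voxels, frames) series.

    ``fwhm_mm`` is converted to a kernel sigma in voxels via
    sigma = FWHM / (2 sqrt(2 ln 2)) / voxel size. FWHM 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    volume_series = np.asarray(volume_series, dtype=float)
    if fwhm_mm == 0:
        return volume_series.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size_mm
    vols = volume_series.reshape(*grid.dims, -1)
    out = ndimage.gaussian_filter(vols, sigma=(sigma_vox,) * 3 + (0.0,), mode="nearest")
    return out.reshape(grid.n_voxels, -1)


def framewise_displacement(
    confounds: pd.DataFrame,
    head_radius_mm: float = 50.0,
    voxel_size_mm: float = 3.0,
) -> MotionSummary:
    """Framewise displacement from the 6 rigid-body motion parameters.

    FD_t = sum |delta translation| + head_radius * sum |delta rotation|,
    the small-angle arc-length convention with a 50 mm head radius.
    """
    if head_radius_mm <= 0:
        raise ValueError(f"head_radius_mm must be > 0, got {head_radius_mm}")
    missing = [c for c in MOTION_COLUMNS if c not in confounds.columns]
    if missing:
        raise ValueError(f"missing motion columns: {missing}")
    motion = confounds.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float)
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(len(confounds))
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    body = fd[1:]
    if body.size == 0:
        mean = sd = 0.0
        frac = 1.0
    else:
        mean = float(body.mean())
        sd = float(body.std(ddof=1)) if body.size > 1 else 0.0
        frac = float(np.mean(body < voxel_size_mm))
    return MotionSummary(
        fd_series=fd,
        fd_mean=mean,
        fd_sd=sd,
        frac_subvoxel=frac,
        head_radius_mm=head_radius_mm,
        voxel_size_mm=voxel_size_mm,
    )


def condition_subject(
    ts: SubjectTimeSeries,
    confounds: pd.DataFrame,
    low_hz: float = 0.008,
    high_hz: float = 0.09,
    apply_filter: bool = True,
    filter_confounds: bool = False,
) -> tuple[SubjectTimeSeries, np.ndarray]:
    """Standard conditioning chain: regress -> band-pass -> detrend/normalize.

    ``filter_confounds`` band-passes the confound columns identically before
    the regression (off by default). Returns the conditioned series and the
    degenerate-voxel flags from normalization.
    """
    if filter_confounds and apply_filter:
        conf_ts = SubjectTimeSeries(
            subject_id=ts.subject_id,
            data=confounds.to_numpy(dtype=float).T,
            tr_s=ts.tr_s,
            run_boundaries=ts.run_boundaries,
        )
        conf_ts = temporal_filter(conf_ts, low_hz, high_hz)
        confounds = pd.DataFrame(conf_ts.data.T, columns=confounds.columns)
    out = regress_nuisance(ts, confounds)
    if apply_filter:
        out = temporal_filter(out, low_hz, high_hz)
    return detrend_normalize(out)
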