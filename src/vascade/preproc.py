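"""Motion censoring and denoising of ROI time series.

The stage order is fixed: demean/nuisance-regress (fitting on retained
frames only), linear interpolation across censored frames, zero-phase
band-pass, then removal of the censored frames. Run boundaries are never
interpolated or filtered across; each run is processed separately and
retained frames are concatenated afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import MotionTrace, RoiTimeSeries

#: Sphere radius (mm) used to convert rotations to arc displacement.
ROTATION_RADIUS_MM = 50.0


@dataclass
class FDfiltSeries:
    """Per-frame filtered frame-wise displacement, in mm."""

    values: np.ndarray
    cutoff_hz: float = 0.1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("displacement values must be non-negative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CensorMask:
    """Per-frame retention mask (True = frame retained)."""

    retained: np.ndarray

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def __len__(self) -> int:
        return self.retained.size


@dataclass
class NuisanceSet:
    """Global/CSF/WM signals plus the 24 Volterra motion regressors."""

    global_signal: np.ndarray
    csf: np.ndarray
    wm: np.ndarray
    motion_volterra: np.ndarray  # (n_frames, 24)

    def design(self) -> np.ndarray:
        """Stack into the (n_frames, 27) nuisance design matrix."""
        cols = np.column_stack(
            [self.global_signal, self.csf, self.wm, self.motion_volterra]
        )
        if cols.shape[1] != 27:
            raise ValueError(f"expected 27 nuisance columns, got {cols.shape[1]}")
        return cols

    @property
    def names(self) -> list[str]:
        return (
            ["global", "csf", "wm"]
            + [f"motion{i}" for i in range(1, 7)]
            + [f"motion{i}_prev" for i in range(1, 7)]
            + [f"motion{i}_sq" for i in range(1, 7)]
            + [f"motion{i}_prev_sq" for i in range(1, 7)]
        )


def lowpass_motion(params: np.ndarray, tr: float, cutoff_hz: float = 0.1,
                   order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass of the six motion parameters."""
    nyq = 0.5 / tr
    if cutoff_hz >= nyq:
        return params.copy()
    b, a = signal.butter(order, cutoff_hz / nyq, btype="low")
    return signal.filtfilt(b, a, params, axis=0)


def compute_fdfilt(motion: MotionTrace, cutoff_hz: float = 0.1,
                   rotation_radius_mm: float = ROTATION_RADIUS_MM) -> FDfiltSeries:
    """Filtered frame-wise displacement.

    Each motion parameter is low-pass filtered at ``cutoff_hz`` (to remove
    respiratory oscillation), first-differenced, and the absolute
    differences are summed per frame. Rotations (radians) are converted to
    mm of arc displacement on a sphere of ``rotation_radius_mm`` before
    summation. The first frame is assigned zero displacement.
    """
    if motion.n_frames < 2:
        raise ValueError("need at least two frames to difference")
    params = motion.params.copy()
    params[:, 3:] *= rotation_radius_mm  # radians -> mm on sphere surface
    filtered = lowpass_motion(params, motion.tr, cutoff_hz)
    fd = np.abs(np.diff(filtered, axis=0)).sum(axis=1)
    return FDfiltSeries(values=np.concatenate([[0.0], fd]), cutoff_hz=cutoff_hz)


def build_censor_mask(fd: FDfiltSeries, threshold: float = 0.1,
                      edge_trim: int = 5, min_segment: int = 5) -> CensorMask:
    """Mark frames for removal.

    A frame is censored when its displacement exceeds ``threshold`` mm,
    when it lies within the first/last ``edge_trim`` frames of the run, or
    when it belongs to a surviving contiguous retained segment shorter
    than ``min_segment`` frames.
    """
    n = len(fd)
    if n < 2 * edge_trim:
        raise ValueError("run shorter than twice the edge trim")
    retained = fd.values <= threshold
    if edge_trim:
        retained[:edge_trim] = False
        retained[-edge_trim:] = False
    # drop short surviving segments
    for start, stop in _segments(retained):
        if stop - start < min_segment:
            retained[start:stop] = False
    return CensorMask(retained=retained)


def _segments(mask: np.ndarray):
    """Yield (start, stop) of contiguous True runs."""
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return zip(starts, stops)


def qc_min_frames(masks: list[CensorMask], min_per_run: int = 50) -> bool:
    """Inclusion decision: every run must retain at least ``min_per_run``."""
    if not masks:
        raise ValueError("need at least one run")
    return all(m.n_retained >= min_per_run for m in masks)


def volterra_expansion(motion: MotionTrace) -> np.ndarray:
    """24 motion regressors: current and previous-frame parameters, squared.

    The previous-frame copy of frame 0 is zero-padded.
    """
    p = motion.params
    prev = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.column_stack([p, prev, p**2, prev**2])


def nuisance_regress(ts: RoiTimeSeries, nuis: NuisanceSet,
                     mask: CensorMask) -> RoiTimeSeries:
    """Demean and regress out nuisance signals, fitting on retained frames.

    Betas are estimated by least squares on the retained frames only; the
    fitted values are then subtracted at *all* frames so interpolation
    downstream operates on residuals. Demeaning uses retained frames only.
    """
    if len(mask) != ts.n_frames:
        raise ValueError("mask length does not match run")
    keep = mask.retained
    design = nuis.design()
    if design.shape[0] != ts.n_frames:
        raise ValueError("nuisance length does not match run")
    if keep.sum() <= design.shape[1]:
        raise ValueError("fewer retained frames than regressors")

    x = design - design[keep].mean(axis=0)
    rank = np.linalg.matrix_rank(x[keep])
    if rank < x.shape[1]:
        bad = _collinear_columns(x[keep], nuis.names)
        raise ValueError(f"rank-deficient nuisance design; offending: {bad}")
    y = ts.data - ts.data[keep].mean(axis=0)
    beta, *_ = np.linalg.lstsq(x[keep], y[keep], rcond=None)
    return ts.copy_with(y - x @ beta)


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Name columns that do not increase the design rank."""
    bad, rank = [], 0
    kept = np.empty((x.shape[0], 0))
    for j in range(x.shape[1]):
        trial = np.column_stack([kept, x[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept, rank = trial, r
        else:
            bad.append(names[j])
    return bad


def interpolate_censored(ts: RoiTimeSeries, mask: CensorMask) -> RoiTimeSeries:
    """Linearly interpolate censored frames from flanking retained frames.

    Leading/trailing censored frames are held at the nearest retained
    value (np.interp clamps at the edges).
    """
    keep = mask.retained
    if keep.sum() < 2:
        raise ValueError("need at least two retained frames to interpolate")
    frames = np.arange(ts.n_frames)
    out = ts.data.copy()
    for j in range(ts.n_rois):
        out[~keep, j] = np.interp(frames[~keep], frames[keep], ts.data[keep, j])
    return ts.copy_with(out)


def bandpass(ts: RoiTimeSeries, low: float = 0.009, high: float = 0.08,
             order: int = 1) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass, per ROI."""
    nyq = 0.5 / ts.tr
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz at or above Nyquist {nyq} Hz")
    b, a = signal.butter(order, [low / nyq, high / nyq], btype="band")
    return ts.copy_with(signal.filtfilt(b, a, ts.data, axis=0))


def apply_censor(ts: RoiTimeSeries, mask: CensorMask) -> RoiTimeSeries:
    """Drop the censored frames, keeping retained frames in order."""
    if len(mask) != ts.n_frames:
        raise ValueError("mask length does not match run")
    return ts.copy_with(ts.data[mask.retained])


def concat_runs(runs: list[RoiTimeSeries]) -> RoiTimeSeries:
    """Concatenate censored runs frame-wise (ROI rosters must agree)."""
    if not runs:
        raise ValueError("no runs to concatenate")
    ids = runs[0].roi_ids
    for r in runs[1:]:
        if r.roi_ids != ids:
            raise ValueError("ROI rosters differ across runs")
    return RoiTimeSeries(
        data=np.vstack([r.data for r in runs]),
        tr=runs[0].tr,
        roi_ids=list(ids),
        run_id="+".join(r.run_id for r in runs),
    )


def preprocess_run(ts: RoiTimeSeries, motion: MotionTrace, nuis: NuisanceSet,
                   fd_threshold: float = 0.1, edge_trim: int = 5,
                   min_segment: int = 5) -> tuple[RoiTimeSeries, CensorMask, FDfiltSeries]:
    """Full single-run chain: censor mask, regression, interpolation,
    band-pass, frame removal. Returns the censored series, the mask and
    the displacement series (whose retained-frame mean is the subject's
    motion covariate)."""
    fd = compute_fdfilt(motion)
    mask = build_censor_mask(fd, threshold=fd_threshold, edge_trim=edge_trim,
                             min_segment=min_segment)
    if mask.n_retained == 0:
        return ts.copy_with(ts.data[:0]), mask, fd
    clean = nuisance_regress(ts, nuis, mask)
    interp = interpolate_censored(clean, mask)
    filtered = bandpass(interp)
    return apply_censor(filtered, mask), mask, fd
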