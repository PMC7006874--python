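"""Arterial elasticity scoring from optical pulse recordings (PReFx).

The pulse relaxation function (PReFx) summarizes the shape of the
arterial pulse between the systolic peak and the diastolic trough. The
segment is rescaled to unit time and unit amplitude (diastole = 0,
systole = 1) and its area is computed by the trapezoidal rule; PReFx is
that area minus 0.5, the area of a straight-line (constant-speed)
relaxation. Elastic arteries relax concavely (PReFx > 0); stiff arteries,
where the reflected pressure wave returns early and overlaps the forward
wave, relax convexly (PReFx < 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import PulseRecording


@dataclass
class RPeakSeries:
    """Times of EKG R-wave peaks and the interbeat intervals."""

    times: np.ndarray  # seconds, strictly increasing
    threshold: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def ibis(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def n_beats(self) -> int:
        return self.times.size


@dataclass
class AveragedPulse:
    """R-wave-locked mean pulse waveform over one cardiac cycle."""

    time: np.ndarray  # seconds from R peak, starts at 0
    waveform: np.ndarray  # normalized intensity
    n_beats: int

    def __post_init__(self) -> None:
        if self.n_beats < 2:
            raise ValueError("need at least 2 beats in the average")
        if self.time[0] != 0:
            raise ValueError("time base must start at the R peak")


@dataclass
class Landmarks:
    systole_time: float
    systole_amp: float
    diastole_time: float
    diastole_amp: float
    systole_idx: int
    diastole_idx: int


@dataclass
class PReFxResult:
    """Normalized systole-to-diastole area and the PReFx score."""

    area: float  # in [0, 1] for well-behaved pulses
    prefx: float  # area - 0.5
    landmarks: Landmarks
    n_beats: int


def detect_r_peaks(ekg: np.ndarray, fs: float, threshold_scale: float = 0.5,
                   ibi_range: tuple[float, float] = (0.33, 1.5)) -> RPeakSeries:
    """Find R-wave peaks above a per-recording threshold.

    The threshold is ``threshold_scale`` times the recording's maximum
    excursion above its median (scaled per participant, since EKG gain
    varies). Candidate peaks closer together than the minimum plausible
    interbeat interval are resolved in favor of the taller peak, which
    dismisses artifact spikes riding close to a true R wave; intervals
    longer than the maximum are tolerated as dropped beats.
    """
    ekg = np.asarray(ekg, dtype=float)
    if ekg.size < 2 * fs:
        raise ValueError("need at least 2 s of EKG")
    baseline = np.median(ekg)
    excursion = ekg.max() - baseline
    if excursion <= 0:
        raise ValueError("no peaks found: flat EKG")
    thr = baseline + threshold_scale * excursion
    min_dist = max(1, int(round(ibi_range[0] * fs)))
    idx, _ = signal.find_peaks(ekg, height=thr, distance=min_dist)
    if idx.size == 0:
        raise ValueError("no peaks found above threshold")
    return RPeakSeries(times=idx / fs, threshold=thr)


def bandpass_pulse(optical: np.ndarray, fs: float, low: float = 0.5,
                   high: float = 5.0, order: int = 2) -> np.ndarray:
    """Zero-phase band-pass of the optical intensity; mean removed."""
    nyq = fs / 2
    if fs <= 10:
        raise ValueError("optical sampling rate too low")
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz at or above Nyquist {nyq} Hz")
    b, a = signal.butter(order, [low / nyq, high / nyq], btype="band")
    out = signal.filtfilt(b, a, optical - np.mean(optical))
    return out - out.mean()


def average_pulse(optical: np.ndarray, fs: float, peaks: RPeakSeries,
                  n_samples: int = 100) -> AveragedPulse:
    """Ensemble-average the optical signal time-locked to the R peaks.

    Each beat's segment spans from its R peak to the median interbeat
    interval, resampled onto a common ``n_samples`` grid; beats truncated
    by the recording edges are dropped. Polarity is normalized so the
    systolic excursion is a maximum: if the early part of the averaged
    waveform deflects mostly downward the waveform is flipped.
    """
    optical = np.asarray(optical, dtype=float)
    if peaks.n_beats < 2:
        raise ValueError("need at least 2 beats")
    window = float(np.median(peaks.ibis))
    t_grid = np.linspace(0.0, window, n_samples)
    t_signal = np.arange(optical.size) / fs
    segments = []
    for t0 in peaks.times:
        if t0 + window > t_signal[-1]:
            continue  # truncated by recording edge
        segments.append(np.interp(t0 + t_grid, t_signal, optical))
    if len(segments) < 2:
        raise ValueError("fewer than 2 complete cycles")
    mean_wave = np.mean(segments, axis=0)
    centered = mean_wave - mean_wave.mean()
    # Polarity: the systolic upstroke is steeper than the relaxation decay,
    # so with systole-up the largest positive sample-to-sample slope exceeds
    # the largest negative one. Flip when that is reversed.
    dw = np.diff(centered)
    if -dw.min() > dw.max():
        centered = -centered
    return AveragedPulse(time=t_grid, waveform=centered, n_beats=len(segments))


def find_landmarks(pulse: AveragedPulse, systole_window: float = 0.4) -> Landmarks:
    """Locate the systolic peak and the subsequent diastolic trough.

    Systole is the global maximum within the first ``systole_window``
    fraction of the cycle; diastole is the global minimum after it.
    """
    w = pulse.waveform
    if np.ptp(w) == 0:
        raise ValueError("flat pulse: landmarks undefined")
    n_early = max(2, int(np.ceil(systole_window * w.size)))
    sys_idx = int(np.argmax(w[:n_early]))
    after = w[sys_idx + 1:]
    if after.size < 2 or after.min() >= w[sys_idx]:
        raise ValueError("no relaxation segment after systole")
    dia_idx = sys_idx + 1 + int(np.argmin(after))
    return Landmarks(
        systole_time=float(pulse.time[sys_idx]),
        systole_amp=float(w[sys_idx]),
        diastole_time=float(pulse.time[dia_idx]),
        diastole_amp=float(w[dia_idx]),
        systole_idx=sys_idx,
        diastole_idx=dia_idx,
    )


def compute_prefx(pulse: AveragedPulse, landmarks: Landmarks) -> PReFxResult:
    """Normalized area of the systole-to-diastole segment, minus 0.5.

    Time is rescaled so systole sits at 0 and diastole at 1; amplitude so
    diastole = 0 and systole = 1. The trapezoidal area of the rescaled
    segment is 0.5 for a straight-line relaxation, hence PReFx = 0 there.
    """
    i0, i1 = landmarks.systole_idx, landmarks.diastole_idx
    if i1 - i0 < 2:
        raise ValueError("degenerate segment: fewer than 3 samples")
    seg = pulse.waveform[i0:i1 + 1]
    t = pulse.time[i0:i1 + 1]
    amp = landmarks.systole_amp - landmarks.diastole_amp
    if amp <= 0:
        raise ValueError("systolic and diastolic amplitudes do not differ")
    y = (seg - landmarks.diastole_amp) / amp
    x = (t - t[0]) / (t[-1] - t[0])
    area = float(np.trapezoid(y, x))
    return PReFxResult(area=area, prefx=area - 0.5, landmarks=landmarks,
                       n_beats=pulse.n_beats)


def prefx_from_recording(rec: PulseRecording,
                         threshold_scale: float = 0.5,
                         ibi_range: tuple[float, float] = (0.33, 1.5)) -> PReFxResult:
    """Full chain: R-peak detection, band-pass, averaging, landmarking."""
    peaks = detect_r_peaks(rec.ekg, rec.fs_ekg, threshold_scale, ibi_range)
    optical = bandpass_pulse(rec.optical, rec.fs_optical)
    pulse = average_pulse(optical, rec.fs_optical, peaks)
    marks = find_landmarks(pulse)
    return compute_prefx(pulse, marks)


def global_prefx(regional: list[float]) -> tuple[float, int]:
    """Mean regional PReFx; non-finite regions are skipped and counted.

    Returns ``(mean, n_used)``.
    """
    vals = np.asarray(regional, dtype=float)
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("no finite regional values")
    return float(vals[ok].mean()), int(ok.sum())
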