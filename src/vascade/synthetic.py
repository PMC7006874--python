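"""Synthetic cohort generator.

Every input the downstream stages consume can be generated here with the
statistical structure the analysis assumes:

* subject-level variables from a linear-Gaussian latent chain
  age -> vascular -> structure -> function -> cognition,
* ROI time series with block-structured covariance (tunable within- and
  between-network correlation) plus optional low-frequency confounds,
* six-parameter motion traces with transient single-frame spikes,
* two-channel pulse recordings built from a forward pressure wave plus a
  delayed, scaled reflected wave, where a single ``overlap`` knob moves
  the reflection earlier (stiffer arteries) or later (more elastic).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ASSOCIATION_NETWORKS,
    SENSORIMOTOR_NETWORKS,
    MotionTrace,
    PulseRecording,
    RoiTimeSeries,
    SystemPartition,
    default_class_map,
)


@dataclass
class CascadeParams:
    """Parameters of the latent cascade chain.

    ``path_coefficients`` are the four signed, unit-scale weights for
    age->vascular, vascular->structure, structure->function and
    function->cognition; ``noise_sd`` is the innovation SD at each level
    (scalar, or one value per level).
    """

    n_subjects: int = 46
    age_range: tuple[float, float] = (18.0, 75.0)
    path_coefficients: tuple[float, float, float, float] = (-0.6, 0.7, 0.7, 0.7)
    noise_sd: float | tuple[float, ...] = 0.7
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        paths = np.asarray(self.path_coefficients, dtype=float)
        if paths.shape != (4,) or not np.all(np.isfinite(paths)):
            raise ValueError("need 4 finite path coefficients")
        sds = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (4,))
        if np.any(sds < 0) or not np.all(np.isfinite(sds)):
            raise ValueError("noise SDs must be finite and non-negative")
        if not self.age_range[1] > self.age_range[0]:
            raise ValueError("age range must be increasing")

    @property
    def noise_sds(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (4,)).copy()


LATENT_LEVELS = ("vascular", "structure", "function", "cognition")


def generate_subjects(params: CascadeParams) -> pd.DataFrame:
    """Per-subject latent scores at the four cascade levels.

    Age is drawn uniformly over ``age_range`` and standardized before
    entering the chain; each subsequent level is
    ``path * previous + Normal(0, noise_sd)``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    age = rng.uniform(*params.age_range, size=n)
    prev = (age - age.mean()) / age.std()
    paths = np.asarray(params.path_coefficients, dtype=float)
    sds = params.noise_sds
    out = {"subject_id": [f"sub{i + 1:03d}" for i in range(n)], "age": age,
           "sex": rng.integers(0, 2, size=n)}
    for name, p, sd in zip(LATENT_LEVELS, paths, sds):
        prev = p * prev + rng.normal(0.0, sd, size=n)
        out[name] = prev
    return pd.DataFrame(out).set_index("subject_id")


def default_partition(n_per_network: int = 4,
                      networks: tuple[str, ...] | None = None) -> SystemPartition:
    """Partition with ``n_per_network`` ROIs in each canonical network."""
    if networks is None:
        networks = ASSOCIATION_NETWORKS + SENSORIMOTOR_NETWORKS
    roi_to_network = {}
    for net in networks:
        stem = net.replace(" ", "_").replace("-", "_")
        for k in range(1, n_per_network + 1):
            roi_to_network[f"{stem}_{k:02d}"] = net
    return SystemPartition(roi_to_network=roi_to_network,
                           network_to_class=default_class_map(list(networks)))


def generate_roi_timeseries(target_within: float, target_between: float,
                            partition: SystemPartition, n_frames: int,
                            tr: float = 2.0, seed: int | None = None,
                            confound_strength: float = 0.0,
                            run_id: str = "run1",
                            ) -> tuple[RoiTimeSeries, dict[str, np.ndarray]]:
    """Multivariate Gaussian frames with block covariance.

    Off-diagonal correlation is ``target_within`` inside a network and
    ``target_between`` across networks (any class). Realized via a shared
    factor (loading sqrt(between)), one factor per network (loading
    sqrt(within - between)) and unit-completing idiosyncratic noise, so
    the population correlation matrix is exactly the requested block
    matrix when ``confound_strength`` is 0.

    Also returns three low-frequency nuisance channels (global, CSF, WM);
    with ``confound_strength > 0`` a mixture of them is added to every
    ROI (partially shared), giving nuisance regression something real to
    remove at the cost of perturbing the block structure.
    """
    if not 0 <= target_between <= target_within:
        raise ValueError("need 0 <= between <= within: requested block "
                         "covariance is not positive definite")
    if target_within >= 1:
        raise ValueError("within-network correlation must be < 1")
    if n_frames < 10:
        raise ValueError("need at least 10 frames")
    rng = np.random.default_rng(seed)
    roi_ids = partition.roi_ids
    labels = partition.network_labels(roi_ids)
    networks = list(dict.fromkeys(labels))
    shared = rng.standard_normal(n_frames)
    net_factors = {net: rng.standard_normal(n_frames) for net in networks}
    eps = rng.standard_normal((n_frames, len(roi_ids)))
    a = np.sqrt(target_between)
    b = np.sqrt(target_within - target_between)
    c = np.sqrt(1.0 - target_within)
    data = (a * shared[:, None]
            + b * np.column_stack([net_factors[l] for l in labels])
            + c * eps)

    channels = {name: _slow_drift(n_frames, tr, rng) for name in ("global", "csf", "wm")}
    if confound_strength > 0:
        mix = np.column_stack(list(channels.values()))  # (n_frames, 3)
        loadings = rng.uniform(0.3, 1.0, size=(3, len(roi_ids)))
        data = data + confound_strength * (mix @ loadings) / np.sqrt(3)
    ts = RoiTimeSeries(data=data, tr=tr, roi_ids=roi_ids, run_id=run_id)
    return ts, channels


def _slow_drift(n_frames: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized low-frequency drift (sum of slow sinusoids)."""
    t = np.arange(n_frames) * tr
    total = n_frames * tr
    freqs = rng.uniform(0.2 / total, 0.02, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    amps = rng.uniform(0.5, 1.0, size=4)
    x = np.sum([a * np.sin(2 * np.pi * f * t + ph)
                for a, f, ph in zip(amps, freqs, phases)], axis=0)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_motion_trace(n_frames: int, tr: float = 2.0,
                          spike_prob: float = 0.03, spike_amp_mm: float = 1.0,
                          drift_sd: float = 0.01,
                          seed: int | None = None) -> MotionTrace:
    """Smooth random-walk motion baseline plus single-frame spikes.

    Translations drift with step SD ``drift_sd`` mm, rotations with a
    step SD that maps to the same arc displacement on the 50-mm sphere;
    spike frames (ground truth in ``spike_frames``) get a transient
    ``spike_amp_mm`` offset on the first translation axis.
    """
    if not 0 <= spike_prob <= 1:
        raise ValueError("spike probability must be in [0, 1]")
    if drift_sd < 0 or spike_amp_mm < 0:
        raise ValueError("amplitudes must be non-negative")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_frames, 6))
    steps[:, :3] *= drift_sd
    steps[:, 3:] *= drift_sd / 50.0  # radians; x50 mm below matches drift_sd
    walk = np.cumsum(steps, axis=0)
    # light smoothing keeps the baseline below the 0.1 Hz displacement band
    kernel = np.ones(5) / 5.0
    baseline = np.apply_along_axis(
        lambda col: np.convolve(col, kernel, mode="same"), 0, walk)
    params = baseline.copy()
    candidates = np.arange(1, max(n_frames - 1, 1))
    spikes = candidates[rng.random(candidates.size) < spike_prob]
    params[spikes, 0] += spike_amp_mm
    return MotionTrace(params=params, tr=tr, spike_frames=spikes)


def _gamma_wave(t: np.ndarray, period: float, peak_frac: float,
                shape: float) -> np.ndarray:
    """Gamma-shaped pressure wave, unit peak at ``peak_frac * period``."""
    tp = peak_frac * period
    x = np.maximum(t, 0.0) / tp
    return x**shape * np.exp(shape * (1.0 - x))


#: Forward (systolic) wave: sharp, peaking early in the cycle.
_FORWARD = dict(peak_frac=0.15, shape=3.0)
#: Reflected wave: broader and lower, as returned from the periphery.
_REFLECTED = dict(peak_frac=0.30, shape=2.0)
_REFLECTION_AMP = 0.9
#: Maximum reflection delay as a fraction of the cycle (overlap = 0).
_MAX_DELAY_FRAC = 0.175


def _cycle_wave(t: np.ndarray, period: float, overlap: float) -> np.ndarray:
    delay = _MAX_DELAY_FRAC * (1.0 - overlap) * period
    return (_gamma_wave(t, period, **_FORWARD)
            + _REFLECTION_AMP * _gamma_wave(t - delay, period, **_REFLECTED))


def pulse_cycle_template(overlap: float, period: float,
                         n_samples: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """One cardiac cycle: forward wave plus delayed reflected wave.

    The reflected wave is a broader, scaled copy of the forward wave,
    delayed by an amount that shrinks linearly to zero as ``overlap``
    grows: at overlap 0 the reflection returns well into the relaxation
    phase (elastic arteries, slow pulse wave, concave relaxation), at
    overlap 1 it rides on top of the systolic peak (stiff arteries, fast
    wave, convex relaxation). Returns (time, waveform), systole-up.
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    t = np.linspace(0.0, period, n_samples, endpoint=False)
    return t, _cycle_wave(t, period, overlap)


def generate_pulse_recording(overlap: float, heart_rate_bpm: float = 60.0,
                             duration_s: float = 120.0,
                             fs_optical: float = 39.0625, fs_ekg: float = 200.0,
                             noise_sd: float = 0.0, ibi_jitter_sd: float = 0.0,
                             seed: int | None = None) -> PulseRecording:
    """Two-channel synthetic recording: optical pulse plus EKG.

    The optical channel repeats the two-wave cycle template (systole-up
    polarity); the EKG channel carries a sharp R spike at each cycle
    onset. Optional white noise on the optical channel and Gaussian
    jitter on the interbeat intervals.
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    if not 40 <= heart_rate_bpm <= 120:
        raise ValueError("heart rate must be in [40, 120] bpm")
    period = 60.0 / heart_rate_bpm
    if duration_s < 2 * period:
        raise ValueError("duration too short for two cardiac cycles")
    rng = np.random.default_rng(seed)

    # beat onsets (exact multiples of the period when unjittered, so cycle
    # boundaries land consistently relative to the sample grid)
    n_beats = int(np.ceil(duration_s / period)) + 1
    if ibi_jitter_sd > 0:
        ibis = np.clip(period + rng.normal(0.0, ibi_jitter_sd, size=n_beats),
                       0.5 * period, 1.5 * period)
        onsets = np.concatenate([[0.0], np.cumsum(ibis)])
    else:
        onsets = period * np.arange(n_beats + 1, dtype=float)
    onsets = onsets[onsets < duration_s]

    t_opt = np.arange(int(duration_s * fs_optical)) / fs_optical
    ends = np.append(onsets[1:], duration_s)
    k = np.clip(np.searchsorted(onsets, t_opt, side="right") - 1, 0, None)
    optical = _cycle_wave(t_opt - onsets[k], ends[k] - onsets[k], overlap)
    if noise_sd > 0:
        optical = optical + rng.normal(0.0, noise_sd, size=optical.size)

    t_ekg = np.arange(int(duration_s * fs_ekg)) / fs_ekg
    ekg = np.zeros_like(t_ekg)
    for t0 in onsets:
        ekg += np.exp(-0.5 * ((t_ekg - t0) / 0.008) ** 2)  # R spike, ~8 ms
        ekg += 0.15 * np.exp(-0.5 * ((t_ekg - t0 - 0.25) / 0.04) ** 2)  # T wave
    ekg += rng.normal(0.0, 0.01, size=ekg.size)

    return PulseRecording(optical=optical, fs_optical=fs_optical, ekg=ekg,
                          fs_ekg=fs_ekg, true_r_times=onsets,
                          true_overlap=overlap)


# ---------------------------------------------------------------------------
# observed-cohort plumbing: map latent scores to the measured quantities
# ---------------------------------------------------------------------------

@dataclass
class SubjectTargets:
    """Generator settings derived from one subject's latent scores."""

    overlap: float
    target_within: float
    target_between: float


def subject_targets(row: pd.Series) -> SubjectTargets:
    """Map latent vascular/function scores to pulse and connectivity knobs.

    Lower vascular scores (stiffer arteries) push the reflected-wave
    overlap up; higher function scores push within-network correlation up
    and between-network correlation down, raising segregation.
    """
    overlap = float(1.0 / (1.0 + np.exp(row["vascular"])))
    tw = float(np.clip(0.40 + 0.06 * row["function"], 0.15, 0.75))
    tb = float(np.clip(0.12 - 0.025 * row["function"], 0.01, tw - 0.05))
    return SubjectTargets(overlap=overlap, target_within=tw, target_between=tb)


def generate_raw_scores(subjects: pd.DataFrame,
                        seed: int | None = None) -> pd.DataFrame:
    """Raw cognitive test scores plus structural volumes per subject.

    Test scores load on the cognition latent (timed tests negatively,
    via a log-linear model keeping times positive); raw lesion volume is
    log-normal with a negative structure loading plus ICV and sex
    effects; mean cortical thickness loads positively on structure.
    """
    rng = np.random.default_rng(seed)
    n = len(subjects)
    c = subjects["cognition"].to_numpy(dtype=float)
    s = subjects["structure"].to_numpy(dtype=float)
    sex = subjects["sex"].to_numpy(dtype=float)

    def noisy(base, scale, loading, sd=0.5):
        return base + scale * (loading * c + rng.normal(0, sd, n))

    out = pd.DataFrame(index=subjects.index)
    out["logical_memory_immediate"] = noisy(28, 6, 0.7)
    out["logical_memory_delayed"] = noisy(25, 7, 0.7)
    out["verbal_pairing_immediate"] = noisy(30, 8, 0.6)
    out["verbal_pairing_delayed"] = noisy(9, 3, 0.6)
    out["trail_a"] = 30 * np.exp(-0.25 * c + rng.normal(0, 0.15, n))
    out["trail_b"] = 70 * np.exp(-0.30 * c + rng.normal(0, 0.18, n))
    out["cfl"] = noisy(40, 9, 0.5)
    out["ospan"] = noisy(45, 12, 0.6)
    out["raven"] = noisy(20, 6, 0.7)
    out["kbit_nonverbal"] = noisy(30, 7, 0.7)
    out["shipley_vocab"] = noisy(32, 4, 0.4)
    out["kbit_verbal"] = noisy(45, 8, 0.4)

    icv = rng.normal(1.5e6, 1.2e5, n) + 1.0e5 * sex
    out["icv"] = icv
    out["raw_wmsa"] = np.exp(7.0 - 0.8 * s + 1.5e-6 * (icv - icv.mean())
                             + rng.normal(0, 0.4, n))
    out["cortical_thickness"] = 2.45 + 0.12 * s + rng.normal(0, 0.04, n)
    out["sex"] = subjects["sex"]
    out["age"] = subjects["age"]
    return out
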