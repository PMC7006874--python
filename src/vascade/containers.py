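"""Shared in-memory containers for the pipeline stages.

All time series are plain NumPy arrays wrapped with the minimal metadata
(sampling interval, labels) the downstream stages need; tabular data are
pandas DataFrames keyed by opaque subject IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Networks whose segregation indexes higher-order cognition.
ASSOCIATION_NETWORKS = (
    "cingulo-opercular",
    "dorsal attention",
    "default",
    "fronto-parietal",
    "memory",
    "salience",
    "ventral attention",
)

#: Networks tied to sensory and motor processing.
SENSORIMOTOR_NETWORKS = (
    "auditory",
    "sensorimotor hand",
    "sensorimotor mouth",
    "visual",
)


@dataclass
class RoiTimeSeries:
    """Frames x ROIs numeric matrix for one resting-state run."""

    data: np.ndarray  # (n_frames, n_rois)
    tr: float  # sampling interval, seconds
    roi_ids: list[str]
    run_id: str = "run1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ROI time series must be 2-D (frames x ROIs)")
        if self.data.shape[1] != len(self.roi_ids):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.roi_ids)} ROI ids"
            )
        if self.tr <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "RoiTimeSeries":
        return RoiTimeSeries(data=data, tr=self.tr, roi_ids=list(self.roi_ids),
                             run_id=self.run_id)


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame.

    Columns 0-2 are translations in mm, columns 3-5 rotations in radians.
    """

    params: np.ndarray  # (n_frames, 6)
    tr: float  # frame interval, seconds
    spike_frames: np.ndarray | None = None  # generator ground truth

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must have shape (n_frames, 6)")
        if self.params.shape[0] < 1:
            raise ValueError("motion trace needs at least one frame")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")
        if self.tr <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class PulseRecording:
    """Two-channel pulse recording: optical intensity plus EKG.

    The channels are sampled at independent rates (optical instruments
    multiplex slowly; EKG amplifiers run fast). Ground-truth fields are
    populated only by the synthetic generator.
    """

    optical: np.ndarray
    fs_optical: float
    ekg: np.ndarray
    fs_ekg: float
    true_r_times: np.ndarray | None = None
    true_overlap: float | None = None

    def __post_init__(self) -> None:
        self.optical = np.asarray(self.optical, dtype=float)
        self.ekg = np.asarray(self.ekg, dtype=float)
        if self.optical.size == 0 or self.ekg.size == 0:
            raise ValueError("both channels must be non-empty")
        if self.fs_optical <= 0 or self.fs_ekg <= 0:
            raise ValueError("sampling rates must be positive")

    @property
    def duration_s(self) -> float:
        return self.optical.size / self.fs_optical


@dataclass
class SystemPartition:
    """ROI -> network labels plus network -> system-class mapping.

    ``system_class`` is one of ``association``, ``sensorimotor`` or
    ``excluded``; ROI rosters are data-driven, never hard-coded.
    """

    roi_to_network: dict[str, str]
    network_to_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.network_to_class:
            self.network_to_class = default_class_map(
                sorted(set(self.roi_to_network.values()))
            )
        valid = {"association", "sensorimotor", "excluded"}
        for net, cls in self.network_to_class.items():
            if cls not in valid:
                raise ValueError(f"unknown system class {cls!r} for network {net!r}")
        for roi, net in self.roi_to_network.items():
            if net not in self.network_to_class:
                raise ValueError(f"network {net!r} of ROI {roi!r} has no system class")

    @property
    def roi_ids(self) -> list[str]:
        return list(self.roi_to_network)

    def networks_in_class(self, system_class: str) -> list[str]:
        return [n for n, c in self.network_to_class.items() if c == system_class]

    def rois_in_network(self, network: str) -> list[str]:
        return [r for r, n in self.roi_to_network.items() if n == network]

    def network_labels(self, roi_ids: list[str]) -> np.ndarray:
        return np.array([self.roi_to_network[r] for r in roi_ids])


def default_class_map(networks: list[str]) -> dict[str, str]:
    """Assign each network label to its canonical system class."""
    out = {}
    for net in networks:
        if net in ASSOCIATION_NETWORKS:
            out[net] = "association"
        elif net in SENSORIMOTOR_NETWORKS:
            out[net] = "sensorimotor"
        else:
            out[net] = "excluded"
    return out


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI matrix, on the r or Fisher-Z scale.

    The diagonal is stored as zero; ``negatives_zeroed`` records whether
    negative entries have been clipped to zero.
    """

    values: np.ndarray
    roi_ids: list[str]
    scale: str = "r"  # "r" or "z"
    negatives_zeroed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roi_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ROI roster")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if self.negatives_zeroed and self.values.min() < 0:
            raise ValueError("negatives_zeroed flag set but matrix has negatives")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.roi_ids, columns=self.roi_ids)
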