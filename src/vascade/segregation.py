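"""Connectivity matrices and resting-state system segregation.

System segregation quantifies the relative excess of within-system over
between-system connectivity::

    segregation = (Zw - Zb) / Zw

where ``Zw`` is the mean within-system Fisher-Z correlation and ``Zb``
the mean between-system Fisher-Z correlation, computed separately for
the association and sensorimotor system classes. Negative Z values are
set to zero before averaging, per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ConnectivityMatrix, RoiTimeSeries, SystemPartition


@dataclass
class SegregationResult:
    """Within/between means and their normalized difference."""

    system_class: str
    z_within: float
    z_between: float
    segregation: float
    n_within_pairs: int
    n_between_pairs: int


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation for every ROI pair.

    The diagonal is zeroed for storage. A zero-variance ROI is an error
    (its correlation is undefined) and is reported by name.
    """
    if ts.n_frames < 3:
        raise ValueError("need at least 3 frames")
    if ts.n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.roi_ids[i] for i in dead]
        raise ValueError(f"zero-variance ROI(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2  # enforce exact symmetry
    return ConnectivityMatrix(values=r, roi_ids=list(ts.roi_ids), scale="r")


def fisher_z(mat: ConnectivityMatrix) -> ConnectivityMatrix:
    """Entrywise atanh; off-diagonal |r| = 1 is an error."""
    if mat.scale != "r":
        raise ValueError("input must be on the r scale")
    vals = mat.values
    off = ~np.eye(len(mat.roi_ids), dtype=bool)
    if np.any(np.abs(vals[off]) >= 1):
        raise ValueError("off-diagonal |r| >= 1: Fisher Z undefined")
    z = np.arctanh(vals)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, roi_ids=list(mat.roi_ids), scale="z",
                              negatives_zeroed=mat.negatives_zeroed)


def zero_negatives(mat: ConnectivityMatrix) -> ConnectivityMatrix:
    """Clip negative entries to zero (idempotent); sets the flag."""
    return ConnectivityMatrix(values=np.maximum(mat.values, 0.0),
                              roi_ids=list(mat.roi_ids), scale=mat.scale,
                              negatives_zeroed=True)


def system_segregation(mat: ConnectivityMatrix, partition: SystemPartition,
                       system_class: str) -> SegregationResult:
    """Segregation of one system class (association or sensorimotor).

    Within pairs: unordered ROI pairs inside the same network of the
    class. Between pairs: unordered pairs spanning two *different*
    networks of the same class. Pairs touching networks outside the class
    never enter either mean; the diagonal is excluded.
    """
    if not mat.negatives_zeroed:
        raise ValueError("zero negatives before computing segregation")
    networks = partition.networks_in_class(system_class)
    if len(networks) < 2:
        raise ValueError(f"need >= 2 networks in class {system_class!r}")
    roi_ids = mat.roi_ids
    labels = np.array([partition.roi_to_network.get(r) for r in roi_ids], dtype=object)
    in_class = np.isin(labels, networks)
    idx = np.flatnonzero(in_class)
    if idx.size < 2:
        raise ValueError(f"fewer than 2 ROIs in class {system_class!r}")
    sub = mat.values[np.ix_(idx, idx)]
    same_net = labels[idx][:, None] == labels[idx][None, :]
    iu = np.triu_indices(idx.size, k=1)
    within = sub[iu][same_net[iu]]
    between = sub[iu][~same_net[iu]]
    zw = float(within.mean()) if within.size else np.nan
    zb = float(between.mean()) if between.size else np.nan
    if not zw > 0:
        raise ValueError("mean within-system connectivity is not positive; "
                         "segregation undefined")
    return SegregationResult(
        system_class=system_class,
        z_within=zw,
        z_between=zb,
        segregation=(zw - zb) / zw,
        n_within_pairs=int(within.size),
        n_between_pairs=int(between.size),
    )


def connectivity_pipeline(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Correlate, Fisher-transform, zero negatives — the per-subject chain."""
    return zero_negatives(fisher_z(correlation_matrix(ts)))
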