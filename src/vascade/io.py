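"""Delimited-text I/O for every artifact the pipeline reads or writes.

All tables are header-bearing CSV/TSV (diffable fixtures, no binary
formats); square matrices carry ROI/variable labels on both axes. Every
writer drops a ``<name>.config.txt`` sidecar echoing the parameters and
seed needed to regenerate the file bit-identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MotionTrace, RoiTimeSeries, SystemPartition


class SchemaError(ValueError):
    """Input file does not match the expected layout."""


def write_config_echo(path: Path | str, params: dict) -> None:
    lines = [f"{k}={v}" for k, v in sorted(params.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config_echo(path: Path | str) -> dict[str, str]:
    out = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        if "=" not in line:
            raise SchemaError(f"{path}: line {i}: expected key=value")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


# -- ROI time series ---------------------------------------------------------

def write_timeseries(path: Path | str, ts: RoiTimeSeries) -> None:
    df = pd.DataFrame(ts.data, columns=ts.roi_ids)
    df.insert(0, "frame", np.arange(ts.n_frames))
    df.to_csv(path, index=False)
    write_config_echo(str(path) + ".config.txt",
                     {"tr_s": ts.tr, "run_id": ts.run_id, "n_rois": ts.n_rois})


def read_timeseries(path: Path | str) -> RoiTimeSeries:
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise SchemaError(f"{path}: missing 'frame' column")
    cfg = read_config_echo(str(path) + ".config.txt")
    return RoiTimeSeries(
        data=df.drop(columns="frame").to_numpy(dtype=float),
        tr=float(cfg.get("tr_s", 2.0)),
        roi_ids=[c for c in df.columns if c != "frame"],
        run_id=cfg.get("run_id", Path(path).stem),
    )


# -- motion ------------------------------------------------------------------

_MOTION_COLS = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                "rot_x_rad", "rot_y_rad", "rot_z_rad"]


def write_motion(path: Path | str, motion: MotionTrace) -> None:
    df = pd.DataFrame(motion.params, columns=_MOTION_COLS)
    df.insert(0, "frame", np.arange(motion.n_frames))
    df.to_csv(path, index=False)
    write_config_echo(str(path) + ".config.txt", {"tr_s": motion.tr})


def read_motion(path: Path | str) -> MotionTrace:
    df = pd.read_csv(path)
    missing = [c for c in _MOTION_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing motion columns {missing}")
    cfg = read_config_echo(str(path) + ".config.txt")
    return MotionTrace(params=df[_MOTION_COLS].to_numpy(dtype=float),
                       tr=float(cfg.get("tr_s", 2.0)))


# -- partition ---------------------------------------------------------------

def write_partition(path: Path | str, partition: SystemPartition,
                    class_map_path: Path | str | None = None) -> None:
    rows = [f"{roi}\t{net}" for roi, net in partition.roi_to_network.items()]
    Path(path).write_text("roi_id\tnetwork_label\n" + "\n".join(rows) + "\n")
    if class_map_path is not None:
        rows = [f"{net}\t{cls}" for net, cls in partition.network_to_class.items()]
        Path(class_map_path).write_text(
            "network_label\tsystem_class\n" + "\n".join(rows) + "\n")


def read_partition(path: Path | str,
                   class_map_path: Path | str | None = None) -> SystemPartition:
    roi_to_network = {}
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["roi_id", "network_label"]:
        raise SchemaError(f"{path}: line 1: expected header 'roi_id\\tnetwork_label'")
    for i, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not all(p.strip() for p in parts):
            raise SchemaError(f"{path}: line {i}: expected 'roi_id\\tnetwork_label'")
        roi_to_network[parts[0].strip()] = parts[1].strip()
    if not roi_to_network:
        raise SchemaError(f"{path}: no ROI rows")
    network_to_class: dict[str, str] = {}
    if class_map_path is not None:
        for i, line in enumerate(Path(class_map_path).read_text().splitlines()[1:], 2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SchemaError(f"{class_map_path}: line {i}: expected 2 columns")
            network_to_class[parts[0].strip()] = parts[1].strip()
    return SystemPartition(roi_to_network=roi_to_network,
                           network_to_class=network_to_class)


# -- matrices and tables -----------------------------------------------------

def write_matrix(path: Path | str, values: np.ndarray, labels: list[str]) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path)


def read_matrix(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise SchemaError(f"{path}: not a labeled square matrix")
    df.columns.name = None
    return df


def write_pulse(optical_path: Path | str, ekg_path: Path | str, rec) -> None:
    t_opt = np.arange(rec.optical.size) / rec.fs_optical
    pd.DataFrame({"time_s": t_opt, "optical": rec.optical}).to_csv(
        optical_path, index=False)
    t_ekg = np.arange(rec.ekg.size) / rec.fs_ekg
    pd.DataFrame({"time_s": t_ekg, "ekg": rec.ekg}).to_csv(ekg_path, index=False)
    write_config_echo(str(optical_path) + ".config.txt",
                      {"fs_optical_hz": rec.fs_optical, "fs_ekg_hz": rec.fs_ekg,
                       "true_overlap": rec.true_overlap})


def read_pulse(optical_path: Path | str, ekg_path: Path | str):
    from .containers import PulseRecording

    opt = pd.read_csv(optical_path)
    ekg = pd.read_csv(ekg_path)
    for df, name, col in ((opt, optical_path, "optical"), (ekg, ekg_path, "ekg")):
        if col not in df.columns or "time_s" not in df.columns:
            raise SchemaError(f"{name}: expected columns time_s,{col}")
    cfg = read_config_echo(str(optical_path) + ".config.txt")
    return PulseRecording(
        optical=opt["optical"].to_numpy(dtype=float),
        fs_optical=float(cfg.get("fs_optical_hz", 39.0625)),
        ekg=ekg["ekg"].to_numpy(dtype=float),
        fs_ekg=float(cfg.get("fs_ekg_hz", 200.0)),
    )


def write_subject_table(path: Path | str, table: pd.DataFrame) -> None:
    table.to_csv(path, index=True, index_label="subject_id")


def read_subject_table(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: missing 'subject_id' column")
    return df.set_index("subject_id")
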