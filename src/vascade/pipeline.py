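"""End-to-end stage runners binding the library modules to a cohort
directory layout.

Layout written by :func:`simulate_cohort` and consumed by the other
stages::

    cohort/
      partition.tsv, class_map.tsv, config.txt
      subjects.csv                 # latent + demographic columns
      raw_scores.csv               # cognitive tests, volumes
      <subject_id>/
        roi_run1.csv, roi_run2.csv, nuisance_run1.csv, ...
        motion_run1.csv, motion_run2.csv
        pulse_optical.csv, pulse_ekg.csv
      derived/
        zmatrix_<subject_id>.csv   # after the fc stage
        subject_table.csv          # accumulating analysis variables
        cascade_report.txt

Each stage logs per-subject retained-frame counts and exclusions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cascade as casc
from . import io as vio
from .constructs import adjust_wmsa, constructs_from_raw
from .containers import RoiTimeSeries
from .preproc import (
    CensorMask,
    NuisanceSet,
    build_censor_mask,
    compute_fdfilt,
    concat_runs,
    preprocess_run,
    qc_min_frames,
    volterra_expansion,
)
from .prefx import prefx_from_recording
from .segregation import connectivity_pipeline, system_segregation
from .synthetic import (
    CascadeParams,
    default_partition,
    generate_motion_trace,
    generate_pulse_recording,
    generate_raw_scores,
    generate_roi_timeseries,
    generate_subjects,
    subject_targets,
)

log = logging.getLogger("vascade")


def simulate_cohort(outdir: Path | str, params: CascadeParams,
                    n_per_network: int = 4, n_frames: int = 160,
                    n_runs: int = 2, tr: float = 2.0,
                    confound_strength: float = 0.3,
                    pulse_duration_s: float = 60.0) -> Path:
    """Generate and write a full synthetic cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    subjects = generate_subjects(params)
    partition = default_partition(n_per_network)
    vio.write_partition(outdir / "partition.tsv", partition,
                        outdir / "class_map.tsv")
    subjects.to_csv(outdir / "subjects.csv", index_label="subject_id")
    raw = generate_raw_scores(subjects, seed=int(rng.integers(2**31)))
    raw.to_csv(outdir / "raw_scores.csv", index_label="subject_id")

    for sid, row in subjects.iterrows():
        sdir = outdir / str(sid)
        sdir.mkdir(exist_ok=True)
        tgt = subject_targets(row)
        for run in range(1, n_runs + 1):
            seed = int(rng.integers(2**31))
            ts, channels = generate_roi_timeseries(
                tgt.target_within, tgt.target_between, partition, n_frames,
                tr=tr, seed=seed, confound_strength=confound_strength,
                run_id=f"run{run}")
            vio.write_timeseries(sdir / f"roi_run{run}.csv", ts)
            pd.DataFrame(channels).to_csv(sdir / f"nuisance_run{run}.csv",
                                          index=False)
            motion = generate_motion_trace(n_frames, tr=tr,
                                           seed=int(rng.integers(2**31)))
            vio.write_motion(sdir / f"motion_run{run}.csv", motion)
        rec = generate_pulse_recording(
            tgt.overlap, duration_s=pulse_duration_s, noise_sd=0.02,
            ibi_jitter_sd=0.02, seed=int(rng.integers(2**31)))
        vio.write_pulse(sdir / "pulse_optical.csv", sdir / "pulse_ekg.csv", rec)

    vio.write_config_echo(outdir / "config.txt", {
        "n_subjects": params.n_subjects,
        "age_range": params.age_range,
        "path_coefficients": tuple(params.path_coefficients),
        "noise_sd": params.noise_sd,
        "seed": params.seed,
        "n_per_network": n_per_network,
        "n_frames": n_frames,
        "n_runs": n_runs,
        "tr_s": tr,
        "confound_strength": confound_strength,
        "pulse_duration_s": pulse_duration_s,
    })
    log.info("simulated cohort of %d subjects at %s", params.n_subjects, outdir)
    return outdir


def _subject_dirs(cohort_dir: Path) -> list[Path]:
    subjects = pd.read_csv(cohort_dir / "subjects.csv")["subject_id"]
    return [cohort_dir / str(s) for s in subjects]


def _load_nuisance(sdir: Path, run: int, ts: RoiTimeSeries,
                   motion) -> NuisanceSet:
    chan = pd.read_csv(sdir / f"nuisance_run{run}.csv")
    return NuisanceSet(
        global_signal=ts.data.mean(axis=1),
        csf=chan["csf"].to_numpy(dtype=float),
        wm=chan["wm"].to_numpy(dtype=float),
        motion_volterra=volterra_expansion(motion),
    )


def run_fc(cohort_dir: Path | str, fd_threshold: float = 0.1,
           edge_trim: int = 5, min_segment: int = 5,
           min_per_run: int = 50) -> pd.DataFrame:
    """Preprocess every subject's runs and write connectivity Z-matrices.

    Returns a per-subject log frame (retained counts per run, mean
    displacement, inclusion flag).
    """
    cohort_dir = Path(cohort_dir)
    derived = cohort_dir / "derived"
    derived.mkdir(exist_ok=True)
    records = []
    for sdir in _subject_dirs(cohort_dir):
        sid = sdir.name
        runs, retained, fd_means = [], [], []
        run = 1
        while (sdir / f"roi_run{run}.csv").exists():
            ts = vio.read_timeseries(sdir / f"roi_run{run}.csv")
            motion = vio.read_motion(sdir / f"motion_run{run}.csv")
            nuis = _load_nuisance(sdir, run, ts, motion)
            clean, mask, fd = preprocess_run(
                ts, motion, nuis, fd_threshold=fd_threshold,
                edge_trim=edge_trim, min_segment=min_segment)
            runs.append(clean)
            retained.append(mask.n_retained)
            fd_means.append(float(fd.values.mean()))
            run += 1
        include = qc_min_frames(
            [CensorMask(np.ones(r, dtype=bool)) for r in retained],
            min_per_run=min_per_run) if retained else False
        rec = {"subject_id": sid, "included": include,
               "mean_fdfilt": float(np.mean(fd_means)),
               **{f"retained_run{i + 1}": r for i, r in enumerate(retained)}}
        if include:
            z = connectivity_pipeline(concat_runs(runs))
            vio.write_matrix(derived / f"zmatrix_{sid}.csv", z.values, z.roi_ids)
        else:
            log.warning("subject %s excluded: retained %s", sid, retained)
        records.append(rec)
    log_df = pd.DataFrame(records).set_index("subject_id")
    log_df.to_csv(derived / "fc_log.csv")
    return log_df


def run_segregate(cohort_dir: Path | str) -> pd.DataFrame:
    """Segregation of both system classes for every included subject."""
    cohort_dir = Path(cohort_dir)
    derived = cohort_dir / "derived"
    partition = vio.read_partition(cohort_dir / "partition.tsv",
                                   cohort_dir / "class_map.tsv")
    from .containers import ConnectivityMatrix

    rows = []
    for mat_path in sorted(derived.glob("zmatrix_*.csv")):
        sid = mat_path.stem.replace("zmatrix_", "")
        df = vio.read_matrix(mat_path)
        z = ConnectivityMatrix(values=df.to_numpy(dtype=float),
                               roi_ids=list(df.index), scale="z",
                               negatives_zeroed=True)
        assoc = system_segregation(z, partition, "association")
        sm = system_segregation(z, partition, "sensorimotor")
        rows.append({"subject_id": sid,
                     "assoc_segregation": assoc.segregation,
                     "sm_segregation": sm.segregation})
    out = pd.DataFrame(rows).set_index("subject_id")
    _merge_into_subject_table(derived, out)
    return out


def run_prefx(cohort_dir: Path | str) -> pd.DataFrame:
    """Pulse elasticity score for every subject with a pulse recording."""
    cohort_dir = Path(cohort_dir)
    rows = []
    for sdir in _subject_dirs(cohort_dir):
        rec = vio.read_pulse(sdir / "pulse_optical.csv", sdir / "pulse_ekg.csv")
        res = prefx_from_recording(rec)
        rows.append({"subject_id": sdir.name, "prefx": res.prefx,
                     "prefx_n_beats": res.n_beats})
    out = pd.DataFrame(rows).set_index("subject_id")
    _merge_into_subject_table(cohort_dir / "derived", out)
    return out


def run_constructs(cohort_dir: Path | str) -> pd.DataFrame:
    """Construct composites and adjusted lesion volume from raw scores."""
    cohort_dir = Path(cohort_dir)
    raw = pd.read_csv(cohort_dir / "raw_scores.csv").set_index("subject_id")
    test_cols = [c for c in raw.columns
                 if c not in ("icv", "raw_wmsa", "cortical_thickness",
                              "sex", "age")]
    out = constructs_from_raw(raw[test_cols])
    out["wmsa"] = adjust_wmsa(raw["raw_wmsa"], raw["icv"], raw["sex"])
    out["cortical_thickness"] = raw["cortical_thickness"]
    out["age"] = raw["age"]
    out["sex"] = raw["sex"]
    _merge_into_subject_table(cohort_dir / "derived", out)
    return out


def _merge_into_subject_table(derived: Path, new: pd.DataFrame) -> None:
    derived.mkdir(exist_ok=True)
    path = derived / "subject_table.csv"
    if path.exists():
        table = vio.read_subject_table(path)
        table = table.drop(columns=[c for c in new.columns if c in table],
                           errors="ignore")
        table = table.join(new, how="outer")
    else:
        table = new
    vio.write_subject_table(path, table)


def run_cascade(subject_table: Path | str | pd.DataFrame,
                n_boot: int = 10_000, seed: int | None = None,
                report_path: Path | str | None = None,
                from_matrix: bool = False) -> casc.CascadeResult:
    """Cascade analysis from a subject table, or in closed form from a
    labeled correlation-matrix CSV (``from_matrix=True``)."""
    if from_matrix:
        R = (subject_table if isinstance(subject_table, pd.DataFrame)
             else vio.read_matrix(subject_table))
        result = casc.cascade_from_matrix(R)
    else:
        table = (subject_table if isinstance(subject_table, pd.DataFrame)
                 else vio.read_subject_table(subject_table))
        result = casc.bootstrap_cascade(table, n_boot=n_boot, seed=seed)
    if report_path is not None:
        Path(report_path).write_text(format_cascade_report(result))
    return result


def format_cascade_report(result: casc.CascadeResult) -> str:
    """Human-readable summary of a cascade analysis."""
    lines = ["cascade level correlation matrix (|r|):"]
    header = "          " + "  ".join(f"{n:>10}" for n in result.level_names)
    lines.append(header)
    for name, row in zip(result.level_names, result.abs_matrix):
        lines.append(f"{name:>10}" + "  ".join(f"{v:10.3f}" for v in row))
    m1, m2, m3 = result.m_raw
    lines.append(f"off-diagonal means (raw |r|): 1-off={m1:.3f} "
                 f"2-off={m2:.3f} 3-off={m3:.3f}")
    f1, f2, f3 = result.m_fisher
    lines.append(f"off-diagonal means (Fisher):  1-off={f1:.3f} "
                 f"2-off={f2:.3f} 3-off={f3:.3f}")
    if result.bootstrap_p:
        lines.append(f"bootstrap (B={result.n_boot}, seed={result.seed}, "
                     f"redrawn={result.n_degenerate_redrawn}):")
        lines.append("  " + json.dumps(result.bootstrap_p))
    return "\n".join(lines) + "\n"
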