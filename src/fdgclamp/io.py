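"""CSV/YAML serialization of cohorts, curves and results.

All tabular data are plain CSV with unit-bearing column names; voxel maps
are whitespace text arrays with a shape header line.  A simulated cohort
is written as one directory per subject::

    cohort/
      metadata.csv            # one row per subject: observables only
      truth.csv               # generator targets (for validation)
      manifest.yaml           # seed, config hash, package version
      sub-LR001/
        tac_thorax.csv        # frame_start_s, frame_end_s, <region>_kbq_ml...
        tac_abdomen.csv, tac_thigh.csv, tac_neck_static.csv, tac_brain_static.csv
        plasma.csv            # time_min, activity_kbq_per_ml
        clamp.csv             # time_min, gir_umol_kg_min, glucose_mmol_l, ...
        voxel_map.txt
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clamp import ClampRecord, TracerBalance
from .cohort import TISSUE_PLAN, Cohort, SubjectRecord
from .frames import PRESETS, FrameSchedule, TimeActivityCurve
from .input_function import PlasmaSample

FLOAT_FMT = "%.10g"

# metadata columns the analysis pipeline is allowed to see (observables);
# everything else sampled by the generator is ground truth
OBSERVABLE_COLS = [
    "age_years", "weight_kg", "ffm_kg",
    "mass_brain", "mass_muscle", "mass_vat", "mass_sat_abdominal",
    "mass_sat_femoral", "mass_liver", "mass_bat", "mass_myocardium",
    "glucose_fasting_mmol_l", "insulin_fasting_pmol_l",
    "glucose_ogtt2h_mmol_l", "insulin_ogtt2h_pmol_l",
    "hba1c_ifcc_mmol_mol", "ffa_fasting_mmol_l",
    "dose_mbq", "urinary_mbq", "t_steady_min",
]


def write_tac_table(path: Path, tacs: dict[str, TimeActivityCurve]) -> None:
    """Write one or more same-schedule TACs as a frame table."""
    schedules = {id(t.schedule): t.schedule for t in tacs.values()}
    first = next(iter(tacs.values())).schedule
    for t in tacs.values():
        if t.schedule.frames != first.frames:
            raise ValueError("all regions in one table must share a schedule")
    df = pd.DataFrame({
        "frame_start_s": first.starts_s,
        "frame_end_s": first.ends_s,
    })
    for region, tac in tacs.items():
        df[f"{region}_kbq_ml"] = tac.values
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_tac_table(path: Path) -> dict[str, TimeActivityCurve]:
    """Read a frame table back into per-region TACs (validated, sorted)."""
    df = pd.read_csv(path)
    for col in ("frame_start_s", "frame_end_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    regions = [c for c in df.columns if c.endswith("_kbq_ml")]
    if not regions:
        raise ValueError(f"{path}: no '<region>_kbq_ml' activity columns")
    df = df.sort_values("frame_start_s", kind="stable").reset_index(drop=True)
    starts = df["frame_start_s"].to_numpy(dtype=float)
    durs = df["frame_end_s"].to_numpy(dtype=float) - starts
    schedule = FrameSchedule(tuple(zip(starts, durs)))  # validates overlap
    return {
        c[: -len("_kbq_ml")]: TimeActivityCurve(
            schedule, df[c].to_numpy(dtype=float), region=c[: -len("_kbq_ml")])
        for c in regions
    }


def write_plasma(path: Path, samples: list[PlasmaSample]) -> None:
    pd.DataFrame({
        "time_min": [s.time_min for s in samples],
        "activity_kbq_per_ml": [s.activity_kbq_ml for s in samples],
    }).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_plasma(path: Path) -> list[PlasmaSample]:
    df = pd.read_csv(path)
    for col in ("time_min", "activity_kbq_per_ml"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [PlasmaSample(float(t), float(a))
            for t, a in zip(df["time_min"], df["activity_kbq_per_ml"])]


def write_clamp(path: Path, rec: ClampRecord) -> None:
    pd.DataFrame({
        "time_min": rec.times_min,
        "gir_umol_kg_min": rec.gir_umol_kg_min,
        "glucose_mmol_l": rec.glucose_mmol_l,
        "insulin_pmol_l": rec.insulin_pmol_l,
        "ffa_mmol_l": rec.ffa_mmol_l,
    }).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_clamp(path: Path, steady_start_min: float) -> ClampRecord:
    """Read a clamp series; the steady-state window runs from
    ``steady_start_min`` to the end of the record."""
    df = pd.read_csv(path)
    cols = ("time_min", "gir_umol_kg_min", "glucose_mmol_l",
            "insulin_pmol_l", "ffa_mmol_l")
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    times = df["time_min"].to_numpy(float)
    return ClampRecord(
        times_min=times,
        gir_umol_kg_min=df["gir_umol_kg_min"].to_numpy(float),
        glucose_mmol_l=df["glucose_mmol_l"].to_numpy(float),
        insulin_pmol_l=df["insulin_pmol_l"].to_numpy(float),
        ffa_mmol_l=df["ffa_mmol_l"].to_numpy(float),
        steady_state_min=(float(steady_start_min), float(times[-1])),
    )


def write_voxel_map(path: Path, arr: np.ndarray) -> None:
    """Plain-text 3-D array with a '# shape: a b c' header."""
    arr = np.asarray(arr, dtype=float)
    with open(path, "w") as fh:
        fh.write("# shape: " + " ".join(str(d) for d in arr.shape) + "\n")
        np.savetxt(fh, arr.reshape(arr.shape[0], -1), fmt=FLOAT_FMT)


def read_voxel_map(path: Path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# shape:"):
            raise ValueError(f"{path}: missing shape header")
        shape = tuple(int(x) for x in header.split(":")[1].split())
        return np.loadtxt(fh).reshape(shape)


def _group_tacs_by_schedule(sub: SubjectRecord) -> dict[str, dict[str, TimeActivityCurve]]:
    by_preset: dict[str, dict[str, TimeActivityCurve]] = {}
    for tissue, (preset, _m) in TISSUE_PLAN.items():
        by_preset.setdefault(preset, {})[tissue] = sub.tacs[tissue]
    by_preset.setdefault("thorax", {})["left_ventricle"] = sub.idif
    return by_preset


def write_cohort(cohort: Cohort, out_dir: Path,
                 config_hash: str | None = None) -> None:
    """Serialize a simulated cohort to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows, truth_rows = [], []
    for sub in cohort.subjects:
        sdir = out_dir / f"sub-{sub.subject_id}"
        sdir.mkdir(exist_ok=True)
        for preset, tacs in _group_tacs_by_schedule(sub).items():
            write_tac_table(sdir / f"tac_{preset}.csv", tacs)
        write_plasma(sdir / "plasma.csv", sub.plasma_samples)
        write_clamp(sdir / "clamp.csv", sub.clamp_record)
        write_voxel_map(sdir / "voxel_map.txt", sub.voxel_map)
        row = {"subject_id": sub.subject_id, "group": sub.group}
        row.update({k: sub.metadata[k] for k in OBSERVABLE_COLS
                    if k in sub.metadata})
        row["urinary_mbq"] = sub.tracer_balance.urinary_mbq
        meta_rows.append(row)
        truth = {"subject_id": sub.subject_id, "group": sub.group}
        truth.update(sub.metadata)
        for tissue, kp in sub.kinetics.items():
            truth[f"k1_{tissue}"] = kp.k1
            truth[f"ki_true_{tissue}"] = kp.ki_true
        truth["input_scale"] = sub.input_scale
        truth_rows.append(truth)
    pd.DataFrame(meta_rows).to_csv(out_dir / "metadata.csv", index=False,
                                   float_format=FLOAT_FMT)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False,
                                    float_format=FLOAT_FMT)
    manifest = {
        "seed": cohort.seed,
        "n_subjects": len(cohort.subjects),
        "groups": sorted({s.group for s in cohort.subjects}),
        "package_version": __version__,
        "config_hash": config_hash,
    }
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def config_hash(obj) -> str:
    """Stable short hash of a config's serialized form."""
    text = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
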