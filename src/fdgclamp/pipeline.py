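"""End-to-end analysis: raw cohort directory -> per-subject measures -> stats.

For each subject the pipeline (i) assembles the hybrid input function
from the left-ventricle curve and the plasma samples, (ii) estimates
tissue tracer uptake by Patlak regression (myocardium, liver, femoral
muscle -- dynamically imaged tissues) or FUR (VAT, abdominal and femoral
SAT, BAT, brain -- late/static acquisitions), (iii) converts rates to
per-mass and whole-depot glucose uptake, and (iv) computes the clamp
indices (M value, tracer-based Rd, EGP = Rd - GIR, FFA suppression,
Matsuda-ISI, HbA1c conversion).  The cohort table then enters the
statistical layer: BH-FDR-corrected two-group comparisons, correlations
of the M value with tissue uptake (overall and per group, brain uptake
age-adjusted first), and a voxelwise two-sample map of the brain arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clamp as cl
from . import io as cio
from . import kinetics as kin
from . import stats as st
from .cohort import FUR_BLOCK_MID_MIN, TISSUE_PLAN
from .config import PipelineConfig
from .input_function import InputFunction, build_hybrid_input

log = logging.getLogger("fdgclamp")

# variables entering the two-group comparison family (BH-FDR corrected)
COMPARISON_VARS = [
    "age_years", "weight_kg", "ffm_kg", "mass_vat", "mass_sat_abdominal",
    "mass_sat_femoral", "glucose_fasting_mmol_l", "insulin_fasting_pmol_l",
    "hba1c_ngsp_pct", "matsuda_isi", "m_umol_kg_min", "m_ffm_umol_kg_min",
    "rd_umol_kg_min", "egp_umol_kg_min", "ffa_suppression_pct",
    "gu_muscle", "gu_liver", "gu_vat", "gu_sat_abdominal", "gu_sat_femoral",
    "gu_bat", "gu_brain", "gu_brain_age_adj", "gu_myocardium",
    "depot_gu_muscle", "depot_gu_vat", "depot_gu_sat_abdominal",
    "depot_gu_sat_femoral", "depot_gu_brain",
]

# M-value correlation partners (study's association analyses)
CORRELATION_VARS = [
    "gu_muscle", "gu_bat", "gu_liver", "gu_vat", "gu_sat_abdominal",
    "gu_sat_femoral", "gu_myocardium", "gu_brain_age_adj",
    "rd_umol_kg_min", "egp_umol_kg_min", "mass_vat", "mass_sat_abdominal",
]



@dataclass
class PipelineResult:
    subjects: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    voxel: st.VoxelMapResult | None
    config: PipelineConfig

    def write(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out_dir / "subjects.csv", index=False,
                             float_format=cio.FLOAT_FMT)
        self.comparisons.to_csv(out_dir / "group_comparisons.csv", index=False,
                                float_format=cio.FLOAT_FMT)
        self.correlations.to_csv(out_dir / "correlations.csv", index=False,
                                 float_format=cio.FLOAT_FMT)
        cfg_dump = self.config.model_dump()
        manifest = {
            "config_hash": cio.config_hash(cfg_dump),
            "seed": self.config.seed,
            "n_subjects": int(len(self.subjects)),
        }
        if self.voxel is not None:
            manifest["voxel_significant"] = int(self.voxel.mask.sum())
            manifest["voxel_clusters"] = {
                int(k): int(v) for k, v in self.voxel.cluster_sizes.items()}
            cio.write_voxel_map(out_dir / "voxel_t_map.txt", self.voxel.t_map)
        (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        self.config.to_yaml(out_dir / "config_used.yaml")


class StageError(RuntimeError):
    """Wraps any per-subject failure with subject id and stage name."""


def _subject_measures(sdir: Path, meta: pd.Series,
                      config: PipelineConfig) -> dict[str, float]:
    registry = config.tissue_registry()
    out: dict[str, float] = {}

    def stage(name):
        log.debug("subject %s: stage %s", meta["subject_id"], name)
        return name

    try:
        current = stage("read")
        tacs: dict[str, object] = {}
        for preset in ("thorax", "abdomen", "thigh", "neck_static",
                       "brain_static"):
            tacs.update(cio.read_tac_table(sdir / f"tac_{preset}.csv"))
        plasma = cio.read_plasma(sdir / "plasma.csv")
        rec = cio.read_clamp(sdir / "clamp.csv",
                             steady_start_min=float(meta["t_steady_min"]))

        current = stage("input_function")
        idif = tacs["left_ventricle"]
        f = build_hybrid_input(idif.mid_times_min, idif.values, plasma,
                               switch_time_min=config.switch_time_min,
                               calibrate_idif=config.calibrate_idif)
        f.fit_tail(config.tail_knots)

        current = stage("clamp_indices")
        mask = rec.window_mask()
        glucose_ss = float(np.mean(rec.glucose_mmol_l[mask]))
        m, m_ffm = cl.m_value(rec, meta["weight_kg"], meta["ffm_kg"],
                              vd_l_per_kg=config.vd_l_per_kg)
        out["m_umol_kg_min"] = m
        out["m_ffm_umol_kg_min"] = m_ffm
        out["glucose_ss_mmol_l"] = glucose_ss
        gir_ss = float(np.trapezoid(rec.gir_umol_kg_min[mask],
                                    rec.times_min[mask])
                       / (rec.times_min[mask][-1] - rec.times_min[mask][0]))
        if np.isfinite(meta["urinary_mbq"]):
            tb = cl.TracerBalance(meta["dose_mbq"], meta["urinary_mbq"],
                                  meta["weight_kg"])
            rd = cl.rd_from_tracer(tb, f, glucose_ss, lc_wb=config.lc_whole_body)
            out["rd_umol_kg_min"] = rd
            out["egp_umol_kg_min"] = cl.egp(rd, gir_ss)
            out["egp_ffm_umol_kg_min"] = (out["egp_umol_kg_min"]
                                          * meta["weight_kg"] / meta["ffm_kg"])
        else:
            out["rd_umol_kg_min"] = np.nan
            out["egp_umol_kg_min"] = np.nan
            out["egp_ffm_umol_kg_min"] = np.nan
        clamp_ffa = float(np.mean(rec.ffa_mmol_l[mask]))
        out["ffa_suppression_pct"] = cl.ffa_suppression(
            meta["ffa_fasting_mmol_l"], clamp_ffa)

        current = stage("screening_indices")
        out["matsuda_isi"] = cl.matsuda_isi(
            meta["glucose_fasting_mmol_l"], meta["insulin_fasting_pmol_l"],
            (meta["glucose_fasting_mmol_l"] + meta["glucose_ogtt2h_mmol_l"]) / 2,
            (meta["insulin_fasting_pmol_l"] + meta["insulin_ogtt2h_pmol_l"]) / 2)
        out["hba1c_ngsp_pct"] = cl.ifcc_to_ngsp(meta["hba1c_ifcc_mmol_mol"])

        current = stage("kinetics")
        for tissue, (preset, method) in TISSUE_PLAN.items():
            tac = tacs[tissue]
            if method == "patlak":
                est = kin.patlak_fit(tac, f, t_star_min=config.t_star_min)
            else:
                value = float(np.mean(tac.values))
                est = kin.fur(value, FUR_BLOCK_MID_MIN[preset], f)
            gu = kin.gu_from_rate(est, glucose_ss, registry[tissue])
            out[f"rate_{tissue}"] = est.rate_per_min
            out[f"gu_{tissue}"] = gu.gu_umol_per_kg_min
            out[f"depot_gu_{tissue}"] = kin.depot_gu(gu, meta[f"mass_{tissue}"])
    except Exception as exc:
        raise StageError(
            f"subject {meta['subject_id']}, stage {current}: {exc}") from exc
    return out


def compute_subject_table(
        cohort_dir: Path, config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, list[np.ndarray]]]:
    """Per-subject quantification over a cohort directory.

    Returns the tidy subjects table (metadata + derived measures) and the
    per-group voxel maps found alongside the tabular data.
    """
    config = config or PipelineConfig()
    cohort_dir = Path(cohort_dir)
    try:
        meta = pd.read_csv(cohort_dir / "metadata.csv")
    except pd.errors.EmptyDataError:
        meta = pd.DataFrame(columns=["subject_id", "group"])
    log.info("quantification start: %d subjects, config %s", len(meta),
             cio.config_hash(config.model_dump()))

    rows = []
    voxel_maps: dict[str, list[np.ndarray]] = {}
    for _, m in meta.iterrows():
        sdir = cohort_dir / f"sub-{m['subject_id']}"
        row = {"subject_id": m["subject_id"], "group": m["group"]}
        row.update({k: m[k] for k in meta.columns
                    if k not in ("subject_id", "group")})
        row.update(_subject_measures(sdir, m, config))
        rows.append(row)
        vm_path = sdir / "voxel_map.txt"
        if vm_path.exists():
            voxel_maps.setdefault(m["group"], []).append(
                cio.read_voxel_map(vm_path))
    return pd.DataFrame(rows), voxel_maps


def analyze_cohort(subjects: pd.DataFrame,
                   voxel_maps: dict[str, list[np.ndarray]] | None = None,
                   config: PipelineConfig | None = None) -> PipelineResult:
    """Statistical layer over an already-quantified subjects table."""
    config = config or PipelineConfig()
    voxel_maps = voxel_maps or {}
    subjects = subjects.copy()
    if subjects.empty:
        empty_cmp = pd.DataFrame(columns=["variable", "test", "statistic",
                                          "p", "p_adjusted", "significant"])
        empty_cor = pd.DataFrame(columns=["x", "y", "stratum", "r", "p", "n"])
        return PipelineResult(subjects, empty_cmp, empty_cor, None, config)

    # age adjustment of brain uptake to the whole-sample mean age
    subjects["gu_brain_age_adj"] = st.age_adjust(
        subjects["gu_brain"].to_numpy(), subjects["age_years"].to_numpy())

    groups = subjects["group"].to_numpy()
    cmp_rows = []
    for var in COMPARISON_VARS:
        if var not in subjects.columns:
            continue
        try:
            c = st.compare_groups(subjects[var].to_numpy(float), groups,
                                  test=config.group_test, variable=var)
        except ValueError as exc:
            log.warning("comparison of %s skipped: %s", var, exc)
            continue
        ga, gb = sorted(set(groups.tolist()))
        cmp_rows.append({
            "variable": var, "test": c.test, "statistic": c.statistic,
            "p": c.p_value, "group_a": ga, "group_b": gb,
            "n_a": c.n_a, "n_b": c.n_b,
            "mean_a": c.mean_a, "mean_b": c.mean_b,
        })
    comparisons = pd.DataFrame(cmp_rows)
    adj, sig = st.bh_fdr(comparisons["p"].to_numpy(), q=config.fdr_q)
    comparisons["p_adjusted"] = adj
    comparisons["significant"] = sig

    cor_rows = []
    m_vals = subjects["m_umol_kg_min"].to_numpy(float)
    for var in CORRELATION_VARS:
        if var not in subjects.columns:
            continue
        try:
            results = st.correlate(m_vals, subjects[var].to_numpy(float),
                                   by_group=groups, method=config.correlation)
        except ValueError as exc:
            log.warning("correlation m_value~%s skipped: %s", var, exc)
            continue
        for r in results:
            cor_rows.append({"x": "m_umol_kg_min", "y": var,
                             "stratum": r.stratum, "r": r.r, "p": r.p_value,
                             "n": r.n})
    correlations = pd.DataFrame(cor_rows)

    voxel = None
    labels = sorted(voxel_maps)
    if len(labels) == 2 and all(len(voxel_maps[g]) >= 2 for g in labels):
        # HR - LR contrast: first stack is HR so positive t means higher HR
        voxel = st.voxelwise_group_map(np.stack(voxel_maps[labels[0]]),
                                       np.stack(voxel_maps[labels[1]]),
                                       q=config.fdr_q)

    log.info("analysis done: %d subjects, %d comparisons, %d correlations",
             len(subjects), len(comparisons), len(cor_rows))
    return PipelineResult(subjects, comparisons, correlations, voxel, config)


def run_pipeline(cohort_dir: Path,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Full analysis over a simulated (or format-equivalent) cohort dir."""
    config = config or PipelineConfig()
    subjects, voxel_maps = compute_subject_table(cohort_dir, config)
    return analyze_cohort(subjects, voxel_maps, config)
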