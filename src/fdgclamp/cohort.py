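"""Two-group synthetic cohorts with the study's statistical structure.

The subject-level data behind the published cohort are not deposited, so
this module generates statistically matched stand-ins: a low-risk (LR,
n=22) and a high-risk (HR, n=19) group of healthy males whose
anthropometric, clamp and tissue-uptake variables are drawn from
truncated normals with the published group means and SDs, and whose PET
raw data (plasma curve, frame-binned tissue TACs) are *forward-simulated*
from kinetic parameters back-solved to honor each subject's sampled
glucose-uptake target.  Running the analysis pipeline on a simulated
cohort therefore recovers, up to sampling noise, the group structure it
was generated from -- which is exactly what makes every downstream stage
testable.

Variables are sampled independently within subject (the published tables
give marginals only); between-variable correlation arises through the
group structure alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.stats import truncnorm

from . import frames as fr
from .clamp import ClampRecord, TracerBalance
from .input_function import PLASMA_SAMPLE_TIMES_MIN, InputFunction, PlasmaSample
from .kinetics import TISSUE_REGISTRY
from .synthetic import (
    DEFAULT_NOISE_SCALE,
    InputModelParams,
    KineticParams,
    add_frame_noise,
    back_solve_k1,
    generate_input_curve,
    input_function_from_model,
    simulate_tissue_tac,
)


class VarSpec(BaseModel):
    """Mean/SD (and optional lower truncation) of one cohort variable."""

    mean: float
    sd: float = Field(ge=0)
    lower: float | None = None


class GroupSpec(BaseModel):
    """Sampling specification for one risk group."""

    label: str
    n: int = Field(ge=0)
    variables: dict[str, VarSpec]
    n_missing_urine: int = Field(default=0, ge=0)
    # regional brain-uptake elevation (umol/kg/min) planted inside
    # VOXEL_SIGNAL_BLOCK of every subject's voxel map
    voxel_block_effect: float = 0.0

    @model_validator(mode="after")
    def _feasible(self) -> "GroupSpec":
        for name, v in self.variables.items():
            if v.lower is not None and v.sd == 0 and v.mean < v.lower:
                raise ValueError(
                    f"{self.label}/{name}: mean {v.mean} below lower "
                    f"truncation {v.lower} with sd=0 is unsatisfiable"
                )
        return self


def _v(mean, sd, lower=None) -> VarSpec:
    return VarSpec(mean=mean, sd=sd, lower=lower)


# Published group characteristics (means +- SD).  Per-mass GU for tissues
# with published depot values is depot GU / depot mass; liver, BAT and
# myocardium per-mass GU group values are NOT published in the tables and
# these defaults are plausible fabrications consistent with the reported
# group directionality (lower in HR except myocardium, no difference).
LR_DEFAULT = GroupSpec(
    label="LR", n=22, n_missing_urine=1,
    variables={
        "age_years": _v(23, 3, 18),
        "weight_kg": _v(70.3, 7.5, 45),
        "ffm_kg": _v(59.2, 6.6, 35),
        "mass_brain": _v(1.7, 0.2, 1.0),
        "mass_muscle": _v(5.6, 0.6, 2.0),
        "mass_vat": _v(1.4, 0.7, 0.2),
        "mass_sat_abdominal": _v(2.7, 1.0, 0.5),
        "mass_sat_femoral": _v(2.1, 0.7, 0.3),
        "mass_liver": _v(1.6, 0.25, 0.8),           # fabricated
        "mass_bat": _v(0.15, 0.06, 0.02),           # fabricated
        "mass_myocardium": _v(0.30, 0.04, 0.15),    # fabricated
        "glucose_ss_mmol_l": _v(5.3, 0.2, 3.5),
        "insulin_ss_pmol_l": _v(510.5, 76.8, 200),
        "glucose_fasting_mmol_l": _v(4.9, 0.5, 3.0),
        "insulin_fasting_pmol_l": _v(38.7, 21.0, 6.0),
        "glucose_ogtt2h_mmol_l": _v(4.8, 1.0, 2.0),
        "insulin_ogtt2h_pmol_l": _v(160.7, 140.1, 15.0),
        "hba1c_ifcc_mmol_mol": _v(29, 2, 20),
        "ffa_fasting_mmol_l": _v(0.3, 0.1, 0.05),
        "ffa_clamp_mmol_l": _v(0.03, 0.01, 0.005),
        "m_umol_kg_min": _v(58.0, 14.7, 10.0),
        "egp_umol_kg_min": _v(-3.4, 6.7),
        "gu_muscle": _v(52.2, 14.3, 10.0),
        "gu_liver": _v(18.0, 5.0, 4.0),             # fabricated
        "gu_vat": _v(30.1, 13.1, 5.0),
        "gu_sat_abdominal": _v(19.3, 8.6, 3.0),
        "gu_sat_femoral": _v(19.0, 9.1, 3.0),
        "gu_bat": _v(30.0, 15.0, 3.0),              # fabricated
        "gu_brain": _v(151.8, 27.2, 60.0),
        "gu_myocardium": _v(600.0, 150.0, 150.0),   # fabricated
        "dose_mbq": _v(156, 10, 100),
        "urine_fraction": _v(0.10, 0.03, 0.01),
        # insulin-infusion start to steady glycemia (protocol: 80 +- 13 min)
        "t_steady_min": _v(80, 13, 40),
        # subject-level spread of the terminal plasma clearance rate
        "input_l3": _v(-0.012, 0.0012),
    },
)

HR_DEFAULT = GroupSpec(
    label="HR", n=19, voxel_block_effect=30.0,
    variables={
        "age_years": _v(27, 4, 18),
        "weight_kg": _v(90.1, 9.3, 55),
        "ffm_kg": _v(62.8, 5.7, 40),
        "mass_brain": _v(1.7, 0.1, 1.0),
        "mass_muscle": _v(5.8, 0.5, 2.0),
        "mass_vat": _v(3.7, 1.2, 0.5),
        "mass_sat_abdominal": _v(6.8, 2.4, 1.0),
        "mass_sat_femoral": _v(2.8, 0.8, 0.5),
        "mass_liver": _v(1.8, 0.3, 0.9),            # fabricated
        "mass_bat": _v(0.12, 0.05, 0.02),           # fabricated
        "mass_myocardium": _v(0.33, 0.05, 0.15),    # fabricated
        "glucose_ss_mmol_l": _v(5.3, 0.3, 3.5),
        "insulin_ss_pmol_l": _v(581.7, 94.9, 250),
        "glucose_fasting_mmol_l": _v(5.5, 0.4, 3.5),
        "insulin_fasting_pmol_l": _v(61.8, 20.8, 10.0),
        "glucose_ogtt2h_mmol_l": _v(5.9, 1.4, 2.5),
        "insulin_ogtt2h_pmol_l": _v(328.2, 236.5, 20.0),
        "hba1c_ifcc_mmol_mol": _v(32, 3, 20),
        "ffa_fasting_mmol_l": _v(0.3, 0.1, 0.05),
        "ffa_clamp_mmol_l": _v(0.05, 0.03, 0.008),
        "m_umol_kg_min": _v(38.7, 13.7, 8.0),
        "egp_umol_kg_min": _v(0.9, 6.0),
        "gu_muscle": _v(34.5, 13.0, 6.0),
        "gu_liver": _v(15.0, 5.0, 3.0),             # fabricated
        "gu_vat": _v(18.6, 7.3, 3.0),
        "gu_sat_abdominal": _v(11.7, 5.1, 2.0),
        "gu_sat_femoral": _v(11.3, 5.2, 2.0),
        "gu_bat": _v(16.0, 8.0, 2.0),               # fabricated
        "gu_brain": _v(158.9, 25.4, 60.0),
        "gu_myocardium": _v(600.0, 150.0, 150.0),   # fabricated
        "dose_mbq": _v(156, 10, 100),
        "urine_fraction": _v(0.10, 0.03, 0.01),
        "t_steady_min": _v(80, 13, 40),
        "input_l3": _v(-0.012, 0.0012),
    },
)

# Kinetic constants k2, k3 (1/min) and Vb per tissue.  The study reports
# no compartmental constants (only Ki/FUR-derived GU); these are
# fabricated simulation defaults, and K1 is back-solved per subject so
# that the tissue's GU target is honored regardless of them.
TISSUE_KINETIC_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "muscle": (0.15, 0.05, 0.04),
    "liver": (0.50, 0.02, 0.25),
    "vat": (0.10, 0.02, 0.03),
    "sat_abdominal": (0.10, 0.02, 0.03),
    "sat_femoral": (0.10, 0.02, 0.03),
    "bat": (0.12, 0.04, 0.08),
    "brain": (0.12, 0.06, 0.04),
    "myocardium": (0.25, 0.10, 0.30),
}

# analysis time point for FUR tissues: mid-time of the covering block
FUR_BLOCK_MID_MIN = {"abdomen": 47.5, "thigh": 62.5,
                     "neck_static": 75.0, "brain_static": 85.0}

# which acquisition covers which tissue, and which method the pipeline uses
TISSUE_PLAN: dict[str, tuple[str, str]] = {
    "myocardium": ("thorax", "patlak"),
    "liver": ("abdomen", "patlak"),
    "vat": ("abdomen", "fur"),
    "sat_abdominal": ("abdomen", "fur"),
    "muscle": ("thigh", "patlak"),
    "sat_femoral": ("thigh", "fur"),
    "bat": ("neck_static", "fur"),
    "brain": ("brain_static", "fur"),
}

VOXEL_MAP_SHAPE = (8, 8, 4)
VOXEL_SIGNAL_BLOCK = (slice(2, 5), slice(2, 5), slice(1, 3))


@dataclass
class SubjectRecord:
    """One simulated subject: metadata, targets, and raw study data."""

    subject_id: str
    group: str
    metadata: dict[str, float]
    kinetics: dict[str, KineticParams]
    input_model: InputModelParams
    input_scale: float
    tacs: dict[str, "fr.TimeActivityCurve"]
    idif: "fr.TimeActivityCurve"
    plasma_samples: list[PlasmaSample]
    clamp_record: ClampRecord
    tracer_balance: TracerBalance
    voxel_map: np.ndarray

    @property
    def true_input_function(self) -> InputFunction:
        """The noise-free ground-truth plasma curve."""
        base = input_function_from_model(self.input_model)
        return InputFunction(base.times_min, base.activities * self.input_scale)


@dataclass
class Cohort:
    seed: int
    subjects: list[SubjectRecord] = field(default_factory=list)

    def by_group(self, label: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == label]


def _sample_var(rng: np.random.Generator, v: VarSpec) -> float:
    if v.sd == 0:
        return v.mean
    if v.lower is None:
        return float(rng.normal(v.mean, v.sd))
    a = (v.lower - v.mean) / v.sd
    return float(truncnorm.rvs(a, np.inf, loc=v.mean, scale=v.sd,
                               random_state=rng))


def _feng_auc_inf(p: InputModelParams) -> float:
    """Closed-form AUC(0,inf) of the Feng bolus model."""
    return p.a1 / p.l1**2 + (p.a2 + p.a3) / p.l1 - p.a2 / p.l2 - p.a3 / p.l3


def make_clamp_record(m_target: float, glucose_ss: float, insulin_ss: float,
                      ffa_fasting: float, ffa_clamp: float,
                      t_steady_min: float, rng: np.random.Generator | None,
                      gir_noise_sd: float = 1.5,
                      glucose_noise_sd: float = 0.04,
                      t_end_min: float = 160.0,
                      dt_min: float = 5.0) -> ClampRecord:
    """A clamp record whose steady-state mean GIR equals ``m_target``.

    GIR ramps linearly from 0 to the target over the equilibration period
    (the protocol reached steady glycemia 80 +- 13 min after the insulin
    start) and is flat thereafter; glycemia is held at ``glucose_ss``.
    With ``rng=None`` the record is noise-free and the M value computed
    from it equals ``m_target`` exactly.
    """
    t = np.arange(0.0, t_end_min + dt_min / 2, dt_min)
    ramp = np.clip(t / t_steady_min, 0.0, 1.0)
    gir = m_target * ramp
    glucose = np.full_like(t, glucose_ss)
    insulin = insulin_ss * (1.0 - np.exp(-t / 20.0))
    ffa = ffa_clamp + (ffa_fasting - ffa_clamp) * np.exp(-t / 25.0)
    if rng is not None:
        steady = t >= t_steady_min
        gir = gir + np.where(steady, rng.normal(0, gir_noise_sd, t.shape), 0.0)
        glucose = glucose + rng.normal(0, glucose_noise_sd, t.shape)
        gir = np.clip(gir, 0.0, None)
        glucose = np.clip(glucose, 0.5, None)
    return ClampRecord(times_min=t, gir_umol_kg_min=gir,
                       glucose_mmol_l=glucose, insulin_pmol_l=insulin,
                       ffa_mmol_l=ffa,
                       steady_state_min=(t_steady_min, t[-1]))


def _simulate_subject(subject_id: str, spec: GroupSpec, idx: int,
                      rng: np.random.Generator, noise_scale: float,
                      plasma_noise_frac: float,
                      lc_wb: float = 1.0) -> SubjectRecord:
    md = {name: _sample_var(rng, v) for name, v in spec.variables.items()}

    # tracer balance; Rd target follows from the M and EGP targets
    missing_urine = idx < spec.n_missing_urine
    dose = md["dose_mbq"]
    urine_mbq = dose * md["urine_fraction"]
    rd_target = max(md["m_umol_kg_min"] + md["egp_umol_kg_min"], 2.0)
    md["rd_target_umol_kg_min"] = rd_target

    # scale the bolus model so the plasma AUC(0,inf) is consistent with
    # the tracer balance: CL = (dose - urine)/AUC = Rd*lc_wb*weight/glucose
    base = InputModelParams(l3=min(float(md["input_l3"]), -1e-4))
    cl_l_min = (rd_target * lc_wb * md["weight_kg"]
                / (md["glucose_ss_mmol_l"] * 1000.0))
    auc_target = (dose - urine_mbq) * 1000.0 / (cl_l_min * 1000.0)
    scale = auc_target / _feng_auc_inf(base)
    input_fn = input_function_from_model(base)
    input_fn = InputFunction(input_fn.times_min, input_fn.activities * scale)

    # back-solve per-tissue K1 so the *estimator used for that tissue*
    # recovers the sampled GU target on noise-free data: the Patlak slope
    # of C_T is (1-Vb)*Ki, and the equilibrium FUR additionally carries
    # the distribution-volume term [(1-Vb)*V_t + Vb] * Cp(T)/AUC(0,T)
    # with V_t = Ki*k2/(k3*(k2+k3))
    kinetics: dict[str, KineticParams] = {}
    for tissue, (k2, k3, vb) in TISSUE_KINETIC_DEFAULTS.items():
        cfg = TISSUE_REGISTRY[tissue]
        rate_target = (md[f"gu_{tissue}"] * cfg.lumped_constant
                       * cfg.density_kg_per_l
                       / (md["glucose_ss_mmol_l"] * 1000.0))
        preset, method = TISSUE_PLAN[tissue]
        if method == "patlak":
            ki = rate_target / (1.0 - vb)
        else:
            t_fur = FUR_BLOCK_MID_MIN[preset]
            cpr = float(input_fn(t_fur)) / input_fn.auc(t_fur)
            vt_per_ki = k2 / (k3 * (k2 + k3))
            ki = ((rate_target - vb * cpr)
                  / ((1.0 - vb) * (1.0 + vt_per_ki * cpr)))
            ki = max(ki, 1e-6)
        kinetics[tissue] = KineticParams(back_solve_k1(ki, k2, k3), k2, k3, vb)

    tacs: dict[str, fr.TimeActivityCurve] = {}
    for tissue, (preset, _method) in TISSUE_PLAN.items():
        tac = simulate_tissue_tac(kinetics[tissue], input_fn,
                                  fr.PRESETS[preset], region=tissue)
        if noise_scale > 0:
            tac = add_frame_noise(tac, rng, scale=noise_scale)
        tacs[tissue] = tac

    # image-derived input: left-ventricle blood pool = plasma curve binned
    # to the thorax frames
    idif_vals = np.array([
        input_fn.auc(e, t_start=s) / (e - s)
        for s, e in zip(fr.THORAX.starts_s / 60.0, fr.THORAX.ends_s / 60.0)
    ])
    idif = fr.TimeActivityCurve(fr.THORAX, idif_vals, region="left_ventricle")
    if noise_scale > 0:
        # blood-pool activity is strictly positive; clip so the assembled
        # input function keeps its nonnegativity contract
        idif = add_frame_noise(idif, rng, scale=noise_scale,
                               clip_nonnegative=True)

    sample_vals = np.asarray(input_fn(np.array(PLASMA_SAMPLE_TIMES_MIN)))
    if plasma_noise_frac > 0:
        sample_vals = sample_vals * (
            1.0 + rng.normal(0, plasma_noise_frac, sample_vals.shape))
    plasma = [PlasmaSample(t, max(v, 0.0))
              for t, v in zip(PLASMA_SAMPLE_TIMES_MIN, sample_vals)]

    clamp_rng = rng if noise_scale > 0 or plasma_noise_frac > 0 else None
    clamp_rec = make_clamp_record(
        md["m_umol_kg_min"], md["glucose_ss_mmol_l"], md["insulin_ss_pmol_l"],
        md["ffa_fasting_mmol_l"], md["ffa_clamp_mmol_l"],
        md["t_steady_min"], clamp_rng)

    tb = TracerBalance(injected_mbq=dose,
                       urinary_mbq=np.nan if missing_urine else urine_mbq,
                       weight_kg=md["weight_kg"])
    md["urine_missing"] = float(missing_urine)

    # small voxel map of brain uptake around the subject's brain GU
    # target, with the group's regional elevation planted in a block
    vox = rng.normal(md["gu_brain"], 20.0, size=VOXEL_MAP_SHAPE)
    vox[VOXEL_SIGNAL_BLOCK] += spec.voxel_block_effect

    return SubjectRecord(
        subject_id=subject_id, group=spec.label, metadata=md,
        kinetics=kinetics, input_model=base, input_scale=scale,
        tacs=tacs, idif=idif, plasma_samples=plasma, clamp_record=clamp_rec,
        tracer_balance=tb, voxel_map=vox,
    )


def simulate_cohort(lr: GroupSpec = LR_DEFAULT, hr: GroupSpec = HR_DEFAULT,
                    seed: int = 0,
                    noise_scale: float = DEFAULT_NOISE_SCALE,
                    plasma_noise_frac: float = 0.02) -> Cohort:
    """Generate a reproducible two-group cohort.

    The same seed yields a bit-identical cohort.  ``noise_scale`` is the
    PET frame-noise scale (0 for noise-free raw data);
    ``plasma_noise_frac`` the relative SD of plasma-sample noise.
    """
    rng = np.random.default_rng(seed)
    cohort = Cohort(seed=seed)
    for spec in (lr, hr):
        for i in range(spec.n):
            sid = f"{spec.label}{i + 1:03d}"
            cohort.subjects.append(
                _simulate_subject(sid, spec, i, rng, noise_scale,
                                  plasma_noise_frac))
    return cohort
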