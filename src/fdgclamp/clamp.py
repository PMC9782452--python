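"""Whole-body metabolic indices from the hyperinsulinemic-euglycemic clamp.

During the clamp a fixed insulin infusion is paired with a variable
glucose infusion that holds glycemia constant; at steady state the glucose
infusion rate (GIR) indexes whole-body insulin sensitivity (the M value).
Pairing the clamp with an FDG tracer balance additionally yields the rate
of disappearance of glucose (Rd) from plasma clearance, and from it the
endogenous glucose production EGP = Rd - GIR, which under strong insulin
stimulation is near zero or negative (full suppression).

Formulas implemented here:

* M value: mean GIR over the steady-state window, minus a glucose-space
  correction SC = dG * vd / window (dG the glucose change over the window
  converted to umol/L, vd the glucose distribution volume, 0.19 L/kg by
  default) and minus measured urinary glucose loss (default 0).
* Rd from tracer balance: plasma clearance CL = (injected - urinary
  activity) / AUC(0,inf) of the plasma curve, so
  Rd = CL * glucose / (LC_wb * weight) with whole-body lumped constant 1.
* Matsuda insulin-sensitivity index from fasting and mean OGTT
  glucose/insulin, 10000 / sqrt(G0 * I0 * Gmean * Imean) in conventional
  units (mg/dL, uU/mL).
* IFCC<->NGSP HbA1c master equation: NGSP% = 0.09148 * IFCC + 2.152.
* FFA suppression: 100 * (1 - clamp FFA / fasting FFA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .input_function import InputFunction

VD_GLUCOSE_L_PER_KG = 0.19       # glucose distribution volume
LC_WHOLE_BODY = 1.0              # whole-body lumped constant (glucose equivalents)
GLUCOSE_MMOL_L_TO_MG_DL = 18.016
INSULIN_PMOL_L_TO_UU_ML = 1 / 6.0
NGSP_SLOPE = 0.09148             # IFCC (mmol/mol) -> NGSP (%) master equation
NGSP_INTERCEPT = 2.152


@dataclass
class ClampRecord:
    """Time series of a clamp study with its steady-state window.

    All series are sampled at ``times_min``; ``gir`` in umol/kg/min,
    ``glucose`` mmol/L, ``insulin`` pmol/L, ``ffa`` mmol/L.
    """

    times_min: np.ndarray
    gir_umol_kg_min: np.ndarray
    glucose_mmol_l: np.ndarray
    insulin_pmol_l: np.ndarray
    ffa_mmol_l: np.ndarray
    steady_state_min: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        for name in ("gir_umol_kg_min", "glucose_mmol_l",
                     "insulin_pmol_l", "ffa_mmol_l"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times_min.shape:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.gir_umol_kg_min < 0):
            raise ValueError("GIR must be >= 0")
        lo, hi = self.steady_state_min
        if lo < self.times_min[0] - 1e-9 or hi > self.times_min[-1] + 1e-9:
            raise ValueError("steady-state window outside record span")

    def window_mask(self) -> np.ndarray:
        lo, hi = self.steady_state_min
        return (self.times_min >= lo - 1e-9) & (self.times_min <= hi + 1e-9)


@dataclass(frozen=True)
class TracerBalance:
    """FDG dose accounting for the whole-body clearance calculation."""

    injected_mbq: float
    urinary_mbq: float  # NaN marks a missing urine collection
    weight_kg: float

    def __post_init__(self) -> None:
        if not np.isnan(self.urinary_mbq) and not (
                0 <= self.urinary_mbq <= self.injected_mbq):
            raise ValueError("urinary activity must be in [0, injected]")
        if self.weight_kg <= 0:
            raise ValueError("weight must be > 0")


@dataclass
class MetabolicIndices:
    """Per-subject derived clamp and screening indices."""

    m_umol_kg_min: float
    m_ffm_umol_kg_min: float
    rd_umol_kg_min: float | None = None
    egp_umol_kg_min: float | None = None
    egp_ffm_umol_kg_min: float | None = None
    ffa_suppression_pct: float | None = None
    matsuda_isi: float | None = None
    hba1c_ngsp_pct: float | None = None


def m_value(rec: ClampRecord, weight_kg: float, ffm_kg: float,
            urinary_glucose_umol: float = 0.0,
            vd_l_per_kg: float = VD_GLUCOSE_L_PER_KG) -> tuple[float, float]:
    """M value (umol/kg/min) and its fat-free-mass normalization.

    M = mean steady-state GIR - space correction - urinary loss, where the
    space correction charges glucose accumulating in its distribution
    space (rising glycemia inflates GIR without reflecting disposal).
    """
    if weight_kg <= 0 or ffm_kg <= 0:
        raise ValueError("weight and FFM must be > 0")
    mask = rec.window_mask()
    if mask.sum() < 2:
        raise ValueError("steady-state window holds < 2 samples")
    t = rec.times_min[mask]
    window_min = t[-1] - t[0]
    gir_mean = float(np.trapezoid(rec.gir_umol_kg_min[mask], t) / window_min)
    d_glucose_umol_l = (rec.glucose_mmol_l[mask][-1]
                        - rec.glucose_mmol_l[mask][0]) * 1000.0
    space_corr = d_glucose_umol_l * vd_l_per_kg / window_min
    urinary_corr = urinary_glucose_umol / (weight_kg * window_min)
    m = gir_mean - space_corr - urinary_corr
    return m, m * weight_kg / ffm_kg


def rd_from_tracer(tb: TracerBalance, plasma: InputFunction,
                   glucose_ss_mmol_l: float,
                   lc_wb: float = LC_WHOLE_BODY) -> float:
    """Whole-body rate of glucose disappearance from FDG clearance.

    Plasma clearance CL [L/min] = (injected - urinary) / AUC(0,inf) of the
    plasma activity curve (mono-exponential tail extrapolation), then
    Rd [umol/kg/min] = CL * glucose [umol/L] / (lc_wb * weight).
    """
    if glucose_ss_mmol_l <= 0:
        raise ValueError("steady-state glucose must be > 0")
    auc_inf = plasma.auc(np.inf, extrapolate=True)  # kBq*min/mL
    if not np.isfinite(auc_inf) or auc_inf <= 0:
        raise ValueError("extrapolated AUC(0,inf) is not finite and positive")
    net_kbq = (tb.injected_mbq - tb.urinary_mbq) * 1000.0
    clearance_l_min = net_kbq / auc_inf / 1000.0  # mL/min -> L/min
    return clearance_l_min * glucose_ss_mmol_l * 1000.0 / (lc_wb * tb.weight_kg)


def egp(rd_umol_kg_min: float, gir_ss_umol_kg_min: float) -> float:
    """Endogenous glucose production: EGP = Rd - GIR (may be negative)."""
    if not (np.isfinite(rd_umol_kg_min) and np.isfinite(gir_ss_umol_kg_min)):
        raise ValueError("Rd and GIR must be finite")
    return rd_umol_kg_min - gir_ss_umol_kg_min


def matsuda_isi(g0_mmol_l: float, i0_pmol_l: float,
                g_mean_mmol_l: float, i_mean_pmol_l: float) -> float:
    """Matsuda whole-body insulin sensitivity index from OGTT data.

    Inputs in SI units (mmol/L, pmol/L) are converted to the conventional
    mg/dL and uU/mL the index is defined in.
    """
    vals = (g0_mmol_l, i0_pmol_l, g_mean_mmol_l, i_mean_pmol_l)
    if any(v <= 0 for v in vals):
        raise ValueError("all glucose/insulin inputs must be > 0")
    g0 = g0_mmol_l * GLUCOSE_MMOL_L_TO_MG_DL
    gm = g_mean_mmol_l * GLUCOSE_MMOL_L_TO_MG_DL
    i0 = i0_pmol_l * INSULIN_PMOL_L_TO_UU_ML
    im = i_mean_pmol_l * INSULIN_PMOL_L_TO_UU_ML
    return 10000.0 / np.sqrt(g0 * i0 * gm * im)


def ifcc_to_ngsp(hba1c_mmol_mol: float) -> float:
    """Convert HbA1c from IFCC (mmol/mol) to NGSP (%)."""
    if hba1c_mmol_mol <= 0:
        raise ValueError("HbA1c must be > 0")
    return NGSP_SLOPE * hba1c_mmol_mol + NGSP_INTERCEPT


def ngsp_to_ifcc(hba1c_pct: float) -> float:
    """Inverse of :func:`ifcc_to_ngsp`."""
    if hba1c_pct <= 0:
        raise ValueError("HbA1c must be > 0")
    return (hba1c_pct - NGSP_INTERCEPT) / NGSP_SLOPE


def ffa_suppression(fasting_ffa_mmol_l: float, clamp_ffa_mmol_l: float) -> float:
    """Percent suppression of free fatty acids by insulin during the clamp."""
    if fasting_ffa_mmol_l <= 0:
        raise ValueError("fasting FFA must be > 0")
    return 100.0 * (1.0 - clamp_ffa_mmol_l / fasting_ffa_mmol_l)
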