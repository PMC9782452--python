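"""Fractional tracer uptake and its conversion to glucose uptake.

FDG is irreversibly trapped (as FDG-6-phosphate) on the time scale of a
PET scan, so its kinetics linearize in the Patlak-Gjedde coordinates

    C_T(t)/C_p(t)  =  Ki * AUC_Cp(0,t)/C_p(t)  +  V,     t >= t*

where the slope Ki = K1*k3/(k2+k3) (1/min) is the net influx constant and
the intercept V the effective distribution volume.  For tissues imaged
with a single late static frame the fractional uptake rate

    FUR = C_T(T) / AUC_Cp(0,T)

is the standard late-time approximation of Ki.  Either rate converts to a
glucose uptake per kilogram of tissue via the plasma glucose level during
the scan, the tissue density and a lumped constant LC accounting for
transport/phosphorylation differences between FDG and glucose:

    GU [umol/kg/min] = rate [1/min] * glucose [umol/L] / (LC * density [kg/L])
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .frames import TimeActivityCurve
from .input_function import InputFunction

T_STAR_DEFAULT_MIN = 10.0  # start of the linear Patlak window for FDG


@dataclass
class RateEstimate:
    """A fitted Ki (Patlak) or FUR with diagnostics."""

    method: str                     # "patlak" | "fur"
    rate_per_min: float             # Ki or FUR
    intercept: float | None = None  # distribution volume V (patlak only)
    t_star_min: float | None = None
    n_points: int = 1
    r_squared: float | None = None
    rate_se: float | None = None


@dataclass(frozen=True)
class TissueConfig:
    """Per-tissue constants for the FDG->glucose conversion."""

    name: str
    lumped_constant: float
    density_kg_per_l: float

    def __post_init__(self) -> None:
        if self.lumped_constant <= 0 or self.density_kg_per_l <= 0:
            raise ValueError("lumped constant and density must be > 0")


# LC values: 1.2 skeletal muscle, 1.0 liver, 1.14 adipose (study protocol);
# brain LC is NOT stated by the protocol (brain analysis was delegated to an
# external tool) -- 0.65 is a conventional literature value, NOT the study's.
# Densities are literature-standard; the protocol states none.
TISSUE_REGISTRY: dict[str, TissueConfig] = {
    cfg.name: cfg
    for cfg in [
        TissueConfig("muscle", 1.2, 1.06),
        TissueConfig("liver", 1.0, 1.05),
        TissueConfig("vat", 1.14, 0.925),
        TissueConfig("sat_abdominal", 1.14, 0.925),
        TissueConfig("sat_femoral", 1.14, 0.925),
        TissueConfig("bat", 1.14, 0.925),
        TissueConfig("brain", 0.65, 1.04),
        TissueConfig("myocardium", 1.0, 1.05),
        TissueConfig("whole_body", 1.0, 1.0),
    ]
}


@dataclass
class GlucoseUptake:
    """Insulin-stimulated glucose uptake of one tissue."""

    tissue: str
    gu_umol_per_kg_min: float
    depot_gu_umol_min: float | None = None


class FitError(ValueError):
    """Raised when a rate fit is impossible (too few usable frames)."""


class DataError(ValueError):
    """Raised when input data make the requested quantity undefined."""


def patlak_fit(tac: TimeActivityCurve, input_fn: InputFunction,
               t_star_min: float = T_STAR_DEFAULT_MIN,
               weights: np.ndarray | None = None) -> RateEstimate:
    """Patlak-Gjedde graphical estimate of the net influx constant Ki.

    Ordinary least squares of y_j = C_T(t_j)/C_p(t_j) on
    x_j = AUC(0,t_j)/C_p(t_j) over frames with mid-time >= ``t_star_min``.

    Parameters
    ----------
    weights:
        Optional per-frame OLS weights (e.g. frame durations); default is
        unweighted.
    """
    mids = tac.mid_times_min
    use = mids >= t_star_min
    if use.sum() < 2:
        raise FitError(
            f"Patlak fit needs >= 2 frames with mid-time >= {t_star_min} min, "
            f"got {int(use.sum())}"
        )
    t = mids[use]
    ct = tac.values[use]
    cp = np.asarray(input_fn(t), dtype=float)
    if np.any(cp <= 0):
        raise DataError("plasma activity must be > 0 at every used frame")
    x = np.array([input_fn.auc(tj) for tj in t]) / cp
    y = ct / cp

    if weights is not None:
        w = np.asarray(weights, dtype=float)[use]
        sw = np.sqrt(w / w.sum())
        X = np.column_stack([x * sw, sw])
        slope, intercept = np.linalg.lstsq(X, y * sw, rcond=None)[0]
        resid = y - (slope * x + intercept)
        ss_res = float(np.sum(w * resid**2))
        ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        se = np.nan
        if x.size > 2:
            sxx = float(np.sum(w * (x - np.average(x, weights=w)) ** 2))
            se = float(np.sqrt(ss_res / (x.size - 2) / sxx))
    else:
        res = sps.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        r2 = res.rvalue**2
        se = res.stderr
    return RateEstimate(
        method="patlak",
        rate_per_min=float(slope),
        intercept=float(intercept),
        t_star_min=t_star_min,
        n_points=int(use.sum()),
        r_squared=float(r2),
        rate_se=float(se) if se == se else None,
    )


def fur(static_value_kbq_ml: float, t_min: float,
        input_fn: InputFunction, extrapolate: bool = False) -> RateEstimate:
    """Fractional uptake rate: tissue activity over the plasma integral.

    ``t_min`` is the mid-time of the static frame; ``static_value`` its
    (frame-averaged) tissue activity.
    """
    if t_min <= 0:
        raise DataError("FUR time must be > 0")
    denom = input_fn.auc(t_min, extrapolate=extrapolate)
    if denom <= 0:
        raise DataError("plasma AUC(0,T) must be > 0 for FUR")
    return RateEstimate(method="fur",
                        rate_per_min=float(static_value_kbq_ml / denom),
                        n_points=1)


def gu_from_rate(est: RateEstimate, plasma_glucose_mmol_l: float,
                 cfg: TissueConfig) -> GlucoseUptake:
    """Convert a Ki or FUR to glucose uptake per kg of tissue."""
    if plasma_glucose_mmol_l <= 0:
        raise ValueError("plasma glucose must be > 0")
    glucose_umol_l = plasma_glucose_mmol_l * 1000.0
    gu = est.rate_per_min * glucose_umol_l / (cfg.lumped_constant * cfg.density_kg_per_l)
    return GlucoseUptake(tissue=cfg.name, gu_umol_per_kg_min=float(gu))


def depot_gu(gu: GlucoseUptake, mass_kg: float) -> float:
    """Whole-depot glucose uptake (umol/min) = per-mass GU x depot mass."""
    if mass_kg < 0:
        raise ValueError("tissue mass must be >= 0")
    return gu.gu_umol_per_kg_min * mass_kg


def lookup_tissue(name: str,
                  registry: dict[str, TissueConfig] | None = None) -> TissueConfig:
    reg = TISSUE_REGISTRY if registry is None else registry
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown tissue {name!r}; known: {sorted(reg)}"
        ) from None
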