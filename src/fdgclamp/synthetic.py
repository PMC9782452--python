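"""Synthetic FDG kinetics: parametric input curves, tissue curves, noise.

The study's measured arterial data are replaced in simulation by a
Feng-type tri-exponential bolus model

    Cp(t) = (A1*(t-tau) - A2 - A3) * exp(l1*(t-tau))
            + A2 * exp(l2*(t-tau)) + A3 * exp(l3*(t-tau)),   t >= tau

(zero before the delay tau), the standard parametric description of a
venous FDG bolus: a fast ramp-and-crash term plus two decaying
exponentials, with rate constants l1 <= l2 <= l3 < 0.  Tissue curves
follow the irreversible two-tissue-compartment model

    dC1/dt = K1*Cp - (k2 + k3)*C1
    dC2/dt = k3*C1
    C_T    = (1 - Vb)*(C1 + C2) + Vb*Cp

whose net influx constant is Ki = K1*k3/(k2+k3).  All simulated
activities are decay-corrected (no isotope decay is simulated), matching
the decay-corrected inputs the analysis pipeline assumes.

Frame noise is Gaussian on frame means with sd proportional to
sqrt(value/duration) -- the standard count-statistics approximation where
relative noise falls with frame duration and activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .frames import FrameSchedule, TimeActivityCurve
from .input_function import InputFunction


@dataclass(frozen=True)
class InputModelParams:
    """Feng tri-exponential bolus parameters.

    ``a1`` is the ramp amplitude (kBq/mL/min); ``a2``, ``a3`` plain
    amplitudes (kBq/mL); ``l1 <= l2 <= l3 < 0`` rate constants (1/min);
    ``tau`` the bolus arrival delay (min).
    """

    a1: float = 800.0
    a2: float = 20.0
    a3: float = 21.0
    l1: float = -4.0
    l2: float = -0.5
    l3: float = -0.012
    tau: float = 0.5

    def __post_init__(self) -> None:
        if not (self.l1 <= self.l2 <= self.l3 < 0):
            raise ValueError("rate constants must satisfy l1 <= l2 <= l3 < 0")
        if self.tau < 0:
            raise ValueError("delay tau must be >= 0")


def generate_input_curve(params: InputModelParams, times_min) -> np.ndarray:
    """Evaluate the Feng bolus model at ``times_min`` (sorted, >= 0)."""
    t = np.asarray(times_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted")
    p = params
    s = t - p.tau
    out = np.where(
        s < 0,
        0.0,
        (p.a1 * s - p.a2 - p.a3) * np.exp(p.l1 * s)
        + p.a2 * np.exp(p.l2 * s)
        + p.a3 * np.exp(p.l3 * s),
    )
    return out


def input_function_from_model(params: InputModelParams,
                              t_end_min: float = 95.0,
                              dt_min: float = 0.05) -> InputFunction:
    """Densely sample the bolus model into an :class:`InputFunction`."""
    t = np.arange(0.0, t_end_min + dt_min / 2, dt_min)
    cp = np.clip(generate_input_curve(params, t), 0.0, None)
    return InputFunction(t, cp)


@dataclass(frozen=True)
class KineticParams:
    """Irreversible two-tissue-compartment rate constants."""

    k1: float   # mL plasma / mL tissue / min
    k2: float   # 1/min
    k3: float   # 1/min
    vb: float = 0.0  # blood volume fraction

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.k3) < 0:
            raise ValueError("rate constants must be >= 0")
        if not 0 <= self.vb <= 1:
            raise ValueError("Vb must lie in [0, 1]")

    @property
    def ki_true(self) -> float:
        """Net influx constant K1*k3/(k2+k3); 0 when k3 = 0."""
        if self.k3 == 0:
            return 0.0
        return self.k1 * self.k3 / (self.k2 + self.k3)


_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-10


def simulate_tissue_curve(kp: KineticParams, input_fn, times_min) -> np.ndarray:
    """Tissue activity C_T at ``times_min`` for the two-compartment model.

    ``input_fn`` is any callable Cp(t in minutes).  Integrated with LSODA
    at rtol=1e-8 / atol=1e-10.
    """
    t = np.asarray(times_min, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted and >= 0")

    def rhs(ti, y):
        cp = float(input_fn(ti))
        return [kp.k1 * cp - (kp.k2 + kp.k3) * y[0], kp.k3 * y[0]]

    t_end = float(t[-1]) if t.size else 0.0
    if t_end == 0.0:
        c1 = c2 = np.zeros_like(t)
    else:
        sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0], t_eval=t,
                        method="LSODA", rtol=_ODE_RTOL, atol=_ODE_ATOL)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        c1, c2 = sol.y
    cp_t = np.asarray(input_fn(t), dtype=float)
    return (1.0 - kp.vb) * (c1 + c2) + kp.vb * cp_t


def simulate_tissue_tac(kp: KineticParams, input_fn,
                        schedule: FrameSchedule,
                        region: str = "tissue") -> TimeActivityCurve:
    """Noise-free frame-averaged TAC of the two-compartment model.

    Frame means are exact: the ODE state is augmented with the running
    integral of C_T, and each frame value is the integral difference over
    the frame divided by its duration.
    """
    edges_min = np.unique(np.concatenate([schedule.starts_s, schedule.ends_s])) / 60.0

    def rhs(ti, y):
        cp = float(input_fn(ti))
        c1, _c2, _i = y
        ct = (1.0 - kp.vb) * (c1 + _c2) + kp.vb * cp
        return [kp.k1 * cp - (kp.k2 + kp.k3) * c1, kp.k3 * c1, ct]

    sol = solve_ivp(rhs, (0.0, edges_min[-1]), [0.0, 0.0, 0.0],
                    t_eval=edges_min, method="LSODA",
                    rtol=_ODE_RTOL, atol=_ODE_ATOL)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    cum = dict(zip(edges_min, sol.y[2]))
    values = np.empty(schedule.n_frames)
    for j, (start_s, dur_s) in enumerate(schedule.frames):
        a, b = start_s / 60.0, (start_s + dur_s) / 60.0
        values[j] = (cum[b] - cum[a]) / (b - a)
    return TimeActivityCurve(schedule=schedule, values=values, region=region)


# ROI-level frame-noise scale (kBq/mL per sqrt(kBq/mL per min)): TACs are
# region averages over many voxels, so their noise is far below voxel level
DEFAULT_NOISE_SCALE = 0.1


def add_frame_noise(tac: TimeActivityCurve, rng: np.random.Generator,
                    scale: float = DEFAULT_NOISE_SCALE,
                    clip_nonnegative: bool = False) -> TimeActivityCurve:
    """Add Gaussian frame noise with sd = scale*sqrt(value/duration_min).

    Values may go negative (decay-corrected PET means can); pass
    ``clip_nonnegative=True`` to clamp at zero.
    """
    dur_min = tac.schedule.durations_s / 60.0
    sd = scale * np.sqrt(np.clip(tac.values, 0.0, None) / dur_min)
    noisy = tac.values + rng.normal(0.0, 1.0, tac.values.shape) * sd
    if clip_nonnegative:
        noisy = np.clip(noisy, 0.0, None)
    return TimeActivityCurve(schedule=tac.schedule, values=noisy,
                             region=tac.region)


def back_solve_k1(ki_target: float, k2: float, k3: float) -> float:
    """K1 giving the requested net influx constant for fixed k2, k3."""
    if ki_target < 0:
        raise ValueError("Ki target must be >= 0")
    if k3 <= 0:
        raise ValueError("back-solving K1 requires k3 > 0")
    return ki_target * (k2 + k3) / k3


def simulate_voxel_maps(shape: tuple[int, int, int], n_a: int, n_b: int,
                        rng: np.random.Generator,
                        baseline: float = 150.0, sd: float = 20.0,
                        signal_block: tuple[slice, slice, slice] | None = None,
                        effect_sd: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Small synthetic per-subject uptake maps for the voxelwise analysis.

    Group B receives an additive offset of ``effect_sd`` standard
    deviations inside ``signal_block`` (no offset if None).  Returns two
    stacks of shape ``(n, *shape)``.
    """
    a = rng.normal(baseline, sd, size=(n_a, *shape))
    b = rng.normal(baseline, sd, size=(n_b, *shape))
    if signal_block is not None and effect_sd != 0.0:
        b[(slice(None), *signal_block)] += effect_sd * sd
    return a, b
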