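"""The arterial input function C_p(t).

The study protocol measures the tracer concentration in arterial plasma by
combining an image-derived curve from the left-ventricle blood pool (good
early temporal sampling during the bolus) with arterialized venous plasma
samples drawn from 4.5 min onward (the reference measurement once the
bolus has dispersed).  This module assembles that hybrid curve and provides
evaluation, trapezoidal integration and mono-exponential tail
extrapolation, the three primitives every downstream kinetic quantity
(Patlak abscissa, FUR denominator, tracer clearance) is built on.

Conventions: times are minutes from injection, activities are
decay-corrected kBq/mL, interpolation between knots is linear, and the
curve is zero at times before the first knot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SWITCH_TIME_MIN = 4.5  # protocol hand-over from image-derived to plasma data

# protocol arterialized sampling times (min from injection): five early
# samples plus the mid-times of the abdomen, thigh, neck and brain blocks
PLASMA_SAMPLE_TIMES_MIN = (4.5, 7.5, 10.0, 20.0, 30.0, 47.5, 62.5, 75.0, 85.0)


@dataclass(frozen=True)
class PlasmaSample:
    """One arterialized plasma measurement."""

    time_min: float
    activity_kbq_ml: float

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("sample time must be >= 0")
        if self.activity_kbq_ml < 0:
            raise ValueError("sample activity must be >= 0")


class InputFunction:
    """Piecewise-linear plasma tracer curve with a mono-exponential tail.

    Parameters
    ----------
    times_min, activities:
        Sorted knots.  Duplicate times are not allowed.
    provenance:
        Per-knot origin flag, ``"idif"`` or ``"plasma"``.
    """

    def __init__(self, times_min, activities, provenance=None):
        t = np.asarray(times_min, dtype=float)
        a = np.asarray(activities, dtype=float)
        if t.ndim != 1 or t.shape != a.shape or t.size < 2:
            raise ValueError("need >= 2 matching (time, activity) knots")
        if np.any(np.diff(t) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("knot times must be >= 0")
        if np.any(a < 0):
            raise ValueError("activities must be >= 0")
        if provenance is None:
            provenance = ["plasma"] * t.size
        provenance = list(provenance)
        if t[0] > 0:
            # anchor at injection: activity is zero at t=0 and rises
            # linearly to the first knot, keeping evaluation continuous
            # and the trapezoidal AUC exactly additive
            t = np.concatenate(([0.0], t))
            a = np.concatenate(([0.0], a))
            provenance = ["origin"] + provenance
        self.times_min = t
        self.activities = a
        self.provenance = provenance
        self._tail: tuple[float, float] | None = None  # (coefficient, rate>0)

    # -- evaluation ---------------------------------------------------------

    def __call__(self, t):
        """Evaluate C_p at time(s) ``t`` (min); 0 before the first knot.

        Beyond the last knot the fitted tail is used when available,
        otherwise the last knot value is held.
        """
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.times_min, self.activities)
        out = np.where(t < self.times_min[0], 0.0, out)
        beyond = t > self.times_min[-1]
        if np.any(beyond):
            if self._tail is not None:
                coeff, rate = self._tail
                out = np.where(beyond, coeff * np.exp(-rate * t), out)
            # else: hold last value (np.interp default)
        return out if out.ndim else float(out)

    # -- tail ---------------------------------------------------------------

    def fit_tail(self, n_knots: int = 3) -> tuple[float, float]:
        """Fit C_p ~ coeff * exp(-rate*t) to the last ``n_knots`` knots.

        Log-linear least squares; requires positive activities there.
        Returns ``(coeff, rate)`` and caches them for extrapolation.
        """
        if n_knots < 2:
            raise ValueError("tail fit needs >= 2 knots")
        t = self.times_min[-n_knots:]
        a = self.activities[-n_knots:]
        if np.any(a <= 0):
            raise ValueError("tail fit requires positive activities")
        slope, intercept = np.polyfit(t, np.log(a), 1)
        rate = -slope
        if rate <= 0:
            raise ValueError("tail is not decaying; cannot extrapolate")
        self._tail = (float(np.exp(intercept)), float(rate))
        return self._tail

    # -- integration --------------------------------------------------------

    def auc(self, t_end: float, extrapolate: bool = False,
            t_start: float = 0.0) -> float:
        """Trapezoidal integral of C_p over [t_start, t_end] (kBq*min/mL).

        ``t_end=np.inf`` (or any t_end beyond the last knot) requires
        ``extrapolate=True`` and adds the analytic integral of the fitted
        mono-exponential tail.
        """
        if t_end < t_start:
            raise ValueError("t_end must be >= t_start")
        last = self.times_min[-1]
        if t_end > last and not extrapolate:
            raise ValueError(
                f"t_end={t_end} beyond data ({last} min); pass extrapolate=True"
            )
        if t_end > last:
            if self._tail is None:
                self.fit_tail()
            coeff, rate = self._tail
            head = self.auc(last, t_start=min(t_start, last)) if t_start < last else 0.0
            a = max(t_start, last)
            if np.isinf(t_end):
                tail = coeff / rate * np.exp(-rate * a)
            else:
                tail = coeff / rate * (np.exp(-rate * a) - np.exp(-rate * t_end))
            return head + tail
        # grid = knots within (t_start, t_end) plus the two endpoints
        inner = self.times_min[(self.times_min > t_start) & (self.times_min < t_end)]
        grid = np.concatenate(([t_start], inner, [t_end]))
        return float(np.trapezoid(self(grid), grid))


def build_hybrid_input(idif_times_min, idif_activities, samples,
                       switch_time_min: float = SWITCH_TIME_MIN,
                       calibrate_idif: bool = False) -> InputFunction:
    """Splice an image-derived curve to plasma samples at ``switch_time``.

    Knots strictly before ``switch_time`` come from the image-derived
    left-ventricle curve; knots at or after come from the plasma samples
    (blood sampling is the reference measurement, so a plasma sample
    exactly at the switch time wins the tie).

    Parameters
    ----------
    idif_times_min, idif_activities:
        The image-derived curve (e.g. frame mid-times / values of a
        left-ventricle TAC).  Must cover ``[0, switch_time]``.
    samples:
        Iterable of :class:`PlasmaSample`; at least two must lie at or
        after ``switch_time``.
    calibrate_idif:
        If True, multiplicatively rescale the image-derived segment so it
        matches the first plasma sample at the junction (off by default:
        the protocol states no cross-calibration).
    """
    it = np.asarray(idif_times_min, dtype=float)
    ia = np.asarray(idif_activities, dtype=float)
    if np.any(np.diff(it) <= 0):
        raise ValueError("image-derived times must be strictly increasing")
    samples = sorted(samples, key=lambda s: s.time_min)
    st = np.array([s.time_min for s in samples])
    sa = np.array([s.activity_kbq_ml for s in samples])
    if np.any(np.diff(st) <= 0):
        raise ValueError("duplicate plasma sample times")
    late = st >= switch_time_min
    if late.sum() < 2:
        raise ValueError("need >= 2 plasma samples at/after the switch time")
    if it[-1] < switch_time_min - 1e-9:
        raise ValueError(
            f"image-derived curve ends at {it[-1]} min, before the "
            f"{switch_time_min}-min switch: coverage gap"
        )

    keep = it < switch_time_min
    idif_t, idif_a = it[keep], ia[keep]
    if calibrate_idif and idif_t.size:
        ref = sa[late][0]
        at_switch = float(np.interp(st[late][0], it, ia))
        if at_switch > 0:
            idif_a = idif_a * (ref / at_switch)
    times = np.concatenate([idif_t, st[late]])
    acts = np.concatenate([idif_a, sa[late]])
    prov = ["idif"] * idif_t.size + ["plasma"] * int(late.sum())
    return InputFunction(times, acts, prov)
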