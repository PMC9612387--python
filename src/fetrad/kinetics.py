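"""Synthetic time-activity-curve (TAC) model for FET-like tracer kinetics.

The phantom does not attempt compartmental realism. It provides a smooth
non-negative curve with two directly controllable properties that the
downstream analysis actually measures:

* the time at which the noiseless curve attains its maximum (``peak_time``,
  minutes p.i.) — this is what a TTP map recovers;
* the mean of the curve over the late 20 min–end window, expressed as a ratio
  (``late_level``) to a fixed background reference level — this is what a
  TBR_20–40 image recovers.

Healthy grey matter shows an early peak (a few minutes p.i.) followed by a
gentle plateau; gliomas with ascending kinetics peak at or beyond the end of
the acquisition; photopenic tumors sit below background at all late times.

Functional form
---------------
Early-peaking curves are a gamma-variate rise/washout term plus a saturating
plateau term,

    s(t) = g(t; t_g, alpha) + lam * (1 - exp(-t / tau)),
    g(t; t_g, a) = (t/t_g)^a * exp(a * (1 - t/t_g)),

with ``t_g`` solved numerically so that the stationary point of ``s`` falls
exactly at the requested ``peak_time``. Ascending curves use the bare
gamma-variate with its own peak at ``peak_time`` (monotone increasing up to
that point). The curve is then scaled so that its late-window mean equals
``amplitude * late_level * BACKGROUND_LATE_MEAN``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .schedule import FrameSchedule, default_frame_schedule

__all__ = ["KineticParams", "tac_model", "BACKGROUND_LATE_MEAN", "PHENOTYPES"]

#: Absolute activity (arbitrary units) of the healthy-background late-window mean.
BACKGROUND_LATE_MEAN = 1.0

#: Start of the late quantification window, minutes p.i.
LATE_WINDOW_START_MIN = 20.0

PHENOTYPES = ("background", "isometabolic", "photopenic")

# shape constants (dimensionless / minutes); see docs/methods.md
_ALPHA_EARLY = 3.0   # gamma-variate sharpness for early-peaking curves
_ALPHA_ASC = 1.2     # gentler rise for ascending tumor curves
_PLATEAU_FRAC = 0.4  # weight of the saturating plateau term
_PLATEAU_TAU = 3.0   # plateau time constant, minutes

# curves with peak_time at/after this are modelled as purely ascending
_ASCENDING_THRESHOLD_MIN = 20.0


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth kinetic description of one tissue class.

    Parameters
    ----------
    phenotype : {"background", "isometabolic", "photopenic"}
    amplitude : float
        Overall activity scale (arbitrary units), >= 0. The late-window mean
        of the noiseless curve is ``amplitude * late_level * BACKGROUND_LATE_MEAN``.
    peak_time : float
        Minutes p.i. at which the noiseless curve attains its maximum.
    late_level : float
        Target late-window mean as a ratio to the background reference.
    """

    phenotype: str
    amplitude: float
    peak_time: float
    late_level: float

    def validate(self, t_end_min: float) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0.0 <= self.peak_time <= t_end_min):
            raise ValueError(
                f"peak_time {self.peak_time} min outside acquisition [0, {t_end_min:.2f}]"
            )
        if self.late_level <= 0 and self.phenotype == "background":
            raise ValueError("background late_level must be > 0")
        if self.phenotype == "isometabolic":
            if self.peak_time <= 30.0:
                raise ValueError("isometabolic curves must peak after 30 min p.i.")
            if abs(self.late_level - 1.0) > 0.1:
                raise ValueError("isometabolic late_level must be ~1 (within 10%)")
        if self.phenotype == "photopenic" and not (0 < self.late_level < 1):
            raise ValueError("photopenic late_level must be in (0, 1)")


def _gamma_variate(t: np.ndarray, t_peak: float, alpha: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / t_peak
    out[pos] = np.exp(alpha * (np.log(x) + 1.0 - x))
    return out


def _solve_gamma_peak(peak_time: float, t_end_min: float) -> float:
    """Gamma-peak location t_g making s'(peak_time) = 0 for the early branch."""

    def dshape(t_g: float) -> float:
        g = float(_gamma_variate(np.array([peak_time]), t_g, _ALPHA_EARLY)[0])
        dg = g * _ALPHA_EARLY * (1.0 / peak_time - 1.0 / t_g)
        dplat = _PLATEAU_FRAC / _PLATEAU_TAU * np.exp(-peak_time / _PLATEAU_TAU)
        return dg + dplat

    # dshape > 0 at t_g -> peak_time^- and for very small t_g; it dips negative
    # in between. Bracket the root closest to peak_time.
    grid = np.linspace(0.999 * peak_time, 0.05 * peak_time, 400)
    vals = [dshape(g) for g in grid]
    for i in range(len(grid) - 1):
        if vals[i] > 0 >= vals[i + 1] or vals[i] <= 0 < vals[i + 1]:
            return brentq(dshape, min(grid[i], grid[i + 1]), max(grid[i], grid[i + 1]))
    raise ValueError(
        f"no early-peak solution for peak_time={peak_time} min; "
        "choose a peak_time further from 0"
    )


def _shape_curve(params: KineticParams, t_min: np.ndarray, t_end_min: float) -> np.ndarray:
    """Unnormalized noiseless shape s(t), t in minutes."""
    if params.peak_time >= _ASCENDING_THRESHOLD_MIN:
        return _gamma_variate(t_min, params.peak_time, _ALPHA_ASC)
    t_g = _solve_gamma_peak(params.peak_time, t_end_min)
    return _gamma_variate(t_min, t_g, _ALPHA_EARLY) + _PLATEAU_FRAC * (
        1.0 - np.exp(-np.asarray(t_min, dtype=float) / _PLATEAU_TAU)
    )


def _late_window_mean(params: KineticParams, t_end_min: float) -> float:
    """Mean of the shape over [20 min, acquisition end] on a 1 s grid."""
    grid = np.arange(LATE_WINDOW_START_MIN, t_end_min + 1e-9, 1.0 / 60.0)
    return float(np.trapezoid(_shape_curve(params, grid, t_end_min), grid)) / (
        grid[-1] - grid[0]
    )


def tac_model(
    params: KineticParams,
    times_min,
    schedule: FrameSchedule | None = None,
) -> np.ndarray:
    """Evaluate the noiseless time-activity curve at ``times_min`` (minutes p.i.).

    The returned curve is non-negative, attains its maximum at
    ``params.peak_time`` (on a dense grid, to within grid resolution), and its
    mean over the late window [20 min, acquisition end] equals
    ``params.amplitude * params.late_level * BACKGROUND_LATE_MEAN``.

    Raises
    ------
    ValueError
        If ``params`` violate its invariants (negative amplitude, peak_time
        outside the acquisition, ...), or times fall outside the acquisition.
    """
    schedule = schedule or default_frame_schedule()
    t_end_min = schedule.end_s / 60.0
    params.validate(t_end_min)
    t = np.asarray(times_min, dtype=float)
    if t.ndim > 0 and np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    if np.any(t < 0) or np.any(t > t_end_min + 1e-9):
        raise ValueError("times outside the acquisition span")
    if params.amplitude == 0:
        return np.zeros_like(t)
    shape = _shape_curve(params, t, t_end_min)
    scale = (
        params.amplitude
        * params.late_level
        * BACKGROUND_LATE_MEAN
        / _late_window_mean(params, t_end_min)
    )
    return scale * shape


def default_params(phenotype: str) -> KineticParams:
    """Reference kinetic parameters per tissue phenotype.

    Background peaks at 5 min with a late plateau at the reference level;
    isometabolic tumors ascend through the whole acquisition with a late
    level equal to background (visually FET-negative but kinetically late);
    photopenic tumors also ascend but sit well below background.
    """
    if phenotype == "background":
        return KineticParams("background", 1.0, 5.0, 1.0)
    if phenotype == "isometabolic":
        return KineticParams("isometabolic", 1.0, 39.5, 1.0)
    if phenotype == "photopenic":
        return KineticParams("photopenic", 1.0, 39.5, 0.65)
    if phenotype == "ventricle":
        # CSF/blood-pool-like: early bolus peak, low late retention
        return KineticParams("background", 1.0, 2.5, 0.3)
    raise ValueError(f"unknown phenotype {phenotype!r}")
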