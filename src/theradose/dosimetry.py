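"""Voxel dosimetry: time-integrated activity, S-value dose maps, SUV images.

Absorbed dose follows the MIRD-style local-energy-deposition approximation:
each voxel's time-integrated activity (TIA, MBq·s) is multiplied by a single
organ-level S-value (mGy per MBq·s).  The default S-value, 2.2e-04
mGy/MBq/s, is the ICRP-110-derived left-kidney-cortex value for Lu-177 and is
applied to every organ unless a per-organ table is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import TimeActivityCurve

__all__ = [
    "KIDNEY_CORTEX_S_VALUE",
    "TIAMap",
    "DoseMap",
    "SUVImage",
    "time_integrated_activity",
    "tia_from_curves",
    "absorbed_dose_map",
    "suv_image",
]

#: Lu-177 left-kidney-cortex S-value, mGy per MBq·s (ICRP 110 reference phantom).
KIDNEY_CORTEX_S_VALUE = 2.2e-4

#: Default injected therapy activity per cycle, MBq (clinical 7.3 +/- 0.3 GBq).
DEFAULT_THERAPY_ACTIVITY_MBQ = 7300.0

#: Default PET tracer activity, MBq, and patient weight, kg.
DEFAULT_PET_ACTIVITY_MBQ = 118.4
DEFAULT_BODY_WEIGHT_KG = 78.7


@dataclass
class TIAMap:
    """Voxel time-integrated activity (MBq·s), zero outside organ masks."""

    values: np.ndarray
    tail_model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("time-integrated activity must be nonnegative")


@dataclass
class DoseMap:
    """Voxel absorbed dose (mGy) and the S-value used to produce it."""

    values: np.ndarray
    s_value: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("absorbed dose must be nonnegative")


@dataclass
class SUVImage:
    """Standardised-uptake-value image at a single post-injection time."""

    values: np.ndarray
    t_pet_min: float
    injected_mbq: float
    weight_kg: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("SUV must be nonnegative")


def _tail_lambda(times: np.ndarray, values: np.ndarray, lambda_phys: float):
    """Effective terminal decay rate(s) by log-linear fit on the final decade.

    Fits ln(A) against t over the trailing samples whose time lies within the
    last decade of the grid (t >= t_end / 10), requiring at least 3 positive
    samples there; the result is floored at the physical decay constant.
    values may be (n_vox, T).  Returns (lam_eff, usable_mask).
    """
    t_end = times[-1]
    window = times >= t_end / 10.0
    if window.sum() < 3:
        window = np.zeros_like(times, dtype=bool)
        window[-3:] = True
    tw = times[window]
    vw = values[..., window]
    positive = np.all(vw > 0, axis=-1) & (values[..., -1] > 0) & (values[..., -2] > 0)
    lam = np.zeros(values.shape[:-1])
    if np.any(positive):
        logv = np.log(vw[positive])
        t_c = tw - tw.mean()
        slope = (logv * t_c).sum(axis=-1) / (t_c**2).sum()
        lam[positive] = -slope
    if np.isfinite(lambda_phys) and lambda_phys > 0:
        lam = np.maximum(lam, lambda_phys)
    return lam, positive


def tia_from_curves(
    times: np.ndarray,
    values: np.ndarray,
    voxel_volume_ml: float,
    lambda_phys: float = 0.0,
) -> np.ndarray:
    """Vectorised TIA (MBq·s) for curves sampled on a shared grid.

    Trapezoidal integral over the grid plus an analytic single-exponential
    tail A(T)/lambda_eff, with lambda_eff from a log-linear fit to the final
    decade of samples, floored at the physical decay constant.  Curves whose
    last two samples are not positive get a zero tail.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if np.any(values < 0):
        raise ValueError("activity values must be nonnegative")
    core = np.trapezoid(values, times, axis=-1)
    lam, usable = _tail_lambda(times, values, lambda_phys)
    tail = np.zeros_like(core)
    if np.any(usable):
        lam_u = lam[usable]
        if np.any(lam_u <= 0):
            raise ValueError("non-decaying tail: fitted effective lambda <= 0")
        tail[usable] = values[..., -1][usable] / lam_u
    # concentrations are MBq/mL over minutes: x60 -> MBq·s/mL, then x volume
    return (core + tail) * 60.0 * voxel_volume_ml


def time_integrated_activity(tac: TimeActivityCurve, voxel_volume_ml: float = 1.0,
                             lambda_phys: float = 0.0) -> float:
    """TIA (MBq·s) of a single voxel TAC; see :func:`tia_from_curves`."""
    return float(
        tia_from_curves(tac.times, tac.values[None, :], voxel_volume_ml, lambda_phys)[0]
    )


def absorbed_dose_map(tia: TIAMap, s_value: float = KIDNEY_CORTEX_S_VALUE) -> DoseMap:
    """dose(v) = TIA(v) * S, local-energy-deposition approximation."""
    if s_value <= 0:
        raise ValueError("S-value must be positive")
    if np.any(tia.values < 0):
        raise ValueError("time-integrated activity must be nonnegative")
    return DoseMap(values=tia.values * s_value, s_value=float(s_value))


def suv_image(
    concentration_mbq_ml: np.ndarray,
    injected_mbq: float,
    weight_kg: float,
    t_pet_min: float = 60.0,
) -> SUVImage:
    """SUV(v) = conc(v)[Bq/mL] * weight[g] / injected[Bq].

    Concentration is given in MBq/mL; the MBq factors cancel so the
    computation reduces to conc * weight_g / injected_MBq... in consistent
    units: SUV = conc_MBq_per_mL * (weight_kg * 1000) / injected_MBq.
    """
    if injected_mbq <= 0 or weight_kg <= 0:
        raise ValueError("injected activity and body weight must be positive")
    conc = np.asarray(concentration_mbq_ml, dtype=float)
    if np.any(conc < 0):
        raise ValueError("activity concentration must be nonnegative")
    suv = conc * (weight_kg * 1000.0) / injected_mbq
    return SUVImage(
        values=suv,
        t_pet_min=float(t_pet_min),
        injected_mbq=float(injected_mbq),
        weight_kg=float(weight_kg),
    )
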