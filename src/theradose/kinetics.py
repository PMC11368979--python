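"""Two-tissue-compartment (2TCM) kinetics for theranostic compound pairs.

The tracer/therapy activity concentration in a voxel is modelled with the
standard reversible two-tissue compartment model: plasma concentration
``Cp(t)`` feeds a free compartment (rate ``k1``, clearance ``k2``) which
exchanges with a bound compartment (``k3`` forward, ``k4`` back).  The tissue
impulse response is the well-known biexponential

    h(t) = k1/(a2-a1) * [(k3+k4-a1) e^{-a1 t} + (a2-k3-k4) e^{-a2 t}]

with eigenrates ``a1 <= a2`` the roots of ``s^2 - (k2+k3+k4) s + k2 k4``.
The measured concentration adds a fractional blood volume ``Vb`` and the
physical decay of the nuclide:

    C(t) = exp(-lambda_phys * t) * [(1 - Vb) * (h (*) Cp)(t) + Vb * Cp(t)]

All convolutions with the Feng-type arterial input function are evaluated in
closed form (sums of ``t^m exp(-r t)`` terms), so whole parameter *fields*
can be simulated vectorised over voxels.  Rate constants are interpreted as
decay-corrected kinetics; physical decay enters only through the explicit
exponential factor above.

Units: times and rates are minutes and 1/min; concentrations follow the
input-function units (MBq/mL by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticParams",
    "InputFunction",
    "ImpulseResponse",
    "NuclideSpec",
    "TimeActivityCurve",
    "GA68",
    "LU177",
    "PET_INPUT_DEFAULT",
    "THERAPY_INPUT_DEFAULT",
    "tcm_impulse_response",
    "simulate_tac",
    "simulate_tac_field",
    "pet_time_grid",
    "therapy_time_grid",
]

LN2 = math.log(2.0)

# Relative eigenrate gap below which the repeated-eigenvalue limit form is used.
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class KineticParams:
    """2TCM rate constants for one voxel or sub-tissue and one compound.

    k1 : mL·min⁻¹·cm⁻³ plasma-to-tissue transport
    k2, k3, k4 : min⁻¹ exchange rates
    vb : unitless fractional blood volume, 0 <= vb <= 1
    """

    k1: float
    k2: float
    k3: float
    k4: float
    vb: float

    def __post_init__(self) -> None:
        vals = (self.k1, self.k2, self.k3, self.k4, self.vb)
        if any(not np.isfinite(v) or v < 0 for v in vals):
            raise ValueError(f"kinetic parameters must be finite and >= 0, got {vals}")
        if self.vb > 1:
            raise ValueError(f"blood volume fraction vb must be <= 1, got {self.vb}")

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4, self.vb])

    @staticmethod
    def from_array(a) -> "KineticParams":
        a = np.asarray(a, dtype=float)
        return KineticParams(*a.tolist())


@dataclass(frozen=True)
class NuclideSpec:
    """Radionuclide physical-decay constants (half-life in minutes)."""

    name: str
    half_life_min: float

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant in min⁻¹ (= ln2 / half-life)."""
        return LN2 / self.half_life_min


GA68 = NuclideSpec("Ga-68", 67.71)
LU177 = NuclideSpec("Lu-177", 6.647 * 24 * 60)
STABLE = NuclideSpec("stable", math.inf)


@dataclass(frozen=True)
class InputFunction:
    r"""Feng-type triexponential arterial input function.

    Cp(t) = (A1 t - A2 - A3) e^{-l1 t} + A2 e^{-l2 t} + A3 e^{-l3 t}

    with eigenrates ``l1 > l2 > l3 >= 0`` so that Cp(0) = 0 by construction.
    Coefficients carry the concentration unit (MBq/mL); A1 is per minute.
    """

    a1: float
    a2: float
    a3: float
    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        if not (self.l1 > self.l2 > self.l3 >= 0):
            raise ValueError("input-function eigenrates must satisfy l1 > l2 > l3 >= 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            (self.a1 * t - self.a2 - self.a3) * np.exp(-self.l1 * t)
            + self.a2 * np.exp(-self.l2 * t)
            + self.a3 * np.exp(-self.l3 * t)
        )

    def validate_on(self, times: np.ndarray) -> None:
        vals = self(times)
        if np.any(vals < -1e-12 * max(1.0, float(np.max(np.abs(vals))))):
            raise ValueError("input function is negative on the simulation grid")

    def terms(self) -> list[tuple[float, int, float]]:
        """Decomposition into (coefficient, power m, rate r) of c·t^m·e^{-rt}."""
        return [
            (self.a1, 1, self.l1),
            (-(self.a2 + self.a3), 0, self.l1),
            (self.a2, 0, self.l2),
            (self.a3, 0, self.l3),
        ]


# Default input functions: a fast-peaking bolus for the PET session (minutes
# scale) and a slower, long-tailed curve for the therapy compound (clearance
# half-times of ~1 h and ~20 h).  Both are config-overridable; amplitudes are
# chosen so simulated organ SUV and absorbed dose land in clinically familiar
# ranges.
PET_INPUT_DEFAULT = InputFunction(a1=0.18, a2=0.004, a3=0.003, l1=4.0, l2=0.12, l3=0.012)
THERAPY_INPUT_DEFAULT = InputFunction(
    a1=2.0, a2=0.12, a3=0.05, l1=0.8, l2=0.012, l3=0.0006
)


@dataclass(frozen=True)
class ImpulseResponse:
    """Closed-form 2TCM tissue impulse response.

    h(t) = amp1 e^{-alpha1 t} + amp2 e^{-alpha2 t}          (alpha1 < alpha2)
    h(t) = (amp1 + amp2 t) e^{-alpha1 t}                    (degenerate)
    """

    amp1: float
    amp2: float
    alpha1: float
    alpha2: float
    degenerate: bool = False

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.degenerate:
            return (self.amp1 + self.amp2 * t) * np.exp(-self.alpha1 * t)
        return self.amp1 * np.exp(-self.alpha1 * t) + self.amp2 * np.exp(-self.alpha2 * t)


def tcm_impulse_response(params: KineticParams) -> ImpulseResponse:
    """Eigen-decompose the 2TCM into its biexponential impulse response.

    Raises ValueError for a non-clearing tissue (k2+k3+k4 = 0 with k1 > 0),
    whose impulse response integral diverges.  The repeated-eigenvalue case is
    returned in its analytic ``(c0 + c1 t) e^{-alpha t}`` limit form.
    """
    k1, k2, k3, k4 = params.k1, params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    if s == 0.0:
        if k1 > 0:
            raise ValueError(
                "non-clearing tissue: k2 + k3 + k4 = 0 with k1 > 0 "
                "(impulse response does not decay)"
            )
        return ImpulseResponse(0.0, 0.0, 0.0, 0.0)
    disc = s * s - 4.0 * k2 * k4
    # disc >= 0 always for nonnegative rates: s^2 - 4 k2 k4 >= (k2 - k4)^2.
    root = math.sqrt(max(disc, 0.0))
    alpha1 = 0.5 * (s - root)
    alpha2 = 0.5 * (s + root)
    if root <= _DEGENERATE_RTOL * s:
        alpha = 0.5 * (alpha1 + alpha2)
        # h -> k1 e^{-alpha t} + k1 (k3 + k4 - alpha) t e^{-alpha t}
        return ImpulseResponse(k1, k1 * (k3 + k4 - alpha), alpha, alpha, degenerate=True)
    amp1 = k1 * (k3 + k4 - alpha1) / root
    amp2 = k1 * (alpha2 - k3 - k4) / root
    return ImpulseResponse(amp1, amp2, alpha1, alpha2)


@dataclass
class TimeActivityCurve:
    """Sampled activity-concentration curve (times min, values MBq/mL)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing from 0")
        if self.values.shape[-1] != self.times.shape[0]:
            raise ValueError("values length must match times")


# --- stable building blocks -------------------------------------------------
#
# With b = alpha - lam, x = b t, E_a = e^{-alpha t}, E_l = e^{-lam t}, and all
# convolutions (f*g)(t) = int_0^t f(t-s) g(s) ds, the closed forms are
#
#   e^{-at} * e^{-lt}         = (E_l - E_a) / b
#   e^{-at} * (t e^{-lt})     = ((x-1) E_l + E_a) / b^2
#   (t e^{-at}) * e^{-lt}     = (E_l - (1+x) E_a) / b^2
#   (t e^{-at}) * (t e^{-lt}) = ((x-2) E_l + (2+x) E_a) / b^3
#
# Every exponent is nonpositive (no overflow for any alpha, lam, t >= 0); the
# cancellation as alpha -> lam is handled by switching to the Taylor series of
# the scaled forms E_l t^(m+1) P(x) below a small-|x| threshold, which also
# covers b = 0 exactly.

_SMALL = 0.05


def _series(x, coeffs):
    out = np.zeros_like(x)
    for c in reversed(coeffs):
        out = out * x + c
    return out


# Taylor coefficients in x of the scaled convolution kernels:
#   P_E0 = (1 - e^{-x})/x                     -> E_l t   P_E0(x)
#   P_E1 = (x - 1 + e^{-x})/x^2               -> E_l t^2 P_E1(x)
#   P_F0 = (1 - (1+x) e^{-x})/x^2             -> E_l t^2 P_F0(x)
#   P_F1 = (x - 2 + (2+x) e^{-x})/x^3         -> E_l t^3 P_F1(x)
_C_E0 = (1.0, -1 / 2, 1 / 6, -1 / 24, 1 / 120, -1 / 720)
_C_E1 = (1 / 2, -1 / 6, 1 / 24, -1 / 120, 1 / 720, -1 / 5040)
_C_F0 = (1 / 2, -1 / 3, 1 / 8, -1 / 30, 1 / 144, -1 / 840)
_C_F1 = (1 / 6, -1 / 12, 1 / 40, -1 / 180, 1 / 1008, -1 / 6720)


def _conv_exp(alpha, coef, m, lam, t):
    """(e^{-alpha t}) convolved with coef * t^m * e^{-lam t} on grid t.

    alpha may be an array broadcast against t (voxels x times).
    """
    b = alpha - lam
    x = b * t
    el = np.exp(-lam * np.asarray(t, dtype=float)) * np.ones_like(x)
    ea = np.exp(-alpha * t) * np.ones_like(x)
    small = np.abs(x) < _SMALL
    bs = np.where(np.abs(b) > 0, b, 1.0) * np.ones_like(x)
    if m == 0:
        direct = (el - ea) / bs
        series = el * t * _series(x, _C_E0)
    else:
        direct = ((x - 1.0) * el + ea) / bs**2
        series = el * t**2 * _series(x, _C_E1)
    return coef * np.where(small, series, direct)


def _conv_texp(alpha, coef, m, lam, t):
    """(t e^{-alpha t}) convolved with coef * t^m * e^{-lam t} on grid t."""
    b = alpha - lam
    x = b * t
    el = np.exp(-lam * np.asarray(t, dtype=float)) * np.ones_like(x)
    ea = np.exp(-alpha * t) * np.ones_like(x)
    small = np.abs(x) < _SMALL
    bs = np.where(np.abs(b) > 0, b, 1.0) * np.ones_like(x)
    if m == 0:
        direct = (el - (1.0 + x) * ea) / bs**2
        series = el * t**2 * _series(x, _C_F0)
    else:
        direct = ((x - 2.0) * el + (2.0 + x) * ea) / bs**3
        series = el * t**3 * _series(x, _C_F1)
    return coef * np.where(small, series, direct)


def _convolve_input(h: ImpulseResponse, input_fn: InputFunction, t: np.ndarray) -> np.ndarray:
    """Analytic (h (*) Cp)(t) for a scalar impulse response."""
    out = np.zeros_like(t, dtype=float)
    for coef, m, lam in input_fn.terms():
        if h.degenerate:
            out += h.amp1 * _conv_exp(h.alpha1, coef, m, lam, t)
            out += h.amp2 * _conv_texp(h.alpha1, coef, m, lam, t)
        else:
            out += h.amp1 * _conv_exp(h.alpha1, coef, m, lam, t)
            out += h.amp2 * _conv_exp(h.alpha2, coef, m, lam, t)
    return out


def simulate_tac(
    params: KineticParams,
    input_fn: InputFunction,
    nuclide: NuclideSpec,
    times: np.ndarray,
) -> TimeActivityCurve:
    """Simulate the measured voxel TAC for one parameter set.

    C(t) = e^{-lambda_phys t} [ (1-Vb) (h (*) Cp)(t) + Vb Cp(t) ]
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing from 0")
    input_fn.validate_on(times)
    cp = input_fn(times)
    if params.k1 > 0 or params.k2 + params.k3 + params.k4 > 0:
        h = tcm_impulse_response(params)
        tissue = _convolve_input(h, input_fn, times)
    else:
        tissue = np.zeros_like(times)
    c = (1.0 - params.vb) * tissue + params.vb * cp
    lam = nuclide.lambda_phys
    if np.isfinite(lam) and lam > 0:
        c = np.exp(-lam * times) * c
    # clip tiny negative round-off
    np.clip(c, 0.0, None, out=c)
    return TimeActivityCurve(times, c)


def simulate_tac_field(
    fields: np.ndarray,
    input_fn: InputFunction,
    nuclide: NuclideSpec,
    times: np.ndarray,
) -> np.ndarray:
    """Vectorised TAC simulation for N voxels.

    Parameters
    ----------
    fields : array (5, N) of [k1, k2, k3, k4, vb] per voxel.
    times : 1-D grid, strictly increasing from 0.

    Returns
    -------
    array (N, T) of activity concentrations.
    """
    fields = np.asarray(fields, dtype=float)
    if fields.ndim != 2 or fields.shape[0] != 5:
        raise ValueError("fields must have shape (5, n_voxels)")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing from 0")
    input_fn.validate_on(times)

    k1, k2, k3, k4, vb = fields
    if np.any(fields < 0) or np.any(vb > 1):
        raise ValueError("invalid kinetic parameter field (negative or vb > 1)")
    s = k2 + k3 + k4
    if np.any((s == 0) & (k1 > 0)):
        raise ValueError("non-clearing voxels: k2 + k3 + k4 = 0 with k1 > 0")

    disc = np.maximum(s * s - 4.0 * k2 * k4, 0.0)
    root = np.sqrt(disc)
    alpha1 = 0.5 * (s - root)
    alpha2 = 0.5 * (s + root)
    degen = root <= _DEGENERATE_RTOL * np.maximum(s, 1e-300)

    t = times[None, :]
    a1c = alpha1[:, None]
    a2c = alpha2[:, None]
    tissue = np.zeros((fields.shape[1], times.size))

    # non-degenerate amplitudes (safe divide; degenerate rows overwritten below)
    root_safe = np.where(degen, 1.0, root)
    amp1 = (k1 * (k3 + k4 - alpha1) / root_safe)[:, None]
    amp2 = (k1 * (alpha2 - k3 - k4) / root_safe)[:, None]

    for coef, m, lam in input_fn.terms():
        tissue += amp1 * _conv_exp(a1c, coef, m, lam, t)
        tissue += amp2 * _conv_exp(a2c, coef, m, lam, t)

    if np.any(degen):
        idx = np.flatnonzero(degen)
        alpha = (0.5 * (alpha1 + alpha2))[idx][:, None]
        c0 = k1[idx][:, None]
        c1 = (k1 * (k3 + k4 - 0.5 * (alpha1 + alpha2)))[idx][:, None]
        td = times[None, :]
        block = np.zeros((idx.size, times.size))
        for coef, m, lam in input_fn.terms():
            block += c0 * _conv_exp(alpha, coef, m, lam, td)
            block += c1 * _conv_texp(alpha, coef, m, lam, td)
        tissue[idx] = block

    cp = input_fn(times)[None, :]
    c = (1.0 - vb)[:, None] * tissue + vb[:, None] * cp
    lam_p = nuclide.lambda_phys
    if np.isfinite(lam_p) and lam_p > 0:
        c = np.exp(-lam_p * times)[None, :] * c
    np.clip(c, 0.0, None, out=c)
    return c


def pet_time_grid(t_end: float = 90.0, step: float = 1.0) -> np.ndarray:
    """Default PET session grid: 0..t_end minutes, 1-min steps."""
    return np.arange(0.0, t_end + 0.5 * step, step)


def therapy_time_grid(
    t_end_days: float = 14.0, n_points: int = 220, t_first_min: float = 0.5
) -> np.ndarray:
    """Default therapy grid: t=0 plus log-spaced points out to t_end_days."""
    if n_points < 200:
        raise ValueError("therapy grid needs >= 200 points for stable tail fits")
    end = t_end_days * 24.0 * 60.0
    grid = np.geomspace(t_first_min, end, n_points)
    return np.concatenate([[0.0], grid])
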