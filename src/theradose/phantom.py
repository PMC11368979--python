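"""Synthetic organ phantoms with sub-tissue-resolved kinetic-parameter fields.

A phantom is a 3-D label volume (background 0) containing ellipsoidal organs,
each split into two concentric sub-tissues: a cortex-like rim (sub-tissue 1)
and a core (sub-tissue 2).  Every organ voxel carries a five-vector of 2TCM
parameters for the PET tracer, built as

    kp_i(v) = mean_i(sub-tissue) * g(v) * eps_i(v)

where ``g`` is a radial gradient factor varying linearly from
``1 + gradient_amplitude`` at the organ boundary to ``1 - gradient_amplitude``
at the centre (one common factor for all five parameters), and ``eps_i`` are
independent multiplicative truncated-normal noise factors (mean 1, coefficient
of variation ``noise_cv``, truncated below at 0.01) so positivity is
structural.  Therapy-compound fields follow from per-sub-tissue ratio vectors
rho_ij = kp_ij / kt_ij: identical vectors in both sub-tissues define the
homogeneous pharmacokinetic linkage, diverging vectors the heterogeneous one.

Generation is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kinetics import KineticParams

__all__ = [
    "LinkageSpec",
    "OrganSpec",
    "PhantomConfig",
    "Phantom",
    "generate_phantom",
    "link_therapy_params",
    "sub_tissue_label",
]

_PARAM_NAMES = ("k1", "k2", "k3", "k4", "vb")
_NOISE_FLOOR = 0.01


def sub_tissue_label(organ_id: int, sub: int) -> int:
    """Label code for (organ, sub-tissue): organ_id*10 + sub, sub in {1, 2}."""
    if sub not in (1, 2):
        raise ValueError("sub-tissue index must be 1 (rim) or 2 (core)")
    return organ_id * 10 + sub


@dataclass(frozen=True)
class LinkageSpec:
    """Tracer-to-therapy kinetic ratio vectors rho_ij = kp_ij / kt_ij.

    mode is 'homogeneous' (both sub-tissues share one ratio vector) or
    'heterogeneous' (the vectors differ in at least one component).
    """

    mode: str
    ratios_sub1: tuple[float, float, float, float, float]
    ratios_sub2: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if self.mode not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown linkage mode {self.mode!r}")
        r1 = np.asarray(self.ratios_sub1, dtype=float)
        r2 = np.asarray(self.ratios_sub2, dtype=float)
        if r1.shape != (5,) or r2.shape != (5,):
            raise ValueError("ratio vectors must have five components")
        if np.any(r1 <= 0) or np.any(r2 <= 0):
            raise ValueError("all kp/kt ratios must be > 0")
        same = np.allclose(r1, r2, rtol=0, atol=0)
        if self.mode == "homogeneous" and not same:
            raise ValueError("homogeneous linkage requires identical ratio vectors")
        if self.mode == "heterogeneous" and same:
            raise ValueError("heterogeneous linkage requires differing ratio vectors")

    @staticmethod
    def homogeneous(ratios=(1.0, 1.0, 1.0, 1.0, 1.0)) -> "LinkageSpec":
        r = tuple(float(x) for x in ratios)
        return LinkageSpec("homogeneous", r, r)

    def ratio_for(self, sub: int) -> np.ndarray:
        return np.asarray(self.ratios_sub1 if sub == 1 else self.ratios_sub2, dtype=float)


@dataclass(frozen=True)
class OrganSpec:
    """One ellipsoidal organ: integer id >= 1, centre and radii in voxels."""

    organ_id: int
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    mean_params_sub1: KineticParams = KineticParams(0.6, 0.3, 0.08, 0.0, 0.10)
    mean_params_sub2: KineticParams = KineticParams(0.42, 0.21, 0.056, 0.0, 0.07)
    core_fraction: float = 0.8  # core = ellipsoid scaled by this radius fraction

    def __post_init__(self) -> None:
        if self.organ_id < 1:
            raise ValueError("organ_id must be >= 1")
        if not 0 < self.core_fraction < 1:
            raise ValueError("core_fraction must be in (0, 1)")
        if any(r <= 0 for r in self.radii):
            raise ValueError("organ radii must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    organs: tuple[OrganSpec, ...] = ()
    gradient_amplitude: float = 0.3
    noise_cv: float = 0.02
    linkage: LinkageSpec = field(default_factory=LinkageSpec.homogeneous)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.gradient_amplitude < 1:
            raise ValueError("gradient_amplitude must be in [0, 1)")
        if not self.organs:
            raise ValueError("config must define at least one organ")


@dataclass
class Phantom:
    """Generated phantom: labels plus paired tracer/therapy parameter fields.

    labels : int volume, 0 background, organ_id*10 + sub_tissue inside organs.
    tracer_fields / therapy_fields : dict name -> 3-D float volume, zero
    outside organ masks and strictly positive inside.
    """

    labels: np.ndarray
    tracer_fields: dict[str, np.ndarray]
    therapy_fields: dict[str, np.ndarray]
    voxel_size_mm: tuple[float, float, float]
    seed: int
    config: PhantomConfig

    @property
    def organ_mask(self) -> np.ndarray:
        return self.labels > 0

    def mask_for(self, organ_id: int, sub: int | None = None) -> np.ndarray:
        if sub is None:
            return (self.labels // 10) == organ_id
        return self.labels == sub_tissue_label(organ_id, sub)

    def field_matrix(self, which: str, mask: np.ndarray) -> np.ndarray:
        """Stack the five parameter volumes into a (5, n_masked) matrix."""
        fields = self.tracer_fields if which == "tracer" else self.therapy_fields
        return np.stack([fields[n][mask] for n in _PARAM_NAMES])

    @property
    def voxel_volume_ml(self) -> float:
        vx = np.prod(self.voxel_size_mm)  # mm^3
        return float(vx) / 1000.0


def _ellipsoid_radius(shape, center, radii) -> np.ndarray:
    """Normalised ellipsoidal radius field rho(v) (1 on the surface)."""
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    return np.sqrt(
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    )


def _truncnorm_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise: truncated normal, mean 1, sd cv, lower bound 0.01."""
    if cv == 0:
        return np.ones(size)
    a = (_NOISE_FLOOR - 1.0) / cv
    return stats.truncnorm.rvs(a, np.inf, loc=1.0, scale=cv, size=size, random_state=rng)


def generate_phantom(config: PhantomConfig, seed: int) -> Phantom:
    """Generate a seeded phantom with tracer and therapy parameter fields.

    Raises ValueError if organ ellipsoids overlap or the linkage would push a
    therapy blood-volume fraction above 1.
    """
    shape = tuple(config.grid_shape)
    labels = np.zeros(shape, dtype=np.int32)
    rho_map = np.zeros(shape, dtype=float)

    for organ in config.organs:
        rho = _ellipsoid_radius(shape, organ.center, organ.radii)
        inside = rho < 1.0
        if not inside.any():
            raise ValueError(f"organ {organ.organ_id} lies outside the grid")
        if np.any(labels[inside] != 0):
            raise ValueError(
                f"organ {organ.organ_id} overlaps a previously placed organ"
            )
        core = rho < organ.core_fraction
        labels[inside] = sub_tissue_label(organ.organ_id, 1)
        labels[core] = sub_tissue_label(organ.organ_id, 2)
        rho_map[inside] = rho[inside]

    rng = np.random.default_rng(seed)
    tracer = {n: np.zeros(shape) for n in _PARAM_NAMES}

    # radial gradient: 1 + A at the boundary (rho=1) down to 1 - A at the centre
    grad = 1.0 + config.gradient_amplitude * (2.0 * rho_map - 1.0)

    for organ in config.organs:
        for sub, means in ((1, organ.mean_params_sub1), (2, organ.mean_params_sub2)):
            m = labels == sub_tissue_label(organ.organ_id, sub)
            n = int(m.sum())
            if n == 0:
                continue
            mean_vec = means.as_array()
            noise = _truncnorm_factors(rng, config.noise_cv, (5, n))
            for i, name in enumerate(_PARAM_NAMES):
                tracer[name][m] = mean_vec[i] * grad[m] * noise[i]
    vb = tracer["vb"]
    np.clip(vb, None, 1.0, out=vb)

    therapy = link_therapy_params(tracer, config.linkage, labels)
    return Phantom(
        labels=labels,
        tracer_fields=tracer,
        therapy_fields=therapy,
        voxel_size_mm=tuple(config.voxel_size_mm),
        seed=int(seed),
        config=config,
    )


def link_therapy_params(
    tracer: dict[str, np.ndarray], linkage: LinkageSpec, labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Derive therapy-compound fields kt_i(v) = kp_i(v) / rho_i,j(v).

    In homogeneous mode the empirical kp/kt ratio field is constant (zero
    variance) across the whole organ by construction.
    """
    therapy = {n: np.zeros_like(tracer[n]) for n in _PARAM_NAMES}
    organ_ids = sorted({int(l) // 10 for l in np.unique(labels) if l > 0})
    for organ_id in organ_ids:
        for sub in (1, 2):
            m = labels == sub_tissue_label(organ_id, sub)
            if not m.any():
                continue
            rho = linkage.ratio_for(sub)
            for i, name in enumerate(_PARAM_NAMES):
                therapy[name][m] = tracer[name][m] / rho[i]
    bad = therapy["vb"] > 1.0 + 1e-12
    if bad.any():
        v = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            f"therapy blood-volume fraction exceeds 1 at voxel {v} "
            f"(sub-tissue label {int(labels[v])}); lower the vb ratio"
        )
    return therapy
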