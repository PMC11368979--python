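"""Voxel-wise and texture-level PET-vs-dose agreement within organ masks.

Texture heterogeneity is quantified with standard radiomics descriptors:
Gray-Level Co-occurrence Matrix (GLCM: contrast, correlation, energy,
homogeneity, entropy) and Gray-Level Run-Length Matrix (GLRLM: SRE, LRE,
GLN, RLN, RP).  Images are quantised to ``levels`` equal-width bins over the
masked intensity range; matrices are built from the 13 unique 3-D direction
vectors at distance 1 (symmetric accumulation for the GLCM).  Runs are broken
at mask boundaries.

Significance follows the two-sided Pearson test with the default threshold
P < 0.025.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DIRECTIONS_3D",
    "CorrelationResult",
    "TextureFeatures",
    "quantize",
    "voxel_pearson",
    "glcm_features",
    "glrlm_features",
    "cohort_feature_correlation",
]

#: Default two-sided significance threshold.
ALPHA_DEFAULT = 0.025

#: The 13 unique 3-D offsets at Chebyshev distance 1 (one per +/- pair).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13

GLCM_FEATURES = ("glcm_contrast", "glcm_correlation", "glcm_energy",
                 "glcm_homogeneity", "glcm_entropy")
GLRLM_FEATURES = ("glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_rln", "glrlm_rp")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    mask_id: str = ""
    alpha: float = ALPHA_DEFAULT

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class TextureFeatures:
    """Named scalar texture features plus quantisation metadata."""

    values: dict[str, float]
    levels: int
    bin_edges: np.ndarray = field(repr=False, default=None)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _as_volume(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 2:
        a = a[None, ...]
    if a.ndim != 3:
        raise ValueError("expected a 2-D or 3-D image")
    return a


def voxel_pearson(img_a, img_b, mask, mask_id: str = "",
                  alpha: float = ALPHA_DEFAULT) -> CorrelationResult:
    """Pearson correlation of two images over a mask, two-sided p-value.

    Raises on zero variance (undefined r) rather than returning NaN.
    """
    mask = np.asarray(mask).astype(bool)
    a = np.asarray(img_a, dtype=float)[mask]
    b = np.asarray(img_b, dtype=float)[mask]
    if a.size < 3:
        raise ValueError("need at least 3 voxels in the mask")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("images must be finite on the mask")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson r undefined: zero variance within the mask")
    res = stats.pearsonr(a, b)
    return CorrelationResult(
        r=float(res.statistic), p_value=float(res.pvalue), n=int(a.size),
        mask_id=mask_id, alpha=alpha,
    )


def quantize(img, mask, levels: int) -> np.ndarray:
    """Equal-width quantisation of masked intensities to 0..levels-1.

    Returns an int volume with -1 outside the mask.  A constant masked image
    maps entirely to level 0.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = _as_volume(img)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        mask = np.broadcast_to(mask, img.shape)
    vals = img[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    lo, hi = float(vals.min()), float(vals.max())
    q = np.full(img.shape, -1, dtype=np.int64)
    if hi == lo:
        q[mask] = 0
        return q
    edges = np.linspace(lo, hi, levels + 1)
    idx = np.clip(np.searchsorted(edges, img[mask], side="right") - 1, 0, levels - 1)
    q[mask] = idx
    return q


def _bin_edges(img, mask, levels):
    vals = np.asarray(img, dtype=float)[np.asarray(mask).astype(bool)]
    return np.linspace(float(vals.min()), float(vals.max()), levels + 1)


def _glcm_matrix(q: np.ndarray, levels: int, offset) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset (vectorised shifts)."""
    dz, dy, dx = offset
    s = q.shape

    def sl(d, n):
        if d >= 0:
            return slice(d, n), slice(0, n - d)
        return slice(0, n + d), slice(-d, n)

    az, bz = sl(dz, s[0])
    ay, by = sl(dy, s[1])
    ax, bx = sl(dx, s[2])
    p = q[az, ay, ax]
    r = q[bz, by, bx]
    ok = (p >= 0) & (r >= 0)
    pv, rv = p[ok], r[ok]
    mat = np.zeros((levels, levels))
    np.add.at(mat, (pv, rv), 1.0)
    np.add.at(mat, (rv, pv), 1.0)
    return mat


def glcm_features(img, mask, levels: int = 64,
                  offsets=DIRECTIONS_3D) -> TextureFeatures:
    """Haralick features from the offset-averaged, normalised GLCM.

    Each offset's symmetric co-occurrence matrix is normalised to unit sum;
    the matrices are then averaged over offsets and the features computed
    once on the aggregate.
    """
    img = _as_volume(img)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        mask = np.broadcast_to(mask, img.shape).copy()
    q = quantize(img, mask, levels)
    mats = []
    for off in offsets:
        m = _glcm_matrix(q, levels, off)
        tot = m.sum()
        if tot > 0:
            mats.append(m / tot)
    if not mats:
        raise ValueError("mask admits no voxel pair along any offset")
    P = np.mean(mats, axis=0)

    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((P * (ii - jj) ** 2).sum())
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())
    if var > 0:
        correlation = float((P * (ii - mu) * (jj - mu)).sum() / var)
    else:
        correlation = 1.0  # constant image: perfectly self-correlated
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + (ii - jj) ** 2)).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return TextureFeatures(
        values={
            "glcm_contrast": contrast,
            "glcm_correlation": correlation,
            "glcm_energy": energy,
            "glcm_homogeneity": homogeneity,
            "glcm_entropy": entropy,
        },
        levels=levels,
        bin_edges=_bin_edges(img, mask, levels),
    )


def _runs_for_direction(q: np.ndarray, levels: int, direction) -> np.ndarray:
    """Run-length matrix R[level, length-1] for one direction.

    A run starts at a masked voxel whose predecessor along the direction is
    out of bounds, unmasked, or a different level; its length is the count of
    equal-level masked successors (index-array walking).
    """
    shape = q.shape
    d = np.asarray(direction)
    inside = q >= 0
    coords = np.argwhere(inside)
    if coords.size == 0:
        return np.zeros((levels, 1))

    def level_at(c):
        return q[c[:, 0], c[:, 1], c[:, 2]]

    def valid(c):
        return np.all((c >= 0) & (c < np.asarray(shape)), axis=1)

    prev = coords - d
    pv = valid(prev)
    same_prev = np.zeros(len(coords), dtype=bool)
    if pv.any():
        same_prev[pv] = level_at(prev[pv]) == level_at(coords[pv])
        # predecessor must also be masked; unmasked has level -1 so equality fails
    starts = coords[~same_prev]
    lengths = np.ones(len(starts), dtype=np.int64)
    frontier = starts.copy()
    active = np.arange(len(starts))
    base_level = level_at(starts)
    while active.size:
        nxt = frontier + d
        ok = valid(nxt)
        cont = np.zeros(len(nxt), dtype=bool)
        if ok.any():
            cont[ok] = level_at(nxt[ok]) == base_level[active][ok]
        lengths[active[cont]] += 1
        frontier = nxt[cont]
        active = active[cont]
    max_len = int(lengths.max()) if len(lengths) else 1
    R = np.zeros((levels, max_len))
    np.add.at(R, (base_level, lengths - 1), 1.0)
    return R


def glrlm_features(img, mask, levels: int = 64,
                   directions=DIRECTIONS_3D) -> TextureFeatures:
    """Run-length features computed per direction and averaged over directions.

    SRE/LRE weight runs by inverse/direct squared length; GLN and RLN measure
    gray-level and run-length non-uniformity; RP is runs per masked voxel.
    """
    img = _as_volume(img)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        mask = np.broadcast_to(mask, img.shape).copy()
    q = quantize(img, mask, levels)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty mask")
    feats = {name: [] for name in GLRLM_FEATURES}
    for d in directions:
        R = _runs_for_direction(q, levels, d)
        n_runs = R.sum()
        if n_runs == 0:
            continue
        lengths = np.arange(1, R.shape[1] + 1, dtype=float)
        rl = R.sum(axis=0)  # runs per length
        gl = R.sum(axis=1)  # runs per level
        feats["glrlm_sre"].append(float((rl / lengths**2).sum() / n_runs))
        feats["glrlm_lre"].append(float((rl * lengths**2).sum() / n_runs))
        feats["glrlm_gln"].append(float((gl**2).sum() / n_runs))
        feats["glrlm_rln"].append(float((rl**2).sum() / n_runs))
        feats["glrlm_rp"].append(float(n_runs / n_vox))
    if not feats["glrlm_rp"]:
        raise ValueError("mask admits no run along any direction")
    return TextureFeatures(
        values={k: float(np.mean(v)) for k, v in feats.items()},
        levels=levels,
        bin_edges=_bin_edges(img, mask, levels),
    )


def cohort_feature_correlation(
    pet_features: dict[str, TextureFeatures] | pd.DataFrame,
    dose_features: dict[str, TextureFeatures] | pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Across-subject Pearson r per named texture feature.

    Input maps subject id -> TextureFeatures (or a subjects x features frame).
    Returns a frame indexed by feature with columns r, p_value, n, family,
    defined; zero-variance features are flagged undefined and excluded from
    the per-family mean rows ('glcm_mean', 'glrlm_mean').
    """

    def to_frame(x):
        if isinstance(x, pd.DataFrame):
            return x.sort_index()
        return pd.DataFrame({k: v.values for k, v in x.items()}).T.sort_index()

    fa, fb = to_frame(pet_features), to_frame(dose_features)
    if list(fa.index) != list(fb.index):
        raise ValueError("mismatched subject sets between PET and dose features")
    if len(fa) < 3:
        raise ValueError("need at least 3 subjects")
    common = [c for c in fa.columns if c in fb.columns]
    if not common:
        raise ValueError("no matching feature names")
    rows = {}
    for feat in common:
        x, y = fa[feat].to_numpy(float), fb[feat].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows[feat] = dict(r=np.nan, p_value=np.nan, n=len(x),
                              family=feat.split("_")[0], defined=False)
            continue
        res = stats.pearsonr(x, y)
        rows[feat] = dict(r=float(res.statistic), p_value=float(res.pvalue),
                          n=len(x), family=feat.split("_")[0], defined=True)
    out = pd.DataFrame(rows).T
    for fam in ("glcm", "glrlm"):
        sub = out[(out["family"] == fam) & (out["defined"] == True)]  # noqa: E712
        if len(sub):
            out.loc[f"{fam}_mean"] = dict(
                r=float(sub["r"].mean()), p_value=np.nan, n=sub["n"].iloc[0],
                family=fam, defined=True,
            )
    return out
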