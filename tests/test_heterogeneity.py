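"""Voxel correlation and GLCM/GLRLM textures vs brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from theradose.heterogeneity import (
    DIRECTIONS_3D,
    cohort_feature_correlation,
    glcm_features,
    glrlm_features,
    quantize,
    voxel_pearson,
)


# --- independent brute-force oracles ---------------------------------------

def glcm_oracle(q, levels, offsets):
    """Naive voxel-pair enumeration, matrices averaged over offsets."""
    mats = []
    shape = q.shape
    for off in offsets:
        mat = np.zeros((levels, levels))
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if q[z, y, x] < 0:
                        continue
                    z2, y2, x2 = z + off[0], y + off[1], x + off[2]
                    if not (0 <= z2 < shape[0] and 0 <= y2 < shape[1]
                            and 0 <= x2 < shape[2]):
                        continue
                    if q[z2, y2, x2] < 0:
                        continue
                    mat[q[z, y, x], q[z2, y2, x2]] += 1
                    mat[q[z2, y2, x2], q[z, y, x]] += 1
        if mat.sum() > 0:
            mats.append(mat / mat.sum())
    P = np.mean(mats, axis=0)
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = (i * px).sum()
    var = (((i - mu) ** 2) * px).sum()
    nz = P[P > 0]
    return {
        "glcm_contrast": (P * (ii - jj) ** 2).sum(),
        "glcm_correlation": (P * (ii - mu) * (jj - mu)).sum() / var if var > 0 else 1.0,
        "glcm_energy": (P**2).sum(),
        "glcm_homogeneity": (P / (1 + (ii - jj) ** 2)).sum(),
        "glcm_entropy": -(nz * np.log2(nz)).sum(),
    }


def glrlm_oracle(q, levels, directions):
    """Naive run scanning: walk every start voxel along each direction."""
    n_vox = int((q >= 0).sum())
    feats = {k: [] for k in ("glrlm_sre", "glrlm_lre", "glrlm_gln",
                             "glrlm_rln", "glrlm_rp")}
    shape = q.shape

    def inb(c):
        return all(0 <= c[i] < shape[i] for i in range(3))

    for d in directions:
        runs = []
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    c = (z, y, x)
                    if q[c] < 0:
                        continue
                    prev = (z - d[0], y - d[1], x - d[2])
                    if inb(prev) and q[prev] == q[c]:
                        continue  # interior of a run
                    length = 1
                    nxt = (z + d[0], y + d[1], x + d[2])
                    while inb(nxt) and q[nxt] == q[c]:
                        length += 1
                        nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
                    runs.append((q[c], length))
        if not runs:
            continue
        n_runs = len(runs)
        gl = np.zeros(levels)
        maxlen = max(l for _, l in runs)
        rl = np.zeros(maxlen)
        sre = lre = 0.0
        for g, l in runs:
            gl[g] += 1
            rl[l - 1] += 1
            sre += 1.0 / l**2
            lre += float(l**2)
        feats["glrlm_sre"].append(sre / n_runs)
        feats["glrlm_lre"].append(lre / n_runs)
        feats["glrlm_gln"].append((gl**2).sum() / n_runs)
        feats["glrlm_rln"].append((rl**2).sum() / n_runs)
        feats["glrlm_rp"].append(n_runs / n_vox)
    return {k: float(np.mean(v)) for k, v in feats.items()}


class TestVoxelPearson:
    def test_perfect_correlation(self, rng):
        img = rng.normal(size=(6, 6, 6))
        mask = np.ones_like(img, dtype=bool)
        res = voxel_pearson(img, img, mask)
        assert res.r == pytest.approx(1.0)
        assert res.significant

    def test_affine_anticorrelation(self, rng):
        img = rng.normal(size=(5, 5, 5))
        mask = np.ones_like(img, dtype=bool)
        res = voxel_pearson(img, -img + 5.0, mask)
        assert res.r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        a = np.array([[[1.0, 2.0, 3.0]]])
        b = np.array([[[1.0, 2.0, 4.0]]])
        res = voxel_pearson(a, b, np.ones_like(a, dtype=bool))
        assert res.r == pytest.approx(0.98198, abs=1e-5)

    def test_affine_invariance(self, rng):
        a = rng.normal(size=(5, 5, 5))
        b = rng.normal(size=(5, 5, 5))
        mask = np.ones_like(a, dtype=bool)
        r0 = voxel_pearson(a, b, mask).r
        r1 = voxel_pearson(2.5 * a + 3.0, 0.7 * b - 1.0, mask).r
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_zero_variance_raises(self):
        a = np.ones((3, 3, 3))
        b = np.random.default_rng(0).normal(size=(3, 3, 3))
        with pytest.raises(ValueError, match="zero variance"):
            voxel_pearson(a, b, np.ones_like(a, dtype=bool))

    def test_mask_too_small(self):
        a = np.ones((3, 3, 3))
        mask = np.zeros_like(a, dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="at least 3"):
            voxel_pearson(a, a, mask)


class TestGLCM:
    def test_constant_image(self):
        img = np.full((4, 4, 4), 7.0)
        f = glcm_features(img, np.ones_like(img, dtype=bool), levels=8)
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_energy"] == pytest.approx(1.0)
        assert f["glcm_homogeneity"] == pytest.approx(1.0)

    def test_two_by_two_hand_enumeration(self):
        """[[0,0],[1,1]] with a horizontal offset: P(0,0)=P(1,1)=0.5."""
        img = np.array([[0.0, 0.0], [1.0, 1.0]])[None]
        mask = np.ones_like(img, dtype=bool)
        f = glcm_features(img, mask, levels=2, offsets=[(0, 0, 1)])
        assert f["glcm_contrast"] == pytest.approx(0.0)
        assert f["glcm_energy"] == pytest.approx(0.5)

    def test_matches_bruteforce_on_random_patches(self, rng):
        for _ in range(3):
            img = rng.uniform(0, 10, size=(8, 8, 8))
            mask = rng.uniform(size=img.shape) > 0.25
            mask[:2] = True  # ensure enough voxels
            levels = 6
            f = glcm_features(img, mask, levels=levels)
            q = quantize(img, mask, levels)
            ref = glcm_oracle(q, levels, DIRECTIONS_3D)
            for name, val in ref.items():
                assert f[name] == pytest.approx(val, rel=1e-12), name

    def test_feature_ranges(self, rng):
        img = rng.uniform(size=(6, 6, 6))
        f = glcm_features(img, np.ones_like(img, dtype=bool), levels=4)
        assert 0 < f["glcm_energy"] <= 1
        assert 0 < f["glcm_homogeneity"] <= 1


class TestGLRLM:
    def test_single_row_hand_enumeration(self):
        """Row (1,1,2): runs {(1,2),(2,1)}; RP = 2/3, SRE = 0.625."""
        img = np.array([1.0, 1.0, 2.0])[None, None]
        mask = np.ones_like(img, dtype=bool)
        f = glrlm_features(img, mask, levels=2, directions=[(0, 0, 1)])
        assert f["glrlm_rp"] == pytest.approx(2.0 / 3.0)
        assert f["glrlm_sre"] == pytest.approx(0.625)

    def test_constant_row_single_run(self):
        n = 7
        img = np.full((1, 1, n), 3.0)
        f = glrlm_features(img, np.ones_like(img, dtype=bool), levels=2,
                           directions=[(0, 0, 1)])
        assert f["glrlm_rp"] == pytest.approx(1.0 / n)
        assert f["glrlm_lre"] == pytest.approx(n**2)

    def test_matches_bruteforce_on_random_patches(self, rng):
        for _ in range(3):
            img = rng.integers(0, 4, size=(8, 8, 8)).astype(float)
            mask = rng.uniform(size=img.shape) > 0.2
            mask[:2] = True
            levels = 4
            f = glrlm_features(img, mask, levels=levels)
            q = quantize(img, mask, levels)
            ref = glrlm_oracle(q, levels, DIRECTIONS_3D)
            for name, val in ref.items():
                assert f[name] == pytest.approx(val, rel=1e-12), name

    def test_runs_broken_at_mask_boundary(self):
        img = np.full((1, 1, 5), 2.0)
        mask = np.array([[[True, True, False, True, True]]])
        f = glrlm_features(img, mask, levels=2, directions=[(0, 0, 1)])
        # two runs of length 2 among 4 masked voxels
        assert f["glrlm_rp"] == pytest.approx(0.5)
        assert f["glrlm_lre"] == pytest.approx(4.0)


class TestCohortCorrelation:
    def _frames(self, n=4):
        rng = np.random.default_rng(0)
        pet = pd.DataFrame(
            {"glcm_contrast": rng.uniform(1, 2, n),
             "glrlm_sre": rng.uniform(0.3, 0.9, n)},
            index=[f"s{i}" for i in range(n)],
        )
        return pet

    def test_identical_features_give_unit_r(self):
        pet = self._frames()
        out = cohort_feature_correlation(pet, pet.copy())
        assert out.loc["glcm_contrast", "r"] == pytest.approx(1.0)
        assert out.loc["glcm_mean", "r"] == pytest.approx(1.0)
        assert out.loc["glrlm_mean", "r"] == pytest.approx(1.0)

    def test_constant_feature_flagged_undefined(self):
        pet = self._frames()
        dose = pet.copy()
        dose["glcm_contrast"] = 1.0
        out = cohort_feature_correlation(pet, dose)
        assert not out.loc["glcm_contrast", "defined"]
        assert "glcm_mean" not in out.index  # only undefined glcm feature
        assert out.loc["glrlm_mean", "r"] == pytest.approx(1.0)

    def test_linear_plus_vanishing_noise(self):
        pet = self._frames(5)
        dose = 2.0 * pet + 1e-12
        out = cohort_feature_correlation(pet, dose)
        assert out.loc["glcm_contrast", "r"] == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_subjects_rejected(self):
        pet = self._frames()
        dose = pet.copy()
        dose.index = ["x" + s for s in dose.index]
        with pytest.raises(ValueError, match="[Mm]ismatch"):
            cohort_feature_correlation(pet, dose)
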