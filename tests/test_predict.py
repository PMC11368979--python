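"""Organ-dose projection, patch extraction, and the learned dose predictor."""

import numpy as np
import pytest

from theradose.dosimetry import DoseMap, SUVImage
from theradose.evaluate import nrmse, organ_mape
from theradose.experiment import default_scenario, simulate_suv_and_dose
from theradose.phantom import generate_phantom
from theradose.predict import (
    DosePredictor,
    OrganDoseInput,
    PredictorConfig,
    extract_patches,
    organ_dose_projection,
    predict_dose_map,
    train_dose_predictor,
)


class TestOrganDoseProjection:
    def test_uniform_pet(self):
        pet = np.ones((4, 4, 4))
        mask = np.zeros_like(pet, bool)
        mask[1:3, 1:3, 1:3] = True
        dmap = organ_dose_projection(pet, mask, OrganDoseInput("m", 2.0))
        np.testing.assert_allclose(dmap.values[mask], 2.0)
        np.testing.assert_array_equal(dmap.values[~mask], 0.0)

    def test_scale_invariance(self, rng):
        pet = rng.uniform(0.1, 5, (4, 4, 4))
        mask = rng.uniform(size=pet.shape) > 0.4
        od = OrganDoseInput("m", 3.0)
        a = organ_dose_projection(pet, mask, od).values
        b = organ_dose_projection(17.3 * pet, mask, od).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_hand_arithmetic(self):
        pet = np.array([1.0, 2.0, 3.0])[None, None]
        mask = np.ones_like(pet, bool)
        dmap = organ_dose_projection(pet, mask, OrganDoseInput("m", 2.0))
        np.testing.assert_allclose(dmap.values[0, 0], [1.0, 2.0, 3.0])
        assert dmap.values[mask].mean() == pytest.approx(2.0)

    def test_mean_preservation_is_exact(self, rng):
        """Theoretical-optimal mode has organ MAPE 0 by construction."""
        pet = rng.uniform(0.5, 4, (6, 6, 6))
        gt = rng.uniform(1, 9, (6, 6, 6))
        mask = rng.uniform(size=pet.shape) > 0.3
        od = OrganDoseInput.theoretical_optimal(gt, mask)
        dmap = organ_dose_projection(pet, mask, od)
        assert organ_mape(dmap.values, gt, mask) == pytest.approx(0.0, abs=1e-9)

    def test_zero_pet_rejected(self):
        pet = np.zeros((3, 3, 3))
        with pytest.raises(ValueError, match="zero"):
            organ_dose_projection(pet, np.ones_like(pet, bool),
                                  OrganDoseInput("m", 1.0))


class TestExtractPatches:
    def test_non_overlapping_count(self, rng):
        vol = rng.uniform(size=(64, 64, 64))
        ps = extract_patches(vol, 32, 32)
        assert len(ps) == 8

    def test_half_stride_count(self, rng):
        vol = rng.uniform(size=(64, 64, 64))
        ps = extract_patches(vol, 32, 16)
        assert len(ps) == 27

    def test_end_alignment(self, rng):
        """A stride that does not divide evenly adds an end-aligned origin."""
        vol = rng.uniform(size=(20, 20, 20))
        ps = extract_patches(vol, 8, 5)
        axis = sorted(set(ps.origins[:, 0]))
        assert axis == [0, 5, 10, 12]

    def test_empty_mask_gives_empty_set(self, rng):
        vol = rng.uniform(size=(16, 16, 16))
        ps = extract_patches(vol, 8, 8, mask=np.zeros_like(vol, bool))
        assert len(ps) == 0

    def test_patch_content_matches_volume(self, rng):
        vol = rng.uniform(size=(16, 16, 16))
        ps = extract_patches(vol, 8, 8)
        for patch, (z, y, x) in zip(ps.patches, ps.origins):
            np.testing.assert_array_equal(patch, vol[z:z + 8, y:y + 8, x:x + 8])

    def test_oversized_patch_rejected(self, rng):
        with pytest.raises(ValueError, match="patch_size"):
            extract_patches(rng.uniform(size=(8, 8, 8)), 16, 8)


def _cases(scenario_name, seeds, grid=(32, 32, 32)):
    scn = default_scenario(scenario_name, grid)
    out = []
    for s in seeds:
        ph = generate_phantom(scn.phantom_config(), s)
        suv, dose, _ = simulate_suv_and_dose(ph, scn)
        out.append((ph, suv, dose))
    return out


class TestDosePredictor:
    def test_requires_two_phantoms(self):
        with pytest.raises(ValueError, match="at least 2"):
            DosePredictor().fit([(np.ones((16,) * 3), np.ones((16,) * 3),
                                  np.ones((16,) * 3, bool))])

    def test_training_is_seed_deterministic(self):
        (ph, suv, dose), = _cases("homogeneous", [0])
        pairs = [(suv, dose, ph.organ_mask)] * 2
        cfg = PredictorConfig(seed=3, epochs=2)
        m1 = DosePredictor(cfg).fit(pairs)
        m2 = DosePredictor(cfg).fit(pairs)
        assert m1.final_loss_ == m2.final_loss_
        for a, b in zip(m1.net_.params, m2.net_.params):
            np.testing.assert_array_equal(a, b)
        p1 = m1.predict(suv, ph.organ_mask).values
        p2 = m2.predict(suv, ph.organ_mask).values
        np.testing.assert_array_equal(p1, p2)

    def test_overfit_profile_beats_projection(self):
        """Trained and evaluated on one phantom, the learned predictor's
        masked NRMSE falls below the theoretical-optimal projection's."""
        (ph, suv, dose), = _cases("homogeneous", [0])
        mask = ph.organ_mask
        model = DosePredictor(PredictorConfig(seed=0)).fit(
            [(suv, dose, mask)] * 2
        )
        learned = model.predict(suv, mask)
        proj = organ_dose_projection(
            suv, mask, OrganDoseInput.theoretical_optimal(dose.values, mask)
        )
        n_learned = nrmse(learned.values, dose.values, mask)
        n_proj = nrmse(proj.values, dose.values, mask)
        assert n_learned < n_proj

    def test_zero_pet_gives_zero_prediction(self):
        (ph, suv, dose), = _cases("homogeneous", [0])
        mask = ph.organ_mask
        model = DosePredictor(PredictorConfig(seed=0, epochs=2)).fit(
            [(suv, dose, mask)] * 2
        )
        pred = model.predict(np.zeros_like(suv.values), mask)
        np.testing.assert_array_equal(pred.values, 0.0)

    def test_overlap_averaging_consistency(self, rng):
        """With a zero-correction net, overlapping patch predictions agree on
        every overlap, so averaged stitching reproduces the scaled input for
        any stride (and stride = patch_size is exact tiling)."""

        class ZeroNet:
            def forward(self, x, want_cache=False):
                return np.zeros_like(x)

        vol = rng.uniform(0.5, 3.0, (32, 32, 32))
        for stride in (16, 8, 5):
            model = DosePredictor(PredictorConfig(stride=stride))
            model.net_ = ZeroNet()
            model.suv_ref_, model.dose_ref_ = 2.0, 6.0
            out = model.predict(vol)
            np.testing.assert_allclose(out.values, vol * 3.0, rtol=1e-12)

    def test_functional_wrappers(self):
        (ph, suv, dose), = _cases("homogeneous", [0])
        model = train_dose_predictor([(suv, dose, ph.organ_mask)] * 2,
                                     PredictorConfig(seed=1, epochs=2))
        dmap = predict_dose_map(model, suv, ph.organ_mask)
        assert isinstance(dmap, DoseMap)
        assert dmap.values.shape == suv.values.shape
        assert np.all(dmap.values >= 0)

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            DosePredictor().predict(np.zeros((16,) * 3))

    def test_adversarial_profile_runs_and_is_seeded(self):
        (ph, suv, dose), = _cases("homogeneous", [0])
        pairs = [(suv, dose, ph.organ_mask)] * 2
        cfg = PredictorConfig(seed=5, epochs=2, lambda_adv=0.01)
        l1 = DosePredictor(cfg).fit(pairs).final_loss_
        l2 = DosePredictor(cfg).fit(pairs).final_loss_
        assert np.isfinite(l1)
        assert l1 == l2

    def test_get_set_params_roundtrip(self):
        m = DosePredictor(PredictorConfig(epochs=7))
        params = m.get_params()
        assert params["epochs"] == 7
        m.set_params(epochs=9, channels=4)
        assert m.config.epochs == 9 and m.config.channels == 4
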