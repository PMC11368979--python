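"""Pre-therapy voxel dose-map prediction.

Two strategies are implemented:

1. **Organ-dose-guided direct projection** — the PET image is rescaled inside
   the organ mask so that its mask mean equals a supplied organ dose (either
   an external prediction or, in "theoretical optimal" mode, the ground-truth
   organ mean); the spatial dose pattern is the PET pattern itself.

2. **Patch-based learned predictor** — a compact 3-D convolutional network
   (numpy, see :mod:`theradose._nn`) trained on (PET patch -> dose patch)
   pairs with a voxel mean-squared reconstruction loss and, optionally, a
   small adversarial term from a patch discriminator.  Intensities are
   normalised by fixed per-model reference values (division), so zero input
   maps to zero output and volumes remain comparable across phantoms.

The learned predictor follows the familiar fit/predict estimator idiom.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from ._nn import Adam, ConvNet3D, PatchDiscriminator
from .dosimetry import DoseMap, SUVImage

__all__ = [
    "OrganDoseInput",
    "PatchSet",
    "PredictorConfig",
    "DosePredictor",
    "organ_dose_projection",
    "extract_patches",
    "train_dose_predictor",
    "predict_dose_map",
]


@dataclass(frozen=True)
class OrganDoseInput:
    """Mean absorbed organ dose (mGy) driving the projection approach."""

    mask_id: str
    mean_dose_mgy: float
    source: str = "external"  # or "theoretical_optimal"

    def __post_init__(self) -> None:
        if self.mean_dose_mgy < 0:
            raise ValueError("organ mean dose must be >= 0")

    @staticmethod
    def theoretical_optimal(dose, mask, mask_id: str = "organ") -> "OrganDoseInput":
        """Ground-truth-mean mode: the upper bound of the projection approach."""
        dose = np.asarray(dose, dtype=float)
        mask = np.asarray(mask).astype(bool)
        return OrganDoseInput(mask_id, float(dose[mask].mean()), "theoretical_optimal")


def _pet_array(pet) -> np.ndarray:
    if isinstance(pet, SUVImage):
        return pet.values
    return np.asarray(pet, dtype=float)


def organ_dose_projection(pet, mask, organ_dose: OrganDoseInput,
                          s_value: float = float("nan")) -> DoseMap:
    """Rescale the PET pattern so its mask mean equals the organ dose.

    D(v) = PET(v) * organ_dose * N / sum_mask(PET) inside the mask, 0 outside;
    the mask mean of the output equals ``organ_dose.mean_dose_mgy`` exactly,
    and the result is invariant to any positive rescaling of the PET image.
    """
    vals = _pet_array(pet)
    mask = np.asarray(mask).astype(bool)
    total = float(vals[mask].sum())
    if total <= 0:
        raise ValueError("projection scale undefined: PET sums to zero in the mask")
    out = np.zeros_like(vals, dtype=float)
    out[mask] = vals[mask] * (organ_dose.mean_dose_mgy * mask.sum() / total)
    return DoseMap(values=out, s_value=s_value)


@dataclass
class PatchSet:
    """Fixed-size cubic patches plus their origin indices in the volume."""

    patches: np.ndarray  # (N, ps, ps, ps)
    origins: np.ndarray  # (N, 3)
    volume_shape: tuple[int, int, int]
    patch_size: int
    stride: int

    def __len__(self) -> int:
        return len(self.patches)


def _origin_axis(dim: int, ps: int, stride: int) -> np.ndarray:
    starts = list(range(0, dim - ps + 1, stride))
    if starts[-1] != dim - ps:
        starts.append(dim - ps)
    return np.asarray(starts)


def extract_patches(volume, patch_size: int, stride: int, mask=None) -> PatchSet:
    """Regular-grid cubic patches clipped to fit, filtered to mask overlap.

    Origins advance by ``stride`` per axis with an end-aligned origin added
    when the grid does not land exactly; only patches intersecting the mask
    are kept (all patches if mask is None).  Ordering is deterministic
    (z-major origin order).
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D volume")
    ps = int(patch_size)
    if any(ps > d for d in volume.shape):
        raise ValueError("patch_size exceeds a volume dimension")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    axes = [_origin_axis(d, ps, stride) for d in volume.shape]
    patches, origins = [], []
    m = None if mask is None else np.asarray(mask).astype(bool)
    for z in axes[0]:
        for y in axes[1]:
            for x in axes[2]:
                if m is not None and not m[z : z + ps, y : y + ps, x : x + ps].any():
                    continue
                patches.append(volume[z : z + ps, y : y + ps, x : x + ps])
                origins.append((z, y, x))
    if patches:
        parr = np.stack(patches)
        oarr = np.asarray(origins)
    else:
        parr = np.empty((0, ps, ps, ps))
        oarr = np.empty((0, 3), dtype=int)
    return PatchSet(parr, oarr, volume.shape, ps, int(stride))


@dataclass(frozen=True)
class PredictorConfig:
    """Desk-scale training profile for the learned predictor.

    ``lambda_adv`` = 0 keeps training fully deterministic (pure
    reconstruction loss); > 0 enables the adversarial profile.
    ``suv_ref`` / ``dose_ref`` default to the training-set masked means.
    """

    patch_size: int = 16
    stride: int = 8
    channels: int = 8
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 3e-3
    lambda_adv: float = 0.0
    seed: int = 0
    suv_ref: float | None = None
    dose_ref: float | None = None


class DosePredictor:
    """Patch-based learned SUV-to-dose voxel predictor (fit/predict API).

    Fitted attributes (set by :meth:`fit`): ``net_``, ``suv_ref_``,
    ``dose_ref_``, ``loss_history_``, ``final_loss_``.
    """

    def __init__(self, config: PredictorConfig | None = None, **overrides):
        cfg = config or PredictorConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        self.config = cfg

    # -- sklearn-style parameter plumbing -----------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return asdict(self.config)

    def set_params(self, **params) -> "DosePredictor":
        self.config = replace(self.config, **params)
        return self

    # ------------------------------------------------------------------------
    def fit(self, pairs: list[tuple]) -> "DosePredictor":
        """Train on [(pet, dose, mask), ...] volume triples.

        pet/dose may be SUVImage/DoseMap or plain arrays.  Raises on fewer
        than 2 training phantoms or a non-finite loss.
        """
        if len(pairs) < 2:
            raise ValueError("need at least 2 training phantoms")
        cfg = self.config
        triples = [
            (_pet_array(p), np.asarray(getattr(d, "values", d), dtype=float),
             np.asarray(m).astype(bool))
            for p, d, m in pairs
        ]
        suv_ref = cfg.suv_ref
        dose_ref = cfg.dose_ref
        if suv_ref is None:
            suv_ref = float(np.mean([p[m].mean() for p, _, m in triples]))
        if dose_ref is None:
            dose_ref = float(np.mean([d[m].mean() for _, d, m in triples]))
        if suv_ref <= 0 or dose_ref <= 0:
            raise ValueError("normalisation references must be positive")

        xs, ys = [], []
        for p, d, m in triples:
            px = extract_patches(p / suv_ref, cfg.patch_size, cfg.stride, m)
            py = extract_patches(d / dose_ref, cfg.patch_size, cfg.stride, m)
            xs.append(px.patches)
            ys.append(py.patches)
        X = np.concatenate(xs)[:, None]  # (N,1,ps,ps,ps)
        Y = np.concatenate(ys)[:, None]
        if len(X) == 0:
            raise ValueError("no training patches intersect the masks")

        rng = np.random.default_rng(cfg.seed)
        net = ConvNet3D(channels=cfg.channels, rng=rng)
        opt = Adam(net.params, lr=cfg.learning_rate)
        zero_patch = np.zeros((1, 1, cfg.patch_size, cfg.patch_size, cfg.patch_size))
        disc = d_opt = None
        if cfg.lambda_adv > 0:
            disc = PatchDiscriminator(rng=rng)
            d_opt = Adam(disc.params, lr=cfg.learning_rate)

        losses = []
        n = len(X)
        for epoch in range(cfg.epochs):
            # step-decay anneal: x0.1 at 70 % and again at 90 % of training
            opt.lr = cfg.learning_rate * (
                0.1 ** ((epoch >= 0.7 * cfg.epochs) + (epoch >= 0.9 * cfg.epochs))
            )
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X[idx], Y[idx]
                # zero-anchored residual: pred = x + f(x) - f(0), so the
                # identity map is the starting point and 0 maps to 0 exactly
                raw, cache = net.forward(xb, want_cache=True)
                anchor, cache0 = net.forward(zero_patch, want_cache=True)
                pred = xb + raw - anchor
                resid = pred - yb
                loss = float(np.mean(resid**2))
                dpred = 2.0 * resid / resid.size
                if disc is not None:
                    # non-saturating generator term: -log sigmoid(D(pred))
                    logit, dcache = disc.forward(pred, want_cache=True)
                    sig = 1.0 / (1.0 + np.exp(-logit))
                    loss += cfg.lambda_adv * float(np.mean(-np.log(sig + 1e-12)))
                    _, _, dx_adv = disc.backward(dcache, (sig - 1.0) / len(logit))
                    dpred = dpred + cfg.lambda_adv * dx_adv
                    # discriminator update on real vs generated patches
                    logit_r, cr = disc.forward(yb, want_cache=True)
                    logit_f, cf = disc.forward(pred, want_cache=True)
                    sr = 1.0 / (1.0 + np.exp(-logit_r))
                    sf = 1.0 / (1.0 + np.exp(-logit_f))
                    gr, gbr, _ = disc.backward(cr, (sr - 1.0) / len(logit_r))
                    gf, gbf, _ = disc.backward(cf, sf / len(logit_f))
                    d_opt.step([a + b for a, b in zip(gr, gf)])
                    disc.bl -= d_opt.lr * (gbr + gbf)
                grads, _ = net.backward(cache, dpred)
                grads0, _ = net.backward(cache0, -dpred.sum(axis=0, keepdims=True))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss {loss}; lower the learning rate"
                    )
                opt.step([g + g0 for g, g0 in zip(grads, grads0)])
                epoch_loss += loss * len(idx)
            losses.append(epoch_loss / n)

        self.net_ = net
        self.suv_ref_ = suv_ref
        self.dose_ref_ = dose_ref
        self.loss_history_ = losses
        self.final_loss_ = losses[-1]
        return self

    def predict(self, pet, mask=None) -> DoseMap:
        """Whole-volume inference by averaging overlapping patch predictions.

        Voxels covered by no retained patch are 0; output is clipped at 0.
        """
        if not hasattr(self, "net_"):
            raise RuntimeError("predictor is not fitted")
        cfg = self.config
        vals = _pet_array(pet) / self.suv_ref_
        if vals.ndim != 3:
            raise ValueError("expected a 3-D PET volume")
        if any(cfg.patch_size > d for d in vals.shape):
            raise ValueError("volume smaller than the training patch size")
        pset = extract_patches(vals, cfg.patch_size, cfg.stride, mask)
        acc = np.zeros(vals.shape)
        cnt = np.zeros(vals.shape)
        if len(pset):
            ps_ = cfg.patch_size
            anchor = self.net_.forward(np.zeros((1, 1, ps_, ps_, ps_)))
            preds = (pset.patches[:, None]
                     + self.net_.forward(pset.patches[:, None]) - anchor)[:, 0]
            ps = cfg.patch_size
            for patch, (z, y, x) in zip(preds, pset.origins):
                acc[z : z + ps, y : y + ps, x : x + ps] += patch
                cnt[z : z + ps, y : y + ps, x : x + ps] += 1.0
        covered = cnt > 0
        acc[covered] /= cnt[covered]
        out = np.clip(acc * self.dose_ref_, 0.0, None)
        return DoseMap(values=out, s_value=float("nan"))


def train_dose_predictor(pairs: list[tuple],
                         config: PredictorConfig | None = None) -> DosePredictor:
    """Functional wrapper: fit a :class:`DosePredictor` on volume triples."""
    return DosePredictor(config).fit(pairs)


def predict_dose_map(model: DosePredictor, pet, mask=None) -> DoseMap:
    """Functional wrapper over :meth:`DosePredictor.predict`."""
    return model.predict(pet, mask)
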