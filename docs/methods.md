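# Methods

## Model

Each voxel's activity concentration follows the standard two-tissue
compartment model (2TCM). The plasma concentration Cp(t) feeds a free
compartment at rate k1 (mL·min⁻¹·cm⁻³), which clears back to plasma at k2
(min⁻¹) and exchanges with a bound compartment at k3/k4 (min⁻¹); a fraction
Vb of the voxel is blood. The tissue impulse response is biexponential with
eigenrates α₁,₂ = ½[(k2+k3+k4) ∓ √((k2+k3+k4)² − 4k2k4)]; the repeated-root
case is handled by the analytic (c₀ + c₁t)e^{−αt} limit form, not by
perturbation. The measured curve is

    C(t) = e^{−λ_phys t} · [(1−Vb)(h ⊛ Cp)(t) + Vb·Cp(t)],

with rate constants interpreted as decay-corrected kinetics and physical
decay applied as an explicit factor (Ga-68 half-life 67.71 min; Lu-177
6.647 d).

All convolutions are evaluated in closed form. With b = α − λ and x = bt,
the four needed kernels reduce to combinations of e^{−αt} and e^{−λt} with
polynomial prefactors divided by powers of b; every exponent is nonpositive
(no overflow at day-scale times) and the α → λ cancellation is bridged by
Taylor series of the scaled kernels below |x| < 0.05. The closed forms agree
with stiff ODE integration (Radau, rtol 1e-10) to better than 1e-6 relative
over 100 random parameter draws — this dual route (analytic vs ODE) is kept
as a permanent test.

### Arterial input functions

The model is driven by a Feng-type triexponential input
Cp(t) = (A1·t − A2 − A3)e^{−λ1t} + A2e^{−λ2t} + A3e^{−λ3t}, which starts at
zero by construction. Separate default coefficient sets are provided for the
PET session (fast bolus, eigenrates 4.0/0.12/0.012 min⁻¹, amplitudes scaled
so organ SUV lands near 5–10) and for the therapy compound (clearance
half-times ≈ 1 h and ≈ 19 h, amplitudes consistent with ~GBq administration
into a blood-like distribution volume). Both are config-overridable; no
claim is made that they match any individual patient.

## Phantoms

A phantom is one or more ellipsoidal organs on a 3-D grid (default 128-like
64³ for experiments, 4 mm isotropic voxels), each split into a cortex-like
rim (sub-tissue 1, normalized ellipsoidal radius ρ ∈ [0.8, 1]) and a core
(sub-tissue 2). Tracer parameters per voxel are

    kpᵢ(v) = meanᵢ(sub-tissue) × g(v) × εᵢ(v),

where g varies linearly from 1+A at the organ boundary to 1−A at the centre
(one common factor for all five parameters; default amplitude A = 0.3), and
εᵢ are independent multiplicative truncated-normal factors (mean 1, CV =
`noise_cv`, truncated below at 0.01) so positivity is structural rather than
clipped. Therapy parameters follow from per-sub-tissue ratio vectors
ρᵢⱼ = kpᵢⱼ/ktᵢⱼ; identical vectors in both sub-tissues define the
homogeneous pharmacokinetic linkage. Generation is a pure function of
(config, seed) via `numpy.random.default_rng`.

### Default kinetic means

Printed per-patient kinetic values are not available for this tracer class,
so the defaults are documented config values: rim (0.6, 0.3, 0.08, 0.0,
0.10), core 0.7 × rim. **k4 defaults to 0** (effectively irreversible
binding). This is deliberate and load-bearing: PSMA ligands internalise, and
if k4 were large compared with the Lu-177 decay constant (7.2e-5 min⁻¹) the
time-integrated activity would approach the washout equilibrium
k1(k3+k4)/(k2k4)·∫Cp — a quantity invariant under a common scaling of all
rate constants — and the absorbed dose would decouple from delivery
entirely. With k4 ≈ 0 the dose is governed by the trapping flux
k1k3/(k2+k3), which scales with local uptake, reproducing the observed
coupling between PET uptake and dose.

## Dosimetry

Voxel time-integrated activity is the trapezoidal integral of the therapy
TAC over a log-spaced 14-day grid (221 points) plus an analytic tail
A(T)/λ_eff, where λ_eff comes from a log-linear fit over the samples in the
final decade of the time axis and is floored at λ_phys; curves whose last
two samples are not positive get a zero tail. Absorbed dose is the
local-deposition product dose = TIA × S with one organ-level S-value
(default 2.2e-4 mGy/MBq/s, kidney cortex, ICRP-110-derived); kernel
convolution and Monte Carlo transport are out of scope. Because a
whole-organ S-value is applied to per-voxel TIA, absolute dose values are
on an arbitrary-but-consistent scale; every downstream metric (Pearson r,
NRMSE, SSIM, MAPE, DVH R², identity slope) is scale-aware or scale-free.
SUV is conc[Bq/mL]·weight[g]/injected[Bq], evaluated at a single default
time point t = 60 min.

## Frozen scenarios

Three scenario configurations are tuned once, frozen, and documented here;
experiments never adjust them.

- **homogeneous** — rim and core tracer means on a common ray (core = 0.7 ×
  rim), one shared ratio vector (1.5, 1.2, 1.5, 1.2, 1.0), gradient 0.3,
  noise CV 0.02. SUV and dose stay on a single monotone branch; global
  voxel r ≈ 0.9999.
- **two_cluster** — tracer side as above; ratio vectors identity (rim) vs
  (3, ⅓, 3, ⅓, 1) (core), i.e. inverted k-ratios. Each sub-tissue stays
  internally coherent (r ≈ 0.998) while the joint scatter splits into two
  disjoint dose bands; global r ≈ 0.975.
- **strong_heterogeneity** — core tracer means equal to rim except 5 %
  higher k1 and k3, noise CV 0.10, core ratio vector (5, 0.2, 5, 0.2, 1).
  The two sub-tissues' SUV distributions overlap while their doses diverge
  by two orders of magnitude, so the pooled correlation collapses
  (global r ≈ 0.29) even though each sub-tissue alone keeps r ≈ 0.99. The
  5 % offset is the calibrated, frozen value that places the pooled r in
  the weak-positive regime.

## Dose-map prediction

**Organ-dose projection** rescales the PET pattern inside the organ mask so
its mean equals a supplied organ dose; the "theoretical optimal" mode uses
the ground-truth organ mean and therefore has organ MAPE 0 by construction.
It is exact when dose ∝ SUV and structurally unable to represent
sub-tissue-dependent SUV→dose relations.

**Learned predictor** is a patch-based 3-D convolutional network written in
numpy with manual backprop (three 3×3×3 conv layers, leaky-ReLU 0.1,
8 channels, receptive field 7³), trained with Adam (lr 3e-3, ×0.1 step
decay at 70 % and 90 % of epochs, 30 epochs, batch 16) on 16³ patches with
stride 8 and a voxel MSE loss. Design choices that proved load-bearing:

- *Zero-anchored residual output*: the prediction is x + f(x) − f(0).
  Training starts from the identity map (the output conv layer is
  zero-initialised), and zero input maps to exactly zero output regardless
  of trained biases.
- *Normalisation by fixed per-model references* (training-set masked means
  of SUV and dose, division only) keeps intensities comparable across
  phantoms and preserves zeros.
- *Leaky ReLU*: with plain ReLU the second layer's units die under Adam on
  these small patch sets and the model collapses to the identity map.
- An optional adversarial term (tiny patch discriminator, non-saturating
  generator loss, weight `lambda_adv`) is off by default so the default
  profile is fully deterministic.

Inference tiles the volume with the training stride, averages overlapping
patch predictions per voxel (unweighted), zeroes uncovered voxels, and
clips at 0. Patches are retained only where they intersect the organ mask.

On the two-cluster scenario (six 32³ test phantoms, three training
phantoms) the learned predictor reaches roughly a third of the projection's
masked NRMSE with SSIM ≈ 0.92 vs ≈ 0.55 — the qualitative ordering the
method is designed to demonstrate. A per-voxel isotonic regression of dose
on SUV fitted to the evaluation phantom itself remains a few-fold better
than the network on homogeneous phantoms (≈ 0.24 % vs ≈ 1.3 % NRMSE): that
oracle sees the test answers and has no spatial-discontinuity burden at the
organ boundary, so it bounds, rather than measures, desk-scale performance.

## Evaluation suite

NRMSE is normalised by the ground-truth range within the evaluation region
(mean normalisation available). SSIM uses a uniform 7³ window, sample
(N−1) covariance, stabilisers K1 = 0.01 / K2 = 0.03 on the ground-truth
range, and averages the local map over the border-cropped interior (or a
mask within it); it matches the standard reference implementation to 1e-6.
DVHs are cumulative V(d) = fraction of masked voxels ≥ d on 200 even bins,
extending 2 % past the maximum so the curve completes its drop; curves to
be compared are sampled on one common grid before R². Identity fits are
unconstrained OLS of predicted on true voxel values. Metric comparisons use
the two-sided paired Wilcoxon signed-rank test (α = 0.05 for NRMSE
comparisons, 0.025 for correlation analyses); identical paired samples
return p = 1 with a flag. Because the two-sided exact test cannot reach
p < 0.05 with four pairs, the default benchmark uses six test phantoms.

## Texture features

Images are quantised to equal-width bins (default 64 levels) over the
masked min–max range. GLCMs are accumulated symmetrically for the 13 unique
3-D unit offsets, each normalised, then averaged over offsets before the
Haralick features (contrast, correlation, energy, homogeneity, entropy) are
computed on the aggregate matrix. GLRLMs are built per direction with runs
broken at mask boundaries; SRE, LRE, GLN, RLN and RP are averaged across
directions. Both implementations are checked against naive voxel-pair /
run-walking enumeration on small volumes.

## What the synthetic data does and does not show

The phantom generator emulates the *structure* of the clinical setting —
two sub-tissues with distinct kinetics, radial parameter gradients,
voxel-level parameter noise, a single pre-therapy PET time point, multi-day
therapy dosimetry — but not PET/SPECT image formation (no PSF, no Poisson
counts, no reconstruction artifacts), not patient motion or registration
error, and not inter-patient anatomical variability. Passing results
demonstrate that the pipeline's statistical machinery behaves as designed
under controlled pharmacokinetic linkage, and that heterogeneous linkage is
sufficient to break voxel-wise PET–dose correlation; they do not establish
clinical prediction accuracy, which requires real cohorts.

## Numerical choices and degenerate inputs

- Kinetics: series/direct switch at |x| = 0.05; degenerate eigenrates below
  a 1e-9 relative gap use the limit form. Non-clearing tissue
  (k2+k3+k4 = 0 with k1 > 0) is rejected.
- TIA: non-monotone grids and growing tails are errors; all-zero curves
  integrate to 0.
- Pearson with zero variance, NRMSE with zero ground-truth range, DVH R²
  with a constant reference, and empty masks raise instead of returning
  NaN.
- Problem sizes: experiments default to 64³ grids (~28k organ voxels);
  tests and the prediction benchmark use 32³ as the package's desk-scale
  profile. One full scenario run takes a few seconds; the benchmark
  (training + evaluation) a couple of minutes on one CPU.

## Known limitations

- The learned predictor is intentionally small; it demonstrates the
  ordering against organ projection, not a performance ceiling.
- Local-deposition dosimetry ignores cross-voxel energy transport; organ
  S-values applied per voxel make absolute dose scale conventional.
- The input functions and kinetic means are documented defaults, not fits
  to data; conclusions are about linkage structure, not parameter values.
- Single-organ scenarios are the default; multi-organ phantoms are
  supported but the frozen experiments do not use them.
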