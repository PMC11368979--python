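# theradose

Voxel-wise theranostic dosimetry simulation and pre-therapy dose-map
prediction for PSMA-style radiopharmaceutical therapy (RPT).

In theranostics, a diagnostic PET tracer (e.g. [⁶⁸Ga]Ga-PSMA-11) and a
therapy compound (e.g. [¹⁷⁷Lu]Lu-PSMA I&T) share a molecular target, so the
pre-therapy PET image carries information about the therapy dose
distribution. Whether that information survives at the **voxel** level
depends on how the two compounds' pharmacokinetics are linked inside each
organ. `theradose` builds the full desk-scale machinery to study this:

- **Synthetic organ phantoms** with two concentric sub-tissues (cortex-like
  rim, core), spatially varying two-tissue-compartment (2TCM) kinetic
  parameter fields `[k1, k2, k3, k4, Vb]` for both compounds, linked by
  per-sub-tissue ratio vectors ρᵢⱼ = kpᵢⱼ/ktᵢⱼ (homogeneous:
  ρᵢ₁ = ρᵢ₂; heterogeneous: ρᵢ₁ ≠ ρᵢ₂).
- **Kinetics**: closed-form 2TCM time–activity curves
  `C(t) = e^{−λt}[(1−Vb)(h ⊛ Cp)(t) + Vb·Cp(t)]` with a Feng-type arterial
  input, vectorised over whole parameter fields.
- **Dosimetry**: voxel time-integrated activity (trapezoid + analytic tail)
  and absorbed dose via the MIRD-style S-value (default 2.2e-4 mGy/MBq/s,
  kidney cortex, Lu-177); single-time-point SUV images.
- **Heterogeneity**: voxel Pearson correlation, GLCM and GLRLM radiomics
  texture features within organ masks.
- **Prediction**: (1) organ-dose-guided direct projection (PET rescaled to a
  target organ-mean dose) and (2) a patch-based learned voxel predictor (a
  compact 3-D convolutional network in numpy, trained on 16³ patches).
- **Evaluation**: NRMSE, 3-D SSIM, organ-mean MAPE, cumulative DVHs with R²,
  identity-plot fits, paired Wilcoxon tests.

## Worked example

```python
import theradose as td

scenario = td.default_scenario("two_cluster")   # heterogeneous linkage
result = td.run_pk_correlation_experiment(scenario, seed=1)
print(f"global r = {result.global_corr.r:.4f}")
for name, corr in result.sub_corrs.items():
    print(f"{name}: r = {corr.r:.4f} (n = {corr.n})")
```

prints

```
global r = 0.9750
sub1: r = 0.9992 (n = 13608)
sub2: r = 0.9980 (n = 14272)
```

Each sub-tissue is internally consistent (r ≈ 0.998–0.999) while the joint
scatter (persisted in `result.scatter`) splits into two dose bands — exactly
the situation in which an organ-level rescaling of PET cannot recover the
voxel dose pattern. Under the `homogeneous` scenario the global r rises to
≈ 1.0, and under `strong_heterogeneity` it collapses to ≈ 0.29.

The same experiments are available from the shell:

```bash
theradose experiment --scenario two_cluster --seed 1 --out runs/two_cluster
theradose experiment --scenario two_cluster --seed 1 --benchmark --out runs/bench
```

which writes `metrics.json`, the heat-scatter table, and (with
`--benchmark`) the learned-predictor vs organ-projection comparison.

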