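# plumspec

Vis/NIR chemometrics for non-destructive prediction of polyphenol-oxidase
(PPO) activity in plums.

Polyphenol oxidase drives enzymatic browning, the main post-harvest quality
loss in stone fruit. Wet-lab PPO assays are destructive and slow; visible /
near-infrared diffuse-reflectance spectroscopy (350–1100 nm) is neither.
`plumspec` implements the full calibration workflow that links the two: it
converts raw reflectance scans to absorbance, compares linear and
non-linear regression models under a repeated random-split protocol, and
compresses the spectrum to a handful of informative wavelengths with
wrapper feature selection. It is written for chemometricians and
food-quality researchers who want a tested, scriptable, fully seeded
version of this pipeline — together with a synthetic spectra generator
whose ground truth makes every stage verifiable.

## What it computes

**Calibration and preprocessing.** Absorbance `A(λ) = −log10((S−D)/(W−D))`
against dark and white reference frames; four replicate scans per fruit are
averaged and the noisy 350–510 nm region is discarded. Eight preprocessing
operators: min–max normalization, SNV, MSC, moving-average / median
(window 5) and Gaussian (σ = 2) filters, linear detrending, mean centering.
MSC and mean centering are fitted on training rows only.

**Models.** Three families behind one fit/predict contract:
ε-SVR (linear, polynomial order 3, RBF kernels; C = 1, ε = IQR(y)/13.49,
kernel scale "auto" = median pairwise training distance), CART regression
trees grown best-first under an explicit split budget (`max_splits` ∈
{5, 10, 20, 50, 100}), and PLSR with up to 10 latent variables chosen by
validation RMSE.

**Evaluation.** For each partition with observed `dᵢ`, predicted `pᵢ`:

    RMSE = sqrt( Σᵢ (dᵢ − pᵢ)² / N ),   SD = sample standard deviation of d,
    RPD  = SD / RMSE,                   R² = squared Pearson correlation.

RPD is classified into the Chang bands (<1 very poor, 1–1.4 weak, 1.4–1.8
acceptable, 1.8–2 good, 2–2.5 very good, >2.5 excellent). The protocol
draws repeated random 60/20/20 train/validation/test splits (200 by
default), scores every preprocessing × model cell on each, and fixes the
best split (highest mean test RPD among repetitions with above-median
validation RPD) for the final comparison. Per-model significance uses the
correlation t-test; paired model comparisons use the exact Wilcoxon
signed-rank test on absolute residuals.

**Wavelength selection.** Seven metaheuristics — PSO, GA, ACO, ICA, LA,
HTS, LCA — search binary wavelength masks (≤ 15 wavelengths) whose fitness
is the validation RMSE of an SVR refitted on the masked columns of one
fixed split. All share a memoizing evaluator, cardinality repair and an
elitist archive; an exhaustive enumerator provides the ground-truth optimum
on small pools. Selected subsets are then re-modeled with DT, SVR and PLSR.

**Synthetic campaigns.** `GeneratorConfig`/`generate_dataset` emulate the
study conditions: 160 fruit in two cultivars (Khormaei, Khoni), PPO
activities from cultivar-specific truncated normals, pigment bands in the
visible region, the ~970 nm water band, per-sample baseline/scatter
artifacts, i.i.d. detector noise, and a PPO-correlated signal planted at
ten visible wavelengths (linear, or a cultivar-oriented low/high step).
The returned `PhantomTruth` records everything needed to score recovery.

## Worked example

```python
import numpy as np
from plumspec import (GeneratorConfig, generate_dataset, truncate_wavelengths,
                      make_split, ModelSpec, fit, predict, compute_metrics,
                      OptimizerConfig, run_selector)

cfg = GeneratorConfig(seed=0)                    # two cultivars, 80 fruit each
spectra, reference, truth = generate_dataset(cfg)
spectra = truncate_wavelengths(spectra)          # keep 510-1100 nm
y = reference.aligned_to(spectra)
split = make_split(spectra.n_samples, seed=0)    # 96 / 32 / 32

for spec in (ModelSpec("svr", kernel="linear"), ModelSpec("dt", max_splits=10),
             ModelSpec("plsr", n_components=8)):
    model = fit(spec, spectra.absorbance[split.train], y[split.train])
    m = compute_metrics(y[split.test], predict(model, spectra.absorbance[split.test]))
    print(f"{spec.label():12s} test R2={m.r2:.2f} RMSE={m.rmse:.5f} RPD={m.rpd:.2f} ({m.rpd_class})")

result = run_selector(OptimizerConfig(algorithm="la", k_max=15, iterations=30, seed=0),
                      spectra.absorbance, y, spectra.wavelengths_nm, split)
print("LA selected", result.n_selected, "wavelengths:",
      ", ".join(f"{w:g}" for w in sorted(result.best_wavelengths_nm)))
covered = sum(1 for p in truth.planted_wavelengths_nm
              if np.min(np.abs(result.best_wavelengths_nm - p)) <= 2.0)
print(f"recovered {covered}/10 planted wavelengths within +-2 nm")
```

prints

```
svr-linear   test R2=0.99 RMSE=0.00023 RPD=6.21 (excellent)
dt-10        test R2=0.83 RMSE=0.00059 RPD=2.40 (very good)
plsr-8       test R2=0.99 RMSE=0.00012 RPD=11.45 (excellent)
LA selected 15 wavelengths: 520, 534, 536, 548, 550, 585, 586, 587, 602, 624, 626, 631, 634, 667, 668
recovered 8/10 planted wavelengths within +-2 nm
```

Under this campaign's default *linear* planted response the linear models
shine (RMSE and RPD are in activity units, absorbance·min⁻¹·g⁻¹); with
`GeneratorConfig(response_form="threshold")` the relationship becomes a
cultivar-dependent step and the ordering reverses — the regression tree
dominates while PLSR collapses to RPD ≈ 1. The learning-automata selector
lands almost exactly on the ten planted visible wavelengths.

A command-line interface wraps the same pipeline:

```
plumspec generate --out out/ --seed 1          # spectra.csv, reference.csv, truth.json
plumspec compare  --out out/ --seed 1 --reps 20
plumspec full     --config run.yaml --out out/
```

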