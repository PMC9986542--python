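# flavimetry

Autofluorescence metabolic imaging of brain tumors: spectral redox metrics,
frequency-domain flavin fluorescence lifetimes, cohort statistics and
multi-class tumor-entity classification, driven by a synthetic-cohort
generator calibrated to published five-group summary statistics.

## The problem

Endogenous fluorophores report on cellular metabolism without exogenous
dyes.  Free NAD(P)H fluorescence (peak ≈ 462 nm) rises with glycolysis; FAD
fluorescence (peak ≈ 530 nm) rises with oxidative phosphorylation; and
protein-bound FMN (peak ≈ 495 nm, ~10× the quantum yield of FAD, long
~4.7 ns lifetime) accumulates when glycolytic catabolism leaves FMN
oxidized in mitochondria.  Three scalar metrics capture this per measured
region:

- **Optical redox ratio** `RR = FAD / (NAD(P)H + FAD)`, from emission-band
  integrals 430–475 nm (NAD(P)H) and 520–600 nm (FAD);
- **R_flavin** `= I495 / I530`, the protein-bound-FMN-to-FAD peak ratio;
- **Flavin fluorescence lifetime** (500–580 nm band) from single-frequency
  frequency-domain FLIM: phase lifetime `τ_φ = tan(φ) / 2πf`.

Tumor entities (low-/high-grade glioma, meningioma, metastasis) shift these
metrics away from non-tumorous brain in characteristic ways: more
glycolysis → lower RR, higher R_flavin, longer flavin lifetime (FMN's
4.7 ns component dominating FAD's ~0.3 ns).  The package reproduces that
whole analysis chain on a synthetic cohort of 361 data points
(16 CTL / 71 LGG / 117 HGG / 64 MNG / 93 MET) whose group-wise quartiles,
spectral peak anchors and pooled R_flavin-vs-RR correlation (−0.87) are
calibration targets, then asks whether the three metrics classify the five
groups under a SMOTE-balanced, 50×-repeated stratified 5-fold
cross-validation protocol.

## Worked example

```python
import numpy as np
from flavimetry import (
    default_presets, generate_cohort, metric_regression,
    hypothesis_battery, FeatureTable, CVPlan,
    repeated_stratified_cv, aggregate_confusion,
)

presets = default_presets()               # calibrated once per process (~5 s)
cohort = generate_cohort(presets, seed=1) # 361 records, 16/71/117/64/93
df = cohort.to_dataframe()

reg = metric_regression(df["r_flavin"], df["redox_ratio"])
print(f"pooled Pearson r = {reg.pearson_r:.3f}")

battery = hypothesis_battery(df)
mng_tau = battery.query("group == 'MNG' and metric == 'tau_ns'").iloc[0]
print(f"MNG lifetime median {mng_tau['median']:.2f} ns, p = {mng_tau['p_value']:.2e}")

table = FeatureTable.from_cohort(df)
preds = repeated_stratified_cv(table, CVPlan(n_folds=5, n_repeats=50, seed=1))
summary = aggregate_confusion(preds)
print(f"{summary.total} predictions; CTL sensitivity "
      f"{summary.sensitivity['CTL']:.1f}%")
```

Output:

```
pooled Pearson r = -0.876
MNG lifetime median 4.03 ns, p = 1.26e-09
18050 predictions; CTL sensitivity 88.6%
```

The regression confirms the built-in coupling: across all 361 points, a
lower redox ratio (more glycolysis) goes with more protein-bound FMN
fluorescence.  The battery row shows the meningioma group's long flavin
lifetimes separating cleanly from control tissue, and the classification
summary aggregates all 250 validation folds (50 repeats × 361 samples =
18,050 predictions) into per-class one-vs-rest sensitivities.

A command-line interface wraps the stages:

```bash
flavimetry simulate --seed 1 --out out/        # cohort.csv, spectra TSVs, FLIM TIFFs
flavimetry analyze  --cohort out/cohort.csv --out out/
flavimetry classify --cohort out/cohort.csv --out out/
flavimetry report   --cohort out/cohort.csv --out out/
flavimetry all --seed 1 --out out/             # everything
```

## Layout

| module | contents |
|---|---|
| `flavimetry.spectra` | `Spectrum`, band integration, `redox_ratio`, `r_flavin`, group-average normalization, TSV I/O |
| `flavimetry.flim` | phasor forward model, phase/modulation lifetime estimators, `FLIMImage`/`ROI`, TIFF I/O |
| `flavimetry.photophysics` | fluorophore component library, emission mixtures, abundance-vs-glycolytic-index model, flavin-band lifetime |
| `flavimetry.cohort` | group presets, two-piece-normal marginals, cohort generation (metric-space and photophysics modes), FLIM image synthesis, CSV I/O |
| `flavimetry.calibration` | calibration targets and the three fits (marginals, spectral anchors, latent coupling), preset TOML I/O |
| `flavimetry.stats` | group summaries, one-sided Mann-Whitney-U battery, KS subgroup check, regression, violin summaries |
| `flavimetry.classify` | SMOTE, repeated stratified CV, model zoo, confusion aggregation |
| `flavimetry.cli` | `simulate` / `analyze` / `classify` / `report` / `all` |

See `docs/methods.md` for the model assumptions, calibration details and
known limitations.
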