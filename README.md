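# meatspec

Vis/NIR chemometrics toolkit for predicting meat-quality properties from
reflectance spectra: spectral preprocessing, calibration/prediction sample
division, univariate NIPALS partial least squares regression with
leave-one-out latent-variable selection, and RPD-graded model evaluation —
plus a seeded synthetic-data generator so the whole pipeline is testable
end-to-end without any measured data.

## What it does

* **Synthetic data** (`meatspec.generate`) — emulates a multi-day
  acquisition design (days × carcasses × six cut types, 150 samples by
  default). Six physicochemical reference values per sample (pH, CIELAB
  L\*/a\*/b\*, cooking loss %, shear force N) are drawn from per-cut
  truncated multivariate normal distributions with literature-informed
  moments and correlations; spectra are built from Gaussian absorption
  bands (defaults at 430/550/760/980 nm on a 400–1000 nm grid, 0.6 nm
  step) linearly linked to the properties, with multiplicative/additive
  scatter, baseline tilt and noise applied per replicate scan and averaged.
  Also: white/dark acquisition arithmetic and the cooking-loss formula.
* **Preprocessing** (`meatspec.preprocess`) — MSC, SNV, polynomial
  detrend, Savitzky–Golay smoothing and 1st/2nd derivatives, wavelength
  trimming, and composable chains with fit-on-calibration /
  replay-on-prediction state (the MSC reference). Eight named presets:
  `original`, `msc`, `snv`, `sg`, `sg_1der`, `sg_2der`, `sg_detrend_msc`,
  `sg_detrend_snv`.
* **Sample division** (`meatspec.split`) — concentration-gradient
  (one-in-four along the sorted property) and whole-carcass hold-out
  schemes, plus per-subset descriptive statistics.
* **PLSR** (`meatspec.pls`) — univariate-response NIPALS implemented from
  scratch, LOOCV RMSECV latent-variable selection, JSON model
  serialisation.
* **Evaluation** (`meatspec.evaluate`) — RMSEC/RMSEP, R², RPD and its
  quality grades (`not recommended` < 2.0 … `excellent` ≥ 4.0), full
  property × preprocessing experiment grids, per-cut descriptive tables
  and Pearson correlation tables.

## CLI

```bash
# 1. generate a synthetic dataset (spectra/metadata/references CSVs)
meatspec generate --config examples/config.yaml --seed 1 --out data/

# 2. run the full preprocessing x property experiment grid
meatspec run --config examples/config.yaml --data data/ --split gradient \
    --seed 1 --out results/

# 3. apply a saved best model (frozen preprocessing included) to new spectra
meatspec predict --model results/model_pH.json --spectra data/spectra.csv \
    --out predictions.csv

# 4. pretty-print a report
meatspec report --report results/report.csv
```

`run` writes `report.csv` / `report.txt` (one row per property ×
preprocessing chain: LVs, R²c, RMSEC, R²p, RMSEP, RPD, grade, with the
best chain per property flagged), `best_models.csv`, and one
`model_<property>.json` per property. Every output directory carries a
`manifest.json` with the seed and config hash. See `examples/config.yaml`
for the configuration schema.

## Python API

```python
from meatspec import (GeneratorConfig, generate_dataset,
                      run_experiment_grid, report_to_frame)

dataset = generate_dataset(GeneratorConfig(seed=1))
reports = run_experiment_grid(dataset, split_method="gradient", seed=1)
print(report_to_frame(reports))
```

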