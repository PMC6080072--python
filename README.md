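# ddlibs

Data-driven calibration for laser-induced breakdown spectroscopy (LIBS).
The package quantifies an element (potassium by default) from emission
spectra by combining three stages:

1. **HDWT** — a higher-density discrete wavelet transform: a three-channel
   filter bank whose third channel is not decimated, giving an ~3×
   oversampled, approximately shift-invariant coefficient frame (a
   512-point spectral window expands to 1,520 coefficients at scale 4).
2. **MRFA** — a modified random frog algorithm: the stochastic
   random-frog variable search repeated under bagged 70/30 resampling,
   with per-variable visit frequencies summed into an accumulated
   selection probability; the top coefficient is kept.
3. **PLS** — mean-centered partial least squares on the selected
   coefficient(s); with a single coefficient the final model has exactly
   one factor.

A synthetic LIBS spectrum simulator (potassium doublet at 766.57 /
769.95 nm on the 751.90–774.86 nm, 512-point grid, with per-sample peak
shift, broadening, laser-energy fluctuation, self-absorption saturation,
baseline, noise and interfering matrix lines) stands in for instrument
data, so every stage is testable offline.

## Library quick start

```python
from ddlibs import (
    DDLIBSConfig, compare_methods, ddlibs_predict, ddlibs_train,
    simulate_dataset, split_dataset,
)
from ddlibs.synthetic import stressed_config

ds = simulate_dataset(90, stressed_config(seed=1))
cal, val = split_dataset(ds, 65, seed=1)

model = ddlibs_train(cal, DDLIBSConfig(seed=1))
pred = ddlibs_predict(model, val)

report = compare_methods(cal, val, DDLIBSConfig(seed=1))
print(report.to_frame())   # univariate x3, PLS, RFA-PLS, HDWT-RFA-PLS, ddlibs
```

## CLI

```bash
ddlibs simulate -n 90 --seed 1 --stressed \
    --spectra-out spectra.csv --concentrations-out conc.csv
ddlibs hdwt-check                       # PR residuals, moments, count law
ddlibs normalize spectra.csv normed.csv --normalize mean
ddlibs select spectra.csv conc.csv selection.csv --runs 50
ddlibs train spectra.csv conc.csv model.json --seed 1
ddlibs predict model.json spectra.csv predictions.csv
ddlibs compare spectra.csv conc.csv comparison.csv --n-cal 65
ddlibs compare-norm spectra.csv conc.csv norms.csv --ref-line 752.8
```

Spectra tables are plain CSV, wide (first column wavelength, one column
per sample) or long (`sample_id,wavelength,intensity`); concentrations are
a two-column table keyed by sample id. Models persist as a single JSON
archive with a format-version field.

## Tests and acceptance report

```bash
python -m pytest -q                      # full suite (~10 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the headline checks: the 1,520
coefficient count, perfect reconstruction (< 1e-8) for all four filter
banks, near shift-invariance versus an in-repo critically-sampled DWT,
brute-force metric fidelity, MRFA selection power and null behavior, the
stressed-regime ordering (DD-LIBS beats raw-spectrum PLS on RMSEP in
≥ 80 % of 20 seeded replicates, using 1 PLS factor against > 1), and
noiseless parameter recovery (held-out R² > 0.99).

`scripts/acceptance.py` recomputes the structural acceptance target from
scratch (simulate → transform → count) and writes JSON.

## Conventions worth knowing

- The RMSE divides by `m − 1`, not `m`, for both cross-validation and
  prediction errors — a deliberate fidelity choice; see
  `ddlibs.calibration.rmse_eq1`.
- The transform's default boundary mode is zero-padded full convolution
  (the convention under which 512 → 1,520 holds); `periodic` is also
  supported and exactly invertible.
- All stochastic stages (splits, frog search, bagging) fan out from one
  master seed and are bit-reproducible.
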