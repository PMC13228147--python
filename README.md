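# fecalnirs

Global and locally weighted PLS calibration of fecal near-infrared spectra
for predicting the organic matter digestibility (OMD, g/g) of cattle diets.

In vivo digestibility trials are slow, costly and invasive; NIR spectra of
feces are a practical proxy, conventionally calibrated with one global PLS
regression over the whole sample library. Feces are a heterogeneous material,
though: different diets put the samples in different spectral regimes, and
the spectrum→OMD relationship is then only *locally* linear. This package
implements and compares, under one reproducible protocol, the global model
and three locally weighted alternatives that build a dedicated weighted PLS
model for every sample to be predicted:

- **PLSR** — global PLS1 regression (mean-centered NIPALS),
- **LWPLSR** — all calibration samples, weighted by
  `w_i = exp(−d_i/(h·median(d)))` where `d_i` are standardized distances in
  the latent score space of a preliminary PLS,
- **KNN-LWPLSR** — the same, restricted to the k nearest calibration samples,
- **KNN-LWPLSR-AGG** — KNN-LWPLSR predictions averaged over
  nlv = nlv_min…nlv_max latent variables.

Around the estimators the package provides the full study workflow:
log10(1/R) conversion, Savitzky–Golay first derivative (11-point window,
3rd-order polynomial) and SNV scatter correction; Kennard–Stone
calibration/validation splitting; standardized Mahalanobis H (> 3) outlier
screening; five-fold interleaved cross-validation over the hyperparameter
grids (h, k, nlv); RMSEP / bias / RMSEP(C) / R² reporting with ±1.96·RMSEP
prediction intervals; paired bias t-tests and Pitman–Morgan SEP-ratio
comparisons with significance letters; and the two-means power analysis
`n = 2(Z_α+Z_{1−β})²·SD²/d²`. A seeded synthetic generator emulates
multi-diet fecal spectra (cluster-heterogeneous local slopes, scatter
artifacts, 0.0135 g/g reference noise) so the whole stack is testable without
proprietary data. See `docs/methods.md` for the model details and design
choices.

## Worked example

```python
import fecalnirs as fn

# a 466-sample, 3-cluster synthetic population on the 400–2500 nm @ 2 nm grid
spectra, reference = fn.generate_dataset(fn.SyntheticConfig(seed=1))
pp = fn.preprocess(spectra)                      # SG 1st derivative + SNV

cal = slice(0, 300)
res = fn.PLS(reference.omd[cal], pp.absorbance[cal]).fit(nlv=3)
global_pred = res.predict(pp.absorbance[300:])

local = fn.LWPLSR(reference.omd[cal], pp.absorbance[cal], h=0.5, nlv=3).fit()
local_pred = local.predict(pp.absorbance[300:])

for name, pred in [("PLS", global_pred), ("LWPLSR", local_pred)]:
    print(fn.evaluate(pred, reference.omd[300:], label=name).summary())
```

prints (seed 1):

```
PLS: n=166  RMSEP=0.0153 g/g (2.17%)  bias=+0.0010  RMSEP(C)=0.0153  R2=0.789  IP=±0.030
LWPLSR: n=166  RMSEP=0.0137 g/g (1.94%)  bias=+0.0011  RMSEP(C)=0.0137  R2=0.832  IP=±0.027
```

i.e. on this heterogeneous population the sharply weighted local model cuts
the prediction error from 0.0153 to 0.0137 g/g — essentially the 0.0135 g/g
noise of the in vivo reference method, which no spectral model can beat — and
narrows the 95% prediction interval of an individual OMD value from ±0.030 to
±0.027 g/g. With `fn.minimum_detectable_difference(0.0137)` ≈ 0.054 g/g two
animals must differ by about 0.05 g/g in OMD before the spectral prediction
can tell them apart. (In practice h and nlv come from `fn.cross_validate`
rather than being fixed by hand.)

The same workflow is scriptable end to end:

```bash
fecalnirs run-all --out-dir results/run1 --seed 1           # full pipeline
fecalnirs power --sd 0.016 --d 0.024                        # power analysis
fecalnirs simulate --seed 7 --out-prefix toy                # data only
```

`run-all` writes the calibration (RMSECV/R²CV per tuned model), prediction
(RMSEP/bias/RMSEP(C)/R²P/IP per subset and model), comparison-letter and
power tables plus a JSON manifest of every stage.

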