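# texcomplex

Quantifying *visual texture complexity* — the perceived degree of disorder in
the spatial distribution of luminance and color elements of a surface — and
linking it to computable image texture measures.

The package is aimed at researchers in visual psychophysics and perceptual
image analysis who need the full chain in one place:

* **Psychophysical scaling.** A panel of S observers rank-orders T samples
  (ties allowed) by how strongly each expresses an attribute (complexity,
  randomness, strongness, color variation, regularity, repetitiveness,
  homogeneity). The visual rank score of a sample is

  VRS = (1 / (S·(T−1))) · Σₜ t·Qₜ,

  where Qₜ counts the observers who placed the sample at position t; scores
  are linearly rescaled to 0–10 per attribute. Observer consistency is
  quantified with STRESS (standardized residual sum of squares, a 0–100
  scale-invariant disagreement index).
* **Texture measures.** Per channel in five color spaces (sRGB + intensity,
  HSV, YCbCr, Ohta I1I2I3, CIELAB, each channel tagged luminance /
  chrominance): first-order statistics (μ, σ, histogram skewness, kurtosis,
  energy, entropy); the five co-occurrence-matrix features (energy,
  contrast, correlation, entropy, homogeneity), feature-averaged over eight
  angles across a distance sweep; rotation-invariant uniform LBP (riu2)
  histograms and their two single-number summaries over a radius sweep; and
  Gabor filter-bank energy features (mean and std of the response modulus,
  averaged over six orientations, six frequencies).
* **Linking statistics.** Pearson correlation sweeps of every feature cell
  against the complexity scores; PCA of the attribute-score covariance; the
  weighted-sum complexity model VTCₚ = X·k fitted by least squares with no
  intercept (`VTCModel(...).fit()` returns a results object with
  coefficients, MSE, R², and `summary()`); and single-common-factor analysis
  of the headline measures (`SingleFactorModel`).
* **Synthetic ground truth.** Because per-sample visual data for the
  physical textiles that motivated this pipeline were never published, a
  texture generator with known latent attributes and a simulated observer
  panel provide a fully controlled test bed; the latent complexity is the
  weighted sum 0.50·randomness + 0.34·color variation + 0.41·strongness −
  0.19·regularity − 0.14·repetitiveness.

## Worked example

Simulate a 23-sample study with the default 10-observer panel, score the
ranks, and fit the attribute-level complexity model:

```python
import numpy as np, pandas as pd
from texcomplex import synthetic, psychophysics, statmodels

params = synthetic.sample_params(23, seed=7, size_px=128)
latent = synthetic.attribute_table(params)
cols = list(synthetic.ATTRIBUTE_NAMES)
rng = np.random.default_rng(7)
vrs = {}
for name in cols + ["complexity"]:
    panel = synthetic.ObserverPanel(seed=int(rng.integers(2**31)))
    rm = synthetic.simulate_rankings(latent[name].to_numpy(), panel, replicates=2)
    vrs[name] = psychophysics.vrs(rm).rescaled
scores = pd.DataFrame(vrs, index=latent.index)
model = statmodels.VTCModel(scores["complexity"].to_numpy(),
                            scores[cols].to_numpy(), labels=cols)
print(model.fit().summary())
```

prints

```
Weighted-sum complexity model (no intercept)
  n = 23, predictors = 5
  MSE = 1.4445   R^2 = 0.8469   r(target, fitted) = 0.9206
  condition number = 5.81

  predictor             coef   std err
  randomness          0.5154    0.0963
  color_variation     0.4248    0.1188
  strongness          0.4253    0.1087
  regularity         -0.1975    0.0980
  repetitiveness     -0.0661    0.0976
```

— the fitted weights recover the generating values (0.50, 0.34, 0.41, −0.19,
−0.14) up to the rank-scale noise of a 23-sample panel, and the fitted
complexity correlates with the observed scores at r = 0.92. The same panel's
consistency:

```python
rm = synthetic.simulate_rankings(latent["complexity"].to_numpy(),
                                 synthetic.ObserverPanel(seed=3), replicates=2)
psychophysics.intra_observer_stress(rm).intra   # 21.4 STRESS units
psychophysics.inter_observer_stress(rm).inter   # 37.7 STRESS units
```

Intra-observer disagreement (repeat sessions of one observer) is well below
inter-observer disagreement, as expected of a reasonably consistent panel.

## Command line

```sh
texcomplex simulate --n-samples 23 --out study/          # images + latent + rank CSVs
texcomplex pipeline study/images study/ --out reports/   # full analysis
texcomplex features images/ --out features.csv
texcomplex vrs study/ranks_Cpx.csv --out vrs.csv
```

`pipeline` writes tidy CSV reports (features, rank scores, correlation
sweep, PCA, weighted-sum model, factor analysis) plus a manifest with the
config hash and seed that make the run reproducible.

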