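# expotox

Identification of biological indicators of environmental-pollution exposure
from smart-city sensor data and health-examination records.

Urban monitoring networks produce continuous multichannel environmental
series (PM2.5, SO2, temperature, humidity, light, wind, water quality), and
hospital examination centres produce large panels of exam records with
numeric features and binary disease/indicator-positivity labels (fatty
liver, hypertension, diabetes; CKMB, LDH, CRP, CYFRA21-1, NSE positivity).
`expotox` links the two: it asks which clinical indicators move with
pollutant exposure, how strongly, and in which direction, and forecasts
daily indicator case counts from exposure history.  It is written for
epidemiologists and public-health data scientists working with this kind of
paired sensor/exam data; because real hospital panels are private, the
package ships a synthetic-data generator that emulates both tables with
configurable planted exposure–indicator correlations, so every stage runs
and is tested end to end without external data.

## The models

**Preprocessing.** Exam features are min-max normalized,
x' = (x − min x)/(max x − min x), with parameters fitted on the training
split only.  Multi-label disease data is reduced either by Binary Relevance
(BR: one single-label dataset per indicator) or Label Powerset (LP: one
class per observed label combination).  Because BR ignores label
dependence, training can couple the per-label heads through the
**association loss** CL = loss + Σᵢ αᵢ·lossᵢ, where loss is the anchor
label's cross-entropy and αᵢ is the training-set Pearson correlation
between the anchor label and label i.

**Seasonal/dynamic-factor decomposition.** Each pollutant channel is split
as y_t = trend_t + seasonal_t + remainder_t (classical additive
decomposition); the deseasonalized series trend + remainder is then
modelled by dynamic factor analysis: y_t = Z f_t + D x_t + ε_t with
random-walk common trends f_t = f_{t−1} + η_t, estimated by EM on the
state-space form.  The number of common trends is selected by
AIC = 2m′ − 2 ln L, with per-channel goodness of fit measured by the
Nash–Sutcliffe efficiency C_eff = 1 − Σ(Q₀ₜ − Qₘₜ)²/Σ(Q₀ₜ − Q̄₀)².

**GroupNet.** A 1-D CNN over the normalized feature vector: the signal is
split into uniform groups convolved independently (8 kernels per unit),
fused by a 1×1 clustered convolution (12 kernels), then max-pool, dropout
(0.5), a 372-unit dense layer and a softmax pᵢ = exp(Zᵢ)/Σⱼ exp(Zⱼ).
Grouping makes the trunk sparse: with 4 groups the convolutional trunk
holds ~26% of the parameters of the equivalent dense convolution.

**GA-GRU forecaster.** Daily case counts are forecast from (y, x) history
windows, y′_t = F(y₁…y_{t−1}, x₁…x_{t−1}), with a gated recurrent unit
(r_t = σ(W_r x_t + U_r h_{t−1}), z_t = σ(W_z x_t + U_z h_{t−1}),
h̃_t = tanh(U x_t + W(r_t ⊙ h_{t−1}) + b_h),
h_t = z_t ⊙ h_{t−1} + (1 − z_t) ⊙ h̃_t) trained by Adam on the MSE.  A
real-coded genetic algorithm selects the input channels and the GRU's
hidden size and learning rate: fitness E(yᵢ) is validation MSE, selection
is inverse-fitness roulette P_s = (1/Eᵢ)/Σ(1/Eⱼ), crossover swaps genome
positions, mutation resamples positions within slot bounds, and elitism
makes the best-fitness trace monotone.

**Association accounting.** For each indicator, records are tabulated per
calendar quarter (total, positive, exposure-attributed cases), the percent
of positive cases associated with exposure is 100·associated/positive
(half-up, 2 decimals), and the Pearson correlation between weekly-binned
positivity rate and mean exposure classifies the indicator as positive-,
negative- or not-associated (|r| ≥ 0.3 by default); not-associated rows
have their attributed counts suppressed ("–").

## Worked example

```python
import numpy as np
import expotox as ex
import expotox.assoc as assoc

# linked synthetic panels: 2 years of daily sensors + 5000 exam records
env = ex.generate_env(ex.EnvGenConfig(n_days=730, seed=0))
health = ex.generate_health(ex.HealthGenConfig(n_records=5000, seed=1), env)

# is CYFRA21-1 positivity associated with PM2.5 exposure?
r = assoc.indicator_correlation(
    health.labels["CYFRA21_1"].to_numpy(), health.exposure.to_numpy(),
    timestamps=health.timestamps, freq="W")
print(f"CYFRA21-1 weekly-binned r with PM2.5 window mean: {r:.3f}")
print(f"identified as: {assoc.identify(r, 0.3).value}")
print(f"record-level r (planted -0.597): "
      f"{np.corrcoef(health.exposure, health.labels['CYFRA21_1'])[0, 1]:.3f}")
```

prints

```
CYFRA21-1 weekly-binned r with PM2.5 window mean: -0.868
identified as: negative-associated
record-level r (planted -0.597): -0.599
```

The generator planted a record-level exposure–positivity correlation of
−0.597 (the default CYFRA21-1 setting) and the panel reproduces it to three
decimals; the weekly-binned correlation used by the identification rule is
stronger in magnitude because binning averages out the record-level
Bernoulli noise.  The sign is recovered and the indicator is correctly
flagged as negatively exposure-associated.

Dynamic-factor trend selection on a simulated 4-channel panel driven by one
random-walk common trend:

```python
panel = ex.dfa.simulate_trend_panel(4, 1, 250, noise_sd=0.5, seed=3)
best, report, fits = ex.select_trends(panel, [1, 2, 3])
print(f"selected m = {best} common trend(s)")
print(report.round(2).to_string())
```

prints

```
selected m = 1 common trend(s)
      aic  log_likelihood  mean_ceff
m
1 -516.24          266.12       0.98
2 -508.61          266.30       0.98
3 -499.72          265.86       0.98
```

AIC picks the generating single trend — the extra loadings of m = 2, 3 buy
almost no likelihood — and the one-trend fit explains the channels with a
mean Nash–Sutcliffe efficiency of 0.98.

A command-line interface mirrors the library:
`expotox simulate`, `expotox decompose`, `expotox train-cnn`,
`expotox train-gru`, `expotox associate`, `expotox evaluate`
(see `expotox --help`).

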