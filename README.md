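# leadgwqr

Global and **geographically weighted quantile regression (GWQR)** for areal
disease-rate mapping, built around the motivating application of childhood
lead poisoning: the per-census-block incident rate of elevated blood lead
levels (BLL ≥ 5 µg/dL among tested children) modelled against building age,
housing taxable value and soil lead concentration.

Because real lead-surveillance records are confidential, the package ships a
**calibrated synthetic census-block generator** that reproduces the
published statistical structure of such data — a zero-inflated rate in
[0, 1] (mean ≈ 0.14, ~45% exact zeros, upper quartile ≈ 0.18, 90th
percentile ≈ 0.40), three correlated covariates (building year 1923 ± 17.6,
taxable value 58.4 ± 23.8 K$, soil lead 186 ± 112 ppm; pairwise Pearson
correlations −0.54, +0.40, −0.38) and spatially clustered block centroids —
plus controllable spatially varying coefficient surfaces for
parameter-recovery studies.

## The models

**Global quantile regression.** For quantile level τ ∈ (0, 1) the
conditional τ-quantile of the rate Y is modelled as

    Q_τ(Y | x) = β₀(τ) + β₁(τ)·year + β₂(τ)·ln(tax) + β₃(τ)·soil,

with β̂(τ) minimising the total check loss Σ ρ_τ(yᵢ − xᵢ'β), where
ρ_τ(r) = τ·r for r ≥ 0 and (τ−1)·r otherwise. The minimisation is solved
exactly as a linear program. Inference is by paired bootstrap (percentile
CIs, normal-approximation p-values); standardized coefficients (STB) are
obtained by refitting on z-scored data.

**GWQR.** At every location (u, v) a separate quantile regression is
fitted by minimising the kernel-weighted check loss
Σ W₀ᵢ ρ_τ(yᵢ − xᵢ'β(u, v)), with W₀ᵢ = K(d₀ᵢ/h) a gaussian (or bisquare)
kernel of bandwidth h, giving coefficient surfaces β_k(τ)(u, v), local
bootstrap t surfaces and local predictions Q̂_τ = x'β̂(u, v). The bandwidth
is chosen either by a leave-one-out quantile AIC over a grid or as the
practical range of the AIC-best semivariogram model (gaussian / spherical /
exponential) fitted to the rate or to regression residuals.

**Diagnostics.** Spatial nonstationarity of each coefficient is assessed by
comparing the interquartile range of its local estimates with twice the
global coefficient's standard error (IQR > 2·SE ⇒ "Nonstationary"), and
spatial autocorrelation of rates and residuals by Moran's I with
normality-assumption z-scores on row-standardized k-nearest-neighbour
weights.

## Worked example

```python
from leadgwqr import (SyntheticConfig, generate_block_table, fit_qr,
                      GWQuantileRegressor, build_weights, morans_i)

table = generate_block_table(SyntheticConfig(n_blocks=1393, seed=7))
X = table[["building_year", "log_tax", "soil_lead"]]
y = table["rate"].to_numpy()

fit = fit_qr(X, y, tau=0.75)
print(fit.beta_.round(4))          # [ 3.552  -0.0015 -0.1671  0.0009]

res = morans_i(y, build_weights(table[["u", "v"]].to_numpy()))
print(round(res.I, 4), round(res.z_score, 1))   # 0.1419 10.9

gw = GWQuantileRegressor(tau=0.75, bandwidth=2400.0).fit(
    X, y, table[["u", "v"]].to_numpy())
print(gw.local_coef_.shape)        # (1393, 3)
```

The 0.75-quantile slopes are negative for building year (−0.0015 per year)
and log taxable value (−0.17 per log-K$) and positive for soil lead
(+0.0009 per ppm): newer, higher-value housing lowers the upper-quartile
risk of elevated BLL while soil contamination raises it. Moran's I of
0.14 (z ≈ 11) shows the rates are significantly spatially clustered, and
the local coefficient surfaces let those relationships vary across the
study area.

The same workflow is scriptable end-to-end:

```sh
lead-gwqr run --synthetic-n 1393 --seed 7 --bandwidth variogram --out results/run
lead-gwqr synth --n 500 --seed 1 --out blocks.csv
lead-gwqr qr --input blocks.csv --taus 0.25,0.5,0.75,0.9 --out qr.csv
```

which writes coefficient tables (estimate, 95% CI, p, STB per τ), Moran and
nonstationarity summaries, and GeoJSON point layers with per-location
estimates, t values and a `significant` (|t| > 1.96) flag.

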