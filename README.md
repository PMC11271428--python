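# metstab

Stability and genetic-parameter analysis of multi-environment trials (METs).

Plant-breeding programs evaluate candidate genotypes in trials repeated over
locations and years. Whenever genotype-by-environment (G×E) interaction is
large, the best genotype in one environment is not the best in another, and a
recommendation must weigh *mean performance* against *stability*. `metstab`
implements the full analysis chain used in variety-release (VCU) studies of
this kind — developed around a published cassava trial series of 12 genotypes
× 12 environments × 3 blocks in the Brazilian tropics — on any balanced
randomized-complete-block MET:

* **Joint ANOVA and genetic parameters.** The plot model
  `y_ijk = μ + g_i + τ_j + (gτ)_ij + b_k(j) + ε_ijk` is partitioned into
  G, E, blocks-within-E, G×E and residual sums of squares. Expected mean
  squares give the variance components
  `σ̂e² = MS_res`, `σ̂ge² = (MS_GxE − MS_res)/r`, `σ̂g² = (MS_G − MS_GxE)/(re)`,
  from which broad-sense heritability `h² = σg²/σp²`, the coefficients of
  variation CVg/CVp/CVr, expected genetic gain `GA = K·σp·h²` and selective
  accuracy `r̂ = √(1 − 1/F)` (F = MS_G/MS_GxE) follow. Scott–Knott
  likelihood-ratio clustering groups the genotype means.
* **AMMI**: SVD of the doubly centered residual
  `Z_ij = Ȳ_ij − Ȳ_i. − Ȳ_.j + Ȳ_..` into interaction principal components,
  with per-axis shares of the G×E sum of squares and the ASV stability value.
* **GGE**: SVD of the environment-centered matrix (genotype main effect plus
  G×E), which-won-where mega-environment partitioning, and environment
  discrimination/representativeness.
* **Univariate stability indices**: Wricke ecovalence `W_i`, Lin–Binns
  superiority `P_i`, Eberhart–Russell joint regression (b_i, S²d_i, RMSE, R²),
  Perkins–Jinks (B_i, D_i), Annicchiarico confidence indices on the
  percentage scale (overall / favorable / unfavorable environments), Roemer
  environmental variance S²x, plot-level standard deviation DP, and the
  Nassar–Hühn nonparametric rank statistics S⁽¹⁾, S⁽⁶⁾.
* **BLUP-based simultaneous selection**: exact balanced-case mixed-model
  BLUPs of genotype and G×E effects, the harmonic mean of genotypic values
  (HMGV) and the weighted average of absolute BLUP interaction scores
  (WAASB), plus the mean×stability four-quadrant classification.
* **Method concordance**: a genotype × method rank matrix with per-method
  direction rules, Spearman correlations between methods, PCA of the rank
  correlation matrix, Ward clustering of methods, and dynamic/static
  stability-concept labels.

A synthetic-trial generator (`metstab.simulate`) draws balanced METs with
configurable variance components, so every stage runs and can be validated
without external data. The published summary tables of the cassava reference
study (ANOVA sums of squares, genetic parameters, per-genotype index values
and rankings for fresh root yield and dry matter content) ship as package
data under `metstab.datasets`.

## Worked example

```python
from metstab import SyntheticConfig, generate_met, trait_summary
from metstab.anova import selective_accuracy

met = generate_met(SyntheticConfig(seed=7))   # 12 x 12 x 3, reference magnitudes
out = trait_summary(met, "FRY")
vc, gp = out["components"], out["parameters"]
print(f"sigma_g2 {vc.var_g:.2f}, sigma_ge2 {vc.var_ge:.2f}, sigma_e2 {vc.var_e:.2f}")
print(f"h2 {gp.h2:.2f}  CVg {gp.cv_g:.2f}%  accuracy {selective_accuracy(out['anova']):.3f}")
```

prints

```
sigma_g2 25.57, sigma_ge2 13.63, sigma_e2 6.41
h2 0.56  CVg 18.08%  accuracy 0.975
```

— the EMS estimates for this particular draw (configured truth 20.16, 17.87,
6.54; heritability 0.45 in expectation), and a selective accuracy high
enough to trust the genotype ordering. The scripts in `examples/` continue
from here, one per capability: stability indices and their rankings, AMMI/GGE
decompositions with mega-environments, BLUP-based HMGV/WAASB selection, and
the cross-method concordance analysis (which, on the published cassava
rankings, recovers the known block of performance-tracking methods —
confidence indices, P_i, S⁽⁶⁾, HMGV — around the trait mean).

A thin CLI wraps the same pipeline:

```sh
metstab all --seed 1 --out results/        # simulate + full analysis bundle
metstab analyze my_trial.csv --trait FRY   # long-format CSV input
```

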