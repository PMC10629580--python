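# chronodiv

Did historic climate change drive speciation, or did diversity just
accumulate with time?  `chronodiv` implements the statistical pipeline
used to ask that question for large time-calibrated phylogenies such as
the terrestrial orchids: environment-dependent birth–death model fitting
with AICc evidence ratios, detrended cross-correlation analysis (DCCA)
between posterior speciation-rate curves and paleoclimate proxies, and
phylogenetically corrected tip-rate association tests — together with a
synthetic-data module that generates every input the pipeline consumes,
so the whole method can be exercised and calibrated offline.

## The model

Speciation and extinction rates are parametric functions of age `t`
(My before present, present = 0):

    constant:   λ(t) = λ0
    exp. time:  λ(t) = λ0 · exp(β t)
    exp. env.:  λ(t) = λ0 · exp(α T(t))

where `T(t)` is a paleoclimate proxy (e.g. δ18O), Tukey-smoothed and
linearly interpolated.  The likelihood is the reconstructed birth–death
process with sampling fraction `f`: with `r(t) = ∫₀ᵗ (λ−μ) du` and
`g(t) = 1/f + ∫₀ᵗ λ e^{r}`, each edge from age `s` to `t` contributes
`Ψ(s,t) = e^{r(t)−r(s)} (g(s)/g(t))²`, each internal node contributes
`λ(tᵢ)`, and the likelihood is conditioned on crown survival by dividing
by `λ(t_c)(1−Φ(t_c))²` with `Φ(t) = 1 − e^{r(t)}/g(t)`.  Six models are
compared — exponential speciation driven by temperature or by time, each
with no, constant, or exponential extinction — via AICc weights, and the
family-level support is summarized as the evidence ratio
`Σ AICω(temperature) / Σ AICω(time)`.

Complementary analyses: DCCA coefficients between each posterior
rate-through-time curve and a proxy (with a rank test of the coefficient
distribution against zero); equal-splits tip rates (DR); Es-Sim and
STRAPP permutation tests of rate–trait association; the Fritz–Purvis D
statistic for binary-trait phylogenetic signal; and per-bioregion
summaries (endemic filtering, occurrence-grid richness/rate maps,
rate-through-time correlation matrices, exponential rate-vs-temperature
fits).

## Worked example

Simulate the bundled orchid-like scenario (65 My crown, Cenozoic-like
cooling proxy, temperature-driven speciation with α = −0.15, sampling
fraction 0.3) and run every stage:

```bash
chronodiv all --out-dir demo --seed 3
```

From `demo/fits.json` (six-model comparison on the simulated tree,
156 tips in this run):

```
evidence_ratio_env_vs_time : 3.65
best_model                 : env_spec_no_ext
  lambda0 = 0.1343, lambda_slope (alpha) = -0.1449
```

The evidence ratio above 1 means the temperature-dependent family
carries more AICc weight than the time-dependent family, and the fitted
slope recovers the generating α = −0.15 closely on this replicate.
From `demo/dcca.json`:

```
whole_tree.temperature : mean = -0.898, p = 1.4e-34, n_samples = 200
```

a strongly negative mean DCCA coefficient: speciation rates rise as the
proxy falls (cooling).  `demo/tiprate_tests.json` reports the Es-Sim,
STRAPP and D-statistic results on the simulated covariates (here traits
are independent of rates by construction, so the association tests stay
non-significant), and `demo/bioregion.json` holds endemic counts per
region, the cross-region rate-through-time Pearson correlation matrix,
and per-region exponential rate-vs-temperature fits over the last 10 My
whose slopes recover the generating α ≈ −0.15.

The same stages run on real data by pointing the subcommands
(`chronodiv fit / dcca / tiptests / bioregion`) or a pipeline YAML at a
Newick tree, proxy CSVs (`age_mya,value`), a rate-ensemble CSV, a tip
table, and occurrence/region tables.

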