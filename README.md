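# nitracer

Nitrate source apportionment and connectivity–nitrogen–microbiome coupling
analysis for river–lake systems.

`nitracer` implements, as a tested and reusable Python pipeline, the
computational chain used in watershed nitrogen studies that combine
dual-isotope source tracing with sediment microbiome surveys:

1. **Bayesian stable-isotope mixing model.** Each water sample carries a
   dual nitrate isotope observation (δ¹⁵N, δ¹⁸O, in ‰). The observation
   model for isotope *j* of sample *i* is

   ```
   X_ij = Σₖ p_k q_jk (S_jk + C_jk) / Σₖ p_k q_jk + ε_ij
   S_jk ~ N(μ_jk, ω_jk²)   C_jk ~ N(λ_jk, τ_jk²)   ε_ij ~ N(0, σ_j²)
   ```

   with source proportions **p** on the simplex, source signatures
   S, fractionation offsets C, concentration weights q, and residual error
   ε. The source and fractionation randomness is integrated out
   analytically and the posterior over (p, σ) under Dirichlet ×
   half-normal priors is sampled by adaptive random-walk Metropolis MCMC,
   with split-chain R̂ and effective-sample-size diagnostics.
2. **Source-category apportionment.** Posterior draws are aggregated into
   non-point sources (NPS: atmospheric deposition AP, chemical fertilizer
   CF, soil nitrogen SN) versus point sources (PS: manure & sewage M&S),
   with per-stratum contribution tables in percent.
3. **Community statistics.** Chao1 richness, Shannon entropy (natural
   log), Simpson dominance Σp², Bray–Curtis dissimilarity, principal
   coordinates analysis, and seeded permutation tests (Mantel, ANOSIM with
   Clarke's R) — implemented from first principles and cross-checked
   against scikit-bio in the test suite.
4. **Coupling analysis.** Pearson/Spearman correlations between the
   river–lake connectivity index, nitrogen concentrations and diversity
   indices; a piecewise structural-equation path model (one standardized
   OLS submodel per endogenous variable, reporting standardized path
   coefficients, p-values and per-endpoint R²); indirect effects as
   coefficient products along paths; Nash–Sutcliffe efficiency and R² as
   model-evaluation utilities.
5. **Synthetic data generators.** Seeded generators reproduce the
   statistical structure the analysis assumes — four-source isotope
   mixtures, single-latent-factor watershed tables with prescribed
   correlations, linear-Gaussian structural data, count tables whose
   evenness tracks a connectivity gradient, and paired distance matrices
   with a prescribed Mantel correlation — so the whole pipeline runs and
   is testable without any field data.

## Worked example

Fit the mixing model to 100 synthetic dry-season samples and apportion the
posterior:

```python
import nitracer as nt

samples = nt.generate_isotope_dataset(nt.SCENARIO_DRY, seed=1)
post = nt.fit_mixing_model(samples, nt.SCENARIO_DRY.signatures,
                           nt.MixingConfig(seed=1))
print(nt.posterior_summary(post).round(3))
print(nt.aggregate_sources(post).summary.round(3))
```

prints

```
     parameter    kind   mean  median     lo     hi
0           AP  source  0.434   0.435  0.369  0.494
1           CF  source  0.208   0.206  0.008  0.423
2           SN  source  0.201   0.203  0.008  0.382
3           MS  source  0.157   0.156  0.114  0.200
4  sigma[d15n]   sigma  0.745   0.777  0.175  1.142
5  sigma[d18o]   sigma  0.506   0.499  0.032  1.061
  category   mean     lo     hi
0      NPS  0.843  0.800  0.886
1       PS  0.157  0.114  0.200
```

The dry-season scenario's true mixture is 43.9% atmospheric deposition;
the posterior mean recovers it at 43.4% with a 95% credible interval of
[36.9, 49.4], and non-point sources together account for ~84% of nitrate.
The wide CF/SN intervals reflect the real weak identifiability of a
four-source, two-isotope system — the data constrain their sum far better
than their split.

The same chain is available from the shell:

```bash
nitracer run --seed 1 --out results/demo   # one-command synthetic pipeline
nitracer report --results results/demo    # human-readable summary
```

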