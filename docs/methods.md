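# Methods

## The mixing model and its marginal likelihood

The dual-isotope mixing model treats each nitrate sample's (δ¹⁵N, δ¹⁸O)
pair as a concentration-weighted convex combination of K candidate source
signatures plus fractionation and residual error:

```
X_ij = Σₖ p_k q_jk (S_jk + C_jk) / Σₖ p_k q_jk + ε_ij,
S_jk ~ N(μ_jk, ω_jk²),  C_jk ~ N(λ_jk, τ_jk²),  ε_ij ~ N(0, σ_j²).
```

Rather than sampling the latent S and C per observation, the package
integrates them out analytically (the standard treatment in this model
family), giving a Gaussian marginal with

```
mean_j(p) = Σₖ p_k q_jk (μ_jk + λ_jk) / Σₖ p_k q_jk
var_j(p)  = Σₖ p_k² q_jk² (ω_jk² + τ_jk²) / (Σₖ p_k q_jk)²
```

and total observation variance `var_j(p) + σ_j²`. The synthetic isotope
generator draws from exactly this marginal, so simulation and inference
are self-consistent by construction.

**Priors.** p ~ Dirichlet(1, …, 1) (uniform on the simplex) and
σ_j ~ half-normal with scale 5‰. Both are weakly informative at the scale
of nitrate isotope data; the Dirichlet concentration and the half-normal
scale are configurable.

**Concentration weights and fractionation.** q_jk default to 1 (no
concentration dependence) and fractionation defaults to zero — the usual
assumptions for nitrate source mixing — but both are read from the
sources CSV when supplied.

## MCMC: parameterization matters more than the kernel

The sampler is adaptive random-walk Metropolis, run as several lock-step
vectorized chains: per-chain scalar step sizes target a 0.2–0.4
acceptance rate during burn-in, and a proposal covariance is estimated
from the pooled burn-in history (refreshed every 250 iterations, frozen
at the end of burn-in so the sampling phase is a true Markov chain).

The non-obvious design choice is the coordinate system. With K = 4
sources and J = 2 isotopes the mean constraints leave a one-dimensional
weakly identified direction, so the posterior concentrates on a long thin
ridge inside the simplex. That ridge is **straight in p-coordinates** (for
the default unit concentration weights) but **curved** under log-ratio
transforms; covariance-adapted proposals in ilr coordinates keep stepping
off the curved ridge and stall (R̂ ≈ 1.2–1.9 at the default budget),
whereas sampling the first K−1 simplex coordinates directly — rejecting
proposals that leave the simplex, which is exact for a symmetric
proposal — lets the adapted covariance stretch along the straight ridge
(R̂ ≤ 1.01, ESS > 600 at the default budget). σ is sampled on its natural
scale with reflection at zero (|σ + step| is a symmetric proposal on the
half-line, so no Jacobian is needed), which keeps the near-zero region
compact instead of stretching it into a long log-scale tail.

Correctness of the sampled posterior is pinned by two independent
oracles in the test suite: dense grid quadrature over (p₁, σ) on
two-source/one-isotope problems (agreement of posterior mean and 95%
interval endpoints within 0.02) and the analytic behaviour of degenerate
cases (single source, symmetric mixtures, prior recovery with no data).

**Defaults.** 4 chains × 10,000 iterations, 5,000 burn-in, thinning 5.
Convergence is declared when every parameter has split-chain R̂ ≤ 1.05
and effective sample size ≥ 200 (computed with arviz); the flag is
reported, never silently enforced. With zero observations the model
returns its prior, which the tests use as a self-check.

## Synthetic scenarios: what they emulate, and what they do not

The shipped scenarios encode the study system's headline structure:

* `SCENARIO_DRY` — true proportions (AP, CF, SN, MS) =
  (0.439, 0.200, 0.200, 0.161): dry-season nitrate dominated by
  atmospheric deposition at 43.9%; the three remaining proportions are
  free simplex-completion choices.
* `SCENARIO_WET` — (0.300, 0.233, 0.203, 0.264): wet-season fertilizer at
  23.3% and manure & sewage at 26.4%.
* Default signatures (**synthetic stand-ins** — the study's field
  signature values are not published): (δ¹⁵N, δ¹⁸O) means of
  AP (0.5, 56.7), CF (3.9, 23.0), SN (11.608, 8.9), MS (34.9, 8.4) ‰ with
  SDs 1–3‰, zero fractionation, unit weights, and per-isotope residual SD
  1‰. Two constraints fixed this geometry once, before any fitting: the
  dry-season analytic δ¹⁵N mixture mean must equal the observed 8.94‰
  (solved exactly by the SN value), and the scenario truths must sit near
  the centre of the feasible segment of the weakly identified direction,
  so a flat prior does not bias the posterior mean along it. The MS δ¹⁵N
  of 34.9‰ is higher than typical literature manure/sewage values — a
  consequence of calibrating the mixture mean with AP at 43.9% — which is
  acceptable for a stand-in whose job is structural realism, not
  literature fidelity.
* `SCENARIO_COUPLING` — a single latent connectivity factor Z with
  loadings (TN 0.76, NO₃⁻ 0.79, NH₄⁺ 0.75, Chao1 −0.74, Shannon −0.72)
  and native margins from the dry season (TN 1.94 ± 1.22, NO₃⁻
  1.42 ± 1.91, NH₄⁺ 0.23 ± 0.44 mg/l; Chao1 3600 ± 500; Shannon
  5.5 ± 0.7; connectivity 0.18 ± 0.06, spanning the reported river index
  range). Every variable is r·Z + √(1−r²)·noise mapped affinely to its
  margin, which guarantees a positive-definite joint correlation
  structure for any loadings. Nitrogen concentrations are clipped at
  zero; at these margins clipping moves the TN mean by about +0.03 mg/l
  and its connectivity correlation from 0.76 to about 0.75 — inside every
  stated tolerance — while NH₄⁺, with mean only half an SD above zero, is
  distorted more (r ≈ 0.70) and is deliberately not used as a calibration
  surface.
* `SCENARIO_SEM` — linear-Gaussian structural equations in topological
  order with standardized coefficients: connectivity→nitrogen 0.43,
  nitrogen→microbial −0.42, population→wastewater 0.51, and three free
  completion edges at 0.30 (agriculture→nitrogen, wastewater→nitrogen,
  environment→microbial). The nitrogen→microbial path is simulated
  negative — consistent with the negative diversity correlations — and
  checked by magnitude. Endogenous residual SDs are auto-derived so every
  variable has unit variance; the standardized variables are then mapped
  affinely onto positive native margins (nitrogen as TN, the microbial
  axis as Shannon) because the watershed container requires non-negative
  concentrations, and standardized path coefficients are invariant to
  affine maps so the recovery contract is unaffected.
* Community tables: per-site log-normal relative abundances whose
  log-scale is exp(−loading·z/2) in the standardized connectivity z, then
  multinomial sampling at fixed depth (default 20,000 reads) — a negative
  loading makes high-connectivity sites less even, hence lower Shannon.
* Distance pairs: upper triangles drawn bivariate normal at the target
  correlation, shifted +4 into the positive range. These matrices are
  dissimilarity-like, not metric; Mantel statistics need no triangle
  inequality.

What the generators do **not** emulate: spatial autocorrelation among
sites, taxon–taxon interaction structure, compositional sequencing
artefacts, non-Gaussian margins, and any load-accounting (kg/year)
quantity — those come from an external watershed model and are out of
scope. Passing tests therefore demonstrate that the estimators recover
the structures they assume, not that field data meet those assumptions.

## Community statistics

Chao1 uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), defined
even without doubletons; the classical F₁²/(2F₂) form is an option.
Shannon is natural-log entropy; Simpson is reported as dominance Σp²
(lower = more even), with 1−D and 1/D also emitted. Bray–Curtis is the
dissimilarity for ordination and group tests — the standard choice in
amplicon ecology. PCoA double-centres −½D² and eigendecomposes;
proportions explained are relative to the positive eigenvalue sum, and
axis requests beyond the positive spectrum are truncated with a warning.
No rarefaction is applied; a warning is logged when site depths differ by
more than 10×.

Permutation tests default to 999 permutations and include the observed
statistic in the null (the "+1" convention), so p-values live in
(1/(1+n_perm), 1]. Mantel permutes rows and columns of the second matrix
jointly, one-tailed; a 4×4 exhaustive-enumeration oracle pins the
p-value. ANOSIM uses Clarke's statistic R = (r̄_between − r̄_within) /
(n(n−1)/4) on ranked pairwise distances — note the divisor is n(n−1)/4,
which is what makes complete separation give exactly R = 1. For Mantel
tests of community structure against a single environmental variable,
the scalar is turned into a distance by absolute difference
(`scalar_to_distance`).

## Piecewise SEM

"Piecewise" structural equation modelling here means one ordinary
least-squares submodel per endogenous variable on z-standardized
variables: the reported numbers are standardized path coefficients with
slope-t p-values and per-endpoint R². There is no global covariance fit,
no latent variables and no global fit index — this matches how path
diagrams with per-path coefficients and per-endpoint R² are produced in
practice, and it makes single-parent coefficients equal the Pearson
correlation of the pair (a property the tests check to 1e-10). Collinear
parent sets (condition number > 1e8) raise a conditioning error rather
than returning unstable coefficients. Raw p-values are reported without
multiplicity correction. Indirect effects are products of coefficients
along a directed path.

Note that per-endpoint R² in a path model is not recoverable from the
path coefficients alone once unmodelled covariates exist, so the package
reports R² but no scenario calibrates to it; scenario targets are the
path coefficients themselves.

## Problem sizes and numerical choices

The acceptance script and tests use the study-scale sizes: 100 isotope
samples per seasonal mixing fit (4 chains × 10,000 iterations), 2,000
rows for correlation recovery, 5,000 for SEM recovery, 20 seeded pairs of
60-item distance matrices with 999 permutations each for the Mantel mean,
and 20,000 / 50,000 draws for generator moment checks. A full acceptance
run completes in well under a minute on one core.

Degenerate inputs fail fast with typed errors: off-simplex proportions,
negative SDs or concentrations, all-zero count vectors, zero-variance
correlation inputs, cyclic edge sets, singleton ANOSIM groups and
mismatched distance labels all raise subclasses of `NitracerError`.
Zero total observation variance in the likelihood returns −inf rather
than raising, so the sampler can reject such states naturally. Posterior
draws are renormalized to the simplex at 1e-9 tolerance before being
returned.

## Known limitations

* With four sources and two isotopes the source split within the
  non-point category is weakly identified; credible intervals for CF and
  SN are honest about this (they are wide), and the posterior mean along
  the weak direction is prior-sensitive. Users supplying their own
  signatures should check the implied geometry.
* The Mantel/ANOSIM permutation loops are O(n_perm · n²); for thousands
  of sites a blocked or vectorized permutation scheme would be needed.
* The pipeline's seasonal stratification is a simple column split; the
  full region × season stratification of field studies is available by
  running `fit-mix --group-by region` on user data.
* Written result tables round to 6 significant digits; typed data formats
  round-trip at 12.
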