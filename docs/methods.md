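# Methods

## Model

For each inbred line *i* with centered phenotypes *y<sub>i,P</sub>* (a
phenological trait, days) and *y<sub>i,A</sub>* (an influenced trait, cm),
the recursive bivariate structural model is

```
y_i,P = x_i,P' β_P + u_i,P + e_i,P
y_i,A = L(y_i,P) · y_i,P + x_i,A' β_A + u_i,A + e_i,A
```

with gene-incidence design vectors **x** (intercept plus 0/1 dummies coded
against a reference line; the phenology-gene columns appear in both
designs, the influenced trait's own genes only in the second), polygenic
effects (**u**<sub>P</sub>, **u**<sub>A</sub>) ~ MVN(0, **G** ⊗ **K**) with
**K** the VanRaden genomic relationship matrix, and residual pairs
(e<sub>P</sub>, e<sub>A</sub>) ~ N₂(0, **R**).  The structural matrix is
strictly lower-triangular with unit diagonal, so the transformation from
residuals to phenotypes has unit Jacobian and the joint density of a
line's phenotype pair is the bivariate normal density of the structural
residuals.  Setting L ≡ 0 yields the ordinary bivariate linear model
(OLM); the likelihoods nest exactly.

The influence function L(y) — the trait-value-dependent slope (cm/day)
with which the phenological phenotype enters the second equation — is a
cubic B-spline with eight basis functions on twelve knots: four coincident
knots at each boundary and four equally spaced interior knots.  Knots are
placed per dataset from the observed centered range [y_min, y_max] of the
phenological trait by a midpoint rule: with interval δ = range/4, the
lower boundary sits at y_min − δ/2 and the upper at y_max + δ/2, so the
observed extremes are the midpoints of the outermost non-empty intervals
and all five intervals are equal.  Eight basis functions keep the
trajectory smooth by construction; the count is exposed as a configuration
knob (`ModelSpec.n_basis`) but there is no data-driven selection — a
phenological influence is not expected to meander, and the
second-difference prior below penalises curvature anyway.

Evaluation uses the Cox–de Boor recursion with half-open intervals and the
upper boundary mapped into the last non-empty interval, so the basis sums
to one on the entire closed range.  L is never evaluated outside the knot
range (the counterfactual predictor clamps, with a flag).

## Priors

* **G**, **R**: inverse-Wishart with 4 degrees of freedom and scale equal
  to half the phenotypic covariance matrix of the two traits; for a 2×2
  matrix ν − p − 1 = 1, so the prior mean equals the scale.  For the
  zero-residual-covariance variant the scale off-diagonals are dropped:
  that variant attributes the inter-trait covariance to the influence
  term, so seeding the genetic-covariance prior with the full observed
  covariance would double-count exactly the signal the constraint exists
  to isolate (observed consequence: a uniform downward bias of the
  recovered influence level).
* Fixed effects β: improper flat.
* Spline weights: P₀, P₁ ~ N(0, 1000 σ²_P); P_m | P_{m−1}, P_{m−2} ~
  N(2P_{m−1} − P_{m−2}, σ²_P) for m ≥ 2 — a second-difference random walk
  that penalises curvature but is flat on level and trend.
* σ²_P: a *proper* weakly-informative scaled-inverse-chi-square prior
  with 1 degree of freedom and scale 0.01 (cm/day units squared — a
  typical curvature step of 0.1).  The improper 1/σ² limit is unusable in
  this model: when the likelihood leaves the weights unconstrained, the
  Gibbs conditional contracts E[σ²] geometrically (by 1/3 per sweep) and
  the chain collapses to σ² → 0, freezing the influence function at an
  arbitrary small offset with a spuriously narrow band — the classical
  improper-hierarchical-variance pathology.  The conjugate conditional is
  Inv-χ² with df = 9 and scale sum the six squared second differences,
  (P₀² + P₁²)/1000, plus the prior contribution; a floor of 1e−12 on the
  statistics guards the exact-zero corner (warned when hit).

## Sampler

Metropolis-within-Gibbs with a fixed update order per iteration:
β_P, β_A → **u** → **G** → **R** → P₀…P₇ → level move → σ²_P.
All randomness flows through one seeded `numpy` generator in documented
order; identical seeds give bit-identical chains.

* **β (Gibbs)** — conditioning trait-on-trait: given the partner trait's
  residual, the target trait's residuals are independent normals, so the
  conditional is normal around the OLS solution on the partner-adjusted
  working response (for the influenced trait the working response is
  y_A − L(y_P)·y_P throughout).
* **u (Gibbs, joint)** — in the eigenbasis of **K** (one symmetric
  eigendecomposition, reused) the 2n-dimensional conditional factorises
  into n independent bivariate normals with prior precision G⁻¹/λ_j and
  data precision R⁻¹; all 2×2 algebra is vectorised closed-form.
* **G, R (Gibbs)** — conjugate inverse-Wishart draws,
  IW(4 + n, S₀ + UᵀK⁻¹U) and IW(4 + n, S₀ + EᵀE), sampled by a 2×2
  Bartlett construction.  The zero-residual-covariance variant pins
  R₁₂ = 0 and draws each variance from the p = 1 inverse-Wishart
  (scaled-inverse-chi-square) conditional with the matching scale entry.
* **weights (Metropolis)** — random-walk proposal N(P_m, σ²_prop) with
  σ²_prop = 0.04, fixed (no adaptation).  The likelihood ratio is
  evaluated only over lines whose phenological phenotype lies in the
  support of basis m (basis functions vanish outside their five defining
  knots); the prior ratio includes every random-walk term in which P_m
  appears.  Acceptance rates are logged per weight index.
* **level (generalized Gibbs)** — a constant shift δ of L leaves the
  likelihood *exactly* invariant once β_A, u_A, G and R are
  co-transformed (the phenology design is nested in the influenced
  design; the residual/genetic covariances transform by the unimodular
  T = [[1,0],[−δ,1]]).  The level of the influence function is therefore
  informed only by the priors, and single-site updates freeze on this
  orbit.  The sampler moves along the orbit with a generalized-Gibbs step:
  all transformation Jacobians are one and the inverse-Wishart
  log-determinants are invariant, so the conditional density of δ along
  the orbit is Gaussian (from the two inverse-Wishart trace terms and the
  two boundary weight-prior terms) and is sampled exactly.  The move is
  skipped under the zero-residual-covariance constraint — the constraint
  breaks the invariance, which is precisely why it identifies a constant
  influence — and when the designs are not nested.

This orbit structure is the model's version of the classical
constant-influence/residual-covariance confounding in recursive
two-trait systems: the *shape* of L is identified by the data (a
value-varying influence generates line-specific covariance between the
traits), the *level* rides on the priors.  Consequences embraced by the
package: recovery of L is scored by correlation (level-free); the
replicate studies simulate from pilot-fit posterior means, so the truth
lies on the estimator's identified manifold; a constant influence is only
recoverable under the zero-covariance constraint.

Initialization: β = 0, u = 0, G = R = prior scale matrices, P = 0,
σ²_P = 1 — chosen for determinism, not stated to matter beyond burn-in.
Default chain settings are 1.1×10⁶ iterations, 10⁵ burn-in, thinning 100;
`MCMCConfig.desk()` (5×10⁴ / 5×10³ / 10) is the interactive and
simulation-study scale.  Retained draws store per-line log-likelihoods
for WAIC.  A non-finite likelihood at a retention point aborts with a
state dump.

## Model comparison

Variance-form WAIC from the stored per-line log-likelihood draws:
lppd = Σ_i log(mean_s exp ℓ_is) (log-sum-exp), p_waic = Σ_i Var_s(ℓ_is)
with the unbiased (ddof = 1) variance, WAIC = −2(lppd − p_waic).  "Mean
log likelihood" is reported as the posterior mean of the total
log-likelihood over retained draws (one of several consistent readings;
documented in output).  The comparison delta is WAIC(NSE) − WAIC(OLM),
negative favoring the nonlinear model.  Empirical quantiles everywhere
use numpy's default linear-interpolation convention.

## Reporting layer

Major-gene effects are reported at twice the fitted allele-substitution
coefficient (homozygous inbreds carry two copies), applied uniformly to
haplotype dummies as well; raw coefficients are stored alongside.  An
effect is called non-significant iff 0 lies within the posterior 2.5–97.5%
interval.  Identifiability is monitored by the Pearson correlation of each
weight chain with the R₁₂ chain.  The counterfactual predictor shifts a
line's design row, propagates Δy_P = Δxᵀβ_P per draw, clamps the edited
phenology into the knot range (flagged), and reports the posterior of the
new influence and the influenced trait's deviation from the panel mean.

## Synthetic data

The generator emulates a diverse inbred cultivar panel; nothing real is
bundled.  Defaults (chosen once, on the scale of the motivating rice
panel):

* 110 lines, 3,102 biallelic homozygous markers; 20 founder genotypes in
  two subpopulations (allele frequencies Uniform(0.1, 0.9) with offsets);
  each line descends from a founder with 15% of markers resampled.
  Families of close relatives are essential, not decoration: without
  near-zero kinship eigenvalues the genetic and residual covariances are
  statistically confounded and no variance-component method can work.
* An early-phenology family (~8% of lines, like nine cultivars of 110)
  carrying two private large-effect alleles (−12 and −15 days; the second
  segregates within the family) and a line-specific polygenic earliness
  shift of mean −10 days — the bimodal phenology distribution and the
  negative-u_P × positive-L contamination channel that motivate the
  model.
* Gene effects: phenology genes N(0, 12²) days; their *direct* effects on
  the influenced trait N(0, 2²) cm (mostly indirect is the point); the
  influenced trait's own major genes (dwarfing-gene analogues) N(0, 8²) cm.
* G = [[90, 20], [20, 50]], R = [[25, 5], [5, 30]] (days², day·cm, cm²):
  residual covariance 5 and a phenotypic inter-trait correlation above
  0.5, on the reported scale of the motivating data.
* Influence schemes: `nonlinear` (a decreasing weight vector crossing
  zero, strongest for early lines), `linear` (constant 1.2 cm/day),
  `none` (0); 20 replicate datasets by default.

Phenotype generation redraws a line's residual pair until the phenology
falls inside the pre-set knot bounds (truncation only in the tails; redraw
counts logged), then re-centers both traits and stores the removed means
with the truth.

The replicate recovery study (`study_pipeline`) mirrors the original
design: a stand-in "observed" dataset is simulated, the spline model (or
the linear baseline, for the linear/no-influence schemes) is pilot-fitted
to it, and the pilot's posterior means — fixed effects, per-line polygenic
effects, residual covariance, fitted weights — become the generating
truth, with only residual pairs redrawn per replicate.  Recovery is scored
by Pearson correlation between true and posterior-mean values of the
per-line influence L(y_i,P), the per-line polygenic effect on the
influenced trait, and the influenced trait's gene coefficients (intercept
excluded), plus the WAIC delta.

What passing these studies does **not** show about real data: the
generator draws gene incidences independently of the marker background
(no linkage disequilibrium between major genes and the genome-wide
markers), uses a two-level family structure rather than a real pedigree,
has no genotype-environment interaction or multi-location structure, and
its truth is calibrated to the estimator's own identified manifold — so
the studies validate internal consistency and the comparative behavior of
the two models, not absolute level recovery against an arbitrary external
truth.

## Numerical choices

* Kinship: mean imputation of missing marker genotypes per marker,
  monomorphic markers dropped (both logged); diagonal jitter
  (default 10⁻⁶ × mean diagonal, escalated tenfold until a Cholesky
  succeeds, recorded in the fit manifest).
* Likelihood and all 2×2 covariance algebra in closed form; residual
  covariance must be positive definite or the likelihood raises.
* Lines missing either trait are dropped before centering (complete-case
  per dataset); line IDs are aligned across files by intersection with
  the phenotype file's order preserved.
* Output tables are TSV with 10 significant digits; CSV accepted on read.
* Desk-scale study settings used by the acceptance checks: n = 150 lines,
  600 markers, 5 replicates, chains 40,000/10,000/30 (1,000 retained
  draws) for the scheme studies and 50,000/5,000/10 for the
  linear-baseline recovery check — sizes chosen so the full suite runs on
  a laptop-class single core while leaving the studies' contrasts
  resolvable.

## Known limitations

* Exactly two traits, one-way influence; no feedback, no multi-location
  joint fit, no dominance (heterozygotes enter the kinship as 0 but the
  gene designs are 0/1).
* The level of L is prior-identified (see above); trajectories should be
  read for shape, and constant influences require the zero-covariance
  variant.
* σ²_prop is fixed; very differently scaled data may need a different
  proposal variance (acceptance rates are logged for exactly this check).
* WAIC is the only comparison criterion implemented (no LOO-CV, Bayes
  factors, or formal trajectory tests).
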