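# Methods

## The twin design and what it identifies

`twinclocks` fits classical twin variance-component models to same-sex
monozygotic (MZ) and dizygotic (DZ) pairs. A phenotype — here, an epigenetic
age metric — is decomposed into latent standard-normal sources loading
through path coefficients:

* **A** additive genetic, shared 1.0 within MZ pairs, 0.5 within DZ pairs;
* **C** common environment, shared 1.0 by both zygosities;
* **D** dominance genetic, shared 1.0 (MZ) / 0.25 (DZ);
* **E** unique environment plus measurement error, unshared.

With twins reared together, C and D are not jointly identifiable: the design
supplies only two within-pair covariances (MZ, DZ) to separate them, so
models come from the ACE family (ACE, AE, CE, E) or the ADE family
(ADE, AE, E). Squared paths are variance components; heritability is
h² = a²/V for the ACE family and (a² + d²)/V for the ADE family, with
V = a² + c² + d² + e².

The implied pair moments are

    var  = a² + c² + d² + e²
    cov  = a² + c² + d²          (MZ)
    cov  = ½a² + c² + ¼d²        (DZ)

and the likelihood is the product of bivariate-normal pair densities.
Pairs with one missing twin contribute their marginal univariate density
(full-information maximum likelihood); nothing is imputed or dropped beyond
that.

## Longitudinal bivariate Cholesky model

For the same trait measured at two waves ~5 years apart, each component K
loads through a lower-triangular 2×2 matrix `[[k11, 0], [k21, k22]]`:
k11² is the wave-1 variance of K, k21² the wave-2 variance transmitted from
wave 1, k22² the wave-2 innovation, and k11·k21 the cross-wave covariance.
The within-twin 2×2 block is Σ_K L_K L_Kᵀ; the cross-twin block scales each
component block by its zygosity sharing (E contributes nothing). Variable
order is (twin1-wave1, twin1-wave2, twin2-wave1, twin2-wave2), and pairs
with any subset of the four entries observed contribute the density of the
observed subvector.

Derived summaries:

* wave heritabilities  h²₁ = a11²/V1, h²₂ = (a21² + a22²)/V2;
* cross-time component correlations  R_K = k11·k21 / √(k11²·(k21² + k22²)),
  defined as 0 (and flagged) when either wave's K variance vanishes;
* phenotypic cross-wave correlation  R_ph = Σ_K k11·k21 / √(V1·V2), and its
  decomposition P_K = (k11·k21)_K / Σ_K (k11·k21) with ΣP_K = 1 whenever
  R_ph ≠ 0. On the standardized scale (V1 = V2 = 1) this reduces to the
  identity R_ph = Ra·√(h²₁h²₂) + Rc·√(c²₁c²₂) + Re·√(e²₁e²₂), which the
  test suite asserts to 1e-10;
* model-implied cross-twin cross-trait (CTCT) correlations
  MZ: (cov_A + cov_C + cov_D)/√(V1·V2), DZ with ½/¼ genetic scalings.
  The *observed* CTCT is the Pearson correlation over double-entered pairs
  — each pair contributes (twin1 wave 1, twin2 wave 2) and (twin2 wave 1,
  twin1 wave 2) — with a Fisher-z interval that conservatively uses the
  number of pairs, not entries, as the effective sample size. Both versions
  are reported because published tables rarely state which convention was
  used.

## Preprocessing

Age acceleration (AA) is the residual from an OLS regression of a clock on
six blood-cell proportions and chronological age, fitted with an intercept
on all individuals with complete predictors; rows with a missing predictor
receive a missing AA and are excluded from the fit. Constant predictor
columns (e.g. a cell fraction that never varies) carry no information beyond
the intercept and are given a zero coefficient rather than raising a
collinearity error; genuinely collinear non-constant columns are named in
the error. Residualization may be run pooled across waves (default) or per
wave — the appropriate choice depends on how the source data were processed,
and both are supported.

Metrics are z-scored before modelling (sample SD, n−1 denominator; recorded
in the output parameters). Covariate adjustment for the twin models (sex for
the four AA metrics; sex and chronological age for a pace-of-aging metric
that is not itself age-residualized) enters the *means model* of every
fitted model — including the saturated reference — with coefficients shared
across zygosity and twin order, not through a second residualization pass.

## Estimation and numerics

* **Parameterization.** Paths (a, c/d, e) are optimized unconstrained;
  squares are reported, and the sign indeterminacy is resolved by reporting
  absolute values (bivariate: diagonal entries k11, k22 ≥ 0, k21 free).
* **Optimizer.** Five starts — a moments-based start (Falconer-style
  component guesses from double-entered group correlations; pooled OLS for
  means) plus four jittered copies with a fixed jitter seed — each run
  through L-BFGS-B, then a Nelder-Mead polish of the best. Convergence
  requires a finite objective and small gradient norm; failures are flagged
  on the fit object and exit code 3 in the CLI, never silent.
* **Positive definiteness.** Path parameterizations imply a PD covariance
  whenever e-paths are nonzero; degenerate proposals return a large finite
  objective (1e12) so line searches retreat.
* **Saturated models.** Per-zygosity free means and covariances
  (log-SD/atanh-r for the 2×2 case; a log-diagonal Cholesky factor for the
  4×4 case), the −2lnL reference for every likelihood-ratio test. With a
  singleton twin the slot-specific saturated moments are not attributable
  to a slot, so singletons contribute a slot-averaged marginal density.
* **Model selection.** Fit saturated, ACE and ADE; pick the family by AIC;
  fit the family's sub-models. A candidate is admissible when its LRT
  against its parent (E→AE→ACE/ADE→saturated lattice) and against the
  saturated model are both non-significant at α = 0.05; lowest AIC wins,
  ties to fewest parameters; if nothing is admissible the full family model
  is returned with a warning. LRT statistics are floored at zero and
  referred to a naive χ² — the common software default — even though
  variance components sit on the boundary under the null, which makes the
  test conservative toward the larger model.
* **Confidence intervals.** Profile likelihood: the bound is where the
  profiled −2lnL rises by χ²₁(0.95) = 3.841, found by bracketed
  root-finding; share bounds clip to [0,1], correlation bounds to [−1,1].
  Profiling reparameterizes the constrained quantity exactly (total
  variance × shares for h²; per-component wave variances with fixed
  correlation for Ra/Re) so the constraint is honored by construction. If
  profiling fails the interval falls back to the delta method and the fit
  is flagged (`ci_method = "delta"`).

## Synthetic data

The generator draws each pair directly from the model-implied multivariate
normal for its zygosity — exactly equivalent in distribution to simulating
latent A/C/D/E scores (a latent-draw variant exists for didactic traces)
and easier to verify against closed-form moments. Defaults mirror the study
design being emulated: same-sex pairs (sex is a pair-level Bernoulli(0.5)
draw), pair-level age uniform on 19–82 years, covariate effects zero unless
requested so recovery experiments are clean. Recovery experiments default
to 4000 MZ + 4000 DZ pairs: large enough that Monte-Carlo error (~±0.01 on
a variance share) is well inside reporting precision, small enough that a
simulate-plus-fit cycle takes seconds.

What the generator does *not* emulate: non-normal phenotypes, array batch
effects, probe-level noise, selection into the cohort, or missingness that
depends on the phenotype. Passing recovery tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not
robustness of the published estimates to violations of them.

## Known limitations

* Boundary estimates (ĉ² = 0) make naive χ² LRT p-values conservative; no
  mixture-χ² correction is applied.
* The observed-CTCT Fisher interval treats double-entered rows as one
  observation per pair, which over-covers slightly.
* Only 1- and 2-wave same-trait models are supported — no ≥3-wave Cholesky,
  simplex/growth models, sex-limitation, or cross-trait designs.
* Profile CIs are recomputed by repeated constrained optimizations and
  dominate runtime on large inputs; they can be disabled (`compute_ci=False`,
  `--no-ci`).
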