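# Methods

## Model

`adoptsem` treats genotypes as continuous, centered polygenic scores and the
offspring phenotype as a continuous, pre-residualized trait; only covariance
structure is modelled (no means). Each of the eleven family structures
defines which relatives' scores are observed; everything else is latent and
marginalized analytically.

All observed variables are linear in a small set of independent sources: the
founder genotypes (the parents, biological and — in adoptive structures —
adoptive), a segregation deviation, and a phenotype residual. The founder
covariance matrix places Φ on the diagonal, ρ within each couple (the same
value for biological and adoptive couples), and — in G8–G11 only — the fixed
relatedness covariance *r* on the designated adoptive-biological pair.
Standard path-tracing applies: a trace may contain at most one double-headed
arrow, so ρ and *r* never chain. Offspring genotype follows
Zo = ½·mother + ½·father + N(0, Φ/2), which makes Var(Zo) = Φ + ½ρ under one
round of assortment; no equilibrium model of multi-generation assortment is
attempted. Prenatal paternal effects are fixed at zero by design.

The residual phenotype variance is ε₁² in biological families (G1–G4) and
ε₂² in all adopted structures (G5–G11), accommodating differences in the
range of environments adoptees experience.

## Estimation

Each group g contributes the normal-theory covariance ML discrepancy

F_g = n_g · [ ln|Σ_g(θ)| + tr(S_g Σ_g(θ)⁻¹) − ln|S_g| − p_g ],

weighted by n (not n−1) so that the total objective sits on the −2·Δlog-
likelihood (chi-square) scale and, when fitted to population matrices,
equals the noncentrality parameter directly. Sample covariances are
divide-by-n for the same reason. Because every structure fixes exactly which
variables are observed, per-group sample covariances are sufficient
statistics; no raw-data missing-value likelihood is needed.

Minimization uses L-BFGS-B with an exact analytic gradient: since
Σ = Λ D Λᵀ with the tiny loading matrix Λ (effects enter only the phenotype
row) and source covariance D (Φ, ρ, r, ε² enter only here), every ∂Σ/∂θ is
closed-form, and ∂F/∂θ = n·tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)∂Σ]. A short safeguarded
Newton polish (using a central-difference Hessian of the analytic gradient)
tightens solutions to ~1e-10 in the parameters, which matters for the
deterministic pseudo-true analyses below. Non-positive-definite trial Σ
receives a large penalty (a rejected step); up to five seeded, jittered
restarts run on non-convergence. Variance parameters are bounded below at
1e-8 rather than log-transformed so boundary solutions remain visible in the
diagnostics. Start values are moment-based: effects 0.05, Φ the pooled
observed genotype variance, ρ the observed spousal covariance in trios (else
0), residuals half the pooled phenotype variance.

Standard errors come from the observed information of the objective,
Cov(θ̂) = 2 H⁻¹, and are withheld when H is not positive definite. Wald
z-tests are provided per parameter; the prenatal/postnatal hypothesis tests
and all power calculations use the likelihood-ratio chi-square. `r` is never
estimated: it is fixed at 0 by default and at its known value (0.5 Φ
sibling, 0.125 Φ cousin) when relatedness is modelled, since in practice the
relationship type — not its covariance — is what a study could ascertain.

Local identification is checked numerically: the rank of the Jacobian of all
stacked implied-covariance entries with respect to the free parameters,
evaluated at a generic interior point (all paths nonzero and distinct).
Flat directions are reported; biological structures alone leave the
direction γm ↔ βm (and ε₂²) unidentified, while adding any adopted group
with trios restores full rank. The power calculator refuses (rather than
returning α) when asked for an unidentified configuration.

## Power

The noncentrality parameter for testing a constraint (e.g. γm = 0) is the
minimized total discrepancy of the reduced model fitted to the exact
population covariance blocks at the true parameters; the full model fits
them perfectly, so its value is 0. Power is P[χ²(ν, ς) > χ²₁₋α(ν)] with
ν the number of constrained parameters. The NCP is exactly linear in the
group sizes.

For the headline calculations the convention is Φ = 1 with residual
variances set so total phenotypic variance is 1 in both family types;
"variance explained" by an effect is then its squared path coefficient. The
inverse search (`effect_for_power`) bisects on the path coefficient until
the power matches the target within 1e-4, renormalizing residuals at every
trial value. Under UK-Biobank-like sizes (1000 trios, 4000 mother-offspring
pairs, 1800 father-offspring pairs, 300 000 biological singletons, 6000
adopted singletons, 50 biological-mother-adoptee pairs) this yields ≈ 79%
power at 1.5% (prenatal) and 0.9% (postnatal) variance explained, and the
80%-power search returns ≈ 1.54% and ≈ 0.93%.

## Simulator

`simulate_families` draws founder scores jointly multivariate normal from
the structure's founder covariance, applies the Mendelian rule for Zo and
the linear phenotype model. Scores are Gaussian throughout — no discrete
allele counts, linkage disequilibrium, selection, or non-random placement of
adoptees — so passing simulation tests demonstrates correctness of the
covariance algebra and estimator calibration under the model's own
assumptions, not robustness to features of real genotype data (allelic
discreteness, ascertainment, stratification). Sibling/cousin relatedness is
induced directly through the founder covariance *r* rather than by building
explicit grandparents. A master seed expands into per-group seeds via
`SeedSequence.spawn` in sorted structure-code order, making every table
reproducible row by row.

`simulate_misspecified_adoptees` mixes round(f·n) families generated under a
G8–G11 scenario with (1−f)·n plain G5 families and labels everything G5 —
the analyst cannot tell them apart, reproducing misclassification of
adoptees raised by relatives. The as-analyzed covariance of the mixture is
(1−f)·Σ_G5 + f·Σ_scenario since all variables are centered.

## Misspecification analysis

`misspec_bias_study` repeats the full pipeline (simulate → covariances → fit
full and reduced → LRT) over a grid of misclassified fractions, under either
the misspecified analysis (everything pooled as G5) or the corrected one
(related adoptees analyzed as their true structure with *r* fixed).
`pseudo_true_fit` is its deterministic twin: the analysis model fitted to
the exact population covariances of the generating mixture, giving the
replication-free limiting estimates.

For the deterministic equivalence checks (maternal- vs paternal-side
relatedness being indistinguishable, zero bias when the relevant postnatal
effect is absent, exact recovery when *r* is modelled) the analysis
configuration deliberately omits G7 (headline sizes G1–G5 only). Reason: the
G8/G9 (and G10/G11) scenario pairs imply identical genotype-phenotype
covariances but phenotype variances differing by 2·γm·βm·r·f (respectively
2·γm·βp·r·f); when the mixture is the only adopted group, the free ε₂²
absorbs that offset exactly and the remaining estimates coincide to
optimizer precision, with the closed-form limit

γ̂m = γm + f·r·β/(Φ+ρ),  β̂m = βm − f·r·β/(Φ+ρ)  (β = βm for G8/G9, βp for G10/G11).

With further adopted groups sharing ε₂² (e.g. G7) the equivalence is only
approximate. The stochastic bias study keeps the full size configuration
including G7, where the same conclusions hold directionally.

## Problem sizes and defaults

Replicated studies default to a tenth of the headline group sizes with 200
replicates (1000 for type I error calibration), preserving every qualitative
conclusion at desk scale; the CLI `study` command applies this scaling
unless `full_scale: true` is set. The acceptance script's quantities are
fully deterministic and run in seconds.

## Known limitations

No dominance, epistasis, X-linkage, sibling shared environment,
multi-generation assortment, or estimation of unknown mixtures of
relationship types (f and r are design inputs, never estimated). The
likelihood is normal-theory: heavy-tailed phenotypes would call for robust
corrections that are not implemented. Wald and LRT p-values are asymptotic;
with very small groups (e.g. 5 families) they are approximate, which is
visible as mild finite-sample noise in the calibration studies.
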