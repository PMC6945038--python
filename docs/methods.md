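# Methods

## Problem and pipeline

`capescan` discovers pairwise genetic interactions (epistasis) that
influence several related traits at once, in cohorts far too small for a
naive exhaustive two-locus search to be well powered. The pipeline has
two halves:

1. **Filtering.** All marker pairs are scanned exhaustively per trait
   with the two-locus interaction model, and markers are reduced to a
   candidate set that is both *epistatic* (participates in significant
   interactions) and *pleiotropic* (those interactions touch more than
   one trait).
2. **Influence inference.** Traits are combined into orthogonal
   eigentraits by SVD; pairwise regressions on the two leading
   eigentraits are reparametrized into directed marker-to-marker
   influence coefficients, whose significance is assessed by permutation
   with FDR control. Significant directed edges form the interaction
   network.

## Models

### Two-locus interaction model

For dominant-coded markers `x1, x2 ∈ {0, 1}` and a response `y`:

    y = β0 + β1·x1 + β2·x2 + β12·x1·x2 + ε

The filtering scan tests `β12 = 0` with the OLS t-test on `n − 4`
degrees of freedom. Because the binary design saturates the four
two-locus genotype cells, the OLS solution is the cell-mean contrast

    β12 = ȳ11 − ȳ10 − ȳ01 + ȳ00,   Var(β12) = σ²·Σ_g 1/n_g,

and all cell counts and sums for *all* pairs come from the matrix
products `AᵀA` and `Aᵀdiag(y)A` of the genotype matrix `A`. This gives
an exhaustive scan in matrix-multiplication time that is numerically
identical to per-pair OLS (verified against an independent
statsmodels-based route to ~1e-15 in p). A pair is estimable when all
four cells are populated and the residual sum of squares is positive;
rank-deficient designs (e.g. duplicated markers) and constant traits are
flagged, never raised.

### Pleiotropic candidate selection

Given per-trait sets of significant pairs (default α = 1e-6), selection
proceeds in stages: (1) pairs significant for more than one trait
contribute both members; (2) for t = #traits down to 2, individual
markers whose significant interactions span exactly t distinct traits
are added — their single-trait partners are not. Within a stage markers
are ranked by best supporting p, ties broken lexicographically by marker
ID, and selection stops at K markers (default 1500; synthetic tests use
20–50). The stage ranking and tie-break are our own determinism choices;
the staging logic itself follows the hub-keeps/partners-drop semantics
of the filtering scheme.

### Eigentraits

The trait matrix (binary traits included) is column-standardized and
decomposed as `Y_std = U·S·Vᵀ`. Per-eigentrait variance explained is
`S²ᵢ/ΣS²`. Sign ambiguity is fixed by orienting each `V` column so its
largest-magnitude loading is positive. Regressions use the
variance-weighted scores `U·S`, so rotating per-ET effects back to trait
space is simply `V @ effects` and reproduces direct trait-space
regression coefficients exactly when all ETs are selected. The
delta/m influence parameters below are invariant to any per-ET
rescaling (scaling an ET scales the corresponding row of the
main-effect matrix and the interaction vector equally), so this
convention affects only back-rotation bookkeeping.

Quantitative traits are rank-Z normalized (`Φ⁻¹((r − 0.5)/n)`, average
ranks for ties; Blom offset available) before the SVD; binary traits are
standardized but not rank-transformed.

### Directed influence (delta/m reparametrization)

For each pair, the interaction model is fitted per eigentrait (with sex
as an additive covariate whenever sex is not itself a pair member). With
rows indexed by ET and columns by marker, the main-effect matrix
`M = [[β1¹, β2¹], [β1², β2²]]` and interaction vector
`b = (β12¹, β12²)` define

    (δ1, δ2)ᵀ = M⁻¹ b,
    δ1 = m12(1 + δ2),   δ2 = m21(1 + δ1)
      ⇒ m12 = δ1/(1 + δ2),   m21 = δ2/(1 + δ1).

δ measures how much one marker's presence rescales the other's
phenotypic effects; m12/m21 are the directed influences. A positive m is
an *enhancing* interaction, a negative m *suppressing*
(less-than-additive). The matrix-index convention (rows = ETs,
columns = markers) is the one that yields a solvable 2×2 system with two
eigentraits; exactly two ETs are supported.

Singularity handling: `|det M| ≤ 1e-10·‖M‖²` marks the pair
non-estimable; `|1 + δ| ≤ 1e-10` marks that direction non-estimable.
Both return flagged results, not exceptions.

**Identifiability.** The reparametrization assumes the two markers have
linearly independent effect profiles across the two eigentraits — M
must be well conditioned. Two regimes degrade it: markers with
(near-)proportional trait profiles, and complete suppression, which
places δ at the pole of m = δ/(1 + δ) where the reverse direction is
undefined and estimates near the pole flip sign under noise. Reciprocal
(mutual) suppression drives both deltas toward that pole
simultaneously and is similarly unstable. Partial suppression of a
marker with a distinct profile is the regime in which the method is
reliable, and the planted-network generator (below) uses it.

### Error propagation

SE(m12), SE(m21) are obtained by propagating the per-ET OLS coefficient
covariances (3×3 blocks for β1, β2, β12; cross-ET covariance set to
zero, justified by ET orthogonality and validated against a parametric
bootstrap) through the composite map β → δ → m with a second-order
multivariate Taylor expansion:

    Var(m) ≈ gᵀΣg + ½·tr(HΣHΣ)

with gradient g and Hessian H evaluated by central finite differences
(relative step 1e-4, floor 0.1). On well-conditioned simulated pairs
(n = 2000) the Taylor SE agrees with a 1000-draw parametric bootstrap
within 20%, and doubles when the residual SD doubles.

### Significance

The null distribution pools standardized statistics `m/SE` from both
directions over repeated joint permutations of the eigentrait rows
relative to the genotypes (which breaks all genotype–trait association
while preserving trait covariance). Whole permutation batches are
collected until the requested size is reached (default 1e5 at desk
scale; 1e4 in tests). Two-sided empirical p-values use the add-one rule
`p = (1 + #{|null| ≥ |stat|})/(N + 1)` — never zero, p = 1 at stat = 0 —
and Benjamini–Hochberg controls the FDR across all candidate directed
edges (threshold q < 0.05).

A property worth knowing: the null distribution of `m/SE` is *not*
symmetric about zero — it is left-skewed, because under 0/1 coding the
OLS interaction estimate is negatively correlated with the main-effect
estimates, and the correlation propagates through δ = M⁻¹b. This does
not affect validity: the permutation null reproduces the sampling
distribution of observed statistics on a null cohort (two-sample KS
agreement), empirical p-values are calibrated, and full-pipeline runs on
global-null cohorts return empty networks.

### Additive predictions

For a significant pair and a raw trait, the four two-locus genotype
groups are summarized (mean, SE, count) and compared with the additive
expectation: predicted double-alternate effect `β1 + β2` (relative to
the reference group, intercept subtracted), with an error band equal to
the sum of the standard errors of the four group means. With equal group
SEs the band is about twice the SE of the interaction contrast, so a
purely additive pair falls inside it in ≥95% of replicates; a fully
suppressing pair falls below it.

## Synthetic cohorts

The generator emulates the structure of a small autoimmune cohort:
416 individuals (male fraction 47/416); markers drawn independently as
Binomial(2, MAF) dosages with per-marker MAF ~ U(0.1, 0.5) by default;
two roughly normal quantitative lung-function traits with target
correlation 0.48; two binary autoantibody traits at prevalence 0.26 with
latent correlation −0.5, which makes them nearly mutually exclusive
(roughly half the cohort negative for both, ~2% double-positive); unit
residual SD. Trait correlations are imposed through a Cholesky factor on
the noise covariance; binary traits threshold a latent liability at the
Gaussian quantile matching the configured prevalence, so planted genetic
effects shift realized prevalence and correlations — tests therefore use
wide tolerances. A single integer seed drives named substreams for
genotypes, traits and MAF draws.

What the generator does **not** emulate: linkage disequilibrium,
population structure, missing genotypes, genotyping error, and
covariate–genotype association. Passing tests therefore demonstrate
correctness of the machinery and calibration under the model's own
assumptions, not robustness to the confounders of real cohort data.
Structure correction is deliberately out of scope: the intended use case
is single-ancestry patient cohorts where the `qq_inflation` diagnostic
shows no systematic inflation.

`simulate.suppressing_subnetwork()` provides the reference planted
architecture used in recovery tests: a hub marker with an
antibody-contrast profile partially suppressing (75%) two partner
markers that carry main effects (1 residual SD) on all four traits,
planted MAF 0.45 against a 0.30 background, n = 1000. See
*Identifiability* above for why this — rather than complete or mutual
suppression — is the regime where recovery is expected.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_maf` | 0.1 | MAF filter threshold (inclusive; monomorphic always dropped) |
| `alpha_filter` | 1e-6 | per-trait significance for scan pairs entering selection |
| `n_candidates` (K) | 1500 | candidate markers kept by pleiotropic selection |
| `ld_max` | 0.5 | pairs with dominant-genotype \|r\| above this are excluded |
| `n_eigentraits` | 2 | leading ETs analyzed (the delta solve requires exactly 2) |
| `n_perm_values` | 1e5 | pooled permutation-null size (1e4 in tests) |
| `q_threshold` | 0.05 | BH FDR threshold for network edges |

## Problem sizes used in tests and the acceptance report

Scan-vs-OLS agreement uses 60 markers × 300 individuals (1770 pairs);
type-I control uses 20 global-null cohorts of 416 individuals × 50
candidates with 1e4-value nulls; recovery uses 20 replicates of the
planted subnetwork at n = 1000; the Taylor/bootstrap comparison uses 50
pairs at n = 2000 with 1000 bootstrap draws. These sizes keep the full
suite in the low minutes while leaving every stage of the pipeline
exercised end to end; the acceptance script repeats the same
computations at 5 replicates where 20 are used in tests.

## Known limitations

- Exactly two eigentraits: more would make the delta system
  overdetermined (weighted least squares), which is out of scope.
- The influence parametrization is ill-posed at complete suppression
  (δ = −1) and unstable for mutually suppressing or profile-parallel
  pairs; such pairs surface with large SEs or non-estimable flags.
- Binary traits are treated linearly throughout (consistent with the
  liability-threshold generator); logistic alternatives are not
  provided.
- The permutation null is pooled across pairs and directions; per-pair
  nulls would be prohibitively expensive and are not implemented.
- The permutation null represents "no genotype–trait association at
  all". In cohorts with strong true interactions, pairs that share a
  marker with a truly interacting pair have inflated interaction-term
  sampling variance (the tested product term is collinear with the
  omitted true product term through the shared marker), which the null
  does not capture. Networks on strong-signal cohorts therefore show a
  halo of weaker suppressing edges around the true subnetwork, and
  results are best read as discovery hypotheses rather than
  confirmatory findings. Global-null calibration is unaffected.
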