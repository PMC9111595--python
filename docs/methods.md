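# Methods

## Model

The phenotype is QoL on a 1–10 ladder, observed at up to two occasions
("pre" = the most recent pre-lockdown measurement, "pan" = during the
first lockdown). Per family, the observed phenotype cells are modelled
jointly as multivariate normal. Order the cells person-major with the two
occasions innermost; the model covariance is

    Σ_f = Σ_k R_k ⊗ Γ_k,   k ∈ {A, C, D, E},

where Γ_k is a symmetric 2×2 block (variance at each occasion plus the
cross-occasion covariance) and R_k encodes how the component is shared
between relatives:

- **A** (additive genetic): R_A = 2Φ, the expected additive relatedness
  from the recursive kinship coefficient. Founders are unrelated,
  Φ(i,i) = (1 + Φ(father, mother))/2, Φ(i,j) averages over the parents of
  whichever member is not ancestral to the other. MZ co-twins are merged
  into one genetic node *before* recursion, which simultaneously gives
  the co-twin pair relatedness 1 and makes relatives-through-a-twin
  correct (a child of one MZ twin has Φ = 1/4 with the aunt/uncle twin,
  children of two MZ twins are genetic half-sibs with Φ = 1/8). Missing
  parents are unique unrelated founders.
- **C** (common environment): shared household. Because the sample is
  adult, "household" means spouse pairs (parents of twins, or a twin and
  their spouse); R_C is the 0/1 same-household indicator with unit
  diagonal for every individual, so C contributes to every person's
  variance but only spouses' covariance. The unit diagonal for
  un-partnered members is required for the standardized shares to sum to
  one per occasion.
- **D** (dominance): the non-inbred fraternity coefficient
  Δ(i,j) = Φ(f_i,f_j)Φ(m_i,m_j) + Φ(f_i,m_j)Φ(m_i,f_j), diagonal 1, MZ
  pairs 1 (full sibs 1/4). The formula assumes non-inbred pairs; inbred
  pedigrees are accepted by the kinship recursion but dominance
  coefficients would need the full condensed-identity treatment, which
  is out of scope.
- **E** (unique environment, incl. measurement error): R_E = I, so E is
  purely within-person but still carries a cross-occasion covariance.

Missing cells are deleted from Σ_f row/column-wise (cell-wise deletion),
never whole families: a person observed at one occasion still
contributes. Two grand means (one per occasion) are estimated jointly;
after residualization they converge near zero but estimating them mirrors
standard variance-components practice and costs nothing.

Age and sex are regressed out per occasion (OLS on intercept + linear
occasion-specific age + a sex indicator) before fitting; a constant
covariate is dropped from the design with a warning rather than failing.

## Estimation

Each Γ_k is parameterized by the log-Cholesky factor of its 2×2 block
(log ℓ₁₁, ℓ₂₁, log ℓ₂₂), which enforces positive semidefiniteness without
constrained optimization. The total log-likelihood sums family-block MVN
densities; families with identical relatedness matrices and missingness
pattern are grouped so one Cholesky factorization per pattern serves the
whole group, which makes 10⁴–10⁵-family likelihoods cheap. Optimization
is L-BFGS-B from a deterministic moment-based start (each occasion's
phenotypic variance split equally across components, cross-covariances at
half the phenotypic cross-covariance) plus seeded random restarts
(default: up to two, stopping early once a restart confirms the optimum).
Convergence uses scipy's ftol 1e-12 / gtol 1e-7. A component whose fitted
block sits numerically on the PSD boundary is flagged, not an error.

Standard errors of the unstandardized block entries are observed-
information: a central-difference Hessian of the negative log-likelihood
in the unconstrained parameterization, inverted and propagated through
the numerically differentiated block-entry Jacobian (delta method).

Nested models are compared with χ² on −2ΔLL with df equal to the
parameter-count difference. When the dropped component is at its boundary
under the null (variances cannot be negative) the nominal χ² reference is
conservative — rejection rates run below the nominal level; the tests and
the pipeline use the plain χ² with that caveat. Identical specs compare
to (χ² = 0, df = 0, p = 1). Tiny negative −2ΔLL values (optimizer noise,
up to 1e-3) are clipped to zero; larger ones raise.

## Kinship correlations

Within-family pairs are classified into spouse (shared household id),
MZM/MZF (shared MZ-group code), DZM/DZF/DOS, parent–offspring by sex,
sibling by sex, or "other" (grandparental, avuncular,
children-of-twins…). The file dialect carries no DZ twin code, so co-born
DZ pairs are recognized as full sibs with identical recorded age at an
occasion — exact for generated data, a documented convention for real
files (register exports usually carry a twin code; users can pre-map it
onto ages or extend the classifier).

Weights: pair (i, j) of a type gets 1/√(kᵢkⱼ) with kₓ the number of pairs
of that type containing x — symmetric, and 1 for disjoint pairs, so the
weighted N equals the pair count in the clean case. The exact weighting of
register tooling is not published; this geometric-mean rule is the
package's declared choice.

Symmetric types (twins, siblings, spouses) are double-entered at half
weight; directed types (parent–offspring) enter once with the parent
first. For cross-time correlations the double entry swaps *members*
(pre of twin 2 against pan of twin 1), never variables — swapping
variables would pool the two occasions' different means and variances and
bias r toward zero. The two directional cross-time estimates are pooled
by fixed-effect meta-analysis: Fisher z, inverse-variance weights n − 3,
back-transformed, with the pooled z-scale standard error delta-propagated
to r. Confidence intervals are r ± 1.96·s_r throughout.

## Change scores

The paired t test uses difference pre − pan, so the observed QoL drop
prints as a positive t; change classification uses pan − pre so a
negative change score means decline. Cohen's d for paired samples is
mean(diff)/sd(diff) = t/√n. The unrelated subsample is, per family, a
largest subset with pairwise kinship zero (spouses retainable), found
exactly for families up to 12 members with seeded-random tie-breaking,
greedily above that; the selection is deterministic given the seed.
Scores of 0 from the one 0–10-scaled instrument are pooled into 1 before
analysis.

## Synthetic-data generator

The generator emulates a register sample: twin-pair families in an
MZF/MZM/DZF/DZM/DOS mix (0.36/0.14/0.19/0.10/0.21 by default, the
approximate zygosity proportions of the motivating register), each with
both parents present structurally — phenotyped with probability 0.65
(mothers) / 0.40 (fathers), as register parents often never return a
survey — plus a non-twin sibling (p = 0.08), a spouse of the first twin
(p = 0.02), and optionally spouse-only families. Parents of twins share a
household, as do twin–spouse couples. Twin age is N(36, 16²) truncated at
16 (adult register); co-twins share their exact age; mothers are the twin
age + N(28, 4) and fathers the mother + N(3, 3), keeping generations
consistent; the second occasion is 3 years after the first. Grand means
default to 7.73/7.02 with small age (−0.01/yr) and sex (+0.1 for female)
effects; the default truth is the published ACE decomposition
(Γ_A = [0.3503, 0.1828; 0.1828, 0.2835], Γ_C = [0.4837, 0.1936; 0.1936,
0.4731], Γ_E = [0.2983, 0.0292; 0.0292, 1.0754]).

Phenotypes are drawn per family from MVN(mean + covariate effects, Σ_f)
with Σ_f built by the same relatedness code the fitter uses; families
sharing a template reuse one Cholesky factor. Missingness is MCAR per
occasion (defaults 0.15 pre / 0.35 pan, roughly the register's response
pattern); discretization (clamp-and-round onto 1–10) is **off** by
default so parameter-recovery studies run on the scale the model assumes,
and **on** for realism demos.

What the generator does *not* emulate: assortative mating (spousal
resemblance arises only through C), informative non-response, skewness
and ceiling effects of real QoL (continuous mode is exactly Gaussian;
discretized mode adds quantization), cohort structure in ages, or
children-of-twins linkage across nuclear families. Passing tests
therefore demonstrate correctness of the estimator under its own
assumptions, not robustness to these real-data features.

Note on discretization: clamp-and-round does **not** reduce total
variance at these parameter values — rounding adds ≈1/12 quantization
variance, which exceeds the loss from clipping tails at 2–3 sd. What it
does attenuate is the correlation structure (quantization noise is
independent across cells), and that is what the test suite asserts.

## Numerical and design choices

- Continuous-mode simulated phenotypes live on the model's latent scale
  and may fall outside [1, 10]; file reading enforces the instrument
  bounds by default (`check_bounds=False` to accept latent-scale files).
- Infection-flagged individuals leave the sample by phenotype blanking,
  keeping pedigree structure intact (a flagged parent may still link
  unflagged relatives).
- Degenerate inputs: zero phenotypic variance, fewer than 3 pairs, or
  zero weighted variance raise typed errors; a zero-variance component's
  cross-time correlation is reported as NaN (undefined), never 0.
- Family blocks are processed exactly whatever their size (cost is cubic
  per block); grouping keeps the common case linear in families.
- The recovery and model-selection test experiments use complete
  continuous phenotypes (missingness off, discretization off): they
  measure the estimator's operating characteristics, for which MCAR
  thinning would only add noise. The main recovery experiment uses
  10,000 families in the tests and 40,000 in the acceptance script
  (Monte-Carlo error on recovered heritabilities < 0.6 percentage
  points); model selection uses 2,000 families × 20 seeds.

## Known limitations

- Dominance coefficients assume non-inbred pairs; no X-linked or
  mitochondrial relatedness; households limited to spouse pairs (size 2).
- Boundary-of-parameter-space p-values are conservative (no 50:50
  χ² mixtures).
- The weighted-kinship-correlation weight rule and the unrelated-
  subsample selection rule are reconstructions of under-specified
  register tooling, documented above as the package's own choices.
- No sex-limitation, age-moderation, assortative-mating or cultural-
  transmission models; no REML; no genotype data.
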