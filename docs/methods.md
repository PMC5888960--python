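# Methods

This note documents the models implemented in `namqxe`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## 1. Population simulator (`simpop`)

### Crossing scheme

A NAM panel is simulated family by family. Each family descends from an
F1 between the recurrent parent (all-reference haplotype) and a wild
donor, followed by `backcrosses` crosses to the recurrent parent and
`selfings` generations of single-seed descent (default BC1S3). Meioses
are simulated at the gamete level: between adjacent markers the
recombination probability comes from the map distance via the **Haldane**
map function, r = ½(1 − e^(−2d/100)) with d in cM — chosen because it is
the simplest self-consistent choice for a simulator without crossover
interference. Chromosomes segregate independently.

The single-locus genotype distribution implied by the scheme is available
in closed form (`expected_genotype_freqs`) from a three-state Markov
chain: a backcross maps (p₀, p₁, p₂) → (p₀ + p₁/2, p₁/2 + p₂, 0) and a
selfing maps it to (p₀ + p₁/4, p₁/2, p₂ + p₁/4). For BC1S3 this gives
(0.71875, 0.0625, 0.21875); the gamete-level simulator converges to these
values, which is asserted at n = 10,000 within three binomial SEs.

### Donor alleles and missingness

Donor alleles are family-private: each donor carries the non-reference
allele at a given marker independently with probability 0.5 (default), so
markers segregate only in a subset of families — the property that makes
the "polymorphic in at least one family" filter meaningful. Missing
genotype calls are injected completely at random at 2% by default, enough
to exercise the <10% missingness filter without dominating the data.
One master seed is used; per-family generator streams are spawned from it
deterministically, so output is byte-identical across runs at fixed seed.

### Phenotype model

For each line, year and environment:

    value = [ μ + F_family + Σ_locus effect + E_WL·1[WL] + u + ε ] · year_scale

- Locus effects are parameterised as the Hs/Hs − Hv/Hv difference;
  heterozygotes get half the effect (or the full effect with the
  dominance flag). The Q×E term `qxe_wl` is an additional Hs/Hs − Hv/Hv
  difference added only under WL.
- The polygenic deviation `u` is drawn **once per line** (shared across
  environments and years) from N(0, σ²_g K). σ²_g is set from the
  specified heritability h² as σ²_g = h²/(1−h²) · mean(σ²_e), so that
  σ²_g/(σ²_g + mean residual variance) = h². A variance-decomposition
  test (identity K, 3,000 lines) recovers h² within ±0.05.
- Residual noise is independent per record with a per-environment SD;
  making the WL SD larger than the WW SD reproduces the inflated
  coefficient of variation observed under water limitation.
- `year_scale` multiplies all records of a year by a common factor,
  emulating between-season level shifts — exactly the distortion the
  cross-year adjustment is designed to undo.

What the generator does **not** emulate: genotyping error, selection
during line development, segregation distortion, multi-allelic markers,
spatial field trends, phenotype missingness patterns correlated with the
genotype, and family-specific allele series at a locus (each causal locus
has one effect across all families). A green test therefore establishes
correctness of the statistical machinery under the stated model, not
robustness to these real-data features.

## 2. Files, filters and kinship (`genodata`)

File dialects are plain tab-separated text (genotypes: line, family, then
one column per marker with cells 0/1/2/NA; map: marker, chromosome,
position_cm; phenotypes: long format line/family/year/environment/trait/
value). Round-trip identity is tested.

Marker filters run in a fixed order: (1) drop markers monomorphic within
every family; (2) drop markers with ≥10% missing calls (the "<10%" rule
is strict); (3) among markers identical at every jointly non-missing line
("complete LD"), keep the first in map order. A pair counts as complete
LD only if jointly non-missing at ≥50% of lines. Deduplication is greedy
in map order with an exact verification pass; candidate pairs are
pre-screened by mean-imputed correlation (r ≥ 0.8) purely for speed —
near-monomorphic columns, where the screen is unreliable, are all checked
against each other. The LD rule is applied globally (not within-family);
that choice is configurable only by filtering per family externally.

Kinship defaults to the **allele-sharing proportion**
K[a,b] = mean over markers of (1 − |g_a − g_b|/2), which is exact on hand
examples, bounded in [0,1] and provably PSD (it is an average of interval-
overlap kernels). A VanRaden-style centred-cross-product estimator
(rescaled to mean diagonal 1) is available as an option. Missing codes
are mean-imputed per marker *only* inside the kinship computation; the
association tests instead drop lines missing at the tested marker.

## 3. Trait preparation (`traitprep`)

Derived traits: GFP = MAT − HEA, HI = PGY/TDM (missing when TDM = 0, with
a warning), VDW = TDM − PGY. The cross-year adjustment multiplies every
value of a (trait, year) by all-year mean / year mean, which equalises
per-year trait means, preserves the grand mean and is idempotent. Year
means pool both environments by default (environment-stratified factors
are a switch), because the level shifts the adjustment targets are
season-wide. The pipeline order is fixed: **derive → adjust → average
years**. For the linear derived traits the first two steps commute when
year shifts are a common multiplicative factor (tested); for the ratio
trait HI they do not, and computing the ratio on raw within-year values
is the biologically meaningful choice. Per-line means across years, per
environment, are the response passed to the scans.

## 4. Mixed-model engine (`mmscan`)

REML estimation follows the EMMA approach: one eigendecomposition
K = U S Uᵀ, rotation of y and X into the eigenbasis, and 1-D maximisation
of the profiled restricted log-likelihood over λ = σ²_g/σ²_e. λ is
searched on a 64-point log₁₀ grid spanning [10⁻⁵, 10⁵] (λ = 0 is always a
candidate) followed by bounded scalar refinement to 10⁻⁸ in the best grid
cell. The optimum is verified in tests against a 10,000-point dense grid.
Under the null (σ²_g = 0) the λ estimator has a point mass at the
boundary; its median over replicate draws is ~0, and tests assert that
rather than a single-draw value.

Marker tests are GLS F-tests under V = σ²_g K + σ²_e I: the marker enters
as genotype-class dummies with Hv/Hv as reference (the joint 2-df test is
the headline p-value; additive dosage coding is an option), and with
K = I the test reduces exactly to the ordinary linear-model F-test
(asserted to 10⁻⁸). Variance components are estimated once per
trait/environment on the no-marker model and reused for all markers
(P3D/EMMAX behaviour); the exact per-marker refit changes −log₁₀ p by
< 0.2 on tested instances and is available with `p3d=False`. Lines
missing at the tested marker are dropped and the whitening is redone on
the subset covariance (Cholesky; the full covariance matrix is cached per
scan). Family enters as fixed dummies *alongside* the kinship random
effect, as the model formula states.

## 5. Interaction scan and acceptance rule (`qxescan`)

The Q×E model stacks each line's two environment records. The two records
share the line's single polygenic effect, so the stacked covariance is
σ²_g (K ⊗ J₂) + σ²_e I with J₂ the 2×2 all-ones block; residuals are
independent across environments. The eigendecomposition of K ⊗ J₂
follows from that of K (eigenvalues {2sᵢ} ∪ {0}), so the REML machinery
is reused unchanged. Fixed effects are μ, family, environment, marker
class and marker × environment; the interaction F-test compares the full
model against the model retaining the marker main effect. Environment-
specific marker effects are reported per class (WW = main effect, WL =
main + interaction). Lines heterozygous at the marker are kept as their
own class. Marker-based kinship is the default (for parity with the
per-se scan); a pedigree-derived kinship can be supplied since `crossval`
and the scans accept any PSD matrix over the lines.

Cross-validation draws ⌈0.70·n_f⌉ lines per family without replacement
(ceiling, so small families are never lost), re-estimates variance
components on each subsample, and accepts a marker when the detection
rate (replicates with p < 0.05 / total) reaches 0.30. The kinship matrix
is computed once on the full panel and subset per replicate rather than
recomputed from subsample genotypes — cheaper and deterministic, and both
estimators converge to the same relatedness. Window peaks tile
each chromosome into half-open [k·5, (k+1)·5) cM windows anchored at 0
and take the marker with minimal p per window, ties broken by lower cM
then lexical id — a reproducible, order-independent convention.

Reaction norms are least-squares means of the three genotype classes per
environment from an OLS fit with family adjustment, averaging predictions
over family levels with equal weights; restricting to one family gives
the family-wise dissection of a locus.

**Known limitation.** The model contains no family × environment term
(faithful to the model formula it implements). A strong background Q×E
QTL therefore induces family-level G×E that is not absorbed and can leak
into unlinked markers that correlate with family structure. Relatedly,
all markers of one scan share one phenotype draw, so empirical
type-I-error rates *within a single dataset* are conditionally biased by
that draw; calibration tests pool p-values across independent replicate
traits scanned on disjoint marker blocks.

## 6. Senescence scoring (`senescence`)

RGB photographs are converted to YCbCr (ITU-R BT.601, full range). A
pixel is (1) forced to background if it matches the white-background rule
(Y ≥ 220 and |Cb−128| ≤ 12 and |Cr−128| ≤ 12); otherwise (2) assigned the
class of the nearest reference shade in (Cb, Cr) if that Euclidean chroma
distance is within the tolerance, else background. Distances ignore luma
by default — brightness differences between photo sessions then cannot
flip labels (tested) — with full 3-D distance behind a flag. The original
analysis's exact shades and tolerance are unpublished; the shipped
defaults (4 green + 4 yellow/brown shades, tolerance 20 8-bit chroma
units) are one reasonable instantiation and every number is configurable.
The yellow/brown percentage is taken over leaf pixels only (green +
yellow/brown; the standardised white background is excluded from the
denominator), and senescence is the difference of that percentage between
two photo dates. The fixture generator paints known pixel counts, so
classification accuracy is asserted against exact ground truth; with
chroma noise up to tolerance/3, ≥99% pixel accuracy holds by the distance
geometry and is verified by simulation. No morphological cleanup is
applied by default.

## 7. Pot statistics (`potstats`)

Lines are grouped as wild-allele carriers (codes 1 or 2 → Hs/_) versus
cultivated homozygotes (code 0 → Hv/Hv); missing genotypes are excluded
with a warning. The factorial ANOVA (drought treatment × allelic state,
with interaction) uses Type-II sums of squares because the pot designs
are unbalanced; with balanced cells it equals the sequential
projection-matrix decomposition, which is the oracle used in tests. When
a treatment × allele cell is empty the interaction is dropped with a
warning. Compact letter displays come from the insert-and-absorb
algorithm over pairwise tests — per-pair Student's t by default (matching
per-figure comparisons) or Tukey–Kramer — and are verified to be a valid
covering (groups share a letter iff not significantly different).
Percent reductions are 100·(reference − stressed)/reference, reported to
one decimal with round-half-even; comparisons against whole-number
reports should allow ±0.5 for the reporting rounding.

## 8. Budgets and determinism

Every stochastic routine takes an explicit seed (tests are fixed-seed;
hypothesis property tests are derandomised). The test suite runs in
about a minute; the acceptance script (a full pipeline at 1,000 lines ×
280 markers with 50 cross-validation replicates) in a few minutes on one
CPU — replicate counts are deliberately scaled below the 200 used in the
original field analysis to stay within those budgets, which widens the
Monte-Carlo error of detection rates but does not change any acceptance
threshold.
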