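# Methods

## Compositional handling

Input tables are taxon-by-sample counts or proportions. All
abundance-association analyses run on centred log-ratio (clr) values:
counts are first closed to proportions, a pseudocount is added, and each
sample's log abundances are centred by their mean. The paper-standard
alternative — relative abundances — is supported everywhere; clr is the
default because the unit-sum constraint otherwise manufactures negative
correlations between taxa, which matters most for the coabundance networks.

Zeros: the pseudocount defaults to half the smallest nonzero relative
abundance in the table (`pseudocount="auto"`), a conventional additive
replacement that sits below every observed value and preserves rank order.
It is configurable per call; a zero pseudocount is accepted only for
zero-free tables.

Range scaling (used before averaging taxa into grouped abundances) maps each
taxon to [0, 1] across the samples of one study cohort — the same per-study
scope as every other computation; a global scope is available. A taxon that
is constant within the scope maps to all zeros (with a warning) rather than
NA, so that group means stay defined.

Prevalence filtering keeps taxa detected (abundance > 0) in at least 5% of
samples in at least 60% of studies, enforced separately within the shotgun
and amplicon strata by default, so the retained panel is observable under
both profiling technologies.

## Distances and uniqueness

Four pairwise sample distances: Bray-Curtis and Jaccard on the full taxon
set (scipy `pdist`), Aitchison as Euclidean distance between clr vectors,
and Kendall as `d = (1 − τ_b)/2` where `τ_b` is the tie-corrected rank
correlation of the two abundance vectors over the union of taxa detected in
at least one of the two samples. Dropping taxa absent from both samples
keeps shared zeros from diluting τ toward zero; ties among one sample's
zeros are handled by the `τ_b` tie correction.

The all-pairs Kendall matrix is computed without a pairwise loop: with
`A_x[i,j] = sign(x_i − x_j)` flattened into rows of a matrix `M`,
`(M Mᵀ)_{xy} = 2(C − D)` and `(M Mᵀ)_{xx}` counts non-tied taxon pairs, and
the both-absent-taxa exclusion reduces to a closed-form correction involving
only presence counts (shared-presence, both-absence, per-sample richness).
The sign products are accumulated in float32 — exact for these ±1/0 integer
sums as long as the pair count stays below 2²⁴, i.e. up to ~5,000 taxa —
and all divisions run in float64. A per-pair `scipy.stats.kendalltau`
double loop over the union universe is kept in the test suite as the
oracle; the two agree to 1e-10.

Uniqueness is the minimum distance to any other sample of the same study
(the Methods-stated reference population); a pooled-reference mode exists
but is off by default. Diversity-adjusted uniqueness is the residual of a
per-study Huber regression of uniqueness on Shannon diversity; a study with
constant diversity degenerates to centred uniqueness with a warning.

## Robust fits and meta-analysis

Per-study associations use Huber M-estimation (statsmodels `RLM`, tuning
constant 1.345 for 95% Gaussian efficiency, configurable) with a Wald-type
two-sided robust F-test of the slope on (1, n − p) degrees of freedom. A
perfect fit (zero residual scale) reports the smallest positive double as a
lower-bound p rather than zero.

Cross-study pooling is DerSimonian-Laird: fixed weights `w = 1/v`,
heterogeneity `Q = Σw(y − ȳ_w)²`, `τ² = max(0, (Q − (k−1))/C)` with
`C = Σw − Σw²/Σw`, pooled estimate re-weighted by `1/(v + τ²)`. A single
study passes through with τ² = 0. Two p-values are attached: the z-test on
the pooled estimate and a two-sided sign-flip permutation test (each of B
draws flips each study's slope sign independently and re-pools; default
B = 999, seeded; p lives on the grid {1/(B+1), …, 1}). Directional
consistency is the fraction of studies whose slope sign matches the pooled
sign, zeros counting against.

Multiplicity control follows the analysis scoping: BH within study per
index family, BH across taxa on pooled p-values per analysis, Bonferroni
per focal taxon for network edges. The Bonferroni denominator for edges is
the focal taxon's partner count (per-focal correction); a global-denominator
mode is available.

PERMANOVA uses the Gower-centred inner-product decomposition
`F = (tr(HGH)/df₁) / (tr((I−H)G(I−H))/df₂)` with the hat matrix built from
a dummy-coded categorical or a centred continuous covariate (regression
form), and free permutation of the covariate. The residual-df check
(df₂ ≥ 1) replaces a fixed sample-size floor so the 4-sample closed-form
case remains computable. Because permutations are drawn with replacement
from the permutation group, a perfectly separated design can draw
group-preserving permutations that tie the observed statistic; p then
exceeds 1/(B+1) by the tie count, which is the correct behaviour of a
sampled permutation test.

## Taxon groups, age screen, markers

Classification: a taxon is Kendall-negative (health-associated) when its
pooled association with Kendall uniqueness is negative with q ≤ 0.05 and
consistency ≥ 2/3, Kendall-positive symmetrically, otherwise "other". The
partition is exhaustive and exclusive.

Age screen: studies qualify with ≥ 50 samples aged ≥ 60 (both
configurable); step 1 keeps taxa whose per-study slope signs agree in
≥ 2/3 of qualifying studies; step 2 pools survivors and flags q ≤ 0.1.
The selection step deliberately trades type-I calibration for cross-study
reproducibility: conditional on surviving the sign filter, a null taxon's
pooled p-value is stochastically smaller than uniform, so the realized
false-discovery proportion of the flagged set can exceed the nominal q —
the recovery experiment in the acceptance script measures exactly this,
and an abstract simulation with exactly known study-level standard errors
shows the excess is a property of the screen itself, not of the robust
fits. Users who need strict FDR control should treat the flagged set as a
screening output.

Marker ranking: clinical measures are oriented so larger = less healthy
(declared polarity; the registry ships with conventional geriatric
measures — frailty, inflammation, depression and comorbidity scores
unhealthy-positive; functional independence, Barthel, grip, gait, MMSE,
praxis, fluency and memory scores unhealthy-negative — and unknown measures
must be declared, never guessed). Continuous measures: robust regression of
the feature on the oriented measure. Binary: two-sided Mann-Whitney
(exact enumeration for combined n ≤ 12 without ties, otherwise the
tie/continuity-corrected normal approximation), direction from the median
difference. Scenarios below the 20-microbiome floor are skipped and
logged. BH runs per repository-measure combination; a feature is a marker
in a direction with hits in ≥ 3 distinct repositories and ≤ 2 opposite
hits anywhere. The younger-adult variant swaps q ≤ 0.1 for raw p ≤ 0.05.
Disease-marker replication verdicts use repository × disease scenarios with
matched same-study controls in multi-study repositories and pooled
non-disease controls in single-cohort repositories; a marker replicates
with > 2 expected-direction hits and ≤ 2 opposite, or ≤ 2 expected and
zero opposite.

## Networks and guilds

For each unordered taxon pair, clr(focal) is regressed on clr(partner)
within each study; pooled per focal direction; Bonferroni per focal taxon.
An edge requires a positive pooled estimate at q ≤ 0.001 in at least one
focal direction (a strict both-directions mode exists). Centralities:
degree, unnormalised shortest-path betweenness, and hub score = the
principal eigenvector of the whole adjacency matrix normalised to max 1
(dense symmetric eigendecomposition; mass concentrates on the dominant
component and isolated nodes score 0, matching the behaviour of the
field-standard hub score on undirected graphs). Guild extraction greedily
removes the roster member with the lowest internal degree (ties broken
lexicographically) until every member is adjacent to at least
`ceil(frac·(m−1))` of the other m−1 members (frac = 0.5 by default); the
greedy peel matches exhaustive search on all rosters small enough to
enumerate, which the tests verify.

## Synthetic cohorts

`generate_cohorts` draws, per sample, latent log abundances
`baseline + study offset + loading·factor + slope·max(0, age−60)/10 +
N(0, σ)`, applies a softmax and a multinomial draw at the configured depth.
Defaults: 10 studies of 150–500 samples, 120 taxa, depth 50,000, ages
uniform on 18–100, alternating shotgun/amplicon labels, five repositories.
One latent factor loads on the health-core roster (default 20 taxa,
loading 0.8) and one on each disease subhub (8 + 8, loading 0.8), planting
the coabundance architecture. Age slopes (clr-units per decade past 60;
defaults +0.5 disease, −0.25 health, σ_between-study = 0.1) plant the aging
signal. A disruption score — a logistic transform of the disease-factor
liability, which also drifts upward with age — attenuates and rank-jitters
the most dominant core taxa, the mechanism by which loss of core structure
(hence Kendall uniqueness) is coupled to ill health. Clinical measures are
`ρ·z + √(1−ρ²)·noise` with z the standardised disease-group clr abundance
(so the coupling is the correlation; default ρ = 0.3), one measure emitted
inverted (cognition-score style) to exercise polarity handling, and binary
labels threshold a latent liability at 30% prevalence. A 5% forced
detection dropout emulates detection limits. What the generator does *not*
emulate: phylogeny, strain structure, sequencing error, batch effects
between profiling technologies beyond a label, or realistic taxon
abundance distributions — passing recovery tests therefore demonstrates
the statistical machinery, not performance on real data.

The dominance-reshuffling community (used for the uniqueness-diversity
contrast) is a single cohort with two independent per-sample axes:
richness (a random subset of a large rare pool whose mass share grows with
the number detected — raising both Shannon diversity and Bray-Curtis/Jaccard
uniqueness) and disruption δ ~ U(0,1) (the core power-law exponent steepens
with δ, lowering evenness, while the assignment of subdominant core taxa to
rank slots is jittered in proportion to δ, scrambling the hierarchy; the
four most dominant rank slots keep fixed taxon identities so that disrupted
samples stay mutually close in abundance-weighted space). This is the
construction under which Kendall uniqueness falls with diversity while
Bray-Curtis uniqueness rises with it.

## Experiment design in the recovery checks

The age-screen recovery experiment uses 10 studies × 150 older-adult
samples with balanced planted slopes (16 health-core taxa at −0.5 and 16
disease taxa at +0.5 clr-units/decade) so that compositional closure plants
no net trend in the 88 null taxa, and disables the disruption channel and
the forced dropout: both plant *genuine* secondary age signal (disruption
couples to age by construction; dropout creates detection-driven trends in
rare taxa), which would corrupt the truth oracle by counting real effects
as false positives. The network recovery experiment similarly isolates the
factor channel (one 10-taxon module, loading 0.8, 5 studies × 400 samples)
and evaluates edge precision/recall over a 30-taxon roster against the
planted module. Problem sizes throughout the tests and the acceptance
script are desk-scale versions of the multi-repository design: one CPU and
a few minutes rather than 21,000 microbiomes.

## Numerical choices and degenerate inputs

* Permutation p-values are always `(1 + #{extreme}) / (B + 1)`; B ≥ 99
  enforced; all randomness flows through seeded `numpy.random.Generator`s.
* Robust fits require n ≥ 3 and a non-constant predictor; constant-Shannon
  studies and constant taxa degrade to centred values / zeros with
  warnings rather than errors where a defined fallback exists.
* Kendall τ on a pair whose union universe leaves one sample constant is
  defined as 0 (maximal uncertainty); a globally constant sample is an
  error naming the sample.
* The table reader parses floats with correctly-rounded `strtod`
  (pandas' fast parser is not round-trip safe), so write-then-read is
  bitwise identical.
* `run-all` writes a manifest (package version, seed, configuration hash,
  per-stage row counts) and no timestamps, so a rerun with the same seed is
  byte-identical.

## Known limitations

* DerSimonian-Laird z-tests are mildly anti-conservative at small k; the
  sign-flip permutation p is attached for exactly this reason, but with
  k ≤ 5 studies its resolution (≥ 1/(B+1), granularity 2⁻ᵏ distinct sign
  patterns) is limited.
* The two-step age screen does not control FDR strictly at the nominal q
  (see above).
* The consensus-network edge rule tests pairwise association only; it does
  not distinguish direct from factor-induced coabundance, which is why the
  recovery experiment plants factors rather than a partial-correlation
  structure.
* Grouped abundances depend on the range-scaling scope; cross-study
  comparability of the group means relies on the per-study scope being
  applied consistently, not on the scales being identical across studies.
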