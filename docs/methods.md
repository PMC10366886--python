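# Methods

This note documents the statistical procedures, the synthetic cohort model
behind every test, the numerical choices, and the package's known
limitations.  Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential calling

**Expression.** The DE engine is a Welch two-sample t-test on
log2(CPM + 1), with the fold change computed as
log2((mean tumor CPM + 0.5) / (mean normal CPM + 0.5)).  A gene passes at
|log2FC| > 1.0 (strict) and Benjamini–Hochberg FDR < 0.05 (strict).
All-zero genes are flagged untested; genes constant in both groups get
p = 1.  The engine is deliberately simple and exactly specified — the
package's contribution is the network pipeline downstream, and the engine
sits behind a single function (`differential_expression`) so a count-model
engine can replace it.

**Methylation.** Only distal probes enter: minimum absolute distance to
any TSS ≥ 2000 bp, *inclusive* ("at least 2 kb").  Per probe, one-sided
Welch t-tests are run per direction (tumor < normal for hypo, > for
hyper); BH is applied within each direction across that direction's
candidate probes.  A probe passes at |Δβ| ≥ 0.3 (inclusive) and adjusted
p < 0.01 (strict).  Probes constant across all samples are skipped with a
log entry.

**Pairing.** Each passing probe is paired with its 10 nearest passing DE
genes with TSS strictly below its position and 10 strictly above, by
absolute TSS distance on the same chromosome, ties broken by gene id.
Up/downstream is genomic-coordinate order; gene strand is ignored (the
choice is isolated in `nearest_genes`).  Pair significance is a two-sided
rank-sum test of the gene's expression between the lowest-20% and
highest-20% methylation samples; a pair is eligible only if ≥ 5% of its
beta values are < 0.3 and ≥ 5% are > 0.3, and the extreme groups must hold
≥ 5 samples.  The exact rank-sum null is used for extreme groups of ≤ 12
samples without ties; the normal approximation otherwise.  BH across all
eligible pairs at 0.05.

**DEMG.** Gene-level methylation is the arithmetic mean over a gene's
significant paired probes.  Gene direction is a majority vote over those
probes' directions; ties stay unassigned (logged).  DEMG_hypo/hyper =
passing DE genes ∩ genes with that methylation direction.  Direction
concordance with the expression sign is *not* required (plain
intersection); a stricter concordant mode would be a one-line filter on
the DE sign and was left out because the thresholds already imply strong
effects in both layers.

## Correlation networks

For gene profiles X (log2(CPM+1) for expression, gene-level betas for
methylation; tumor samples only, since the modules of interest are tumor
programs): Pearson r per pair; Fisher z = atanh(r) with r clipped to
±(1 − 10⁻⁷) (atanh diverges at ±1); μ and σ taken over the off-diagonal
**upper triangle** (each pair counted once) with the sample (n−1) SD —
whether to count pairs once or twice is unstated in the procedure this
follows, and the triangle choice is configurable in spirit: for a
symmetric matrix the two choices differ only in the (n−1) correction;
z' = (z − μ)/σ; edge weight |tanh(z')|, zero diagonal.  σ = 0 (all
correlations equal) is degenerate and maps every weight to 0 with a
warning.  Constant gene profiles correlate 0 with everything (warning)
rather than aborting.

A consequence worth knowing: after standardization, *null* gene pairs get
weights distributed as |tanh(N(0,1))| (mean ≈ 0.52) — the transformation
spreads pairs by their rank, it does not shrink noise.  Separation of real
modules therefore comes from the far tail and, later, from fusion.

## Similarity network fusion

Inputs are already similarities in [0,1], so the reference method's
distance-to-affinity kernel — where the α hyper-parameter acts — is not
applied; α is accepted in the config but inert (with a warning).  With
common genes only:

* full kernel: P(i,j) = W(i,j) / (2·Σ_{k≠i} W(i,k)), P(i,i) = ½ (rows sum
  to 1; zero rows fall back to uniform off-diagonal);
* local kernel: row-normalize over each node's K = 9 strongest neighbours
  (ties by gene order), zeros elsewhere;
* diffusion, t = 20 iterations of the simultaneous updates
  P₁ ← Ŝ₁ P₂ Ŝ₁ᵀ, P₂ ← Ŝ₂ P₁ Ŝ₂ᵀ with Ŝ = (S + I)/2, each step followed by
  symmetrization and adding the identity;
* fused = (P₁+P₂)/2, one final full-kernel normalization, symmetrization,
  min-max normalization over off-diagonal entries, zero diagonal.

Two stabilization choices deviate from the obvious reading and are
deliberate.  (1) Our similarity matrices have **zero diagonals**, so the
raw KNN kernel has no self-transition mass; the direct term
S(i,i)·P(i,j)·S(j,j) then vanishes and the diffusion scores two-hop paths
only, which demonstrably *inverts* edge rankings.  Ŝ = (S + I)/2 restores
the self-affinity the reference formulation gets from its kernel
diagonal.  (2) Renormalizing rows *inside* the loop divides rows holding
strong edges by their larger sums and again suppresses exactly the links
fusion should reinforce; the identity regularization per step plus one
final normalization is the reference scheme's behaviour.  Both effects are
pinned by tests (ranking preservation on a degree-balanced tiered toy;
cross-layer reinforcement on a planted two-layer toy) and the whole
iteration is verified against an independent straight-line implementation
to 10⁻¹⁰.

## Community detection and cluster scoring

Fast Greedy, Louvain and Infomap run through python-igraph on the weighted
fused graph; igraph draws from Python's `random`, which is seeded per call
for determinism.  Isolated vertices become singleton modules.

**Bioscore** of a module: test every cancer-related term of one source
(GO-BP or KEGG) for over-representation with the one-sided hypergeometric
tail; BH across terms within the module; each gene scores the number of
significant (adjusted p < 0.05) terms containing it; module score = sum of
gene scores; normalized min-max across the partition's modules (a single
module, or all-equal raw scores, normalize to 0).  The enrichment
background is the gene set of the network under analysis — the
conservative choice, since every network gene had the same chance to enter
a module.  The per-gene tally reading of the score (gene in k significant
cancer terms contributes k) follows "the score of this gene increases by
1" per such term.

**BHI**: the mean over modules with ≥ 2 annotated genes of the fraction of
ordered pairs of distinct annotated genes sharing ≥ 1 functional class.
All annotation classes are used (not only cancer-related ones) — BHI
measures homogeneity, not cancer specificity.

**Selection**: highest average GO-BP Bioscore, ties by average BHI, then
method name.  This makes "the better algorithm per dataset" reproducible.

## Consensus biomarkers

Module ids are arbitrary per partition, so "same module everywhere" is
formalized as pairwise co-membership: per dataset, all unordered gene
pairs sharing a module, restricted to the genes that are DEMG of the given
direction in **all** eight datasets (4 cancers × train/validation);
intersect the eight pair sets; consensus groups are the connected
components (≥ 2 genes) of the surviving pair graph.  Genes whose every
partner was severed are reported separately as singletons.  The operation
is monotone (adding a dataset never enlarges a group) and order-invariant,
both property-tested.

Mutation profiles count distinct mutated patients per biomarker gene among
untreated stage-I/II patients, normalized by the number of patients with
≥ 1 mutation in the filtered table, with a variant-classification tally.

## Prognostic score and survival

score = 0.5·expr + 0.3·β + 0.2·mut per patient and DEMG_Common gene
(DEMG of the direction present in both splits of the cancer type).  expr
is per-gene min-max of log2(count+1) across the cancer's patients
(per-gene, not global: the score should rank a patient within each gene's
own dynamic range); β is the gene-level methylation; mut ∈ {0,1}.  Genes
without gene-level methylation contribute β = 0 and are flagged in the
log, keeping the score defined and the imputation auditable.  Mutation
gets the smallest weight because mutation data are missing for many genes;
expression the largest because survival signatures are predominantly
expression-driven.  The 0.4/0.4/0.2 alternative is available through
`compare_weight_schemes`.

Cutoffs: per gene, mean ± 1 sample SD (n−1) of its scores; per cancer
type, the averages of those per-gene high/low levels over the DEMG_Common
genes.  Labels: score < avg-low → "low", > avg-high → "high", boundaries
inclusive → "normal" (the rule is strict "less/higher than", so equality
falls in the middle band).

Survival time is days-to-death for deceased patients (event 1), else
days-to-last-follow-up (event 0); non-positive or missing times drop the
patient with a log entry.  Cox PH is fit by lifelines with the label as a
categorical covariate, "normal" as the reference, Breslow tie handling;
one factor model per gene rather than one fit per level, so the two
contrasts share a baseline.  The screen keeps (gene, level) rows with
HR > 1.0 and Wald p < 0.05 and reports n and deaths at the level.
Kaplan–Meier curves come from the product-limit estimator (lifelines),
verified against a brute-force enumeration.  Single-omics screens reuse
the identical cutoff/label pipeline on one component; the mutation screen
uses the binary status directly as the group label.

## The synthetic cohort model

Each simulated cancer type draws, under one RNG seed:

* **Genome**: 1000 genes on four chromosomes in contiguous blocks (50 kb
  spacing ± 5 kb jitter), 2000 probes of which 70% are placed 5–15 kb
  downstream of a gene's TSS (hence distal by construction) and 30%
  within ±1.5 kb (proximal).
* **Planted layout** (defaults): three 12-gene hypo modules opening
  chr1–chr3, one 10-gene hyper module opening chr4, 50 + 25 background
  DEMG genes further along the chromosomes, 100 probe-less DE-only genes —
  half placed directly after each module as *buffer blocks* so the
  10-up/10-down pairing window of a module's probes cannot reach the
  background blocks (and vice versa), keeping each probe neighbourhood
  single-direction.  This mirrors the regional coherence of real distal
  methylation domains, where neighbouring probes report on the same
  regulatory region.
* **Counts**: NB with lognormal baselines (median ≈ 200, dispersion 0.3).
  Planted genes shift tumor means by 2^±2 (hypo-direction genes up —
  hypomethylation activates — hyper-direction genes down), with baselines
  damped ×0.5 (up) / lifted ×2 (down) so planted read mass keeps tumor
  library sizes comparable; DE-only genes alternate sign.  Module genes
  share a per-sample latent Gaussian factor on the log-mean scale
  (loading 0.6), with negative sign in hyper modules (silencing).
* **Betas**: logistic-normal.  Planted probe group means (0.65/0.25 hypo,
  0.35/0.75 hyper at Δβ = 0.4) are *calibrated by Gauss–Hermite
  quadrature* so the realized means equal the planted ones despite the
  mean-shrinking nonlinearity; module probes carry the shared factor on
  the logit scale (loading 1.0, sign matching the direction).
  Non-planted probes are Beta-distributed around Uniform(0.3, 0.7) means.
* **Mutations**: per tumor patient, Bernoulli(0.3) on the planted mutated
  genes (which include all prognostic genes, making the planted
  prognostic effect genuinely tri-modal) plus Poisson(5) random background
  records; variant classes drawn with missense dominating.
* **Survival**: exponential with baseline median 900 days; the hazard is
  multiplied by exp(1.5 · burden), where burden is the standardized
  per-patient mean of the planted prognostic genes' own
  0.5/0.3/0.2-weighted omics profile.  The 1.5 per-SD log-hazard is the
  strength of a strong composite signature (HR ≈ 4.5 per burden SD);
  censoring is an independent Uniform(0, h) horizon with h solved so the
  expected censored fraction at baseline equals the configured 40%.
* **Clinical**: 80% of tumor patients untreated stage I/II; the rest
  treated or stage III/IV.  The pipeline's cohort filter *keeps* untreated
  stage-I/II patients (the polarity is configurable, `keep=False` drops
  them instead; the kept-polarity matches the downstream mutation and
  survival analyses, which explicitly analyze untreated early-stage
  patients).

What the generator does **not** emulate: array probe chemistry and batch
effects, read-level data, copy number/miRNA layers, overdispersed library
size variation, correlated censoring, or gene-length/GC biases.  Passing
tests therefore demonstrate that the pipeline's logic recovers planted
structure of realistic effect size at realistic n — not that the specific
thresholds are optimal on real tumors.

Two generator-driven behaviours are worth flagging.  The supervised pair
test is confounded by the tumor/normal contrast (any DE gene × DM probe
pair associates through group status), so the pair counts are large — as
they are in real supervised pairings — and the DEMG sets contain more than
the planted genes.  And because background DEMG genes near each other
share paired probes, their gene-level methylation is regionally
correlated in every simulated cancer type, so consensus groups contain
some non-module background genes; recovery is measured on the planted
module genes, and the extra genes are a real (shared-structure) signal of
the generated data, not a bookkeeping error.

## Calibration and replication checks

* Null calibration uses cohorts with **no planted effects** for the DE
  pass rate, independent uniform score matrices with independent
  exponential survival for the screen's nominal level, and eight
  *independent random partitions* of a shared gene universe for the
  consensus null — a fully null generator produces empty DEMG sets, which
  would make the consensus check vacuous rather than informative.
* The end-to-end check runs the full four-cancer pipeline once (consensus
  recovery of planted module genes) and replicates the generation →
  scoring → survival-screen path across 20 seeds (planted prognostic
  genes flagged at HR > 1, p < 0.05).  The replication path takes the
  probe→gene map from the planted truth rather than re-running the pairing
  stage each time; the pairing stage's own recovery is exercised by the
  full run and its dedicated tests.
* Cox parameter recovery simulates exponential survival with a true HR of
  2 for "high" vs "normal" (label fractions 0.35/0.5/0.15, full
  follow-up, so the log-HR standard error ≈ 0.1 at n = 500 is precise
  enough for the [1.6, 2.5] acceptance band).

## Numerical and degenerate-input choices

* r clipped to ±(1 − 10⁻⁷) before atanh; σ = 0 → all weights 0 (flagged).
* Zero rows in the full kernel → uniform off-diagonal fallback (flagged).
* KNN ties broken by gene order; community seeds set explicitly.
* Min-max of a constant matrix → all zeros (flagged); single-module
  Bioscore normalizes to 0.
* Chi-square without continuity correction (matches the hand-computed
  2×2 value); single-category variables return (0, 1) and a warning.
* lifelines defaults for Cox (Breslow ties, Newton–Raphson); degenerate
  labelings (one level present, no events, separation) are skipped in the
  screen with a debug log rather than failing the run.

## Limitations

* The DE stand-in is a t-test on transformed CPM, not a count model; at
  very small n its power profile differs from NB-based engines.
* Consensus via pair intersection is strict: a single noisy partition
  removes a pair; with many datasets the output shrinks toward core
  modules (monotonicity is by design, but it means sensitivity drops as
  cancer types are added).
* The Bioscore depends on the cancer-term catalog; with the synthetic
  catalog, terms are aligned to planted modules by construction, so the
  metric's discrimination on real annotation databases is not measured
  here.
* Runtime scales with pairs (rank-sum tests) and with genes × Cox fits in
  the screen; the default study scale (~1000 genes, 4 cancers) runs in
  about a minute, chosen to keep a full study desk-scale.
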