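# Methods

## The problem

Spacecraft-assembly cleanrooms are surveyed for biological contamination
with two complementary instruments: the NASA standard assay (NSA), a
culture count of heat-shock-resistant spores used as the regulatory
bioburden proxy, and 16S rRNA amplicon sequencing of surface wipes, which
sees the whole community (including the non-cultivable majority) but
neither distinguishes live from dead cells nor spores from vegetative
cells on its own. This package implements the computational chain that
connects the two: cleaning the amplicon table of reagent contaminants,
predicting which community members can sporulate, quantifying spatial
structure in the spore/non-spore balance, and converting spore counts into
viable-bioburden estimates.

## Contaminant rule

A feature is flagged iff (1) its raw count is positive in **every**
control sample and (2) its mean raw count over the no-template controls
exceeds its mean over the floor samples. Two control sets are
distinguished deliberately: the 100%-prevalence clause uses all controls
(field, wipe-only negative, extraction), because all of them share the
reagent stream, while the abundance clause uses only the no-template
controls (negative + extraction), because field controls are air-exposed
and legitimately carry room biology. Both sets are configurable. The
abundance aggregator is the arithmetic mean of raw counts (median and max
available); "present" means raw count > 0 before rarefaction, and
decontamination runs before rarefaction. Flagging requires full control
prevalence rather than mere presence in negatives because features seen in
negatives are often well-to-well bleed-over from adjacent samples rather
than true reagent contaminants.

## QC and rarefaction

Samples below a minimum depth (default 5000 reads, boundary inclusive) are
dropped. Rarefaction is a single multivariate-hypergeometric draw per
sample (subsampling without replacement to exactly the target depth),
seeded and logged — not an average over repeated draws. Per-(feature,
sample) rarefied counts never exceed the originals and follow the
hypergeometric marginal, which the tests check against the closed-form
expectation.

## Sporulation hidden state prediction

Reference tips are labeled from trait records by **exact** sequence
identity (after uppercasing and gap stripping); a record matching several
identical tips labels all of them, conflicts resolve by majority, and an
exact tie leaves the tip unknown. Prediction is the empirical-frequency
estimator: for node v, f(v) = (labeled spore-formers under v)/(labeled
tips under v); an unlabeled tip takes f(a) from the first node a on the
path from its parent to the root with a defined frequency, always
excluding the focal tip itself from every count. That exclusion makes
leave-one-out evaluation leakage-free with a single global tally, so LOOCV
on n labeled tips costs one postorder pass plus n root-ward walks. The
estimator deliberately uses topology only; probabilities are invariant to
branch-length rescaling (a property test asserts this), which is the
price of the empirical method's robustness to rate misspecification.

Decision threshold τ = 0.5 with ties classified as spore-former —
conservative in the planetary-protection direction, and configurable.
Average precision uses the step-interpolated sweep with tied scores
processed as one group; it equals the standard precision-recall AUC
definition and is cross-checked against scikit-learn in the test suite.

Query placement is best-hit p-distance attachment: the query becomes a
sibling of its closest reference tip (normalized p-distance over
pairwise-overlapping positions, computed positionally for pre-aligned
input or over a unit-score global alignment otherwise; ties go to the
lexicographically smallest label), with pendant length equal to the
p-distance. A zero-length-effect internal node carries the anchor tip's
original branch length, so all distances among pre-existing tips are
unchanged. This is a deliberate simplification of phylogenetic-placement
insertion; it is adequate here because the downstream estimator is
topology-local — a query attached next to its nearest reference inherits
exactly that neighborhood's empirical frequency.

## Compositional statistics

Group log-ratios use natural log of summed raw counts of two disjoint
taxon sets; samples with a zero sum in either group are dropped and listed
(a +1 pseudocount mode exists behind a flag). Log-ratios are
scale-invariant, so unequal sequencing depth cancels without rarefaction.
Group comparisons use the Welch (unequal-variance) two-sided t test with
Bonferroni adjustment p·m capped at 1. The spatial gradient statistic is
the Pearson correlation between per-location mean log-ratio and the
location's radial distance from the entrance; the location mean pools all
sessions and, by default, only PMA-treated floor samples, because the
viable community is the planetary-protection-relevant one. Radius units
are opaque to every statistic (the survey design records them as schematic
pixels). Since swapping numerator and denominator flips only the sign of
r, interfaces require an explicit orientation and report that the opposite
orientation gives −r.

Richness comparisons (observed features per sample on a rarefied table)
use Kruskal–Wallis across sample-type × PMA groups with pairwise
Mann–Whitney post hoc tests, Benjamini–Hochberg-adjusted across the
pairwise family.

## Spore-category accounting

Each feature above a strict read-total threshold (default > 100 reads
across all samples) is NSA spore-former (spore-forming AND genus in the
NSA list), non-NSA spore-former (spore-forming otherwise), or
non-spore-former; the default NSA genus list is the twelve spore-forming
genera recovered by the assay in this facility (Bacillus, Brevibacillus,
Cohnella, Gracilibacillus, Oceanobacillus, Paenibacillus, Psychrobacillus,
Rummeliibacillus, Sporosarcina, Streptomyces, Terribacillus,
Virgibacillus) and is user-overridable. A feature with no resolvable genus
is categorized from its spore call alone and can never be NSA. Category
fractions are read sums over included features, normalized per group.

## Bioburden arithmetic

Replicate pour plates are pooled — Σ colonies / Σ plated volume — rather
than averaged per plate and then scaled; the two coincide for equal
volumes and pooling is the robust choice for unequal ones. The heat-shocked
aliquot is treated as having the concentrate's titre (no correction for
the unplated remainder of the aliquot). The SSB conversion multiplies
spores/m² by 50,000 viable cells per NSA spore; `observed_ratio` reports a
measured viable density as a multiple of the spore density and as a
fraction of that specification, returning an explicit undefined flag
(not infinity) at zero spores.

## Synthetic study generator

The generator reproduces the statistical structure the analysis assumes,
with defaults fixed to the survey design: 13 locations at radii spaced
uniformly on [50, 1000] pixels, 11 sessions, 98 floor sampling events
(each a PMA-naive/PMA-treated pair sharing location and session), and
12/12/8 field/negative/extraction controls. Features are tips of a random
rooted binary tree (random joins, exponential(1) branch lengths) carrying
a binary spore trait simulated root-to-tip under an equal-input two-state
Markov chain with stationary probability equal to the spore fraction
(default 0.3) and transition rate 0.1 per unit branch length. Expected
floor composition per taxon is a log-normal baseline times
exp(β·radius·[spore-former]) with β = −0.002 per pixel, split into a live
fraction (Beta(1, 2) per taxon, mean 1/3 — matching the observation that
roughly a third of observed richness is attributable to live cells) seen
by all samples and a dead layer seen only by PMA-naive samples. Seven
contaminant features dominate control reads, receive a guaranteed seed
read in every control (so the flagging rule holds by construction without
breaking the exact column-sum invariant), and enter floor samples at 1% of
sample intensity. Depths are negative-binomial (mean 50,000, shape 5) with
20% of samples forced below the 5000-read QC gate, mirroring the observed
~22% QC failure rate. Counts are multinomial at the drawn depth, so column
sums equal depths exactly.

What the generator does **not** emulate: sequence-level read simulation
(chimeras, PCR error), batch or run effects, well-to-well cross-talk
structure beyond a flat background, session-level temporal drift, and any
coupling between the trait and the baseline abundance. Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to those real-data pathologies.

## Problem sizes and numerical choices

Tests and the reproduction script run at desk scale: 300-feature studies
(228 samples) for pipeline-level checks, 500-tip trees for the
trait-prediction benchmark (20 replicates), 200 random instances for each
oracle-equivalence check, and 10,000 seeds for the rarefaction
calibration. The trait-prediction benchmark uses the symmetric trait model
(stationary probability 0.5) at transition rate 0.05, the regime of a
strongly conserved trait; under it, mean LOOCV average precision is ≥ 0.9
and decreases as the rate grows. Stage seeds in the pipeline derive
deterministically from the master seed and the stage name (CRC32 mix), so
a serialized config reproduces a run byte-for-byte. Degenerate inputs are
handled explicitly: identical groups give t = 0/p = 1, zero-variance
richness gives a zero Kruskal–Wallis statistic, zero-spore densities give
flagged-undefined ratios, and missing Newick branch lengths become 0.0
with a warning so path arithmetic stays total.

## Known limitations

- The placement stand-in ignores alignment uncertainty and multifurcating
  attachment; do not use its pendant lengths for divergence estimates.
- The empirical HSP estimator cannot exceed the information in its
  nearest informative ancestor; for sparsely labeled trees the effective
  neighborhood becomes the root and predictions collapse toward the global
  spore prevalence.
- The contaminant rule is deterministic and threshold-free; it does not
  model frequency-dependent contamination and will miss contaminants that
  drop out of even one control by chance at low depth.
- Category accounting is genus-resolution; NSA membership of a genus is a
  curated input, not an inference.
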