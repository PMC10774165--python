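# Methods

This note records the models, conventions and numerical choices behind the
package, in the order data flows through the pipeline.

## Uptake-rate reduction

An uptake assay follows one sugar's supernatant concentration after a fixed
induction. The rate is the two-point depletion

    rate = (C(0) − C(t_end)) [µM] · V [L] · 1000 / (t_end [min] · DW [mg])

in nmol·min⁻¹·mg dry weight⁻¹, with t_end = 15 min by default. We
deliberately use the two-point estimator rather than a regression over all
time points: it matches the assay protocol the pipeline is built around,
and depletion curves are only approximately linear (uptake slows as the
substrate is consumed), so the 0–15 min secant is the quantity of record.
Longer time series are used only for percent-remaining curves
(100·C(t)/C(0) per replicate).

Conventions: replicate rates are combined by arithmetic mean; a negative
raw rate (evaporation or measurement error exceeding uptake of a
non-transported sugar) is preserved and flagged in the assay record but
clipped to zero before averaging, so that noise on non-substrates cannot
manufacture negative correlations. Cells absent from the design are NaN,
never zero. The per-biomass unit (nmol·min⁻¹·mg DW⁻¹) is a documented
choice; any consistent unit works since the downstream analysis z-scores
each row.

## Expression transforms and 2^−ΔΔCT

Expression values arrive in arbitrary units. Before clustering each row is
log₂(x + 1)-transformed (pseudocount 1; the log base is immaterial under
Pearson correlation) and z-scored with the sample standard deviation
(ddof = 1). Constant rows cannot be z-scored; they are mapped to zeros and
carried with a `constant` flag rather than dropped, because weakly- or
un-expressed genes are themselves informative in the final report. Row
normalisation is configurable ({zscore, none}); it does not change any
Pearson correlation (affine invariance) but does change exported matrices.

qPCR quantification follows the standard relative method: per sample,
ΔCT = mean(target Ct triplicate) − mean(reference Ct triplicate);
ΔΔCT = mean over treatment samples − mean over calibrator samples; fold
change = 2^−ΔΔCT. The per-group uncertainty is the standard error of the
per-sample ΔCT values — Ct space is where qPCR noise is approximately
additive. Amplification-efficiency correction is out of scope.

## Joint correlation clustering and ranking

Uptake rows and expression rows are restricted to their shared conditions
(≥ 3 required; order follows the uptake matrix), transformed identically
but as independent blocks, and stacked into one matrix with role-tagged row
labels. Dissimilarity is d = 1 − r (Pearson), so d ∈ [0, 2]; pairs
involving a constant row get d = 1 (equivalent to r = 0) and are flagged.

Hierarchical clustering uses unweighted average linkage (UPGMA) by default
— the standard profile-clustering choice — with {complete, single} as
alternatives. The implementation maintains exact cross-pair distance sums,
so the inter-cluster distance is always the unweighted mean over *original*
dissimilarities, and merging is associative. Ties in the minimum distance
are broken by the lexicographically smallest cluster-id pair (ids in
creation order), which makes the dendrogram reproducible across platforms.
Average linkage is monotone; the implementation asserts nondecreasing merge
heights and clamps only sub-1e-12 floating-point jitter.

Flat clusters come from cutting the dendrogram at k clusters (default
k = 5, matching how such heatmaps are usually annotated; the cut criterion
is a free parameter and exposed as such) or at a height. Cluster ids are
numbered by first appearance in the dendrogram's display order.

Per sugar, all genes are ranked by descending r with the sugar's uptake
profile; genes with undefined r (constant profiles) keep a NaN sentinel and
rank last. `same_cluster` records co-membership at the k-cut. Ranking is
invariant to per-row affine rescaling of the inputs. Deconvolving a sugar's
uptake onto multiple transporters by regression is explicitly out of scope;
the method reasons from correlation and cluster proximity only.

Two failure modes are first-class:

* **Redundancy.** If several transporters carry a sugar, uptake is their
  summed contribution, so each single gene's r is < 1 even without noise,
  while the sum of the involved expression rows correlates perfectly. The
  simulator's two-equal-transporter scenario quantifies this.
* **Decoupling.** A post-transcriptionally regulated transporter
  contributes a condition-independent activity; its expression carries no
  signal about its substrate's uptake. The report flags any sugar with
  measurable uptake whose best gene correlation is below a threshold
  (default r < 0.5) as a decoupling suspect rather than promoting a wrong
  candidate.

## Phylogenetics

Distances: p = proportion of differing residues over sites where *neither*
sequence has '-' or 'X' (pairwise deletion; 'X' is treated as missing), and
d = −ln(1 − p), the Poisson correction for multiple hits. Since the
correction diverges as p → 1, saturated pairs are capped at p = 0.99 and
flagged — with hundreds of diverse transporter sequences, saturated pairs
are expected, and a capped finite distance keeps the matrix usable.

Trees: Saitou–Nei neighbor joining, joining the pair that minimises
Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k), with the standard
branch-length formulas. Q-ties break on the smallest node-creation-order
pair. Negative branch-length estimates are clamped to zero (no length
transfer to adjacent edges) and counted; clamping affects lengths, not
topology. NJ is consistent on additive inputs, which the test suite and
acceptance script verify against randomly generated trees whose patristic
distances are computed independently by dendropy.

Bootstrap: alignment columns resampled with replacement; the support of
each internal edge of the *original* tree is the fraction of usable
replicate NJ trees containing the same bipartition (leaf-set split
equality, canonicalised by the side not containing the alphabetically
first leaf). Replicates in which some pair has no overlapping sites are
skipped with a warning and removed from the denominator. Support is
attached to the original tree's edges (classical bootstrap), not a
consensus tree.

Clade assignment formalises the usual visual read of such trees: a query
leaf is assigned clade X iff it lies inside the smallest bipartition side
that contains all reference members of X, no reference member of any other
clade, and whose edge support meets a threshold (default 0.5; edges without
support values count as fully supported). Such minimal pure sides for
different clades are necessarily disjoint, so assignments are unambiguous;
queries on the backbone between clades return "unplaced". This is one
defensible formalisation of a step that is usually done by eye, and is
labelled as such.

## Group statistics

Two groups (n ≥ 3 each): Shapiro–Wilk on each; if both pass at α, a
two-tailed Student t-test (equal variance — the classical procedure this
mirrors specifies Student, not Welch); otherwise Mann–Whitney U, exact when
the pooled sample is ≤ 20 without ties, normal approximation with tie
correction otherwise. Stars: * p<0.05, ** p<0.01, *** p<0.001. Degenerate
zero-variance-equal-means input reports p = 1 rather than erroring. More
than two groups: one-way ANOVA with Tukey HSD, summarised as a compact
letter display via insert-and-absorb so that two groups share a letter iff
not significantly different. The empirical type-I error of the two-group
procedure under a normal null is checked to sit in [0.03, 0.07] at
α = 0.05.

## Synthetic transportome simulator

The simulator is the package's validation instrument; its defaults encode
the study design the method targets: 44 transporters × 15 induction
conditions (including a no-carbon control and a sucrose-like repressing
condition) × 10 assayed sugars, three biological replicates, 4-h induction
snapshot semantics.

Generative model, in order:

* **Expression** E(t,c) = basal_t × fold-induction on t's inducing
  conditions × CCR factor (default 0.2) on the repressing condition for
  all non-exempt transporters. Constitutive transporters ignore induction.
  Expression is piecewise-constant per condition — a snapshot, not a
  dynamic model, because the measurement design is one induction endpoint
  per condition.
* **Activity** act(t,c) = E(t,c) for coupled transporters; a constant
  (the basal level) for decoupled ones — the minimal model of
  post-transcriptional regulation.
* **Uptake** U(s,c) = Σ_t A(t,s)·act(t,c), strictly additive in
  transporter contributions; A(t,s) ≥ 0 is capacity per expression unit.
  Observed uptake multiplies each cell by an independent mean-1 lognormal
  factor with coefficient of variation `noise_cv` (default 0.1) —
  multiplicative because depletion measurements are positive and their
  error scales with signal; no replicate-level error model is published
  for such assays, so the default is a documented free choice.
* **Assays** invert the rate formula: C(t_end) = C(0) − rate·t_end·DW/(V·1000),
  with optional lognormal replicate noise; implied negative concentrations
  clamp to 0 with a `depleted` flag. At zero noise the reduction recovers
  the true rates exactly (round trip < 1e-9), provided C(0) is large
  enough not to clamp — validation runs use c0 = 2000 µM for this reason,
  while the 100 µM assay default reflects realistic tracer concentrations.
* **Ground truth** assignment shares are each transporter's mean
  contribution across conditions, normalised per sugar.
* **Alignments** evolve i.i.d. sites down a given tree under the
  equal-rate 20-state Markov model (branch lengths in expected
  substitutions/site): P(unchanged | b) = 1/20 + (19/20)e^(−20b/19), other
  states uniform. The expected observed p-distance at path length b is
  (19/20)(1 − e^(−20b/19)), which the tests check by Monte Carlo at 10⁵
  sites. `random_tree` grows random unrooted binary topologies with
  uniform branch lengths; their patristic distances are additive, the
  regime where NJ must be exact.
* **qPCR tables** place the group difference in ΔCT space
  (ΔΔCT = −log₂ fold) with additive Gaussian technical noise, three
  technical Ct values per sample per gene.

The `neurospora_like` preset wires the confounders together: dedicated
arabinose and galacturonic-acid transporters, two redundant cellodextrin
transporters carrying cellobiose/lactose/mannobiose, a minor
lactose+galactose side-activity transporter, redundant glucose and xylose
carriers, one constitutive high-expression transporter, one CCR-exempt
transporter, one decoupled rhamnose transporter, and 30 expression decoys
with no activity on the assayed sugars. The `dedicated` preset (one
transporter per sugar, decoys induced on two-condition sets so no decoy is
collinear with a dedicated single-condition profile) is the
assignment-accuracy benchmark: top-1 accuracy is exactly 1.0 noise-free
and ≥ 0.9 averaged over 20 simulations at 10% noise.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: saturable (Michaelis–Menten) kinetics,
intracellular metabolism feeding back on uptake, growth differences
between strains, correlated (batch) measurement error, and expression
measurement noise. Real expression compendia also mix platforms and
normalisations; the pipeline treats expression units as arbitrary, which
Pearson-based analysis tolerates but which matters for any absolute
interpretation.

## Problem sizes and determinism

Validation sizes are chosen to exercise the method at the scale it targets
while remaining quick: 100 random trees of 4–10 taxa for NJ consistency,
100 random 8×8 matrices for the UPGMA oracle, 20 simulation replicates for
assignment accuracy, 1000 bootstrap replicates on a 10-taxon 200-site
alignment, 2000 null simulations for test calibration. Every stochastic
component funnels through numpy `default_rng` seeds derived from a single
master seed; reruns with the same configuration are byte-identical, and
the pipeline manifest records the derived stage seeds.
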