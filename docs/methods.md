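# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `implinet`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Step-function binarization

Each gene is fitted independently. With values sorted ascending, every
split index k ∈ [1, n−1] defines a two-segment constant fit (means of
the first k and last n−k values); the SSE of each split is computed in
O(n) from cumulative sums, and the smallest k attaining the minimal SSE
is chosen (deterministic tie-break). The step significance is the usual
one-extra-parameter F ratio, F = (SST − SSE)/(SSE/(n−2)); a perfect step
reports F = ∞, a constant gene F = 0 and a degenerate (zero-height)
fit. At least 4 finite values are required; missing values are excluded
from fitting and coded MISSING.

Ternarization uses a fixed intermediate margin of **0.5 log2 units**
around the threshold (boundary inclusive on both sides). The margin is
the method family's convention for log2-scale data and is configurable;
it is only meaningful on log2 input, which is why raw-scale matrices
must be read with the `log2(x+1)` flag.

**Informativeness filter.** Pairwise analysis assumes bimodal genes. A
gene enters the pair stage only if its observed dynamic range is ≥ 1.0
log2 units and at least 3 samples code LOW and 3 HIGH. The source
analyses do not print their filter; this one is our declared stand-in,
chosen so that a gene must show a real step (1 log2 unit ≈ two-fold)
supported on both sides. Constant genes are coded all-INTERMEDIATE and
excluded.

## The sparse-quadrant implication statistic

For a pair (A, B), samples binarized in both genes fill a 2×2 table.
For quadrant (i, j) with observed count O, row total R (samples with
A = i), column total C (B = j) and n usable samples:

    E = R·C/n,   S = (E − O)/√E,   p_err = (O/R + O/C)/2

A quadrant is sparse when **S > 3.0 and p_err < 0.1** — the method
family's published defaults (the source analyses print only resulting S
values and an FDR bound, not the cutoffs). Quadrants with an empty row
or column are untestable and treated as non-sparse. Pairs with fewer
than **20** usable samples are skipped (statistic unstable below that;
configurable). Exactly one sparse quadrant maps to the corresponding
asymmetric implication; the off-diagonal pair to *equivalent*; the
diagonal pair to *opposite*; every other sparse-set (0, a row/column
pair, 3, 4) to *none*.

Asymmetric relations are stored once, directed from the
lexicographically earlier gene of the pair; the contrapositive
restatement (A low ⇒ B low ≡ B high ⇒ A high) is recovered via a fixed
converse map, so nothing is double-counted in the FDR.

**Permutation FDR.** Each permutation shuffles every gene's codes
across samples independently (preserving per-gene marginals, destroying
all inter-gene structure); FDR = mean permuted significant-pair count /
observed count, defined 0 when nothing is observed. The FDR is a
network-level qualifier by default; a per-relation-type breakdown is
available behind a flag.

A property worth stating explicitly: under the permutation null the
count O in quadrant (i, j) has standard deviation √(E(1−r)(1−c)) for
split fractions r, c, so S > 3 demands at least a 3/√((1−r)(1−c)) ≥ 6
s.d. departure. Chance implications are therefore essentially absent at
these cutoffs regardless of n — on a fully random 500×150 matrix both
the observed and the permuted counts are 0, and the discovery/null
counts only separate when real structure exists. The acceptance script
reports both counts rather than their (degenerate 0/0) ratio.

## Clusters and the cluster graph

The equivalence graph is clustered greedily: the unassigned gene with
the most unassigned equivalence partners seeds a cluster (ties to the
lexicographically smallest id); its unassigned equivalent neighbors are
considered in degree order and admitted when their closed equivalence
neighborhood shares a Jaccard fraction ≥ **0.5** ("at least half the
equivalences", counting the pair itself) with the seed *and with every
member already admitted*. Requiring agreement with all admitted members
— not just the seed — keeps a hub gene from bridging two leaves that
share nothing with each other; on clique-like planted clusters the two
rules coincide. The result is a partition; singletons are allowed, and
every cluster is named by its seed gene.

Cluster-graph edges: for each ordered cluster pair, the support of a
relation type is the fraction of cross-cluster gene pairs carrying it
significantly (orientation mapped through the converse map). The
maximal-support type becomes an edge when support > **0.5**
("overwhelming"); conflicts above threshold are logged and the maximum
kept. Symmetric relations produce one edge (id order); asymmetric
relations appear in both orientations, each stated from its source
cluster, which lets path enumeration traverse either presentation.

**Second-cohort refinement.** The published maps filter a training
cluster set through a second cohort without stating the rule. Ours:
a member survives when it is equivalent (in the second cohort's
implication table) to at least half of its cluster's other members
present there.

**Signature selection.** "Machine learning" path selection is
operationalized as exhaustive enumeration of simple directed paths of
up to `max_len` (default 3) clusters, each scored by the training
ROC-AUC of its composite score; ties rank shorter paths, then lexical
order, first. At realistic graph sizes (a handful of multi-gene
clusters) exhaustive search is exact, transparent and deterministic,
which we prefer to an unnamed learner. Cluster direction (up/down) is
the sign of the case-minus-control difference of mean
threshold-centered member expression.

## Composite scores and classification

A gene's normalized value is z = (x − t)/3: centered on its step
threshold and divided by a fixed **3 log2 units** so that typical
bimodal genes (two-fold to ten-fold steps) land near [−1, 1] and
cluster means stay comparable across genes; the divisor is configurable
and cancels in ROC-AUC ranking. Cluster weight w_k = ±k (sign from
direction, magnitude from path position). Per sample: score = Σ w_k ×
mean(z of cluster k's present members); missing genes drop out of the
mean and a sample is scored NaN only when an entire cluster is missing.
A ternary-codes variant (LOW = −1, INT = 0, HIGH = +1) is available
behind a flag since the published scores' exact inputs are not printed;
continuous is the default.

ROC-AUC is the Mann-Whitney probability that a random case outscores a
random control, ties ½ (sklearn). Group comparisons use the two-tailed
Welch t (scipy, `equal_var=False`), with Benjamini-Hochberg adjustment
across batches (statsmodels). Degenerate inputs: two zero-variance
groups with equal means give (t=0, p=1); unequal means give infinite t
with p clamped to the smallest positive float and a warning. Multiclass
displays are sequences of pairwise reports against a declared reference
class.

## Progression models

States are pure ternary-quadrant memberships — no soft assignment — to
mirror the quadrant-confinement argument. A sample is UNASSIGNED when
any seed gene is INTERMEDIATE/MISSING or when zero or multiple states
match; assignment is order-independent. Model files are small
declarative text (`state`, `implication` lines). Invariance checks run
the exact pairwise sparseness statistic on each model-implied
implication, so "invariant" means the same thing pair-wise and
model-wise; the report includes the forbidden-quadrant fraction. A
cohort that should *not* conform (e.g. squamous carcinomas against the
BE-continuum model) is checked with the same call and is expected to
fail — a recipe, not a special case.

## Synthetic cohorts

The default cohort is the package's reference study condition: three
states (NE, BE, EAC) × 50 samples; three 20-gene clusters with level
designs high-in-NE-only, high-in-BE-and-EAC, high-in-EAC-only (the
nested design plants the "CXCL8 high ⇒ SLC44A4 high" asymmetry
automatically, and the first gene of each cluster carries the seed-gene
name); 500 background genes (half flat noise, half bimodal with random
state-independent splits, split fraction ~ U(0.3, 0.7)); modes at 4 and
8 log2 units; Gaussian noise σ = 0.3; and a 1% per-entry rate of
cluster-gene measurements planted at the threshold midpoint to exercise
the INTERMEDIATE path (real arrays have mid-range values; 1% keeps
~97% of samples fully binarized across three seed genes, a realistic
light contamination). An additive batch shift is available (off by
default). Everything is deterministic per seed, and the ground truth
(gene → cluster, sample → state, the implied relation for every planted
cluster pair, derived from quadrant occupancy of the level designs) is
emitted alongside.

What the generator does **not** emulate: probe-level noise, platform
and normalization effects beyond an additive shift, correlated
background genes, partial-membership clusters, dropout-heavy single-cell
sparsity, or label noise. Passing tests therefore demonstrate that the
pipeline recovers the structure it is designed to detect under clean
bimodal signal with moderate noise — not that it is robust to every
artifact of real cohorts; real-data behavior should be validated per
dataset.

SNP tables draw binomial carrier counts per group from planted
frequencies. The enrichment contrast feeds each allele's signed log
odds ratio (progressor vs nonprogressor, Haldane-Anscombe +0.5 on all
cells so zero counts stay finite and direction-preserving) into Welch's
t between the protective and risk allele groups; the two-sided binomial
test doubles the smaller exact tail (capped at 1). Both conventions are
our choices where the source is silent. The exact Fisher test is
conservative at n = 40/40, so its realized null rejection rate sits
below the nominal 5% (the acceptance script reports the measured rate,
typically ~3–5%).

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated
data at the study conditions above: 1,000 random vectors for the step
oracle, 500 random pairs for the statistic oracle, the 560×150 default
cohort with a 10-permutation FDR, a 500×150 random matrix, 1,000 null
SNP replicates and 100 power replicates — a few tens of seconds on one
CPU in total. All randomness flows through explicit seeds
(`numpy.random.default_rng`); pair classification is fully vectorized
(indicator-matrix products), so all-pairs analysis of a few thousand
genes remains interactive.

## Known limitations

- Probe-to-gene collapsing is the caller's responsibility; the reader
  rejects duplicate gene ids rather than aggregating them.
- Cross-platform normalization is out of scope; the implication
  statistic is per-dataset, and cross-cohort use should binarize each
  cohort separately.
- The clustering is greedy and order-deterministic, not a global
  optimum; on weakly connected equivalence graphs the partition depends
  on the admission order (by design, for reproducibility).
- Conditional (triplet) implications, correlation/Bayesian network
  alternatives, survival modeling on scores, and two-step binarization
  variants are deliberately not implemented.
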