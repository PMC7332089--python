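# Methods

This note documents the model behind `hypbench`, its tunable parameters and
their defaults, the design choices made where the design was genuinely open,
and what the synthetic benchmark does and does not establish.

## Site windows

A candidate site is the window of W = 13 residues centered on a proline
(W is configurable and must be odd; real predictors use contexts up to 21).
Two rules make every window exactly W characters over the 20 canonical
residues plus the gap symbol `-`:

* positions beyond either sequence terminus are padded with gaps;
* any non-canonical letter (B, Z, J, U, O, X, …) becomes a gap — but the
  center itself must be a genuine canonical residue.

Positions are 1-based in all external tables (UniProt convention); the
conversion to 0-based indexing happens once, at window extraction.

## Similarity, distance, clustering

Windows are compared column by column, with no realignment: residue pairs
score by BLOSUM62, and each maximal run of columns where *either* window
carries a gap costs a single affine penalty, gap_open + (len−1)·gap_extend
(defaults −5 and −1). Charging the union of the two gap masks once — rather
than each window's gaps separately — is the minimal affine reading for
pre-aligned windows; a column where both windows have gaps belongs to the
run, not to the substitution sum.

"Distance as the inverse of similarity" cannot be 1/s for scores that reach
zero or negative values, so the order-reversing affine transform
d(i,j) = S_max − s(i,j) is used instead, with S_max the maximum score over
all pairs including self-pairs. This preserves the similarity ordering
exactly (rank correlation −1) and makes d non-negative with every site
nearest to itself.

Clustering is UPGMA (unweighted average linkage), implemented in-package
with the Lance–Williams update and a fixed tie rule: among equal-height
candidate merges, the pair with the lexicographically smallest
(min cluster id, max cluster id) merges first. Window scores are small
integers, so exact ties are common; the fixed rule makes cluster ids a
deterministic function of the distance matrix. The implementation is
cross-checked in the test suite against SciPy's average linkage on tie-free
random matrices and against a brute-force oracle on tie-rich window
instances. Flat clusters come from cutting the tree at `cut_height`.

**Choosing the cut.** The cut is a required, logged configuration value; the
default (48) is calibrated on the default synthetic benchmark so that
windows sharing roughly ≥ 70% identical columns co-cluster: the mean window
self-score is ≈ 65, a 70%-identical pair scores ≈ 0.7 × 65 − 4 ≈ 41, and the
observed S_max is ≈ 89, putting such pairs at distance ≈ 48. Under this cut
collagen windows (which share the repeat frame in register around the
central Y-proline) merge into sizeable clusters, while signalling-motif
windows — identical only across the 6-residue motif, with random flanks —
mostly stay apart. The resulting granularity, a handful of sites per cluster
outside collagen, matches what redundancy clustering of real hydroxylation
sites produces.

## Benchmark assembly

* **Negative filtering.** A negative falling in a cluster that contains at
  least one hydroxylated proline is removed; the survivors form one negative
  pool shared by every split. This is the leakage control at the heart of
  the methodology: near-duplicates of positives must not serve as negatives.
* **Splits.** Positives partition by evidence source — Literature (curated
  single-protein experiments), MS-HeLa, MS-Kim, MS = MS-HeLa ∪ MS-Kim
  (deduplicated by site) — and by the collagen flag of the host protein.
  The collagen flag is consumed as input (it stands in for collagen-repeat
  domain recognition); feature tracks likewise arrive as annotations, never
  computed here.
* **Confidence filter.** MS-HeLa positives below confidence 0.8 are dropped
  before splitting. The filter's source list is configurable because it is
  genuinely ambiguous whether high-throughput re-analysis confidence should
  also gate other MS sources; the default applies it to MS-HeLa only, the
  source that reports per-site assignment probabilities.
* **Replicas.** Each evaluation uses 1,000 balanced replicas: ⌊0.7·P⌋
  positives sampled without replacement plus the same number of pool
  negatives, negatives re-drawn independently for every replica. ⌊·⌋ rather
  than rounding keeps the draw conservative and within the pool for any P.
  Replica r uses the derived random stream (master_seed, r), so any single
  replica is reproducible without regenerating the rest.

## Metrics

Site-centric counting: every modified and unmodified proline is an
independent example. Sn, Sp, WACC = (Sn+Sp)/2, PREC, F1 and MCC use their
standard definitions; any 0/0 ratio (e.g. precision with no positive calls,
MCC with a zero denominator) is reported as 0 and logged, keeping replica
aggregation total and preserving the convention that a predictor worse than
random earns a negative MCC. Aggregation reports the mean and *sample*
(n−1) standard deviation over replicas, since replicas are draws from a
resampling distribution. ROC/PR curves sweep the unique scores with ties
grouped; ROC AUC is trapezoidal; a degenerate all-equal score set yields a
single-point curve and AUC 0.5 with a warning. Each (method, quality-level)
pair is treated as an independent predictor. The consensus baseline is a
strict majority vote with ties resolved to *not modified* — the consensus
exists to suppress false positives. Curves can be computed on replicas or on
the full site set; both modes are exposed because neither is canonical.

## Naive profile baseline

Every cluster containing ≥ 1 positive seeds one profile, built from **all**
member windows (negatives inside seed clusters are deliberately retained).
Because windows are fixed-length and pre-aligned on the central proline, a
positional log-odds matrix carries the same information a profile HMM would
at this width; no insert/delete states are needed. Gaps are a 21st emission
symbol — terminal padding is itself informative of sequence-terminal sites.
Background frequencies default to the input proteome's residue composition
(plus 1% gap mass).

Counts are smoothed with pseudocount 0.05 per symbol. The value is
deliberately ≪ 1/21: most seeds outside collagen have one or two members,
and heavier smoothing both blunts singleton seeds and pulls members of
large, internally diverse collagen clusters out of the far tail, which
would make the decision threshold matter when it empirically should not.

A scanned window's best score s over the database of D profiles becomes
E(s) = D × P_null(best-of-database score ≥ s), where the null is a Gumbel —
the natural family for a maximum — fitted to the max-over-profiles scores of
20,000 windows sampled i.i.d. from the background. Calls are positive at
E ≤ 1.0. Under this calibration a background window passes E ≤ 1 with
probability ≈ 1/D, and seed members sit so deep in the tail that tightening
the threshold to 10⁻³ barely moves sensitivity. A per-profile null
calibration was evaluated and rejected: taking the minimum of per-profile
E-values inflates the null positive rate by an order of magnitude and
halves specificity on the negative pool. This baseline's training positives
overlap the test set by construction; it is an upper bound for predictor
performance, not a usable predictor.

## Synthetic benchmark

The generator emulates the statistical label structure of the real problem,
not mass-spectrometry physics.

* **Collagen-like proteins** (default 10): random flanks of 20–40 residues
  around 25 (X-Y-Gly) triplets; X is proline with probability 0.28 and Y
  with 0.45; a Y-proline is a true site with probability 0.85, giving the
  canonical ≈ 38% Y-hydroxyproline rate. The repeat region is marked
  low-complexity.
* **Non-collagen proteins** (default 150, lengths 150–350): background
  composition (average proteome frequencies), 1–3 disorder intervals of
  25–60 residues, and two 6-residue proline-bearing signalling motifs
  embedded only inside disorder: a *known* motif (LSPTEK) and a *novel*
  motif (WNPFGQ), each occurring Poisson(0.6) times per protein and true-
  positive with probability 0.8.
* **Prevalence.** The defaults put the true-positive fraction among prolines
  at ≈ 0.11 (analytically computable from the config; the generator refuses
  configurations whose expectation strays from the target 0.10 by more than
  a factor of two).
* **Sources and eras.** Collagen and known-motif positives go mostly to
  Literature (85% / 70%, remainder MS-Kim); novel-motif positives split
  evenly between MS-HeLa and MS-Kim. This encodes the era structure the
  methodology probes — curated literature as the training-era sample,
  mass-spectrometry as the after-training discoveries — and makes MS-HeLa a
  purely novel-motif split. MS-HeLa confidences are 1.0 with probability
  0.75, else uniform on [0.5, 1); Literature positives carry the
  manual-assertion evidence code.
* **Incompleteness.** A fraction h of true positives is relabeled negative
  in the observed table (default h = 0: the fully observed condition). True
  labels live in a separate manifest that the pipeline never reads; tests
  use it to verify thinning and to quantify apparent false positives that
  are actually unlabeled positives.
* **Simulated predictor.** Calls fire with probability
  λ·1[max window similarity to a training positive ≥ τ] + (1−λ)·g·1[true site],
  then flip with noise ε; the pre-noise propensity is the score. Defaults
  λ = 1, τ = 35, g = 0, ε = 0.01 give the pure memorizer: τ lies between
  within-motif-family similarities (≥ 40, and self-similarity ≥ 52 for any
  gap-free window) and cross-family similarities (≈ 25), and ε must be small
  because noise alone bounds |MCC| at √(ε/(2−ε)) on a split with no
  recognizable positives (already ≈ 0.10 at ε = 0.02).

**What passing tests show — and do not.** On this benchmark the pipeline
demonstrably (i) filters every negative that shares a cluster with a
positive, (ii) scores a random baseline at WACC 0.50 ± 0.02 over 1,000
replicas, (iii) recovers ≥ 99% of profile-seed positives at E ≤ 1 with
< 0.05 sensitivity change across E ∈ [10⁻³, 1], and (iv) separates a
memorizer's training-era MCC (> 0.6, in practice ≈ 0.98) from its
novel-motif MCC (|MCC| < 0.1). The generator does not model peptide
digestion or detection bias, inter-protein homology beyond shared motifs,
or the long-tailed cluster-size distribution of real proteomes, so absolute
metric values on real data will differ; what transfers is the machinery and
the qualitative phenomena.

## Numerical choices and degenerate inputs

* Metric 0/0 → 0 with a log note; aggregation requires ≥ 2 replicas.
* UPGMA rejects non-finite distances; a single site forms cluster 1; flat
  cluster ids are renumbered contiguously from 1 in site order.
* An empty negative pool (every negative co-clustered with positives) is a
  warning at filtering time and an error at replica construction, naming
  required vs available counts.
* Missing predictions for replica sites are a hard error by default; the
  count-as-negative policy is opt-in and logs its tally.
* Loader rejections (residue mismatches, filtered evidence codes) are
  returned as a report, never silently dropped: accepted + rejected equals
  the input row count.
* The problem sizes used throughout (≈ 2,100 sites, 1,000 replicas, 20,000
  null windows) are the package's standard desk-scale conditions; every
  stage scales to larger inputs through the same blocked similarity and
  O(n²)-memory clustering paths.

## Known limitations

* The dendrogram cut that real hydroxylation data would require is not
  recoverable from published numbers; it must be chosen and reported with
  any real-data use of this pipeline (the default is a synthetic-data
  calibration).
* The profile baseline's E-values are calibrated against an i.i.d.
  background null; they are decision scores, not HMMER E-values, and only
  threshold-insensitivity and seed-recovery behavior are meaningful.
* Conflicting annotations for the same site across sources are kept at load
  time; a site positive under any source is excluded from the negative pool
  globally, which is one defensible reconciliation among several.
* No significance testing between predictors is provided.
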