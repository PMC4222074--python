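# Methods

This note documents the statistical machinery behind `dgsearch`: the models
and procedures each stage implements, the generative model of the synthetic
cohorts, parameter defaults and why they hold, and the numerical choices
made where the design was genuinely open.

## Segmentation and CNA calling

**Profile noise.** Each profile's internal noise is one-fourth of the
median absolute difference between consecutive probes, pooled across
chromosomes (differences never span a chromosome boundary). This is a
robust scale estimate: for i.i.d. Gaussian probe noise of SD σ the
statistic converges to `median|N(0, 2σ²)| / 4 ≈ 0.2386 σ`, and a single
aberrant segment moves only a handful of the differences, leaving the
median essentially untouched.

**Circular binary segmentation.** Within each chromosome the maximal arc
statistic

    T = max_{i<j} |mean(x[i:j]) − mean(rest)| / sqrt(1/k + 1/(m−k)),  k = j−i

is compared with its permutation null (probe values shuffled within the
segment under test); the split is accepted when the add-one permutation
p-value falls below `alpha` (default 0.01), cutting at the arc bounds and
recursing on the pieces. Arcs must leave at least `min_width = 2` probes on
each side of the cut, matching the usual minimum width for a *changed*
segment; a flank shorter than that can still arise from a double cut, as in
reference implementations. The statistic is scale-free under permutation,
so no variance estimate enters the test itself. Permutation count defaults
to 1000 per split test in `segment_profile`; the pipeline default is 500,
which leaves the attainable p-value floor (1/501) far below `alpha` while
halving the cost of segmenting a 120-subject cohort — the α = 0.01 decision
is unchanged for any segment whose true p is not within ±0.001 of the
threshold. Constant segments (`ptp < 1e-12`) are never split. All
permutation seeds derive from the caller's single seed in a fixed recursion
order (FIFO), so identical seeds give identical segmentations. The kernels
are numba-jitted with a pure-numpy fallback implementing the same
algorithm.

**Two calling regimes.** The noise-adaptive regime calls segments with
`|mean| > noise` and ≥ 3 probes, labelling gain/loss by sign and
amplification above a log2 ratio of 1.0; it feeds the differential
(ANOVA) path. The fixed regime applies four conjunctive conditions —
`|mean| ≥ 0.15`, per-segment FDR < 1e-05, ≥ 10 probes, length ≥ 1 kb — and
feeds recurrent-region discovery. Ties at the printed thresholds are
resolved exactly as printed: "less than 10 probes … filtered out" removes
n = 9 and keeps n = 10; FDR must be strictly below 1e-05; a mean of
exactly ±0.15 is kept.

**Per-segment FDR.** The upstream smooth-segmentation engine this filter
emulates reports a per-segment FDR without an exposed formula; here it is
computed as a two-sided one-sample t test of the segment's member probes
against zero, BH-adjusted across the segments of one profile
(configurable). A flat nonzero segment (zero within-segment variance) gets
the smallest representable p; a flat zero segment gets p = 1.

## Recurrent regions

Per-subject calls (closed on probe positions) are converted to half-open
intervals (`end + 1`) and the genome is atomised at the union of all call
breakpoints. Maximal runs of contiguous atoms whose subject→state map stays
constant become regions — the most conservative reading of a "recurrent CNA
region", verified in tests against a per-base brute-force scan. The
recurrence denominator is the number of subjects with at least one call
anywhere; the ≥ 10% cut is applied on subject counts rounded to the nearest
integer (a 121-subject denominator keeps regions altered in 12 subjects and
drops 11), matching how such thresholds are reported in cohort analyses.

**Polarity.** A region is `amp_only`/`del_only` when the minority-polarity
fraction among its altered subjects is strictly below the mixture
tolerance: 0 for the gene path (any mixture excludes the region) and 0.10
for the miRNA path. A region whose minority fraction equals the tolerance
is `mixed`.

**Differential regions and clusters.** One-way ANOVA runs per region on
one value per subject — the mean of the subject's segmented values
(each probe carrying its segment mean) over the region's probes — across
the AC/SCC/LCC groups, BH-adjusted, significant at FDR < 1e-05. Groups
need ≥ 2 usable subjects; a region with fewer than two such groups is
reported missing. Significant regions merge greedily left-to-right into
clusters while every (state, histology) aberration frequency stays within
1 percentage point of the *first* region of the running cluster (anchored,
not pairwise, to prevent drift; configurable) and never across
chromosomes.

## Driver search

**Filters.** Candidates are features inside pure-polarity recurrent
regions. Variability: sample SD across subjects ≥ 0.25 (the printed
exclusion is SD < 0.25, so the boundary is kept). CNA–expression
consistency: a one-sided Welch t test of altered vs copy-neutral subjects
in the polarity's direction (subjects altered elsewhere but neutral at the
region count as neutral), fold change `2^(Δ mean log2)` required > 2 in the
polarity direction for genes (no fold-change rule for miRNAs, whose Welch
threshold is p < 0.01), and "consistent over-expression" operationalised as
≥ 90% of altered subjects with log2(T/N) of the matching sign. The 90%
default tolerates one outlier in a typical 10–40-subject altered group at
realistic noise; a strict 100% mode is a parameter away. Groups smaller
than two yield a rejection with reason `insufficient_data` rather than an
error.

**Modules.** Pearson correlation (Spearman by flag) between candidate
drivers and all variable genes outside recurrent regions; p-values from the
t transform with n−2 df. Each target with at least one driver at raw
p < 0.001 joins the significant driver with the largest |r| (exact ties to
the lexicographically first driver id), giving a partition of assigned
targets.

**Sparse CCA.** Each module is refined by a rank-1 sparse canonical
correlation fit via alternating soft-thresholded power iterations on the
cross-covariance of the standardized blocks — the penalized-matrix-
decomposition formulation, with each side's l1 budget expressed as a
fraction of √(block size) and enforced by bisection on the soft threshold.
With both penalties off, the iteration runs on the *whitened*
cross-covariance, so the result coincides with classical CCA (verified to
1e-6 against a closed-form oracle); with penalties, within-block covariance
is treated as diagonal, the standard approximation when targets outnumber
subjects. Initialisation is deterministic (the dominant column of the
cross-covariance); non-convergence after `max_iter` raises an error
carrying the last iterate and delta. Targets whose canonical weight is
thresholded to zero leave the module. The target-side penalty defaults to
`"auto"`: the value on a small grid maximising the gap between the real
canonical correlation and its mean over subject-permuted refits (5
permutations, fixed seed).

**Ranking.** Final drivers pass fold change > 4 and Welch p < 0.001 and are
ordered by descending refined module size — the count of targets a driver
influences being the working proxy for its importance — with ties broken by
descending fold change, then feature id.

## Histology prediction

**AUC** is Mann–Whitney U scaled to [0,1] with ties counted 0.5,
equivalently the probability a random positive outscores a random negative;
it is checked exhaustively against pair counting on all small instances.

**L1 signature.** For a requested signature size s, the lasso path of an
L1-penalized logistic regression (liblinear) is searched — a log-spaced
bracket followed by bisection on C — until the active set has exactly s
features; if the path jumps over s the nearest attainable size is returned
and flagged. Cross-validation is stratified k-fold (default 10, clamped to
the minority class size), shuffled with the caller's seed; each training
fold re-standardises features and re-selects C, and the reported AUC pools
out-of-fold decision scores (per-fold averaging is available). The final
signature comes from a full-data fit at the matched size.

**Monte-Carlo nulls.** Signature significance draws `n_draws` random
same-size feature sets and scores each with the same cross-validated
protocol; single-feature significance draws random features from the same
matrix (matching a "random genes" null rather than label permutation,
which preserves the matrix's correlation structure in the null). Both use
the add-one rule `p = (1 + #{null ≥ observed}) / (n_draws + 1)`, so p is
never exactly zero and "p < 0.001" requires 1000 draws beaten. The
single-feature test folds AUC and 1−AUC into one departure-from-0.5
statistic by default (one-sided mode available); a constant feature has no
ranking and raises an error. These p-values are discrete and therefore
conservative (super-uniform) under their nulls — ties in the null counts
can only push p upward — which the calibration tests check with the
one-sided KS statistic.

**Regional amplification test.** A one-sided one-sample t test of a
window's probe intensities against the standardized global mean (zero),
declaring amplification below a caller-supplied α; used for
external-cohort style validation of a driver's locus.

## Network enrichment

The statistic is the number of network edges with one endpoint in the
target set and one in the pathway set; an edge inside the intersection
counts once (a double-count mode exists behind a flag). The default null
rewires the observed network by degree-preserving double-edge swaps,
advancing the chain `10 × |edges|` attempted swaps between successive
samples, so every draw preserves the exact degree multiset; z standardises
the observed count against the permutation moments and p is the one-sided
upper add-one permutation p-value, BH-adjusted across testable pathways
(a pathway with no gene on the network is flagged untestable). A
closed-form binomial approximation under the configuration model
(`q = 2·q_A·q_B − q_{A∩B}²` on degree fractions) is provided for speed and
cross-checked qualitatively against the permutation null. Target sets are
trimmed before testing to roughly 100 genes by walking a correlation-cutoff
grid and taking the smallest cutoff whose count fits; miRNA modules skip
the trim because miRNA–target expression correlation is not assumed.

## Synthetic cohorts

The generator emulates a paired tumor/normal design, where log2(T/N)
ratios cancel germline background:

* **Copy number:** per-subject probe values are i.i.d. `N(0, σ_probe²)`
  plus `mean_amplitude` inside each carried region — consistent with the
  consecutive-difference noise statistic the segmentation assumes.
* **Carriers:** each planted region draws `round(f × n)` carriers
  uniformly, or per histology group when a bias map is given (that is how
  a histology-associated driver arises).
* **Expression:** background genes are independent `N(0, σ_expr²)`. A
  region's driver gains `±target_effect` per copy state (sign following
  polarity). Each of its targets is `β·(driver − mean) + noise` with β set
  from the model variances so the *population* driver–target correlation
  equals `module_corr`; the latent factor is the scaled driver signal
  itself. Passenger genes inside regions get no expression effect — they
  exist to exercise the consistency filters. A configurable fraction of
  background genes (4%) receive a histology main effect (0.5 log2 units,
  cycling through SCC/AC/LCC) so the signature task is non-degenerate:
  one such gene alone reaches AUC ≈ 0.8, a random 15-gene draw stays near
  0.6–0.9, and the tuned 15-gene signature approaches 1 — the qualitative
  pattern a real subtype-structured cohort shows.
* **miRNAs:** independent noise, except miRNAs residing inside a planted
  region inherit its dosage effect, creating driver-miRNA candidates for
  the relaxed filter path.
* **Determinism:** one global seed spawns named substreams (histology,
  carriers, probes, expression, miRNA, assignments); identical seeds give
  byte-identical cohorts.

**Default study cohort** (`default_cohort_config`): 120 subjects with
histology proportions 57:50:13 (AC:SCC:LCC), 3 chromosomes × 40 probes at
50 kb spacing, 1500 genes, 150 miRNAs, three amplified 15-probe regions
(amplitude +0.8, carrier fraction 0.30, the first biased toward SCC),
driver effect 2.5 log2 units (fold change ≈ 5.7, comfortably above the
final fold-change-4 filter at the cohort's estimation error of ≈ 0.08
log2), modules of 110/120/130 targets at correlation 0.6, probe noise SD
0.1, expression noise SD 0.4. The plain `SimConfig` default for probe
noise is 0.15, a free choice exposed in the config since real-cohort noise
scales vary; noise SDs of zero are allowed to support exactness checks.
These sizes keep a full 20-seed pipeline study within desk-scale runtime
while leaving every planted effect many standard errors from its filter
threshold.

**What passing tests do not show.** The generator's noise is Gaussian and
homoscedastic, probes evenly spaced, regions non-overlapping with constant
amplitude, and modules generated by a single shared factor. Real aCGH
waves, GC artefacts, heteroscedastic expression, overlapping/nested CNAs
and pathway-level co-regulation are absent, so planted-truth recovery here
demonstrates the pipeline's logic and calibration, not its performance on
any real cohort.

## Degenerate inputs and tie-breaks (summary)

Zero-variance features: correlation and AUC undefined (missing value or
error, per operation). Empty call sets: empty region list, not an error.
Both gene sets empty on the network: error; one empty: zero links. Exact
|r| ties in module assignment: lexicographically first driver. Equal
module sizes in ranking: larger fold change first, then feature id.
Constant segments: never split; flat nonzero segments get the minimal
representable p in the FDR step. BH is the multiple-testing adjustment
throughout (statsmodels).

## Known limitations

The CBS implementation tests arcs against a within-segment permutation
null without DNAcopy's hybrid tail approximation or changepoint pruning,
so very long profiles (≫ 10³ probes per chromosome) would benefit from the
pruning it omits. The binomial NEA mode ignores degree heterogeneity
beyond first moments. The sparse-CCA penalty form is the PMD soft-l1
constraint; other sparse CCA variants (elastic-net, structured) are out of
scope. The miRNA path shares the gene machinery and does not model
miRNA→mRNA repression directionality.
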