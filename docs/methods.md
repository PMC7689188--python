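# Methods

## The dysregulation model

For each candidate miRNA *i* / mRNA *j* pair the score
`S = |rho_t − rho_n|` contrasts the Spearman rank correlation of the
pair across tumor samples with the same correlation across normal
samples. S ranges over [0, 2]; S ≈ 0 means the regulatory relation is
unchanged even if expression levels shifted, S near 2 means the relation
flipped sign. Spearman is the default because rank correlation is
invariant to the monotone normalizations RNA-seq expression values
typically undergo; a Pearson switch exists for users who prefer the
linear statistic (`method="pearson"` throughout).

**Permutation null.** The tumor/normal partition of the samples is
shuffled with group sizes fixed, jointly for the miRNA and mRNA vectors
(sample identity is never broken), and S is recomputed. The p-value is
the plain fraction of permutations with `S_perm ≥ S_obs`; ties count
against the observed score, which keeps the estimator valid and slightly
conservative, and the observed score is recomputed by the same code path
so the comparison is exact up to a 1e−12 float guard. The plain fraction
can return 0; a `(b+1)/(n+1)` pseudo-count variant is available behind a
flag. Each pair draws its permutations from a stream derived from
`(seed, pair index)`, so p-values are reproducible independent of
evaluation order or parallelism. An exhaustive mode enumerates all
`C(n, n_t)` partitions when their number is below a cap (default
50,000); at 3+3 samples this is 20 partitions and the smallest possible
p is 1/20. Permutations that render a within-group vector constant have
their correlation set to 0 rather than dropped, keeping the denominator
fixed; observed pairs with constant within-condition vectors are skipped
with a logged reason because their correlation is undefined.

**Network.** Edges are pairs with p strictly below alpha (default 0.05,
unadjusted — raw per-pair significance is the intended operating point
for this screen; a BH option exists on the caller's side via
`bh_adjust`). The network is a directed bipartite miRNA→gene graph with
no isolated nodes. Topology summaries: the miRNA out-degree histogram
with an ordinary-least-squares slope of log10(count) on log10(degree)
over nonzero bins (a descriptive statistic only, not a power-law fit),
and the histogram of pairwise miRNA–miRNA shortest paths on the
undirected view, where two miRNAs sharing a target are at distance 2 and
unreachable pairs are counted separately rather than binned. A
miRNA-projection distance, if wanted, is the bipartite distance halved.

## Risk classification

Labels come from the data themselves. TP = union of curated disease
miRNA lists ∩ network miRNAs. TN candidates are ranked by the sum of six
ranks — mean expression and variance, each over all / tumor-only /
normal-only samples, rank 1 = smallest, average ranks for ties, final
ties broken lexicographically for determinism — and the k lowest (k = 95
by default) are filtered to exclude TP members and miRNAs outside the
network. The intent is that miRNAs that are both lowly and stably
expressed everywhere are unlikely to be functional.

Five features per network miRNA: out-degree; number of co-regulating
miRNAs (sharing ≥ 1 target); fraction of those co-regulators in the
disease set (0 when there are none); number of own targets also
targeted by a disease miRNA other than itself (bounded by out-degree);
and log2((mean_t + 1)/(mean_n + 1)) — the pseudo-count keeps the fold
change finite and symmetric on a log scale, since a raw ratio is
undefined at zero means.

The classifier is an RBF-kernel SVM. Features are z-scored inside each
training fold only (no leakage into validation folds). A real-coded
genetic algorithm searches (log10 C ∈ [−2, 3], log10 gamma ∈ [−3, 1])
with population 20, 15 generations, tournament size 3, uniform crossover
(p = 0.5), Gaussian mutation (sigma = 0.3, per-gene probability 0.5) and
elitism 2; fitness is the mean stratified 5-fold cross-validated AUC on
folds fixed once per training call, with a cache so repeated genomes are
not re-evaluated. Everything is seeded and deterministic. The final
model is refit on all labeled miRNAs with a Platt-style sigmoid fitted
within cross-validation, giving probability-like scores in [0, 1]. AUC
is computed as the normalized Mann–Whitney U statistic (ties count 1/2);
scikit-learn's ROC implementation serves only as a cross-check in the
tests.

**Recognition threshold.** The cutoff is the maximum score of any TN
example nudged up by one representable float, so the strict rule
`score > threshold` labels zero TN positive by construction. This is the
normative behavior; any particular numeric cutoff (such as 0.825 on a
real cohort) is a consequence of the TN scores, not a tunable input.

## Set statistics

Overlap surprise is the hypergeometric upper tail
`P(X ≥ x) = 1 − Σ_{t<x} C(M,t)·C(N−M,K−t)/C(N,K)`, computed by
log-sum-exp over log-pmf terms for numerical stability; the tail
includes x (the enrichment convention). Elements of either set absent
from the universe are dropped with a warning and never enlarge N — the
universe is an explicit argument because overlap p-values are only
meaningful relative to a stated background. BH adjustment is the
standard step-up (delegated to statsmodels), applied within one screen
or one enrichment run and never pooled across screens.

## Survival

Median splits assign ties at the median to the low group (deterministic;
configurable in spirit by negating the values). Kaplan–Meier estimation
and the one-degree-of-freedom log-rank test are delegated to lifelines,
with events processed before censorings at tied times (the standard
convention). No events in either group returns chi2 = 0, p = 1 with a
warning instead of failing. The screen reports per-feature group sizes,
chi2, raw p, BH q across the screened features (whether to adjust is
left to the reader, so both are reported), and a direction label from
comparing restricted mean survival time up to the smaller group maximum
(`high_worse` when the high-expression group has the shorter restricted
mean). Features with a degenerate split or a group below 2 samples are
skipped with a logged reason.

## Phenotype associations

One screening core serves both phenotype types: pairwise-complete
observations, a minimum-n guard (default 20 for drugs, 3 for
abundances), constant vectors skipped, BH across the whole screen. The
immune screen uses Spearman (abundance fractions are bounded and
skewed); the drug screen uses Pearson on log-IC50 with the significance
rule |r| ≥ 0.2 (inclusive; a 1e−12 epsilon absorbs float round-off for
correlations constructed exactly at the boundary) and q < 0.05. Negative
drug correlations mean high expression tracks lower IC50 (more
sensitive lines). IC50 values are assumed already log-transformed, the
GDSC convention. High-vs-low group comparisons reuse the ≤-median rule
and a two-sided Wilcoxon rank-sum test (exact for small tie-free
samples via scipy's automatic method selection).

## Synthetic data

The generators emulate the statistical structure the pipeline assumes,
not RNA-seq count mechanics. Expression is a Gaussian copula with
log-normal marginals: each pair's latent layer is bivariate normal with
Pearson parameter `2·sin(pi·rho_s/6)`, the exact relation that makes the
realized Spearman equal the target `rho_s`; the monotone marginal
transform preserves ranks. Dysregulated pairs use (rho_tumor,
rho_normal) = (0.6, 0.0) by default, null pairs an equal rho in both
conditions (0 by default). Each gene is the coupled partner of at most
one planted pair, so planted correlations never interfere.

The default desk-scale scenario — 60+60 samples, 150 miRNAs, 600 genes,
2,000 candidate pairs of which 200 are rewired, 1,000 permutations —
runs the full pipeline in a few minutes on one CPU while leaving every
stage's signal detectable. The planted structure: a risk block (10% of
miRNAs) receives 6–12 rewired targets each, membership in two
overlapping disease-list analogs (padded with decoy ids absent from the
matrices so the network-intersection step is exercised), and a 1.0 log2
fold change; a disjoint TN block (20 miRNAs) receives one rewired edge
(so it is in the network), plus strictly smaller marginal mean and
variance than every other miRNA, making it the provably correct answer
of the rank-sum negative selection.

Survival times are exponential with log-hazard linear in the mean
standardized log-expression of the driver features (baseline hazard
1/1000 per day, coefficient 0.8 by default); censoring is an
independent exponential whose rate is solved numerically so the expected
censored fraction is 30%. Immune abundances are exact compositions: the
last cell type is a dominant filler absorbing the remainder (mimicking
the one-or-two-dominant-cell-types shape of deconvolution output), the
others are bounded Beta fractions, and planted cell types are reordered
along a Gaussian-copula latent so the realized Spearman with the chosen
feature hits its target exactly in rank terms. Cell-line expression uses
Gaussian log-scale marginals (clipped at zero, a negligible tail) so
planted drug correlations are Pearson-exact; ~10% of IC50 entries are
masked as missing. All generators are pure functions of (config, seed)
and every scenario is written with machine-readable ground-truth files.

**What passing tests do not show:** the generator has no library-size or
count-noise structure, no batch effects, no tumor subtypes, and its
planted effects are homogeneous. Recovery rates on it demonstrate the
correctness and calibration of the machinery, not expected performance
on a real cohort, where effect sizes, confounding and annotation error
dominate.

## Pipeline

Stages (filter → dysregulation → network → labels → features → classify
→ overlap/enrichment → survival → associations) each read declared files
and write TSV/JSON outputs plus a manifest with parameter echoes,
wall-clock and sha256 checksums. One global seed; per-stage substreams
derive from a hash of (seed, stage name) so reordering stages cannot
silently reshuffle randomness. `resume` loads any stage whose outputs
already exist; the fitted SVM is not serialized (training is
deterministic and cheap), so deleting the predictions re-runs the
classify stage.

## Numerical choices and limitations

- Zero in the expression filter means exactly 0.0 after parsing
  (inputs are count-derived normalized values); "more than 10%" is a
  strict inequality, so exactly 10% zeros is kept. The filter consults
  normal samples only, with an all-samples switch defaulting off.
- Permutation p-values are unadjusted across pairs by design; the
  5% false-positive rate among null pairs is the expected behavior.
- The log-log degree slope uses OLS on binned counts and is reported
  as a description, not a scale-free test.
- Feature ids are case-sensitive strings; no miRBase alias resolution.
- The GA is a small heuristic search: it matches or beats a coarse
  grid on the test scenarios but carries no global-optimality claim.
- Classifier label sets at desk scale are small (tens of miRNAs), so
  per-fold AUCs are coarse-grained; the cross-validated mean is the
  quantity to trust.
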