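# Methods

`benchrank` analyzes *assessment data* from benchmark challenges: for a
challenge with *m* tasks, *p* competing algorithms and *n_k* test cases
per task, the input is the long table of per-case metric values (one
value per task × algorithm × case), together with a single
metric-direction flag for the whole run. The package computes
rankings, quantifies their stability, and renders the standard figure
family. This note records the model and procedure choices, their
defaults, and the limits of what the synthetic tests demonstrate.

## Data handling and imputation

Missing per-case values (an algorithm failed to produce a result for a
test case) are imputed with an unfavorable constant before any
ranking: 0 by default for a larger-is-better metric, the observed
per-task maximum for a smaller-is-better one, both overridable. The
imputation is applied per task and only for algorithms that have at
least one record in that task; an algorithm entirely absent from a
task is excluded from that task's ranking and flagged in the
validation report, rather than being assigned fabricated performance.
Imputed values participate everywhere downstream — in aggregates, in
per-case ranks, and in the paired significance tests — and the report
states the imputed count. Imputation is idempotent.

## Ranking schemes and ties

Three schemes are implemented, all sharing the min-rank tie
convention (tied algorithms receive the minimum of the ranks they
span; after a tie of k algorithms at rank r the next distinct rank is
r + k):

* **aggregate-then-rank** — per-algorithm aggregate across cases
  (mean, median with the mid-point convention for even counts, or an
  empirical quantile with linear interpolation between order
  statistics), then rank.
* **rank-then-aggregate** — min-tie ranks within every case,
  aggregated per algorithm (mean or median), then re-ranked.
* **test-based** — for every ordered pair (A, B) a one-sided paired
  Wilcoxon signed-rank test of "A superior to B"; an algorithm's score
  is its number of significant superiorities after Holm adjustment,
  and algorithms are ranked by descending score, equal counts sharing
  a rank.

The default scheme throughout (CLI, report, figure ordering) is
aggregate-then-rank with the mean.

## Significance testing

The one-sided signed-rank test drops zero differences before ranking
magnitudes (the classic convention; the dropped count is recorded).
For up to 25 nonzero pairs (configurable) the exact conditional null
distribution is used, computed by convolving the per-rank two-point
distributions — with midranks doubled to integers this is identical
to enumerating all 2^n sign assignments, including under tied
magnitudes. Beyond 25 pairs a normal approximation with continuity
and tie correction is used.

The Holm family is all p·(p−1) one-sided hypotheses within one task —
the most conservative reading consistent with a per-task significance
map; adjustment never spans tasks. Degenerate pairs (all differences
zero) contribute p = 1 and are counted. On null data this controls
the family-wise error at the nominal level, which the suite verifies
empirically across 200 simulated null challenges.

## Comparing rankings and consensus

Kendall's tau uses the tie-corrected tau-b variant, since challenge
rankings frequently contain ties; it is undefined (and signaled as
such) when a ranking is fully tied. Computed values are rounded at
1e−12 so exact concordance and inversion report exactly ±1.
Spearman's footrule and squared-rank distance difference whatever
rank convention the caller supplies.

The cross-task consensus first re-expresses each task's ranks in the
average-tie convention, then either (default) averages ranks across
tasks — each task weighted equally, independent of its sample size or
stability — and min-tie-ranks the averages, or searches for the
tie-free ordering minimizing the summed footrule/squared-rank distance
to the per-task rankings (exhaustive for p ≤ 8, pairwise-swap local
search seeded by the mean-rank ordering beyond; among tied minimizers
the lexicographically smallest ordering is reported). With the
squared-rank distance the mean-rank ordering is itself always a
minimizer, which the suite checks by exhaustive enumeration over
random tie-free profiles.

## Bootstrap stability

One bootstrap sample of a task with n cases is n cases drawn with
replacement; a case drawn twice contributes twice to aggregates and
tests. The full ranking procedure — including per-replicate Holm
adjustment for the test-based scheme — is re-run on each of b
replicates (default b = 1000). Replicates where the method ties
everything are kept; their tau against the full-data ranking is
undefined and excluded from violin summaries with a logged count.
Summaries are the per-algorithm rank-frequency matrix, median rank,
and a percentile interval (default 95%: the 2.5th–97.5th percentiles,
linear interpolation between order statistics). Resampling is driven
by `numpy.random.default_rng(seed)`; identical inputs give
bit-identical results. A caution is emitted for tasks with fewer than
20 cases, where bootstrap summaries are fragile.

## Figures

Every figure separates a pure, seeded computation from rendering, so
all plot data is unit-testable. Podium tie-breaking uses random
placement of tied algorithms under its own logged seed; dot plots
jitter horizontally only; blob areas scale linearly with relative
rank frequency (scaling constant 2000 pt² per unit frequency); the
violin input is exactly the bootstrap tau distribution, never a
separate computation. Axes order algorithms by the selected ranking
(single task) or the consensus (multi-task); beyond ten algorithms
the marker/linestyle alphabet doubles (circles/solid, then
triangles/dashed). Podium plots refuse more than 30 algorithms and
suggest top-list truncation. Task similarity uses the footrule
distance by default, complete-linkage agglomeration for the
dendrogram, and target edge lengths exp(0.05·distance) for the
network graph; node colors mark unique task winners, ties leave the
node uncolored. Rendering aesthetics are best-effort, not pixel-exact.

## Synthetic challenges

Two canonical single-task scenarios, both emulating a bounded
larger-is-better metric such as the Dice coefficient over 5 algorithms
and 50 cases:

* **ideal** — algorithm A_k draws uniformly from [1 − 0.1k, 1.1 − 0.1k);
  the disjoint strata make the true ranking unambiguous for any seed,
  so every scheme must return 1..5 in stratum order and every
  stability summary must collapse (all bootstrap replicates identical,
  all tau = 1, full upper-triangle significance).
* **random** — 250 draws from Normal(mean 1.5, variance 1) mapped
  through the logistic function 1/(1+e^−x) onto (0, 1) and assigned
  sequentially to the algorithms; all algorithms share one skewed
  distribution, so any observed difference is chance.

`generate_custom` generalizes these to multiple tasks, other
distributions (uniform, logistic-normal, beta) and pre-imputation
missingness. These generators emulate the *distributional* features
of challenge data (bounded skewed metrics, separability extremes,
per-case failures) but not others — per-case correlation between
algorithms (all columns are drawn independently), heterogeneous case
difficulty, or algorithm-specific failure modes. Tests passing on
them therefore demonstrate correctness of the procedures, not
stability properties of any real challenge.

## Problem sizes and determinism

The suite exercises the study conditions directly: n = 50, p = 5,
b = 1000 for the degenerate-scenario checks; 200 seeded replications
for type-I control; 500 random profiles for the consensus
equivalence; full 2^n enumeration up to n = 10 for the exact test.
Smaller b is used only where the check is exactly invariant to b
(e.g. reproducibility, frequency marginals). All randomness flows
from explicit seeds.

## Known limitations

* Task weights in the consensus are uniform; weighted consensus is
  not implemented.
* No bias-corrected/accelerated bootstrap intervals — plain
  percentile intervals only.
* Mean-rank-style post-hoc test diagrams are deliberately not offered
  for ranking (their outcome for a pair depends on the other
  algorithms present); only the significant-count test-based scheme is
  provided.
* Multi-metric single-task challenges are handled by relabeling
  metrics as tasks; there is no dedicated multi-metric schema.
* The local-search fallback of the distance-minimizing consensus
  (p > 8) is a heuristic and may return a local optimum.
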