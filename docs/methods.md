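# Methods

This note documents the statistical procedures implemented in `drga`, the
choices made where the design was genuinely open, and what the synthetic
data used in the test suite does and does not establish.

## Data model and input handling

Expression is a genes × samples numeric matrix; orientation is controlled by
a flag at load time. Non-numeric cells become missing, and all downstream
correlation statistics use pairwise-complete observations — this maximizes
usable data but means different gene/feature pairs can rest on different
sample subsets. Genes with fewer than two distinct finite values are flagged
constant and excluded from correlation-based analyses (their correlations
are undefined).

Clinical features are auto-typed: a numeric column with ≤ 5 distinct
non-missing values is treated as categorical (tumour-stage-like ordinal
codes), other numeric columns as continuous, non-numeric columns as
categorical. The threshold of 5 is a heuristic for stage/grade-style codes;
explicit per-column overrides always win. Survival requires a nonnegative
time and a 0/1 event indicator; samples with missing survival are kept in
the dataset and dropped only inside survival analyses.

Sample alignment intersects expression and clinical samples (expression
order wins), drops driver genes absent from the matrix with a warning, and
errors on an empty intersection or an empty surviving driver list.

## Enrichment

Over-representation of the driver list in each gene set is scored by the
one-sided hypergeometric tail P[X ≥ k | N, K, n]: N the universe size
(default: all genes in the expression matrix — the background a gene had a
chance to be called from), K the set size within the universe, n the query
size, k the observed overlap. This equals the one-sided Fisher exact test on
the 2×2 overlap table, which the test suite verifies directly. Multiple
testing uses Benjamini–Hochberg across the returned (overlap ≥ 1) sets;
q ≤ 0.05 flags a set. Term-graph-aware corrections used by web enrichment
services require the annotation hierarchy and are deliberately out of scope;
BH over user-supplied GMT collections is the transparent, reproducible
replacement. Sets are treated uniformly regardless of source; "which
organism" reduces to "which GMT files you pass".

## Gene–feature and gene–survival screening

Correlation methods: Pearson (linear), Spearman (ranks), Kendall's
τ = (C − D)/(C + D) over concordant/discordant pairs. The tie-free τ (tau-a)
is undefined behaviour under ties, so with ties present the tie-corrected
tau-b is computed and the deviation logged. p-values are two-sided
throughout: Pearson/Spearman via the t approximation with n − 2 df, Kendall
by exact enumeration for n ≤ 10 without ties and the normal approximation
otherwise. BH families are per feature (each feature's gene family is
adjusted separately), matching the one-report-per-analysis output layout.

The survival screen dichotomizes each gene at its median (default; the mean
is available) — a sample is "up" when expression strictly exceeds the
threshold — then fits a univariate Cox proportional-hazards model on the
group indicator. The hazard ratio is exp(β̂) with a Wald 95% CI on the log
scale; the p-value is the log-rank (score) test, which for a binary
covariate is the standard two-group log-rank comparison. Ties use the Efron
approximation (less biased than Breslow at moderate tie rates). The Newton
solver runs at a 1e-10 step tolerance: with small n the partial likelihood
is flat enough that looser tolerances stop visibly short of the MLE. BH is
applied across all genes in the screen; q ≤ 0.05 flags a gene. Limitations:
censoring is handled only through the Cox partial likelihood (no competing
risks, no time-varying effects), and dichotomization discards within-group
dose information by construction.

## Co-expression modules

Gene dissimilarity is 1 − |r| (unsigned, default) or (1 − r)/2 (signed).
This is a deliberately minimal similarity construction: no soft-threshold
adjacency power and no topological overlap — the automation being tested
here is linkage and cut selection, and a TOM layer can be slotted in front
of the clustering without touching it.

Agglomeration supports single, complete, average, and Ward linkage via the
Lance–Williams recurrences. "Ward" is the D2 variant: the recurrence runs on
squared dissimilarities and merge heights are square roots, which minimizes
the within-cluster error sum of squares when distances are Euclidean. All
four linkages are monotone, so merge heights never decrease.

The linkage is selected automatically by the Kaufman–Rousseeuw agglomerative
coefficient, AC = mean over items of (1 − h_first(i)/h_final): values near 1
mean items join tight clusters long before the final merge. The linkage with
the largest AC wins; exact ties (e.g. n = 2, where every AC is 0) resolve by
the fixed precedence ward > average > complete > single. AC is invariant to
uniform rescaling of the dissimilarities, so linkages are compared on shape,
not scale. Note AC tends to grow with n and with heavier-tailed linkages
(Ward's heights aggregate, inflating h_final), so comparisons are only ever
made between linkages on the same data, never across datasets.

The number of modules reuses the three-index consensus described below over
k = 2..min(15, n_genes − 1); without consensus the silhouette-best k is used
with a prominent warning. Clusters below `min_module_size` (default 30, the
common co-expression convention; lower it for small panels) are relabelled
"grey" (unassigned); surviving modules get colour names by decreasing size.

The module eigengene is the first principal component of the standardized
(z-scored per gene, ddof = 1) member expression, sign-oriented to correlate
positively with the mean member profile and rescaled to zero mean/unit
variance — so a single-gene module's eigengene is that gene's standardized
profile exactly, and eigengenes are invariant to per-gene affine rescaling
of raw expression. Module–trait association is the Pearson r and p between
each eigengene and each continuous feature, rendered as a heatmap PDF with
r and p printed per cell. Hub genes are the top five per module by
intramodular connectivity k_in(g) = Σ |r(g, g′)| over same-module partners,
ties broken lexicographically; modules smaller than five return all members.

## Patient stratification

Samples are clustered on Euclidean distance over per-gene standardized
driver expression (so each driver contributes equally regardless of its raw
scale); constant drivers and drivers with missing values are dropped first.
Linkage is auto-selected as above. Candidate subgroup numbers (default
2..min(10, n − 1)) are scored by three internal validity indices:

- **average silhouette** (maximize, in [−1, 1]): mean of (b − a)/max(a, b);
  singletons score 0;
- **Dunn's index** (maximize, ≥ 0): minimum between-cluster pointwise
  distance over maximum within-cluster diameter; an all-singleton partition
  has zero diameter and is reported as +inf;
- **connectivity** (minimize, ≥ 0): for each point, a penalty 1/j for each
  of its L nearest neighbours (default L = 10, the index's conventional
  default) assigned to another cluster; 0 iff every local neighbourhood is
  cluster-pure. Neighbour ties break by item order, making the index
  deterministic.

Each index votes for its best k (ties to the smallest k — parsimony). The
chosen k is the unanimous vote, else the value two of three agree on, else
none: "no optimal number" is a first-class outcome — the validity traces are
still written and the CLI exits with a distinct status (3) so workflows can
branch on it.

Subgroups (ids 1..k by decreasing size) are compared on survival by
univariate Cox: one HR for k = 2; for k > 2, each smaller subgroup versus
the largest as reference, one contrast per fit. Clinical features are
compared with an automatically dispatched test:

| declared type + normality | test (2 groups / >2) | summary |
|---|---|---|
| continuous, Shapiro–Wilk accepts in **every** subgroup | Welch t / one-way ANOVA | mean (SD) |
| continuous, rejected anywhere | Mann–Whitney U / Kruskal–Wallis | median [IQR] |
| categorical (incl. ≤ 5-level numerics) | χ² (no continuity correction); Fisher exact for 2×2 with any expected count < 5 | counts (%) |

Normality is assessed per subgroup at α = 0.05 (Shapiro–Wilk, Royston
algorithm, 3 ≤ n ≤ 5000) because the parametric tests assume normality
within groups, not marginally; subgroups too small to test (n < 3) force the
nonparametric branch as the conservative default. The summary style follows
the dispatch branch rather than being configured per column, which keeps
the comparison table self-describing. Output goes to CSV (canonical,
diff-friendly) with an xlsx twin.

## Synthetic data

The generators plant known structure so recovery can be scored exactly:

- **Modular expression**: gene g in module m is
  x_g = √b·u + √(w − b)·v_m + √(1 − w)·e_g with shared factor u, module
  factor v_m, and noise e_g — within-module correlation w, between-module b,
  positive semi-definite for any 0 ≤ b ≤ w < 1 by construction. Defaults
  (60 genes, 3 modules, w = 0.8, b = 0, 200 samples) give planted modules
  that clean co-expression methods should recover essentially perfectly.
- **Subgrouped expression**: even sample split with a per-group mean shift
  (default 2 SD on 20 genes, n = 60) — a strong but not degenerate subtype
  signal.
- **Survival**: exponential event times with the group-1 hazard multiplied
  by exp(log HR) (default ln 2, baseline rate 0.1) and independent
  exponential censoring (default rate 0.02, ≈ 17% censoring); the event
  fraction follows the competing-exponentials identity rate/(rate + censor).
- **Clinical features**: normal, lognormal, or categorical with per-group
  effects, recorded in a plain-text truth sidecar.

One seed fans out to independent per-generator streams
(`SeedSequence([seed, stream])`), so adding a generator never perturbs
existing fixtures, and identical (parameters, seed) give bit-identical data.

What passing on this synthetic data does **not** show: real expression is
not multivariate normal (counts, skew, heavy tails), real modules are not
exchangeable blocks with sharp boundaries, real subtypes differ on subsets
of genes with unequal effect sizes, and real censoring is rarely
independent-exponential. The tests establish correctness of the machinery
and its decision logic under the stated models, not field performance.

The `drga simulate` demo bundle superimposes a 2-SD two-subgroup shift on
the modular expression and ties survival to the subgroups, so a single
fixture exercises every stage with recoverable signal.

## Numerical and degenerate-input choices

- Dissimilarity matrices must be symmetric (1e-12), finite, nonnegative,
  zero-diagonal; they are exactly symmetrized before condensed-form
  conversion.
- A tree whose final merge height is 0 (all items identical) has no defined
  AC and errors as degenerate.
- Dichotomization errors on constant vectors and on splits leaving a group
  empty (e.g. a median equal to the maximum).
- Cox fits error on zero events or an empty group after missing-survival
  removal; groups separated in time give divergent β̂ and an infinite HR/CI
  bound, reported as-is.
- Index traces may contain +inf (Dunn on all-singleton partitions); index
  votes treat exact ties, including tied infinities, as "smallest k wins".
- Reported tables use 6 significant digits, tab-delimited, LF endings, so
  repeated runs are byte-identical.

## Problem sizes in the validation suite

The acceptance checks run at the sizes their statistics need and no larger:
200 random instances (n ≤ 12) for brute-force oracle equivalence, 60 genes ×
200 samples for module recovery, 60 samples for subgroup recovery, 200
replicates at n = 500 for Cox log-HR bias, 100 screens of 10 genes at
n = 200 for the null discovery rate, and 10,000 replicates at n = 50 for the
Shapiro–Wilk type-I rate. The full suite runs in about a minute on one CPU.
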