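# Methods

## Data model

The unit of observation is a *disease incidence*: one (miRNA id, disease
id, direction) record, direction ∈ {UP, DOWN}. Exact duplicate records are
collapsed at ingestion with a logged warning; records that differ only in
direction are retained as distinct incidences (a pair reported both UP and
DOWN is biologically meaningful and is surfaced as BOTH in rule
annotations). Identifiers are free non-empty tokens without tabs; the
pipeline is vocabulary-agnostic, though the packaged fixtures use the
conventional disease abbreviations (ATS, HF, TAA, …) and `hsa-miR-*` names.

## Bipartite network and hubs

The network collapses incidences to undirected (miRNA, disease) edges;
direction is deliberately excluded from the topology and lives in the
statistics and mining layers. Degree is the only centrality computed. Hub
criteria follow the ">5 disease edges" / ">10 miRNA edges" convention,
implemented as degree ≥ 6 and ≥ 11 respectively (strict inequality on the
printed thresholds); both are parameters. All tables are emitted in
deterministic order (descending degree, lexicographic tie-break) so reports
are byte-stable. Exports are SIF (edges only; isolated nodes as bare-name
lines, which SIF cannot type and readers therefore skip) and GraphML with
`partition` and boolean `hub` node attributes (via networkx); GraphML
round-trips nodes, partitions and edges exactly.

## Disease-specific dysregulation statistics

Per disease: n_up, n_down, dominant direction (TIE on equality), and the
dominant percentage under **truncation** at one decimal, computed in
integer arithmetic as ⌊1000·k/n⌋/10. Truncation, not rounding, is the
convention of the summary tables this mirrors (e.g. 12/23 → 52.1,
19/36 → 52.7, 8/9 → 88.8; rounding would give 52.2, 52.8, 88.9). Whether
such denominators count events or distinct miRNAs is ambiguous in curated
summaries; we count events, consistent with the incidence data model.

The association test uses the only 2×2 construction expressible from
event tallies: rows = this disease vs all other diseases, columns = UP vs
DOWN events; a + b + c + d = total incidences. The two-tailed Fisher exact
test is computed from first principles: with margins fixed, the
unnormalized hypergeometric weights C(r1,k)·C(r2,c1−k) are enumerated over
the support of k, and the two-sided p is the weight sum over tables with
weight ≤ the observed weight (minimum-likelihood convention, the dominant
reading of "Fisher two-tailed"), divided by C(N,c1). All comparisons happen
on exact integers, so ties are resolved exactly and the only floating-point
step is one correctly-rounded division (observed agreement with an
independent hypergeometric-enumeration oracle over all 628,055 tables with
N ≤ 60: max |Δ| ≈ 7e-16). Weights are memoized per margin triple.

`fisher_two_tailed` refuses tables with a zero margin (the test is
undefined). The batch runner `run_all_diseases` handles one principled
degenerate case itself: when an entire dataset contains only one direction,
a column margin is zero and the conditional distribution collapses onto the
single achievable table, so those diseases report p = 1.0 rather than
aborting a whole run on data that simply carry no directional contrast.
Raw p-values are reported by default; Benjamini–Hochberg step-up adjustment
(delegated to statsmodels) is available behind a flag, as multiplicity
correction is an option, not the default convention, for this analysis.

## Association-rule mining

Transactions are diseases; items are the miRNAs with ≥ 1 incidence there
(set semantics; direction-agnostic by default, since published rule tables
annotate directions per rule rather than mining signed items — a signed
mode tagging items as `mirna:UP` / `mirna:DOWN` is available behind a
flag). The frequency threshold converts fractional support as
support_count ≥ ceil(min_support × n_transactions), with a 1e-9 guard on
the float product so exact multiples (0.2 × 30) are not pushed up a count.

FP-Growth is implemented in full: global item order by descending support
count with lexicographic tie-break, FP-tree with header-table node links,
recursive conditional-pattern-base projection, and the single-path shortcut
(all subsets of an unbranched path, support = deepest node count). An
independent levelwise Apriori (candidate join + subset prune, supports by
direct transaction scans, guarded to ≤ 20 items) shares no code with the
FP-tree and serves as the equivalence oracle in tests.

Rules enumerate every non-empty proper subset of each frequent itemset of
size ≥ 2 as antecedent (multi-item consequents allowed, since published
clusters include 2⇒2 rules) and keep those with confidence ≥
min_confidence (+1e-12 tolerance on the float comparison). Annotation lists
the supporting diseases (transactions containing all rule items, sorted)
and, per disease, each item's direction (UP/DOWN/BOTH), one entry per item
per disease — published pattern columns are looser than this (sometimes
fewer direction letters than diseases), so we do not imitate their layout.

Defaults min_support = 0.2 and min_confidence = 0.6 are the thresholds of
the study this pipeline reimplements.

## Synthetic data generator

The generator emulates a curated cardiac miRNA snapshot. Defaults: 191
miRNAs, 30 diseases, 388 incidences, global up-fraction 224/388 ≈ 0.577 —
the published scale. Generation is layered, deterministic given the
mandatory seed:

1. **Planted itemsets** are embedded verbatim (every item × disease of the
   set, stated direction) so mining-stage recovery is exact by construction.
2. **Forced hubs**: for each (count, min_degree) requirement, randomly
   chosen miRNAs receive targeted edges to new diseases until the degree is
   met; infeasible requirements (min_degree > n_disease) error before any
   sampling.
3. **Coverage** (default on): every still-unreported miRNA gets one
   incidence — a curated snapshot only lists molecules with ≥ 1 report, so
   at the default scale all 191 miRNAs appear, giving mean degree ≈ 2.
4. **Background**: remaining incidences sample the disease from a weight
   vector (uniform by default), the miRNA from a truncated power-law over
   rank (exponent 1.3 by default — heavy enough that degree-≥ 6 hubs arise
   naturally at 388 draws), and the direction Bernoulli from the disease's
   bias or the global fraction. A sampled duplicate triple is resampled, so
   the incidence target is met exactly; a resampling budget converts
   near-infeasible configurations into errors.

Known distortion: near triple-space saturation, duplicate rejection is
direction-asymmetric (the majority direction collides more often), pulling
empirical biases toward 0.5. Bias-recovery checks therefore run at low
saturation (large item universe, flat tail), which is also the realistic
regime. What the generator does **not** emulate: real miRNA nomenclature
or family structure, literature citation sparsity patterns, and any
correlation between a disease's size and its direction bias — so passing
tests demonstrate algorithmic correctness on HMDD-like structure, not
biological conclusions about real data.

Two literature-derived fixtures ship with the package: `table1_fixture`
(per-disease UP/DOWN counts with dataset totals 224/164; DOWN counts
derived from each printed dominant fraction; undisclosed diseases pooled
into one remainder pseudo-disease when materialized) and `table2_fixture`
(a six-disease all-DOWN co-occurrence dataset whose mined rules at
0.2/0.6 reproduce the published cluster associations). The published rule
table is internally inconsistent about one rule's disease list ("155 ⇒
133a-1" must hold wherever "155 ⇒ 133a-1, 133a-2" does); the fixture
realizes the consistent reading, and its one single-disease rule (the AF
cluster) falls below the 2-of-6-transaction support floor and is
intentionally not recoverable at the default thresholds.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs chosen as the smallest sizes
that exercise each property: exhaustive Fisher validation at N ≤ 60
(628k tables), 200 random databases (≤ 10 items, ≤ 30 transactions) for
FP-Growth/Apriori equivalence, 2000 disease-level null tests for the
rejection-rate bound (Fisher is conservative; the observed rate sits well
below 0.05, asserted ≤ 0.07), and 3600-incidence generations for bias
recovery within 0.05. The snapshot-dependent headline counts of the
original study (16 hub miRNAs; 50 rules / 26 frequent itemsets; the printed
per-disease p-values, whose 2×2 construction is not derivable from the
published tallies) are properties of an unavailable database snapshot, not
of the method, and are deliberately not asserted; planted-structure
recovery substitutes for them.
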