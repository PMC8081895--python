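# Methods

## Scope and data model

`airprio` operationalizes a biomarker-prioritization workflow for three
related airway conditions — respiratory allergy (RA), allergic asthma (AA)
and non-allergic asthma (NA). The central data structure is the disease
characterization: a catalogue of 16 molecular motifs, each marked per
disease as strongly implicated, weakly implicated, or not implicated, and
each carrying a set of effector proteins. Disease-level effector sets are
the union over implicated motifs; a configuration question left open by the
source characterization is whether weakly implicated motifs should count at
reduced weight — we include them at full weight (the conservative reading of
"weaker but still relevant") and keep the implication level in the data
model so alternative weightings can be layered on without changing the
format.

Three motif groups have *differential weight* per disease and drive the
specificity analysis: acute response and late-phase response for RA;
Th2-mediated pulmonary inflammation, goblet-cell hyperplasia and
granulocyte (eosinophil) infiltration for AA; Th17-mediated pulmonary
inflammation and neutrophil infiltration for NA.

## Relationship scoring

The original analysis scored candidates with a proprietary artificial-
neural-network system whose stated mechanism is finding short paths between
candidates and disease effectors. We implement that mechanism directly and
transparently. For candidate $c$ and network-present effectors $E'$:

* **decay_shortest_path** (default): $s = 100\,|E'|^{-1}\sum_{e\in E'}
  \lambda^{d(c,e)}$ with per-hop decay $\lambda = 0.5$ (one hop halves a
  contribution; configurable in $(0,1)$) and $\lambda^{\infty}=0$ for
  unreachable effectors. The score is bounded, monotone under moving closer
  to effectors, and strictly decreases when a far effector joins the set
  (it is an average, not a sum — deliberate, so that score 100 means "is
  the effector set", not "is near many effectors").
* **random_walk_restart**: personalized PageRank from the candidate with
  restart probability 0.15; the mean stationary mass on $E'$ is normalized
  by the candidate's own stationary mass so the trivial self-case scores
  100, and clamped to $[0,100]$. Offered because pure shortest paths ignore
  path multiplicity; not used by the packaged analyses.

Effectors absent from the network are dropped with a warning rather than
treated as infinitely far — the same convention the source analysis applied
to candidates without reported interactions. Candidates absent from the
network are a hard error; `validate_candidates` partitions a panel into
retained / absent / hub proteins first. Hub exclusion (degree above a
network-wide degree quantile) defaults to off, since absence is the only
exclusion documented for the original panel (one candidate of 94).

Scores map onto four categories with lower-bound-inclusive thresholds
≥ 92 very high, ≥ 78 high, ≥ 38 medium, else low. These thresholds are part
of the published scale and are configuration, not fitted values.

**Permutation p-values.** The published category scale carries p-value
bands without a stated null model, so the package reports its own
construction separately from the category: the score is compared against
uniformly drawn non-effector network nodes (candidate excluded), with
add-one smoothing $p = (1+k)/(1+n)$. When the null population is no larger
than the requested draw count it is enumerated exhaustively, making small-
graph p-values exact.

## Specificity

The published ranking combines whole-disease and specific-motif scores into
a specificity flag without printing a formula. The codified rule is the
minimal one consistent with the published flags:

1. *gate*: the candidate reaches at least the high category for the disease,
   via the whole-disease score or the best specific-motif score;
2. *dominance*: its best score over the disease's specific motifs strictly
   exceeds its best score over every other disease's specific motifs.

Maxima (not means) are used across motifs because a published allergy-
specific example combines one very-high motif score with a near-zero one.
Strictness makes flags mutually exclusive; candidates whose best motif
scores tie across diseases are specific to nowhere, which is exactly how the
packaged score panel encodes published "highly related but non-specific"
proteins. Both the gate category and strict-vs-non-strict comparison are
exposed as parameters for sensitivity analysis. Candidates that clear the
high bar for a disease without any specificity flag are reported separately
(`high_nonspecific`).

The record keeps three classification views: the whole-disease level, the
specific-motif level, and their combination (the view printed in the source
tables).

## Triggering

"Can this protein activate the disease effectors?" is operationalized as
reachability: the trigger set of a protein is the set of effectors reachable
from it, optionally within a path-length bound, following directed edges
forward, and — when sign information exists — optionally requiring some path
with net-activating parity (an even number of inhibiting edges). Individual
probability = triggered fraction of network-present effectors, in $[0,1]$.

The star display uses four cutpoints; by default they are the quintiles of
the panel's probability distribution (the published scale is explicitly
approximate), overridable with fixed cutpoints.

Cumulative coverage uses standard greedy maximum coverage: repeatedly take
the protein adding the most uncovered effectors (ties: higher individual
probability, then lexicographic symbol), stop at zero marginal gain. The
curve is non-decreasing by construction and ends at the coverage of the
union of all trigger sets. The published accumulated-score column is not
monotone in its printed order, so its exact definition (ordered cumulative
vs leave-one-in) is ambiguous; the package therefore reports both the greedy
curve and a per-protein leave-one-in coverage, and asserts neither as the
original's definition. Greedy coverage is within $(1-1/e)$ of the optimal
k-cover; the test suite verifies this bound against exhaustive set cover on
small instances.

## Expression validation

Inputs are genes × subjects matrices of log2 expression (or ΔCt) with group
labels and optional severity strata. Per comparison:

* fold change $RQ = 2^{\bar{x}_A-\bar{x}_B}$ (geometric, so label swap
  inverts it), two-tailed unpaired t-test on the log2 values, and
  Benjamini–Hochberg adjustment across the gene panel (the published tables
  say "adjusted P" without naming a method; BH is the field default and the
  method is configurable);
* ROC per gene with the Mann–Whitney AUC (ties counted half), a DeLong 95%
  confidence interval (hand-coded; cross-checked in the test suite against
  R's pROC implementation), and the Youden-optimal threshold. The AUC is
  reported for the stated comparison direction without flipping; the
  significance rule — the whole CI inside $[0.70, 1]$ — then selects
  discriminative genes.

The clinical design enumerator produces 18 comparisons from 4 groups with
severity strata in the two asthma groups: 6 pairwise group contrasts, 2
within-group severity splits, 2 same-severity cross-asthma contrasts, and 8
stratum-vs-control/allergy contrasts. The exact published composition is not
enumerated anywhere, so the enumerator is configuration-driven and the count
is checked, not the identity of each contrast.

## Synthetic data: what it emulates and what it does not

The interactome used by the original study is proprietary, and no
per-subject expression was deposited; the generator exists so that every
algorithm can be exercised against known ground truth.

* **Networks**: Barabási–Albert background by default (biological networks
  are heavy-tailed; attachment parameter 3 at 250–300 nodes for test-scale
  runs), Erdős–Rényi as an alternative. Each motif module is a connected
  subgraph (spanning path plus boost edges) whose members are the motif's
  effectors. Candidates are fresh nodes attached through dedicated chains,
  so their shortest-path distance to the module is exact by construction; a
  distance-0 candidate joins the module with several intra-module edges like
  any other member. Every planted distance is re-verified by BFS before the
  network is returned. Generation is deterministic under the spec seed.
* **Expression**: homoscedastic log-normal, control ~ N(8, σ²) on the log2
  scale, each group shifted by log2(RQ). The published tables carry no
  variance information, so σ is a preset parameter; the shipped preset uses
  the published fold changes of the four allergy-specific genes (0.21, 0.13,
  0.30, 0.15) at the published group sizes (27 controls vs 14 patients) with
  σ = 0.8, a typical qPCR between-subject spread. At these settings all four
  genes are recovered at BH-adjusted p < 0.05 in at least 95% of
  replicates, which the acceptance suite verifies over 100 seeds.

What passing these benchmarks shows: the estimators recover what was
planted, under clean modular structure and homoscedastic noise. What it does
not show: performance on the real proprietary interactome (unknown edge
semantics, density, annotation layers) or on real qPCR data (plate effects,
reference-gene normalization, heteroscedasticity) — the published numeric
ANN scores and AUC values are therefore *inputs* (fixtures) here, never
regenerated quantities.

## Numerical and degenerate-input conventions

* BFS hop distances; unreachable nodes are absent from distance maps.
* Undirected edges are stored once and count once toward degree; directed
  edges count in and out. Self-loops are ignored (no distance content).
* Ranking ties break by candidate symbol ascending, so all outputs are
  byte-reproducible under a fixed seed.
* Genes with zero variance in both groups: equal means → RQ 1, p 1;
  unequal → skipped with a warning. Constant genes in ROC → AUC 0.5,
  degenerate flag, never significant.
* Category classification rejects scores outside $[0,100]$; the decay score
  is clamped against floating-point overshoot before classification.

## Fixtures and provenance

The packaged tables transcribe published values exactly where they were
printed (whole-disease scores of the top two categories, the RA specificity
panel's motif columns, RQ tables, ROC summaries, the triggering table) and
are synthetic elsewhere, always inside the published category band for the
protein and motif concerned; synthetic files and rows are labelled as such
in headers and `source` columns. The 94-candidate panel contains the 80
published symbols plus 14 labelled placeholders, since the full list was
never published. Analyses that depend only on printed values (high-set
counts, overlaps, motif counts) are exact reproductions; the specificity
counts additionally depend on the synthetic in-band panel and are
regressions against the construction documented in the fixture headers.

## Known limitations

* The decay score is not calibrated to the original ANN scale; identical
  categories, not identical numbers, are the reproduction target.
* Trigger "activation" is reachability, not dynamics; no Boolean or
  quantitative simulation is attempted.
* The specificity rule is a reconstruction; other rules consistent with the
  published prose exist (the gate category and strictness switches bound the
  reasonable alternatives).
* Hub exclusion uses a single global degree quantile; no biological claim is
  attached to it.
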