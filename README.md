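# airprio

Network-based prioritization of biomarker candidates for asthma and
respiratory allergy.

Chronic airway diseases — respiratory allergy (RA), allergic asthma (AA) and
non-allergic asthma (NA) — are clinically heterogeneous, and candidate-gene
expression studies typically end with *too many* plausible biomarkers.
`airprio` implements a transparent systems-biology prioritization layer for
such panels: each disease is characterized as a set of pathophysiological
**molecular motifs** (e.g. *acute response*, *neutrophil infiltration*), each
with its **effector proteins**; candidate proteins are then scored by their
mechanistic proximity to those effector sets on a protein interaction
network, classified, checked for disease specificity, assessed as potential
disease *triggers*, and finally validated against grouped expression data.

The package is a library first: the importable API plus the short scripts in
`examples/` are the intended interface, with a thin `airprio` command-line
driver for running the pipeline from a shell.

## The model

**Relationship score.** For a candidate $c$ and an effector set $E$ on a
network with hop distance $d(\cdot,\cdot)$, the default score is the decayed
proximity

$$s(c, E) = \frac{100}{|E'|}\sum_{e \in E'} \lambda^{d(c,e)}, \qquad
\lambda = 0.5,\; \lambda^{\infty} = 0,$$

over the network-present effectors $E'$. It is bounded in $[0, 100]$,
monotone in distance, and equals 100 when the candidate is the sole effector.
A random-walk-with-restart variant is available when path multiplicity
matters. Scores fall into four categories: **very high** (≥ 92), **high**
(78–92), **medium** (38–78), **low** (< 38). An empirical permutation
p-value against a random-node null can be attached to any score.

**Specificity.** A candidate is *specific* to a disease when (a) it is at
least highly related to it — through the whole-disease score or a
disease-specific motif — and (b) its best score over that disease's specific
motifs strictly exceeds its best score over every other disease's specific
motifs. Strictness makes the flags mutually exclusive.

**Triggering.** A protein's trigger set is the subset of effectors it can
reach on the network (optionally bounded path length and sign-aware); its
individual probability is the fraction of effectors reached, shown on a
1–5 star scale, and a greedy maximum-coverage pass reports the cumulative
percentage of effectors covered by the best protein combination.

**Validation.** Differential expression is reported as the geometric fold
change $RQ = 2^{\bar{x}_A - \bar{x}_B}$ (log2 scale) with an unpaired t-test
and Benjamini–Hochberg adjustment; discrimination per gene uses the
rank-statistic AUC with a DeLong 95% CI and a Youden-optimal threshold, a
biomarker being called significant when its CI lies within $[0.70, 1]$.

Because the interaction network behind the original analysis is proprietary,
the package ships the published score tables as fixtures (classification,
overlap and specificity run on them exactly) and a **synthetic-data module**
that generates scale-free interactomes with planted effector modules,
candidates at exact planted distances, and qPCR-like expression with
prescribed fold changes — so every algorithm is testable against known
ground truth.

## Worked example

```bash
python examples/02_prioritize_and_specificity.py
```

```
high-or-stronger candidates per disease:
  AA: 17
  NA: 16
  RA: 11
overlap AA&NA: 13 | RA&AA: ['IL4R'] | all three: []
disease-specific candidates:
  AA (12): ALOX5, CCL11, CCL17, CCL5, CD40, IL17A, ITGAL, POSTN, RNASE3, SELL, SERPINB2, TGFB1
  NA (2): IL25, LGALS3
  RA (7): IL10, IL2, IL2RB, IL4, IL9, PTGER2, TNF
```

Reading: 11/17/16 candidates reach a high-or-stronger relationship with
RA/AA/NA; the two asthma types share 13 of them while RA and AA share only
the IL-4 receptor, and no protein is highly related to all three conditions.
The specificity rule then isolates 7 allergy-specific, 12 allergic-asthma-
specific and 2 non-allergic-asthma-specific biomarkers.

The other examples show the characterization queries, proximity scoring with
permutation p-values on a synthetic interactome, the triggering/coverage
analysis, and the expression validation layer:

```bash
python examples/05_expression_validation.py
```

```
   gene     RQ     adj p |   AUC        95% CI signif
  IL2RB   0.23  2.96e-10 |  0.96 [0.91, 1.00] yes
    TNF   0.13  3.91e-17 |  1.00 [1.00, 1.00] yes
 PTGER2   0.27  1.11e-08 |  0.95 [0.89, 1.00] yes
   IL10   0.14  2.92e-14 |  1.00 [1.00, 1.00] yes
```

Here RQ < 1 means down-regulation in allergy versus healthy controls (as
planted by the simulation preset), and all four genes discriminate the groups
with the whole AUC confidence interval inside the significance band.

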