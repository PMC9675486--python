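# implinet

Boolean implication networks for disease-progression transcriptomics.

`implinet` builds asymmetric gene-expression networks of the kind used to
model the normal esophagus → Barrett's metaplasia → esophageal
adenocarcinoma (NE → BE → EAC) continuum: it binarizes each gene with a
one-step fit, classifies every gene pair into one of six Boolean
implication relationships (BIRs), groups equivalent genes into clusters,
assembles a directed cluster graph, scores path signatures on samples,
and tests seed-gene progression logic. It is aimed at computational
biologists who want these primitives as a reusable, tested library with a
thin CLI, together with the downstream enrichment statistics
(hypergeometric overlap, Fisher/binomial SNP tests) and a fully
ground-truthed synthetic-cohort generator.

## The method

**Binarization (StepMiner).** For each gene, sort its expression values
(log2 scale) and fit a one-step function: values split at index *k* into
a low segment with mean *m₁* and a high segment with mean *m₂*, choosing
*k* to minimize the residual sum of squares. The threshold is
*t = (m₁ + m₂)/2*. Samples are ternarized: LOW if *x ≤ t − 0.5*, HIGH if
*x ≥ t + 0.5*, INTERMEDIATE otherwise (intermediates are excluded from
pairwise counts).

**Implication discovery (BooleanNet statistic).** For genes A and B,
samples binarized in both populate a 2×2 quadrant table. A quadrant with
observed count *O* and independence-expected count *E = (row × col)/n* is
*sparse* when

    S = (E − O)/√E > 3      and      p_err = ½(O/row + O/col) < 0.1

One sparse quadrant yields one of the four asymmetric implications (a
sparse (A-low, B-high) quadrant reads "A low ⇒ B low"); the two sparse
off-diagonal quadrants together give *equivalent*, the two diagonal ones
*opposite*. A network-level FDR is estimated by shuffling each gene's
codes across samples and re-running discovery.

**Clusters, graph, signatures.** Genes sharing at least half their
equivalences are grouped into clusters (named by their seed gene, e.g.
the SPINK7 or SLC44A4 cluster); the directed cluster graph carries the
majority BIR between each cluster pair. Simple paths through the graph
become signatures: each cluster gets a signed weight (sign = up/down in
cases, magnitude = path position), a sample's composite score is the
weighted sum of cluster-mean threshold-centered expression
(*z = (x − t)/3*), and candidate paths are ranked by training ROC-AUC.

**Progression logic.** Disease states are quadrant constraints on seed
genes — NE (SPINK7 high, SLC44A4 low, CXCL8 low), BE (SLC44A4 high,
CXCL8 low), EAC (SLC44A4 high, CXCL8 high). A sample is assigned only
when exactly one state matches. The model's ordering is falsifiable: the
implied invariants (SPINK7 high ⇒ SLC44A4 low; CXCL8 high ⇒ SLC44A4
high) must pass the same sparse-quadrant test, i.e. the forbidden
quadrant (CXCL8 high, SLC44A4 low) must be empty-ish — which is what
forces BE to precede EAC.

## Worked example

```python
import implinet
from implinet import synthetic
from implinet.progression import default_esophagus_model

matrix, annotations, truth = synthetic.generate_cohort(synthetic.default_spec(seed=7))
model = implinet.BooleanImplicationNetwork(matrix, annotations)
results = model.fit(n_permutations=20, seed=1)
print(results.summary())
```

```
Boolean Implication Network Results
=====================================
Samples:                150
Genes:                  560 (551 informative)
Pairs classified:       151525
Significant relations:  1770
  low=>low     400
  high=>low    400
  equivalent   570
  opposite     400
Clusters:               494
  C1[CXCL8] n=20, C2[SLC44A4] n=20, C3[SPINK7] n=20
Cluster-graph edges:    5
Permutation FDR:        0
```

The three planted 20-gene clusters are recovered exactly (the remaining
"clusters" are background singletons); the 1,770 significant relations
are precisely the planted ones: 570 within-cluster equivalences
(3 × C(20,2)) and 3 × 400 cross-cluster relations, with a permutation
FDR of 0. Continuing:

```python
ranked = results.select_signature(case_label="EAC", max_len=3)
print(ranked[0], ranked[0].auc)            # C1:+1 1.0  (CXCL8-like cluster alone)
report = results.check_invariance(default_esophagus_model())
print(report[["implication", "S", "forbidden_fraction", "passes"]])
```

```
                  implication         S  forbidden_fraction  passes
0  SPINK7 high => SLC44A4 low  5.753965                 0.0    True
1  CXCL8 high => SLC44A4 high  4.054424                 0.0    True
```

The top signature separates EAC from the other states with ROC-AUC 1.0,
and both model-implied invariants hold with empty forbidden quadrants —
the planted cohort conforms to the NE → BE → EAC ordering. State
assignment against the generating labels is ≈ 95–98% correct (the rest
are UNASSIGNED samples with an intermediate seed-gene code).

The same pipeline is available from the shell:

```
implinet simulate cohort --out-prefix demo --seed 7
implinet binarize --in demo.matrix.tsv --out demo.ternary.tsv
implinet implications --ternary demo.ternary.tsv --out demo.pairs.tsv --fdr-perms 20 --seed 1
implinet network --pairs demo.pairs.tsv --out demo.graph.json
implinet signature --graph demo.graph.json --matrix demo.matrix.tsv \
    --thresholds demo.ternary.tsv.thresholds.tsv --labels demo.annotations.tsv --case EAC
```

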