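# kvotes

Consensus integration of protein–protein interaction (PPI) networks by
edge voting, with SCAN structural clustering and module-quality
evaluation for choosing the consensus level.

## The problem

Public PPI databases (BioGRID, HPRD, IntAct, …) each curate a partial,
noisy view of the same interactome. Simply taking the union of their
edge sets maximizes coverage but imports every database's false
positives; taking the intersection is clean but discards most known
biology. `kvotes` treats the *n* source networks G₁…Gₙ as a committee
of experts: an interaction (an unordered protein pair) enters the
integrated network Ĝₖ iff at least *k* of the *n* networks contain it.
k = 1 is the union, k = n the intersection, and the edge sets nest,
E(Ĝₖ₊₁) ⊆ E(Ĝₖ).

To decide which k gives the most useful network, each Ĝₖ is clustered
with **SCAN** (Structural Clustering Algorithm for Networks) over a grid
of similarity thresholds ε, and each clustering is scored with four
module-quality measures:

- **Modularity** `Q_N = Σ_s [ l_s/L − (d_s/2L)² ]` — within-cluster edge
  fraction minus its random expectation;
- **Similarity-based modularity** `Q_S` — the same form with edge counts
  replaced by summed structural similarities
  `σ(u,v) = |Γ(u)∩Γ(v)| / √(|Γ(u)||Γ(v)|)` (closed neighborhoods), which
  mitigates the resolution limit;
- **Clustering score** `n_S / (n_S + n_I)` — the fraction of clusters
  whose best hypergeometric pathway-enrichment p-value beats α = 0.05;
- **Enrichment** — mean annotation-cosine similarity of within-cluster
  protein pairs over the network-wide mean, min–max normalized across
  the ε grid.

A measure "possesses an optimum" for a network when its ε-profile has a
clear interior maximum (trends and flat profiles do not count). The
chosen k is the smallest one whose network couples a statistical optimum
(Q_N or Q_S) with both biological optima; if no level manages that, the
level with the most optima wins, smallest on ties.

Because real database snapshots are moving targets, the package ships a
synthetic benchmark: a planted-partition truth network observed by n
noisy "databases" (limited sensitivity, calibrated false-positive load)
plus a matching gene-set catalog, so the entire pipeline is testable
against a known ground truth.

## Worked example

```python
import kvotes as kv
from kvotes.sweep import STUDY_GRID

truth, databases, pathways = kv.simulate_study(seed=1)
result = kv.evaluate_k_range(databases, STUDY_GRID, pathways)
print(result.presence_frame().to_string(index=False))
print("chosen k =", result.chosen_k)

g1 = kv.integrate_k_votes(databases, 1)
g2 = kv.integrate_k_votes(databases, 2)
print(f"union precision {kv.edge_precision(g1, truth):.3f}  "
      f"k=2 precision {kv.edge_precision(g2, truth):.3f}")
```

prints

```
 k  n_vertices  n_edges  optimal_modularity  optimal_similarity_modularity  optimal_clustering_score  optimal_enrichment
 1         200     3145               False                          False                     False               False
 2         200      843                True                           True                      True               False
 3         200      674                True                           True                      True               False
 4         200      534                True                           True                      True               False
 5         197      331                True                           True                      True               False
 6         142      114               False                          False                      True               False
 7          32       16               False                          False                     False               False
chosen k = 2
union precision 0.231  k=2 precision 0.851
```

The union (k=1) holds 3145 edges but only 23% of them are real; its
quality profiles never develop an interior optimum. Requiring two votes
shrinks the network ~3.7-fold to 843 edges at 85% precision, and k=2 is
the smallest level whose modularity, similarity-based modularity and
clustering score all peak at an interior ε — so the committee's verdict
is k = 2.

Single quantities are just as accessible; the enrichment p-value of a
10-protein module fully contained in a 29-gene pathway against a
5197-gene annotation universe:

```python
>>> print("%.3g" % kv.hypergeom_tail(10, 10, 29, 5197))
5.1e-24
```

## Command line

The same stages are available as a CLI:

```
kvotes simulate --seed 42 -o study/          # synthetic benchmark files
kvotes integrate --k 2 study/db*.tsv -o g2.tsv
kvotes cluster g2.tsv --epsilon 0.5 -o clusters.tsv
kvotes evaluate g2.tsv clusters.tsv --gmt study/annotations.gmt
kvotes sweep --gmt study/annotations.gmt --report report.json study/db*.tsv
```

Edge lists are two-column TSV (or SIF); gene sets are GMT; every flag
can come from a YAML file via `--config`.

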