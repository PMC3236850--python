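# Methods

## Data model

Networks are simple undirected graphs over opaque string gene
identifiers (Entrez-style IDs in practice). Canonicalization happens at
ingest: every edge is stored as a lexicographically ordered pair,
self-interactions are dropped, duplicates collapse. Interaction-type
and evidence columns in source files are ignored — consensus voting is
per protein pair, and a database listing both orientations of a pair
still casts a single vote. The vertex set of an integrated network is
derived from its surviving edges; proteins whose every interaction fell
below the vote threshold do not appear. ID unification is a
single-valued source→unified mapping; edges that collapse onto one
unified ID become self-loops and are removed. Many-to-many or obsolete
ID resolution is out of scope.

## k-votes consensus

Votes are tallied once per ensemble (`KVotesIntegrator.fit`), and any
consensus level is a threshold query on the tally. The operator is
order-invariant in the ensemble and satisfies, by construction,
Ĝ₁ = union, Ĝₙ = intersection, and E(Ĝₖ₊₁) ⊆ E(Ĝₖ); the test suite
checks these identities against independently computed set unions and
pairwise intersections.

## SCAN

Structural similarity uses closed neighborhoods with the geometric-mean
denominator, σ(u,v) = |Γ(u)∩Γ(v)|/√(|Γ(u)||Γ(v)|), the original SCAN
definition. Thresholding is σ ≥ ε (with ≥ rather than >, so ε = 1 can
still match identical closed neighborhoods). A vertex is a core when
its ε-neighborhood — itself plus its adjacent vertices with σ ≥ ε —
holds at least μ members; μ defaults to 2, the customary SCAN default.
Clusters are connected components of cores under direct structure
reachability; non-core border vertices join the cluster of their
lexicographically smallest reaching core (a deterministic tie-break for
the rare border vertex reachable from several clusters). Remaining
vertices are hubs when adjacent to two or more clusters, otherwise
outliers. Because membership follows from the reachability relation and
tie-breaks use canonical IDs only, the result is independent of visit
order; a brute-force reference that materializes the full σ matrix
backs this in the tests. Note that with μ = 2 a cluster can be as small
as a core plus one neighbor.

Similarities are only ever needed along edges, so they are computed
once per network and shared across a whole ε sweep.

## Quality measures

**Modularity.** Q_N = Σ_s [l_s/L − (d_s/2L)²] with degrees taken in the
full network; hub/outlier vertices contribute to L and to degree sums
but to no cluster. Putting everything into one cluster gives exactly 0;
random assignments average near 0 (slightly negative on small networks,
since E[(d_s)²] > (E[d_s])²). Q_N can be negative; where a
non-negative summary is wanted downstream it may be clipped for
reporting, but the profile keeps the raw value.

**Similarity-based modularity.** The same functional form with edge
counts replaced by σ sums: IS_i over within-cluster edges, DS_i over all
edge endpoints in the cluster, TS over all edges. Under σ ≡ 1 it reduces
algebraically to Q_N, which the tests assert on random
(network, partition) pairs. Pair similarity is restricted to adjacent
pairs throughout; treating non-adjacent within-cluster pairs as
contributing σ = 0 keeps TS, IS and DS on one convention.

**Clustering score.** Each cluster's enrichment is the minimum, over
annotation terms, of the hypergeometric upper tail
p = Σ_{i=m}^{min(n,M)} C(M,i)C(N−M,n−i)/C(N,n); a cluster is significant
when that minimum is below α = 0.05 (raw; an optional Bonferroni
correction over the number of catalog terms exists but is off by
default). The score is
n_S/(n_S+n_I); no clusters ⇒ 0. The background N defaults to the
annotation-catalog universe — the only convention that reproduces the
reference p-values — with the network vertex set available as an
alternative. The tail is evaluated in log space (log-gamma binomials +
logsumexp), exact to well beyond 6 significant digits for N ≤ 10⁶; a
rational-arithmetic enumeration serves as the oracle in tests.

**Enrichment.** Binary annotation vectors per gene; cosine similarity;
unannotated genes are similarity 0 against everything and remain in the
network-wide average (removing them would silently change denominators).
Within-cluster pairs are pooled across clusters (size-weighted) before
averaging; singleton clusters contribute no pairs; the ratio's
denominator is the all-pairs network average. Normalization across an
ε grid is min–max; a constant series maps to zeros.

## The ε sweep and optimum detection

The fine grid ε = 0.01…0.99 (step 0.01) is the default for single
network sweeps; a 0.1-step coarse grid is available. Consensus-level
selection uses a 0.05-step grid (`STUDY_GRID`): desk-scale clusterings
change at a handful of discrete σ values, and on a 0.01 grid every such
transition row becomes its own one-point spike, which no local-maximum
criterion should be asked to interpret.

A measure possesses an optimum when its profile has a *clear interior
maximum*. Operationally: rows whose clustering is trivial (no clusters,
or clusters covering under 10% of the network) are not considered;
runs of equal values collapse to plateaus; the global maximum over the
interior of the usable series — excluding a `boundary_fraction` (default
0.38) of usable points at each end — must strictly exceed the adjacent
distinct values on both sides, stay out of the excluded regions, and
strictly exceed every excluded value. This makes monotone trends, flat
profiles, edge peaks, and collapse cliffs all "no optimum", and is
invariant under positive affine transformations of the measure. The
0.38 default reflects the short usable ranges (typically 10–15
informative grid points) at desk scale; with long smooth profiles a
smaller fraction is reasonable.

Selection rule: the smallest k with (Q_N or Q_S optimal) AND
(clustering score and enrichment optimal); otherwise the k with the most
optima, smallest on ties. The returned rationale string names the branch
applied.

## Synthetic benchmark

The generator emulates committee integration at desk scale:

- **Truth**: stochastic block model, 10 modules of 20 proteins,
  p_in = 0.35, p_out = 0.005 (≈ 725 edges on 200 vertices) — dense
  enough for structural clustering, small enough for full sweeps in
  seconds.
- **Databases**: each of 7 replicates keeps a true edge with
  sensitivity 0.6 and reports a false pair at a rate calibrated so
  ~45% of its observed edges are spurious. That false-positive load is
  chosen to match the empirical ~3.7× edge-count shrinkage from the
  union to the two-vote consensus when integrating seven real public
  PPI databases; database errors are independent (each member is an
  independent expert — no correlated curation errors).
- **Annotations**: one term per module holding 80% of the module's
  members plus random fillers to 50 genes, 5 random background terms,
  leftover genes attached to background terms so the universe covers
  every protein. Purity below 1 and filler genes mimic gene sets that
  neither cover their pathway completely nor stay confined to one
  module; at this universe size they also make two-member clusters
  insignificant at α = 0.05, so the clustering score genuinely rises
  and falls over ε instead of saturating.

All randomness flows from one root seed through a single generator
(child seeds for truth, noise, annotations), so a fixed seed reproduces
a study bit-for-bit.

What the generator does **not** emulate: scale-free degree
heterogeneity, literature bias (well-studied proteins appearing in more
databases), correlated database errors, proteins outside the annotation
universe, and hierarchically overlapping pathways. Consequently,
passing the synthetic verdict shows the pipeline's logic is sound under
committee-style noise — not that k = 2 is optimal for any particular
set of real databases; with real snapshots the whole evaluation should
be rerun.

## Numerical and degenerate-input choices

- Hypergeometric tails: log-space summation; m = 0 returns exactly 1;
  bound violations raise.
- Modularity on an empty edge set raises (undefined), as does
  enrichment when no annotated pair exists in the network.
- Empty consensus networks at high k are recorded with zero counts and
  an all-absent optimality report rather than aborting the k range.
- Failed sweep rows carry NaN and are skipped by detection; enrichment
  normalization runs over the finite values only.
- Cluster IDs sort by lexicographically smallest member; all outputs
  are deterministic byte-for-byte for identical inputs.

## Limitations

- The strict-interior-maximum rule is intentionally conservative: noisy
  profiles whose maximum hugs the usable boundary report "no optimum"
  even when a human eye might call it a peak.
- Vote counting is unweighted; databases of very different reliability
  are treated as equal experts (a weighted variant is out of scope).
- SCAN here is the plain unweighted, non-overlapping variant.
- The hypergeometric minimum-p per cluster is reported without
  multiple-testing correction, matching the evaluation convention it
  implements; interpret absolute significance counts accordingly.
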