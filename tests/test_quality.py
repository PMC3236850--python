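import itertools
import math
import random
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import hypergeom

from kvotes import (
    AnnotationCatalog,
    Clustering,
    InteractionNetwork,
    annotation_cosine,
    cluster_min_pvalue,
    clustering_score,
    enrichment,
    hypergeom_tail,
    modularity,
    normalize_series,
    read_gmt,
    significance_table,
    similarity_modularity,
)
from kvotes.quality import _cosine_matrix
from kvotes.scan import edge_similarities

from conftest import clique_edges


def hypergeom_tail_exact(n, m, M, N):
    """Independent oracle: exact rational upper tail by direct summation."""
    denom = math.comb(N, n)
    total = sum(
        Fraction(math.comb(M, i) * math.comb(N - M, n - i), denom)
        for i in range(m, min(n, M) + 1)
    )
    return float(total)


# ---------------------------------------------------------------------
# Hypergeometric tail
# ---------------------------------------------------------------------

def test_tail_is_one_at_m_zero():
    assert hypergeom_tail(10, 0, 50, 1000) == 1.0


@pytest.mark.parametrize(
    "n,m,M,expected",
    [
        (10, 10, 29, 5.10e-24),
        (17, 12, 48, 5.22e-22),
        (12, 12, 138, 7.61e-20),
        (12, 11, 114, 4.09e-18),
    ],
)
def test_tail_known_pathway_values(n, m, M, expected):
    """Enrichment p-values for published module/pathway overlaps against a
    5197-gene annotation universe."""
    p = hypergeom_tail(n, m, M, 5197)
    assert p == pytest.approx(expected, rel=5e-3)


def test_tail_matches_scipy_survival_function():
    rng = random.Random(3)
    for _ in range(50):
        N = rng.randint(20, 5000)
        M = rng.randint(1, N)
        n = rng.randint(1, min(N, 60))
        m = rng.randint(0, min(n, M))
        ours = hypergeom_tail(n, m, M, N)
        ref = float(hypergeom.sf(m - 1, N, M, n))
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)


def test_tail_monotone_in_m():
    last = 1.1
    for m in range(0, 13):
        p = hypergeom_tail(12, m, 86, 5197)
        assert p <= last
        last = p


def test_tail_bound_violations_rejected():
    with pytest.raises(ValueError):
        hypergeom_tail(5, 6, 10, 100)
    with pytest.raises(ValueError):
        hypergeom_tail(5, 2, 200, 100)


# ---------------------------------------------------------------------
# Catalog & per-cluster significance
# ---------------------------------------------------------------------

def block_catalog(n_terms=3, size=4):
    terms = {
        f"t{j}": {f"g{j}_{i}" for i in range(size)} for j in range(n_terms)
    }
    return AnnotationCatalog(terms), terms


def test_catalog_universe_and_vectors():
    cat = AnnotationCatalog({"a": {"x", "y"}, "b": {"y", "z"}})
    assert cat.universe == {"x", "y", "z"}
    assert cat.annotations("y") == {"a", "b"}
    assert list(cat.vector("y")) == [1, 1]
    assert list(cat.vector("unknown")) == [0, 0]


def test_read_gmt_roundtrip_and_errors(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("t1\tdesc\tA\tB\tB\nt2\tdesc\tB\tC\n")
    cat = read_gmt(p)
    assert cat.terms["t1"] == {"A", "B"}
    assert len(cat.universe) == 3

    empty = tmp_path / "empty.gmt"
    empty.write_text("")
    with pytest.raises(ValueError):
        read_gmt(empty)

    dup = tmp_path / "dup.gmt"
    dup.write_text("t\td\tA\nt\td\tB\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_gmt(dup)

    zero = tmp_path / "zero.gmt"
    zero.write_text("t0\td\nt1\td\tA\n")
    with pytest.warns(UserWarning, match="no genes"):
        cat = read_gmt(zero)
    assert list(cat.terms) == ["t1"]


def test_cluster_min_pvalue_pure_module():
    """10 genes forming a 29-gene term in a 5197-gene universe."""
    term = {f"t{i}" for i in range(29)}
    filler = {f"f{i}" for i in range(5197 - 29)}
    cat = AnnotationCatalog({"path": term, "rest": filler})
    cluster = set(itertools.islice(term, 10))
    sig = cluster_min_pvalue(cluster, cat)
    assert sig.best_term == "path"
    assert (sig.n, sig.m, sig.M) == (10, 10, 29)
    assert sig.p_value == pytest.approx(5.10e-24, rel=5e-3)
    assert sig.significant


def test_cluster_without_annotations_is_insignificant():
    cat, _ = block_catalog()
    sig = cluster_min_pvalue({"u1", "u2"}, cat)
    assert sig.p_value == 1.0 and not sig.significant and sig.best_term is None


def test_min_pvalue_matches_bruteforce_enumeration():
    """Random small catalogs: the reported minimum equals exhaustive
    enumeration over terms with exact rational tails."""
    rng = random.Random(42)
    for _ in range(30):
        universe = [f"g{i}" for i in range(rng.randint(8, 30))]
        terms = {}
        for j in range(rng.randint(1, 5)):
            k = rng.randint(1, len(universe))
            terms[f"t{j}"] = set(rng.sample(universe, k))
        cat = AnnotationCatalog(terms)
        bg = cat.universe
        cluster = set(rng.sample(universe, rng.randint(1, len(universe))))
        got = cluster_min_pvalue(cluster, cat)
        best = 1.0
        for t, genes in terms.items():
            m = len(cluster & bg & genes)
            if m == 0:
                continue
            p = hypergeom_tail_exact(len(cluster & bg), m, len(genes & bg), len(bg))
            best = min(best, p)
        assert got.p_value == pytest.approx(best, rel=1e-9)


def test_clustering_score_counts_and_bounds():
    assert clustering_score((97, 61)) == pytest.approx(0.6139, abs=5e-5)
    assert clustering_score((5, 0)) == 1.0
    assert clustering_score((0, 7)) == 0.0
    assert clustering_score((0, 0)) == 0.0


def test_clustering_score_from_clustering(two_cliques):
    terms = {
        "ta": {f"a{i}" for i in range(5)} | {f"x{i}" for i in range(45)},
        "tb": {f"b{i}" for i in range(5)} | {f"y{i}" for i in range(45)},
        "bg": {f"z{i}" for i in range(400)},
    }
    cat = AnnotationCatalog(terms)
    clu = Clustering(
        [{f"a{i}" for i in range(5)}, {f"b{i}" for i in range(5)}], {}, 0.7, 2
    )
    assert clustering_score(clu, cat) == 1.0
    tbl = significance_table(clu, cat)
    assert list(tbl.columns[:3]) == ["cluster_id", "best_term", "n"]
    assert (tbl["significant"]).all()


# ---------------------------------------------------------------------
# Annotation cosine & enrichment
# ---------------------------------------------------------------------

def test_annotation_cosine_cases():
    cat = AnnotationCatalog(
        {"t1": {"i", "j"}, "t2": {"i"}, "t3": {"j"}, "t4": {"k"}, "t5": {"l"}}
    )
    assert annotation_cosine("i", "i", cat) == 1.0
    # A_i={t1,t2}, A_j={t1,t3}: 1/sqrt(2*2)
    assert annotation_cosine("i", "j", cat) == pytest.approx(0.5)
    assert annotation_cosine("k", "l", cat) == 0.0
    assert annotation_cosine("k", "unannotated", cat) == 0.0


def test_cosine_matrix_agrees_with_scalar():
    cat, _ = block_catalog()
    genes = sorted(cat.universe) + ["nope"]
    C = _cosine_matrix(genes, cat)
    for i, gi in enumerate(genes):
        for j, gj in enumerate(genes):
            assert C[i, j] == pytest.approx(annotation_cosine(gi, gj, cat))


def test_enrichment_single_cluster_is_one(two_cliques):
    cat = AnnotationCatalog(
        {"ta": {f"a{i}" for i in range(5)}, "tb": {f"b{i}" for i in range(5)}}
    )
    clu = Clustering([set(two_cliques.vertices)], {}, 0.5, 2)
    assert enrichment(clu, two_cliques, cat) == pytest.approx(1.0)


def test_enrichment_matching_blocks_exceeds_one(two_cliques):
    cat = AnnotationCatalog(
        {"ta": {f"a{i}" for i in range(5)}, "tb": {f"b{i}" for i in range(5)}}
    )
    clu = Clustering(
        [{f"a{i}" for i in range(5)}, {f"b{i}" for i in range(5)}], {}, 0.7, 2
    )
    # all within-cluster pairs share a term (cos 1); network average is
    # 20 same-term pairs of 45 total
    expected = 1.0 / (20 / 45)
    assert enrichment(clu, two_cliques, cat) == pytest.approx(expected)


def test_enrichment_random_clustering_near_one():
    """Random partitions of an annotation-random vertex set average E ~ 1."""
    rng = random.Random(8)
    genes = [f"g{i}" for i in range(40)]
    net = InteractionNetwork("r", [(genes[i], genes[i + 1]) for i in range(39)])
    terms = {f"t{j}": set(rng.sample(genes, 10)) for j in range(6)}
    cat = AnnotationCatalog(terms)
    vals = []
    for _ in range(40):
        vs = genes[:]
        rng.shuffle(vs)
        clu = Clustering([set(vs[:10]), set(vs[10:20]), set(vs[20:30])],
                         {v: "outlier" for v in vs[30:]}, 0.5, 2)
        vals.append(enrichment(clu, net, cat))
    assert np.mean(vals) == pytest.approx(1.0, abs=0.1)


def test_enrichment_errors_without_annotated_pairs():
    net = InteractionNetwork("n", [("a", "b")])
    cat = AnnotationCatalog({"t": {"zzz"}})
    clu = Clustering([{"a", "b"}], {}, 0.5, 2)
    with pytest.raises(ValueError):
        enrichment(clu, net, cat)


def test_normalize_series():
    assert normalize_series([2, 4, 6]) == [0.0, 0.5, 1.0]
    assert normalize_series([3, 3, 3]) == [0.0, 0.0, 0.0]
    rng = random.Random(5)
    for _ in range(20):
        xs = [rng.uniform(-5, 5) for _ in range(rng.randint(1, 30))]
        ys = normalize_series(xs)
        assert all(0.0 <= y <= 1.0 for y in ys)
        for (x1, y1), (x2, y2) in zip(
            sorted(zip(xs, ys)), sorted(zip(xs, ys))[1:]
        ):
            assert (x1 <= x2) == (y1 <= y2)


# ---------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------

def random_clustered_network(rng, n_min=6, n_max=25):
    n = rng.randint(n_min, n_max)
    names = [str(i) for i in range(n)]
    pairs = list(itertools.combinations(names, 2))
    edges = rng.sample(pairs, rng.randint(n // 2, len(pairs)))
    net = InteractionNetwork("r", edges)
    vs = sorted(net.vertices)
    rng.shuffle(vs)
    n_clusters = rng.randint(1, max(1, len(vs) // 2))
    clusters = [set() for _ in range(n_clusters)]
    cut = rng.randint(0, len(vs))
    for i, v in enumerate(vs[:cut]):
        clusters[i % n_clusters].add(v)
    clusters = [c for c in clusters if c]
    unclassified = {v: "outlier" for v in vs[cut:]}
    return net, Clustering(clusters, unclassified, 0.5, 2)


def test_modularity_single_cluster_is_zero(two_cliques):
    clu = Clustering([set(two_cliques.vertices)], {}, 0.5, 2)
    assert modularity(two_cliques, clu) == pytest.approx(0.0, abs=1e-12)


def test_modularity_two_triangles_half():
    net = InteractionNetwork(
        "tt", clique_edges(["x", "y", "z"]) + clique_edges(["p", "q", "r"])
    )
    clu = Clustering([{"x", "y", "z"}, {"p", "q", "r"}], {}, 0.5, 2)
    assert modularity(net, clu) == pytest.approx(0.5)
    # unit similarities inside triangles: Q_S equals Q_N here
    assert similarity_modularity(net, clu) == pytest.approx(0.5)


def test_modularity_random_assignment_averages_zero():
    rng = random.Random(19)
    names = [str(i) for i in range(30)]
    pairs = list(itertools.combinations(names, 2))
    net = InteractionNetwork("r", rng.sample(pairs, 120))
    vals = []
    for _ in range(150):
        vs = sorted(net.vertices)
        rng.shuffle(vs)
        third = len(vs) // 3
        clu = Clustering(
            [set(vs[:third]), set(vs[third:2 * third]), set(vs[2 * third:])],
            {}, 0.5, 2,
        )
        vals.append(modularity(net, clu))
    # finite networks bias the degree-sum term slightly negative; the
    # mean still sits near zero on the scale of the measure
    assert abs(np.mean(vals)) < 0.05


def test_similarity_modularity_reduces_to_modularity_under_unit_sigma():
    """With sigma replaced by the constant 1, Q_S equals Q_N exactly on
    random (network, clustering) pairs."""
    rng = random.Random(77)
    for _ in range(100):
        net, clu = random_clustered_network(rng)
        if net.n_edges == 0:
            continue
        unit = {e: 1.0 for e in net.edges}
        assert similarity_modularity(net, clu, sims=unit) == pytest.approx(
            modularity(net, clu), abs=1e-10
        )


def test_similarity_modularity_uses_structural_similarity(two_cliques):
    clu = Clustering(
        [{f"a{i}" for i in range(5)}, {f"b{i}" for i in range(5)}], {}, 0.7, 2
    )
    sims = edge_similarities(two_cliques)
    direct = similarity_modularity(two_cliques, clu)
    assert direct == pytest.approx(similarity_modularity(two_cliques, clu, sims=sims))
    assert direct == pytest.approx(0.5)  # cliques: all sigma = 1


def test_modularity_empty_edge_set_errors():
    net = InteractionNetwork("e", vertices=["a", "b"])
    clu = Clustering([{"a"}], {"b": "outlier"}, 0.5, 2)
    with pytest.raises(ValueError):
        modularity(net, clu)
    with pytest.raises(ValueError):
        similarity_modularity(net, clu)


def test_bonferroni_tightens_significance():
    """With many terms, a borderline cluster loses significance once the
    cutoff is divided by the number of terms."""
    universe = [f"g{i}" for i in range(60)]
    terms = {f"t{j}": set(universe[j: j + 10]) for j in range(0, 45, 3)}
    cat = AnnotationCatalog(terms)
    cluster = set(universe[0:2])  # pure pair: p = C(10,2)/C(60,2) ~ 0.025
    raw = cluster_min_pvalue(cluster, cat)
    corrected = cluster_min_pvalue(cluster, cat, bonferroni=True)
    assert corrected.p_value == raw.p_value
    assert 0.05 / cat.n_terms < raw.p_value < 0.05
    assert raw.significant and not corrected.significant
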