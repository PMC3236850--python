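"""SCAN: Structural Clustering Algorithm for Networks.

SCAN groups vertices that share many common neighbors.  The structural
similarity of two vertices is the cosine of their closed neighborhoods,

    sigma(u, v) = |Gamma(u) & Gamma(v)| / sqrt(|Gamma(u)| * |Gamma(v)|),

with Gamma(x) = N(x) | {x}.  A vertex whose epsilon-neighborhood
{w in Gamma(v) : sigma(v, w) >= epsilon} contains at least mu vertices is
a *core*; clusters are the transitive closure of direct structure
reachability seeded from cores, and non-core vertices reachable from a
core join its cluster as *border* vertices.  Vertices in no cluster are
classified as *hubs* (adjacent to two or more clusters) or *outliers*.

The implementation is deterministic and visit-order invariant: cluster
membership follows from the reachability relation alone, border vertices
reachable from several clusters go to the cluster of the lexicographically
smallest reaching core, and cluster ids are assigned by sorting clusters
on their smallest member.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Union

from sklearn.base import BaseEstimator, ClusterMixin

from .network import Edge, InteractionNetwork, canonical_edge

__all__ = [
    "structural_similarity",
    "edge_similarities",
    "eps_neighborhood",
    "Clustering",
    "SCAN",
    "scan_cluster",
]

HUB = "hub"
OUTLIER = "outlier"


def structural_similarity(net: InteractionNetwork, u: str, v: str) -> float:
    """Cosine similarity of the closed neighborhoods of ``u`` and ``v``.

    Symmetric, in [0, 1], and exactly 1 for identical closed
    neighborhoods (in particular ``sigma(v, v) == 1``).
    """
    gu = net.neighbors(u) | {u}
    gv = net.neighbors(v) | {v}
    return len(gu & gv) / math.sqrt(len(gu) * len(gv))


def edge_similarities(net: InteractionNetwork) -> dict[Edge, float]:
    """Structural similarity for every adjacent pair, keyed by canonical edge.

    SCAN only ever thresholds similarities along edges, so this table —
    computable once per network and reusable across the whole epsilon
    grid — is the only similarity state the algorithm needs.
    """
    adj = {v: net.neighbors(v) | {v} for v in net.vertices}
    sims: dict[Edge, float] = {}
    for u, v in net.edges:
        gu, gv = adj[u], adj[v]
        sims[(u, v)] = len(gu & gv) / math.sqrt(len(gu) * len(gv))
    return sims


def eps_neighborhood(
    net: InteractionNetwork,
    v: str,
    epsilon: float,
    sims: Optional[dict[Edge, float]] = None,
) -> set[str]:
    """Members of the closed neighborhood of ``v`` with similarity >= epsilon.

    Always contains ``v`` itself (sigma(v, v) = 1 >= epsilon for any
    epsilon < 1; equality at epsilon = 1 still includes it).
    """
    if sims is None:
        return {v} | {
            w for w in net.neighbors(v)
            if structural_similarity(net, v, w) >= epsilon
        }
    return {v} | {
        w for w in net.neighbors(v)
        if sims[canonical_edge(v, w)] >= epsilon
    }


class Clustering:
    """Result of a SCAN run: disjoint clusters plus hub/outlier labels.

    Attributes
    ----------
    clusters : list[set[str]]
        Disjoint non-empty vertex sets, ordered by their smallest member.
    unclassified : dict[str, str]
        Vertices in no cluster, mapped to ``"hub"`` or ``"outlier"``.
    epsilon, mu :
        The parameters that produced the clustering.
    network_ref : str
        Name of the clustered network.
    """

    def __init__(self, clusters, unclassified, epsilon, mu, network_ref=""):
        self.clusters = [set(c) for c in clusters]
        self.unclassified = dict(unclassified)
        self.epsilon = epsilon
        self.mu = mu
        self.network_ref = network_ref

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, Union[int, str]]:
        """vertex -> cluster index, or ``"hub"`` / ``"outlier"``."""
        lab: dict[str, Union[int, str]] = dict(self.unclassified)
        for i, c in enumerate(self.clusters):
            for v in c:
                lab[v] = i
        return lab

    def membership(self) -> dict[str, int]:
        """vertex -> cluster index for clustered vertices only."""
        return {v: i for i, c in enumerate(self.clusters) for v in c}

    def all_vertices(self) -> set[str]:
        out = set(self.unclassified)
        for c in self.clusters:
            out |= c
        return out

    def write_tsv(self, path: Union[str, Path]) -> None:
        """Two-column TSV: vertex, cluster id or hub/outlier label."""
        lab = self.labels()
        with open(path, "wt", encoding="utf-8") as fh:
            for v in sorted(lab):
                fh.write(f"{v}\t{lab[v]}\n")

    def to_json(self, path: Union[str, Path]) -> None:
        doc = {
            "network": self.network_ref,
            "params": {"epsilon": self.epsilon, "mu": self.mu},
            "clusters": [sorted(c) for c in self.clusters],
            "unclassified": dict(sorted(self.unclassified.items())),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    def __repr__(self) -> str:
        return (
            f"Clustering(n_clusters={self.n_clusters}, "
            f"n_unclassified={len(self.unclassified)}, "
            f"epsilon={self.epsilon}, mu={self.mu})"
        )


class SCAN(ClusterMixin, BaseEstimator):
    """SCAN structural graph clusterer.

    Parameters
    ----------
    epsilon : float in (0, 1]
        Similarity threshold; a neighbor w of v belongs to v's
        epsilon-neighborhood when sigma(v, w) >= epsilon.
    mu : int >= 2
        Minimum epsilon-neighborhood size (vertex itself included) for a
        vertex to be a core.

    Attributes
    ----------
    clustering_ : Clustering
        Full clustering result after :meth:`fit`.
    labels_ : dict[str, int | str]
        Per-vertex cluster index or hub/outlier label.
    cores_ : set[str]
        The core vertices.
    """

    def __init__(self, epsilon: float = 0.5, mu: int = 2):
        self.epsilon = epsilon
        self.mu = mu

    def _validate(self):
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError(f"epsilon must be in (0, 1], got {self.epsilon}")
        if self.mu < 2:
            raise ValueError(f"mu must be >= 2, got {self.mu}")

    def fit(
        self,
        net: InteractionNetwork,
        y=None,
        sims: Optional[dict[Edge, float]] = None,
    ) -> "SCAN":
        """Cluster ``net``; ``sims`` optionally supplies precomputed edge
        similarities (reused across an epsilon sweep)."""
        self._validate()
        if sims is None:
            sims = edge_similarities(net)
        eps, mu = self.epsilon, self.mu

        # epsilon-neighborhoods along edges; v always belongs to its own
        eps_nbrs: dict[str, set[str]] = {}
        for v in net.vertices:
            eps_nbrs[v] = {v} | {
                w for w in net.graph.neighbors(v)
                if sims[canonical_edge(v, w)] >= eps
            }
        cores = {v for v, nb in eps_nbrs.items() if len(nb) >= mu}

        # clusters = connected components of cores under direct reachability
        parent = {v: v for v in cores}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                # root at the smaller id for determinism
                if ra < rb:
                    parent[rb] = ra
                else:
                    parent[ra] = rb

        for u in cores:
            for w in eps_nbrs[u]:
                if w in cores:
                    union(u, w)

        # border assignment: non-core vertices reachable from a core join
        # the cluster of the smallest reaching core
        reaching_core: dict[str, str] = {}
        for u in cores:
            for w in eps_nbrs[u]:
                if w not in cores:
                    if w not in reaching_core or u < reaching_core[w]:
                        reaching_core[w] = u

        members: dict[str, set[str]] = {}
        for u in cores:
            members.setdefault(find(u), set()).add(u)
        for w, u in reaching_core.items():
            members[find(u)].add(w)

        clusters = sorted(members.values(), key=min)

        # hubs bridge >= 2 clusters; everything else unclassified is an outlier
        in_cluster = {v: i for i, c in enumerate(clusters) for v in c}
        unclassified: dict[str, str] = {}
        for v in net.vertices:
            if v in in_cluster:
                continue
            touched = {in_cluster[w] for w in net.graph.neighbors(v) if w in in_cluster}
            unclassified[v] = HUB if len(touched) >= 2 else OUTLIER

        self.clustering_ = Clustering(
            clusters, unclassified, eps, mu, network_ref=net.name
        )
        self.labels_ = self.clustering_.labels()
        self.cores_ = cores
        return self

    def fit_predict(self, net: InteractionNetwork, y=None) -> dict[str, Union[int, str]]:
        return self.fit(net).labels_


def scan_cluster(
    net: InteractionNetwork,
    epsilon: float,
    mu: int = 2,
    sims: Optional[dict[Edge, float]] = None,
) -> Clustering:
    """Run SCAN on ``net`` and return the :class:`Clustering`."""
    return SCAN(epsilon=epsilon, mu=mu).fit(net, sims=sims).clustering_
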