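"""k-votes consensus integration of an ensemble of interaction networks.

Each member network of the ensemble acts as one expert in a committee of
size n and casts one vote per unordered protein pair it contains.  The
integrated network at consensus level k keeps exactly the edges with at
least k votes, together with their endpoints:

* k = 1 is the plain union of the members (the traditional approach),
* k = n is the edge-set intersection,
* the edge sets are nested: E(G_hat_{k+1}) is a subset of E(G_hat_k).

Vertices are derived from the surviving edges — a protein with no
surviving interaction does not enter the integrated network.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Union

from sklearn.base import BaseEstimator

from .network import Edge, InteractionNetwork, NetworkEnsemble

__all__ = [
    "VoteTable",
    "IntegratedNetwork",
    "KVotesIntegrator",
    "count_votes",
    "integrate_k_votes",
    "nesting_report",
]


class VoteTable:
    """Vote counts per canonical edge across an ensemble.

    ``votes[e]`` is the number of member networks containing edge ``e``;
    counts lie in [1, n] where n is the ensemble size.
    """

    def __init__(self, votes: dict[Edge, int], n_members: int, member_names: list[str]):
        self.votes = votes
        self.n_members = n_members
        self.member_names = member_names

    def edges_with_at_least(self, k: int) -> set[Edge]:
        return {e for e, c in self.votes.items() if c >= k}

    def write_tsv(self, path: Union[str, Path]) -> None:
        """Export as three-column TSV (u, v, votes), sorted by edge."""
        with open(path, "wt", encoding="utf-8") as fh:
            for (u, v) in sorted(self.votes):
                fh.write(f"{u}\t{v}\t{self.votes[(u, v)]}\n")

    def __len__(self) -> int:
        return len(self.votes)


class IntegratedNetwork(InteractionNetwork):
    """An interaction network produced at consensus level ``k``."""

    def __init__(self, name, edges, k: int, source_ensemble: list[str]):
        super().__init__(name, edges)
        self.k = k
        self.source_ensemble = list(source_ensemble)


def count_votes(ensemble: NetworkEnsemble) -> VoteTable:
    """Count, for every edge seen anywhere in the ensemble, how many
    member networks contain it.  A member listing an interaction in both
    orientations still contributes a single vote: edges are unordered
    pairs and each member's edge set has set semantics already.
    """
    counter: Counter[Edge] = Counter()
    for net in ensemble:
        counter.update(net.edges)
    return VoteTable(dict(counter), len(ensemble), ensemble.names)


class KVotesIntegrator(BaseEstimator):
    """Consensus-integration transformer over a network ensemble.

    Parameters
    ----------
    k:
        Consensus threshold, 1 <= k <= n.  ``k=1`` reproduces the union of
        the members, ``k=n`` their intersection.

    Attributes
    ----------
    vote_table_ : VoteTable
        Per-edge vote counts from the last :meth:`fit`.
    n_members_ : int
        Ensemble size n.
    """

    def __init__(self, k: int = 2):
        self.k = k

    def fit(self, ensemble: NetworkEnsemble, y=None) -> "KVotesIntegrator":
        """Tally the committee's votes (the expensive half of integration)."""
        if not isinstance(ensemble, NetworkEnsemble):
            ensemble = NetworkEnsemble(ensemble)
        n = len(ensemble)
        if not (1 <= self.k <= n):
            raise ValueError(f"k={self.k} outside [1, n={n}]")
        self.vote_table_ = count_votes(ensemble)
        self.n_members_ = n
        self.member_names_ = ensemble.names
        return self

    def transform(self, ensemble=None) -> IntegratedNetwork:
        """Return the integrated network at consensus level ``k``.

        ``ensemble`` may be omitted after :meth:`fit`; if given, it must
        be the fitted ensemble (votes are not re-counted).
        """
        if not hasattr(self, "vote_table_"):
            raise RuntimeError("KVotesIntegrator is not fitted")
        edges = self.vote_table_.edges_with_at_least(self.k)
        return IntegratedNetwork(
            f"consensus_k{self.k}", edges, k=self.k,
            source_ensemble=self.member_names_,
        )

    def fit_transform(self, ensemble: NetworkEnsemble, y=None) -> IntegratedNetwork:
        return self.fit(ensemble).transform()

    def network_at(self, k: int) -> IntegratedNetwork:
        """Integrated network at an arbitrary level ``k`` from the fitted votes."""
        if not hasattr(self, "vote_table_"):
            raise RuntimeError("KVotesIntegrator is not fitted")
        if not (1 <= k <= self.n_members_):
            raise ValueError(f"k={k} outside [1, n={self.n_members_}]")
        edges = self.vote_table_.edges_with_at_least(k)
        return IntegratedNetwork(
            f"consensus_k{k}", edges, k=k, source_ensemble=self.member_names_
        )


def integrate_k_votes(ensemble: NetworkEnsemble, k: int) -> IntegratedNetwork:
    """Build the consensus network whose edges have at least ``k`` votes."""
    return KVotesIntegrator(k=k).fit_transform(ensemble)


def nesting_report(ensemble: NetworkEnsemble) -> list[tuple[int, int, int]]:
    """(k, |V|, |E|) for k = 1..n; both counts are non-increasing in k."""
    integ = KVotesIntegrator(k=1).fit(ensemble)
    out = []
    for k in range(1, len(ensemble) + 1):
        g = integ.network_at(k)
        out.append((k, g.n_vertices, g.n_edges))
    return out
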