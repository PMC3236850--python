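"""Evaluation framework: epsilon sweeps and consensus-level selection.

For each integrated network the SCAN threshold epsilon is swept over a
grid; each clustering is scored with the four quality measures
(modularity, similarity-based modularity, clustering score, normalized
enrichment).  A quality measure "possesses an optimum" for a network when
its profile has a strict interior local maximum away from the grid
boundaries — profiles that only trend up or down, or stay flat, do not.
The consensus level k is then chosen as the smallest k whose network
shows at least one statistical optimum (either modularity) together with
both biological optima (clustering score and enrichment).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .integration import KVotesIntegrator
from .network import InteractionNetwork, NetworkEnsemble
from .quality import (
    AnnotationCatalog,
    _cosine_matrix,
    cluster_min_pvalue,
    modularity,
    normalize_series,
    similarity_modularity,
)
from .scan import SCAN, edge_similarities

__all__ = [
    "EpsilonGrid",
    "QualityVector",
    "QualityProfile",
    "OptimalityReport",
    "KSelectionResult",
    "MEASURES",
    "epsilon_sweep",
    "detect_interior_optimum",
    "evaluate_k_range",
    "STUDY_GRID",
]

#: The four module-quality measures, in reporting order.
MEASURES = ("modularity", "similarity_modularity", "clustering_score", "enrichment")

STATISTICAL_MEASURES = ("modularity", "similarity_modularity")
BIOLOGICAL_MEASURES = ("clustering_score", "enrichment")

#: Fraction of usable grid points excluded at each end when deciding
#: whether a profile's maximum is a non-edge optimum.  Desk-scale
#: profiles have short usable ranges (typically 10-15 informative grid
#: points), so a peak is only trusted when it sits well inside the
#: range — roughly the central quarter of usable epsilons.
DEFAULT_BOUNDARY_FRACTION = 0.38


@dataclass(frozen=True)
class EpsilonGrid:
    """An ordered grid of SCAN thresholds in (0, 1)."""

    values: tuple[float, ...]

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ValueError("epsilon grid is empty")
        if any(not (0.0 < v < 1.0) for v in vals):
            raise ValueError("epsilon values must lie strictly in (0, 1)")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("epsilon grid must be strictly increasing")
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_step(cls, start: float = 0.01, stop: float = 0.99, step: float = 0.01):
        """Inclusive arithmetic grid; the default is 0.01, 0.02, ..., 0.99."""
        n = int(round((stop - start) / step)) + 1
        return cls(tuple(round(start + i * step, 10) for i in range(n)))

    @classmethod
    def coarse(cls):
        """The coarse grid 0.1, 0.2, ..., 0.9."""
        return cls.from_step(0.1, 0.9, 0.1)

    @classmethod
    def study(cls):
        """The 0.05-step grid used for consensus-level selection studies."""
        return cls.from_step(0.05, 0.95, 0.05)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


@dataclass
class QualityVector:
    """The four measures for one clustering (NaN marks a failed row)."""

    q_n: float
    q_s: float
    clustering_score: float
    enrichment_raw: float
    enrichment_norm: float = math.nan


@dataclass
class ProfileRow:
    epsilon: float
    quality: QualityVector
    n_clusters: int
    n_clustered: int
    max_cluster_size: int = 0


@dataclass
class QualityProfile:
    """Per-epsilon quality record for one integrated network."""

    network_name: str
    k: Optional[int]
    rows: list[ProfileRow] = field(default_factory=list)

    def series(self, measure: str) -> list[tuple[float, float]]:
        """(epsilon, value) pairs for one measure; NaN rows included."""
        key = {
            "modularity": lambda q: q.q_n,
            "similarity_modularity": lambda q: q.q_s,
            "clustering_score": lambda q: q.clustering_score,
            "enrichment": lambda q: q.enrichment_norm,
            "enrichment_raw": lambda q: q.enrichment_raw,
        }[measure]
        return [(r.epsilon, key(r.quality)) for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epsilon": [r.epsilon for r in self.rows],
                "n_clusters": [r.n_clusters for r in self.rows],
                "n_clustered": [r.n_clustered for r in self.rows],
                "max_cluster_size": [r.max_cluster_size for r in self.rows],
                "modularity": [r.quality.q_n for r in self.rows],
                "similarity_modularity": [r.quality.q_s for r in self.rows],
                "clustering_score": [r.quality.clustering_score for r in self.rows],
                "enrichment_raw": [r.quality.enrichment_raw for r in self.rows],
                "enrichment": [r.quality.enrichment_norm for r in self.rows],
            }
        )


@dataclass
class OptimalityReport:
    """Presence of an interior optimum per quality measure."""

    present: dict[str, bool]
    argmax_epsilon: dict[str, Optional[float]]

    def n_present(self) -> int:
        return sum(self.present.values())

    @classmethod
    def all_absent(cls) -> "OptimalityReport":
        return cls({m: False for m in MEASURES}, {m: None for m in MEASURES})


@dataclass
class KSelectionResult:
    """Outcome of evaluating every consensus level of an ensemble."""

    per_k: dict[int, dict]  # k -> {n_vertices, n_edges, report, profile}
    chosen_k: int
    rationale: str

    def presence_frame(self) -> pd.DataFrame:
        rows = []
        for k, blk in sorted(self.per_k.items()):
            row = {"k": k, "n_vertices": blk["n_vertices"], "n_edges": blk["n_edges"]}
            rep: OptimalityReport = blk["report"]
            for m in MEASURES:
                row[f"optimal_{m}"] = rep.present[m]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: Union[str, Path]) -> None:
        doc = {"chosen_k": self.chosen_k, "rationale": self.rationale, "per_k": {}}
        for k, blk in sorted(self.per_k.items()):
            rep: OptimalityReport = blk["report"]
            doc["per_k"][str(k)] = {
                "n_vertices": blk["n_vertices"],
                "n_edges": blk["n_edges"],
                "presence": rep.present,
                "argmax_epsilon": rep.argmax_epsilon,
                "profile": blk["profile"].to_frame().to_dict(orient="list"),
            }
        Path(path).write_text(json.dumps(doc, indent=1))

    def to_csv(self, path: Union[str, Path]) -> None:
        """Flatten every per-k profile into one long CSV for plotting."""
        frames = []
        for k, blk in sorted(self.per_k.items()):
            df = blk["profile"].to_frame()
            df.insert(0, "k", k)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


#: Grid used by the synthetic benchmark study and consensus-level
#: selection: fine enough to localize optima, coarse enough that
#: single-grid-point clustering transitions do not register as peaks.
STUDY_GRID = EpsilonGrid.from_step(0.05, 0.95, 0.05)


# ---------------------------------------------------------------------
# The sweep
# ---------------------------------------------------------------------

def epsilon_sweep(
    net: InteractionNetwork,
    grid: EpsilonGrid,
    catalog: AnnotationCatalog,
    mu: int = 2,
    alpha: float = 0.05,
    k: Optional[int] = None,
    background: Optional[Iterable[str]] = None,
) -> QualityProfile:
    """Cluster ``net`` at every epsilon in ``grid`` and score each result.

    Edge structural similarities and the annotation-cosine matrix are
    computed once per network and shared across the grid, so the sweep
    costs little more than one SCAN run per epsilon.  A failed row
    (e.g. an empty network) is recorded with NaN measures instead of
    aborting the sweep; normalized enrichment is filled afterwards by
    min–max over the grid's finite raw values.
    """
    profile = QualityProfile(net.name, k)
    empty = net.n_edges == 0
    sims = edge_similarities(net) if not empty else {}

    genes = sorted(net.vertices)
    idx = {g: i for i, g in enumerate(genes)}
    denom = math.nan
    C = None
    if len(genes) >= 2:
        C = _cosine_matrix(genes, catalog)
        pairs_all = len(genes) * (len(genes) - 1) // 2
        denom = (C.sum() - np.trace(C)) / 2.0 / pairs_all

    bg = frozenset(background) if background is not None else None

    for eps in grid:
        if empty:
            profile.rows.append(
                ProfileRow(eps, QualityVector(*[math.nan] * 4), 0, 0, 0)
            )
            continue
        clustering = SCAN(epsilon=eps, mu=mu).fit(net, sims=sims).clustering_
        n_clustered = sum(len(c) for c in clustering.clusters)
        q_n = modularity(net, clustering)
        q_s = similarity_modularity(net, clustering, sims=sims)
        if clustering.n_clusters == 0:
            score = 0.0
        else:
            n_sig = sum(
                cluster_min_pvalue(c, catalog, background=bg, alpha=alpha).significant
                for c in clustering.clusters
            )
            score = n_sig / clustering.n_clusters
        enr = math.nan
        if C is not None and denom > 0:
            total_within, pairs_within = 0.0, 0
            for c in clustering.clusters:
                ids = [idx[v] for v in c]
                m = len(ids)
                if m < 2:
                    continue
                sub = C[np.ix_(ids, ids)]
                total_within += (sub.sum() - np.trace(sub)) / 2.0
                pairs_within += m * (m - 1) // 2
            enr = (total_within / pairs_within) / denom if pairs_within else 0.0
        profile.rows.append(
            ProfileRow(
                eps,
                QualityVector(q_n, q_s, score, enr),
                clustering.n_clusters,
                n_clustered,
                max((len(c) for c in clustering.clusters), default=0),
            )
        )

    finite = [r.quality.enrichment_raw for r in profile.rows
              if math.isfinite(r.quality.enrichment_raw)]
    if finite:
        normed = iter(normalize_series(finite))
        for r in profile.rows:
            if math.isfinite(r.quality.enrichment_raw):
                r.quality.enrichment_norm = next(normed)
    return profile


def detect_interior_optimum(
    series: list[tuple[float, float]],
    boundary_fraction: float = DEFAULT_BOUNDARY_FRACTION,
) -> tuple[bool, Optional[float]]:
    """Decide whether a quality profile has a non-edge (interior) optimum.

    The optimum must be the global maximum over the interior of the
    usable series (the first and last ``boundary_fraction`` of points
    excluded) and a strict local maximum.  Because clusterings only
    change at discrete similarity values, profiles are step functions:
    runs of equal values are treated as a single plateau, which must
    strictly exceed the adjacent *distinct* values on both sides and
    every excluded boundary value, and must not itself reach into the
    excluded boundary regions.  Monotone, flat, and boundary-peaked
    profiles therefore have no optimum.  The reported epsilon is the
    smallest one attaining the peak.  Rows with non-finite values (e.g.
    epsilons yielding only trivial clusterings) are not considered;
    fewer than 5 usable points is an error.
    """
    if not (0.0 < boundary_fraction < 0.5):
        raise ValueError(f"boundary_fraction must be in (0, 0.5), got {boundary_fraction}")
    pts = [(e, v) for e, v in series if v is not None and math.isfinite(v)]
    if len(pts) < 5:
        raise ValueError(f"need at least 5 finite points, got {len(pts)}")
    eps = [p[0] for p in pts]
    val = [p[1] for p in pts]
    m = len(pts)
    b = max(1, math.floor(boundary_fraction * m))
    interior = range(b, m - b)
    if not interior:
        return (False, None)
    i_star = min(interior, key=lambda i: (-val[i], eps[i]))
    v_star = val[i_star]
    # extend the peak plateau over equal values
    lo = i_star
    while lo > 0 and val[lo - 1] == v_star:
        lo -= 1
    hi = i_star
    while hi < m - 1 and val[hi + 1] == v_star:
        hi += 1
    if lo == 0 or hi == m - 1:  # plateau touches a series end: a trend, not a peak
        return (False, None)
    if not (v_star > val[lo - 1] and v_star > val[hi + 1]):
        return (False, None)
    if lo < b or hi >= m - b:  # plateau reaches into an excluded boundary region
        return (False, None)
    if v_star <= max(val[:b]) or v_star <= max(val[m - b:]):
        return (False, None)
    return (True, eps[lo])


#: Rows whose clustering covers less than this fraction of the network
#: are "trivial modules consisting of very few vertices" and are not
#: considered when locating optima.
TRIVIAL_COVERAGE_FRACTION = 0.1


def _is_trivial_row(row: ProfileRow, n_vertices: int) -> bool:
    """Epsilons yielding only trivial clusterings are not considered:
    no clusters at all, or clusters covering only a negligible sliver of
    the network.  (The opposite extreme — everything in one cluster — is
    kept: the quality measures themselves already score it at zero.)"""
    if row.n_clusters == 0:
        return True
    return row.n_clustered < TRIVIAL_COVERAGE_FRACTION * n_vertices


def optimality_report(
    profile: QualityProfile,
    n_vertices: Optional[int] = None,
    boundary_fraction: float = DEFAULT_BOUNDARY_FRACTION,
) -> OptimalityReport:
    """Interior-optimum presence for all four measures of a profile.

    Rows whose clustering is trivial are masked out before detection
    when ``n_vertices`` (the clustered network's size) is given.
    """
    present, argmax = {}, {}
    if n_vertices is None:
        n_vertices = max((r.n_clustered for r in profile.rows), default=0)
    usable = [not _is_trivial_row(r, n_vertices) for r in profile.rows]
    for measure in MEASURES:
        series = [
            (e, v if ok else math.nan)
            for (e, v), ok in zip(profile.series(measure), usable)
        ]
        try:
            p, a = detect_interior_optimum(series, boundary_fraction)
        except ValueError:  # all-trivial or too-short profile: nothing to detect
            p, a = False, None
        present[measure] = p
        argmax[measure] = a
    return OptimalityReport(present, argmax)


def choose_k(reports: dict[int, OptimalityReport]) -> tuple[int, str]:
    """Apply the selection rule to per-k optimality reports.

    Preferred: the smallest k showing at least one statistical optimum
    (modularity or similarity-based modularity) AND both biological
    optima (clustering score and enrichment).  Fallback: the k with the
    most optima present, smallest k on ties.
    """
    for k in sorted(reports):
        rep = reports[k]
        stat = any(rep.present[m] for m in STATISTICAL_MEASURES)
        bio = all(rep.present[m] for m in BIOLOGICAL_MEASURES)
        if stat and bio:
            return k, (
                f"k={k} is the smallest consensus level that is both "
                "statistically significant (optimal modularity or "
                "similarity-based modularity) and biologically meaningful "
                "(optimal clustering score and enrichment)"
            )
    k_best = min(sorted(reports), key=lambda k: (-reports[k].n_present(), k))
    return k_best, (
        f"no consensus level has both statistical and biological optima; "
        f"k={k_best} maximizes the number of present optima "
        f"({reports[k_best].n_present()} of {len(MEASURES)}), smallest k on ties"
    )


def evaluate_k_range(
    ensemble: NetworkEnsemble,
    grid: EpsilonGrid,
    catalog: AnnotationCatalog,
    mu: int = 2,
    alpha: float = 0.05,
    boundary_fraction: float = DEFAULT_BOUNDARY_FRACTION,
    background: Optional[Iterable[str]] = None,
) -> KSelectionResult:
    """Build every consensus network, sweep it, and choose the best k.

    An empty consensus network (possible at high k for sparse, mostly
    disagreeing ensembles) is recorded with zero counts and an all-absent
    report rather than aborting.
    """
    if len(ensemble) < 2:
        raise ValueError("evaluating a k range needs an ensemble of >= 2 networks")
    integ = KVotesIntegrator(k=1).fit(ensemble)
    per_k: dict[int, dict] = {}
    reports: dict[int, OptimalityReport] = {}
    for k in range(1, len(ensemble) + 1):
        g = integ.network_at(k)
        if g.n_edges == 0:
            rep = OptimalityReport.all_absent()
            profile = QualityProfile(g.name, k)
        else:
            profile = epsilon_sweep(
                g, grid, catalog, mu=mu, alpha=alpha, k=k, background=background
            )
            rep = optimality_report(
                profile, n_vertices=g.n_vertices, boundary_fraction=boundary_fraction
            )
        per_k[k] = {
            "n_vertices": g.n_vertices,
            "n_edges": g.n_edges,
            "report": rep,
            "profile": profile,
        }
        reports[k] = rep
    chosen, rationale = choose_k(reports)
    return KSelectionResult(per_k, chosen, rationale)
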