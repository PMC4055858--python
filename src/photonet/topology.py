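"""Final network assembly and topology characterisation.

The regulatory network keeps exactly the TF-target pairs supported by both
evidence streams: the gene sits in the TF's best-cutoff promoter-affinity
target set AND the pair carries a significant mutual-information edge.
Topology statistics (diameter, mean degree, shortest paths, clustering,
power-law degree fit) are computed on the undirected projection of the
largest connected component, matching the convention of the graph-analysis
tooling the field commonly uses.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import CutoffScanResult
from .io import GeneSetAnnotation, OrthologMap
from .mi import MIEdge
from .trap import AffinityMatrix

__all__ = [
    "Edge",
    "RegulatoryNetwork",
    "TopologyReport",
    "build_final_network",
    "shortest_path_stats",
    "clustering_coefficients",
    "degree_distribution_fit",
    "collapse_to_components",
    "topology_report",
]


@dataclass(frozen=True)
class Edge:
    tf_id: str
    gene_id: str
    affinity: float
    mi: float


@dataclass
class RegulatoryNetwork:
    """Directed TF -> target edges carrying both evidence values."""

    edges: list[Edge]
    component_of_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        loops = [e for e in self.edges if e.tf_id == e.gene_id]
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")

    @property
    def tf_ids(self) -> list[str]:
        return sorted({e.tf_id for e in self.edges})

    @property
    def nodes(self) -> list[str]:
        return sorted({e.tf_id for e in self.edges} | {e.gene_id for e in self.edges})

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.tf_id, e.gene_id) for e in self.edges}

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.tf_id, e.gene_id) for e in self.edges)
        return g


@dataclass(frozen=True)
class TopologyReport:
    diameter: int
    mean_neighbors: float
    mean_shortest_path: float
    clustering: dict[str, float]
    mean_clustering: float
    degree_histogram: dict[int, int]
    path_length_histogram: dict[int, int]
    power_law: tuple[float, float] | None  # (regression exponent, r^2)
    ml_exponent: float | None

    def to_dict(self) -> dict:
        return {
            "diameter": self.diameter,
            "mean_neighbors": self.mean_neighbors,
            "mean_shortest_path": self.mean_shortest_path,
            "mean_clustering": self.mean_clustering,
            "degree_histogram": {str(k): v for k, v in sorted(self.degree_histogram.items())},
            "path_length_histogram": {str(k): v for k, v in sorted(self.path_length_histogram.items())},
            "power_law_exponent": None if self.power_law is None else self.power_law[0],
            "power_law_r_squared": None if self.power_law is None else self.power_law[1],
            "ml_exponent": self.ml_exponent,
        }


def build_final_network(
    trap_calls: Sequence[CutoffScanResult],
    mi_edges: Sequence[MIEdge],
    annotation: GeneSetAnnotation | None = None,
    ortholog_map: OrthologMap | None = None,
    affinity: AffinityMatrix | None = None,
) -> RegulatoryNetwork:
    """Intersect promoter-affinity target sets with MI edges.

    TF identifier spaces are reconciled through ``ortholog_map`` (source TF
    id -> expression gene id); an unmapped TF is an error.  TFs sharing an
    ortholog contribute the union of their target sets.  Edge attributes
    carry the TRAP affinity score (when an affinity matrix is supplied) and
    the MI value.
    """
    mi_of: dict[tuple[str, str], float] = {}
    for e in mi_edges:
        key = (e.tf_id, e.gene_id)
        mi_of[key] = max(e.mi, mi_of.get(key, -math.inf))

    trap_pairs: dict[tuple[str, str], float] = {}
    for res in trap_calls:
        if ortholog_map is not None:
            tf_gene = ortholog_map[res.tf_id]  # KeyError if unmapped
        else:
            tf_gene = res.tf_id
        for g in res.target_set_at_best:
            score = math.nan
            if affinity is not None and res.tf_id in affinity.tf_ids:
                row = affinity.row(res.tf_id)
                if g in row.index:
                    score = float(row[g])
            prev = trap_pairs.get((tf_gene, g))
            if prev is None or (not math.isnan(score) and (math.isnan(prev) or score > prev)):
                trap_pairs[(tf_gene, g)] = score

    edges = [
        Edge(tf, gene, trap_pairs[(tf, gene)], mi_of[(tf, gene)])
        for (tf, gene) in sorted(trap_pairs)
        if (tf, gene) in mi_of and tf != gene
    ]
    net = RegulatoryNetwork(
        edges=edges,
        component_of_gene=dict(annotation.component_of_gene) if annotation else {},
    )
    # intersection invariant, asserted on every build
    assert net.edge_pairs() <= set(trap_pairs) and net.edge_pairs() <= set(mi_of)
    return net


def _largest_component(graph: nx.Graph) -> nx.Graph:
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = max(nx.connected_components(graph), key=len)
    return graph.subgraph(nodes)


def shortest_path_stats(
    net: RegulatoryNetwork | nx.Graph,
) -> tuple[int, float, dict[int, int]]:
    """(diameter, mean shortest path, path-length histogram) of the largest
    connected component of the undirected projection.

    The mean is over ordered reachable pairs excluding self-pairs; the
    histogram counts unordered pairs.
    """
    graph = net.to_undirected() if isinstance(net, RegulatoryNetwork) else net
    sub = _largest_component(graph)
    hist: Counter[int] = Counter()
    total = 0
    count = 0
    for src, dists in nx.all_pairs_shortest_path_length(sub):
        for dst, d in dists.items():
            if src == dst:
                continue
            total += d
            count += 1
            if src < dst:
                hist[d] += 1
    if count == 0:
        return 0, 0.0, {}
    diameter = max(hist)
    return diameter, total / count, dict(sorted(hist.items()))


def clustering_coefficients(
    net: RegulatoryNetwork | nx.Graph,
) -> tuple[dict[str, float], float]:
    """Per-node clustering of the undirected projection (degree < 2 -> 0)."""
    graph = net.to_undirected() if isinstance(net, RegulatoryNetwork) else net
    cc = nx.clustering(graph)
    mean = float(np.mean(list(cc.values()))) if cc else 0.0
    return {k: float(v) for k, v in cc.items()}, mean


def degree_distribution_fit(
    net: RegulatoryNetwork | nx.Graph | Mapping[int, int],
) -> tuple[dict[int, int], tuple[float, float] | None, float | None]:
    """Degree histogram plus two power-law exponent estimates.

    The regression estimate is the negated slope of the least-squares line
    on (ln degree, ln count) over positive degrees with positive counts; a
    continuous maximum-likelihood exponent (k_min = 1) is reported
    alongside.  Fewer than 3 distinct positive degrees: fit skipped with a
    warning.  A precomputed degree -> count histogram is accepted in place
    of a graph.
    """
    if isinstance(net, Mapping):
        degrees = [k for k, v in net.items() for _ in range(v)]
    else:
        graph = net.to_undirected() if isinstance(net, RegulatoryNetwork) else net
        degrees = [d for _, d in graph.degree()]
    hist = dict(sorted(Counter(degrees).items()))
    pos = {k: v for k, v in hist.items() if k > 0 and v > 0}
    if len(pos) < 3:
        warnings.warn("fewer than 3 distinct positive degrees: power-law fit skipped")
        return hist, None, None
    ks = np.array(sorted(pos))
    cs = np.array([pos[k] for k in ks], dtype=float)
    x = np.log(ks)
    y = np.log(cs)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    kd = np.array([d for d in degrees if d >= 1], dtype=float)
    ml = 1.0 + kd.size / float(np.log(kd).sum()) if np.log(kd).sum() > 0 else None
    return hist, (float(-slope), r2), ml


def collapse_to_components(net: RegulatoryNetwork) -> pd.DataFrame:
    """Bipartite TF-component view: a TF links to a component iff it targets
    at least one of the component's genes; the weight counts those genes.
    Unannotated targets fall into "unassigned" with a warning."""
    rows: Counter[tuple[str, str]] = Counter()
    warned = False
    for e in net.edges:
        comp = net.component_of_gene.get(e.gene_id)
        if comp is None:
            if not warned:
                warnings.warn("targets without component label placed in 'unassigned'")
                warned = True
            comp = "unassigned"
        rows[(e.tf_id, comp)] += 1
    df = pd.DataFrame(
        [{"tf_id": tf, "component": comp, "weight": w} for (tf, comp), w in rows.items()]
    )
    if df.empty:
        return pd.DataFrame(columns=["tf_id", "component", "weight"])
    return df.sort_values(["tf_id", "component"]).reset_index(drop=True)


def topology_report(net: RegulatoryNetwork) -> TopologyReport:
    graph = net.to_undirected()
    diameter, mean_path, path_hist = shortest_path_stats(graph)
    clustering, mean_cc = clustering_coefficients(graph)
    degrees = [d for _, d in graph.degree()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hist, power_law, ml = degree_distribution_fit(graph)
    return TopologyReport(
        diameter=diameter,
        mean_neighbors=float(np.mean(degrees)) if degrees else 0.0,
        mean_shortest_path=mean_path,
        clustering=clustering,
        mean_clustering=mean_cc,
        degree_histogram=hist,
        path_length_histogram=path_hist,
        power_law=power_law,
        ml_exponent=ml,
    )
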