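"""Dynamic cross-correlation and residue-network allostery analysis.

The dynamic cross-correlation matrix (DCCM) over superposed Cα
displacements,

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>),

feeds a residue contact network: nodes are residues, and an edge joins two
residues whose minimum bead/heavy-atom distance stays within a cutoff
(4.5 Å) for at least an occupancy fraction (75%) of the frames.  Each edge
carries the information-theoretic distance

    d_ij = −log |C_ij|          (natural log; base configurable)

so strongly correlated contacts are "short".  Communities come from the
Girvan–Newman betweenness algorithm with the partition of maximal
modularity; optimal source→sink pathways are shortest d-paths via
Floyd–Warshall, and suboptimal pathways are all simple paths within a
stated tolerance of the optimum, enumerated exactly by bounded
depth-first search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import floyd_warshall

from allopath.conformation import SelectionMask, superpose_to_mean
from allopath.structure_io import EnsembleFrameSet

__all__ = [
    "CorrelationMatrix",
    "AllosteryGraph",
    "CommunityPartition",
    "PathwayReport",
    "compute_dccm",
    "build_graph",
    "detect_communities",
    "intercommunity_strength",
    "optimal_path",
    "suboptimal_paths",
    "pathway_table",
    "write_dot",
]


@dataclass
class CorrelationMatrix:
    """Residue×residue cross-correlations with the index map used."""

    values: np.ndarray
    res_indices: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(np.diag(v) - 1.0) > 1e-10):
            raise ValueError("correlation diagonal must be 1")
        if np.any(np.abs(v) > 1.0 + 1e-10):
            raise ValueError("|C_ij| must be <= 1")


@dataclass
class AllosteryGraph:
    """Occupancy-filtered residue contact graph with −log|C| edge distances."""

    graph: nx.Graph  # nodes: residue indices; edges: occupancy, correlation, distance
    contact_cutoff: float
    occupancy_min: float
    log_base: str  # "e" or "10"

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"residue_i": i, "residue_j": j, **attrs}
            for i, j, attrs in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["residue_i", "residue_j", "occupancy", "correlation", "distance"])


@dataclass
class CommunityPartition:
    """Community id per residue plus the modularity achieved."""

    community_of: dict[int, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.community_of.values()))

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.community_of.values():
            out[c] = out.get(c, 0) + 1
        return out

    def as_sets(self) -> list[set]:
        out: dict[int, set] = {}
        for node, c in self.community_of.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


@dataclass
class PathwayReport:
    """Optimal and (optionally) suboptimal pathways between two residues."""

    source: int
    sink: int
    optimal_path: list[int] | None
    optimal_length: float | None
    n_residues: int | None
    suboptimal_tolerance: float | None = None
    suboptimal_paths: list[list[int]] | None = None
    n_suboptimal: int | None = None
    truncated: bool = False

    @property
    def connected(self) -> bool:
        return self.optimal_path is not None


def compute_dccm(ensemble: EnsembleFrameSet, fit_mask: SelectionMask | None = None) -> CorrelationMatrix:
    """DCCM of Cα displacements about the mean, after superposition."""
    if ensemble.n_frames < 2:
        raise ValueError("DCCM requires at least 2 frames")
    coords = superpose_to_mean(ensemble, fit_mask)
    residues = ensemble.topology.residue_indices
    ca = ensemble.topology.calpha_index
    cols = np.array([ca[int(r)] for r in residues])
    x = coords[:, cols, :]
    dx = x - x.mean(axis=0)
    inner = np.einsum("fid,fjd->ij", dx, dx) / ensemble.n_frames
    var = np.diag(inner)
    if np.any(var <= 0):
        bad = residues[np.flatnonzero(var <= 0)]
        raise ValueError(f"zero-variance residues {bad.tolist()}: correlation undefined")
    c = inner / np.sqrt(np.outer(var, var))
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(values=c, res_indices=np.asarray(residues), n_frames=ensemble.n_frames)


def _min_residue_distances(ensemble: EnsembleFrameSet) -> np.ndarray:
    """(F, n_res, n_res) minimum inter-residue atom distances per frame."""
    top = ensemble.topology
    residues = top.residue_indices
    groups = [top.atom_indices_of_residues([int(r)]) for r in residues]
    if all(len(g) == 1 for g in groups):  # bead model: plain pairwise distances
        cols = np.array([g[0] for g in groups])
        x = ensemble.frames[:, cols, :]
        return np.linalg.norm(x[:, :, None, :] - x[:, None, :, :], axis=-1)
    n = len(groups)
    out = np.empty((ensemble.n_frames, n, n))
    for f in range(ensemble.n_frames):
        coords = ensemble.frames[f]
        for i in range(n):
            for j in range(i, n):
                d = np.linalg.norm(coords[groups[i]][:, None, :] - coords[groups[j]][None, :, :], axis=-1)
                out[f, i, j] = out[f, j, i] = d.min()
    return out


def build_graph(
    ensemble: EnsembleFrameSet,
    dccm: CorrelationMatrix,
    contact_cutoff: float = 4.5,
    occupancy_min: float = 0.75,
    log_base: str = "e",
) -> AllosteryGraph:
    """Occupancy-filtered contact graph with −log|C| edge distances.

    An edge joins residues whose minimum inter-atom distance is within
    ``contact_cutoff`` in at least ``occupancy_min`` of the frames; edges
    with C_ij = 0 are dropped (infinite distance).
    """
    if not 0.0 < occupancy_min <= 1.0:
        raise ValueError("occupancy_min must lie in (0, 1]")
    residues = dccm.res_indices
    dist = _min_residue_distances(ensemble)
    occupancy = (dist <= contact_cutoff).mean(axis=0)
    log_div = 1.0 if log_base == "e" else math.log(10.0)
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in residues)
    n = len(residues)
    for i in range(n):
        for j in range(i + 1, n):
            if occupancy[i, j] < occupancy_min:
                continue
            c = dccm.values[i, j]
            if c == 0.0:
                continue  # infinite distance
            g.add_edge(
                int(residues[i]),
                int(residues[j]),
                occupancy=float(occupancy[i, j]),
                correlation=float(c),
                distance=float(-math.log(abs(c)) / log_div),
            )
    return AllosteryGraph(graph=g, contact_cutoff=contact_cutoff, occupancy_min=occupancy_min, log_base=log_base)


def _most_valuable_edge(g: nx.Graph):
    """Max-betweenness edge with deterministic lowest-node-pair tie-break.

    Betweenness values are rounded to 9 decimals before comparison so that
    symmetry-induced ties (equal in exact arithmetic, apart by float noise)
    resolve to the lexicographically smallest node pair.
    """
    bc = nx.edge_betweenness_centrality(g, weight="distance")
    return min(bc, key=lambda e: (-round(bc[e], 9), tuple(sorted(e))))


def detect_communities(graph: AllosteryGraph) -> CommunityPartition:
    """Girvan–Newman community detection at maximal modularity.

    Edges of highest (distance-weighted) betweenness are removed
    iteratively; among all partitions of the resulting dendrogram —
    including the initial connected components — the one maximizing the
    (unweighted) modularity of the original graph is returned.  Ties in
    betweenness break toward the lexicographically smallest node pair, so
    the result is deterministic.
    """
    g0 = graph.graph
    if g0.number_of_nodes() == 0:
        raise ValueError("empty graph")
    best = [set(c) for c in nx.connected_components(g0)]
    best_q = nx.community.modularity(g0, best, weight=None) if g0.number_of_edges() else 0.0
    work = g0.copy()
    n_comp = len(best)
    while work.number_of_edges():
        work.remove_edge(*_most_valuable_edge(work))
        comps = [set(c) for c in nx.connected_components(work)]
        if len(comps) > n_comp:
            n_comp = len(comps)
            q = nx.community.modularity(g0, comps, weight=None)
            # modularity is rational with denominator (2m)^2, so distinct
            # values differ by far more than this tolerance; exact ties
            # resolve to the earlier (coarser) partition
            if q > best_q + 1e-12:
                best_q, best = q, comps
    community_of = {}
    for cid, members in enumerate(sorted(best, key=lambda s: min(s))):
        for node in members:
            community_of[int(node)] = cid
    return CommunityPartition(community_of=community_of, modularity=float(best_q))


def intercommunity_strength(
    graph: AllosteryGraph, partition: CommunityPartition, measure: str = "betweenness"
) -> pd.DataFrame:
    """Community-pair connection strengths (symmetric matrix).

    ``measure="betweenness"`` sums the distance-weighted edge betweenness
    of the cross-community edges (the convention behind the stick widths
    of community-network diagrams); ``measure="count"`` counts the edges.
    """
    g = graph.graph
    missing = set(g.nodes) - set(partition.community_of)
    if missing:
        raise ValueError(f"partition missing nodes {sorted(missing)}")
    cids = sorted(set(partition.community_of.values()))
    mat = pd.DataFrame(0.0, index=cids, columns=cids)
    bc = nx.edge_betweenness_centrality(g, weight="distance") if measure == "betweenness" else None
    for u, v in g.edges():
        cu, cv = partition.community_of[u], partition.community_of[v]
        if cu == cv:
            continue
        w = bc[(u, v)] if bc is not None and (u, v) in bc else (bc[(v, u)] if bc is not None else 1.0)
        mat.loc[cu, cv] += w
        mat.loc[cv, cu] += w
    return mat


def _fw_matrices(graph: AllosteryGraph):
    nodes = sorted(graph.graph.nodes)
    pos = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.full((n, n), np.inf)
    np.fill_diagonal(adj, 0.0)
    for u, v, attrs in graph.graph.edges(data=True):
        adj[pos[u], pos[v]] = adj[pos[v], pos[u]] = attrs["distance"]
    dist, pred = floyd_warshall(adj, directed=False, return_predecessors=True)
    return nodes, pos, dist, pred


def optimal_path(graph: AllosteryGraph, source: int, sink: int) -> PathwayReport:
    """Shortest −log|C| pathway via all-pairs Floyd–Warshall.

    A disconnected pair yields an explicit no-path report, not an error.
    """
    nodes, pos, dist, pred = _fw_matrices(graph)
    for r in (source, sink):
        if r not in pos:
            raise KeyError(f"residue {r} not in graph")
    i, j = pos[source], pos[sink]
    if not np.isfinite(dist[i, j]):
        return PathwayReport(source=source, sink=sink, optimal_path=None, optimal_length=None, n_residues=None)
    path = [j]
    while path[-1] != i:
        path.append(int(pred[i, path[-1]]))
    path = [nodes[k] for k in reversed(path)]
    return PathwayReport(
        source=source, sink=sink, optimal_path=path,
        optimal_length=float(dist[i, j]), n_residues=len(path),
    )


def suboptimal_paths(
    graph: AllosteryGraph,
    source: int,
    sink: int,
    tolerance: float = 20.0,
    max_expansions: int = 10**6,
) -> PathwayReport:
    """All simple pathways within ``tolerance`` of the optimal length.

    ``tolerance`` is unitless (edge distances are −log-correlations).
    Bounded depth-first search prunes with the exact remaining shortest
    distance to the sink; if the expansion cap is hit the count is a
    flagged lower bound.
    """
    report = optimal_path(graph, source, sink)
    if not report.connected:
        report.suboptimal_tolerance = tolerance
        report.suboptimal_paths = []
        report.n_suboptimal = 0
        return report
    nodes, pos, dist, _ = _fw_matrices(graph)
    limit = report.optimal_length + tolerance + 1e-12
    to_sink = dist[:, pos[sink]]
    g = graph.graph
    found: list[list[int]] = []
    expansions = 0
    truncated = False

    stack = [(source, [source], 0.0)]
    while stack:
        node, path, length = stack.pop()
        expansions += 1
        if expansions > max_expansions:
            truncated = True
            break
        if node == sink:
            found.append(path)
            continue
        for nbr in sorted(g.neighbors(node), reverse=True):
            if nbr in path:
                continue
            new_len = length + g.edges[node, nbr]["distance"]
            if new_len + to_sink[pos[nbr]] <= limit:
                stack.append((nbr, path + [nbr], new_len))

    report.suboptimal_tolerance = tolerance
    report.suboptimal_paths = found
    report.n_suboptimal = len(found)
    report.truncated = truncated
    return report


def pathway_table(
    graph: AllosteryGraph, pairs, tolerance: float = 20.0, max_expansions: int = 10**6
) -> pd.DataFrame:
    """One row per (source, sink): optimal length, residue count, suboptimal count."""
    rows = []
    for source, sink in pairs:
        rep = suboptimal_paths(graph, int(source), int(sink), tolerance, max_expansions)
        rows.append(
            {
                "source": rep.source,
                "sink": rep.sink,
                "optimal_length": rep.optimal_length,
                "n_residues": rep.n_residues,
                "n_suboptimal": rep.n_suboptimal,
                "truncated": rep.truncated,
            }
        )
    return pd.DataFrame(rows)


def write_dot(graph: AllosteryGraph, path) -> None:
    """Minimal DOT export (undirected, distance as edge label)."""
    with open(path, "w") as fh:
        fh.write("graph allostery {\n")
        for node in sorted(graph.graph.nodes):
            fh.write(f"  {node};\n")
        for u, v, attrs in sorted(graph.graph.edges(data=True)):
            fh.write(f'  {u} -- {v} [label="{attrs["distance"]:.4f}"];\n')
        fh.write("}\n")
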