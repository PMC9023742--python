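"""Independent brute-force oracles shared by the test modules.

Everything here is deliberately naive — simple-path enumeration, direct
modularity sums — and never calls into the package's own implementations.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def brute_force_modularity(g: nx.Graph, communities) -> float:
    m = g.number_of_edges()
    q = 0.0
    for c in communities:
        within = sum(1 for u, v in g.edges() if u in c and v in c)
        degree = sum(d for _, d in g.degree(c))
        q += within / m - (degree / (2 * m)) ** 2
    return q


def all_partitions(nodes):
    """Every set partition of ``nodes`` (Bell-number enumeration)."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    head, rest = nodes[0], nodes[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {head}] + part[i + 1 :]
        yield part + [{head}]


def naive_edge_betweenness(g: nx.Graph) -> dict:
    """Distance-weighted edge betweenness via simple-path enumeration."""
    bet = {tuple(sorted(e)): 0.0 for e in g.edges()}
    nodes = sorted(g)
    scale = 2.0 / (len(nodes) * (len(nodes) - 1)) if len(nodes) > 1 else 1.0
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        lengths = [sum(g.edges[a, b]["distance"] for a, b in zip(p, p[1:])) for p in paths]
        shortest = min(lengths)
        geodesics = [p for p, l in zip(paths, lengths) if l <= shortest + 1e-12]
        for p in geodesics:
            for a, b in zip(p, p[1:]):
                bet[tuple(sorted((a, b)))] += 1.0 / len(geodesics)
    return {e: v * scale for e, v in bet.items()}


def naive_girvan_newman(g0: nx.Graph):
    """Reference dendrogram scan: remove max-betweenness edges, return the
    partition of maximal brute-force modularity (coarser one on exact ties)."""
    work = g0.copy()
    comps = [set(c) for c in nx.connected_components(work)]
    best, best_q = comps, brute_force_modularity(g0, comps)
    n_comp = len(comps)
    while work.number_of_edges():
        bet = naive_edge_betweenness(work)
        edge = min(bet, key=lambda e: (-round(bet[e], 9), e))
        work.remove_edge(*edge)
        comps = [set(c) for c in nx.connected_components(work)]
        if len(comps) > n_comp:
            n_comp = len(comps)
            q = brute_force_modularity(g0, comps)
            if q > best_q + 1e-12:
                best_q, best = q, comps
    return {frozenset(c) for c in best}


def random_weighted_graph(rng: np.random.Generator, n_max: int = 10, connected: bool = True) -> nx.Graph:
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.25, 0.45))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    if connected and g.number_of_nodes():
        comps = list(nx.connected_components(g))
        for a, b in zip(comps[:-1], comps[1:]):
            g.add_edge(min(a), min(b))
    for u, v in g.edges():
        g.edges[u, v]["distance"] = float(rng.uniform(0.1, 2.0))
    return g
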