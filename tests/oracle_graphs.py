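"""Brute-force graph oracles used by the unit and acceptance tests.

Everything here is computed from first principles (breadth-first layering,
direct triangle counts, the modularity definition, exhaustive partitions) so
it is independent of the library code paths it checks.
"""

import itertools

import numpy as np


def bf_shortest_paths(g):
    dist = {}
    for src in g.nodes:
        seen = {src: 0}
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in seen:
                        seen[v] = d
                        nxt.append(v)
            frontier = nxt
        dist[src] = seen
    return dist


def bf_avg_geodesic(g):
    dist = bf_shortest_paths(g)
    vals = [d for lengths in dist.values() for d in lengths.values() if d > 0]
    return (float(np.mean(vals)) if vals else float("nan"))


def bf_clustering(g):
    out = []
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
        )
        out.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(out))


def bf_efficiency(g):
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    dist = bf_shortest_paths(g)
    total = sum(
        1.0 / d for lengths in dist.values() for d in lengths.values() if d > 0
    )
    return total / (n * (n - 1))


def bf_modularity(g, partition):
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for comm in partition:
        comm = set(comm)
        lc = sum(1 for u, v in g.edges if u in comm and v in comm)
        dc = sum(g.degree(v) for v in comm)
        q += lc / m - (dc / (2 * m)) ** 2
    return q


def all_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def atlas_graphs(max_nodes=6):
    from networkx.generators.atlas import graph_atlas_g

    for g in graph_atlas_g()[1:]:
        if g.number_of_nodes() > max_nodes:
            break
        if g.number_of_nodes() >= 2 and g.number_of_edges() >= 1:
            yield g
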