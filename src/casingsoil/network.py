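"""Correlation-threshold ecological networks, topology, stability, roles.

Per group: taxa occurring in more than 80% of the group's samples are
retained, pairwise Pearson correlations are computed on
log10(relative abundance + pseudocount), and taxon pairs with |r| >= St
(default 0.75) become signed edges. Modules come from greedy modularity
maximization on the unweighted, unsigned graph. On top of the graph the
module provides the topology statistics of molecular-ecological-network
analysis (average connectivity, geodesic distance, clustering, modularity,
power-law fit of the degree distribution), degree-preserving random-graph
nulls, robustness to random node removal with secondary extinctions,
vulnerability via global efficiency, and Zi-Pi node role classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import CountTable

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


class TooSparseError(ValueError):
    pass


def filter_for_network(
    table: CountTable, occupancy_threshold: float = 0.8
) -> CountTable:
    """Keep taxa occurring in strictly more than 80% of the group's samples."""
    if len(table.sample_ids) < 5:
        raise TooSparseError("need at least 5 samples to build a network")
    arr = table.matrix
    occupancy = (arr > 0).mean(axis=0)
    keep = occupancy > occupancy_threshold
    if keep.sum() < 3:
        raise TooSparseError(
            f"only {int(keep.sum())} taxa pass the occupancy filter"
        )
    return CountTable(table.counts.loc[:, keep].copy())


@dataclass
class EcoNetwork:
    """Undirected signed co-occurrence graph with module assignments."""

    graph: nx.Graph
    modules: dict = field(default_factory=dict)  # node -> module id
    dropped_constant: tuple = ()

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def detect_modules(graph: nx.Graph) -> dict:
    """Greedy modularity maximization; deterministic for a given graph."""
    if graph.number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(graph.nodes))}
    comms = nx.community.greedy_modularity_communities(graph)
    modules: dict = {}
    for mid, comm in enumerate(sorted(comms, key=lambda c: sorted(c)[0])):
        for node in comm:
            modules[node] = mid
    return modules


def correlation_network(
    table: CountTable,
    st: float = 0.75,
    pseudocount: float = 1e-6,
    method: str = "pearson",
) -> EcoNetwork:
    """Threshold a taxon correlation matrix into a signed graph.

    Taxa with constant transformed abundance across samples carry an
    undefined correlation and are dropped with a warning. Only taxa with at
    least one retained edge become network nodes.
    """
    if not 0 < st < 1:
        raise ValueError("st must be in (0, 1)")
    rel = table.matrix / table.matrix.sum(axis=1, keepdims=True)
    x = np.log10(rel + pseudocount)
    sd = x.std(axis=0)
    constant = sd < 1e-12  # tolerance absorbs float noise in the transform
    dropped = tuple(
        t for t, c in zip(table.taxon_ids, constant) if c
    )
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant taxa (undefined correlation)",
            RuntimeWarning,
        )
    taxa = [t for t, c in zip(table.taxon_ids, constant) if not c]
    x = x[:, ~constant]
    if method == "pearson":
        r = np.corrcoef(x, rowvar=False)
    elif method == "spearman":
        from scipy.stats import rankdata

        r = np.corrcoef(rankdata(x, axis=0), rowvar=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    mean_rel = {t: float(m) for t, m in zip(table.taxon_ids, rel.mean(axis=0))}
    graph = nx.Graph()
    n = len(taxa)
    iu, ju = np.triu_indices(n, k=1)
    hits = np.abs(r[iu, ju]) >= st
    for i, j in zip(iu[hits], ju[hits]):
        rij = float(r[i, j])
        graph.add_edge(taxa[i], taxa[j], r=rij, sign=1 if rij > 0 else -1)
    for node in graph.nodes:
        graph.nodes[node]["mean_relabund"] = mean_rel[node]
    net = EcoNetwork(graph=graph, dropped_constant=dropped)
    net.modules = detect_modules(graph)
    return net


@dataclass
class NetworkStats:
    r2_powerlaw: float
    n_nodes: int
    n_links: int
    avg_connectivity: float
    avg_geodesic: float
    avg_clustering: float
    modularity: float
    n_modules: int
    pct_positive_links: float
    pct_negative_links: float
    n_disconnected_pairs: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def degree_powerlaw_r2(graph: nx.Graph) -> float:
    """R^2 of log(frequency) vs log(degree) over degrees with frequency > 0."""
    degrees = np.array([d for _, d in graph.degree()])
    degrees = degrees[degrees > 0]
    if degrees.size == 0:
        return float("nan")
    vals, freq = np.unique(degrees, return_counts=True)
    if vals.size < 2:
        return 1.0
    lx, ly = np.log(vals.astype(float)), np.log(freq.astype(float))
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = ((ly - pred) ** 2).sum()
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    if ss_tot == 0:
        return 1.0
    return float(1.0 - ss_res / ss_tot)


def avg_geodesic_distance(graph: nx.Graph) -> tuple[float, int]:
    """Mean shortest-path length over connected pairs only.

    Returns the mean and the number of (unordered) disconnected pairs.
    """
    n = graph.number_of_nodes()
    total, count = 0.0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        for dist in lengths.values():
            if dist > 0:
                total += dist
                count += 1
    n_pairs = n * (n - 1) // 2
    connected_pairs = count // 2
    if connected_pairs == 0:
        return float("nan"), n_pairs
    return total / count, n_pairs - connected_pairs


def topology(net: EcoNetwork) -> NetworkStats:
    """Topology statistics of an ecological network."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n, e = g.number_of_nodes(), g.number_of_edges()
    geo, n_disc = avg_geodesic_distance(g)
    clustering = float(np.mean(list(nx.clustering(g).values())))
    comms: dict[int, set] = {}
    for node, mid in net.modules.items():
        comms.setdefault(mid, set()).add(node)
    partition = list(comms.values())
    q = nx.community.modularity(g, partition) if e > 0 else 0.0
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    pos = 100.0 * sum(s > 0 for s in signs) / len(signs) if signs else 0.0
    return NetworkStats(
        r2_powerlaw=degree_powerlaw_r2(g),
        n_nodes=n,
        n_links=e,
        avg_connectivity=2.0 * e / n,
        avg_geodesic=geo,
        avg_clustering=clustering,
        modularity=float(q),
        n_modules=len(partition),
        pct_positive_links=pos,
        pct_negative_links=100.0 - pos if signs else 0.0,
        n_disconnected_pairs=n_disc,
    )


def _rewire(graph: nx.Graph, n_attempts: int, rng) -> nx.Graph:
    """Degree-preserving double-edge-swap randomization.

    Each attempt picks two random edges (a-b, c-d) and rewires them to
    (a-d, c-b) when that creates neither a self-loop nor a duplicate edge.
    Attempts that cannot be applied are simply skipped, so the procedure
    works on any graph.
    """
    g = graph.copy()
    edges = [tuple(e) for e in g.edges]
    m = len(edges)
    for _ in range(n_attempts):
        i, j = rng.integers(m), rng.integers(m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
    return g


def random_null(net: EcoNetwork, n_rand: int = 100, seed: int = 0) -> dict:
    """Degree-preserving rewiring nulls for geodesic/clustering/modularity.

    Each randomization applies at least 10 * E double-edge swaps to a copy
    of the empirical graph. Graphs too small or too dense to rewire return
    the empirical values with zero SD and a warning.
    """
    if n_rand < 10:
        raise ValueError("n_rand must be >= 10")
    g = net.graph
    e = g.number_of_edges()
    rng = np.random.default_rng(seed)
    stats = {"avg_geodesic": [], "avg_clustering": [], "modularity": []}
    n = g.number_of_nodes()
    complete = e == n * (n - 1) // 2
    if n < 4 or e < 2 or complete:
        warnings.warn(
            "graph cannot be rewired; returning empirical values",
            RuntimeWarning,
        )
        t = topology(net)
        return {
            "avg_geodesic": (t.avg_geodesic, 0.0),
            "avg_clustering": (t.avg_clustering, 0.0),
            "modularity": (t.modularity, 0.0),
        }
    for _ in range(n_rand):
        rand = _rewire(g, 10 * e, rng)
        rnet = EcoNetwork(graph=rand)
        rnet.modules = detect_modules(rand)
        t = topology(rnet)
        stats["avg_geodesic"].append(t.avg_geodesic)
        stats["avg_clustering"].append(t.avg_clustering)
        stats["modularity"].append(t.modularity)
    return {
        k: (float(np.mean(v)), float(np.std(v))) for k, v in stats.items()
    }


def _cascade(graph: nx.Graph, removed: set) -> int:
    """Survivors after removing ``removed`` plus secondary extinctions.

    Nodes left without any edge after the removal are themselves removed,
    iteratively (in practice one sweep suffices for simple graphs).
    """
    g = graph.copy()
    g.remove_nodes_from(removed)
    while True:
        isolated = [node for node, deg in g.degree() if deg == 0]
        if not isolated:
            break
        g.remove_nodes_from(isolated)
    return g.number_of_nodes()


def robustness(
    net: EcoNetwork,
    removal_fraction: float = 0.5,
    n_rep: int = 100,
    seed: int = 0,
    secondary_extinction: bool = True,
) -> float:
    """Mean proportion of taxa remaining after random node removal.

    Per repetition floor(f * N) nodes are removed uniformly at random;
    with ``secondary_extinction`` nodes left edgeless are then removed
    iteratively. Returns the surviving fraction averaged over repetitions.
    """
    if not 0 < removal_fraction < 1:
        raise ValueError("removal_fraction must be in (0, 1)")
    g = net.graph
    n = g.number_of_nodes()
    nodes = np.array(sorted(g.nodes))
    n_remove = int(np.floor(removal_fraction * n))
    rng = np.random.default_rng(seed)
    remaining = []
    for _ in range(n_rep):
        removed = set(rng.choice(nodes, size=n_remove, replace=False))
        if secondary_extinction:
            surv = _cascade(g, removed)
        else:
            surv = n - n_remove
        remaining.append(surv / n)
    return float(np.mean(remaining))


def global_efficiency(graph: nx.Graph) -> float:
    """Mean over ordered node pairs of 1/shortest-path-length.

    Disconnected pairs contribute 0."""
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        for dist in lengths.values():
            if dist > 0:
                total += 1.0 / dist
    return total / (n * (n - 1))


def vulnerability(net: EcoNetwork) -> float:
    """Maximum relative drop in global efficiency from a single node removal."""
    g = net.graph
    if g.number_of_nodes() < 3:
        raise ValueError("vulnerability undefined for fewer than 3 nodes")
    e_full = global_efficiency(g)
    if e_full == 0:
        raise ValueError("graph has no connected pairs")
    worst = -np.inf
    for node in g.nodes:
        h = g.copy()
        h.remove_node(node)
        drop = (e_full - global_efficiency(h)) / e_full
        worst = max(worst, drop)
    return float(worst)


@dataclass
class NodeRole:
    taxon: str
    zi: float
    pi: float
    role: str


def classify_role(zi: float, pi: float) -> str:
    if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
        return "network_hub"
    if zi > ZI_THRESHOLD:
        return "module_hub"
    if pi > PI_THRESHOLD:
        return "connector"
    return "peripheral"


def zi_pi(net: EcoNetwork) -> list[NodeRole]:
    """Within-module degree z-score and participation coefficient per node."""
    g = net.graph
    modules = net.modules
    if not modules:
        raise ValueError("modules not computed")
    within_degree = {}
    for node in g.nodes:
        mid = modules[node]
        within_degree[node] = sum(
            1 for nb in g.neighbors(node) if modules[nb] == mid
        )
    by_module: dict[int, list] = {}
    for node, kin in within_degree.items():
        by_module.setdefault(modules[node], []).append(kin)
    mod_mean = {m: float(np.mean(v)) for m, v in by_module.items()}
    mod_sd = {m: float(np.std(v)) for m, v in by_module.items()}
    roles = []
    for node in sorted(g.nodes):
        k = g.degree(node)
        mid = modules[node]
        sd = mod_sd[mid]
        zi = 0.0 if sd == 0 else (within_degree[node] - mod_mean[mid]) / sd
        if k == 0:
            pi = 0.0
        else:
            per_module: dict[int, int] = {}
            for nb in g.neighbors(node):
                per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        roles.append(NodeRole(node, float(zi), float(pi), classify_role(zi, pi)))
    return roles


def roles_frame(roles: list[NodeRole]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"taxon": r.taxon, "zi": r.zi, "pi": r.pi, "role": r.role} for r in roles]
    ).set_index("taxon")
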