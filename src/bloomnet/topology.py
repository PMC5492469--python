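"""Global topology metrics, fast-greedy module detection, degree-preserving
null models, and Zi-Pi keystone-role classification.

Modularity follows Q = sum_s [l_s/L - (d_s/2L)^2] over communities s, with
l_s the number of within-community edges and d_s the total degree of the
community; edge signs are ignored (topology only).  Community detection is
agglomerative greedy Q maximization: starting from singleton communities, the
pair of connected communities with the largest Q gain is merged until no
merge improves Q, with ties broken by the lexicographically smallest
community-id pair so reruns are byte-identical.

Node roles use the within-module degree z-score Zi and the among-module
participation coefficient Pi with the conventional cutoffs Zi > 2.5 and
Pi > 0.62 separating module hubs, connectors, network hubs and peripherals.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .rmt import EcologicalNetwork

__all__ = [
    "TopologySummary",
    "NodeRoleRecord",
    "NullSummary",
    "topology_summary",
    "fast_greedy_partition",
    "modularity",
    "randomize_network",
    "null_distribution",
    "zi_pi",
    "classify_roles",
    "ego_subnetwork",
]

ZI_CUT = 2.5
PI_CUT = 0.62


@dataclass
class TopologySummary:
    n_nodes: int
    n_links: int
    avg_k: float                   # average connectivity, 2L/N
    gd: float                      # mean geodesic distance over reachable pairs
    avg_cc: float                  # mean local clustering coefficient
    modularity: float
    n_modules: int
    positive_link_fraction: float


@dataclass
class NodeRoleRecord:
    otu_id: str
    module_id: int
    degree: int
    within_module_degree: int
    zi: float
    pi: float
    role: str = ""


@dataclass
class NullSummary:
    n_randomizations: int
    modularity_mean: float
    modularity_sd: float
    gd_mean: float
    gd_sd: float
    avg_cc_mean: float
    avg_cc_sd: float
    seed: int


def _mean_geodesic_distance(g: nx.Graph) -> float:
    """Mean shortest-path length over all unordered *reachable* pairs.

    Disconnected pairs are skipped so multi-component networks keep a finite
    value.
    """
    total = 0
    pairs = 0
    for component in nx.connected_components(g):
        sub = g.subgraph(component)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            pairs += len(lengths) - 1  # exclude the zero self-distance
    if pairs == 0:
        return float("nan")
    return total / pairs  # each pair counted twice in both numerator and denominator


def topology_summary(net: EcologicalNetwork) -> TopologySummary:
    """Compute the standard topology panel for one network.

    If no partition is attached, fast-greedy community detection is run first
    (and attached).  Local clustering of degree-<2 nodes contributes 0.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if net.partition is None:
        net.partition, _ = fast_greedy_partition(net)
    q = modularity(net, net.partition)
    n = g.number_of_nodes()
    l = g.number_of_edges()
    avg_cc = float(np.mean(list(nx.clustering(g).values())))
    return TopologySummary(
        n_nodes=n,
        n_links=l,
        avg_k=2.0 * l / n,
        gd=_mean_geodesic_distance(g),
        avg_cc=avg_cc,
        modularity=q,
        n_modules=len(set(net.partition.values())),
        positive_link_fraction=net.positive_link_fraction(),
    )


def modularity(net: EcologicalNetwork, partition: dict[str, int]) -> float:
    """Q = sum_s [l_s/L - (d_s/2L)^2]; edge signs are ignored."""
    g = net.graph
    missing = [n for n in g.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition missing nodes: {sorted(missing)[:5]}")
    l_total = g.number_of_edges()
    if l_total == 0:
        return 0.0
    within: dict[int, int] = {}
    degree_sum: dict[int, int] = {}
    for node, deg in g.degree:
        m = partition[node]
        degree_sum[m] = degree_sum.get(m, 0) + deg
    for u, v in g.edges:
        if partition[u] == partition[v]:
            within[partition[u]] = within.get(partition[u], 0) + 1
    q = 0.0
    for m, d in degree_sum.items():
        q += within.get(m, 0) / l_total - (d / (2.0 * l_total)) ** 2
    return q


def fast_greedy_partition(net: EcologicalNetwork, refine: bool = True) -> tuple[dict[str, int], float]:
    """Agglomerative greedy modularity maximization with local refinement.

    Starts from singleton communities and repeatedly merges the connected
    community pair with the largest Q gain (delta Q = l_ab/L - d_a*d_b/(2L^2))
    until no merge has a positive gain.  Ties are broken by the
    lexicographically smallest community-id pair.  A deterministic
    Kernighan-Lin-style sweep then moves single nodes between communities
    (or into their own) while any move still increases Q; this repairs the
    occasional early merge the pure agglomeration cannot undo.  Module ids in
    the returned partition are consecutive integers ordered by each module's
    smallest node id.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    l_total = g.number_of_edges()
    nodes = sorted(g.nodes)
    comm_of = {node: i for i, node in enumerate(nodes)}
    members: dict[int, list[str]] = {i: [node] for i, node in enumerate(nodes)}
    degree_sum = {i: g.degree(node) for i, node in enumerate(nodes)}
    # inter-community edge counts, keyed by ordered community-id pair
    between: dict[tuple[int, int], int] = {}
    for u, v in g.edges:
        a, b = sorted((comm_of[u], comm_of[v]))
        if a != b:
            between[(a, b)] = between.get((a, b), 0) + 1
    if l_total > 0:
        two_l = 2.0 * l_total
        while between:
            best_pair = None
            best_gain = 0.0
            for (a, b), l_ab in between.items():
                # delta Q = l_ab/L - d_a*d_b/(2 L^2)
                gain = l_ab / l_total - degree_sum[a] * degree_sum[b] / (two_l * l_total)
                if gain > best_gain + 1e-12 or (
                    abs(gain - best_gain) <= 1e-12 and best_pair is not None and (a, b) < best_pair
                ):
                    best_gain = gain
                    best_pair = (a, b)
            if best_pair is None or best_gain <= 1e-12:
                break
            a, b = best_pair
            members[a].extend(members.pop(b))
            for node in members[a]:
                comm_of[node] = a
            degree_sum[a] += degree_sum.pop(b)
            merged: dict[tuple[int, int], int] = {}
            for (x, y), cnt in between.items():
                x = a if x == b else x
                y = a if y == b else y
                if x == y:
                    continue
                key = (x, y) if x < y else (y, x)
                merged[key] = merged.get(key, 0) + cnt
            between = merged
    if refine and l_total > 0:
        _refine_partition(g, comm_of, l_total)
    # stable relabeling: module ids ordered by smallest member node id
    members_final: dict[int, list[str]] = {}
    for node, c in comm_of.items():
        members_final.setdefault(c, []).append(node)
    order = sorted(members_final, key=lambda c: min(members_final[c]))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    partition = {node: relabel[comm_of[node]] for node in g.nodes}
    return partition, modularity(net, partition)


def _move_gain(g: nx.Graph, comm_of: dict[str, int], degree_sum: dict[int, int],
               l_total: int, node: str, next_cid: int) -> tuple[float, int]:
    """Best (gain, target community) for moving one node; split allowed."""
    a = comm_of[node]
    k_v = g.degree(node)
    links_to: dict[int, int] = {}
    for nb in g.neighbors(node):
        links_to[comm_of[nb]] = links_to.get(comm_of[nb], 0) + 1
    k_va = links_to.get(a, 0)
    d_a = degree_sum[a]
    two_l2 = 2.0 * l_total * l_total
    best_gain, best_comm = float("-inf"), a
    for b in sorted(links_to) + [next_cid]:
        if b == a:
            continue
        k_vb = links_to.get(b, 0)
        d_b = degree_sum.get(b, 0)
        gain = (k_vb - k_va) / l_total + k_v * (d_a - d_b - k_v) / two_l2
        if gain > best_gain + 1e-12:
            best_gain, best_comm = gain, b
    return best_gain, best_comm


def _apply_move(g: nx.Graph, comm_of: dict[str, int], degree_sum: dict[int, int],
                node: str, target: int) -> int:
    source = comm_of[node]
    k_v = g.degree(node)
    comm_of[node] = target
    degree_sum[source] -= k_v
    degree_sum[target] = degree_sum.get(target, 0) + k_v
    return source


def _refine_partition(g: nx.Graph, comm_of: dict[str, int], l_total: int,
                      max_rounds: int = 30) -> None:
    """Kernighan-Lin-style refinement of a partition (in place).

    Each round tentatively moves every node once — always the single best
    remaining move, even when its gain is negative — tracking cumulative Q
    along the chain, then keeps the best prefix.  Negative early moves let
    the chain escape local optima the agglomeration cannot undo.  Rounds
    repeat until one yields no net gain.  Deterministic: ties resolve to the
    lexicographically smallest node and community.
    """
    degree_sum: dict[int, int] = {}
    for node, deg in g.degree:
        degree_sum[comm_of[node]] = degree_sum.get(comm_of[node], 0) + deg
    next_cid = max(comm_of.values(), default=0) + 1
    nodes = sorted(g.nodes)
    for _ in range(max_rounds):
        unmoved = list(nodes)
        history: list[tuple[str, int]] = []   # (node, previous community)
        cum = 0.0
        best_cum, best_step = 0.0, 0
        while unmoved:
            step_best = None   # (gain, node, target)
            for node in unmoved:
                gain, target = _move_gain(g, comm_of, degree_sum, l_total, node, next_cid)
                if step_best is None or gain > step_best[0] + 1e-12:
                    step_best = (gain, node, target)
            gain, node, target = step_best
            source = _apply_move(g, comm_of, degree_sum, node, target)
            if target == next_cid:
                next_cid += 1
            history.append((node, source))
            unmoved.remove(node)
            cum += gain
            if cum > best_cum + 1e-12:
                best_cum, best_step = cum, len(history)
        for node, source in reversed(history[best_step:]):
            _apply_move(g, comm_of, degree_sum, node, source)
        if best_cum <= 1e-12:
            break


def randomize_network(net: EcologicalNetwork, seed: int, swap_factor: int = 10) -> EcologicalNetwork:
    """Degree-preserving randomization by attempted double-edge swaps.

    Attempts ``swap_factor * L`` swaps; each picks two distinct edges (u,v),
    (x,y) and rewires to (u,x), (v,y), rejecting any swap that would create a
    self-loop or a multi-edge.  Edge attributes travel with the half-edge
    pair they came from.  Deterministic under ``seed``.
    """
    g = net.graph
    l_total = g.number_of_edges()
    if l_total < 2:
        raise ValueError("need at least 2 edges to randomize")
    rng = np.random.default_rng(seed)
    edges = [tuple(sorted((u, v))) for u, v in sorted(g.edges)]
    attrs = {tuple(sorted((u, v))): dict(d) for u, v, d in g.edges(data=True)}
    edge_set = set(edges)
    for _ in range(swap_factor * l_total):
        i, j = rng.integers(0, l_total, size=2)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if len({u, v, x, y}) < 4:
            continue
        new1 = tuple(sorted((u, x)))
        new2 = tuple(sorted((v, y)))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.remove(edges[i])
        edge_set.remove(edges[j])
        edge_set.add(new1)
        edge_set.add(new2)
        a1 = attrs.pop(edges[i])
        a2 = attrs.pop(edges[j])
        attrs[new1] = a1
        attrs[new2] = a2
        edges[i] = new1
        edges[j] = new2
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    for e in edges:
        out.add_edge(*e, **attrs[e])
    return EcologicalNetwork(out, taxonomy=net.taxonomy)


def null_distribution(net: EcologicalNetwork, n_randomizations: int, seed: int) -> NullSummary:
    """Mean +/- sd of modularity, GD and avgCC over degree-preserving nulls.

    Each replicate reruns fast-greedy detection on an independently
    randomized copy; sub-seeds derive deterministically from ``seed``.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_randomizations)
    qs, gds, ccs = [], [], []
    for s in sub_seeds:
        null = randomize_network(net, int(s))
        _, q = fast_greedy_partition(null)
        qs.append(q)
        gds.append(_mean_geodesic_distance(null.graph))
        ccs.append(float(np.mean(list(nx.clustering(null.graph).values()))))
    def _sd(x: list[float]) -> float:
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return NullSummary(
        n_randomizations=n_randomizations,
        modularity_mean=float(np.mean(qs)), modularity_sd=_sd(qs),
        gd_mean=float(np.mean(gds)), gd_sd=_sd(gds),
        avg_cc_mean=float(np.mean(ccs)), avg_cc_sd=_sd(ccs),
        seed=seed,
    )


def zi_pi(net: EcologicalNetwork, partition: dict[str, int] | None = None) -> list[NodeRoleRecord]:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against its module's mean
    and (population) standard deviation, with Zi = 0 when the sd is zero;
    Pi = 1 - sum_s (k_is/k_i)^2 over modules s.
    """
    if partition is None:
        partition = net.partition
    if partition is None:
        raise ValueError("no partition given or attached to the network")
    g = net.graph
    missing = [n for n in g.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition missing nodes: {sorted(missing)[:5]}")
    within: dict[str, int] = {}
    per_module_links: dict[str, dict[int, int]] = {n: {} for n in g.nodes}
    for u, v in g.edges:
        per_module_links[u][partition[v]] = per_module_links[u].get(partition[v], 0) + 1
        per_module_links[v][partition[u]] = per_module_links[v].get(partition[u], 0) + 1
        if partition[u] == partition[v]:
            within[u] = within.get(u, 0) + 1
            within[v] = within.get(v, 0) + 1
    kappa_by_module: dict[int, list[int]] = {}
    for node in g.nodes:
        kappa_by_module.setdefault(partition[node], []).append(within.get(node, 0))
    module_stats = {
        m: (float(np.mean(k)), float(np.std(k)))
        for m, k in kappa_by_module.items()
    }
    records = []
    for node in sorted(g.nodes):
        k_i = g.degree(node)
        kappa = within.get(node, 0)
        mean, sd = module_stats[partition[node]]
        zi = (kappa - mean) / sd if sd > 0 else 0.0
        pi = 1.0 - sum((k_im / k_i) ** 2 for k_im in per_module_links[node].values()) if k_i else 0.0
        records.append(NodeRoleRecord(node, partition[node], k_i, kappa, zi, pi))
    return records


def classify_roles(records: list[NodeRoleRecord], zi_cut: float = ZI_CUT,
                   pi_cut: float = PI_CUT) -> list[NodeRoleRecord]:
    """Label each record by the Zi/Pi threshold taxonomy (in place, returned).

    network hub: Zi > zi_cut and Pi > pi_cut; module hub: Zi > zi_cut only;
    connector: Pi > pi_cut only; otherwise peripheral.
    """
    for rec in records:
        if rec.zi > zi_cut and rec.pi > pi_cut:
            rec.role = "network hub"
        elif rec.zi > zi_cut:
            rec.role = "module hub"
        elif rec.pi > pi_cut:
            rec.role = "connector"
        else:
            rec.role = "peripheral"
    return records


@dataclass
class EgoReport:
    focal: str
    neighbors: list[tuple[str, float, str]]   # (neighbor id, correlation, sign)
    n_positive: int
    n_negative: int


def ego_subnetwork(net: EcologicalNetwork, focal_node: str) -> EgoReport:
    """The focal node's neighbors with per-edge signs and the sign tally."""
    g = net.graph
    if focal_node not in g:
        raise ValueError(f"focal node {focal_node!r} not in network")
    neighbors = []
    for nb in sorted(g.neighbors(focal_node)):
        d = g.edges[focal_node, nb]
        neighbors.append((nb, float(d.get("correlation", float("nan"))), d.get("sign", "")))
    pos = sum(1 for *_, s in neighbors if s == "positive")
    neg = sum(1 for *_, s in neighbors if s == "negative")
    return EgoReport(focal_node, neighbors, pos, neg)
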