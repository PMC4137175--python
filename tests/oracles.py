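"""Brute-force reference implementations, independent of the package code.

These work on plain node sets / edge-pair sets so they cannot share bugs
with the networkx-backed implementations they check.
"""

from collections import Counter, deque


def shortest_path_lengths(nodes, edges, source):
    """Single-source BFS hop counts over plain adjacency dicts."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def neighborhood_nodes(nodes, edges, baits, steps):
    """{v : min over present baits of shortest-path(b, v) <= steps}."""
    present = [b for b in baits if b in nodes]
    keep = set()
    for v in nodes:
        best = None
        for b in present:
            d = shortest_path_lengths(nodes, edges, b).get(v)
            if d is not None and (best is None or d < best):
                best = d
        if best is not None and best <= steps:
            keep.add(v)
    return keep


def induced_edges(edges, keep):
    return {(a, b) for a, b in edges if a in keep and b in keep}


def conservation_counts(network_node_sets, fam_map, unassigned="UNASSIGNED"):
    """Exhaustive loop over (family, network) membership."""
    families = {f for f in fam_map.values() if f != unassigned}
    counts = {}
    for fam in families:
        n = 0
        for nodes in network_node_sets:
            if any(fam_map.get(g) == fam for g in nodes):
                n += 1
        if n > 0:
            counts[fam] = n
    return counts


def collapse_family_edges(nodes, edges, fam_map, unassigned="UNASSIGNED"):
    """Exhaustive double loop over gene pairs; returns (family nodes,
    canonical family edge pairs incl. self-loops)."""
    fam_nodes = {fam_map[g] for g in nodes if fam_map.get(g, unassigned) != unassigned}
    fam_edges = set()
    for a in nodes:
        for b in nodes:
            if a >= b:
                continue
            if (a, b) in edges or (b, a) in edges:
                fa = fam_map.get(a, unassigned)
                fb = fam_map.get(b, unassigned)
                if fa == unassigned or fb == unassigned:
                    continue
                fam_edges.add(tuple(sorted((fa, fb))))
    return fam_nodes, fam_edges


def union_consensus(family_edge_sets):
    """Edge -> number of family networks containing it."""
    occ = Counter()
    for edge_set in family_edge_sets:
        occ.update(edge_set)
    return dict(occ)


def classify(bins, target, unknown):
    tops = {b.split(".", 1)[0] for b in bins}
    if tops & set(target):
        return "target"
    if tops & set(unknown):
        return "unknown"
    return "other"
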