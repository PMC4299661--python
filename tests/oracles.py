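"""Independent brute-force graph oracles used by the tests.

Deliberately naive: plain-dict adjacency, hand-rolled BFS and exhaustive
shortest-path enumeration, no shared code with the package under test.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations


def adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_shortest_paths(adj, dist, source, target):
    """Enumerate every shortest source->target path by backtracking."""
    if target not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == target:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[target]:
                path.append(v)
                extend(path)
                path.pop()

    extend([source])
    return [p for p in paths if len(p) - 1 == dist[target]]


def oracle_betweenness(nodes, edges):
    adj = adjacency(nodes, edges)
    bet = {n: 0.0 for n in nodes}
    for s, t in combinations(sorted(adj), 2):
        dist = bfs_distances(adj, s)
        paths = all_shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bet[v] += 1.0 / len(paths)
    return bet


def oracle_closeness(nodes, edges):
    """Wasserman-Faust component-scaled closeness."""
    adj = adjacency(nodes, edges)
    n = len(adj)
    out = {}
    for u in adj:
        dist = bfs_distances(adj, u)
        k = len(dist)  # component size
        total = sum(dist.values())
        if k <= 1 or total == 0:
            out[u] = 0.0
        else:
            out[u] = ((k - 1) / (n - 1)) * ((k - 1) / total)
    return out


def oracle_state(nodes, edges, removed=()):
    """Edges, components, giant size, mean pairwise distance and diameter of
    the graph induced on nodes minus ``removed``."""
    keep = [n for n in nodes if n not in set(removed)]
    kept_edges = [(a, b) for a, b in edges if a in set(keep) and b in set(keep)]
    adj = adjacency(keep, kept_edges)
    seen = set()
    comp_sizes = []
    for u in adj:
        if u in seen:
            continue
        comp = bfs_distances(adj, u)
        seen.update(comp)
        comp_sizes.append(len(comp))
    total, pairs, diameter = 0, 0, 0
    for u in adj:
        dist = bfs_distances(adj, u)
        for v, d in dist.items():
            if v != u:
                total += d
                pairs += 1
                diameter = max(diameter, d)
    return {
        "n_edges": len(kept_edges),
        "n_components": len(comp_sizes),
        "giant_size": max(comp_sizes) if comp_sizes else 0,
        "avg_shortest_path": total / pairs if pairs else 0.0,
        "diameter": diameter,
    }
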