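"""Independent brute-force oracles for graph and map statistics.

Everything here is deliberately naive (string sets, dict BFS, triple
loops) and shares no code with the package implementation, so that the
two routes can be compared exactly on small spaces.
"""

from __future__ import annotations

import itertools
from collections import deque

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s):
    return "".join(COMP[c] for c in reversed(s))


def canon(s):
    return min(s, rc(s))


def all_canonical(k):
    return sorted({canon("".join(p)) for p in itertools.product("ACGT", repeat=k)})


def mismatches(a, b):
    return sum(x != y for x, y in zip(a, b))


def alignment_distance(a, b):
    return min(mismatches(a, b), mismatches(a, rc(b)))


def is_shift(a, b):
    """One-base shift relation against either strand of b."""
    for t in (b, rc(b)):
        if a[1:] == t[:-1] or t[1:] == a[:-1]:
            return True
    return False


def adjacent(a, b):
    """Full edge rule: point mutation (distance 1) or single shift."""
    if canon(a) == canon(b):
        return False
    return alignment_distance(a, b) == 1 or is_shift(a, b)


def space_edges(k):
    nodes = all_canonical(k)
    return {
        (a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
        if adjacent(a, b)
    }


def neighbor_map(nodes, edges):
    nbrs = {n: set() for n in nodes}
    for a, b in edges:
        nbrs[a].add(b)
        nbrs[b].add(a)
    return nbrs


def induced_edges(nodes, nbrs):
    ns = set(nodes)
    return {(a, b) for a in ns for b in nbrs[a] if b in ns and a < b}


def components(nodes, nbrs):
    ns = set(nodes)
    seen = set()
    comps = []
    for start in sorted(ns):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in nbrs[u]:
                if v in ns and v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def bfs(nodes, nbrs, source):
    ns = set(nodes)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in nbrs[u]:
            if v in ns and v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def diameter_and_cpl(nodes, nbrs):
    nodes = sorted(nodes)
    if len(nodes) == 1:
        return 0, 0.0
    total, diam, count = 0, 0, 0
    for s in nodes:
        dist = bfs(nodes, nbrs, s)
        assert len(dist) == len(nodes), "disconnected"
        for t, d in dist.items():
            if t != s:
                total += d
                count += 1
                diam = max(diam, d)
    return diam, total / count


def clustering(nodes, nbrs):
    nodes = sorted(nodes)
    ns = set(nodes)
    acc = 0.0
    for i in nodes:
        neigh = sorted(nbrs[i] & ns)
        k = len(neigh)
        if k < 2:
            continue
        links = sum(
            1
            for a, b in itertools.combinations(neigh, 2)
            if b in nbrs[a]
        )
        acc += 2.0 * links / (k * (k - 1))
    return acc / len(nodes)


def assortativity(nodes, nbrs):
    ns = set(nodes)
    deg = {n: len(nbrs[n] & ns) for n in ns}
    edges = [(a, b) for a in sorted(ns) for b in sorted(nbrs[a] & ns) if a < b]
    if not edges:
        return float("nan")
    m = len(edges)
    s_jk = sum(deg[a] * deg[b] for a, b in edges) / m
    s_half = sum(0.5 * (deg[a] + deg[b]) for a, b in edges) / m
    s_sq = sum(0.5 * (deg[a] ** 2 + deg[b] ** 2) for a, b in edges) / m
    den = s_sq - s_half**2
    if den == 0:
        return float("nan")
    return (s_jk - s_half**2) / den


def route_factor(nodes, nbrs, all_nodes, all_nbrs, target):
    l_dist = bfs(nodes, nbrs, target)
    d_dist = bfs(all_nodes, all_nbrs, target)
    ratios = [l_dist[i] / d_dist[i] for i in sorted(nodes) if i != target]
    return sum(ratios) / len(ratios)


def local_spectrum(site, memberships, all_nbrs):
    """memberships: phenotype -> set of sites (dominant networks)."""
    nbrs = all_nbrs[site]
    k = len(nbrs)
    return {q: len(nbrs & s) / k for q, s in memberships.items()}


def phi(memberships, all_nbrs):
    out = {}
    for p, sp in memberships.items():
        for q in memberships:
            vals = [local_spectrum(i, memberships, all_nbrs)[q] for i in sorted(sp)]
            out[(q, p)] = sum(vals) / len(vals)
    return out


def overlap(memberships):
    return {
        (q, p): len(memberships[q] & memberships[p]) / len(memberships[p])
        for q in memberships
        for p in memberships
    }


def accessibility(memberships, all_nbrs):
    out = {}
    for p, sp in memberships.items():
        boundary = set().union(*(all_nbrs[i] for i in sp)) - sp
        for q, sq in memberships.items():
            out[(q, p)] = len(boundary & sq) / len(boundary) if boundary else float("nan")
    return out


def bhattacharyya(i, j, memberships, all_nbrs, exclude_shared=True):
    ni, nj = set(all_nbrs[i]), set(all_nbrs[j])
    if exclude_shared:
        shared = ni & nj
        ni, nj = ni - shared, nj - shared
    ci = {q: len(ni & s) for q, s in memberships.items()}
    cj = {q: len(nj & s) for q, s in memberships.items()}
    si, sj = sum(ci.values()), sum(cj.values())
    if si == 0 or sj == 0:
        return float("nan")
    return sum((ci[q] / si * cj[q] / sj) ** 0.5 for q in memberships)


def covering(network, memberships, all_nbrs, variant, max_radius, include_self=True):
    """Mean/sd over source sites of the fraction of phenotypes covered."""
    phenos = list(memberships)
    per_source = []
    for src in sorted(network):
        if variant == "neutral":
            dist = bfs(network, neighbor_map_restrict(network, all_nbrs), src)
        else:
            dist = non_neutral_bfs(src, network, all_nbrs)
        fracs = []
        for n in range(max_radius + 1):
            visited = {v for v, d in dist.items() if d <= n}
            if not include_self:
                visited.discard(src)
            cov = sum(1 for q in phenos if visited & memberships[q])
            fracs.append(cov / len(phenos))
        per_source.append(fracs)
    means = [sum(col) / len(col) for col in zip(*per_source)]
    sds = [
        (sum((x - m) ** 2 for x in col) / len(col)) ** 0.5
        for col, m in zip(zip(*per_source), means)
    ]
    return means, sds


def neighbor_map_restrict(nodes, all_nbrs):
    ns = set(nodes)
    return {n: all_nbrs[n] & ns for n in ns}


def non_neutral_bfs(src, network, all_nbrs):
    """BFS where every step after the source lands outside the network."""
    dist = {src: 0}
    queue = deque([src])
    while queue:
        u = queue.popleft()
        for v in all_nbrs[u]:
            if v not in dist and v not in network:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist
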