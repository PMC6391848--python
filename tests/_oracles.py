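"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity from first principles (exhaustive
enumeration, BFS path counting, closed-form normal equations) without
touching the implementation path it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

_PAIRABLE = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def enumerate_duplex_mfe(mseq: str, tseq: str, model) -> float:
    """Exhaustive minimum energy over all valid intermolecular structures.

    A structure is a chain of pairable (i, j) with i strictly increasing and
    j strictly decreasing; consecutive pairs contribute a stack term when
    adjacent on both strands, otherwise a loop penalty (sides capped by the
    model).  The empty structure has energy 0.
    """
    pairable = [
        (i, j)
        for i, a in enumerate(mseq)
        for j, b in enumerate(tseq)
        if (a, b) in _PAIRABLE
    ]
    cap = model.max_loop
    best = 0.0

    def extend(i, j, energy):
        nonlocal best
        if energy < best:
            best = energy
        for i2, j2 in pairable:
            if i2 <= i or j2 >= j:
                continue
            di, dj = i2 - i - 1, j - j2 - 1
            if di == 0 and dj == 0:
                cost = model.stack(mseq[i] + tseq[j], mseq[i2] + tseq[j2])
            elif di > cap or dj > cap:
                continue
            else:
                cost = model.loop(di, dj)
            extend(i2, j2, energy + cost)

    for i, j in pairable:
        extend(i, j, model.initiation)
    return best


def _all_shortest_paths(adj: dict, s, t) -> list[list]:
    """All shortest s->t paths by BFS layering and recursive expansion."""
    dist = {s: 0}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    if t not in dist:
        return []

    paths = []

    def walk(u, acc):
        if u == t:
            paths.append(acc)
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                walk(v, acc + [v])

    walk(s, [s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def brute_betweenness(nodes, edges) -> dict:
    """Unordered-pair betweenness by explicit shortest-path enumeration."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            bc[v] += through / sigma
    return bc


def brute_closeness(nodes, edges) -> dict:
    """(reachable count) / (sum of BFS distances), 0 for isolated nodes."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    cc = {}
    for s in nodes:
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        others = {n: d for n, d in dist.items() if n != s}
        cc[s] = len(others) / sum(others.values()) if others else 0.0
    return cc


def ols_loglog(ks, counts) -> tuple[float, float]:
    """Slope and R^2 of log10(counts) on log10(ks) via the normal equations."""
    x = np.log10(np.asarray(ks, dtype=float))
    y = np.log10(np.asarray(counts, dtype=float))
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - (resid ** 2).sum() / ss_tot
    return float(slope), float(r2)


def kw_h_statistic(groups) -> float:
    """Tie-corrected Kruskal-Wallis H from rank sums, written out directly."""
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(values)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = values[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank, 1-based
        i = j
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        r = ranks[start:start + k].sum()
        h += r * r / k
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def kw_permutation_pvalue(groups) -> float:
    """Exact permutation p-value of the Kruskal-Wallis H (total n <= 8)."""
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    sizes = [len(g) for g in groups]
    h_obs = kw_h_statistic(groups)
    count = total = 0
    for perm in itertools.permutations(values):
        total += 1
        regrouped, start = [], 0
        for k in sizes:
            regrouped.append(list(perm[start:start + k]))
            start += k
        if kw_h_statistic(regrouped) >= h_obs - 1e-12:
            count += 1
    return count / total


def kappa_from_contingency(a: set, b: set, universe: set) -> float:
    """Cohen's kappa from the 2x2 confusion counts of the two indicators."""
    n11 = n10 = n01 = n00 = 0
    for g in universe:
        ina, inb = g in a, g in b
        if ina and inb:
            n11 += 1
        elif ina:
            n10 += 1
        elif inb:
            n01 += 1
        else:
            n00 += 1
    n = n11 + n10 + n01 + n00
    po = (n11 + n00) / n
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (n * n)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)
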