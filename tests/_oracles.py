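"""Independent brute-force implementations used as test oracles.

Everything here is deliberately naive (python loops, full enumeration) and
shares no code with the package paths it checks.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# DMP calling


def brute_dmp_scan(values, sample_a, sample_b, retained, threshold):
    """Exhaustive probe scan. ``values`` is a probes x samples DataFrame."""
    dmps = set()
    n_retained = 0
    for probe in values.index:
        if probe not in retained:
            continue
        a = values.loc[probe, sample_a]
        b = values.loc[probe, sample_b]
        if math.isnan(a) or math.isnan(b):
            continue
        n_retained += 1
        if abs(b - a) > threshold:
            dmps.add(probe)
    return dmps, n_retained


def brute_union_and_multiplicity(values, samples, retained, threshold):
    union = set()
    mult: dict[str, int] = {}
    for a, b in itertools.combinations(samples, 2):
        dmps, _ = brute_dmp_scan(values, a, b, retained, threshold)
        union |= dmps
        for p in dmps:
            mult[p] = mult.get(p, 0) + 1
    return union, mult


def brute_cna_removed(manifest_table, segs_by_sample, samples, threshold):
    removed = set()
    for sample in samples:
        for seg in segs_by_sample.get(sample, []):
            chrom, start, end, mean = seg
            if mean < threshold:
                for probe, row in manifest_table.iterrows():
                    if row["chrom"] == chrom and start <= row["pos"] <= end:
                        removed.add(probe)
    return removed


# ---------------------------------------------------------------------------
# Statistics


def _avg_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_exact_two_sided(diffs):
    """Exact signed-rank p by full enumeration of all 2^n sign patterns."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = _avg_ranks([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    totals = [
        sum(r for r, bit in zip(ranks, pattern) if bit)
        for pattern in itertools.product([0, 1], repeat=n)
    ]
    ge = sum(1 for t in totals if t >= w_obs - 1e-12)
    le = sum(1 for t in totals if t <= w_obs + 1e-12)
    return min(1.0, 2 * min(ge, le) / 2 ** n)


def welch_formula(x, y):
    """Textbook Welch statistic and Satterthwaite df."""
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def pearson_brute(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def breslow_loglik(beta, times, x, events=None):
    """Naive O(n^2) Breslow log partial likelihood."""
    n = len(times)
    events = [1] * n if events is None else events
    ll = 0.0
    for i in range(n):
        if not events[i]:
            continue
        denom = sum(
            math.exp(beta * x[j]) for j in range(n) if times[j] >= times[i]
        )
        ll += beta * x[i] - math.log(denom)
    return ll


# ---------------------------------------------------------------------------
# Clustering


def brute_agglomerate(D, method):
    """Naive agglomeration; returns merge heights in merge order."""
    n = D.shape[0]
    clusters = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pts = [D[i, j] for i in clusters[a] for j in clusters[b]]
                h = max(pts) if method == "complete" else sum(pts) / len(pts)
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


# ---------------------------------------------------------------------------
# Minimal-evolution trees


def enumerate_topologies(leaves):
    """All unrooted binary topologies over the leaves (1, 3, 15, 105, ...).

    Topologies are adjacency dicts node -> set(neighbours) with internal
    nodes named "i0", "i1", ...
    """
    leaves = list(leaves)
    assert len(leaves) >= 3
    first = {
        leaves[0]: {"i0"}, leaves[1]: {"i0"}, leaves[2]: {"i0"},
        "i0": {leaves[0], leaves[1], leaves[2]},
    }
    topos = [first]
    for k, leaf in enumerate(leaves[3:], start=1):
        new = []
        for adj in topos:
            edges = {frozenset((u, v)) for u in adj for v in adj[u]}
            for e in sorted(edges, key=lambda fs: sorted(map(str, fs))):
                u, v = sorted(e, key=str)
                adj2 = {x: set(s) for x, s in adj.items()}
                w = f"i{k}"
                adj2[u].discard(v)
                adj2[v].discard(u)
                adj2[w] = {u, v, leaf}
                adj2[u].add(w)
                adj2[v].add(w)
                adj2[leaf] = {w}
                new.append(adj2)
        topos = new
    return topos


def _path_edges(adj, a, b):
    parent = {a: None}
    stack = [a]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                stack.append(v)
    path = []
    node = b
    while parent[node] is not None:
        path.append(frozenset((node, parent[node])))
        node = parent[node]
    return path


def ols_total_on_topology(adj, dist_values, leaf_order):
    """OLS branch-length fit of a fixed topology; returns total length."""
    leaves = list(leaf_order)
    edges = sorted(
        {frozenset((u, v)) for u in adj for v in adj[u]},
        key=lambda fs: sorted(map(str, fs)),
    )
    idx = {e: k for k, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(len(leaves)), 2))
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for e in _path_edges(adj, leaves[i], leaves[j]):
            A[r, idx[e]] = 1.0
        d[r] = dist_values[i, j]
    lengths, *_ = np.linalg.lstsq(A, d, rcond=None)
    return float(lengths.sum())


def min_ols_total_exhaustive(dist_values, leaf_order):
    """Global minimum OLS total tree length over all unrooted topologies."""
    best = math.inf
    for adj in enumerate_topologies(leaf_order):
        best = min(best, ols_total_on_topology(adj, dist_values, leaf_order))
    return best


def tree_metric_from_random_tree(n_leaves, rng):
    """An additive (tree) metric from a random binary tree with known lengths.

    Returns (leaf names, distance matrix, total length of the generating tree).
    """
    leaves = [f"L{i}" for i in range(n_leaves)]
    adj = {
        leaves[0]: {"i0"}, leaves[1]: {"i0"}, leaves[2]: {"i0"},
        "i0": {leaves[0], leaves[1], leaves[2]},
    }
    for k, leaf in enumerate(leaves[3:], start=1):
        edges = sorted(
            {frozenset((u, v)) for u in adj for v in adj[u]},
            key=lambda fs: sorted(map(str, fs)),
        )
        u, v = sorted(edges[rng.integers(len(edges))], key=str)
        w = f"i{k}"
        adj[u].discard(v)
        adj[v].discard(u)
        adj[w] = {u, v, leaf}
        adj[u].add(w)
        adj[v].add(w)
        adj[leaf] = {w}
    lengths = {}
    for u in adj:
        for v in adj[u]:
            e = frozenset((u, v))
            if e not in lengths:
                lengths[e] = float(rng.uniform(0.2, 2.0))
    D = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        d = sum(lengths[e] for e in _path_edges(adj, leaves[i], leaves[j]))
        D[i, j] = D[j, i] = d
    return leaves, D, sum(lengths.values())
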