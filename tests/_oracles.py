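"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops, exhaustive path enumeration and direct formula transcription, so they
can serve as oracles for the graph measures, distances and the AUC.
"""
from itertools import combinations, permutations

import numpy as np


def pearson_brute(x, y):
    """Elementwise covariance / sigma Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def clustering_brute(a):
    """Triple-loop transcription of the map clustering coefficient."""
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        s = sum(a[i, j] for j in range(n))
        if s <= 1.0:
            continue
        num = 0.0
        for j in range(n):
            for k in range(n):
                num += a[i, j] * a[i, k] * a[j, k]
        total += num / ((s - 1.0) * s)
    return total / n


def _all_simple_path_lengths(a, lengths, src, dst):
    """Every simple path length from src to dst (exhaustive enumeration)."""
    n = a.shape[0]
    out = []

    def walk(node, visited, acc):
        if node == dst:
            out.append(acc)
            return
        for nxt in range(n):
            if a[node, nxt] > 0 and nxt not in visited:
                walk(nxt, visited | {nxt}, acc + lengths[node, nxt])

    walk(src, {src}, 0.0)
    return out


def shortest_path_brute(a, binarized):
    """All-pairs shortest distances by exhaustive simple-path enumeration."""
    n = a.shape[0]
    lengths = np.zeros_like(a, dtype=float)
    mask = a > 0
    lengths[mask] = 1.0 if binarized else 1.0 / a[mask]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            paths = _all_simple_path_lengths(a, lengths, i, j)
            if paths:
                d[i, j] = min(paths)
    return d


def local_efficiency_brute(a, binarized):
    """Direct transcription of the local network efficiency."""
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        gi = [i] + [j for j in range(n) if j != i and a[i, j] > 0]
        g = len(gi)
        if g < 2:
            continue
        sub = a[np.ix_(gi, gi)]
        d = shortest_path_brute(sub, binarized)
        acc = 0.0
        for jj in range(g):
            for kk in range(g):
                if jj != kk and np.isfinite(d[jj, kk]) and d[jj, kk] > 0:
                    acc += 1.0 / d[jj, kk]
        total += acc / (g * (g - 1))
    return total / n


def modularity_brute(a, labels):
    """Edge-fraction loop: M = sum_p [e_pp - (sum_q e_pq)^2]."""
    n = a.shape[0]
    total_w = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total_w += a[i, j]
    if total_w == 0:
        return 0.0
    comms = sorted(set(labels))
    m = 0.0
    for p in comms:
        e_pp = 0.0
        endpoint = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if a[i, j] <= 0:
                    continue
                in_p = int(labels[i] == p) + int(labels[j] == p)
                if in_p == 2:
                    e_pp += a[i, j]
                    endpoint += a[i, j]
                elif in_p == 1:
                    endpoint += a[i, j] / 2.0
        m += e_pp / total_w - (endpoint / total_w) ** 2
    return m


def nmi_brute(labels1, labels2):
    """Confusion-matrix normalized mutual information, plain loops."""
    n = len(labels1)
    cs1, cs2 = sorted(set(labels1)), sorted(set(labels2))
    c = np.zeros((len(cs1), len(cs2)))
    for l1, l2 in zip(labels1, labels2):
        c[cs1.index(l1), cs2.index(l2)] += 1
    num = 0.0
    for w in range(len(cs1)):
        for v in range(len(cs2)):
            if c[w, v] > 0:
                num += c[w, v] * np.log(c[w, v] * n / (c[w].sum() * c[:, v].sum()))
    num *= -2.0
    den = sum(c[w].sum() * np.log(c[w].sum() / n) for w in range(len(cs1)))
    den += sum(c[:, v].sum() * np.log(c[:, v].sum() / n) for v in range(len(cs2)))
    if den == 0.0:
        return 1.0
    return num / den


def auc_concordance(scores, labels, positive="case"):
    """Mann-Whitney concordance probability (ties credited 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def jaccard_sets_brute(edges1, edges2):
    """1 - |intersection| / |union| on edge sets (binarized maps)."""
    e1, e2 = set(edges1), set(edges2)
    union = e1 | e2
    if not union:
        return 0.0
    return 1.0 - len(e1 & e2) / len(union)
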