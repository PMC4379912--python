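"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exhaustive Steiner
search for networks, double-sum formulas for spatial statistics, indicator
vector algebra for AMOVA sums of squares, and library translation for codon
effects.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np


def hamming_int(a: int, b: int) -> int:
    return bin(a ^ b).count("1")


def steiner_min_length_hypercube(terminals: list[tuple[int, ...]]) -> int:
    """Minimum Steiner tree length for terminals in {0,1}^s (Dreyfus-Wagner)."""
    s = len(terminals[0])
    n_vertices = 1 << s
    term_ints = [int("".join(map(str, t)), 2) for t in terminals]
    t = len(term_ints)
    if t == 1:
        return 0
    full = (1 << t) - 1
    INF = float("inf")
    dp = [[INF] * n_vertices for _ in range(full + 1)]
    for i, ti in enumerate(term_ints):
        for v in range(n_vertices):
            dp[1 << i][v] = hamming_int(ti, v)
    for mask in range(1, full + 1):
        if bin(mask).count("1") < 2:
            continue
        row = dp[mask]
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if other and sub < other:  # visit each split once
                a, b = dp[sub], dp[other]
                for v in range(n_vertices):
                    c = a[v] + b[v]
                    if c < row[v]:
                        row[v] = c
            sub = (sub - 1) & mask
        # Dijkstra relaxation over hypercube unit edges
        heap = [(c, v) for v, c in enumerate(row) if c < INF]
        heapq.heapify(heap)
        while heap:
            c, v = heapq.heappop(heap)
            if c > row[v]:
                continue
            for bit in range(s):
                u = v ^ (1 << bit)
                if c + 1 < row[u]:
                    row[u] = c + 1
                    heapq.heappush(heap, (c + 1, u))
    return int(min(dp[full]))


def steiner_min_length_graph(
    nodes: list, edges: list[tuple[int, int, int]], terminals: list
) -> int:
    """Minimum Steiner tree length restricted to a given weighted graph."""
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for u, v, w in edges:
        adj[index[u]].append((index[v], w))
        adj[index[v]].append((index[u], w))
    term_idx = [index[t] for t in terminals]
    t = len(term_idx)
    if t == 1:
        return 0
    full = (1 << t) - 1
    INF = float("inf")
    dp = [[INF] * n for _ in range(full + 1)]
    for i, ti in enumerate(term_idx):
        dp[1 << i][ti] = 0
    order = sorted(range(1, full + 1), key=lambda m: bin(m).count("1"))
    for mask in order:
        row = dp[mask]
        if bin(mask).count("1") >= 2:
            sub = (mask - 1) & mask
            while sub:
                other = mask ^ sub
                if other and sub < other:
                    a, b = dp[sub], dp[other]
                    for v in range(n):
                        c = a[v] + b[v]
                        if c < row[v]:
                            row[v] = c
                sub = (sub - 1) & mask
        heap = [(c, v) for v, c in enumerate(row) if c < INF]
        heapq.heapify(heap)
        while heap:
            c, v = heapq.heappop(heap)
            if c > row[v]:
                continue
            for u, w in adj[v]:
                if c + w < row[u]:
                    row[u] = c + w
                    heapq.heappush(heap, (c + w, u))
    best = min(dp[full])
    return int(best) if best < INF else -1


def morans_i_double_sum(values, weights) -> float:
    """Literal double-sum Moran's I."""
    x = list(values)
    n = len(x)
    xbar = sum(x) / n
    num = 0.0
    wsum = 0.0
    for i in range(n):
        for j in range(n):
            num += weights[i][j] * (x[i] - xbar) * (x[j] - xbar)
            wsum += weights[i][j]
    den = sum((xi - xbar) ** 2 for xi in x)
    return n / wsum * num / den


def amova_ss_from_indicators(counts: np.ndarray, group_index: list[list[int]]):
    """AMOVA sums of squares via indicator-vector deviations from means.

    Each individual is a one-hot vector over haplogroups; squared Euclidean
    distance / 2 between two individuals is the 0/1 haplogroup distance.
    SS of a pool = sum of squared deviations from the pool mean vector / 1
    (times 1/2 to match the pairwise-distance convention).
    """
    P, H = counts.shape

    def individuals(rows: np.ndarray) -> np.ndarray:
        out = []
        for h in range(H):
            out.extend([np.eye(H)[h]] * int(rows[h]))
        return np.array(out) if out else np.zeros((0, H))

    # sum_i ||x_i - xbar||^2 = (1/n) sum_{i<j} ||x_i - x_j||^2, and for
    # one-hot vectors ||x_i - x_j||^2 = 2 * d01(i, j); the pairwise-distance
    # SSD convention is therefore half the deviation sum of squares.
    def ssd(rows: np.ndarray) -> float:
        pool = individuals(rows)
        dev = pool - pool.mean(axis=0)
        return float((dev**2).sum()) / 2.0

    all_rows = counts.sum(axis=0)
    ssd_total = ssd(all_rows)
    ssd_wp = sum(ssd(counts[i]) for i in range(P))
    ssd_wg = sum(ssd(counts[idx].sum(axis=0)) for idx in group_index)
    return ssd_total - ssd_wg, ssd_wg - ssd_wp, ssd_wp


def iupac_scan(sequence: str, motif: str, anchor_index: int, window: int = 10) -> bool:
    """Independent IUPAC motif scan overlapping an anchor (0-based index)."""
    table = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
        "S": "GC", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
        "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    lo = max(0, anchor_index - window)
    hi = min(len(sequence), anchor_index + window + 1)
    seg = sequence[lo:hi]
    L = len(motif)
    for start in range(0, len(seg) - L + 1):
        if all(seg[start + k] in table[motif[k]] for k in range(L)):
            abs_start = lo + start
            if abs_start <= anchor_index < abs_start + L:
                return True
    return False
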