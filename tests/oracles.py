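"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's optimized code paths: exhaustive
ancestral-state summation instead of pruning, a plain dynamic program for
local alignment, per-column scans, BFS over the raw edge list, and
combinatorial sums for hypergeometric tails.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

AA = "ARNDCQEGHILKMFPSTWYV"


# --- likelihood: exhaustive sum over internal-state assignments -------------

def exhaustive_loglik(tree, rows: dict, model) -> float:
    """Sum P(data, internal states) over all internal-state assignments.

    Uses the model's transition matrices (shared, exact) but none of the
    pruning recursion. Practical only for <=4 taxa and a few sites.
    """
    idx = {a: i for i, a in enumerate(AA)}
    nodes = list(tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    leaves = [nd for nd in nodes if nd.is_leaf()]
    pmats = {
        id(nd): model.transition_matrix(nd.edge.length or 0.0)
        for nd in nodes if nd.parent_node is not None
    }
    pi = model.frequencies
    n_sites = len(next(iter(rows.values())))
    total = 0.0
    for site in range(n_sites):
        site_lik = 0.0
        for assignment in itertools.product(range(20), repeat=len(internal)):
            states = {id(nd): s for nd, s in zip(internal, assignment)}
            for lf in leaves:
                ch = rows[lf.taxon.label][site]
                states[id(lf)] = None if ch == "X" else idx[ch]
            prob = pi[states[id(tree.seed_node)]]
            for nd in nodes:
                if nd.parent_node is None:
                    continue
                parent_state = states[id(nd.parent_node)]
                own = states[id(nd)]
                if own is None:  # missing leaf: sums to 1
                    continue
                prob *= pmats[id(nd)][parent_state, own]
            site_lik += prob
        total += math.log(site_lik)
    return total


# --- Smith-Waterman with affine gaps ----------------------------------------

def sw_affine_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Textbook three-state local alignment DP (Gotoh), no optimizations.

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    neg = -10 ** 9
    M = [[0] * (m + 1) for _ in range(n + 1)]   # match/mismatch state
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                X[i - 1][j] - gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                Y[i][j - 1] - gap_extend,
            )
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0,
                s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]),
            )
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return int(best)


# --- gap columns -------------------------------------------------------------

def gapfree_columns(rows: list[str]) -> list[int]:
    width = len(rows[0])
    return [c for c in range(width) if all(r[c] != "-" for r in rows)]


# --- GO levels by BFS over the raw parent lists ------------------------------

def bfs_levels(parents: dict, roots: list[str]) -> dict:
    children: dict[str, list[str]] = {t: [] for t in parents}
    for t, ps in parents.items():
        for p in ps:
            children[p].append(t)
    level = {r: 1 for r in roots}
    frontier = list(roots)
    while frontier:
        nxt = []
        for t in frontier:
            for c in children[t]:
                if c not in level:
                    level[c] = level[t] + 1
                    nxt.append(c)
        frontier = nxt
    return level


# --- hypergeometric tails by combinatorial sums ------------------------------

def hypergeom_tail(k: int, n: int, K: int, N: int, direction: str) -> float:
    denom = math.comb(N, n)
    lo, hi = max(0, n - (N - K)), min(n, K)
    if direction == "enriched":
        support = range(max(k, lo), hi + 1)
    else:
        support = range(lo, min(k, hi) + 1)
    return sum(math.comb(K, x) * math.comb(N - K, n - x) for x in support) / denom


# --- BY step-up by the definition --------------------------------------------

def by_adjust(pvals) -> np.ndarray:
    p = np.asarray(pvals, float)
    m = len(p)
    c = sum(1.0 / h for h in range(1, m + 1))
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * c / rank * p[i])
        adj[i] = running
    return adj
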