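"""Independent oracles for the test suite.

Each oracle is written directly from the definition of the quantity it
checks (exhaustive enumeration, plain-loop iteration, from-scratch
recomputation) and shares no code with the package implementation.
"""

from __future__ import annotations

import random

import numpy as np

# ---------------------------------------------------------------------------
# Alignment: exhaustive enumeration over alignments under affine gaps.
# Gap of length k costs open + (k - 1) * extend.  States: 0 = last column
# was a residue pair, 1 = gap in b (a consumed), 2 = gap in a (b consumed).


def enumerate_global(a, b, sub, gap_open, gap_extend):
    """Best global alignment score by enumerating every alignment."""
    la, lb = len(a), len(b)
    best = [-float("inf")]

    def rec(i, j, state, score):
        if i == la and j == lb:
            if score > best[0]:
                best[0] = score
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, 0, score + sub[(a[i], b[j])])
        if i < la:
            rec(i + 1, j, 1, score - (gap_extend if state == 1 else gap_open))
        if j < lb:
            rec(i, j + 1, 2, score - (gap_extend if state == 2 else gap_open))

    rec(0, 0, 0, 0.0)
    return best[0]


def enumerate_local(a, b, sub, gap_open, gap_extend):
    """Best local alignment score (0 allowed) by enumeration.

    An optimal local alignment starts and ends on a residue-pair column,
    so enumeration is restricted to such alignments without loss.
    """
    la, lb = len(a), len(b)
    best = [0.0]

    def rec(i, j, state, score):
        # (i, j) are the next free positions; a match column just ended
        if state == 0 and score > best[0]:
            best[0] = score
        if i < la and j < lb:
            rec(i + 1, j + 1, 0, score + sub[(a[i], b[j])])
        if i < la:
            rec(i + 1, j, 1, score - (gap_extend if state == 1 else gap_open))
        if j < lb:
            rec(i, j + 1, 2, score - (gap_extend if state == 2 else gap_open))

    for i in range(la):
        for j in range(lb):
            rec(i + 1, j + 1, 0, sub[(a[i], b[j])])
    return best[0]


def blosum62_dict():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out = {}
    for x in mat.alphabet:
        for y in mat.alphabet:
            out[(x, y)] = 0.0 if "X" in (x, y) else float(mat[x, y])
    return out


# ---------------------------------------------------------------------------
# MCL: plain-loop re-implementation of the expansion/inflation recurrence.


def mcl_reference_partition(nodes, edges, inflation=2.0, prune=1e-5,
                            max_iter=100, eps=1e-8):
    """Hand-iterated MCL on (nodes, weighted edges) -> set of frozensets."""
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = [[0.0] * n for _ in range(n)]
    for u, v, w in edges:
        m[idx[u]][idx[v]] = w
        m[idx[v]][idx[u]] = w
    for i in range(n):
        loop = max((m[j][i] for j in range(n)), default=0.0)
        m[i][i] = loop if loop > 0 else 1.0
    _normalize_columns(m)
    for _ in range(max_iter):
        sq = [[sum(m[i][t] * m[t][j] for t in range(n)) for j in range(n)]
              for i in range(n)]
        infl = [[sq[i][j] ** inflation for j in range(n)] for i in range(n)]
        _normalize_columns(infl)
        for j in range(n):
            col = [infl[i][j] for i in range(n)]
            kept = [x if x >= prune else 0.0 for x in col]
            if sum(kept) == 0:
                kept = [0.0] * n
                kept[col.index(max(col))] = 1.0
            total = sum(kept)
            for i in range(n):
                infl[i][j] = kept[i] / total
        delta = max(
            abs(infl[i][j] - m[i][j]) for i in range(n) for j in range(n)
        )
        m = infl
        if delta < eps:
            break
    # clusters: nodes grouped by the attractors they flow to
    attractors = [i for i in range(n) if m[i][i] > 1e-4]
    if not attractors:
        attractors = list(range(n))
    flows_to = {}
    for j in range(n):
        dest = frozenset(
            i for i in attractors if m[i][j] > 1e-4
        )
        flows_to[j] = dest if dest else frozenset([j])
    # union overlapping attractor sets
    clusters: list[set] = []
    for j in range(n):
        dest = set(flows_to[j])
        merged = {j}
        rest = []
        for c in clusters:
            if c["dest"] & dest or (j in c["members"]):
                dest |= c["dest"]
                merged |= c["members"]
            else:
                rest.append(c)
        rest.append({"dest": dest, "members": merged})
        clusters = rest
    return {frozenset(nodes[i] for i in c["members"]) for c in clusters}


def _normalize_columns(m):
    n = len(m)
    for j in range(n):
        total = sum(m[i][j] for i in range(n))
        if total > 0:
            for i in range(n):
                m[i][j] /= total


# ---------------------------------------------------------------------------
# UPGMA: from-scratch agglomeration recomputing averages over the original
# matrix at every step (no Lance-Williams updates).


def upgma_reference_merges(labels, dmat):
    """List of (members_a, members_b, height) merges, lexicographic ties."""
    index = {lab: i for i, lab in enumerate(labels)}
    clusters = [frozenset([lab]) for lab in labels]
    merges = []
    while len(clusters) > 1:
        pairs = []
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                a, b = clusters[x], clusters[y]
                avg = sum(
                    dmat[index[p]][index[q]] for p in a for q in b
                ) / (len(a) * len(b))
                pairs.append((avg, tuple(sorted((min(a), min(b)))), x, y))
        min_avg = min(p[0] for p in pairs)
        ties = [p for p in pairs if p[0] <= min_avg + 1e-12]
        avg, _, x, y = min(ties, key=lambda p: p[1])
        a, b = clusters[x], clusters[y]
        merges.append((a, b, avg))
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(a | b)
    return merges


# ---------------------------------------------------------------------------
# Random additive trees for neighbor-joining recovery checks.


def random_additive_tree(n_taxa, rng: random.Random):
    """Random binary topology with positive branch lengths.

    Returns (labels, distance matrix as numpy array) where distances are
    exact path lengths on the generated tree.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency with branch lengths; start from a star of 3, then add leaves
    next_internal = [0]

    def new_internal():
        next_internal[0] += 1
        return f"i{next_internal[0]}"

    adj: dict[str, dict[str, float]] = {}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    center = new_internal()
    for lab in labels[:3]:
        connect(center, lab, rng.uniform(0.1, 2.0))
    for lab in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = rng.choice(edges)
        w = adj[u][v]
        split = rng.uniform(0.2, 0.8)
        mid = new_internal()
        disconnect(u, v)
        connect(u, mid, w * split)
        connect(mid, v, w * (1 - split))
        connect(mid, lab, rng.uniform(0.1, 2.0))
    # all-pairs path lengths between leaf labels by BFS/DFS
    d = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node].items():
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    stack.append(nb)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    np.fill_diagonal(d, 0.0)
    return labels, d
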