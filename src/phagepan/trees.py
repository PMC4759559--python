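"""Distances, hierarchical clustering, neighbor joining and Newick I/O.

Binary presence/absence profiles are compared with the Jaccard distance
(1 - |intersection| / |union|); genomes (or families) are then grouped by
average-linkage (UPGMA) agglomeration with a deterministic lexicographic
tie-break, and sequence distance matrices feed a textbook Saitou-Nei
neighbor-joining construction.  Trees serialize to Newick with 6-decimal
branch lengths; unrooted NJ trees are written with a trifurcating root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Dendrogram",
    "jaccard_distance_matrix",
    "average_linkage_hcl",
    "cut_tree",
    "neighbor_joining",
    "to_newick",
    "from_newick",
    "tree_path_lengths",
    "write_merges_tsv",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with a zero diagonal and ordered labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


def jaccard_distance_matrix(
    vectors: np.ndarray, labels: Sequence[str]
) -> DistanceMatrix:
    """Jaccard distance between the rows of a boolean matrix.

    d(x, y) = 1 - |x AND y| / |x OR y|; a pair of all-false vectors is at
    distance 0 by convention.  To compare genome columns of a families x
    genomes presence matrix, pass its transpose.
    """
    x = np.asarray(vectors, dtype=bool).astype(int)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), d)


@dataclass
class Dendrogram:
    """An agglomeration history: leaf labels and ordered merges with heights."""

    labels: list[str]
    # each merge: (members_a, members_b, height); members are leaf-label frozensets
    merges: list[tuple[frozenset[str], frozenset[str], float]] = field(
        default_factory=list
    )

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def average_linkage_hcl(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration with a deterministic tie-break.

    At each step the pair of clusters at minimal average distance is merged;
    among ties the pair whose (smallest-label, smallest-label) key is
    lexicographically least wins.  Merge heights are non-decreasing.
    """
    labels = dm.labels
    if len(labels) == 1:
        return Dendrogram(list(labels))
    clusters: dict[str, frozenset[str]] = {lab: frozenset([lab]) for lab in labels}
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            dist[_pairkey(a, b)] = float(dm.d[i, j])
    merges = []
    while len(clusters) > 1:
        min_val = min(dist.values())
        # ties (within float noise) -> lexicographically smallest label pair
        ka, kb = min(k for k, v in dist.items() if v <= min_val + 1e-12)
        height = dist[(ka, kb)]
        members_a, members_b = clusters.pop(ka), clusters.pop(kb)
        merged = members_a | members_b
        new_key = min(merged)
        # Lance-Williams update for average linkage
        na, nb = len(members_a), len(members_b)
        for other in list(clusters):
            da = dist.pop(_pairkey(ka, other))
            db = dist.pop(_pairkey(kb, other))
            dist[_pairkey(new_key, other)] = (na * da + nb * db) / (na + nb)
        del dist[_pairkey(ka, kb)]
        clusters[new_key] = merged
        merges.append((members_a, members_b, height))
    return Dendrogram(list(labels), merges)


def _pairkey(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def cut_tree(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cut a dendrogram into exactly k clusters by undoing the k-1 top merges.

    Returns label -> cluster id, ids 1..k assigned in order of each
    cluster's smallest member label.
    """
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    keep = dendrogram.merges[: n - k]
    parent: dict[str, str] = {lab: lab for lab in dendrogram.labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for members_a, members_b, _ in keep:
        parent[find(min(members_a))] = find(min(members_b))
    groups: dict[str, set[str]] = {}
    for lab in dendrogram.labels:
        groups.setdefault(find(lab), set()).add(lab)
    ordered = sorted(groups.values(), key=min)
    return {lab: i + 1 for i, members in enumerate(ordered) for lab in members}


@dataclass
class TreeNode:
    """A rooted tree node; an unrooted tree is held at a trifurcating root."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def leaf_names(self) -> list[str]:
        return [leaf.name or "" for leaf in self.leaves()]


def dendrogram_to_tree(dendrogram: Dendrogram) -> TreeNode:
    """Ultrametric tree from a dendrogram: leaf depth equals merge height / 2."""
    nodes: dict[frozenset[str], tuple[TreeNode, float]] = {
        frozenset([lab]): (TreeNode(name=lab), 0.0) for lab in dendrogram.labels
    }
    root = next(iter(nodes.values()))[0]
    for members_a, members_b, height in dendrogram.merges:
        node_a, h_a = nodes.pop(frozenset(members_a))
        node_b, h_b = nodes.pop(frozenset(members_b))
        node_a.length = height / 2 - h_a / 2
        node_b.length = height / 2 - h_b / 2
        parent = TreeNode(children=[node_a, node_b])
        nodes[frozenset(members_a | members_b)] = (parent, height)
        root = parent
    return root


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sibling branch, the usual repair.  Tie-breaking on the
    Q-matrix is lexicographic by label pair, so the construction is
    deterministic.  Two taxa collapse to a single edge; three or more give
    a trifurcating root.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("neighbor joining needs >= 2 labels")
    if n == 2:
        d = float(dm.d[0, 1])
        return TreeNode(children=[
            TreeNode(name=dm.labels[0], length=d),
            TreeNode(name=dm.labels[1], length=0.0),
        ])
    active: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in dm.labels}
    dist = {
        _pairkey(a, b): float(dm.d[i, j])
        for i, a in enumerate(dm.labels)
        for j, b in enumerate(dm.labels)
        if i < j
    }
    counter = 0
    while len(active) > 3:
        names = sorted(active)
        m = len(names)
        r = {a: sum(dist[_pairkey(a, b)] for b in names if b != a) for a in names}
        best_pair, best_q = None, None
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                q = (m - 2) * dist[_pairkey(a, b)] - r[a] - r[b]
                if best_q is None or q < best_q - 1e-12:
                    best_pair, best_q = (a, b), q
        a, b = best_pair
        dab = dist[_pairkey(a, b)]
        la = dab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = _repair_negative(la, lb)
        node = TreeNode(children=[
            _with_length(active.pop(a), la),
            _with_length(active.pop(b), lb),
        ])
        new_name = f"\x00internal{counter}"
        counter += 1
        for c in list(active):
            dist[_pairkey(new_name, c)] = (
                dist.pop(_pairkey(a, c)) + dist.pop(_pairkey(b, c)) - dab
            ) / 2
        del dist[_pairkey(a, b)]
        active[new_name] = node
    names = sorted(active)
    a, b, c = names
    dab, dac, dbc = (
        dist[_pairkey(a, b)], dist[_pairkey(a, c)], dist[_pairkey(b, c)],
    )
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    return TreeNode(children=[
        _with_length(active[a], max(la, 0.0)),
        _with_length(active[b], max(lb, 0.0)),
        _with_length(active[c], max(lc, 0.0)),
    ])


def _with_length(node: TreeNode, length: float) -> TreeNode:
    node.length = length
    return node


def _repair_negative(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += -la
        la = 0.0
    if lb < 0:
        la += -lb
        lb = 0.0
    return la, max(lb, 0.0)


def tree_path_lengths(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree (branch lengths summed)."""
    leaves: list[str] = []
    paths: dict[str, float] = {}
    dmat: dict[tuple[str, str], float] = {}

    def visit(node: TreeNode, depth: float) -> list[tuple[str, float]]:
        here = depth + (node.length or 0.0)
        if node.is_leaf:
            leaves.append(node.name or "")
            return [(node.name or "", here)]
        below: list[list[tuple[str, float]]] = [visit(c, here) for c in node.children]
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for la, da in below[i]:
                    for lb, db in below[j]:
                        dmat[_pairkey(la, lb)] = (da - here) + (db - here)
        return [pair for sub in below for pair in sub]

    visit(tree, -(tree.length or 0.0))
    labels = sorted(leaves)
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dmat[_pairkey(a, labels[j])]
    return DistanceMatrix(labels, out)


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick with branch lengths to 6 decimals."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            body = _quote(node.name or "")
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += _quote(node.name)
        if node.length is not None:
            body += f":{node.length:.6f}"
        return body

    return fmt(tree) + ";"


def _quote(name: str) -> str:
    if any(c in name for c in "(),:; \t'"):
        return "'" + name.replace("'", "''") + "'"
    return name


class NewickError(ValueError):
    pass


def from_newick(text: str) -> TreeNode:
    """Parse a Newick string; errors report the offending position."""
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError(f"missing trailing ';' at position {len(text)}")
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(f"{msg} at position {pos}")

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(text):
                    raise error("unterminated clade")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {text[pos]!r}")
        name = parse_label()
        if name:
            node.name = name
        if pos < len(text) and text[pos] == ":":
            pos += 1
            node.length = parse_number()
        if node.is_leaf and node.name is None:
            raise error("empty node")
        return node

    def parse_label() -> str:
        nonlocal pos
        if pos < len(text) and text[pos] == "'":
            pos += 1
            out = []
            while pos < len(text):
                if text[pos] == "'":
                    if pos + 1 < len(text) and text[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(text[pos])
                pos += 1
            raise error("unterminated quoted label")
        start = pos
        while pos < len(text) and text[pos] not in "(),:;":
            pos += 1
        return text[start:pos]

    def parse_number() -> float:
        nonlocal pos
        start = pos
        while pos < len(text) and (text[pos].isdigit() or text[pos] in "+-.eE"):
            pos += 1
        try:
            return float(text[start:pos])
        except ValueError:
            raise error(f"bad branch length {text[start:pos]!r}") from None

    root = parse_node()
    if pos != len(text) - 1 or text[pos] != ";":
        raise error("trailing content after tree")
    names = root.leaf_names()
    if len(set(names)) != len(names):
        raise NewickError("duplicate leaf labels")
    return root


def write_merges_tsv(dendrogram: Dendrogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("step\tmember_a\tmember_b\theight\n")
        for i, (ma, mb, h) in enumerate(dendrogram.merges, start=1):
            fh.write(
                f"{i}\t{','.join(sorted(ma))}\t{','.join(sorted(mb))}\t{h:.6f}\n"
            )
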