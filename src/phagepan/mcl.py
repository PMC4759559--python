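"""Markov Cluster Algorithm over the reciprocal-hit graph.

MCL simulates flow on the graph: alternately square the column-stochastic
flow matrix (expansion) and raise entries to the inflation power with
column renormalization (inflation), pruning vanishing entries, until the
matrix stops changing.  Clusters are read off the attractor structure of
the limit matrix.  Everything is deterministic; a dense numpy matrix is
ample at the few-thousand-protein scale of a phage collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = ["MCLParams", "ProteinFamily", "build_flow_matrix", "mcl_step",
           "run_mcl", "extract_families", "write_families_tsv",
           "read_families_tsv"]

ATTRACTOR_EPS = 1e-4


@dataclass(frozen=True)
class MCLParams:
    """MCL tuning knobs.

    inflation: the exponent r (> 1); higher r gives finer clusters.
    expansion is fixed at matrix squaring.  self_loop_weight None means
    each node receives a loop equal to its maximum incident edge weight
    (standard damping; prevents bipartite oscillation).
    """

    inflation: float = 2.0
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_eps: float = 1e-8
    self_loop_weight: float | None = None

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class ProteinFamily:
    """An MCL protein family: homologs, paralogs, orthologs or a unique protein."""

    family_id: str
    members: frozenset[tuple[str, str]]  # (genome_id, locus_tag)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a family cannot be empty")

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(gid for gid, _ in self.members)

    @property
    def size(self) -> int:
        return len(self.members)


def build_flow_matrix(
    graph: nx.Graph, params: MCLParams = MCLParams()
) -> tuple[np.ndarray, list[str]]:
    """Symmetric weights + self loops, columns normalized to sum 1.

    Returns the column-stochastic matrix and the node order (sorted ids).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    mat = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        mat[index[u], index[v]] = w
        mat[index[v], index[u]] = w
    for i in range(n):
        if params.self_loop_weight is not None:
            loop = params.self_loop_weight
        else:
            loop = mat[:, i].max()
            if loop <= 0:
                loop = 1.0
        mat[i, i] = loop
    return mat / mat.sum(axis=0, keepdims=True), nodes


def mcl_step(matrix: np.ndarray, params: MCLParams = MCLParams()) -> np.ndarray:
    """One expansion + inflation + prune round; stochasticity is preserved.

    A column that collapses to all zeros after pruning is reset to a point
    mass on its pre-prune argmax (ties to the lowest node index).
    """
    expanded = matrix @ matrix
    inflated = expanded ** params.inflation
    colsum = inflated.sum(axis=0, keepdims=True)
    inflated = np.divide(
        inflated, colsum, out=np.zeros_like(inflated), where=colsum > 0
    )
    pruned = np.where(inflated >= params.prune_threshold, inflated, 0.0)
    dead = pruned.sum(axis=0) == 0
    if dead.any():
        for j in np.nonzero(dead)[0]:
            pruned[int(np.argmax(inflated[:, j])), j] = 1.0
    return pruned / pruned.sum(axis=0, keepdims=True)


def run_mcl(
    graph: nx.Graph, params: MCLParams = MCLParams()
) -> list[frozenset[str]]:
    """Iterate MCL to convergence and read clusters off the limit matrix.

    Attractor nodes (non-vanishing diagonal) linked by residual flow form
    cluster seeds; every other node joins the seed it sends the most flow
    to (ties to the lexicographically smallest cluster).  The result is a
    partition of the graph's nodes; clusters never span weakly connected
    components of the input.
    """
    matrix, nodes = build_flow_matrix(graph, params)
    converged = False
    for _ in range(params.max_iterations):
        nxt = mcl_step(matrix, params)
        if np.abs(nxt - matrix).max() < params.convergence_eps:
            matrix = nxt
            converged = True
            break
        matrix = nxt
    if not converged:
        warnings.warn(
            f"MCL did not converge within {params.max_iterations} iterations; "
            "interpreting the current matrix",
            stacklevel=2,
        )
    return interpret_clusters(matrix, nodes)


def interpret_clusters(
    matrix: np.ndarray, nodes: Sequence[str], eps: float = ATTRACTOR_EPS
) -> list[frozenset[str]]:
    """Partition nodes by the attractor systems of a (near-)limit MCL matrix."""
    n = len(nodes)
    attractors = [i for i in range(n) if matrix[i, i] > eps]
    if not attractors:  # degenerate; should not occur for converged input
        attractors = list(range(n))
    # union attractors connected by residual flow
    parent = {i: i for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    aset = set(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (matrix[i, j] > eps or matrix[j, i] > eps):
                parent[find(i)] = find(j)
    seeds: dict[int, set[int]] = {}
    for i in attractors:
        seeds.setdefault(find(i), set()).add(i)
    clusters = {root: set(members) for root, members in seeds.items()}
    # cluster sort key for deterministic tie-breaking
    key_of = {root: min(nodes[i] for i in members) for root, members in seeds.items()}
    for j in range(n):
        if j in aset:
            continue
        masses = {
            root: sum(matrix[i, j] for i in members)
            for root, members in seeds.items()
        }
        best = max(masses.values())
        if best <= 0:
            clusters[-j - 1] = {j}  # no flow anywhere: singleton
            key_of[-j - 1] = nodes[j]
            continue
        chosen = min(
            (root for root, m in masses.items() if m >= best - 1e-15),
            key=lambda r: key_of[r],
        )
        clusters[chosen].add(j)
    out = [frozenset(nodes[i] for i in members) for members in clusters.values()]
    out.sort(key=lambda c: (-len(c), min(c)))
    return out


def extract_families(
    partition: Sequence[frozenset[str]],
    proteome: Sequence[tuple[str, str, str]],
) -> list[ProteinFamily]:
    """Turn an MCL partition into numbered protein families.

    Proteome entries absent from the partition (proteins with no hits at
    all) become singleton families, so unique proteins count as families.
    Families are numbered F0001.. in decreasing size, ties by smallest
    member.
    """
    node_of = {}
    for gid, locus, _ in proteome:
        node_of[f"{gid}|{locus}"] = (gid, locus)
    clustered: set[str] = set()
    member_sets: list[frozenset[tuple[str, str]]] = []
    for cluster in partition:
        members = frozenset(node_of[n] for n in cluster if n in node_of)
        unknown = [n for n in cluster if n not in node_of]
        if unknown:
            raise ValueError(f"partition contains unknown proteins: {unknown[:3]}")
        if members:
            member_sets.append(members)
        clustered.update(cluster)
    for node, key in node_of.items():
        if node not in clustered:
            member_sets.append(frozenset([key]))
    member_sets.sort(key=lambda m: (-len(m), min(m)))
    return [
        ProteinFamily(family_id=f"F{i + 1:04d}", members=members)
        for i, members in enumerate(member_sets)
    ]


def write_families_tsv(families: Sequence[ProteinFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tsize\tn_genomes\tmembers\n")
        for fam in families:
            members = ",".join(f"{g}|{l}" for g, l in sorted(fam.members))
            fh.write(f"{fam.family_id}\t{fam.size}\t{len(fam.genomes)}\t{members}\n")


def read_families_tsv(path: str | Path) -> list[ProteinFamily]:
    families = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("family_id\t"):
            raise ValueError(f"{path}: not a families TSV")
        for line in fh:
            fid, _, _, members = line.rstrip("\n").split("\t")
            pairs = frozenset(
                tuple(m.split("|", 1)) for m in members.split(",") if m
            )
            families.append(ProteinFamily(family_id=fid, members=pairs))
    return families
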