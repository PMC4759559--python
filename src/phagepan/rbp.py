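"""Receptor binding protein (RBP) typing from C-terminal regions.

Host range of these phages is decided by the interaction of the RBP's
C-terminal (receptor-binding) region with the host cell wall polysaccharide
(CWPS).  RBPs fall into groups I-V, each tied to a CWPS type: I-C, II-B,
III-B&C, IV-U (unknown), V-A.  Queries are typed by global alignment of
their C-terminal region against reference RBPs; anything below the identity
floor is reported as "novel".

The packaged reference set is synthetic (generated sequences standing in
for deposited RBP loci, one per group) so that the machinery is exercisable
offline; substitute a curated FASTA + group map for real collections.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .homology import needleman_wunsch
from .trees import DistanceMatrix, TreeNode, neighbor_joining
from . import genome_io

import numpy as np

__all__ = [
    "RBPReference",
    "RBPAssignment",
    "GROUP_TO_CWPS",
    "extract_cterm",
    "assign_group",
    "build_rbp_tree",
    "load_references",
    "packaged_references",
]

GROUP_TO_CWPS = {"I": "C", "II": "B", "III": "B&C", "IV": "U", "V": "A"}
MIN_RBP_LEN = 30
DEFAULT_CTERM_LEN = 130


@dataclass(frozen=True)
class RBPReference:
    ref_id: str
    group: str
    sequence: str

    def __post_init__(self) -> None:
        if self.group not in GROUP_TO_CWPS:
            raise ValueError(f"unknown RBP group {self.group!r}")

    @property
    def cwps(self) -> str:
        return GROUP_TO_CWPS[self.group]


@dataclass(frozen=True)
class RBPAssignment:
    query_id: str
    best_ref: str
    identity: float
    group: str  # a roman-numeral group or "novel"


def extract_cterm(protein: str, length: int = DEFAULT_CTERM_LEN) -> str:
    """Last ``length`` residues (whole protein if shorter).

    Proteins under 30 aa are rejected as not credible RBPs.
    """
    if len(protein) < MIN_RBP_LEN:
        raise ValueError(
            f"protein of {len(protein)} aa is too short to be an RBP"
        )
    return protein[-length:]


def assign_group(
    query_rbp: str,
    references: Sequence[RBPReference],
    min_identity: float = 0.50,
    cterm_len: int = DEFAULT_CTERM_LEN,
    query_id: str = "query",
) -> RBPAssignment:
    """Type an RBP by its best global C-terminal identity to the references."""
    if not references:
        raise ValueError("empty reference set")
    qc = extract_cterm(query_rbp, cterm_len)
    best_ref, best_ident = None, -1.0
    for ref in references:
        ident = needleman_wunsch(
            qc, extract_cterm(ref.sequence, cterm_len)
        ).identity
        if ident > best_ident:
            best_ref, best_ident = ref, ident
    group = best_ref.group if best_ident >= min_identity else "novel"
    return RBPAssignment(
        query_id=query_id, best_ref=best_ref.ref_id,
        identity=best_ident, group=group,
    )


def build_rbp_tree(
    sequences: Mapping[str, str],
    cterm_len: int = DEFAULT_CTERM_LEN,
) -> TreeNode:
    """Neighbor-joining tree on pairwise p-distances of C-terminal regions.

    p-distance = 1 - global identity; the minimal-assumption distance when
    the original tree-building settings are unknown.
    """
    ids = list(sequences)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(ids) < 3:
        raise ValueError("need >= 3 sequences for a tree")
    cterms = {i: extract_cterm(sequences[i], cterm_len) for i in ids}
    labels = sorted(ids)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = needleman_wunsch(cterms[labels[i]], cterms[labels[j]]).identity
            d[i, j] = d[j, i] = 1.0 - ident
    return neighbor_joining(DistanceMatrix(labels, d))


def load_references(
    fasta_path: str | Path, group_map_path: str | Path
) -> list[RBPReference]:
    """Reference FASTA plus a two-column (ref_id, group) TSV map."""
    groups: dict[str, str] = {}
    with open(group_map_path) as fh:
        header = fh.readline()
        if not header.startswith("ref_id"):
            raise ValueError(f"{group_map_path}: expected a ref_id/group TSV")
        for line in fh:
            ref_id, group = line.rstrip("\n").split("\t")[:2]
            groups[ref_id] = group
    refs = []
    for ref_id, seq in genome_io.read_fasta(fasta_path):
        if ref_id not in groups:
            raise ValueError(f"{ref_id} missing from group map")
        refs.append(RBPReference(ref_id=ref_id, group=groups[ref_id], sequence=seq))
    return refs


def packaged_references() -> list[RBPReference]:
    """The synthetic reference set shipped with the package (one per group)."""
    data = resources.files("phagepan") / "data"
    return load_references(
        str(data / "rbp_references_synthetic.fasta"),
        str(data / "rbp_groups_synthetic.tsv"),
    )
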