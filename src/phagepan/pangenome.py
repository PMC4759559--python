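"""Presence/absence profile, core/variable partition and structural classes.

The core genome is the set of protein families with at least one member in
every genome of the collection; everything else is the variable (non-core)
genome.  Core membership is decided at the family level (paralogs collapse
to presence), while variable-gene counts are taken at the gene level, so a
genome carrying two copies of a variable family contributes two variable
genes.

A genome's structural class describes the gene complement around the major
tail protein gene (mtp): V1 carries neither nps nor tpeX; V2 has tpeX
downstream of mtp; V3 has nps upstream; V4 has both; V5 has tpeX downstream
plus a secondary rbp adjacent to the standard one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import PhageGenome
from .homology import needleman_wunsch
from .mcl import ProteinFamily

__all__ = [
    "PangenomeProfile",
    "build_profile",
    "core_families",
    "variable_counts",
    "group_summary",
    "classify_structural_variant",
    "assign_family_roles",
    "write_presence_tsv",
]

STRUCTURAL_ROLES = ("mtp", "nps", "tpeX", "rbp", "other")


@dataclass
class PangenomeProfile:
    """Families x genomes boolean presence matrix with the core partition."""

    genome_ids: list[str]
    family_ids: list[str]
    presence: np.ndarray  # bool, families x genomes

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.family_ids), len(self.genome_ids)):
            raise ValueError("presence matrix does not match id lists")
        empty = ~self.presence.any(axis=0)
        if empty.any():
            bad = [g for g, e in zip(self.genome_ids, empty) if e]
            raise ValueError(f"genomes with no families: {bad}")

    @property
    def core_ids(self) -> set[str]:
        rows = self.presence.all(axis=1)
        return {fid for fid, r in zip(self.family_ids, rows) if r}

    def column(self, genome_id: str) -> np.ndarray:
        return self.presence[:, self.genome_ids.index(genome_id)]


def build_profile(
    families: Sequence[ProteinFamily], genome_ids: Sequence[str]
) -> PangenomeProfile:
    """Binary matrix: presence[f, g] iff family f has >= 1 member from genome g."""
    genome_ids = list(genome_ids)
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicate genome ids")
    gidx = {g: i for i, g in enumerate(genome_ids)}
    family_ids = [f.family_id for f in families]
    presence = np.zeros((len(families), len(genome_ids)), dtype=bool)
    for fi, fam in enumerate(families):
        for gid in fam.genomes:
            if gid not in gidx:
                raise ValueError(f"family {fam.family_id} references unknown genome {gid}")
            presence[fi, gidx[gid]] = True
    return PangenomeProfile(genome_ids, family_ids, presence)


def core_families(profile: PangenomeProfile) -> set[str]:
    """Families with a member in every genome: the core genome."""
    return profile.core_ids


def variable_counts(
    profile: PangenomeProfile,
    gene_table: Iterable[tuple[str, str, str | None]],
) -> dict[str, int]:
    """Per-genome count of genes whose family is not core.

    ``gene_table`` rows are (genome_id, locus_tag, family_id); a gene with
    no family assignment counts as variable, with a warning.  Gene-level,
    so paralogs of a variable family each count.
    """
    core = profile.core_ids
    counts = {g: 0 for g in profile.genome_ids}
    for gid, locus, fid in gene_table:
        if gid not in counts:
            raise ValueError(f"gene table references unknown genome {gid}")
        if fid is None or fid == "":
            warnings.warn(
                f"{gid}/{locus}: no family assignment, counted as variable",
                stacklevel=2,
            )
            counts[gid] += 1
        elif fid not in core:
            counts[gid] += 1
    return counts


def group_summary(
    counts: Mapping[str, int], grouping: Mapping[str, str]
) -> dict[str, tuple[float, float, int]]:
    """Per-label mean, sample (n-1) standard deviation and n of the counts.

    A label with a single genome gets sd 0 (flagged by n == 1).  Genomes
    missing from ``grouping`` are ignored.
    """
    by_label: dict[str, list[int]] = {}
    for gid, count in counts.items():
        label = grouping.get(gid)
        if label is not None:
            by_label.setdefault(label, []).append(count)
    out = {}
    for label, values in sorted(by_label.items()):
        n = len(values)
        mean = sum(values) / n
        sd = (
            math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            if n > 1
            else 0.0
        )
        out[label] = (mean, sd, n)
    return out


def classify_structural_variant(
    genome: PhageGenome,
    gene_to_family: Mapping[str, str],
    family_roles: Mapping[str, str],
) -> str:
    """Assign the mtp-region structural class V1..V5 (or 'unknown').

    ``gene_to_family`` maps this genome's locus tags to family ids and
    ``family_roles`` maps family ids to one of mtp/nps/tpeX/rbp/other.
    Precedence V5 > V4 > V2/V3 > V1; a genome without an mtp-role gene is
    'unknown'.
    """
    roles = []
    for gene in genome.genes:  # genes are ordered by start coordinate
        fid = gene_to_family.get(gene.locus_tag)
        roles.append(family_roles.get(fid, "other") if fid else "other")
    try:
        mtp_at = roles.index("mtp")
    except ValueError:
        return "unknown"
    nps_upstream = "nps" in roles[:mtp_at]
    tpex_downstream = "tpeX" in roles[mtp_at + 1 :]
    adjacent_rbp = any(
        roles[i] == "rbp" and roles[i + 1] == "rbp" for i in range(len(roles) - 1)
    )
    if tpex_downstream and adjacent_rbp:
        return "V5"
    if nps_upstream and tpex_downstream:
        return "V4"
    if tpex_downstream:
        return "V2"
    if nps_upstream:
        return "V3"
    return "V1"


def assign_family_roles(
    representatives: Mapping[str, str],
    role_references: Mapping[str, Sequence[str]],
    min_identity: float = 0.30,
) -> dict[str, str]:
    """Assign mtp/nps/tpeX/rbp roles to families by homology to references.

    ``representatives`` maps family_id -> a representative protein and
    ``role_references`` maps role -> reference protein sequences.  A family
    takes the role of its best-matching reference when global identity is
    >= min_identity, otherwise 'other'.
    """
    out: dict[str, str] = {}
    for fid, protein in representatives.items():
        best_role, best_ident = "other", min_identity
        for role, refs in role_references.items():
            for ref in refs:
                ident = needleman_wunsch(protein, ref).identity
                if ident > best_ident or (
                    ident == best_ident and best_role == "other"
                ):
                    best_role, best_ident = role, ident
        out[fid] = best_role
    return out


def write_presence_tsv(profile: PangenomeProfile, path: str | Path) -> None:
    """Families as rows, genomes as columns, 0/1 entries."""
    with open(path, "w") as fh:
        fh.write("family_id\t" + "\t".join(profile.genome_ids) + "\n")
        for fid, row in zip(profile.family_ids, profile.presence):
            fh.write(fid + "\t" + "\t".join("1" if x else "0" for x in row) + "\n")
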