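"""Synthetic phage pan-genome generator with planted ground truth.

Emulates the structure of a dairy-phage collection: every genome carries
one member of each core protein family, plus a cluster-structured subset of
accessory families (an accessory family is common in the genomes of its
home cluster and rare elsewhere).  Family members are independently
substituted copies of a random ancestor protein, back-translated with
uniform synonymous codons and concatenated into a genome with 20-nt
spacers and exact CDS annotations.  Optionally one genome receives an
mtp-like gene ending in the CCC-TAG shifty stop, immediately followed by a
+1-frame open reading, so the frameshift scanner has a planted positive.

Everything is a deterministic function of the seed, and the full truth
(gene -> family, family -> core flag, genome -> cluster, planted
junctions) is returned alongside the genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_io import (
    GeneRecord,
    PhageGenome,
    back_translation_table,
)

__all__ = [
    "SyntheticConfig",
    "TruthTable",
    "generate_pangenome",
    "mutate_protein",
    "plant_frameshift",
    "write_truth",
    "read_truth",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SPACER_LEN = 20
NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the generated collection.

    Defaults mirror the observed pan-genome structure of a ~90-genome 936
    collection scaled to a 20-genome desk run: 29 core + 89 accessory
    families, 4 genome clusters, accessory presence 0.8 in the home
    cluster / 0.1 elsewhere, 10% per-residue divergence within a family.
    """

    n_genomes: int = 20
    n_clusters: int = 4
    n_core: int = 29
    n_accessory: int = 89
    p_within: float = 0.8
    p_between: float = 0.1
    divergence: float = 0.1
    protein_len: tuple[int, int] = (80, 600)
    paralog_rate: float = 0.02
    plant_frameshift: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        for p in (self.p_within, self.p_between, self.paralog_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.divergence < 0.5:
            raise ValueError("divergence must lie in [0, 0.5)")
        if self.n_core < 0 or self.n_accessory < 0:
            raise ValueError("family counts must be non-negative")
        if self.n_genomes < 1 or self.n_clusters < 1:
            raise ValueError("need >= 1 genome and >= 1 cluster")
        if self.protein_len[0] < 10 or self.protein_len[0] > self.protein_len[1]:
            raise ValueError("invalid protein length range")


@dataclass
class TruthTable:
    """Planted ground truth for every emitted gene, family and genome."""

    gene_families: dict[tuple[str, str], str] = field(default_factory=dict)
    core_families: set[str] = field(default_factory=set)
    clusters: dict[str, int] = field(default_factory=dict)
    # (genome_id, locus_tag, junction_pos 1-based, fused_length_aa)
    frameshifts: list[tuple[str, str, int, int]] = field(default_factory=list)

    def family_partition(self) -> dict[tuple[str, str], str]:
        return dict(self.gene_families)


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independently substitute each residue with probability ``rate``.

    Substitutions are uniform over the 19 other residues; length is
    preserved (no indels, so within-family identity decays predictably).
    """
    if not 0 <= rate < 0.5:
        raise ValueError("rate must lie in [0, 0.5)")
    if rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        current = arr[i].decode()
        choices = [a for a in AMINO_ACIDS if a != current]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def _random_protein(length: int, rng: np.random.Generator) -> str:
    body = rng.choice(list(AMINO_ACIDS), size=length - 1)
    return "M" + "".join(body)


def _back_translate(
    protein: str, codons: dict[str, list[str]], rng: np.random.Generator
) -> str:
    return "".join(
        codons[aa][rng.integers(len(codons[aa]))] for aa in protein
    )


def _random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def generate_pangenome(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[list[PhageGenome], TruthTable]:
    """Generate the collection and its truth table.

    Genomes are assigned to clusters round-robin; accessory family f's home
    cluster is f mod n_clusters.  A present family contributes one gene, or
    two (a paralog pair) with probability paralog_rate.  When
    ``plant_frameshift`` is set the first genome additionally receives the
    mtp-like shifty-stop construct.
    """
    rng = np.random.default_rng(config.seed)
    codons = back_translation_table()
    lo, hi = config.protein_len

    n_fam = config.n_core + config.n_accessory
    family_ids = [f"fam{i:04d}" for i in range(n_fam)]
    ancestors = {
        fid: _random_protein(int(rng.integers(lo, hi + 1)), rng)
        for fid in family_ids
    }
    core_ids = set(family_ids[: config.n_core])

    truth = TruthTable(core_families=set(core_ids))
    genomes: list[PhageGenome] = []
    for g in range(config.n_genomes):
        gid = f"G{g:03d}"
        cluster = g % config.n_clusters
        truth.clusters[gid] = cluster
        parts: list[str] = []
        genes: list[GeneRecord] = []
        cursor = 0
        gene_n = 0
        for fi, fid in enumerate(family_ids):
            if fid in core_ids:
                present = True
            else:
                home = (fi - config.n_core) % config.n_clusters
                p = config.p_within if cluster == home else config.p_between
                present = rng.random() < p
            if not present:
                continue
            copies = 2 if rng.random() < config.paralog_rate else 1
            for _ in range(copies):
                protein = mutate_protein(ancestors[fid], config.divergence, rng)
                nt = _back_translate(protein, codons, rng) + "TAA"
                spacer = _random_nt(SPACER_LEN, rng)
                parts.append(spacer + nt)
                start = cursor + SPACER_LEN + 1
                end = cursor + SPACER_LEN + len(nt)
                cursor = end
                gene_n += 1
                locus = f"{gid}_{gene_n:03d}"
                genes.append(
                    GeneRecord(
                        locus_tag=locus, start=start, end=end, strand="+",
                        product="hypothetical protein", protein=protein,
                    )
                )
                truth.gene_families[(gid, locus)] = fid
        parts.append(_random_nt(SPACER_LEN, rng))
        genome = PhageGenome(
            genome_id=gid,
            description=f"synthetic phage genome {gid}",
            sequence="".join(parts),
            genes=genes,
            metadata={"cluster": str(cluster), "factory": f"F{cluster + 1}"},
        )
        if config.plant_frameshift and g == 0:
            genome = plant_frameshift(genome, rng, truth=truth)
        genomes.append(genome)
    return genomes, truth


def plant_frameshift(
    genome: PhageGenome,
    rng: np.random.Generator,
    truth: TruthTable | None = None,
) -> PhageGenome:
    """Append an mtp-like CDS ending CCC-TAG with a +1-frame open reading.

    The appended gene's protein ends in proline (the CCC slippery codon);
    the +1 frame resumed one base into the TAG reads 150-250 codons before
    its own stop.  The planted junction is recorded in the truth table when
    one is supplied.
    """
    if not genome.genes:
        raise ValueError("genome has no genes")
    codons = back_translation_table()
    mtp_len = int(rng.integers(250, 351))
    mtp_prot = _random_protein(mtp_len, rng)[:-1] + "P"
    nt = _back_translate(mtp_prot[:-1], codons, rng) + "CCC" + "TAG"

    ext_len = int(rng.integers(150, 251))
    b0 = NUCLEOTIDES[rng.integers(4)]
    first_aa = {"A": "R", "G": "R", "C": "S", "T": "S"}[b0]
    ext_rest = "".join(rng.choice(list(AMINO_ACIDS), size=ext_len - 1))
    ext_nt = b0 + _back_translate(ext_rest, codons, rng) + "TAA"

    spacer = _random_nt(SPACER_LEN, rng)
    start = len(genome.sequence) + SPACER_LEN + 1
    end = start + len(nt) - 1
    locus = f"{genome.genome_id}_mtp"
    gene = GeneRecord(
        locus_tag=locus, start=start, end=end, strand="+",
        product="major tail protein (mtp-like, shifty-stop)", protein=mtp_prot,
    )
    new_genome = PhageGenome(
        genome_id=genome.genome_id,
        description=genome.description,
        sequence=genome.sequence + spacer + nt + ext_nt + _random_nt(SPACER_LEN, rng),
        genes=genome.genes + [gene],
        metadata={**genome.metadata, "planted_frameshift": "1"},
    )
    if truth is not None:
        junction = end - 5  # first base of the CCC codon
        fused_len = len(mtp_prot) + 1 + len(ext_rest)
        truth.frameshifts.append((genome.genome_id, locus, junction, fused_len))
        truth.gene_families[(genome.genome_id, locus)] = "fam_mtp_planted"
    return new_genome


def write_truth(truth: TruthTable, directory: str | Path) -> None:
    """Dump the truth table as four stable-column TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "truth_gene_families.tsv", "w") as fh:
        fh.write("genome_id\tlocus_tag\tfamily_id\n")
        for (gid, locus), fid in sorted(truth.gene_families.items()):
            fh.write(f"{gid}\t{locus}\t{fid}\n")
    with open(directory / "truth_families.tsv", "w") as fh:
        fh.write("family_id\tcore\n")
        families = sorted({*truth.gene_families.values(), *truth.core_families})
        for fid in families:
            fh.write(f"{fid}\t{int(fid in truth.core_families)}\n")
    with open(directory / "truth_clusters.tsv", "w") as fh:
        fh.write("genome_id\tcluster\n")
        for gid, cl in sorted(truth.clusters.items()):
            fh.write(f"{gid}\t{cl}\n")
    with open(directory / "truth_frameshifts.tsv", "w") as fh:
        fh.write("genome_id\tlocus_tag\tjunction_pos\tfused_length_aa\n")
        for gid, locus, pos, flen in sorted(truth.frameshifts):
            fh.write(f"{gid}\t{locus}\t{pos}\t{flen}\n")


def read_truth(directory: str | Path) -> TruthTable:
    directory = Path(directory)
    truth = TruthTable()
    with open(directory / "truth_gene_families.tsv") as fh:
        fh.readline()
        for line in fh:
            gid, locus, fid = line.rstrip("\n").split("\t")
            truth.gene_families[(gid, locus)] = fid
    with open(directory / "truth_families.tsv") as fh:
        fh.readline()
        for line in fh:
            fid, core = line.rstrip("\n").split("\t")
            if core == "1":
                truth.core_families.add(fid)
    with open(directory / "truth_clusters.tsv") as fh:
        fh.readline()
        for line in fh:
            gid, cl = line.rstrip("\n").split("\t")
            truth.clusters[gid] = int(cl)
    with open(directory / "truth_frameshifts.tsv") as fh:
        fh.readline()
        for line in fh:
            gid, locus, pos, flen = line.rstrip("\n").split("\t")
            truth.frameshifts.append((gid, locus, int(pos), int(flen)))
    return truth


def write_config_echo(config: SyntheticConfig, path: str | Path) -> None:
    """Exact key=value dump of the generator configuration, for provenance."""
    with open(path, "w") as fh:
        for key, value in asdict(config).items():
            fh.write(f"{key}={value}\n")
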