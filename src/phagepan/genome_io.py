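"""Reading, writing and basic interpretation of phage genome records.

Genomes arrive either as GenBank flat files with annotated CDS features
(the normal case for deposited phage genomes) or as bare nucleotide FASTA,
in which case a naive six-frame ORF finder with a Shine-Dalgarno score can
stand in for a proper gene caller.  All coordinates follow the GenBank
convention: 1-based, inclusive, on the forward strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

DEFAULT_TABLE = 11
START_CODONS = ("ATG", "GTG", "TTG")
SD_MOTIF = "AGGAGG"

__all__ = [
    "GeneRecord",
    "PhageGenome",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "translate_cds",
    "find_orfs",
    "extract_proteome",
    "write_proteome_tsv",
    "read_proteome_tsv",
]


@dataclass
class GeneRecord:
    """A single CDS: 1-based inclusive coordinates plus its protein product."""

    locus_tag: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein: str = ""
    sd_score: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.locus_tag}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    def cds_sequence(self, genome_sequence: str) -> str:
        """Extract the oriented CDS nucleotides from the genome sequence."""
        seg = genome_sequence[self.start - 1 : self.end]
        return reverse_complement(seg) if self.strand == "-" else seg


@dataclass
class PhageGenome:
    """A phage genome: sequence, ordered CDS annotations and free metadata."""

    genome_id: str
    description: str = ""
    sequence: str = ""
    genes: list[GeneRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        self.sequence = self.sequence.upper()
        self.genes.sort(key=lambda g: (g.start, g.end, g.locus_tag))

    def __len__(self) -> int:
        return len(self.sequence)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(
    cds: str,
    table: int = DEFAULT_TABLE,
    initiator: bool = False,
    allow_internal_stop: bool = False,
) -> str:
    """Translate a CDS with the bacterial/plastid code, trailing stop removed.

    With ``initiator`` set, a leading ATG/GTG/TTG renders methionine as a
    ribosome would read it.  Internal stop codons raise unless explicitly
    suppressed (then rendered '*').
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if not cds:
        return ""
    prot = str(Seq(cds).translate(table=table))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot and not allow_internal_stop:
        raise ValueError(f"internal stop codon at codon {prot.index('*') + 1}")
    if initiator and cds[:3] in START_CODONS and prot:
        prot = "M" + prot[1:]
    return prot


def read_genbank(path: str | Path) -> PhageGenome:
    """Parse a GenBank flat file into a :class:`PhageGenome`.

    One GeneRecord is produced per CDS feature.  The deposited /translation
    qualifier is trusted when present; if re-translation of the CDS
    disagrees, a warning is emitted and the deposited protein is kept
    (family counts in the source collections derive from deposited
    annotations).
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc

    sequence = str(record.seq).upper()
    metadata = _parse_metadata_comment(record.annotations.get("comment", ""))
    genes: list[GeneRecord] = []
    for i, feat in enumerate(record.features):
        if feat.type != "CDS":
            continue
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        locus = feat.qualifiers.get("locus_tag", [f"{record.id}_cds{i}"])[0]
        product = feat.qualifiers.get("product", [""])[0]
        cds_nt = sequence[start - 1 : end]
        if strand == "-":
            cds_nt = reverse_complement(cds_nt)
        deposited = feat.qualifiers.get("translation", [None])[0]
        try:
            derived = translate_cds(cds_nt, initiator=True, allow_internal_stop=True)
        except ValueError:
            derived = None
        if deposited is not None:
            if derived is not None and deposited != derived:
                warnings.warn(
                    f"{locus}: deposited /translation differs from re-translation; "
                    "keeping the deposited protein",
                    stacklevel=2,
                )
            protein = deposited
        else:
            if derived is None:
                warnings.warn(f"{locus}: untranslatable CDS skipped", stacklevel=2)
                continue
            protein = derived
        genes.append(
            GeneRecord(
                locus_tag=locus, start=start, end=end, strand=strand,
                product=product, protein=protein,
            )
        )
    return PhageGenome(
        genome_id=record.id if record.id != "<unknown id>" else record.name,
        description=record.description,
        sequence=sequence,
        genes=genes,
        metadata=metadata,
    )


def write_genbank(genome: PhageGenome, path: str | Path) -> None:
    """Serialize a genome (sequence + CDS features) as a GenBank flat file."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.genome_id,
        name=genome.genome_id[:16],
        description=genome.description,
        annotations={
            "molecule_type": "DNA",
            "comment": _format_metadata_comment(genome.metadata),
        },
    )
    for gene in genome.genes:
        feat = SeqFeature(
            FeatureLocation(gene.start - 1, gene.end, strand=-1 if gene.strand == "-" else 1),
            type="CDS",
            qualifiers={
                "locus_tag": [gene.locus_tag],
                "product": [gene.product],
                "transl_table": [str(DEFAULT_TABLE)],
                "translation": [gene.protein],
            },
        )
        record.features.append(feat)
    SeqIO.write([record], str(path), "genbank")


def _format_metadata_comment(metadata: dict[str, str]) -> str:
    return "; ".join(f"{k}={v}" for k, v in sorted(metadata.items()))


def _parse_metadata_comment(comment: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for part in comment.replace("\n", " ").split(";"):
        if "=" in part:
            k, _, v = part.partition("=")
            meta[k.strip()] = v.strip()
    return meta


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs; ids are the first header token.

    Sequences are upper-cased.  Duplicate ids are an error; an empty file
    yields an empty list.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks).upper()))
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise ValueError(f"{path}: empty FASTA header")
                if name in seen:
                    raise ValueError(f"{path}: duplicate FASTA id {name!r}")
                seen.add(name)
                chunks = []
            elif line.strip():
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    if name is not None:
        records.append((name, "".join(chunks).upper()))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, line_width: int = 70
) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def _sd_score(working: str, start0: int) -> int:
    """Best AGGAGG match (>=5/6 bases) ending 5-15 nt upstream of a start."""
    best = 0
    for gap in range(5, 16):
        lo = start0 - gap - len(SD_MOTIF)
        if lo < 0:
            continue
        window = working[lo : lo + len(SD_MOTIF)]
        matches = sum(a == b for a, b in zip(window, SD_MOTIF))
        best = max(best, matches)
    return best if best >= len(SD_MOTIF) - 1 else 0


def find_orfs(
    sequence: str,
    min_aa: int = 40,
    starts: Sequence[str] = START_CODONS,
) -> list[GeneRecord]:
    """Naive six-frame ORF finder.

    Reports every maximal ORF (first start codon after the previous in-frame
    stop, through the next stop codon, inclusive) of at least ``min_aa``
    residues on both strands, annotated with a Shine-Dalgarno score: the best
    match to AGGAGG (one mismatch allowed) whose 3' end lies 5-15 nt upstream
    of the start codon.  This is a deliberately simple stand-in for a
    statistical gene caller and is only used for un-annotated input.
    """
    sequence = sequence.upper()
    starts = tuple(s.upper() for s in starts)
    length = len(sequence)
    stop_codons = {"TAA", "TAG", "TGA"}
    orfs: list[GeneRecord] = []
    n = 0
    for strand, working in (("+", sequence), ("-", reverse_complement(sequence))):
        for frame in range(3):
            start_at: int | None = None
            for pos in range(frame, length - 2, 3):
                codon = working[pos : pos + 3]
                if start_at is None and codon in starts:
                    start_at = pos
                if codon in stop_codons:
                    if start_at is not None:
                        s0, e0 = start_at, pos + 2
                        aa_len = (e0 - s0 + 1) // 3 - 1
                        if aa_len >= min_aa:
                            protein = translate_cds(
                                working[s0 : e0 + 1], initiator=True
                            )
                            if strand == "+":
                                g_start, g_end = s0 + 1, e0 + 1
                            else:
                                g_start, g_end = length - e0, length - s0
                            n += 1
                            orfs.append(
                                GeneRecord(
                                    locus_tag=f"orf{n:04d}",
                                    start=g_start,
                                    end=g_end,
                                    strand=strand,
                                    product="predicted ORF",
                                    protein=protein,
                                    sd_score=_sd_score(working, s0),
                                )
                            )
                    start_at = None
    orfs.sort(key=lambda g: (g.start, g.end, g.strand))
    return orfs


def extract_proteome(
    genomes: Sequence[PhageGenome],
) -> list[tuple[str, str, str]]:
    """Flatten genomes into (genome_id, locus_tag, protein) entries.

    Ordering is stable (genome order, then gene order).  Genes with an empty
    protein are skipped with a warning.
    """
    entries: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    for genome in genomes:
        for gene in genome.genes:
            key = (genome.genome_id, gene.locus_tag)
            if key in seen:
                raise ValueError(f"duplicate proteome key {key}")
            seen.add(key)
            if not gene.protein:
                warnings.warn(
                    f"{genome.genome_id}/{gene.locus_tag}: empty protein skipped",
                    stacklevel=2,
                )
                continue
            entries.append((genome.genome_id, gene.locus_tag, gene.protein))
    return entries


def write_proteome_tsv(
    entries: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tlocus_tag\tlength\tprotein\n")
        for gid, locus, protein in entries:
            fh.write(f"{gid}\t{locus}\t{len(protein)}\t{protein}\n")


def read_proteome_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["genome_id", "locus_tag"]:
            raise ValueError(f"{path}: not a proteome TSV")
        for line in fh:
            gid, locus, _, protein = line.rstrip("\n").split("\t")
            entries.append((gid, locus, protein))
    return entries


def back_translation_table(table: int = DEFAULT_TABLE) -> dict[str, list[str]]:
    """Amino acid -> list of synonymous codons for the given genetic code."""
    fwd = CodonTable.unambiguous_dna_by_id[table].forward_table
    mapping: dict[str, list[str]] = {}
    for codon, aa in sorted(fwd.items()):
        mapping.setdefault(aa, []).append(codon)
    return mapping
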