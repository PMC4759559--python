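"""Programmed +1 frameshift detection, protein masses and exact-word dotplots.

A 'shifty stop' is a slippery proline codon (CCC) immediately 5' of the
annotated stop (UAG): the ribosome, stalled with the stop in its A-site,
slips forward one base and continues in the +1 frame, fusing the upstream
product (a major tail protein) to a downstream extension (TpeX).  The
scanner verifies the CCC-TAG junction, builds the fused protein by reading
the +1 frame from one base into the stop to the next in-frame stop, and
reports its average molecular mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.SeqUtils import molecular_weight

from .genome_io import GeneRecord, PhageGenome, reverse_complement, translate_cds

__all__ = ["FrameshiftSite", "scan_shifty_stop", "scan_genome",
           "protein_mw", "dotplot_words", "write_frameshift_tsv"]

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class FrameshiftSite:
    """A detected shifty-stop junction and its predicted fusion product."""

    genome_id: str
    upstream_gene: str
    junction_pos: int  # 1-based genome coordinate of the CCC's first base
    motif: str         # the 6-mer CCC+stop at the junction, CDS orientation
    fused_protein: str
    fused_mw_kda: float
    extension_aa: int


def scan_shifty_stop(
    genome: PhageGenome,
    gene: GeneRecord,
    window: int = 1,
    require_tag: bool = True,
    min_extension_aa: int = 30,
) -> FrameshiftSite | None:
    """Test one annotated CDS for a +1 shifty-stop junction.

    A site is reported iff a CCC codon sits within ``window`` codons
    immediately 5' of the annotated stop (default: only the adjacent codon)
    and the stop is TAG (set ``require_tag=False`` to accept any stop), and
    the +1-frame reading resumed one base into the stop runs for at least
    ``min_extension_aa`` residues before its own stop.  Strand-aware: minus
    strand genes are scanned in their reading orientation and the junction
    reported as the genome coordinate of the slippery codon's first base.
    """
    oriented = (
        genome.sequence if gene.strand == "+" else reverse_complement(genome.sequence)
    )
    length = len(oriented)
    # 0-based start of the CDS within the oriented sequence
    if gene.strand == "+":
        cds_start0 = gene.start - 1
    else:
        cds_start0 = length - gene.end
    cds_len = gene.length_nt
    if cds_len % 3 != 0:
        raise ValueError(f"{gene.locus_tag}: CDS length not a multiple of 3")
    stop0 = cds_start0 + cds_len - 3
    stop_codon = oriented[stop0 : stop0 + 3]
    if stop_codon not in STOP_CODONS:
        raise ValueError(
            f"{gene.locus_tag}: CDS does not end in a stop codon ({stop_codon})"
        )
    if require_tag and stop_codon != "TAG":
        return None
    for w in range(1, window + 1):
        ccc0 = stop0 - 3 * w
        if ccc0 < cds_start0 or oriented[ccc0 : ccc0 + 3] != "CCC":
            continue
        resume0 = ccc0 + 4  # net +1 shift: next codon starts one base into the stop
        extension = _translate_until_stop(oriented, resume0)
        if len(extension) < min_extension_aa:
            continue
        fused = gene.protein + extension
        if gene.strand == "+":
            junction = ccc0 + 1
        else:
            junction = length - ccc0
        return FrameshiftSite(
            genome_id=genome.genome_id,
            upstream_gene=gene.locus_tag,
            junction_pos=junction,
            motif=oriented[ccc0 : ccc0 + 6],
            fused_protein=fused,
            fused_mw_kda=protein_mw(fused),
            extension_aa=len(extension),
        )
    return None


def _translate_until_stop(seq: str, start0: int) -> str:
    out = []
    for pos in range(start0, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            break
        if "N" in codon:
            break
        out.append(translate_cds(codon, allow_internal_stop=True))
    return "".join(out)


def scan_genome(
    genome: PhageGenome, window: int = 1, require_tag: bool = True,
    min_extension_aa: int = 30,
) -> list[FrameshiftSite]:
    """Run the shifty-stop scanner over every annotated CDS of a genome."""
    sites = []
    for gene in genome.genes:
        try:
            site = scan_shifty_stop(
                genome, gene, window=window, require_tag=require_tag,
                min_extension_aa=min_extension_aa,
            )
        except ValueError:
            continue  # unannotatable CDS (no stop / bad length): not scannable
        if site is not None:
            sites.append(site)
    return sites


def protein_mw(protein: str) -> float:
    """Average molecular mass of a protein in kDa (residue masses + one water)."""
    if not protein:
        raise ValueError("empty protein")
    try:
        daltons = molecular_weight(protein, seq_type="protein")
    except (ValueError, KeyError) as exc:
        raise ValueError(f"non-standard residue in protein: {exc}") from exc
    return daltons / 1000.0


def dotplot_words(
    seq_a: str, seq_b: str, word: int = 10
) -> list[tuple[int, int]]:
    """Exact shared-word coordinates (1-based), forward strand only.

    Every (i, j) with seq_a[i..i+word) == seq_b[j..j+word) is reported; a
    diagonal run of hits marks conserved synteny, a break marks divergence
    or rearrangement.
    """
    if word < 1:
        raise ValueError("word length must be >= 1")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    index: dict[str, list[int]] = {}
    for j in range(len(seq_b) - word + 1):
        index.setdefault(seq_b[j : j + word], []).append(j)
    hits = []
    for i in range(len(seq_a) - word + 1):
        for j in index.get(seq_a[i : i + word], ()):
            hits.append((i + 1, j + 1))
    return hits


def write_frameshift_tsv(sites: Iterable[FrameshiftSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "genome_id\tupstream_gene\tjunction_pos\tmotif\t"
            "fused_length_aa\tfused_mw_kda\n"
        )
        for s in sites:
            fh.write(
                f"{s.genome_id}\t{s.upstream_gene}\t{s.junction_pos}\t{s.motif}\t"
                f"{len(s.fused_protein)}\t{s.fused_mw_kda:.3f}\n"
            )
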