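"""Pairwise protein alignment and the reciprocal-hit similarity graph.

The original analyses ran BLASTP all-against-all; here the same role is
filled by exact local (Smith-Waterman) and global (Needleman-Wunsch)
alignment under BLOSUM62 with affine gaps, with Karlin-Altschul statistics
E = K * m * n * exp(-lambda * S) supplying the E-value.  A pair of proteins
becomes an undirected edge of the hit graph only if the alignment passes the
thresholds with each sequence as query (a reciprocal hit):
E-value <= 1e-4, identity >= 50%, and >= 50% coverage of either sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "Alignment",
    "HomologyThresholds",
    "smith_waterman",
    "needleman_wunsch",
    "compute_evalue",
    "passes_thresholds",
    "all_vs_all_graph",
    "write_hit_table",
    "write_abc",
    "read_abc",
]

EVALUE_FLOOR = 1e-200
WEIGHT_CAP = 200.0


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul constants.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  The matrix
    is patched so that X (unknown residue) scores 0 against everything.
    lambda/K default to the customary gapped BLOSUM62-11-1 constants.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")

    def substitution_matrix(self):
        mat = substitution_matrices.load(self.matrix).copy()
        if "X" in mat.alphabet:
            ix = mat.alphabet.index("X")
            mat[ix, :] = 0.0
            mat[:, ix] = 0.0
        return mat

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = mode
        aligner.substitution_matrix = self.substitution_matrix()
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class Alignment:
    """A scored pairwise alignment with the quantities the cutoffs threshold."""

    query_id: str
    subject_id: str
    score: float
    identity: float
    coverage_query: float
    coverage_subject: float
    length: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    query_span: tuple[int, int] | None = None
    subject_span: tuple[int, int] | None = None
    evalue: float = math.inf

    @property
    def is_empty(self) -> bool:
        return self.query_span is None

    def swapped(self) -> "Alignment":
        """The same alignment viewed with query and subject exchanged."""
        return replace(
            self,
            query_id=self.subject_id,
            subject_id=self.query_id,
            coverage_query=self.coverage_subject,
            coverage_subject=self.coverage_query,
            query_span=self.subject_span,
            subject_span=self.query_span,
        )


@dataclass(frozen=True)
class HomologyThresholds:
    """Reciprocal-hit cutoffs; comparisons are inclusive.

    ``coverage_mode`` 'either' accepts a hit when at least one of the two
    sequences is >= min_coverage covered by the aligned span; 'both'
    requires each.
    """

    max_evalue: float = 1e-4
    min_identity: float = 0.50
    min_coverage: float = 0.50
    coverage_mode: str = "either"

    def __post_init__(self) -> None:
        if self.coverage_mode not in ("either", "both"):
            raise ValueError("coverage_mode must be 'either' or 'both'")
        if not (0 <= self.min_identity <= 1 and 0 <= self.min_coverage <= 1):
            raise ValueError("identity/coverage thresholds must lie in [0, 1]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be non-negative")


def _check_sequences(a: str, b: str) -> tuple[str, str]:
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return a.upper(), b.upper()


def _from_biopython(aln, a: str, b: str, query_id: str, subject_id: str) -> Alignment:
    counts = aln.counts()
    ncols = counts.gaps + counts.identities + counts.mismatches
    blocks_q, blocks_s = aln.aligned
    qstart, qend = int(blocks_q[0][0]) + 1, int(blocks_q[-1][1])
    sstart, send = int(blocks_s[0][0]) + 1, int(blocks_s[-1][1])
    return Alignment(
        query_id=query_id,
        subject_id=subject_id,
        score=float(aln.score),
        identity=counts.identities / ncols if ncols else 0.0,
        coverage_query=(qend - qstart + 1) / len(a),
        coverage_subject=(send - sstart + 1) / len(b),
        length=ncols,
        mismatches=counts.mismatches,
        gap_opens=len(blocks_q) - 1,
        query_span=(qstart, qend),
        subject_span=(sstart, send),
    )


def smith_waterman(
    a: str, b: str, scheme: ScoringScheme = ScoringScheme(),
    query_id: str = "query", subject_id: str = "subject",
) -> Alignment:
    """Optimal local alignment under affine gaps.

    When no residue pair scores positively the empty alignment (score 0,
    no spans) is returned, mirroring the convention that a local alignment
    may be empty.
    """
    a, b = _check_sequences(a, b)
    aligner = scheme.aligner("local")
    score = aligner.score(a, b)
    if score <= 0:
        return Alignment(query_id, subject_id, 0.0, 0.0, 0.0, 0.0)
    aln = next(iter(aligner.align(a, b)))
    return _from_biopython(aln, a, b, query_id, subject_id)


def needleman_wunsch(
    a: str, b: str, scheme: ScoringScheme = ScoringScheme(),
    query_id: str = "query", subject_id: str = "subject",
) -> Alignment:
    """Optimal global alignment; identity counts gap columns in the denominator."""
    a, b = _check_sequences(a, b)
    aligner = scheme.aligner("global")
    aln = next(iter(aligner.align(a, b)))
    return _from_biopython(aln, a, b, query_id, subject_id)


def compute_evalue(
    score: float, query_len: int, db_residues: int,
    scheme: ScoringScheme = ScoringScheme(),
) -> float:
    """Karlin-Altschul expected chance hits: E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("query_len and db_residues must be positive")
    return scheme.k * query_len * db_residues * math.exp(-scheme.lam * score)


def passes_thresholds(
    alignment: Alignment, thresholds: HomologyThresholds = HomologyThresholds()
) -> bool:
    covs = (alignment.coverage_query, alignment.coverage_subject)
    cov_ok = (
        max(covs) >= thresholds.min_coverage
        if thresholds.coverage_mode == "either"
        else min(covs) >= thresholds.min_coverage
    )
    return (
        alignment.evalue <= thresholds.max_evalue
        and alignment.identity >= thresholds.min_identity
        and cov_ok
    )


def _kmer_candidates(
    seqs: list[str], k: int, min_shared: int
) -> set[tuple[int, int]]:
    """Unordered index pairs sharing >= min_shared distinct k-mers."""
    index: dict[str, list[int]] = {}
    for i, seq in enumerate(seqs):
        for kmer in {seq[j : j + k] for j in range(len(seq) - k + 1)}:
            index.setdefault(kmer, []).append(i)
    shared: dict[tuple[int, int], int] = {}
    for members in index.values():
        if len(members) < 2:
            continue
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                pair = (members[x], members[y])
                shared[pair] = shared.get(pair, 0) + 1
    return {pair for pair, count in shared.items() if count >= min_shared}


def all_vs_all_graph(
    proteome: Sequence[tuple[str, str, str]],
    scheme: ScoringScheme = ScoringScheme(),
    thresholds: HomologyThresholds = HomologyThresholds(),
    prefilter: bool = True,
    prefilter_k: int = 5,
    prefilter_min_shared: int = 2,
) -> nx.Graph:
    """Reciprocal-hit graph over a multi-genome proteome.

    Every unordered protein pair is evaluated in both directions (the local
    alignment is symmetric; the E-value differs through the query length,
    each direction searching the same pooled database of all residues).  An
    undirected edge is kept iff both directions pass the thresholds; its
    weight is -log10 of the worse of the two E-values (E floored at 1e-200,
    weight capped at 200), the customary transform fed to MCL.

    A shared-k-mer prescreen (on by default) skips pairs that share fewer
    than ``prefilter_min_shared`` distinct 5-mers; pairs capable of meeting
    the 50%-identity/50%-coverage cutoffs share many.  Pass
    ``prefilter=False`` for the exhaustive quadratic scan.
    """
    if len(proteome) < 2:
        raise ValueError("need at least 2 proteins")
    ids = [f"{gid}|{locus}" for gid, locus, _ in proteome]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in proteome")
    seqs = [prot.upper() for _, _, prot in proteome]
    db_residues = sum(len(s) for s in seqs)

    graph = nx.Graph()
    for (gid, locus, _), node, seq in zip(proteome, ids, seqs):
        graph.add_node(node, genome_id=gid, locus_tag=locus, length=len(seq))

    if prefilter:
        pairs: Iterable[tuple[int, int]] = sorted(
            _kmer_candidates(seqs, prefilter_k, prefilter_min_shared)
        )
    else:
        n = len(seqs)
        pairs = ((i, j) for i in range(n) for j in range(i + 1, n))

    for i, j in pairs:
        aln = smith_waterman(seqs[i], seqs[j], scheme, ids[i], ids[j])
        if aln.is_empty:
            continue
        fwd = replace(
            aln, evalue=compute_evalue(aln.score, len(seqs[i]), db_residues, scheme)
        )
        rev = replace(
            aln.swapped(),
            evalue=compute_evalue(aln.score, len(seqs[j]), db_residues, scheme),
        )
        if passes_thresholds(fwd, thresholds) and passes_thresholds(rev, thresholds):
            worse = max(max(fwd.evalue, rev.evalue), EVALUE_FLOOR)
            weight = min(-math.log10(worse), WEIGHT_CAP)
            graph.add_edge(
                ids[i], ids[j], weight=weight,
                evalue=worse, identity=aln.identity, score=aln.score,
            )
    return graph


def write_hit_table(alignments: Iterable[Alignment], path: str | Path) -> None:
    """Tab-separated 12-column hit table in the familiar outfmt-6 layout."""
    with open(path, "w") as fh:
        for a in alignments:
            qs, qe = a.query_span or (0, 0)
            ss, se = a.subject_span or (0, 0)
            fh.write(
                f"{a.query_id}\t{a.subject_id}\t{a.identity * 100:.2f}\t"
                f"{a.length}\t{a.mismatches}\t{a.gap_opens}\t"
                f"{qs}\t{qe}\t{ss}\t{se}\t{a.evalue:.3g}\t{a.score:.1f}\n"
            )


def write_abc(graph: nx.Graph, path: str | Path) -> None:
    """Three-column node/node/weight text, interoperable with MCL tooling."""
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.6g}\n")
        for node in sorted(graph.nodes):
            if graph.degree(node) == 0:
                fh.write(f"{node}\t{node}\t0\n")


def read_abc(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed ABC line {line!r}")
            u, v = parts[0], parts[1]
            w = float(parts[2]) if len(parts) > 2 else 1.0
            if u == v:
                graph.add_node(u)
            else:
                graph.add_edge(u, v, weight=w)
    return graph
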