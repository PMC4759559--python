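"""End-to-end orchestration of the pan-genome pipeline.

Stages: proteome extraction -> reciprocal-hit graph -> MCL families ->
presence/absence profile with core/variable partition -> two-way
hierarchical clustering -> RBP typing -> structural classes -> frameshift
scan.  Every stage writes its artefact into the output directory and the
run ends with a machine-readable summary, a config echo and a manifest of
input content hashes, so a rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import genome_io, homology, mcl, pangenome, rbp, seq_features, trees
from .genome_io import PhageGenome
from .homology import HomologyThresholds, ScoringScheme
from .mcl import MCLParams
from .synthetic import SyntheticConfig, generate_pangenome, write_truth, write_config_echo

logger = logging.getLogger("phagepan")

ROLE_PATTERNS = {
    "mtp": re.compile(r"major tail protein|\bmtp\b", re.I),
    "nps": re.compile(r"neck passage", re.I),
    "tpeX": re.compile(r"tail (protein )?extension|\btpex\b", re.I),
    "rbp": re.compile(r"receptor.binding|\brbp\b", re.I),
}


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    input_paths: list[str] = field(default_factory=list)
    synthetic: SyntheticConfig | None = None
    output_dir: str = "phagepan_out"
    thresholds: HomologyThresholds = field(default_factory=HomologyThresholds)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    mcl_params: MCLParams = field(default_factory=MCLParams)
    distance: str = "jaccard"
    linkage: str = "average"
    cut_k: int | None = None
    cterm_len: int = 130
    rbp_min_identity: float = 0.50
    frameshift_require_tag: bool = True
    grouping_key: str = "factory"
    prefilter: bool = True

    def __post_init__(self) -> None:
        if not self.input_paths and self.synthetic is None:
            raise ValueError("provide input genomes or a synthetic config")
        if self.distance != "jaccard":
            raise ValueError("only the jaccard profile distance is implemented")
        if self.linkage != "average":
            raise ValueError("only average linkage is implemented")


def load_genomes(paths: Sequence[str]) -> list[PhageGenome]:
    genomes = []
    for path in paths:
        genomes.append(genome_io.read_genbank(path))
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids among inputs")
    return genomes


def infer_roles_from_products(genomes: Sequence[PhageGenome],
                              gene_to_family: dict[tuple[str, str], str]) -> dict[str, str]:
    """Map family -> structural role using CDS /product annotations."""
    roles: dict[str, str] = {}
    for genome in genomes:
        for gene in genome.genes:
            fid = gene_to_family.get((genome.genome_id, gene.locus_tag))
            if fid is None:
                continue
            for role, pattern in ROLE_PATTERNS.items():
                if pattern.search(gene.product or ""):
                    roles[fid] = role
                    break
    return roles


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write artefacts under ``config.output_dir``.

    Returns the summary dictionary (counts of genomes, genes, families,
    core families, clusters, frameshift sites).  Any stage failure raises;
    artefacts written so far are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _configure_logging()

    logger.info("stage: input")
    if config.synthetic is not None:
        genomes, truth = generate_pangenome(config.synthetic)
        write_truth(truth, out / "truth")
        write_config_echo(config.synthetic, out / "truth" / "config_echo.txt")
        gb_dir = out / "genomes"
        gb_dir.mkdir(exist_ok=True)
        for g in genomes:
            genome_io.write_genbank(g, gb_dir / f"{g.genome_id}.gbk")
            genome_io.write_fasta(
                [(g.genome_id, g.sequence)], gb_dir / f"{g.genome_id}.fasta"
            )
    else:
        genomes = load_genomes(config.input_paths)
    logger.info("loaded %d genomes", len(genomes))

    logger.info("stage: proteome")
    proteome = genome_io.extract_proteome(genomes)
    genome_io.write_proteome_tsv(proteome, out / "proteome.tsv")

    logger.info("stage: homology (%d proteins)", len(proteome))
    graph = homology.all_vs_all_graph(
        proteome, config.scheme, config.thresholds, prefilter=config.prefilter
    )
    homology.write_abc(graph, out / "hits.abc")

    logger.info("stage: mcl (%d edges)", graph.number_of_edges())
    partition = mcl.run_mcl(graph, config.mcl_params)
    families = mcl.extract_families(partition, proteome)
    mcl.write_families_tsv(families, out / "families.tsv")

    logger.info("stage: pangenome (%d families)", len(families))
    genome_ids = [g.genome_id for g in genomes]
    profile = pangenome.build_profile(families, genome_ids)
    pangenome.write_presence_tsv(profile, out / "presence_matrix.tsv")
    core = pangenome.core_families(profile)
    (out / "core_families.txt").write_text(
        "".join(f"{fid}\n" for fid in sorted(core))
    )
    gene_to_family: dict[tuple[str, str], str] = {}
    for fam in families:
        for member in fam.members:
            gene_to_family[member] = fam.family_id
    gene_table = [
        (gid, locus, gene_to_family.get((gid, locus)))
        for gid, locus, _ in proteome
    ]
    var_counts = pangenome.variable_counts(profile, gene_table)
    with open(out / "variable_counts.tsv", "w") as fh:
        fh.write("genome_id\tvariable_genes\n")
        for gid in genome_ids:
            fh.write(f"{gid}\t{var_counts[gid]}\n")
    grouping = {
        g.genome_id: g.metadata[config.grouping_key]
        for g in genomes
        if config.grouping_key in g.metadata
    }
    if grouping:
        summary_by_group = pangenome.group_summary(var_counts, grouping)
        with open(out / "variable_group_summary.tsv", "w") as fh:
            fh.write("group\tmean\tsd\tn\n")
            for label, (mean, sd, n) in summary_by_group.items():
                fh.write(f"{label}\t{mean:.4f}\t{sd:.4f}\t{n}\n")

    logger.info("stage: trees")
    genome_dm = trees.jaccard_distance_matrix(profile.presence.T, genome_ids)
    genome_dendro = trees.average_linkage_hcl(genome_dm)
    trees.write_merges_tsv(genome_dendro, out / "genome_merges.tsv")
    (out / "genome_dendrogram.nwk").write_text(
        trees.to_newick(trees.dendrogram_to_tree(genome_dendro)) + "\n"
    )
    family_dm = trees.jaccard_distance_matrix(profile.presence, profile.family_ids)
    family_dendro = trees.average_linkage_hcl(family_dm)
    trees.write_merges_tsv(family_dendro, out / "family_merges.tsv")
    k = config.cut_k if config.cut_k is not None else min(8, len(genome_ids))
    assignments = trees.cut_tree(genome_dendro, k)
    with open(out / "genome_clusters.tsv", "w") as fh:
        fh.write("genome_id\tcluster\n")
        for gid in genome_ids:
            fh.write(f"{gid}\t{assignments[gid]}\n")

    logger.info("stage: rbp typing")
    references = rbp.packaged_references()
    rbp_rows = []
    for genome in genomes:
        for gene in genome.genes:
            if ROLE_PATTERNS["rbp"].search(gene.product or "") and len(
                gene.protein
            ) >= rbp.MIN_RBP_LEN:
                a = rbp.assign_group(
                    gene.protein, references,
                    min_identity=config.rbp_min_identity,
                    cterm_len=config.cterm_len,
                    query_id=f"{genome.genome_id}|{gene.locus_tag}",
                )
                rbp_rows.append(a)
    with open(out / "rbp_assignments.tsv", "w") as fh:
        fh.write("query\tbest_ref\tidentity\tgroup\n")
        for a in rbp_rows:
            fh.write(f"{a.query_id}\t{a.best_ref}\t{a.identity:.4f}\t{a.group}\n")

    logger.info("stage: structural classes")
    roles = infer_roles_from_products(genomes, gene_to_family)
    with open(out / "structural_classes.tsv", "w") as fh:
        fh.write("genome_id\tstructural_class\n")
        for genome in genomes:
            local_map = {
                gene.locus_tag: gene_to_family.get((genome.genome_id, gene.locus_tag), "")
                for gene in genome.genes
            }
            label = pangenome.classify_structural_variant(genome, local_map, roles)
            fh.write(f"{genome.genome_id}\t{label}\n")

    logger.info("stage: frameshift scan")
    sites = []
    for genome in genomes:
        sites.extend(
            seq_features.scan_genome(
                genome, require_tag=config.frameshift_require_tag
            )
        )
    seq_features.write_frameshift_tsv(sites, out / "frameshifts.tsv")

    summary = {
        "n_genomes": len(genomes),
        "n_genes": len(proteome),
        "n_families": len(families),
        "n_core_families": len(core),
        "n_variable_families": len(families) - len(core),
        "n_clusters": k,
        "n_frameshift_sites": len(sites),
        "mean_variable_genes": (
            sum(var_counts.values()) / len(var_counts) if var_counts else 0.0
        ),
    }
    with open(out / "summary.tsv", "w") as fh:
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    _write_manifest(config, out)
    logger.info("pipeline complete: %s", summary)
    return summary


def _configure_logging() -> None:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)


def _write_manifest(config: RunConfig, out: Path) -> None:
    lines = []
    for path in config.input_paths:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        lines.append(f"{digest}  {path}")
    cfg = asdict(config)
    lines.append("config: " + json.dumps(cfg, default=str, sort_keys=True))
    (out / "manifest.txt").write_text("\n".join(lines) + "\n")
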