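"""Presence/absence profile, core/variable partition, structural classes."""

import math

import pytest

from phagepan.genome_io import GeneRecord, PhageGenome
from phagepan.mcl import ProteinFamily
from phagepan.pangenome import (
    assign_family_roles,
    build_profile,
    classify_structural_variant,
    core_families,
    group_summary,
    variable_counts,
)


def fam(fid, *members):
    return ProteinFamily(family_id=fid, members=frozenset(members))


class TestBuildProfile:
    def test_two_genome_example(self):
        families = [
            fam("A", ("g1", "x1"), ("g2", "y1")),
            fam("B", ("g1", "x2")),
        ]
        profile = build_profile(families, ["g1", "g2"])
        assert profile.presence.tolist() == [[True, True], [True, False]]

    def test_column_sums_are_distinct_family_counts(self, small_families, small_collection):
        families, proteome = small_families
        genomes, _ = small_collection
        profile = build_profile(families, [g.genome_id for g in genomes])
        g2f = {m: f.family_id for f in families for m in f.members}
        for j, gid in enumerate(profile.genome_ids):
            distinct = {g2f[(g, l)] for g, l, _ in proteome if g == gid}
            assert profile.presence[:, j].sum() == len(distinct)

    def test_paralogs_collapse_to_single_presence(self):
        families = [fam("A", ("g1", "x1"), ("g1", "x2"), ("g2", "y1"))]
        profile = build_profile(families, ["g1", "g2"])
        assert profile.presence.sum() == 2

    def test_matches_planted_truth_matrix(self, small_families, small_collection):
        families, _ = small_families
        genomes, truth = small_collection
        gids = [g.genome_id for g in genomes]
        profile = build_profile(families, gids)
        # truth matrix on planted family labels
        truth_fams = sorted({*truth.gene_families.values()})
        truth_presence = {
            (f, g): any(
                fid == f and gid == g
                for (gid, _), fid in truth.gene_families.items()
            )
            for f in truth_fams
            for g in gids
        }
        # map recovered families to planted labels via shared members
        g2f = {m: f.family_id for f in families for m in f.members}
        rec_of_truth = {
            truth.gene_families[m]: g2f[m] for m in truth.gene_families
        }
        fidx = {f: i for i, f in enumerate(profile.family_ids)}
        gidx = {g: j for j, g in enumerate(gids)}
        for f in truth_fams:
            for g in gids:
                assert (
                    profile.presence[fidx[rec_of_truth[f]], gidx[g]]
                    == truth_presence[(f, g)]
                )


class TestCoreFamilies:
    def test_single_genome_all_core(self):
        families = [fam("A", ("g1", "x1")), fam("B", ("g1", "x2"))]
        profile = build_profile(families, ["g1"])
        assert core_families(profile) == {"A", "B"}

    def test_planted_core_recovered_exactly(self, small_families, small_collection):
        families, _ = small_families
        genomes, truth = small_collection
        profile = build_profile(families, [g.genome_id for g in genomes])
        core = core_families(profile)
        g2f = {m: f.family_id for f in families for m in f.members}
        planted_core_recovered = {
            g2f[m]
            for m, fid in truth.gene_families.items()
            if fid in truth.core_families
        }
        assert core == planted_core_recovered
        assert len(core) == len(truth.core_families)

    def test_core_partition_identity(self, small_families, small_collection):
        families, _ = small_families
        genomes, _ = small_collection
        profile = build_profile(families, [g.genome_id for g in genomes])
        core = core_families(profile)
        rows_all_true = profile.presence.all(axis=1).sum()
        assert len(core) == rows_all_true
        assert len(core) + (len(profile.family_ids) - len(core)) == len(
            profile.family_ids
        )

    def test_adding_genomes_shrinks_or_preserves_core(self, small_families, small_collection):
        families, _ = small_families
        genomes, _ = small_collection
        gids = [g.genome_id for g in genomes]
        previous = None
        for n in range(1, len(gids) + 1):
            sub = [
                ProteinFamily(
                    f.family_id,
                    frozenset(m for m in f.members if m[0] in gids[:n]),
                )
                for f in families
                if any(m[0] in gids[:n] for m in f.members)
            ]
            core = core_families(build_profile(sub, gids[:n]))
            if previous is not None:
                assert core <= previous
            previous = core


class TestVariableCounts:
    def test_all_core_means_zero(self):
        families = [
            fam("A", ("g1", "x1"), ("g2", "y1")),
            fam("B", ("g1", "x2"), ("g2", "y2")),
        ]
        profile = build_profile(families, ["g1", "g2"])
        table = [("g1", "x1", "A"), ("g1", "x2", "B"),
                 ("g2", "y1", "A"), ("g2", "y2", "B")]
        assert variable_counts(profile, table) == {"g1": 0, "g2": 0}

    def test_unassigned_gene_counts_as_variable(self):
        families = [fam("A", ("g1", "x1"), ("g2", "y1"))]
        profile = build_profile(families, ["g1", "g2"])
        with pytest.warns(UserWarning, match="no family"):
            counts = variable_counts(
                profile, [("g1", "x1", "A"), ("g1", "x9", None), ("g2", "y1", "A")]
            )
        assert counts == {"g1": 1, "g2": 0}

    def test_matches_planted_accessory_gene_counts(self, small_families, small_collection):
        families, proteome = small_families
        genomes, truth = small_collection
        profile = build_profile(families, [g.genome_id for g in genomes])
        g2f = {m: f.family_id for f in families for m in f.members}
        counts = variable_counts(
            profile, [(g, l, g2f[(g, l)]) for g, l, _ in proteome]
        )
        expected = {g.genome_id: 0 for g in genomes}
        for (gid, _), fid in truth.gene_families.items():
            if fid not in truth.core_families:
                expected[gid] += 1
        assert counts == expected

    def test_core_plus_variable_equals_total(self, small_families, small_collection):
        families, proteome = small_families
        genomes, _ = small_collection
        profile = build_profile(families, [g.genome_id for g in genomes])
        core = core_families(profile)
        g2f = {m: f.family_id for f in families for m in f.members}
        counts = variable_counts(
            profile, [(g, l, g2f[(g, l)]) for g, l, _ in proteome]
        )
        for gid in profile.genome_ids:
            total = sum(1 for g, _, _ in proteome if g == gid)
            n_core_genes = sum(
                1 for g, l, _ in proteome if g == gid and g2f[(g, l)] in core
            )
            assert n_core_genes + counts[gid] == total


class TestGroupSummary:
    def test_hand_arithmetic(self):
        out = group_summary({"a": 2, "b": 4}, {"a": "F1", "b": "F1"})
        mean, sd, n = out["F1"]
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(math.sqrt(2))
        assert n == 2

    def test_equal_counts_zero_sd(self):
        out = group_summary({"a": 5, "b": 5, "c": 5}, dict.fromkeys("abc", "F"))
        assert out["F"] == (5.0, 0.0, 3)

    def test_singleton_label_flagged_by_n(self):
        out = group_summary({"a": 7}, {"a": "F9"})
        assert out["F9"] == (7.0, 0.0, 1)

    def test_permutation_invariant(self):
        counts = {"a": 1, "b": 9, "c": 4, "d": 6}
        grouping = {"a": "x", "b": "x", "c": "y", "d": "y"}
        forward = group_summary(counts, grouping)
        reversed_ = group_summary(
            dict(reversed(counts.items())), grouping
        )
        assert forward == reversed_


def make_genome(roles):
    """Genome whose genes (in order) have the given structural roles."""
    genes = [
        GeneRecord(f"g_{i}", 100 * i + 1, 100 * i + 90, "+", protein="M" * 30)
        for i in range(len(roles))
    ]
    genome = PhageGenome(genome_id="test", sequence="A" * (100 * len(roles) + 100),
                         genes=genes)
    gene_to_family = {f"g_{i}": f"fam{i}" for i in range(len(roles))}
    family_roles = {f"fam{i}": role for i, role in enumerate(roles)}
    return genome, gene_to_family, family_roles


class TestStructuralClass:
    @pytest.mark.parametrize(
        "roles,expected",
        [
            (["other", "mtp", "other"], "V1"),
            (["other", "mtp", "tpeX"], "V2"),
            (["nps", "mtp", "other"], "V3"),
            (["nps", "mtp", "tpeX"], "V4"),
            (["other", "mtp", "tpeX", "rbp", "rbp"], "V5"),
            (["nps", "mtp", "tpeX", "rbp", "rbp"], "V5"),  # V5 beats V4
            (["other", "other"], "unknown"),
            (["tpeX", "mtp", "nps"], "V1"),  # wrong sides of mtp
        ],
    )
    def test_classification(self, roles, expected):
        genome, g2f, froles = make_genome(roles)
        assert classify_structural_variant(genome, g2f, froles) == expected


def test_assign_family_roles_by_homology(rng):
    from phagepan.synthetic import mutate_protein

    AA = "ACDEFGHIKLMNPQRSTVWY"
    refs = {
        role: ["".join(rng.choice(list(AA), size=120))]
        for role in ("mtp", "nps", "tpeX")
    }
    reps = {
        "famA": mutate_protein(refs["mtp"][0], 0.2, rng),
        "famB": mutate_protein(refs["tpeX"][0], 0.2, rng),
        "famC": "".join(rng.choice(list(AA), size=120)),
    }
    roles = assign_family_roles(reps, refs, min_identity=0.30)
    assert roles == {"famA": "mtp", "famB": "tpeX", "famC": "other"}
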