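"""Neighborhood extraction, family clustering, consensus annotation and
presence/absence genome clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagectx import context as ctx
from phagectx.records import GeneAnnotation


def _scaffold(n, genome="g", strand="+"):
    return [
        GeneAnnotation(f"{genome}_g{i}", genome, i * 100, i * 100 + 80, strand)
        for i in range(n)
    ]


class TestExtractNeighborhood:
    def test_truncation_at_scaffold_start(self):
        genes = _scaffold(5)
        nb = ctx.extract_neighborhood(genes, "g_g0", radius=10)
        assert [p for _, p, _ in nb.neighbors] == [0, 1, 2, 3, 4]

    def test_window_size_mid_scaffold(self):
        genes = _scaffold(30)
        nb = ctx.extract_neighborhood(genes, "g_g15", radius=10)
        positions = [p for _, p, _ in nb.neighbors]
        assert len(positions) == 21
        assert positions == list(range(-10, 11))

    def test_missing_anchor_errors(self):
        with pytest.raises(ValueError, match="nope"):
            ctx.extract_neighborhood(_scaffold(5), "nope")

    def test_window_never_exceeds_bound(self):
        genes = _scaffold(8)
        for i in range(8):
            nb = ctx.extract_neighborhood(genes, f"g_g{i}", radius=3)
            assert len(nb.neighbors) <= 7
            positions = [p for _, p, _ in nb.neighbors]
            assert positions == list(range(positions[0], positions[-1] + 1))

    def test_marker_reorientation_mirrors_profile(self):
        """A mirrored genome yields the same positions once reoriented."""
        genes = _scaffold(11)
        genes[8].product_label = "MCP"
        L = 1200
        mirrored = [
            GeneAnnotation(g.gene_id, g.genome_id, L - g.end, L - g.start,
                           "-" if g.strand == "+" else "+", g.product_label)
            for g in genes
        ]
        mirrored.sort(key=lambda g: g.start)
        nb = ctx.extract_neighborhood(genes, "g_g5", 10, reorient_marker_label="MCP")
        nb_m = ctx.extract_neighborhood(mirrored, "g_g5", 10, reorient_marker_label="MCP")
        assert sorted((g, p) for g, p, _ in nb.neighbors) == sorted(
            (g, p) for g, p, _ in nb_m.neighbors
        )


class TestClusterFamilies:
    def test_identical_sequences_one_family(self):
        fams = ctx.cluster_families([("a", "MKLV" * 30), ("b", "MKLV" * 30)])
        assert len(fams) == 1
        assert fams[0].member_protein_ids == ["a", "b"]

    def test_unrelated_random_sequences_split(self):
        rng = np.random.default_rng(6)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aa, size=200))
        b = "".join(rng.choice(aa, size=200))
        fams = ctx.cluster_families([("a", a), ("b", b)])
        assert len(fams) == 2

    def test_random_pair_identity_below_threshold(self):
        """Expected global identity of random 200-aa proteins is far below
        the 0.30 clustering threshold."""
        from phagectx._align import global_identity

        rng = np.random.default_rng(7)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        idents = [
            global_identity(
                "".join(rng.choice(aa, size=200)), "".join(rng.choice(aa, size=200))
            )
            for _ in range(20)
        ]
        assert max(idents) < 0.30

    def test_planted_module_recovered_one_family_per_role(self, cohort):
        _, _, genes, truths = cohort
        module_ids = {
            gid: role for t in truths.values() for role, gid in t.module_genes.items()
        }
        proteins = sorted(
            (g.gene_id, g.protein) for g in genes if g.gene_id in module_ids
        )
        fams = ctx.cluster_families(proteins)
        assign = ctx.assign_families(fams)
        roles_per_family = {}
        for gid, role in module_ids.items():
            roles_per_family.setdefault(assign[gid], set()).add(role)
        assert len(fams) == 7  # one family per module role
        assert all(len(r) == 1 for r in roles_per_family.values())

    def test_partition_is_input_order_invariant(self, cohort):
        _, _, genes, _ = cohort
        proteins = [(g.gene_id, g.protein) for g in genes if g.protein][:60]
        fams_fwd = ctx.cluster_families(proteins)
        fams_rev = ctx.cluster_families(proteins[::-1])
        part_fwd = sorted(tuple(f.member_protein_ids) for f in fams_fwd)
        part_rev = sorted(tuple(f.member_protein_ids) for f in fams_rev)
        assert part_fwd == part_rev

    def test_members_satisfy_identity_and_coverage_contract(self, cohort):
        from phagectx._align import global_identity, mutual_coverage

        _, _, genes, _ = cohort
        proteins = [(g.gene_id, g.protein) for g in genes if g.protein][:80]
        seqs = dict(proteins)
        for fam in ctx.cluster_families(proteins):
            c = seqs[fam.centroid_id]
            for pid in fam.member_protein_ids:
                assert mutual_coverage(seqs[pid], c) >= 0.75
                assert global_identity(seqs[pid], c) >= 0.30


def _brute_consensus(members, hits, e_max=1e-5, min_frac=0.05):
    counts = {}
    for pid, label, e in hits:
        if pid in members and e < e_max:
            counts.setdefault(label, set()).add(pid)
    best_n, best = 0, None
    for label in sorted(counts):
        if len(counts[label]) > best_n:
            best_n, best = len(counts[label]), label
    if best is not None and best_n >= min_frac * len(members):
        return best
    return "hyp"


class TestConsensusAnnotation:
    def _family(self, n):
        return ctx.ProteinFamily("f1", [f"p{i}" for i in range(n)], "p0")

    def test_five_percent_rule(self):
        fam = self._family(20)
        hits = [
            ctx.AnnotationHit("p0", "A", 1e-10),
            ctx.AnnotationHit("p1", "A", 1e-10),
            ctx.AnnotationHit("p2", "B", 1e-10),
        ]
        assert ctx.consensus_annotation(fam, hits) == "A"  # 2/20 = 10% >= 5%

    def test_below_threshold_is_hypothetical(self):
        fam = self._family(40)
        hits = [ctx.AnnotationHit("p0", "A", 1e-10)]  # 1/40 = 2.5%
        assert ctx.consensus_annotation(fam, hits) == "hyp"

    def test_no_hits_is_hypothetical(self):
        assert ctx.consensus_annotation(self._family(5), []) == "hyp"

    def test_e_value_filter_applies(self):
        fam = self._family(4)
        hits = [ctx.AnnotationHit(f"p{i}", "A", 1e-3) for i in range(4)]
        assert ctx.consensus_annotation(fam, hits) == "hyp"

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_reimplementation(self, data):
        n = data.draw(st.integers(1, 30))
        fam = self._family(n)
        labels = ["A", "B", "C", "aa"]
        hits = data.draw(
            st.lists(
                st.tuples(
                    st.integers(0, n - 1).map(lambda i: f"p{i}"),
                    st.sampled_from(labels),
                    st.sampled_from([1e-10, 1e-6, 1e-4, 0.5]),
                ),
                max_size=40,
            )
        )
        got = ctx.consensus_annotation(
            fam, [ctx.AnnotationHit(p, l, e) for p, l, e in hits]
        )
        want = _brute_consensus(set(fam.member_protein_ids), hits)
        assert got == want


class TestPositionProfile:
    def test_planted_module_profile(self, cohort, genes_by_genome):
        _, _, genes, truths = cohort
        proteins = sorted((g.gene_id, g.protein) for g in genes if g.protein)
        fams = ctx.cluster_families(proteins)
        assign = ctx.assign_families(fams)
        nbs = [
            ctx.extract_neighborhood(
                genes_by_genome[gid], truths[gid].module_genes["bS21"]
            )
            for gid in sorted(truths)
        ]
        profile = ctx.position_profile(nbs, assign)
        df = profile.counts.set_index(["family_id", "position"])["count"]
        anchor_fam = assign[truths[nbs[0].genome_id].module_genes["bS21"]]
        assert df[(anchor_fam, 0)] == 12
        left = assign[truths[nbs[0].genome_id].module_genes["hyp_left"]]
        right = assign[truths[nbs[0].genome_id].module_genes["hyp_right"]]
        assert df[(left, -1)] == 12 and df[(right, 1)] == 12
        # structural roles within |position| <= 5
        for role in ("TerL", "portal", "prohead-protease", "MCP"):
            fam = assign[truths[nbs[0].genome_id].module_genes[role]]
            positions = profile.counts[profile.counts.family_id == fam]["position"]
            assert positions.abs().max() <= 5
        # cell counts never exceed the number of genomes
        assert profile.counts["count"].max() <= 12

    def test_empty_input_gives_empty_profile(self):
        profile = ctx.position_profile([], {})
        assert profile.counts.empty

    def test_unassigned_gene_errors(self):
        nb = ctx.Neighborhood("a", "g", [("a", 0, True), ("b", 1, False)])
        with pytest.raises(ValueError, match="b"):
            ctx.position_profile([nb], {"a": "fam1"})


class TestPresenceAbsence:
    def test_identical_genomes_distance_zero(self):
        genes = {
            "g1": [GeneAnnotation("g1_a", "g1", 0, 300, "+")],
            "g2": [GeneAnnotation("g2_a", "g2", 0, 300, "+")],
        }
        fam = {"g1_a": "famX", "g2_a": "famX"}
        shared, dm, newick, _ = ctx.presence_absence_clustering(
            genes, {"g1": 200_000, "g2": 200_000}, fam
        )
        assert shared == 1
        assert dm.loc["g1", "g2"] == 0.0
        assert newick.endswith(";")

    def test_size_filter_excludes_small_genomes(self):
        genes = {
            g: [GeneAnnotation(f"{g}_a", g, 0, 300, "+")] for g in ("g1", "g2", "g3")
        }
        fam = {f"{g}_a": "famX" for g in genes}
        _, dm, _, _ = ctx.presence_absence_clustering(
            genes, {"g1": 200_000, "g2": 150_000, "g3": 50_000}, fam
        )
        assert list(dm.index) == ["g1", "g2"]
        with pytest.raises(ValueError):
            ctx.presence_absence_clustering(
                genes, {"g1": 200_000, "g2": 50_000, "g3": 50_000}, fam
            )

    def test_planted_clades_recovered_with_ari_one(self, cohort, genes_by_genome):
        from sklearn.metrics import adjusted_rand_score

        _, genomes, genes, truths = cohort
        proteins = sorted((g.gene_id, g.protein) for g in genes if g.protein)
        assign = ctx.assign_families(ctx.cluster_families(proteins))
        lengths = {g.genome_id: len(g) for g in genomes}
        clusters = ctx.cut_dendrogram(
            genes_by_genome, lengths, assign, n_clusters=3, min_genome_bp=20_000
        )
        gids = sorted(clusters)
        pred = [clusters[g] for g in gids]
        true = [truths[g].clade for g in gids]
        assert adjusted_rand_score(true, pred) == 1.0
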