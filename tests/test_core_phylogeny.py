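import math

import numpy as np
import pytest

from genustax.core_phylogeny import (
    MultipleAlignment,
    concatenate,
    drop_leaf,
    nj_tree,
    patristic_distances,
    progressive_msa,
    protein_distance,
    supermatrix_distances,
    trim_alignment,
)
from genustax.io_formats import read_newick

from _oracles import random_additive_distance_matrix
from conftest import random_protein


class TestProgressiveMsa:
    def test_identical_sequences_align_gapless(self):
        aln = progressive_msa([("a", "MKVLAW"), ("b", "MKVLAW")])
        assert aln.rows == ["MKVLAW", "MKVLAW"]

    def test_single_insertion_opens_one_gap(self):
        aln = progressive_msa([("a", "MKV"), ("b", "MKAV")])
        assert aln.n_columns == 4
        assert sorted(aln.rows) == ["MK-V", "MKAV"]

    def test_single_sequence_passthrough(self):
        aln = progressive_msa([("x", "MKV")])
        assert aln.rows == ["MKV"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([])

    def test_ungap_recovers_inputs_on_random_families(self, rng):
        for _ in range(25):
            base = random_protein(rng, int(rng.integers(40, 90)))
            seqs = []
            for i in range(int(rng.integers(2, 6))):
                s = list(base)
                for _m in range(int(rng.integers(0, 10))):
                    s[int(rng.integers(len(s)))] = random_protein(rng, 1)
                if rng.random() < 0.4:  # simulate a truncated homolog
                    s = s[: int(rng.integers(30, len(s)))]
                seqs.append((f"s{i}", "".join(s)))
            aln = progressive_msa(seqs)
            for sid, seq in seqs:
                assert aln.ungapped(sid) == seq

    def test_input_order_invariance(self, rng):
        base = random_protein(rng, 60)
        seqs = [("a", base), ("b", base[:50]), ("c", base[5:] + "MK")]
        fwd = progressive_msa(seqs)
        rev = progressive_msa(list(reversed(seqs)))
        assert fwd.ids == rev.ids
        assert fwd.rows == rev.rows


class TestTrimAlignment:
    def test_gapless_unchanged(self):
        aln = MultipleAlignment(["a", "b"], ["MKV", "MKV"])
        assert trim_alignment(aln).rows == ["MKV", "MKV"]

    def test_half_gapped_column_dropped_at_default(self):
        aln = MultipleAlignment(["a", "b", "c", "d"], ["MK-V", "MKAV", "MK-V", "MKAV"])
        out = trim_alignment(aln, 0.2)
        assert out.rows == ["MKV", "MKV", "MKV", "MKV"]

    def test_column_count_matches_direct_recount(self, rng):
        n_rows, n_cols = 6, 40
        rows = []
        for _ in range(n_rows):
            rows.append(
                "".join(
                    "-" if rng.random() < 0.25 else random_protein(rng, 1)
                    for _ in range(n_cols)
                )
            )
        aln = MultipleAlignment([f"s{i}" for i in range(n_rows)], rows)
        threshold = 0.3
        expected = sum(
            1
            for j in range(n_cols)
            if sum(r[j] == "-" for r in rows) / n_rows <= threshold
        )
        if expected == 0:
            with pytest.raises(ValueError):
                trim_alignment(aln, threshold)
        else:
            assert trim_alignment(aln, threshold).n_columns == expected

    def test_all_columns_removed_is_error(self):
        aln = MultipleAlignment(["a", "b"], ["M-", "-K"])
        with pytest.raises(ValueError, match="loosen"):
            trim_alignment(aln, 0.2)


class TestConcatenate:
    def test_two_parts_tile_supermatrix(self):
        a1 = MultipleAlignment(["x", "y"], ["M" * 10, "K" * 10], "c1")
        a2 = MultipleAlignment(["x", "y"], ["W" * 10, "Y" * 10], "c2")
        sm = concatenate([a1, a2], ["x", "y"])
        assert sm.n_columns == 20
        assert sm.partitions == {"c1": (0, 10), "c2": (10, 20)}

    def test_single_part_identity(self):
        a1 = MultipleAlignment(["x", "y"], ["MKV", "MKW"], "c1")
        sm = concatenate([a1], ["x", "y"])
        assert sm.rows == ["MKV", "MKW"]

    def test_missing_genome_named_in_error(self):
        a1 = MultipleAlignment(["x"], ["MKV"], "c9")
        with pytest.raises(ValueError, match="c9.*'y'"):
            concatenate([a1], ["x", "y"])

    def test_slicing_recovers_parts(self, rng):
        ids = ["a", "b", "c"]
        parts = []
        for k in range(4):
            width = int(rng.integers(3, 12))
            rows = [random_protein(rng, width) for _ in ids]
            parts.append(MultipleAlignment(list(ids), rows, f"p{k}"))
        sm = concatenate(parts, ids)
        for part in parts:
            assert sm.part(part.source_cluster_id).rows == part.rows


class TestProteinDistance:
    def test_identical_rows_zero(self):
        assert protein_distance("MKVW", "MKVW") == 0.0

    def test_formula_at_p_10_percent(self):
        row_a = "A" * 90 + "C" * 10
        row_b = "A" * 90 + "D" * 10
        d = protein_distance(row_a, row_b)
        assert d == pytest.approx(-math.log(1 - 0.1 - 0.2 * 0.01))

    def test_monotone_in_p(self):
        distances = []
        for k in range(0, 80, 10):
            row_a = "A" * 100
            row_b = "A" * (100 - k) + "C" * k
            distances.append(protein_distance(row_a, row_b))
        assert distances == sorted(distances)

    def test_saturation_capped_with_warning(self):
        with pytest.warns(UserWarning, match="saturated"):
            d = protein_distance("A" * 100, "C" * 100)
        assert d == 5.0

    def test_gapped_columns_excluded(self):
        assert protein_distance("MK-V", "MKAV") == 0.0

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ValueError):
            protein_distance("M-", "-K")


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4):1)
        ids = ["A", "B", "C", "D"]
        dm = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(dm, ids)
        pm = patristic_distances(tree)
        np.testing.assert_allclose(pm.submatrix(ids).values, dm, atol=1e-9)

    def test_three_taxa(self):
        dm = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = nj_tree(dm, ["a", "b", "c"])
        pm = patristic_distances(tree)
        np.testing.assert_allclose(pm.submatrix(["a", "b", "c"]).values, dm, atol=1e-9)

    def test_random_additive_round_trips(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            labels, dm = random_additive_distance_matrix(rng, n)
            tree = nj_tree(dm, labels)
            pm = patristic_distances(tree)
            np.testing.assert_allclose(pm.submatrix(labels).values, dm, atol=1e-9)

    def test_matches_independent_nj_implementation(self, rng):
        """Cross-check against scikit-bio's neighbor joining."""
        import skbio

        labels, dm = random_additive_distance_matrix(rng, 8)
        ours = patristic_distances(nj_tree(dm, labels))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm, ids=labels))
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert ours.value(a, b) == pytest.approx(
                    sk_tree.find(a).distance(sk_tree.find(b)), abs=1e-6
                )

    def test_ultrametric_midpoint_root_equidistant(self):
        dm = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        tree = nj_tree(dm, ["a", "b", "c", "d"])
        depths = {}
        for leaf in tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        assert max(depths.values()) == pytest.approx(min(depths.values()), abs=1e-9)

    def test_outgroup_rooting_places_outgroup_sister_to_rest(self):
        labels, dm = random_additive_distance_matrix(np.random.default_rng(3), 6)
        tree = nj_tree(dm, labels, outgroup_id=labels[0])
        children = tree.seed_node.child_nodes()
        sides = [sorted(l.taxon.label for l in c.leaf_iter()) for c in children]
        assert [labels[0]] in sides

    def test_asymmetric_matrix_rejected(self):
        dm = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(dm, ["a", "b", "c"])

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])


class TestPatristicDistances:
    def test_path_arithmetic_on_known_tree(self):
        tree = read_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        pm = patristic_distances(tree)
        assert pm.value("A", "B") == pytest.approx(0.3)
        assert pm.value("A", "C") == pytest.approx(0.45)
        assert pm.value("B", "C") == pytest.approx(0.55)

    def test_nonnegative_and_triangle_inequality(self, rng):
        labels, dm = random_additive_distance_matrix(rng, 7)
        pm = patristic_distances(nj_tree(dm, labels))
        v = pm.values
        assert (v >= 0).all()
        n = len(labels)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-9

    def test_drop_leaf_preserves_remaining_distances(self):
        tree = read_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07);")
        before = patristic_distances(tree)
        pruned = drop_leaf(tree, "D")
        after = patristic_distances(pruned)
        for a in "ABC":
            for b in "ABC":
                if a < b:
                    assert after.value(a, b) == pytest.approx(before.value(a, b))


class TestPipelineDistanceRecovery:
    def test_supermatrix_distances_track_planted_divergence(self, null_simulation):
        from genustax.orthology import classify_clusters, clusters_from_genomes
        from genustax.core_phylogeny import concatenate, progressive_msa

        genomes, truth = null_simulation
        clusters = clusters_from_genomes(genomes)
        ids = sorted(g.genome_id for g in genomes)
        seqs = {g.genome_id: dict(g.proteome) for g in genomes}
        alignments = []
        for c in clusters:
            members = sorted(c.members)
            alignments.append(
                progressive_msa([(g, seqs[g][p]) for g, p in members], cluster_id=c.cluster_id)
            )
        sm = concatenate(alignments, ids)
        dm = supermatrix_distances(sm)
        est, planted = [], []
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                est.append(dm[i, j])
                planted.append(truth.divergence(a, ids[j]))
        r = np.corrcoef(est, planted)[0, 1]
        assert r >= 0.95
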