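import pytest

from genustax.io_formats import GenomeRecord
from genustax.orthology import (
    best_hits,
    build_clusters,
    classify_clusters,
    clusters_from_genomes,
    rbh_edges,
)
from genustax.synthetic_data import SimulationConfig, simulate_pangenome

from _oracles import adjusted_rand_index


def _identical_genomes(n, rng, n_genes=8):
    from conftest import random_protein

    proteome = [(f"p{i}", random_protein(rng, 80)) for i in range(n_genes)]
    return [GenomeRecord(f"g{k}", list(proteome)) for k in range(n)]


class TestBestHits:
    def test_identical_proteomes_map_to_namesakes(self, rng):
        a, b = _identical_genomes(2, rng)
        table = best_hits(a, b)
        assert {q: h.subject_id for q, h in table.hits.items()} == {
            f"p{i}": f"p{i}" for i in range(8)
        }

    def test_planted_orthology_recovered_at_low_divergence(self):
        config = SimulationConfig(
            seed=2, newick="(a:0.05,b:0.05);", n_core=20,
            gain_rate=0, loss_rate=0, dup_prob=0, gene_len_range=(100, 150),
        )
        (a, b), truth = simulate_pangenome(config)
        table = best_hits(a, b)
        planted = {
            pid: pid for (gid, pid) in truth.orthology if gid == a.genome_id
        }
        assert {q: h.subject_id for q, h in table.hits.items()} == planted

    def test_identity_threshold_is_strict_ge(self, rng):
        # 99 residues, 50 matching -> identity 50.51 passes; 49 -> 49.49 fails
        from conftest import AA, random_protein

        base = random_protein(rng, 99)

        def mutate(seq, n):
            out = list(seq)
            for i in range(n):
                out[i] = next(c for c in AA if c != out[i])
            return "".join(out)

        a = GenomeRecord("a", [("q", base)])
        b_pass = GenomeRecord("b", [("s", mutate(base, 49))])
        b_fail = GenomeRecord("b", [("s", mutate(base, 50))])
        assert "q" in best_hits(a, b_pass).hits
        assert "q" not in best_hits(a, b_fail).hits


class TestRbhEdges:
    def test_identical_proteomes_perfect_matching(self, rng):
        a, b = _identical_genomes(2, rng)
        ab, ba = best_hits(a, b), best_hits(b, a)
        edges = rbh_edges(ab, ba)
        assert len(edges) == 8

    def test_one_sided_hit_excluded(self):
        from genustax.orthology import BestHitTable
        from genustax.pairwise_align import AlignmentHit

        def hit(q, s):
            return AlignmentHit(q, s, 100, 50, 1e-20, 90, 100, 100, 80)

        ab = BestHitTable("A", "B", {"p": hit("p", "q")})
        ba = BestHitTable("B", "A", {"q": hit("q", "other")})
        assert rbh_edges(ab, ba) == set()

    def test_mismatched_tables_rejected(self):
        from genustax.orthology import BestHitTable

        with pytest.raises(ValueError):
            rbh_edges(BestHitTable("A", "B", {}), BestHitTable("C", "A", {}))


class TestBuildClusters:
    def test_identical_proteomes_give_one_cluster_per_gene(self, rng):
        genomes = _identical_genomes(3, rng)
        clusters = clusters_from_genomes(genomes)
        assert len(clusters) == 8
        assert all(len(c.members) == 3 for c in clusters)

    def test_empty_edges_all_singletons(self, rng):
        genomes = _identical_genomes(2, rng, n_genes=5)
        clusters = build_clusters(set(), genomes)
        assert len(clusters) == 10
        assert all(len(c.members) == 1 for c in clusters)

    def test_partition_property(self, small_simulation):
        genomes, _ = small_simulation
        clusters = clusters_from_genomes(genomes)
        total = sum(len(c.members) for c in clusters)
        assert total == sum(g.n_proteins for g in genomes)
        seen = set()
        for c in clusters:
            assert not (c.members & seen)
            seen |= c.members

    def test_planted_families_recovered_exactly_without_paralogs(self):
        """With duplication off, the cluster partition equals the planted
        families at within/between-genus divergence 0.3/0.6."""
        config = SimulationConfig(
            seed=11, n_genera=3, genomes_per_genus=2, n_core=30,
            gene_len_range=(120, 200), dup_prob=0.0,
        )
        genomes, truth = simulate_pangenome(config)
        clusters = clusters_from_genomes(genomes)
        ours = {}
        for c in clusters:
            for member in c.members:
                ours[member] = c.cluster_id
        assert adjusted_rand_index(ours, truth.orthology) == pytest.approx(1.0)

    def test_planted_families_near_recovered_with_paralogs(self, small_simulation):
        """Duplicated copies may split off their parent family (the truth
        map conflates paralog copies), but agreement stays high."""
        genomes, truth = small_simulation
        clusters = clusters_from_genomes(genomes)
        ours = {}
        for c in clusters:
            for member in c.members:
                ours[member] = c.cluster_id
        assert adjusted_rand_index(ours, truth.orthology) >= 0.95

    def test_order_invariance(self, null_simulation):
        genomes, _ = null_simulation
        forward = clusters_from_genomes(genomes)
        backward = clusters_from_genomes(list(reversed(genomes)))
        assert [c.members for c in forward] == [c.members for c in backward]


class TestClassifyClusters:
    def test_identical_proteomes_all_single_copy_core(self, rng):
        genomes = _identical_genomes(3, rng)
        clusters = clusters_from_genomes(genomes)
        summary = classify_clusters(clusters, [g.genome_id for g in genomes])
        assert summary.core_oc_count == 8
        assert summary.single_copy_core_count == 8
        for counts in summary.per_genome.values():
            assert counts == {"core": 8, "accessory": 0, "unique": 0}

    def test_planted_core_recovered_without_gain_loss(self, null_simulation):
        genomes, _ = null_simulation
        clusters = clusters_from_genomes(genomes)
        summary = classify_clusters(clusters, [g.genome_id for g in genomes])
        assert summary.core_oc_count == 25
        assert summary.single_copy_core_count == 25
        assert summary.total_oc_count == 25

    def test_per_genome_counts_partition_gene_content(self, small_simulation):
        genomes, _ = small_simulation
        clusters = clusters_from_genomes(genomes)
        ids = [g.genome_id for g in genomes]
        summary = classify_clusters(clusters, ids)
        for g in genomes:
            counts = summary.per_genome[g.genome_id]
            n_clusters = sum(1 for c in clusters if g.genome_id in c.genomes())
            assert counts["core"] + counts["accessory"] + counts["unique"] == n_clusters

    def test_absent_genome_rejected(self, rng):
        genomes = _identical_genomes(2, rng)
        clusters = clusters_from_genomes(genomes)
        with pytest.raises(ValueError, match="ghost"):
            classify_clusters(clusters, ["g0", "g1", "ghost"])

    def test_removing_genome_grows_core(self, small_simulation):
        genomes, _ = small_simulation
        clusters = clusters_from_genomes(genomes)
        ids = [g.genome_id for g in genomes]
        full = classify_clusters(clusters, ids)
        reduced = classify_clusters(clusters, ids[:-1])
        assert reduced.core_oc_count >= full.core_oc_count
        assert reduced.single_copy_core_count >= full.single_copy_core_count


class TestThresholdMonotonicity:
    def test_raising_identity_never_increases_edges(self, small_simulation):
        genomes, _ = small_simulation
        a, b = genomes[0], genomes[3]
        counts = []
        for identity in (30.0, 50.0, 70.0, 90.0):
            ab = best_hits(a, b, identity_min=identity)
            ba = best_hits(b, a, identity_min=identity)
            counts.append(len(rbh_edges(ab, ba)))
        assert counts == sorted(counts, reverse=True)
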