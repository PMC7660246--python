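import math

import numpy as np
import pytest

from genustax.genus_demarcation import (
    DemarcationConfig,
    demarcate,
    is_monophyletic,
    major_clades,
    partition_report,
)
from genustax.io_formats import read_newick
from genustax.similarity_metrics import SimilarityMatrix


def _sim_matrix(metric, ids, pair_value):
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                values[i, j] = pair_value(ids[i], ids[j])
    if metric != "EVODIST":
        np.fill_diagonal(values, 100.0)
    return SimilarityMatrix(metric, list(ids), values)


def _two_genus_setup():
    tree = read_newick("((a1:0.1,a2:0.1):0.3,(b1:0.1,b2:0.1):0.3);")
    ids = ["a1", "a2", "b1", "b2"]
    aai = _sim_matrix(
        "AAI", ids, lambda x, y: 85.0 if x[0] == y[0] else 55.0
    )
    dist = _sim_matrix(
        "EVODIST", ids, lambda x, y: 0.2 if x[0] == y[0] else 0.8
    )
    return tree, aai, dist


class TestDemarcate:
    def test_all_pairs_compliant_single_genus(self):
        tree = read_newick("((a:0.05,b:0.05):0.02,(c:0.05,d:0.05):0.02);")
        ids = ["a", "b", "c", "d"]
        aai = _sim_matrix("AAI", ids, lambda x, y: 90.0)
        dist = _sim_matrix("EVODIST", ids, lambda x, y: 0.15)
        partition = demarcate(tree, aai, dist)
        assert partition.n_groups == 1
        assert partition.groups[0].members == ids

    def test_two_planted_genera_split(self):
        tree, aai, dist = _two_genus_setup()
        partition = demarcate(tree, aai, dist)
        assert [g.members for g in partition.groups] == [["a1", "a2"], ["b1", "b2"]]

    def test_dist_max_zero_gives_singletons(self):
        tree, aai, dist = _two_genus_setup()
        partition = demarcate(
            tree, aai, dist, DemarcationConfig(dist_max=0.0)
        )
        assert partition.n_groups == 4
        assert all(len(g.members) == 1 for g in partition.groups)

    def test_missing_genome_in_matrix_is_error(self):
        tree, aai, dist = _two_genus_setup()
        aai_small = aai.submatrix(["a1", "a2", "b1"])
        with pytest.raises(ValueError, match="b2"):
            demarcate(tree, aai_small, dist)

    def test_groups_are_monophyletic(self):
        tree, aai, dist = _two_genus_setup()
        partition = demarcate(tree, aai, dist)
        for group in partition.groups:
            assert is_monophyletic(tree, group.members)

    def test_pass_fraction_spares_single_aberrant_pair(self):
        """A clade keeps its genus when one low-AAI pair is outvoted, the
        way a 96.8 % within-clade pass rate outweighs one 67.3 % pair."""
        tree = read_newick(
            "((((a:0.05,b:0.05):0.05,c:0.08):0.05,(d:0.08,e:0.08):0.04):0.3,z:0.9);"
        )
        ids = ["a", "b", "c", "d", "e", "z"]

        def aai_fn(x, y):
            if "z" in (x, y):
                return 40.0
            if {x, y} == {"d", "e"}:
                return 67.3  # single aberrant pair among 10
            return 85.0

        aai = _sim_matrix("AAI", ids, aai_fn)
        dist = _sim_matrix(
            "EVODIST", ids, lambda x, y: 1.5 if "z" in (x, y) else 0.3
        )
        partition = demarcate(tree, aai, dist, DemarcationConfig(aai_pass_fraction=0.85))
        groups = [g.members for g in partition.groups]
        assert ["a", "b", "c", "d", "e"] in groups

        strict = demarcate(tree, aai, dist, DemarcationConfig(aai_pass_fraction=1.0))
        assert ["a", "b", "c", "d", "e"] not in [g.members for g in strict.groups]

    def test_tightening_thresholds_only_refines(self):
        tree, aai, dist = _two_genus_setup()
        loose = demarcate(tree, aai, dist, DemarcationConfig(aai_min=50.0, dist_max=2.0))
        tight = demarcate(tree, aai, dist, DemarcationConfig(aai_min=70.0, dist_max=0.4))
        # every tight group is contained in some loose group
        for tg in tight.groups:
            assert any(set(tg.members) <= set(lg.members) for lg in loose.groups)

    def test_deterministic_under_leaf_order(self):
        tree1 = read_newick("((a1:0.1,a2:0.1):0.3,(b1:0.1,b2:0.1):0.3);")
        tree2 = read_newick("((b2:0.1,b1:0.1):0.3,(a2:0.1,a1:0.1):0.3);")
        _, aai, dist = _two_genus_setup()
        p1 = demarcate(tree1, aai, dist)
        p2 = demarcate(tree2, aai, dist)
        assert [g.members for g in p1.groups] == [g.members for g in p2.groups]


class TestMajorClades:
    def test_caterpillar_split_at_root(self):
        tree = read_newick("(((a:1,b:1):1,c:2):1,d:3);")
        labeling = major_clades(tree, 2)
        groups = labeling.groups()
        assert sorted(map(sorted, groups.values())) == [["a", "b", "c"], ["d"]]

    def test_n_top_one_single_group(self):
        tree = read_newick("((a:1,b:1):1,c:2);")
        labeling = major_clades(tree, 1)
        assert len(labeling.groups()) == 1

    def test_n_top_exceeding_leaves_rejected(self):
        tree = read_newick("((a:1,b:1):1,c:2);")
        with pytest.raises(ValueError):
            major_clades(tree, 4)

    def test_three_planted_clades_recovered(self):
        tree = read_newick(
            "(((a1:.1,a2:.1):.5,(b1:.1,b2:.1):.5):.2,(c1:.1,c2:.1):.6);"
        )
        labeling = major_clades(tree, 3)
        groups = sorted(map(sorted, labeling.groups().values()))
        assert groups == [["a1", "a2"], ["b1", "b2"], ["c1", "c2"]]


class TestPartitionReport:
    def test_singleton_group_statistics_are_nan(self):
        tree, aai, dist = _two_genus_setup()
        partition = demarcate(tree, aai, dist, DemarcationConfig(dist_max=0.0))
        df = partition_report(partition, aai, dist)
        assert len(df) == 4
        assert df["aai_min"].isna().all()

    def test_two_group_summary_matches_hand_computation(self):
        tree, aai, dist = _two_genus_setup()
        partition = demarcate(tree, aai, dist)
        df = partition_report(partition, aai, dist).set_index("group_id")
        assert df.loc["genus_01", "aai_min"] == pytest.approx(85.0)
        assert df.loc["genus_01", "evodist_max"] == pytest.approx(0.2)
        assert df.loc["genus_02", "aai_median"] == pytest.approx(85.0)

    def test_group_count_matches_partition(self):
        tree, aai, dist = _two_genus_setup()
        partition = demarcate(tree, aai, dist)
        assert len(partition_report(partition, aai, dist)) == partition.n_groups


class TestEndToEndPlantedGenera:
    def test_planted_partition_recovered(self, small_simulation):
        from genustax.pipeline import PipelineConfig, run_analysis

        from _oracles import adjusted_rand_index

        genomes, truth = small_simulation
        result = run_analysis(genomes, PipelineConfig(compute_pocp=False))
        ours = {m: g.group_id for g in result.partition.groups for m in g.members}
        assert adjusted_rand_index(ours, truth.genus_labels) == pytest.approx(1.0)
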