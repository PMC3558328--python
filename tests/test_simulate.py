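import numpy as np
import pytest

from microdelim.distances import build_distance_matrix, k2p_distance
from microdelim.errors import InputError
from microdelim.io import UltrametricTree
from microdelim.simulate import (
    SimSpec,
    assign_morphospecies_labels,
    make_planted_gap_dataset,
    make_suitability_grids,
    sim_sequences_k80,
    sim_species_coalescent_tree,
    sim_tree,
)
from microdelim.threshold import threshold_partition


class TestSimTree:
    def test_yule_structure(self):
        tree = sim_tree(SimSpec(process="yule", n_tips=50, r1=1.0, seed=1))
        assert tree.n_tips == 50
        assert len(tree.internal_ages()) == 49
        assert tree.provenance["seed"] == 1

    def test_same_seed_same_newick(self):
        spec = SimSpec(process="yule", n_tips=12, r1=2.0, seed=42)
        assert sim_tree(spec).as_newick() == sim_tree(spec).as_newick()

    def test_yule_mean_root_age_matches_expectation(self):
        # E[depth] = sum_{i=2}^{N} 1/(i r) for the conditioned pure birth
        n, r = 20, 2.0
        depths = [
            sim_tree(SimSpec(process="yule", n_tips=n, r1=r, seed=s)).depth
            for s in range(500)
        ]
        expected = sum(1.0 / (i * r) for i in range(2, n + 1))
        assert np.mean(depths) == pytest.approx(expected, rel=0.15)

    def test_birthdeath_reconstructed_tree(self):
        tree = sim_tree(SimSpec(process="birthdeath", n_tips=25, r1=1.0, a=0.5, seed=3))
        assert tree.n_tips == 25  # conditioned on the extant count

    def test_yule2rate_requires_r2(self):
        with pytest.raises(InputError):
            sim_tree(SimSpec(process="yule2rate", n_tips=10, r1=1.0, seed=0))

    def test_yule2rate_burst_concentrates_recent_nodes(self):
        tree = sim_tree(SimSpec(process="yule2rate", n_tips=40, r1=5.0, r2=50.0,
                                shift_frac=0.05, seed=4))
        ages = np.array(tree.internal_ages())
        assert np.sum(ages < 0.1 * tree.depth) >= 10


class TestSpeciesCoalescent:
    def test_tip_conservation_and_truth(self):
        tree, truth = sim_species_coalescent_tree(8, 4, separation=20, seed=5)
        assert tree.n_tips == 32
        assert truth.n_blocks == 8
        assert all(len(b) == 4 for b in truth.blocks)

    def test_single_tip_species_are_singletons(self):
        tree, truth = sim_species_coalescent_tree(6, 1, separation=20, seed=6)
        assert tree.n_tips == 6
        assert truth.n_blocks == 6

    def test_clusters_shallower_than_species_boundaries(self):
        tree, truth = sim_species_coalescent_tree(10, 5, separation=20, seed=7)
        ages = tree.internal_ages()
        # 9 speciation events, then 40 within-species coalescences
        assert ages[8] / ages[9] > 10

    def test_provenance_regenerates_identically(self):
        tree, _ = sim_species_coalescent_tree(5, 3, separation=15, seed=9)
        prov = tree.provenance
        again, _ = sim_species_coalescent_tree(
            prov["n_species"], prov["tips_per_species"],
            separation=prov["separation"], species_rate=prov["species_rate"],
            seed=prov["seed"],
        )
        assert again.as_newick() == tree.as_newick()


class TestSequences:
    def test_zero_scale_keeps_sequences_identical(self, balanced_tree):
        aln = sim_sequences_k80(balanced_tree, 100, scale=0.0, seed=0)
        assert len(set(aln.seqs)) == 1

    def test_seeded_determinism(self, balanced_tree):
        a1 = sim_sequences_k80(balanced_tree, 80, seed=3)
        a2 = sim_sequences_k80(balanced_tree, 80, seed=3)
        assert a1 == a2

    def test_k2p_estimates_branch_separation(self):
        # two tips separated by 2 * 0.05 expected substitutions/site
        t = UltrametricTree.from_newick("(A:0.05,B:0.05);")
        dists = [
            k2p_distance(*sim_sequences_k80(t, 2000, kappa=2.0, seed=s).seqs)[0]
            for s in range(100)
        ]
        assert np.mean(dists) == pytest.approx(0.1, rel=0.1)


class TestPlantedGap:
    def test_realized_distances_respect_the_gap(self):
        aln, truth = make_planted_gap_dataset(6, 4, intra_max=0.01,
                                              inter_min=0.06, length=607, seed=2)
        dm = build_distance_matrix(aln)
        for i, a in enumerate(aln.ids):
            for j in range(i + 1, len(aln.ids)):
                b = aln.ids[j]
                if truth.same_block(a, b):
                    assert dm.matrix[i, j] <= 0.01
                else:
                    assert dm.matrix[i, j] >= 0.06

    def test_any_cutoff_inside_gap_recovers_truth(self):
        aln, truth = make_planted_gap_dataset(6, 4, seed=2)
        dm = build_distance_matrix(aln)
        for cutoff in (0.015, 0.032, 0.055):
            assert threshold_partition(dm, cutoff) == truth

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(InputError):
            make_planted_gap_dataset(4, 3, intra_max=0.06, inter_min=0.01)


class TestMorphoLabelGenerator:
    def test_no_edits_reproduce_lineages(self):
        truth_blocks = [[f"s{b}_{i}" for i in range(3)] for b in range(5)]
        from microdelim.io import Partition

        truth = Partition.from_blocks(truth_blocks)
        labels, log = assign_morphospecies_labels(truth, 0, 0, seed=0)
        assert log == []
        assert len(set(labels.labels.values())) == 5

    def test_infeasible_edit_counts_rejected(self):
        from microdelim.io import Partition

        truth = Partition.from_blocks([["a"], ["b"]])
        with pytest.raises(InputError):
            assign_morphospecies_labels(truth, 2, 1)


class TestGrids:
    def test_deterministic_under_seed(self):
        g1a, g2a = make_suitability_grids(separation=3.0, seed=5, noise=0.1)
        g1b, g2b = make_suitability_grids(separation=3.0, seed=5, noise=0.1)
        assert np.array_equal(g1a.values, g1b.values)
        assert np.array_equal(g2a.values, g2b.values)
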