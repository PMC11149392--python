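import random

import dendropy
import numpy as np
import pytest

from orthoclique.downstream import (
    neighbor_joining,
    pcoa,
    robinson_foulds,
    sweep_components,
)
from orthoclique.simulate import SimulationConfig, simulate_transcriptomes

from conftest import clone_transcriptome, make_transcriptome, random_dna


def tree_from(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = False
    return t


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovers_topology(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances; verify the
        # four-point condition before asking NJ to recover the split AB|CD
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        s1 = D[0, 1] + D[2, 3]  # AB|CD
        s2 = D[0, 2] + D[1, 3]
        s3 = D[0, 3] + D[1, 2]
        assert s1 < s2 == s3
        nj = neighbor_joining(D, labels)
        expected = tree_from("((A:2,B:3):1,(C:4,D:5));")
        assert robinson_foulds(nj, expected) == 0

    def test_two_samples_single_edge(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        nj = neighbor_joining(D, ["A", "B"])
        assert len(nj.leaf_nodes()) == 2
        assert nj.length() == pytest.approx(0.4)

    def test_three_taxa_branch_lengths_fit_distances(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        nj = neighbor_joining(D, ["A", "B", "C"])
        pdm = nj.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in nj.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(2.0)
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(3.0)
        assert pdm.distance(taxa["B"], taxa["C"]) == pytest.approx(4.0)

    def test_non_square_input_rejected(self):
        with pytest.raises(ValueError, match="square"):
            neighbor_joining(np.zeros((2, 3)))

    def test_agrees_with_dendropy_on_random_additive_matrices(self):
        rng = random.Random(3)
        for _ in range(5):
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0,
                death_rate=0.0,
                num_extant_tips=7,
                rng=rng,
                repeat_until_success=True,
            )
            pdm = tree.phylogenetic_distance_matrix()
            taxa = list(tree.taxon_namespace)
            n = len(taxa)
            D = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    D[i, j] = D[j, i] = pdm.distance(taxa[i], taxa[j])
            mine = neighbor_joining(D, [t.label for t in taxa])
            ref = pdm.nj_tree()
            ref.is_rooted = False
            assert robinson_foulds(mine, ref) == 0


class TestPcoa:
    def test_zero_matrix_gives_zero_coordinates(self):
        coords, eigvals = pcoa(np.zeros((4, 4)), dims=2)
        assert coords.shape[1] == 0 or np.allclose(coords.values, 0)
        assert np.allclose(eigvals, 0)

    def test_collinear_points_recovered_on_first_axis(self):
        # three points on a line at 0, 1, 2
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        coords, eigvals = pcoa(D, dims=2)
        axis1 = coords.iloc[:, 0].values
        gaps = np.diff(np.sort(axis1))
        assert gaps == pytest.approx([1.0, 1.0], abs=1e-9)
        assert eigvals[1] == pytest.approx(0.0, abs=1e-9)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(6, 3))
        D = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
        coords, _ = pcoa(D, dims=5)
        got = np.linalg.norm(
            coords.values[:, None, :] - coords.values[None, :, :], axis=-1
        )
        assert np.allclose(got, D, atol=1e-9)

    def test_excess_dims_clamped_with_warning(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="clamped"):
            pcoa(D, dims=10)

    def test_agrees_with_skbio_on_random_symmetric_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        mine, _ = pcoa(D, dims=2)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        ref_coords = ref.samples.values[:, :2]
        for axis in range(2):
            a, b = mine.values[:, axis], ref_coords[:, axis]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = tree_from("((A,B),(C,D));")
        assert robinson_foulds(t, tree_from("((A,B),(C,D));")) == 0

    def test_distinct_quartets_distance_two(self):
        t1 = tree_from("((A,B),(C,D));")
        t2 = tree_from("((A,C),(B,D));")
        assert robinson_foulds(t1, t2) == 2

    def test_caterpillar_vs_balanced_six_leaves(self):
        cat = tree_from("(A,(B,(C,(D,(E,F)))));")
        bal = tree_from("((A,(B,C)),(D,(E,F)));")
        # exhaustive split listing (sides away from A): caterpillar
        # {CDEF, DEF, EF}; balanced {BC, DEF, EF} -> symmetric difference
        # {CDEF} vs {BC}, so RF = 2
        assert robinson_foulds(cat, bal) == 2

    def test_label_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="leaf label"):
            robinson_foulds(tree_from("((A,B),(C,D));"), tree_from("((A,B),(C,E));"))

    def test_agrees_with_dendropy_symmetric_difference(self):
        rng = random.Random(8)
        for _ in range(5):
            tns = dendropy.TaxonNamespace([f"L{i}" for i in range(8)])
            t1 = dendropy.simulate.treesim.pure_kingman_tree(tns, rng=rng)
            t2 = dendropy.simulate.treesim.pure_kingman_tree(tns, rng=rng)
            for t in (t1, t2):
                t.is_rooted = False
                t.update_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
            assert robinson_foulds(t1, t2) == expected


@pytest.fixture(scope="module")
def small_sim():
    cfg = SimulationConfig(n_taxa=4, n_transcripts=40, site_rate=0.01, seed=21)
    return simulate_transcriptomes(cfg)


class TestSweeps:
    def test_all_strategy_single_record(self, small_sim):
        records = sweep_components(small_sim.transcriptomes, n_values=[40])
        assert len(records) == 1
        rec = records[0]
        assert rec.s == 4
        assert rec.n_ideal <= rec.n_large

    def test_prefix_strategy_nested_and_monotone(self, small_sim):
        ids = [t.sample_id for t in small_sim.transcriptomes]
        records = sweep_components(
            small_sim.transcriptomes,
            n_values=[40],
            subset_strategy="prefix",
            permutation=ids,
        )
        assert [r.s for r in records] == [2, 3, 4]
        for earlier, later in zip(records, records[1:]):
            assert set(earlier.subset) <= set(later.subset)
            assert later.n_ideal <= earlier.n_ideal

    def test_ideal_count_nondecreasing_in_n_on_clones(self, rng):
        base = make_transcriptome(
            "c0",
            {g: random_dna(rng, 200) for g in range(12)},
            coverages={g: float(g + 1) for g in range(12)},
        )
        clones = [base] + [clone_transcriptome(base, f"c{i}") for i in (1, 2)]
        records = sweep_components(clones, n_values=[3, 6, 12])
        ideals = [r.n_ideal for r in records]
        assert ideals == sorted(ideals)
        assert ideals[-1] == 12

    def test_fair_strategy_covers_all_sizes(self, small_sim):
        records = sweep_components(
            small_sim.transcriptomes,
            n_values=[40],
            subset_strategy="fair",
            trials_per_size=2,
            seed=0,
        )
        sizes = {r.s for r in records}
        assert sizes == {2, 3, 4}
        assert len(records) == 6

    def test_prefix_requires_permutation(self, small_sim):
        with pytest.raises(ValueError, match="permutation"):
            sweep_components(
                small_sim.transcriptomes, n_values=[10], subset_strategy="prefix"
            )
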