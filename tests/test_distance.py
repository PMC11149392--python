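import random
import warnings

import numpy as np
import pandas as pd
import pytest

from orthoclique.distance import (
    distance_matrix,
    hybrid_ideal_then_jaccard,
    kmer_jaccard_matrix,
    matrix_from_match_tables,
    match_tables_from_hsps,
    pairwise_hsp_tables,
    similarity_and_distance,
)
from orthoclique.exceptions import NoComparableOrthologsError
from orthoclique.matching import MATCH_COLUMNS, GeneMatchTable

from _oracles import kmer_jaccard_bruteforce
from conftest import clone_transcriptome, make_transcriptome, mutate, random_dna


def match_table(rows, s1="A", s2="B"):
    df = pd.DataFrame(rows, columns=MATCH_COLUMNS)
    return GeneMatchTable(s1, s2, df)


class TestSimilarityArithmetic:
    def test_perfect_identity(self):
        t = match_table([("g", 0, "g", 0, 100.0, 100, 100, 0)])
        s, d = similarity_and_distance(t)
        assert s == 1.0
        assert d == 0.0

    def test_hand_computed_ratio(self):
        t = match_table(
            [
                ("g1", 0, "h1", 0, 100.0, 90, 100, 0),
                ("g2", 0, "h2", 0, 100.0, 95, 100, 5),
            ]
        )
        s, d = similarity_and_distance(t)
        assert s == pytest.approx(185 / 195, abs=1e-12)
        assert d == pytest.approx(1 - 185 / 195, abs=1e-12)

    def test_empty_table_raises_not_zero(self):
        with pytest.raises(NoComparableOrthologsError):
            similarity_and_distance(match_table([]))

    def test_sums_not_per_row_means(self):
        # S is a ratio of sums, not a mean of per-row ratios
        t = match_table(
            [
                ("g1", 0, "h1", 0, 100.0, 50, 100, 0),
                ("g2", 0, "h2", 0, 100.0, 300, 300, 0),
            ]
        )
        s, _ = similarity_and_distance(t)
        assert s == pytest.approx(350 / 400, abs=1e-12)


class TestDistanceMatrixPipeline:
    def test_clone_identity_all_modes(self, rng):
        base = make_transcriptome(
            "c0", {g: random_dna(rng, 300) for g in range(20)}
        )
        clones = [base] + [clone_transcriptome(base, f"c{i}") for i in range(1, 4)]
        dm_direct = distance_matrix(clones[:2], n=20, mode="two_sample_direct")
        assert np.all(dm_direct.values == 0)
        dm_ideal = distance_matrix(clones, n=20, mode="ideal_filtered")
        assert np.all(dm_ideal.values == 0)

    def test_single_substitution_two_sample_distance(self, rng):
        genes = {g: random_dna(rng, 500) for g in range(10)}
        t1 = make_transcriptome("A", genes)
        genes2 = dict(genes)
        seq = genes2[0]
        genes2[0] = seq[:100] + ("A" if seq[100] != "A" else "C") + seq[101:]
        t2 = make_transcriptome("B", genes2)
        dm = distance_matrix([t1, t2], n=10, mode="two_sample_direct")
        assert dm.values[0, 1] == pytest.approx(1 - 4999 / 5000, abs=1e-12)

    def test_gene_missing_one_edge_excluded_everywhere(self, rng):
        # gene "x" is shared only by A and B; ideal filtering drops it
        shared = {g: random_dna(rng, 300) for g in range(5)}
        xseq = random_dna(rng, 300)
        a = make_transcriptome("A", {**shared, "x": xseq})
        b = make_transcriptome("B", {**shared, "x": mutate(rng, xseq, 0.01)})
        c = make_transcriptome("C", shared)
        hsps = pairwise_hsp_tables([a, b, c])
        tables = match_tables_from_hsps(hsps)
        values, counts = matrix_from_match_tables(
            tables, ["A", "B", "C"], mode="ideal_filtered"
        )
        assert counts["n_ideal"] == 5
        # the A-B entry ignores gene x entirely, so it is exactly zero
        assert values[0, 1] == 0.0

    def test_metadata_records_parameters(self, rng):
        t1 = make_transcriptome("A", {0: random_dna(rng, 120)})
        t2 = clone_transcriptome(t1, "B")
        dm = distance_matrix([t1, t2], n=5, N=2)
        assert dm.metadata["n"] == 5
        assert dm.metadata["N"] == 2
        assert dm.metadata["mode"] == "two_sample_direct"

    def test_values_within_unit_interval(self, rng):
        genes = {g: random_dna(rng, 200) for g in range(8)}
        samples = [
            make_transcriptome("A", genes),
            make_transcriptome("B", {g: mutate(rng, s, 0.03) for g, s in genes.items()}),
            make_transcriptome("C", {g: mutate(rng, s, 0.06) for g, s in genes.items()}),
        ]
        dm = distance_matrix(samples, n=8)
        off = dm.values[~np.eye(3, dtype=bool)]
        assert np.all((off >= 0) & (off < 1))
        assert np.all(np.diag(dm.values) == 0)

    def test_symmetrize_mean_averages_orientations(self, rng):
        genes = {g: random_dna(rng, 200) for g in range(6)}
        samples = [
            make_transcriptome("A", genes),
            make_transcriptome("B", {g: mutate(rng, s, 0.02) for g, s in genes.items()}),
        ]
        dm = distance_matrix(samples, n=6, symmetrize="mean")
        assert np.allclose(dm.values, dm.values.T)


class TestKmerJaccard:
    def test_identical_samples_zero(self, rng):
        genes = {g: random_dna(rng, 100) for g in range(4)}
        samples = [make_transcriptome(f"s{i}", genes) for i in range(3)]
        dm = kmer_jaccard_matrix(samples, k=21)
        assert np.all(dm.values == 0)

    def test_matches_bruteforce_oracle_on_short_sequences(self):
        seqs = [
            ["ACGTACGTAA", "TTGACGTACC"],
            ["ACGTACGTAA", "GGGTTTACCA"],
            ["CCCGTACGTA", "TTGACGTACC"],
        ]
        samples = [
            make_transcriptome(f"s{i}", {j: s for j, s in enumerate(sample)})
            for i, sample in enumerate(seqs)
        ]
        dm = kmer_jaccard_matrix(samples, k=3)
        expected = kmer_jaccard_bruteforce(seqs, k=3)
        for (i, j), d in expected.items():
            assert dm.values[i, j] == pytest.approx(d, abs=1e-12)

    def test_disjoint_kmer_sets_distance_one_with_warning(self):
        samples = [
            make_transcriptome("s0", {0: "AAAAAAAA"}),
            make_transcriptome("s1", {0: "CCCCCCCC"}),
            make_transcriptome("s2", {0: "GTGTGTGT"}),
        ]
        with pytest.warns(UserWarning, match="empty filtered"):
            dm = kmer_jaccard_matrix(samples, k=5)
        off = dm.values[~np.eye(3, dtype=bool)]
        assert np.all(off == 1.0)

    def test_k_longer_than_sequences_is_an_error(self):
        samples = [make_transcriptome(f"s{i}", {0: "ACGTACGT"}) for i in range(3)]
        with pytest.raises(ValueError, match="longer than every sequence"):
            kmer_jaccard_matrix(samples, k=50)

    def test_canonicalization_merges_reverse_complements(self):
        # one sample holds the reverse complement of the other's sequence
        seq = "ACGTTGCAGGTACCGGTAAC"
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        samples = [
            make_transcriptome("s0", {0: seq}),
            make_transcriptome("s1", {0: rc}),
            make_transcriptome("s2", {0: seq}),
        ]
        dm = kmer_jaccard_matrix(samples, k=7)
        assert np.all(dm.values == 0)


class TestHybridMode:
    def test_clones_zero(self, rng):
        base = make_transcriptome("c0", {g: random_dna(rng, 200) for g in range(6)})
        clones = [base] + [clone_transcriptome(base, f"c{i}") for i in (1, 2)]
        dm = hybrid_ideal_then_jaccard(clones, n=6, k=15)
        assert np.all(dm.values == 0)

    def test_equals_plain_jaccard_when_all_genes_ideal(self, rng):
        genes = {g: random_dna(rng, 200) for g in range(6)}
        samples = [
            make_transcriptome("A", genes),
            make_transcriptome("B", {g: mutate(rng, s, 0.01) for g, s in genes.items()}),
            make_transcriptome("C", {g: mutate(rng, s, 0.01) for g, s in genes.items()}),
        ]
        hybrid = hybrid_ideal_then_jaccard(samples, n=6, k=15)
        assert hybrid.metadata["component_counts"]["n_ideal"] == 6
        plain = kmer_jaccard_matrix(samples, k=15)
        assert np.allclose(hybrid.values, plain.values)

    def test_paralog_family_excluded_from_kmer_universe(self, rng):
        # gene "p" has two near-identical copies in sample A -> its component
        # exceeds size s and cannot be ideal, so its k-mers drop out
        genes = {g: random_dna(rng, 200) for g in range(4)}
        pseq = random_dna(rng, 200)
        a = make_transcriptome("A", {**genes, "p1": pseq, "p2": mutate(rng, pseq, 0.005)})
        b = make_transcriptome(
            "B",
            {
                **{g: mutate(rng, s, 0.01) for g, s in genes.items()},
                "p1": mutate(rng, pseq, 0.01),
            },
        )
        c = make_transcriptome("C", {g: mutate(rng, s, 0.01) for g, s in genes.items()})
        hybrid = hybrid_ideal_then_jaccard([a, b, c], n=10, k=15)
        assert hybrid.metadata["component_counts"]["n_ideal"] == 4
        plain = kmer_jaccard_matrix([a, b, c], k=15)
        # the paralog k-mers inflate the plain A-B comparison
        assert hybrid.values[0, 1] != pytest.approx(plain.values[0, 1])


def test_mutation_rate_monotonicity_small_scale(rng):
    genes = {g: random_dna(rng, 300) for g in range(10)}
    base = make_transcriptome("A", genes)
    mean_d = []
    for p in (0.005, 0.02, 0.05):
        other = make_transcriptome("B", {g: mutate(rng, s, p) for g, s in genes.items()})
        dm = distance_matrix([base, other], n=10)
        mean_d.append(dm.values[0, 1])
    assert mean_d[0] < mean_d[1] < mean_d[2]
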