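"""Binary distances, Ward clustering, tree export, correlations, proximity."""

import numpy as np
import pandas as pd
import pytest

from oracles import ward_heights_oracle

from ervmap.comparative_analysis import (
    DistanceMatrix,
    binary_distance,
    length_correlation,
    proximity_fraction,
    transcribed_fraction,
    transcript_proximity,
    tree_to_edges,
    tree_to_newick,
    ward_cluster,
)
from ervmap.model import GenomicInterval, IntervalCluster, Transcript


def matrix(rows, samples):
    return pd.DataFrame(rows, index=samples,
                        columns=[f"c{i}" for i in range(len(rows[0]))])


class TestBinaryDistance:
    def test_identical_rows_distance_zero(self):
        m = matrix([[1, 0, 1], [1, 0, 1]], ["a", "b"])
        assert binary_distance(m).d[0, 1] == 0.0

    def test_distance_is_sqrt_of_hamming_count(self):
        m = matrix([[1, 1, 1, 1, 0], [0, 0, 0, 0, 0]], ["a", "b"])
        assert binary_distance(m).d[0, 1] == pytest.approx(2.0)

    def test_complementary_rows_of_length_nine(self):
        m = matrix([[1] * 9, [0] * 9], ["a", "b"])
        assert binary_distance(m).d[0, 1] == pytest.approx(3.0)

    def test_symmetry_zero_diagonal_triangle_inequality(self):
        rng = np.random.default_rng(13)
        m = matrix(rng.integers(0, 2, size=(6, 12)).tolist(),
                   [f"s{i}" for i in range(6)])
        d = binary_distance(m).d
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestWardCluster:
    def test_two_leaves_merge_at_their_distance(self):
        m = matrix([[1], [0]], ["a", "b"])
        tree = ward_cluster(binary_distance(m))
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(1.0)

    def test_two_tight_pairs_merge_first(self):
        rows = [[1, 1, 0, 0, 1, 0],
                [1, 1, 0, 1, 1, 0],
                [0, 0, 1, 1, 0, 1],
                [0, 1, 1, 1, 0, 1]]
        tree = ward_cluster(binary_distance(matrix(rows, list("abcd"))))
        first_two = {frozenset(map(int, m[:2])) for m in tree.merges[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}
        # frozen independent reference: hclust ward.D2 heights (1, 1, 3)
        assert sorted(tree.merges[:, 2]) == pytest.approx([1.0, 1.0, 3.0])

    def test_identical_points_merge_at_height_zero(self):
        m = matrix([[1, 0]] * 4, list("abcd"))
        tree = ward_cluster(binary_distance(m))
        assert np.allclose(tree.merges[:, 2], 0.0)

    def test_agrees_with_naive_lance_williams_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            x = rng.integers(0, 2, size=(8, 12)).astype(float)
            tree = ward_cluster(binary_distance(
                matrix(x.tolist(), [f"s{i}" for i in range(8)])
            ))
            heights, had_ties = ward_heights_oracle(x)
            if had_ties:
                # tie-invariant check: sum of squared merge heights
                # telescopes to 2x the total within-cluster sum of squares
                assert np.sum(tree.merges[:, 2] ** 2) == pytest.approx(
                    np.sum(np.square(heights)), abs=1e-8
                )
            else:
                assert sorted(tree.merges[:, 2]) == pytest.approx(
                    sorted(heights), abs=1e-8
                )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]))


class TestTreeExport:
    def tree(self, rows, samples):
        return ward_cluster(binary_distance(matrix(rows, samples)))

    def test_two_leaf_newick(self):
        t = self.tree([[1], [0]], ["A", "B"])
        assert tree_to_newick(t) == "(A:1,B:1);"

    def test_edge_count_is_2n_minus_2(self):
        rng = np.random.default_rng(15)
        for n in (3, 5, 8):
            rows = rng.integers(0, 2, size=(n, 15)).tolist()
            t = self.tree(rows, [f"s{i}" for i in range(n)])
            assert len(tree_to_edges(t)) == 2 * n - 2

    def test_newick_round_trip_preserves_topology(self):
        import skbio

        rng = np.random.default_rng(16)
        rows = rng.integers(0, 2, size=(6, 20)).tolist()
        labels = [f"s{i}" for i in range(6)]
        t = self.tree(rows, labels)
        parsed = skbio.TreeNode.read([tree_to_newick(t)])
        assert sorted(tip.name for tip in parsed.tips()) == sorted(labels)
        # sibling sets of the first merge survive the round trip
        first = {labels[int(t.merges[0, 0])], labels[int(t.merges[0, 1])]}
        tip_a = parsed.find(list(first)[0])
        siblings = {tip.name for tip in tip_a.parent.tips()}
        assert first <= siblings


class TestLengthCorrelation:
    def test_exactly_proportional_counts_give_r_one(self):
        lengths = {f"c{i}": (i + 1) * 10**6 for i in range(6)}
        counts = {f"c{i}": (i + 1) * 3 for i in range(6)}
        r, p, n = length_correlation(counts, lengths)
        assert r == pytest.approx(1.0)
        assert n == 6

    def test_perfect_anticorrelation(self):
        lengths = {"a": 1, "b": 2, "c": 3}
        counts = {"a": 6, "b": 4, "c": 2}
        r, p, _ = length_correlation(counts, lengths)
        assert r == pytest.approx(-1.0)

    def test_matches_independent_statistical_reference(self):
        # frozen values from R cor.test on the same 10-point fixture
        x = [12.3, 45.1, 7.7, 88.2, 30.0, 51.9, 19.4, 66.6, 24.8, 40.2]
        y = [3, 11, 2, 16, 9, 12, 4, 13, 8, 10]
        lengths = {f"c{i:02d}": xi for i, xi in enumerate(x)}
        counts = {f"c{i:02d}": yi for i, yi in enumerate(y)}
        r, p, n = length_correlation(counts, lengths)
        assert r == pytest.approx(0.955860914133, abs=1e-9)
        assert p == pytest.approx(1.574273661383e-05, rel=1e-6)

    def test_affine_transform_gives_sign_of_slope(self):
        lengths = {f"c{i}": float(i + 1) for i in range(8)}
        for a in (2.5, -1.5):
            counts = {c: a * l + 7 for c, l in lengths.items()}
            r, _, _ = length_correlation(counts, lengths)
            assert r == pytest.approx(np.sign(a))


class TestTranscriptProximity:
    def cluster(self, start, end, chrom="chr1"):
        return IntervalCluster(interval=GenomicInterval(chrom, start, end))

    def tx(self, start, end, tid="t1", gid="g1", chrom="chr1"):
        return Transcript(gid, tid, GenomicInterval(chrom, start, end))

    def test_cluster_inside_transcript_distance_zero(self):
        df = transcript_proximity(
            [self.cluster(150, 160)], [self.tx(100, 200)]
        )
        assert df.loc[0, "distance"] == 0 and df.loc[0, "within"]

    def test_exact_5kb_gap_is_within(self):
        df = transcript_proximity(
            [self.cluster(0, 1000)], [self.tx(6000, 7000)]
        )
        assert df.loc[0, "distance"] == 5000 and df.loc[0, "within"]

    def test_5001_gap_is_not_within(self):
        df = transcript_proximity(
            [self.cluster(0, 1000)], [self.tx(6001, 7000)]
        )
        assert df.loc[0, "distance"] == 5001 and not df.loc[0, "within"]

    def test_fraction_invariant_to_transcript_order(self):
        clusters = [self.cluster(0, 1000), self.cluster(50_000, 51_000)]
        txs = [self.tx(2000, 3000, "t1"), self.tx(90_000, 91_000, "t2")]
        a = proximity_fraction(transcript_proximity(clusters, txs))
        b = proximity_fraction(transcript_proximity(clusters, txs[::-1]))
        assert a == b == 0.5


class TestTranscribedFraction:
    def tx(self, start, end, tid, gid):
        return Transcript(gid, tid, GenomicInterval("chr1", start, end))

    def test_single_transcript_fraction(self):
        assert transcribed_fraction(
            [self.tx(100, 510, "t1", "g1")], 1000
        ) == pytest.approx(0.41)

    def test_no_transcripts_gives_zero(self):
        assert transcribed_fraction([], 1000) == 0.0

    def test_longest_transcript_per_gene_counted_once(self):
        txs = [self.tx(0, 100, "t1", "g1"), self.tx(200, 400, "t2", "g1")]
        assert transcribed_fraction(txs, 1000) == pytest.approx(0.2)
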