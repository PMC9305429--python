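"""p-distance, UPGMA construction and bootstrap support."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from lavauth import (
    DistanceMatrix,
    bootstrap_support,
    build_upgma,
    p_distance,
    p_distance_matrix,
    upgma_with_support,
)

from oracles import exact_bootstrap_support, upgma_oracle


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("ACNT", "ACGA", 1 / 3),  # N site excluded from both counts
            ("acgt", "ACGA", 0.25),  # case-insensitive
        ],
    )
    def test_known_values(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGTN"), size=50))
            b = "".join(rng.choice(list("ACGTN"), size=50))
            if any(x in "ACGT" and y in "ACGT" for x, y in zip(a, b)):
                assert p_distance(a, b) == p_distance(b, a)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="align"):
            p_distance("ACGT", "ACG")

    def test_no_comparable_positions_rejected(self):
        with pytest.raises(ValueError):
            p_distance("NNNN", "ACGT")


def _tree_merges(tree):
    return {(node.leaf_set(), round(node.height, 12)) for node in tree.internal_nodes()}


class TestUPGMA:
    def test_two_taxa_cherry(self):
        d = DistanceMatrix(labels=["A", "B"], values=np.array([[0, 0.01], [0.01, 0]]))
        tree = build_upgma(d)
        assert tree.height == pytest.approx(0.005)
        assert tree.leaf_set() == frozenset({"A", "B"})

    def test_zero_distance_pair_joined_first_at_height_zero(self):
        labels = ["A", "B", "C"]
        values = np.array([[0, 0.0, 0.2], [0.0, 0, 0.2], [0.2, 0.2, 0]])
        tree = build_upgma(DistanceMatrix(labels=labels, values=values))
        cherry = min(tree.internal_nodes(), key=lambda n: n.height)
        assert cherry.leaf_set() == frozenset({"A", "B"})
        assert cherry.height == 0.0

    @pytest.mark.parametrize("n_taxa", [3, 4, 5, 6])
    def test_matches_brute_force_oracle(self, n_taxa):
        """Topology and node heights equal the naive recompute-from-scratch oracle."""
        for seed in range(25):
            rng = np.random.default_rng(1000 * n_taxa + seed)
            raw = rng.uniform(0.001, 0.5, size=(n_taxa, n_taxa))
            values = (raw + raw.T) / 2
            np.fill_diagonal(values, 0.0)
            labels = [f"t{i}" for i in range(n_taxa)]
            tree = build_upgma(DistanceMatrix(labels=labels, values=values))
            expected = upgma_oracle(labels, values.tolist())
            got = {(leaves, round(h, 12)) for leaves, h in
                   ((n.leaf_set(), n.height) for n in tree.internal_nodes())}
            want = {(leaves, round(h, 12)) for leaves, h in expected}
            assert got == want

    def test_matches_scipy_average_linkage(self):
        """Independent cross-check against scipy's UPGMA on tie-free matrices."""
        rng = np.random.default_rng(5)
        n = 7
        raw = rng.uniform(0.01, 0.6, size=(n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        labels = [f"t{i}" for i in range(n)]
        tree = build_upgma(DistanceMatrix(labels=labels, values=values))
        merges = linkage(squareform(values), method="average")
        scipy_heights = sorted(merges[:, 2] / 2.0)
        own_heights = sorted(node.height for node in tree.internal_nodes())
        assert np.allclose(own_heights, scipy_heights)
        # clade sets must agree too
        clusters = {i: frozenset([labels[i]]) for i in range(n)}
        scipy_clades = set()
        for idx, (a, b, _, _) in enumerate(merges):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + idx] = merged
            scipy_clades.add(merged)
        assert tree.clades() == scipy_clades

    def test_trees_are_ultrametric_with_monotone_heights(self, amplicons):
        from lavauth import concatenate_markers

        concat = concatenate_markers(amplicons, ["B1", "B2", "Lav"])
        tree = build_upgma(p_distance_matrix(concat.sequences))
        assert tree.is_ultrametric()
        for node in tree.internal_nodes():
            for child in node.children:
                assert child.height <= node.height + 1e-12

    def test_constant_shift_preserves_topology(self):
        rng = np.random.default_rng(11)
        n = 6
        raw = rng.uniform(0.05, 0.4, size=(n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        labels = [f"t{i}" for i in range(n)]
        shifted = values + 0.1
        np.fill_diagonal(shifted, 0.0)
        t1 = build_upgma(DistanceMatrix(labels=labels, values=values))
        t2 = build_upgma(DistanceMatrix(labels=labels, values=shifted))
        assert t1.clades() == t2.clades()

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["A", "B"], values=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["A", "B"], values=np.array([[0, -1], [-1, 0]]))
        with pytest.raises(ValueError):
            build_upgma(DistanceMatrix(labels=["A"], values=np.zeros((1, 1))))


class TestBootstrap:
    def test_identical_pair_cherry_gets_full_support(self):
        alignment = {"a": "ACGTACGTAC", "b": "ACGTACGTAC", "c": "GTACTTGCAG"}
        supports = bootstrap_support(alignment, n_replicates=200, seed=0)
        assert supports[frozenset({"a", "b"})] == 100.0

    def test_seed_reproducibility_and_range(self, amplicons):
        from lavauth import concatenate_markers

        concat = concatenate_markers(amplicons, ["B1", "B2"])
        s1 = bootstrap_support(concat.sequences, n_replicates=100, seed=123)
        s2 = bootstrap_support(concat.sequences, n_replicates=100, seed=123)
        assert s1 == s2
        assert all(0.0 <= v <= 100.0 for v in s1.values())
        s3 = bootstrap_support(concat.sequences, n_replicates=100, seed=124)
        assert set(s3) == set(s1)  # same original-tree clades

    def test_matches_exhaustive_resampling_distribution(self):
        """Support at n=1000 is within 3 points of the exact enumeration."""
        alignment = {"a": "AAAAAT", "b": "AAATTT", "c": "TTTTTA"}
        clade = frozenset({"a", "b"})
        exact = exact_bootstrap_support(alignment, clade)
        estimated = bootstrap_support(alignment, n_replicates=1000, seed=2)
        assert 0.0 < exact < 100.0  # the toy case is genuinely uncertain
        assert abs(estimated[clade] - exact) <= 3.0

    def test_requires_at_least_two_sequences(self):
        with pytest.raises(ValueError):
            bootstrap_support({"a": "ACGT"}, n_replicates=10, seed=0)

    def test_supports_attached_to_internal_nodes(self, amplicons):
        from lavauth import concatenate_markers

        concat = concatenate_markers(amplicons, ["B1", "B2", "Lav"])
        tree = upgma_with_support(concat.sequences, n_replicates=50, seed=9)
        for node in tree.internal_nodes():
            assert node.support is not None
            assert 0.0 <= node.support <= 100.0
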