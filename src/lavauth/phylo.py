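"""Distances, UPGMA clustering and nonparametric bootstrap support.

The distance model is the uncorrected p-distance (proportion of differing
sites among positions where both sequences carry a concrete A/C/G/T base).
Trees are rooted, binary and ultrametric: every node carries its height in
expected substitutions per site from the leaves, halving the joined-cluster
distance, which is the standard UPGMA construction.  Tie-breaking between
equally close cluster pairs is by the lexicographically smallest pair of
sorted member-label tuples so that results are reproducible across runs.

Bootstrap support resamples alignment columns with replacement, rebuilds the
UPGMA tree for each replicate and reports, for every internal node of the
original tree, the percentage of replicate trees containing a clade with the
identical leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def p_distance(a: str, b: str) -> float:
    """Uncorrected proportion of differing sites between two aligned sequences.

    Positions where either sequence carries anything other than A/C/G/T
    (e.g. N from an ambiguous consensus call) are excluded from both the
    numerator and the denominator.
    """
    if len(a) != len(b):
        raise ValueError(
            "sequences differ in length; align them before computing p-distance"
        )
    a, b = a.upper(), b.upper()
    comparable = 0
    diff = 0
    for x, y in zip(a, b):
        if x in _CODE and y in _CODE:
            comparable += 1
            if x != y:
                diff += 1
    if comparable == 0:
        raise ValueError("no comparable (unambiguous) positions between sequences")
    return diff / comparable


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must have a zero diagonal")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def encode_alignment(sequences: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode same-length sequences as an (n_taxa, n_columns) uint8 array.

    A/C/G/T -> 0..3, anything else -> 4 (excluded from distance computation).
    """
    if not sequences:
        raise ValueError("empty alignment")
    labels = list(sequences)
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must all have the same length")
    arr = np.full((len(labels), lengths.pop()), 4, dtype=np.uint8)
    for i, label in enumerate(labels):
        seq = sequences[label].upper()
        for j, base in enumerate(seq):
            arr[i, j] = _CODE.get(base, 4)
    return labels, arr


def _distances_from_encoded(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    d = np.zeros((n, n))
    valid = arr < 4
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(
                    "no comparable positions between a sequence pair"
                )
            diff = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = diff / comparable
    return d


def p_distance_matrix(sequences: dict[str, str]) -> DistanceMatrix:
    labels, arr = encode_alignment(sequences)
    return DistanceMatrix(labels=labels, values=_distances_from_encoded(arr))


@dataclass
class Clade:
    """Node of a rooted ultrametric tree.

    ``height`` is in expected substitutions per site measured from the leaf
    level; ``support`` is a bootstrap percentage in [0, 100] and is defined
    only for internal nodes.
    """

    name: str | None = None
    height: float = 0.0
    children: list["Clade"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaf_names())
        return out

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_names())

    def internal_nodes(self) -> list["Clade"]:
        if self.is_leaf:
            return []
        out = [self]
        for child in self.children:
            out.extend(child.internal_nodes())
        return out

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes (including the root)."""
        return {node.leaf_set() for node in self.internal_nodes()}

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        def depths(node: Clade) -> list[float]:
            if node.is_leaf:
                return [node.height]
            out = []
            for child in node.children:
                if child.height > node.height + tol:
                    return [float("nan")]
                out.extend(depths(child))
            return out

        leaf_heights = depths(self)
        return all(abs(h - leaf_heights[0]) <= tol for h in leaf_heights)


def build_upgma(d: DistanceMatrix) -> Clade:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Iteratively joins the closest pair of clusters; the distance between
    merged clusters is the size-weighted arithmetic mean of the member
    distances, and the joined node sits at half the join distance.  Among
    equally close pairs the one with the lexicographically smallest pair of
    sorted member-label tuples is joined first.
    """
    if len(d.labels) < 2:
        raise ValueError("UPGMA needs at least two taxa")
    # cluster key -> (node, size); keys are sorted member-label tuples
    clusters: dict[tuple[str, ...], tuple[Clade, int]] = {
        (label,): (Clade(name=label, height=0.0), 1) for label in d.labels
    }
    dist: dict[frozenset[tuple[str, ...]], float] = {}
    keys = sorted(clusters)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            dist[frozenset((ka, kb))] = d.get(ka[0], kb[0])

    while len(clusters) > 1:
        best_pair: tuple[tuple[str, ...], tuple[str, ...]] | None = None
        best_d = float("inf")
        for pair_key, value in dist.items():
            ka, kb = sorted(pair_key)
            if value < best_d or (value == best_d and (ka, kb) < best_pair):
                best_d = value
                best_pair = (ka, kb)
        assert best_pair is not None
        ka, kb = best_pair
        node_a, size_a = clusters.pop(ka)
        node_b, size_b = clusters.pop(kb)
        merged_key = tuple(sorted(ka + kb))
        merged = Clade(height=best_d / 2.0, children=[node_a, node_b])
        # distances to the remaining clusters: size-weighted mean
        new_dist: dict[frozenset[tuple[str, ...]], float] = {}
        for key in clusters:
            da = dist[frozenset((ka, key))]
            db = dist[frozenset((kb, key))]
            new_dist[frozenset((merged_key, key))] = (
                size_a * da + size_b * db
            ) / (size_a + size_b)
        dist = {
            pair: value
            for pair, value in dist.items()
            if ka not in pair and kb not in pair
        }
        dist.update(new_dist)
        clusters[merged_key] = (merged, size_a + size_b)

    (root, _), = clusters.values()
    return root


def upgma_from_sequences(sequences: dict[str, str]) -> Clade:
    return build_upgma(p_distance_matrix(sequences))


def bootstrap_support(
    alignment: dict[str, str], n_replicates: int, seed: int
) -> dict[frozenset[str], float]:
    """Bootstrap clade support for the UPGMA tree of an alignment.

    Columns are sampled with replacement (same alignment length) for each
    replicate; replicate ``r`` draws from its own spawned random substream so
    results are reproducible regardless of evaluation order.  Returns the
    support percentage for every internal-node leaf set of the tree built
    from the original alignment.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(alignment) < 2:
        raise ValueError("bootstrap needs an alignment of >= 2 sequences")
    labels, arr = encode_alignment(alignment)
    n_cols = arr.shape[1]
    original = build_upgma(
        DistanceMatrix(labels=labels, values=_distances_from_encoded(arr))
    )
    targets = original.clades()
    counts = {clade: 0 for clade in targets}
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    for stream in streams:
        rng = np.random.default_rng(stream)
        cols = rng.integers(0, n_cols, size=n_cols)
        replicate_d = _distances_from_encoded(arr[:, cols])
        tree = build_upgma(DistanceMatrix(labels=labels, values=replicate_d))
        found = tree.clades()
        for clade in targets:
            if clade in found:
                counts[clade] += 1
    return {clade: 100.0 * c / n_replicates for clade, c in counts.items()}


def attach_supports(tree: Clade, supports: dict[frozenset[str], float]) -> None:
    """Write bootstrap percentages onto the internal nodes of ``tree``."""
    for node in tree.internal_nodes():
        node.support = supports.get(node.leaf_set())


def upgma_with_support(
    alignment: dict[str, str], n_replicates: int = 1000, seed: int = 0
) -> Clade:
    tree = upgma_from_sequences(alignment)
    attach_supports(tree, bootstrap_support(alignment, n_replicates, seed))
    return tree
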