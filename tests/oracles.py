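"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import itertools
from statistics import mean

from Bio.Data.IUPACData import ambiguous_dna_values


def scan_primer_sites(sequence: str, primer: str, max_mismatches: int):
    """Every (position, mismatches) binding site, by exhaustive offset scan."""
    sequence, primer = sequence.upper(), primer.upper()
    sites = []
    for pos in range(len(sequence) - len(primer) + 1):
        mism = sum(
            base not in ambiguous_dna_values[code]
            for code, base in zip(primer, sequence[pos : pos + len(primer)])
        )
        if mism <= max_mismatches:
            sites.append((pos, mism))
    return sites


def upgma_oracle(labels, matrix):
    """Naive UPGMA recomputing every cluster distance from the leaf matrix.

    Cluster-to-cluster distance is the plain mean over all cross leaf pairs
    (definitionally equivalent to the incremental size-weighted update).
    Tie-break: lexicographically smallest sorted pair of member tuples.
    Returns the set of merges as (frozenset_of_leaves, height) pairs.
    """
    index = {label: i for i, label in enumerate(labels)}

    def leaf_dist(a, b):
        return matrix[index[a]][index[b]]

    clusters = [(label,) for label in sorted(labels)]
    merges = []
    while len(clusters) > 1:
        best_pair, best_d = None, None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = mean(leaf_dist(x, y) for x in a for y in b)
            pair = tuple(sorted((a, b)))
            if best_d is None or d < best_d or (d == best_d and pair < best_pair):
                best_pair, best_d = pair, d
        a, b = best_pair
        clusters.remove(a)
        clusters.remove(b)
        merged = tuple(sorted(a + b))
        clusters.append(merged)
        merges.append((frozenset(merged), best_d / 2.0))
    return merges


def p_distance_oracle(a: str, b: str) -> float:
    pairs = [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x in "ACGT" and y in "ACGT"
    ]
    return sum(x != y for x, y in pairs) / len(pairs)


def exact_bootstrap_support(alignment: dict[str, str], clade: frozenset[str]):
    """Exact probability (%) that column resampling yields ``clade``.

    Enumerates column multisets with their multinomial weights, so it is
    feasible only for alignments of a handful of columns; UPGMA on the
    resampled matrix is delegated to the independent oracle above.
    """
    from math import comb

    labels = sorted(alignment)
    n_cols = len(next(iter(alignment.values())))
    total_prob = 0.0
    hit_prob = 0.0
    for combo in itertools.combinations_with_replacement(range(n_cols), n_cols):
        counts = [combo.count(c) for c in range(n_cols)]
        # multinomial weight of this column multiset under uniform resampling
        weight = 1.0
        remaining = n_cols
        for c in counts:
            weight *= comb(remaining, c)
            remaining -= c
        weight /= n_cols**n_cols
        resampled = {
            label: "".join(alignment[label][c] for c in combo) for label in labels
        }
        matrix = [
            [p_distance_oracle(resampled[x], resampled[y]) for y in labels]
            for x in labels
        ]
        merges = upgma_oracle(labels, matrix)
        total_prob += weight
        if any(leaves == clade for leaves, _ in merges):
            hit_prob += weight
    assert abs(total_prob - 1.0) < 1e-9
    return 100.0 * hit_prob
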