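"""Marker concatenation and identical-sequence (haplotype) discrimination.

A taxon is "fully differentiated" by a marker set when no other taxon in the
panel shares its exact sequence over that set; taxa with bit-identical
sequences fall into multi-member haplotype groups that the markers cannot
resolve.  Identity is conservative: a sequence containing an ambiguous base
(N) is never considered identical to anything, because an ambiguous position
cannot prove identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Concatenation:
    """Per-taxon joined marker sequences with provenance offsets."""

    sequences: dict[str, str]
    boundaries: dict[str, tuple[int, int]]  # marker -> (start, end), half-open
    markers: list[str] = field(default_factory=list)


def concatenate_markers(
    per_marker_sequences: dict[str, dict[str, str]], markers: list[str]
) -> Concatenation:
    """Join each taxon's sequences over ``markers`` in the given order."""
    if not markers:
        raise ValueError("marker list must be nonempty")
    taxa: set[str] = set()
    for marker in markers:
        if marker not in per_marker_sequences:
            raise KeyError(f"no sequences provided for marker {marker!r}")
        taxa.update(per_marker_sequences[marker])
    gaps = [
        (taxon, marker)
        for marker in markers
        for taxon in sorted(taxa)
        if taxon not in per_marker_sequences[marker]
    ]
    if gaps:
        raise ValueError(f"missing (taxon, marker) sequences: {gaps}")
    sequences = {
        taxon: "".join(per_marker_sequences[m][taxon] for m in markers)
        for taxon in sorted(taxa)
    }
    boundaries: dict[str, tuple[int, int]] = {}
    offset = 0
    any_taxon = next(iter(sequences))
    for marker in markers:
        length = len(per_marker_sequences[marker][any_taxon])
        boundaries[marker] = (offset, offset + length)
        offset += length
    return Concatenation(sequences=sequences, boundaries=boundaries, markers=list(markers))


@dataclass
class HaplotypeGroupSet:
    """Partition of taxa into identical-sequence groups for a marker set."""

    marker_set: list[str]
    groups: list[list[str]]
    fully_differentiated: list[str]

    @property
    def n_differentiated(self) -> int:
        return len(self.fully_differentiated)

    @property
    def unresolved_groups(self) -> list[list[str]]:
        return [g for g in self.groups if len(g) > 1]

    def group_of(self, taxon: str) -> list[str]:
        for group in self.groups:
            if taxon in group:
                return group
        raise KeyError(f"taxon {taxon!r} not in any group")

    def to_dict(self) -> dict:
        return {
            "marker_set": self.marker_set,
            "groups": self.groups,
            "fully_differentiated": self.fully_differentiated,
        }


def discrimination_summary(
    sequences: dict[str, str], marker_set: list[str] | None = None
) -> HaplotypeGroupSet:
    """Partition taxa by exact sequence identity.

    Sequences must be the same length (one aligned marker or concatenation).
    Any sequence containing a base outside A/C/G/T is placed in its own
    group regardless of string equality.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must all have the same length")
    buckets: dict[str, list[str]] = {}
    for taxon in sorted(sequences):
        seq = sequences[taxon].upper()
        if set(seq) - set("ACGT"):
            key = f"__ambiguous__{taxon}"  # never identical to anything
        else:
            key = seq
        buckets.setdefault(key, []).append(taxon)
    groups = sorted(buckets.values(), key=lambda g: g[0])
    return HaplotypeGroupSet(
        marker_set=list(marker_set or []),
        groups=groups,
        fully_differentiated=[g[0] for g in groups if len(g) == 1],
    )
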