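"""In-silico PCR: degenerate primer matching, amplicon extraction, read merging.

Primer matching uses IUPAC semantics on the primer side only: an ambiguity
code in the primer is compatible with any concrete base it stands for, while
the template is expected to be concrete (A/C/G/T/N; N on the template never
satisfies a primer position).  All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .markers import IUPAC_BASES, MarkerDefinition


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class PrimerMatch:
    """Best binding site of a primer on one strand of a template."""

    position: int  # 0-based start on the searched strand
    strand: str  # '+' or '-' (set by the caller's search convention)
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.position + self.length


@dataclass(frozen=True)
class Amplicon:
    taxon_id: str
    marker: str
    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("amplicon coordinates inconsistent with sequence length")


@dataclass(frozen=True)
class NoAmplification:
    """Explicit negative PCR result naming the primer that failed to bind."""

    taxon_id: str
    marker: str
    missing_primer: str  # 'forward' or 'reverse'


def _compatible(primer_code: str, template_base: str) -> bool:
    return template_base in IUPAC_BASES.get(primer_code, frozenset())


def match_primer(
    sequence: str,
    primer: str,
    max_mismatches: int,
    *,
    start: int = 0,
    strand: str = "+",
) -> PrimerMatch | None:
    """Find the lowest-mismatch binding site of ``primer`` on ``sequence``.

    Scans every offset >= ``start`` on the given strand; a primer position is
    compatible when the template base is among the bases its IUPAC code
    denotes.  Ties are broken by the smallest position.  Returns ``None``
    when no site has <= ``max_mismatches`` incompatibilities (including the
    case of a primer longer than the sequence).
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    sequence = sequence.upper()
    primer = primer.upper()
    k = len(primer)
    allowed = [IUPAC_BASES.get(c, frozenset()) for c in primer]
    best: PrimerMatch | None = None
    for pos in range(start, len(sequence) - k + 1):
        mism = 0
        window = sequence[pos : pos + k]
        for base, ok in zip(window, allowed):
            if base not in ok:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            if best is None or mism < best.mismatches:
                best = PrimerMatch(position=pos, strand=strand, mismatches=mism, length=k)
                if mism == 0:
                    break
    return best


def in_silico_pcr(
    sequence: str,
    marker: MarkerDefinition,
    max_mismatches: int = 2,
    taxon_id: str = "",
) -> Amplicon | NoAmplification:
    """Amplify ``sequence`` with a marker's primer pair.

    The forward primer is matched on the plus strand; the reverse primer is
    matched as its reverse complement downstream of the forward site.  The
    amplicon spans the first base of the forward site through the last base
    of the reverse site (primers included).
    """
    if not sequence:
        raise ValueError("cannot amplify an empty sequence")
    sequence = sequence.upper()
    fwd = match_primer(sequence, marker.forward_primer, max_mismatches)
    if fwd is None:
        return NoAmplification(taxon_id, marker.name, "forward")
    rev_site = reverse_complement(marker.reverse_primer)
    rev = match_primer(
        sequence, rev_site, max_mismatches, start=fwd.end, strand="-"
    )
    if rev is None:
        return NoAmplification(taxon_id, marker.name, "reverse")
    return Amplicon(
        taxon_id=taxon_id,
        marker=marker.name,
        sequence=sequence[fwd.position : rev.end],
        start=fwd.position,
        end=rev.end,
    )


class MergeError(ValueError):
    """Raised when paired reads share no acceptable overlap."""


def merge_reads(
    forward: str, reverse: str, min_overlap: int = 30, min_identity: float = 0.8
) -> str:
    """Merge a forward/reverse Sanger-style read pair into a consensus.

    The reverse read is reverse-complemented; the suffix(forward) /
    prefix(rc-reverse) overlap with the highest identity (ties: longest) of
    length >= ``min_overlap`` is chosen.  Positions that disagree inside the
    overlap become N.
    """
    if not forward or not reverse:
        raise ValueError("both reads must be nonempty")
    forward = forward.upper()
    rc = reverse_complement(reverse.upper())
    best_k, best_ident = None, -1.0
    for k in range(min_overlap, min(len(forward), len(rc)) + 1):
        suffix = forward[-k:]
        prefix = rc[:k]
        ident = sum(a == b for a, b in zip(suffix, prefix)) / k
        if ident >= best_ident:  # prefer longer overlap on ties
            best_k, best_ident = k, ident
    if best_k is None or best_ident < min_identity:
        raise MergeError(
            f"no overlap of >= {min_overlap} bases with >= "
            f"{min_identity:.0%} identity between the read pair"
        )
    overlap = "".join(
        a if a == b else "N" for a, b in zip(forward[-best_k:], rc[:best_k])
    )
    return forward[:-best_k] + overlap + rc[best_k:]
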