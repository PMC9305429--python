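"""Barcode marker definitions.

Three loci are used for *Lavandula* authentication: the plastid rbcL gene and
trnH-psbA intergenic spacer (universal plant barcodes, degenerate primers) and
a genus-specific nuclear ITS marker.  Primer strings are written 5'->3' in
IUPAC nucleotide code; the reverse primer anneals to the plus strand as its
reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values

#: IUPAC code -> set of concrete bases it stands for (e.g. W -> {A, T}).
IUPAC_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}


@dataclass(frozen=True)
class MarkerDefinition:
    """A barcode locus with its primer pair and expected amplicon length."""

    name: str
    locus: str
    forward_primer: str
    reverse_primer: str

    def __post_init__(self) -> None:
        for primer in (self.forward_primer, self.reverse_primer):
            bad = set(primer.upper()) - set(IUPAC_BASES)
            if bad:
                raise ValueError(
                    f"primer for marker {self.name!r} contains non-IUPAC "
                    f"characters: {sorted(bad)}"
                )


B1 = MarkerDefinition(
    name="B1",
    locus="rbcL",
    forward_primer="AGACCTWTTTGAAGAAGGTTCWGT",
    reverse_primer="TCGGTYAGAGCRGGCATRTGCCA",
)

B2 = MarkerDefinition(
    name="B2",
    locus="trnH-psbA",
    forward_primer="GTTATGCATGAACGTAATGCTC",
    reverse_primer="CGCGCATGGTGGATTCACAATCC",
)

LAV = MarkerDefinition(
    name="Lav",
    locus="ITS",
    forward_primer="CTGCGGAAGGATCATTGT",
    reverse_primer="TTGATATGCTTAAACTCAGC",
)

DEFAULT_MARKERS: dict[str, MarkerDefinition] = {m.name: m for m in (B1, B2, LAV)}

#: Expected amplicon sizes (bp, primers included) on the reference panel.
DEFAULT_AMPLICON_LENGTHS: dict[str, int] = {"B1": 690, "B2": 273, "Lav": 490}
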