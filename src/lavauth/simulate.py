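"""Synthetic 11-taxon fixture panel.

Emulates the study panel of ten *Lavandula* accessions plus the outgroup
*Perovskia atriplicifolia*.  No reference sequences are deposited for these
accessions, so marker sequences are random DNA constrained to the published
identity structure: per marker set, taxa sharing a haplotype class carry
bit-identical amplicons, while distinct classes differ at a controlled number
of sites.  Likewise, peak tables are synthesized directly from each taxon's
chemotaxonomic criteria profile, with retention-time jitter and off-library
noise peaks as the only realism knobs.

Haplotype classes (identical-sequence groups) encoded in the panel:

  rbcL + trnH-psbA:  A = {White, Abrial, Grosso}, B = {Blue, latifolia},
                     C = {allardi, dentata}; all others singletons.
  ITS:               D = {White, Blue, Abrial, Grosso},
                     E = {allardi, dentata}; all others singletons.

The generator is the ground truth for parameter-recovery tests: the full
pipeline run on its output must recover exactly these partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chemo import (
    DEPSIDE_IDS,
    DITERPENE_IDS,
    ChemotaxonomicKey,
    CompoundLibrary,
    CriteriaProfile,
    PeakTable,
    load_chemokey,
    load_compound_library,
)
from .markers import DEFAULT_AMPLICON_LENGTHS, DEFAULT_MARKERS, IUPAC_BASES, MarkerDefinition
from .pcr import reverse_complement

BASES = "ACGT"


@dataclass(frozen=True)
class TaxonSpec:
    """One panel member with its encoded genetic classes and chemistry row."""

    taxon_id: str
    species: str
    cultivar: str
    genetic_class_b1b2: str
    genetic_class_its: str

    def genetic_class(self, marker_name: str) -> str:
        return self.genetic_class_b1b2 if marker_name in ("B1", "B2") else self.genetic_class_its


def _singleton(taxon_id: str) -> str:
    return f"singleton-{taxon_id}"


PANEL: list[TaxonSpec] = [
    TaxonSpec("ang_white", "Lavandula angustifolia", "White", "A", "D"),
    TaxonSpec("ang_blue", "Lavandula angustifolia", "Blue", "B", "D"),
    TaxonSpec("int_abrial", "Lavandula x intermedia", "Abrial", "A", "D"),
    TaxonSpec("int_grosso", "Lavandula x intermedia", "Grosso", "A", "D"),
    TaxonSpec("allardi", "Lavandula allardi", "", "C", "E"),
    TaxonSpec("canariensis", "Lavandula canariensis", "", _singleton("canariensis"), _singleton("canariensis")),
    TaxonSpec("dentata", "Lavandula dentata", "", "C", "E"),
    TaxonSpec("latifolia", "Lavandula latifolia", "", "B", _singleton("latifolia")),
    TaxonSpec("pinnata", "Lavandula pinnata", "", _singleton("pinnata"), _singleton("pinnata")),
    TaxonSpec("stoechas", "Lavandula stoechas", "Pedunculata", _singleton("stoechas"), _singleton("stoechas")),
    TaxonSpec("perovskia", "Perovskia atriplicifolia", "", _singleton("perovskia"), _singleton("perovskia")),
]


def encoded_partition(taxa: list[TaxonSpec], marker_names: list[str]) -> list[list[str]]:
    """The haplotype partition a marker set encodes (ground truth)."""
    buckets: dict[tuple[str, ...], list[str]] = {}
    for taxon in taxa:
        key = tuple(taxon.genetic_class(m) for m in marker_names)
        buckets.setdefault(key, []).append(taxon.taxon_id)
    return sorted((sorted(g) for g in buckets.values()), key=lambda g: g[0])


@dataclass
class GeneratorConfig:
    """Tunable fixture parameters; the defaults reproduce the study panel."""

    seed: int = 0
    amplicon_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_AMPLICON_LENGTHS)
    )
    flank_length: int = 60
    between_class_divergence: float = 0.02
    within_class_divergence: float = 0.0  # fixed: classes are identical-sequence groups
    read_error_rate: float = 0.0
    n_noise_peaks: int = 5
    rt_jitter_sd: float = 0.01  # minutes
    rt_window: tuple[float, float] = (0.5, 19.5)
    noise_rt_min_gap: float = 0.15  # >= 3 matching-tolerance widths
    major_area: float = 1000.0
    minor_area: float = 20.0
    noise_area: float = 10.0
    area_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.within_class_divergence != 0:
            raise ValueError(
                "within_class_divergence is fixed at 0: haplotype classes are "
                "defined by exact sequence identity"
            )
        if not 0 < self.between_class_divergence < 1:
            raise ValueError("between_class_divergence must be in (0, 1)")
        if self.read_error_rate < 0 or self.read_error_rate >= 1:
            raise ValueError("read_error_rate must be in [0, 1)")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _resolve_degenerate(primer: str, rng: np.random.Generator) -> str:
    """One concrete (seeded) resolution of a primer's IUPAC ambiguity codes."""
    return "".join(rng.choice(sorted(IUPAC_BASES[c])) for c in primer.upper())


def _mutate(core: str, rate: float, rng: np.random.Generator) -> str:
    n_subs = max(1, int(round(rate * len(core))))
    positions = rng.choice(len(core), size=n_subs, replace=False)
    seq = list(core)
    for pos in positions:
        seq[pos] = rng.choice([b for b in BASES if b != seq[pos]])
    return "".join(seq)


def _marker_rng(config: GeneratorConfig, marker: MarkerDefinition) -> np.random.Generator:
    index = {"B1": 0, "B2": 1, "Lav": 2}.get(marker.name, 97)
    return np.random.default_rng([config.seed, index])


def make_marker_references(
    config: GeneratorConfig, taxa: list[TaxonSpec], marker: MarkerDefinition
) -> dict[str, str]:
    """Genomic-context reference sequences for one marker across the panel.

    Each reference is 5'flank + forward-primer site + class core +
    reverse-complemented reverse-primer site + 3'flank, with the
    primer-to-primer span equal to the configured amplicon length.  Taxa
    sharing a haplotype class receive bit-identical amplicons; distinct
    classes differ at >= 1 core site.
    """
    rng = _marker_rng(config, marker)
    length = config.amplicon_lengths[marker.name]
    fwd_site = _resolve_degenerate(marker.forward_primer, rng)
    rev_site = reverse_complement(_resolve_degenerate(marker.reverse_primer, rng))
    core_length = length - len(fwd_site) - len(rev_site)
    if core_length <= 0:
        raise ValueError(
            f"amplicon length {length} for {marker.name} is shorter than the "
            f"combined primer lengths"
        )
    base_core = _random_dna(rng, core_length)
    classes = sorted({t.genetic_class(marker.name) for t in taxa})
    cores: dict[str, str] = {}
    for cls in classes:
        while True:
            candidate = _mutate(base_core, config.between_class_divergence, rng)
            if candidate not in cores.values():
                cores[cls] = candidate
                break
    flank5 = _random_dna(rng, config.flank_length)
    flank3 = _random_dna(rng, config.flank_length)
    return {
        t.taxon_id: flank5 + fwd_site + cores[t.genetic_class(marker.name)] + rev_site + flank3
        for t in taxa
    }


def make_read_pairs(
    reference: str,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Simulate a forward/reverse Sanger read pair covering ``reference``.

    The forward read covers the 5' ~60% and the reverse read is the reverse
    complement of the 3' ~60%, guaranteeing a long overlap.  Per-base errors
    at ``read_error_rate`` are injected only outside the overlap core, so a
    correct consensus is always recoverable.
    """
    if not reference:
        raise ValueError("reference must be nonempty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    length = len(reference)
    read_len = max(int(np.ceil(0.6 * length)), min(length, 40))
    overlap_start = length - read_len
    overlap_end = read_len
    forward = list(reference[:read_len])
    reverse_plus = list(reference[overlap_start:])
    if config.read_error_rate > 0:
        for i in range(len(forward)):
            if i < overlap_start and rng.random() < config.read_error_rate:
                forward[i] = rng.choice([b for b in BASES if b != forward[i]])
        for i in range(len(reverse_plus)):
            if overlap_start + i >= overlap_end and rng.random() < config.read_error_rate:
                reverse_plus[i] = rng.choice([b for b in BASES if b != reverse_plus[i]])
    return "".join(forward), reverse_complement("".join(reverse_plus))


def _jittered(value: float, cv: float, rng: np.random.Generator) -> float:
    return float(value * max(0.1, 1.0 + rng.normal(0.0, cv))) if cv > 0 else float(value)


def make_peak_table(
    taxon: TaxonSpec,
    library: CompoundLibrary,
    config: GeneratorConfig,
    key: ChemotaxonomicKey | None = None,
    rng: np.random.Generator | None = None,
) -> PeakTable:
    """Synthesize one sample's peak table from its criteria-key row.

    Compounds required present by the taxon's profile get a peak at the
    library retention time (plus Gaussian jitter) at major or trace area as
    the criterion demands; required-absent compounds are omitted; noise
    peaks land >= ``noise_rt_min_gap`` minutes from every library entry.
    """
    if key is None:
        key = load_chemokey()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    row = key.by_taxon.get(taxon.taxon_id)
    if row is None:
        raise ValueError(f"taxon {taxon.taxon_id!r} has no row in the chemotaxonomic key")
    profile: CriteriaProfile = row.profile

    emit: dict[int, float] = {}  # compound_id -> area tier
    if profile.c1:
        emit[8] = config.major_area
        emit[14] = config.major_area
        emit[21] = config.major_area  # coumaric-acid relative co-occurs with 8/14
    if profile.c2:
        emit[53] = config.major_area
    if profile.c3:
        emit[15] = config.major_area
        emit[16] = config.major_area
    elif not profile.c4:
        emit[15] = config.minor_area  # exactly one of {15,16}: neither c3 nor c4
    if row.cluster == 2:
        emit[37] = config.major_area  # flavone marker of the allardi/dentata/latifolia group
    if profile.c5:
        for cid in DEPSIDE_IDS:
            emit[cid] = config.minor_area
    if profile.c6:
        emit[93] = config.minor_area
    if profile.c7:
        for cid in DITERPENE_IDS:
            emit[cid] = config.minor_area

    missing = [cid for cid in emit if cid not in library.by_id]
    if missing:
        raise ValueError(f"profile references compounds missing from library: {missing}")

    records = []
    for cid, area in sorted(emit.items()):
        rt = library.by_id[cid].retention_time
        if config.rt_jitter_sd > 0:
            rt += float(rng.normal(0.0, config.rt_jitter_sd))
        records.append({"rt": rt, "area": _jittered(area, config.area_cv, rng)})
    library_rts = np.array([c.retention_time for c in library.entries])
    added = 0
    while added < config.n_noise_peaks:
        rt = float(rng.uniform(*config.rt_window))
        if np.abs(library_rts - rt).min() >= config.noise_rt_min_gap:
            records.append({"rt": rt, "area": _jittered(config.noise_area, config.area_cv, rng)})
            added += 1
    peaks = pd.DataFrame(records, columns=["rt", "area"]).sort_values("rt").reset_index(drop=True)
    return PeakTable(sample_id=taxon.taxon_id, peaks=peaks)


@dataclass
class FixtureSet:
    """Everything one simulated study run produces, in memory."""

    config: GeneratorConfig
    taxa: list[TaxonSpec]
    references: dict[str, dict[str, str]]  # marker -> taxon -> sequence
    read_pairs: dict[str, dict[str, tuple[str, str]]]  # marker -> taxon -> (F, R)
    peak_tables: dict[str, PeakTable]  # taxon -> peaks
    library: CompoundLibrary
    key: ChemotaxonomicKey


def generate_fixture_set(
    config: GeneratorConfig, taxa: list[TaxonSpec] | None = None
) -> FixtureSet:
    """Generate the full panel: references, read pairs and peak tables."""
    if taxa is None:
        taxa = PANEL
    library = load_compound_library()
    key = load_chemokey()
    references: dict[str, dict[str, str]] = {}
    read_pairs: dict[str, dict[str, tuple[str, str]]] = {}
    for name, marker in DEFAULT_MARKERS.items():
        refs = make_marker_references(config, taxa, marker)
        references[name] = refs
        pair_rng = np.random.default_rng([config.seed, 10 + {"B1": 0, "B2": 1, "Lav": 2}[name]])
        read_pairs[name] = {
            taxon: make_read_pairs(ref, config, rng=pair_rng) for taxon, ref in refs.items()
        }
    chem_rng = np.random.default_rng([config.seed, 20])
    peak_tables = {
        t.taxon_id: make_peak_table(t, library, config, key=key, rng=chem_rng) for t in taxa
    }
    return FixtureSet(
        config=config,
        taxa=list(taxa),
        references=references,
        read_pairs=read_pairs,
        peak_tables=peak_tables,
        library=library,
        key=key,
    )


def zero_noise_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Config with no RT jitter, no noise peaks and error-free reads."""
    params = dict(rt_jitter_sd=0.0, n_noise_peaks=0, read_error_rate=0.0, area_cv=0.0)
    params.update(overrides)
    return replace(GeneratorConfig(seed=seed), **params)


def write_fixture_set(fixtures: FixtureSet, outdir: str | Path) -> dict:
    """Write FASTA/CSV fixture files plus a manifest JSON; returns the manifest."""
    from .io import write_fasta
    from .chemo import write_peak_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    for marker, refs in fixtures.references.items():
        path = outdir / f"references_{marker}.fasta"
        write_fasta([(f"{taxon}|{marker}", seq) for taxon, seq in refs.items()], path)
        files.append(path.name)
        reads_path = outdir / f"reads_{marker}.fasta"
        records = []
        for taxon, (fwd, rev) in fixtures.read_pairs[marker].items():
            records.append((f"{taxon}|{marker}|F", fwd))
            records.append((f"{taxon}|{marker}|R", rev))
        write_fasta(records, reads_path)
        files.append(reads_path.name)
    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for taxon, table in fixtures.peak_tables.items():
        path = peaks_dir / f"{taxon}.csv"
        write_peak_table(table, path)
        files.append(f"peaks/{path.name}")
    library_path = outdir / "compound_library.csv"
    fixtures.library.to_frame().to_csv(library_path, index=False)
    files.append(library_path.name)
    manifest = {
        "seed": fixtures.config.seed,
        "n_taxa": len(fixtures.taxa),
        "markers": list(fixtures.references),
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
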