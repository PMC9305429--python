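"""End-to-end pipeline: simulate -> barcode -> chemotype -> authenticate.

Each stage is a thin orchestration over the library modules so that the CLI,
the examples and the test suite all exercise the same code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

from . import chemo
from .combine import AuthenticationVerdict, PanelReport, authenticate, panel_report
from .haplotypes import HaplotypeGroupSet, concatenate_markers, discrimination_summary
from .io import RunConfig, write_newick
from .markers import DEFAULT_MARKERS
from .pcr import Amplicon, NoAmplification, in_silico_pcr, merge_reads
from .phylo import Clade, upgma_with_support
from .simulate import FixtureSet, GeneratorConfig, generate_fixture_set

#: The three marker analyses reported for the panel.
MARKER_SETS: dict[str, list[str]] = {
    "B1B2": ["B1", "B2"],
    "Lav": ["Lav"],
    "B1B2Lav": ["B1", "B2", "Lav"],
}


def consensus_from_reads(
    read_pairs: dict[str, tuple[str, str]], min_overlap: int = 30
) -> dict[str, str]:
    """Merge each taxon's forward/reverse pair into a consensus sequence."""
    return {
        taxon: merge_reads(fwd, rev, min_overlap=min_overlap)
        for taxon, (fwd, rev) in read_pairs.items()
    }


def amplify_panel(
    sequences: dict[str, str], marker_name: str, max_mismatches: int = 2
) -> dict[str, str]:
    """In-silico amplicons for every taxon; raises if any taxon fails to amplify."""
    marker = DEFAULT_MARKERS[marker_name]
    amplicons: dict[str, str] = {}
    failures: list[NoAmplification] = []
    for taxon, seq in sequences.items():
        result = in_silico_pcr(seq, marker, max_mismatches=max_mismatches, taxon_id=taxon)
        if isinstance(result, Amplicon):
            amplicons[taxon] = result.sequence
        else:
            failures.append(result)
    if failures:
        detail = ", ".join(f"{f.taxon_id} ({f.missing_primer} primer)" for f in failures)
        raise ValueError(f"no amplification for marker {marker_name}: {detail}")
    return amplicons


@dataclass
class BarcodingResult:
    marker_set: list[str]
    alignment: dict[str, str]
    tree: Clade
    groups: HaplotypeGroupSet


def run_barcoding(
    amplicons_by_marker: dict[str, dict[str, str]],
    markers: list[str],
    bootstrap_replicates: int = 1000,
    seed: int = 0,
) -> BarcodingResult:
    """Concatenate markers, build the supported UPGMA tree and the partition."""
    concat = concatenate_markers(amplicons_by_marker, markers)
    tree = upgma_with_support(
        concat.sequences, n_replicates=bootstrap_replicates, seed=seed
    )
    groups = discrimination_summary(concat.sequences, marker_set=markers)
    return BarcodingResult(
        marker_set=list(markers), alignment=concat.sequences, tree=tree, groups=groups
    )


@dataclass
class ChemoResult:
    assignments: dict[str, chemo.ChemicalAssignment]
    selected_compounds: list[int]


def run_chemotyping(
    peak_tables: dict[str, chemo.PeakTable],
    library: chemo.CompoundLibrary,
    key: chemo.ChemotaxonomicKey,
    rt_tolerance: float = 0.05,
    presence_threshold: float = 0.05,
    max_hamming: int | None = None,
) -> ChemoResult:
    assignments = {}
    for sample_id, table in peak_tables.items():
        matched = chemo.match_peaks(table, library, rt_tolerance=rt_tolerance)
        profile = chemo.evaluate_criteria(matched, library, presence_threshold)
        assignments[sample_id] = chemo.assign_cluster(
            profile, key, max_hamming=max_hamming, sample_id=sample_id
        )
    selected = chemo.select_marker_compounds(
        list(peak_tables.values()), library, presence_threshold, rt_tolerance
    )
    return ChemoResult(assignments=assignments, selected_compounds=selected)


@dataclass
class RunAllResult:
    fixtures: FixtureSet
    amplicons: dict[str, dict[str, str]]  # marker -> taxon -> amplicon sequence
    barcoding: dict[str, BarcodingResult]  # marker-set name -> result
    chemistry: ChemoResult
    verdicts: dict[str, AuthenticationVerdict]
    report: PanelReport


def run_all(
    config: RunConfig,
    outdir: str | Path | None = None,
    from_reads: bool = True,
) -> RunAllResult:
    """Execute the whole study on a simulated panel.

    When ``from_reads`` is set the amplicons are derived by merging the
    simulated read pairs into consensus sequences first (the full wet-lab
    emulation); otherwise the references are amplified directly.
    """
    gen = GeneratorConfig(seed=config.seed)
    gen = replace(
        gen,
        read_error_rate=config.read_error_rate,
        n_noise_peaks=config.n_noise_peaks,
        rt_jitter_sd=config.rt_jitter_sd,
    )
    fixtures = generate_fixture_set(gen)

    amplicons: dict[str, dict[str, str]] = {}
    for marker in fixtures.references:
        if from_reads:
            templates = consensus_from_reads(fixtures.read_pairs[marker])
        else:
            templates = fixtures.references[marker]
        amplicons[marker] = amplify_panel(
            templates, marker, max_mismatches=config.max_primer_mismatches
        )

    barcoding = {
        name: run_barcoding(
            amplicons, markers, config.bootstrap_replicates, seed=config.seed
        )
        for name, markers in MARKER_SETS.items()
    }

    chemistry = run_chemotyping(
        fixtures.peak_tables,
        fixtures.library,
        fixtures.key,
        rt_tolerance=config.rt_tolerance,
        presence_threshold=config.presence_threshold,
        max_hamming=config.max_hamming,
    )

    verdicts = authenticate(
        barcoding["B1B2Lav"].groups, chemistry.assignments, fixtures.key
    )
    report = panel_report(verdicts)

    result = RunAllResult(
        fixtures=fixtures,
        amplicons=amplicons,
        barcoding=barcoding,
        chemistry=chemistry,
        verdicts=verdicts,
        report=report,
    )
    if outdir is not None:
        write_run_outputs(result, outdir)
    return result


def write_run_outputs(result: RunAllResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, bc in result.barcoding.items():
        write_newick(bc.tree, outdir / f"tree_{name}.nwk")
        (outdir / f"discrimination_{name}.json").write_text(
            json.dumps(bc.groups.to_dict(), indent=2)
        )
    (outdir / "chemistry.json").write_text(
        json.dumps(
            {
                "selected_compounds": result.chemistry.selected_compounds,
                "assignments": {
                    s: a.to_dict() for s, a in result.chemistry.assignments.items()
                },
            },
            indent=2,
        )
    )
    (outdir / "verdicts.json").write_text(
        json.dumps({s: v.to_dict() for s, v in result.verdicts.items()}, indent=2)
    )
    (outdir / "panel_report.json").write_text(
        json.dumps(result.report.to_dict(), indent=2)
    )
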