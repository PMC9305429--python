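"""Fusion of genetic and chemical evidence into authentication verdicts.

Genetics is authoritative: a taxon fully differentiated by sequence identity
is resolved regardless of its chemistry, and chemistry may only refine a
multi-member haplotype group, never merge taxa the markers separate.  Within
a haplotype group, the candidate taxa are intersected with the taxa whose
reference chemistry matches the sample's assigned cluster (and, where a
refinement rule applies, its sub-pattern of criteria).  Conflicts — an empty
intersection — are reported, not auto-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chemo import ChemicalAssignment, ChemotaxonomicKey
from .haplotypes import HaplotypeGroupSet


@dataclass(frozen=True)
class RefinementRule:
    """A named within-cluster chemical split.

    The default rule encodes that, inside chemical cluster 1, joint major
    presence of rosmarinic acid (c2) and the cinnamic-acid derivative pair
    (c3) separates the Blue/Grosso chemotype from the White/Abrial one.
    """

    name: str
    cluster: int
    criteria: tuple[str, ...]


DEFAULT_REFINEMENTS: tuple[RefinementRule, ...] = (
    RefinementRule(name="cluster1-rosmarinic-split", cluster=1, criteria=("c2", "c3")),
)


@dataclass
class AuthenticationVerdict:
    sample_id: str
    genetic_group: list[str]
    chemical_cluster: int | None
    resolution: str  # species_resolved | variety_resolved | group_only | conflict
    candidate_taxa: list[str]
    evidence: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "genetic_group": self.genetic_group,
            "chemical_cluster": self.chemical_cluster,
            "resolution": self.resolution,
            "candidate_taxa": self.candidate_taxa,
            "evidence": self.evidence,
        }


def _criterion(profile, name: str) -> bool:
    return bool(getattr(profile, name))


def _chemically_compatible(
    assignment: ChemicalAssignment,
    key: ChemotaxonomicKey,
    refinements: tuple[RefinementRule, ...],
) -> list[str] | None:
    """Taxa whose key row is consistent with the sample's chemistry.

    Returns None when the sample's chemistry is unassigned (no information).
    """
    if assignment.cluster is None:
        return None
    rows = key.taxa_in_cluster(assignment.cluster)
    rules = [r for r in refinements if r.cluster == assignment.cluster]
    compatible = []
    for row in rows:
        ok = True
        for rule in rules:
            for crit in rule.criteria:
                if _criterion(row.profile, crit) != _criterion(assignment.criteria, crit):
                    ok = False
        if ok:
            compatible.append(row.taxon)
    return compatible


def authenticate(
    genetic: HaplotypeGroupSet,
    chemical: dict[str, ChemicalAssignment],
    key: ChemotaxonomicKey,
    refinements: tuple[RefinementRule, ...] = DEFAULT_REFINEMENTS,
) -> dict[str, AuthenticationVerdict]:
    """Merge per-sample genetic groups and chemical assignments."""
    genetic_samples = {t for g in genetic.groups for t in g}
    missing = sorted(genetic_samples ^ set(chemical))
    if missing:
        raise ValueError(f"samples missing from one evidence set: {missing}")

    verdicts: dict[str, AuthenticationVerdict] = {}
    for sample in sorted(genetic_samples):
        group = genetic.group_of(sample)
        assignment = chemical[sample]
        if len(group) == 1:
            evidence = [
                f"unique haplotype over markers {'+'.join(genetic.marker_set)}"
            ]
            if assignment.cluster is None:
                evidence.append(
                    "chemistry unassigned (nearest profile too distant); "
                    "low-confidence corroboration"
                )
            else:
                evidence.append(f"chemical cluster {assignment.cluster}")
            verdicts[sample] = AuthenticationVerdict(
                sample_id=sample,
                genetic_group=group,
                chemical_cluster=assignment.cluster,
                resolution="species_resolved",
                candidate_taxa=[sample],
                evidence=evidence,
            )
            continue

        compatible = _chemically_compatible(assignment, key, refinements)
        if compatible is None:
            candidates = sorted(group)
            resolution = "group_only"
            evidence = ["chemistry unassigned; genetic group not refinable"]
        else:
            candidates = sorted(set(group) & set(compatible))
            if not candidates:
                resolution = "conflict"
                candidates = sorted(group)
                evidence = [
                    f"chemical cluster {assignment.cluster} members "
                    f"{sorted(compatible)} are disjoint from the genetic group"
                ]
            elif len(candidates) == 1:
                resolution = "species_resolved"
                evidence = [
                    f"genetic group {sorted(group)} refined to a single taxon "
                    f"by chemical cluster {assignment.cluster} sub-pattern"
                ]
            else:
                resolution = "group_only"
                evidence = [
                    f"genetic group {sorted(group)} intersected with chemical "
                    f"cluster {assignment.cluster} leaves {candidates}"
                ]
        # rank by chemical Hamming distance to each candidate's key row, then name
        ranked = sorted(
            candidates,
            key=lambda t: (
                assignment.criteria.hamming(key.by_taxon[t].profile)
                if t in key.by_taxon
                else 99,
                t,
            ),
        )
        verdicts[sample] = AuthenticationVerdict(
            sample_id=sample,
            genetic_group=group,
            chemical_cluster=assignment.cluster,
            resolution=resolution,
            candidate_taxa=ranked,
            evidence=evidence,
        )
    return verdicts


@dataclass
class PanelReport:
    n_samples: int
    n_species_resolved: int
    n_species_resolved_by_genetics: int
    n_group_only: int
    n_conflict: int
    unresolved_groups: list[list[str]]

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_species_resolved": self.n_species_resolved,
            "n_species_resolved_by_genetics": self.n_species_resolved_by_genetics,
            "n_group_only": self.n_group_only,
            "n_conflict": self.n_conflict,
            "unresolved_groups": self.unresolved_groups,
        }


def panel_report(verdicts: dict[str, AuthenticationVerdict]) -> PanelReport:
    """Panel-level counts by resolution class plus residual ambiguous groups."""
    if not verdicts:
        raise ValueError("empty verdict set")
    by_class = {"species_resolved": 0, "variety_resolved": 0, "group_only": 0, "conflict": 0}
    by_genetics = 0
    residual: set[tuple[str, ...]] = set()
    for verdict in verdicts.values():
        by_class[verdict.resolution] += 1
        if verdict.resolution == "species_resolved" and len(verdict.genetic_group) == 1:
            by_genetics += 1
        if verdict.resolution in ("group_only", "conflict"):
            residual.add(tuple(sorted(verdict.candidate_taxa)))
    return PanelReport(
        n_samples=len(verdicts),
        n_species_resolved=by_class["species_resolved"] + by_class["variety_resolved"],
        n_species_resolved_by_genetics=by_genetics,
        n_group_only=by_class["group_only"],
        n_conflict=by_class["conflict"],
        unresolved_groups=sorted(list(g) for g in residual),
    )
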