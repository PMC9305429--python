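"""Chemical fingerprinting: peak matching and the chemotaxonomic key.

Observed UHPLC peaks (retention time, area) are matched to a reference
compound library by retention-time proximity, seven presence/absence
criteria are evaluated on the matched areas, and each sample is assigned to
one of six chemical clusters by nearest reference profile.

The criteria, on the matched compound areas of one sample:

  c1  compounds 8 (coumaric acid hexoside) and 14 (ferulic acid hexoside)
      both at major presence (relative area above threshold)
  c2  compound 53 (rosmarinic acid) at major presence
  c3  compounds 15 and 16 (cinnamic-acid derivatives) both present
  c4  neither compound 15 nor 16 present
  c5  depside family present (>= 2 members matched)
  c6  compound 93 (linalyl acetate) present
  c7  diterpene family present (>= 1 member matched)

"Major presence" is a relative-area cutoff (area / total matched area of the
sample, default 5%); criteria 3-7 use simple presence (any matched peak).
Note that c3 and c4 can never both hold, but both are false for a sample
carrying exactly one of compounds 15 and 16.

The packaged compound library carries the reference retention times; the
retention times of compounds 21 and 37 and the individual depside names are
synthetic placements (no published values), chosen well clear of every other
library entry so they cannot perturb matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

DEPSIDE_IDS = (51, 55, 56, 57, 59, 66, 73, 74, 77)
DITERPENE_IDS = (94, 95, 96)


@dataclass(frozen=True)
class Compound:
    compound_id: int
    name: str
    retention_time: float
    family: str

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError("retention_time must be positive")


@dataclass
class CompoundLibrary:
    entries: list[Compound]

    def __post_init__(self) -> None:
        ids = [c.compound_id for c in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("compound_id values must be unique")
        self.by_id = {c.compound_id: c for c in self.entries}

    def family_members(self, family: str) -> list[Compound]:
        return [c for c in self.entries if c.family == family]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compound_id": c.compound_id,
                    "name": c.name,
                    "retention_time": c.retention_time,
                    "family": c.family,
                }
                for c in self.entries
            ]
        )


def _packaged(name: str) -> Path:
    return Path(str(resources.files("lavauth").joinpath("data", name)))


def load_compound_library(path: str | Path | None = None) -> CompoundLibrary:
    """Load the reference compound library (packaged default or a CSV)."""
    frame = pd.read_csv(path if path is not None else _packaged("compound_library.csv"))
    required = {"compound_id", "name", "retention_time", "family"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"library CSV missing columns: {sorted(missing)}")
    return CompoundLibrary(
        entries=[
            Compound(
                compound_id=int(row["compound_id"]),
                name=str(row["name"]),
                retention_time=float(row["retention_time"]),
                family=str(row["family"]),
            )
            for _, row in frame.iterrows()
        ]
    )


@dataclass
class PeakTable:
    """Observed chromatographic peaks of one sample."""

    sample_id: str
    peaks: pd.DataFrame  # columns: rt (min), area; optional mz

    def __post_init__(self) -> None:
        if "rt" not in self.peaks.columns or "area" not in self.peaks.columns:
            raise ValueError("peak table needs 'rt' and 'area' columns")
        if (self.peaks["area"] < 0).any():
            raise ValueError("peak areas must be non-negative")


def read_peak_table(path: str | Path, sample_id: str | None = None) -> PeakTable:
    """Read a peak-table CSV with columns rt_min, area[, mz][, sample_id]."""
    frame = pd.read_csv(path)
    if "rt_min" not in frame.columns or "area" not in frame.columns:
        raise ValueError(f"{path}: peak CSV needs 'rt_min' and 'area' columns")
    if sample_id is None:
        if "sample_id" in frame.columns and len(frame):
            sample_id = str(frame["sample_id"].iloc[0])
        else:
            sample_id = Path(path).stem
    renamed = frame.rename(columns={"rt_min": "rt"})
    peaks = renamed[[c for c in ("rt", "area", "mz") if c in renamed.columns]]
    return PeakTable(sample_id=sample_id, peaks=peaks.reset_index(drop=True))


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    out = table.peaks.rename(columns={"rt": "rt_min"}).copy()
    out.insert(0, "sample_id", table.sample_id)
    out.to_csv(path, index=False)


def match_peaks(
    table: PeakTable, library: CompoundLibrary, rt_tolerance: float = 0.05
) -> dict[int, float]:
    """Match each library compound to the largest-area peak within tolerance.

    One observed peak may serve several compounds whose reference retention
    times collide within tolerance (the library holds two diterpenes at the
    same retention time).  Unmatched compounds get area 0.
    """
    if rt_tolerance <= 0:
        raise ValueError("rt_tolerance must be positive")
    if not library.entries:
        raise ValueError("empty compound library")
    rts = table.peaks["rt"].to_numpy()
    areas = table.peaks["area"].to_numpy()
    matched: dict[int, float] = {}
    for compound in library.entries:
        in_window = abs(rts - compound.retention_time) <= rt_tolerance
        matched[compound.compound_id] = (
            float(areas[in_window].max()) if in_window.any() else 0.0
        )
    return matched


def relative_areas(matched: dict[int, float]) -> dict[int, float]:
    total = sum(matched.values())
    if total == 0:
        return {cid: 0.0 for cid in matched}
    return {cid: area / total for cid, area in matched.items()}


@dataclass(frozen=True)
class CriteriaProfile:
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    c6: bool
    c7: bool

    def __post_init__(self) -> None:
        if self.c3 and self.c4:
            raise ValueError("criteria 3 and 4 are mutually exclusive")

    def as_tuple(self) -> tuple[bool, ...]:
        return (self.c1, self.c2, self.c3, self.c4, self.c5, self.c6, self.c7)

    def hamming(self, other: "CriteriaProfile") -> int:
        return sum(a != b for a, b in zip(self.as_tuple(), other.as_tuple()))

    @classmethod
    def from_sequence(cls, values) -> "CriteriaProfile":
        values = [bool(v) for v in values]
        if len(values) != 7:
            raise ValueError("a criteria profile has exactly 7 entries")
        return cls(*values)


def evaluate_criteria(
    matched: dict[int, float],
    library: CompoundLibrary,
    presence_threshold: float = 0.05,
) -> CriteriaProfile:
    """Evaluate the seven classification criteria on matched compound areas.

    ``presence_threshold`` is the relative-area cutoff for "major presence"
    (criteria 1 and 2); criteria 3-7 require only a nonzero match.
    """
    rel = relative_areas(matched)
    major = lambda cid: rel.get(cid, 0.0) > presence_threshold
    present = lambda cid: matched.get(cid, 0.0) > 0.0
    n_depsides = sum(present(cid) for cid in DEPSIDE_IDS)
    n_diterpenes = sum(present(cid) for cid in DITERPENE_IDS)
    return CriteriaProfile(
        c1=major(8) and major(14),
        c2=major(53),
        c3=present(15) and present(16),
        c4=not present(15) and not present(16),
        c5=n_depsides >= 2,
        c6=present(93),
        c7=n_diterpenes >= 1,
    )


@dataclass(frozen=True)
class KeyRow:
    taxon: str
    species: str
    cluster: int
    profile: CriteriaProfile


@dataclass
class ChemotaxonomicKey:
    """The reference criteria table: 11 taxon profiles with cluster numbers."""

    rows: list[KeyRow]
    max_hamming: int = 2

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("chemotaxonomic key has no rows")
        self.by_taxon = {row.taxon: row for row in self.rows}

    def taxa_in_cluster(self, cluster: int) -> list[KeyRow]:
        return [row for row in self.rows if row.cluster == cluster]

    @property
    def clusters(self) -> list[int]:
        return sorted({row.cluster for row in self.rows})


def load_chemokey(
    path: str | Path | None = None,
    overrides: dict[str, dict[str, bool]] | None = None,
) -> ChemotaxonomicKey:
    """Load the packaged classification key (or a YAML file of the same shape).

    ``overrides`` patches individual criterion cells, e.g.
    ``{"ang_white": {"c6": False}}`` — provided because one column of the
    printed key is typographically uncertain in the source document.
    """
    raw = yaml.safe_load(
        Path(path if path is not None else _packaged("chemokey.yaml")).read_text()
    )
    rows = []
    for entry in raw["rows"]:
        criteria = list(entry["criteria"])
        if overrides and entry["taxon"] in overrides:
            for name, value in overrides[entry["taxon"]].items():
                idx = int(name.lstrip("c")) - 1
                criteria[idx] = bool(value)
        rows.append(
            KeyRow(
                taxon=str(entry["taxon"]),
                species=str(entry["species"]),
                cluster=int(entry["cluster"]),
                profile=CriteriaProfile.from_sequence(criteria),
            )
        )
    return ChemotaxonomicKey(rows=rows, max_hamming=int(raw.get("max_hamming", 2)))


@dataclass
class ChemicalAssignment:
    sample_id: str
    cluster: int | None
    matched_profile_taxon: str
    hamming_distance: int
    criteria: CriteriaProfile

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "cluster": self.cluster,
            "matched_profile_taxon": self.matched_profile_taxon,
            "hamming_distance": self.hamming_distance,
            "criteria": list(self.criteria.as_tuple()),
        }


def assign_cluster(
    profile: CriteriaProfile,
    key: ChemotaxonomicKey,
    max_hamming: int | None = None,
    sample_id: str = "",
) -> ChemicalAssignment:
    """Assign the nearest reference profile's cluster to a criteria profile.

    Ties are broken by the lowest cluster number, then key row order.  The
    cluster is left unassigned when even the nearest profile differs in more
    than ``max_hamming`` criteria.
    """
    if max_hamming is None:
        max_hamming = key.max_hamming
    best = min(
        key.rows,
        key=lambda row: (profile.hamming(row.profile), row.cluster, key.rows.index(row)),
    )
    distance = profile.hamming(best.profile)
    return ChemicalAssignment(
        sample_id=sample_id,
        cluster=best.cluster if distance <= max_hamming else None,
        matched_profile_taxon=best.taxon,
        hamming_distance=distance,
        criteria=profile,
    )


def select_marker_compounds(
    tables: list[PeakTable],
    library: CompoundLibrary,
    presence_threshold: float = 0.05,
    rt_tolerance: float = 0.05,
) -> list[int]:
    """Compounds with significant relative area in at least one sample.

    Returns compound ids whose relative matched area exceeds
    ``presence_threshold`` in >= 1 sample, ranked by maximum relative area
    across the panel (descending).
    """
    if not tables:
        raise ValueError("at least one peak table is required")
    best_rel: dict[int, float] = {c.compound_id: 0.0 for c in library.entries}
    for table in tables:
        rel = relative_areas(match_peaks(table, library, rt_tolerance))
        for cid, value in rel.items():
            best_rel[cid] = max(best_rel[cid], value)
    selected = [cid for cid, value in best_rel.items() if value > presence_threshold]
    return sorted(selected, key=lambda cid: -best_rel[cid])
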