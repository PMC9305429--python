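"""FASTA and Newick readers/writers plus the run configuration.

Newick dialect: branch lengths are parent height minus child height (so the
tree stays ultrametric on re-read), bootstrap supports are written as
internal-node labels, and leaves keep their taxon ids.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import Clade


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records; sequences upper-cased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not a FASTA file")
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate record ids {dupes}")
    out = []
    for record in records:
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {record.id!r} has a blank sequence")
        out.append((record.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq.upper()), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _newick_node(node: Clade, parent_height: float | None) -> str:
    if node.is_leaf:
        label = node.name or ""
        if not label:
            raise ValueError("all leaves must be named to write Newick")
    else:
        label = "" if node.support is None else str(int(round(node.support)))
    if not node.is_leaf:
        inner = ",".join(_newick_node(c, node.height) for c in node.children)
        label = f"({inner}){label}"
    if parent_height is None:
        return label
    return f"{label}:{parent_height - node.height:.10g}"


def tree_to_newick(tree: Clade) -> str:
    return _newick_node(tree, None) + ";"


def write_newick(tree: Clade, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


def parse_newick(text: str) -> Clade:
    """Parse the dialect written by :func:`tree_to_newick` back into a tree."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse_clade() -> tuple[Clade, float]:
        nonlocal pos
        children: list[Clade] = []
        child_edges: list[tuple[Clade, float]] = []
        if text[pos] == "(":
            pos += 1
            while True:
                child, edge = parse_clade()
                child_edges.append((child, edge))
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ":,()":
            pos += 1
        label = text[start:pos]
        edge = 0.0
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            edge = float(text[start:pos])
        if child_edges:
            node = Clade(support=float(label) if label else None)
            children = []
            for child, child_edge in child_edges:
                children.append((child, child_edge))
            node.children = [c for c, _ in children]
            node._child_edges = [e for _, e in children]  # type: ignore[attr-defined]
        else:
            node = Clade(name=label)
        return node, edge

    root, _ = parse_clade()

    def set_heights(node: Clade) -> float:
        """Heights from stored edges; returns node height."""
        if node.is_leaf:
            node.height = 0.0
            return 0.0
        edges = getattr(node, "_child_edges")
        heights = [set_heights(c) + e for c, e in zip(node.children, edges)]
        node.height = max(heights)
        return node.height

    set_heights(root)
    return root


def read_newick(path: str | Path) -> Clade:
    return parse_newick(Path(path).read_text())


@dataclasses.dataclass
class RunConfig:
    """Top-level pipeline parameters; round-trips losslessly through YAML."""

    seed: int = 0
    bootstrap_replicates: int = 1000
    rt_tolerance: float = 0.05
    presence_threshold: float = 0.05
    max_primer_mismatches: int = 2
    max_hamming: int = 2
    read_error_rate: float = 0.0
    n_noise_peaks: int = 5
    rt_jitter_sd: float = 0.01
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if not 0 < self.rt_tolerance <= 1:
            raise ValueError("rt_tolerance must be in (0, 1] minutes")
        if not 0 <= self.presence_threshold < 1:
            raise ValueError("presence_threshold must be in [0, 1)")
        if self.max_primer_mismatches < 0:
            raise ValueError("max_primer_mismatches must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
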