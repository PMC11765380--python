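"""Orthogroup tables and the aging-gene overlap statistic.

An orthogroup is the set of proteins across species descended from one
ancestral gene. Given an orthogroups table (OrthoFinder ``Orthogroups.tsv``
dialect) and a set of human aging-gene protein accessions, the statistic of
interest is, per model species, the number of orthogroups that contain at
least one mapped human aging protein *and* at least one protein of that
species — i.e. how much of the human aging-gene repertoire has a detectable
ortholog there.

For self-contained runs the module also provides a desk-scale orthogroup
inferrer: reciprocal best hits (RBH) under global Needleman-Wunsch alignment
with BLOSUM62 and affine gaps, linked into connected components. This is a
classical ortholog heuristic, not a reimplementation of OrthoFinder's
MCL-based clustering.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import networkx as nx
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "OrthogroupTable",
    "AgingGeneSet",
    "OverlapCount",
    "read_orthogroups_table",
    "write_orthogroups_table",
    "read_symbol_mapping",
    "read_gene_list",
    "map_aging_genes",
    "count_overlap",
    "nw_align_score",
    "infer_orthogroups_rbh",
]

_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class OrthogroupTable:
    """Orthogroup id -> per-species protein identifier lists."""

    species_order: list[str]
    groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def species_proteins(self, species: str) -> set[str]:
        if species not in self.species_order:
            raise KeyError(f"unknown species label: {species!r}")
        return {
            pid for cells in self.groups.values() for pid in cells.get(species, [])
        }


@dataclass(frozen=True)
class AgingGeneSet:
    """Aging-gene symbols and the protein accessions they map to."""

    symbols: frozenset[str]
    accessions: frozenset[str]
    unmapped: tuple[str, ...] = ()


@dataclass(frozen=True)
class OverlapCount:
    """Orthogroup-overlap result for one target species."""

    species: str
    n_orthogroups: int
    orthogroup_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_orthogroups != len(self.orthogroup_ids):
            raise ValueError("n_orthogroups inconsistent with id list")


def _open(source: str | Path | TextIO) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return open(source, encoding="utf-8")


def read_orthogroups_table(source: str | Path | TextIO) -> OrthogroupTable:
    """Read an ``Orthogroups.tsv``-dialect table.

    First column is the orthogroup id, remaining columns one species each;
    cells hold comma-separated protein ids and may be empty. Duplicate group
    ids and ragged rows are rejected.
    """
    stream = _open(source)
    try:
        reader = csv.reader(stream, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration as exc:
            raise ValueError("empty orthogroups table (no header)") from exc
        species = [s.strip() for s in header[1:]]
        table = OrthogroupTable(species_order=species)
        for rownum, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"ragged row {rownum}: {len(row)} fields, expected {len(header)}"
                )
            og_id = row[0].strip()
            if og_id in table.groups:
                raise ValueError(f"duplicate orthogroup id {og_id!r} at row {rownum}")
            cells: dict[str, list[str]] = {}
            for sp, cell in zip(species, row[1:]):
                ids = [p for p in (p.strip() for p in cell.split(",")) if p]
                if len(ids) != len(set(ids)):
                    raise ValueError(
                        f"duplicate protein id within species {sp!r} at row {rownum}"
                    )
                cells[sp] = ids
            table.groups[og_id] = cells
    finally:
        if stream is not source:
            stream.close()
    return table


def write_orthogroups_table(table: OrthogroupTable, dest: str | Path | TextIO) -> None:
    """Serialize in canonical ``Orthogroups.tsv`` form (``, ``-joined cells)."""
    own = not hasattr(dest, "write")
    stream = open(dest, "w", encoding="utf-8") if own else dest
    try:
        stream.write("Orthogroup\t" + "\t".join(table.species_order) + "\n")
        for og_id, cells in table.groups.items():
            row = [og_id] + [
                ", ".join(cells.get(sp, [])) for sp in table.species_order
            ]
            stream.write("\t".join(row) + "\n")
    finally:
        if own:
            stream.close()


def read_symbol_mapping(source: str | Path | TextIO) -> dict[str, list[str]]:
    """Read a symbol -> accession(s) TSV (two columns, repeated symbols allowed)."""
    stream = _open(source)
    mapping: dict[str, list[str]] = {}
    try:
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            symbol = parts[0].strip().upper()
            for acc in parts[1].split(","):
                acc = acc.strip()
                if acc:
                    mapping.setdefault(symbol, []).append(acc)
    finally:
        if stream is not source:
            stream.close()
    return mapping


def read_gene_list(source: str | Path | TextIO) -> list[str]:
    """Read a plain-text gene list, one symbol per line."""
    stream = _open(source)
    try:
        return [ln.strip() for ln in stream if ln.strip() and not ln.startswith("#")]
    finally:
        if stream is not source:
            stream.close()


def map_aging_genes(
    symbols: Iterable[str],
    mapping: Mapping[str, list[str]],
) -> AgingGeneSet:
    """Translate gene symbols to protein accessions, case-insensitively.

    Unmapped symbols are reported on the result, never fatal — published
    aging-gene lists routinely contain symbols missing from any one
    proteome release.
    """
    symbols = [s.strip().upper() for s in symbols if s.strip()]
    if symbols and not mapping:
        raise ValueError("empty symbol->accession mapping with nonempty gene list")
    normalized = {k.upper(): v for k, v in mapping.items()}
    accessions: set[str] = set()
    unmapped: list[str] = []
    for sym in symbols:
        if sym in normalized:
            accessions.update(normalized[sym])
        else:
            unmapped.append(sym)
    return AgingGeneSet(
        symbols=frozenset(symbols),
        accessions=frozenset(accessions),
        unmapped=tuple(sorted(set(unmapped))),
    )


def count_overlap(
    table: OrthogroupTable,
    aging: AgingGeneSet,
    human_label: str,
    target: str,
) -> OverlapCount:
    """Count orthogroups holding >=1 aging human protein and >=1 target protein."""
    for label in (human_label, target):
        if label not in table.species_order:
            raise KeyError(f"unknown species label: {label!r}")
    hits = sorted(
        og_id
        for og_id, cells in table.groups.items()
        if aging.accessions.intersection(cells.get(human_label, []))
        and cells.get(target, [])
    )
    return OverlapCount(target, len(hits), tuple(hits))


def _aligner(matrix: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Affine convention: a gap of length k costs gap_open + k * gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def nw_align_score(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 10,
    gap_extend: int = 1,
) -> int:
    """Global alignment score with affine gaps (first gap residue costs
    ``gap_open + gap_extend``, each further residue ``gap_extend``)."""
    for name, seq in (("first", a), ("second", b)):
        for pos, ch in enumerate(seq, start=1):
            if ch not in _AMINO_ACIDS:
                raise ValueError(
                    f"illegal amino-acid character {ch!r} at position {pos} "
                    f"of {name} sequence"
                )
    if not a and not b:
        return 0
    return int(_aligner(matrix, gap_open, gap_extend).score(a, b))


def _load_proteome(value: Mapping[str, str] | str | Path) -> dict[str, str]:
    if isinstance(value, (str, Path)):
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(value), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate protein id {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
        return seqs
    return dict(value)


def infer_orthogroups_rbh(
    proteomes: Mapping[str, Mapping[str, str] | str | Path],
    matrix: str = "BLOSUM62",
    gap_open: int = 10,
    gap_extend: int = 1,
) -> OrthogroupTable:
    """Infer orthogroups by reciprocal best hits + connected components.

    For every ordered species pair, each query's best hit is its
    highest-scoring target (ties broken by lexicographically smallest target
    id). Pairs that are each other's best hits form edges; orthogroups are
    the connected components with at least two proteins. Deterministic in
    the input contents and invariant to input ordering.

    ``proteomes`` maps species label to either an ``{id: sequence}`` mapping
    or a FASTA path.
    """
    seqs = {sp: _load_proteome(val) for sp, val in proteomes.items()}
    for sp, prot in seqs.items():
        for pid, seq in prot.items():
            if not seq:
                raise ValueError(f"empty sequence for {pid!r} in {sp!r}")
    species = sorted(seqs)
    aligner = _aligner(matrix, gap_open, gap_extend)

    def best_hit(query_seq: str, targets: dict[str, str]) -> str | None:
        best_id, best_score = None, None
        for tid in sorted(targets):
            score = aligner.score(query_seq, targets[tid])
            if best_score is None or score > best_score:
                best_id, best_score = tid, score
        return best_id

    graph = nx.Graph()
    for sp, prot in seqs.items():
        graph.add_nodes_from((sp, pid) for pid in prot)
    for i, sp_a in enumerate(species):
        for sp_b in species[i + 1:]:
            hits_ab = {pid: best_hit(seq, seqs[sp_b]) for pid, seq in seqs[sp_a].items()}
            hits_ba = {pid: best_hit(seq, seqs[sp_a]) for pid, seq in seqs[sp_b].items()}
            for pid_a, pid_b in hits_ab.items():
                if pid_b is not None and hits_ba.get(pid_b) == pid_a:
                    graph.add_edge((sp_a, pid_a), (sp_b, pid_b))

    components = [sorted(c) for c in nx.connected_components(graph) if len(c) >= 2]
    components.sort()
    table = OrthogroupTable(species_order=species)
    width = max(7, len(str(len(components))))
    for idx, members in enumerate(components):
        cells: dict[str, list[str]] = {sp: [] for sp in species}
        for sp, pid in members:
            cells[sp].append(pid)
        for sp in species:
            cells[sp].sort()
        table.groups[f"OG{idx:0{width}d}"] = cells
    return table
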