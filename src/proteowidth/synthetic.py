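"""Synthetic Swiss-Prot proteomes and ortholog families with planted truth.

Two generators make every pipeline stage testable without any database
download:

* :func:`generate_flatfile` writes a syntactically valid Swiss-Prot DAT
  file in which the number of spliced / SAP-bearing / PTM-bearing genes and
  the events per affected gene are *planted deterministically* (exact counts,
  not Bernoulli draws), together with the parameter vector those plantings
  imply. Parsing the file back must recover that vector exactly.
* :func:`generate_ortholog_families` builds multi-species FASTA proteomes
  from mutated family ancestors at controlled identity levels, plus the
  orthogroup table those families imply and a planted aging-gene subset
  with its symbol-to-accession mapping.

Sequences are uniform random over the 20 amino acids with seeded point
mutation; no codon or compositional realism is attempted (none is needed
for counting logic or for RBH at well-separated identity levels).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction

from .flatfile import GeneKey
from .orthologs import OrthogroupTable
from .widths import ProteomeParameters

__all__ = [
    "SyntheticProteomeSpec",
    "OrthologyScenario",
    "PlantedEntry",
    "FlatfileBundle",
    "OrthologyBundle",
    "FieldDiff",
    "RecoveryReport",
    "generate_flatfile",
    "generate_ortholog_families",
    "recovery_report",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

PARAMETER_FIELDS = (
    "N", "ASg", "ASd", "AS", "ASav",
    "SAPg", "SAPd", "SAP", "SAPav",
    "PTMg", "PTMd", "PTM", "PTMav",
)


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Planted structure of one synthetic Swiss-Prot proteome.

    ``*_gene_fraction`` of the genes (rounded to an exact count) carry the
    respective event class; each affected gene carries exactly
    ``*_per_gene`` events.
    """

    n_genes: int
    as_gene_fraction: float = 0.0
    sap_gene_fraction: float = 0.0
    ptm_gene_fraction: float = 0.0
    as_per_gene: int = 2
    sap_per_gene: int = 1
    ptm_per_gene: int = 1
    taxon_id: int = 9606
    seed: int = 0
    sequence_length: int = 60

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")
        for name in ("as_gene_fraction", "sap_gene_fraction", "ptm_gene_fraction"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if min(self.as_per_gene, self.sap_per_gene, self.ptm_per_gene) < 1:
            raise ValueError("per-gene event counts must be positive")
        if self.as_per_gene < 2:
            # all_named counting: a spliced gene declares >=2 named isoforms
            raise ValueError("as_per_gene must be >= 2 (canonical + alternatives)")

    @property
    def n_as_genes(self) -> int:
        return round(self.as_gene_fraction * self.n_genes)

    @property
    def n_sap_genes(self) -> int:
        return round(self.sap_gene_fraction * self.n_genes)

    @property
    def n_ptm_genes(self) -> int:
        return round(self.ptm_gene_fraction * self.n_genes)

    def planted_parameters(self) -> ProteomeParameters | None:
        if self.n_genes == 0:
            return None
        return ProteomeParameters(
            N=self.n_genes,
            ASg=self.n_as_genes, AS=self.n_as_genes * self.as_per_gene,
            SAPg=self.n_sap_genes, SAP=self.n_sap_genes * self.sap_per_gene,
            PTMg=self.n_ptm_genes, PTM=self.n_ptm_genes * self.ptm_per_gene,
        )


@dataclass(frozen=True)
class PlantedEntry:
    """Ground truth for one generated entry."""

    accession: str
    gene_key: GeneKey
    as_sequences: int
    sap_sequences: int
    ptm_sequences: int


@dataclass(frozen=True)
class FlatfileBundle:
    dat_text: str
    parameters: ProteomeParameters | None
    entries: tuple[PlantedEntry, ...]


@dataclass(frozen=True)
class OrthologyScenario:
    """Planted multi-species family structure for orthogroup inference."""

    n_species: int
    n_families: int
    family_size_per_species: int = 1
    within_family_identity: float = 0.9
    between_family_identity: float = 0.1
    aging_fraction: float = 0.5
    seed: int = 0
    sequence_length: int = 80

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_families < 0:
            raise ValueError("need >=1 species and >=0 families")
        if self.family_size_per_species < 1:
            raise ValueError("family_size_per_species must be positive")
        for name in ("within_family_identity", "between_family_identity",
                     "aging_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.within_family_identity <= self.between_family_identity:
            raise ValueError(
                "within-family identity must exceed between-family identity"
            )

    @property
    def species_labels(self) -> tuple[str, ...]:
        return ("human",) + tuple(f"sp{i}" for i in range(2, self.n_species + 1))


@dataclass(frozen=True)
class OrthologyBundle:
    proteomes: dict[str, dict[str, str]]
    table: OrthogroupTable
    aging_symbols: tuple[str, ...]
    mapping: dict[str, list[str]]


def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_AA) for _ in range(length))


def _mutate(rng: random.Random, seq: str, identity: float) -> str:
    """Point-mutate each position with probability 1 - identity."""
    out = []
    for ch in seq:
        if rng.random() < 1.0 - identity:
            out.append(rng.choice(_AA.replace(ch, "")))
        else:
            out.append(ch)
    return "".join(out)


def _wrap_sequence(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        block = seq[i:i + 60]
        lines.append("     " + " ".join(block[j:j + 10] for j in range(0, len(block), 10)))
    return "\n".join(lines)


def generate_flatfile(spec: SyntheticProteomeSpec) -> FlatfileBundle:
    """Write a DAT proteome with exactly the planted event structure.

    One entry per gene. Which genes carry which event class is drawn with
    the spec's seed (the three subsets are sampled independently), but the
    *numbers* of affected genes and of events per gene are exact, so the
    implied parameter vector is deterministic arithmetic, not sampling.
    Identical specs produce byte-identical output.
    """
    rng = random.Random(spec.seed)
    n = spec.n_genes
    as_set = set(rng.sample(range(n), spec.n_as_genes)) if n else set()
    sap_set = set(rng.sample(range(n), spec.n_sap_genes)) if n else set()
    ptm_set = set(rng.sample(range(n), spec.n_ptm_genes)) if n else set()

    entries: list[PlantedEntry] = []
    blocks: list[str] = []
    for i in range(n):
        accession = f"S{spec.seed % 100:02d}{i:04d}"[:10]
        gene = f"GENE{i:04d}"
        seq = _random_sequence(rng, spec.sequence_length)
        lines = [
            f"ID   G{i:04d}_SYNTH            Reviewed;         {len(seq)} AA.",
            f"AC   {accession};",
            f"OX   NCBI_TaxID={spec.taxon_id};",
            f"GN   Name={gene};",
        ]
        n_as = spec.as_per_gene if i in as_set else 0
        if n_as:
            lines += [
                "CC   -!- ALTERNATIVE PRODUCTS:",
                f"CC       Event=Alternative splicing; Named isoforms={n_as};",
            ]
        n_sap = spec.sap_per_gene if i in sap_set else 0
        for _ in range(n_sap):
            pos = rng.randint(1, len(seq))
            lines.append(f"FT   VARIANT         {pos}")
            lines.append('FT                   /note="planted SAP"')
        n_ptm = spec.ptm_per_gene if i in ptm_set else 0
        for _ in range(n_ptm):
            pos = rng.randint(1, len(seq))
            lines.append(f"FT   MOD_RES         {pos}")
            lines.append('FT                   /note="planted PTM"')
        lines.append(f"SQ   SEQUENCE   {len(seq)} AA;  0 MW;  0000000000000000 CRC64;")
        lines.append(_wrap_sequence(seq))
        lines.append("//")
        blocks.append("\n".join(lines))
        entries.append(
            PlantedEntry(
                accession=accession,
                gene_key=GeneKey(spec.taxon_id, gene),
                as_sequences=n_as,
                sap_sequences=n_sap,
                ptm_sequences=n_ptm,
            )
        )
    text = "\n".join(blocks) + ("\n" if blocks else "")
    return FlatfileBundle(text, spec.planted_parameters(), tuple(entries))


def generate_ortholog_families(scn: OrthologyScenario) -> OrthologyBundle:
    """Build family-structured proteomes plus their implied orthogroup table.

    Each family descends from an ancestor derived from a common root at the
    between-family identity level; every member of every species mutates the
    family ancestor at the within-family level. The planted orthogroup table
    lists all members of each family (empty when only one species exists,
    since cross-species orthology is then undefined). A planted fraction of
    families is marked as aging via their human members' gene symbols.
    """
    rng = random.Random(scn.seed)
    labels = scn.species_labels
    root = _random_sequence(rng, scn.sequence_length)

    proteomes: dict[str, dict[str, str]] = {sp: {} for sp in labels}
    table = OrthogroupTable(species_order=list(labels))
    for fam in range(scn.n_families):
        ancestor = _mutate(rng, root, scn.between_family_identity)
        cells: dict[str, list[str]] = {}
        for sp in labels:
            ids = []
            for m in range(1, scn.family_size_per_species + 1):
                pid = f"{sp}_F{fam:03d}_{m}"
                proteomes[sp][pid] = _mutate(rng, ancestor, scn.within_family_identity)
                ids.append(pid)
            cells[sp] = ids
        if scn.n_species >= 2:
            table.groups[f"OG{fam:07d}"] = cells

    n_aging = round(scn.aging_fraction * scn.n_families)
    aging_fams = sorted(rng.sample(range(scn.n_families), n_aging))
    aging_symbols = tuple(f"AGENE{fam:03d}" for fam in aging_fams)
    mapping = {
        f"AGENE{fam:03d}": [f"human_F{fam:03d}_{m}"
                            for m in range(1, scn.family_size_per_species + 1)]
        for fam in range(scn.n_families)
    }
    return OrthologyBundle(proteomes, table, aging_symbols, mapping)


@dataclass(frozen=True)
class FieldDiff:
    field: str
    planted: Fraction | int
    recovered: Fraction | int

    @property
    def delta(self) -> Fraction:
        return Fraction(self.recovered) - Fraction(self.planted)

    @property
    def equal(self) -> bool:
        return self.delta == 0


@dataclass(frozen=True)
class RecoveryReport:
    diffs: tuple[FieldDiff, ...]

    @property
    def passed(self) -> bool:
        return all(d.equal for d in self.diffs)

    @property
    def failing_fields(self) -> tuple[str, ...]:
        return tuple(d.field for d in self.diffs if not d.equal)


def recovery_report(
    planted: ProteomeParameters,
    recovered: ProteomeParameters,
) -> RecoveryReport:
    """Field-by-field comparison of a planted vs. a pipeline-recovered vector."""
    pd, rd = planted.as_dict(), recovered.as_dict()
    return RecoveryReport(
        tuple(FieldDiff(name, pd[name], rd[name]) for name in PARAMETER_FIELDS)
    )
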