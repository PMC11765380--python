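"""Reading UniProtKB/Swiss-Prot flat-file (DAT) records.

Swiss-Prot reviewed entries carry, per protein, the three annotation layers
that feed proteoform counting:

* the ``CC -!- ALTERNATIVE PRODUCTS`` comment block, which declares how many
  named splice isoforms a gene encodes;
* ``FT VARIANT`` features, each a single-amino-acid polymorphism (SAP);
* PTM-bearing features (``MOD_RES``, ``CARBOHYD``, ``LIPID``, ``CROSSLNK``,
  and structurally oriented ``DISULFID``), each one modified sequence site.

This module turns DAT text into :class:`ProteinEntryRecord` objects and
reduces each record to the entry-level event counts
(:class:`EntryFeatureCounts`) that the width models aggregate per gene.

Entry chunking (on the ``//`` terminator) is done here so a malformed entry
is reported with its line number and skipped; field parsing of each chunk is
delegated to :mod:`Bio.SwissProt`.
"""

from __future__ import annotations

import gzip
import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, TextIO

from Bio import SwissProt

__all__ = [
    "FeatureSite",
    "ProteinEntryRecord",
    "EntryFeatureCounts",
    "GeneKey",
    "FlatfileFormatError",
    "MalformedEntryWarning",
    "PTM_FEATURE_KEYS",
    "DEFAULT_PTM_KEYS",
    "parse_flatfile",
    "extract_feature_counts",
    "resolve_gene_key",
    "write_entry_audit",
]

#: Feature keys that can count as PTM evidence.
PTM_FEATURE_KEYS = frozenset({"MOD_RES", "CARBOHYD", "LIPID", "CROSSLNK", "DISULFID"})

#: Default PTM key set. DISULFID is excluded: disulfide bridges are a
#: structural feature rather than a chemical proteoform in most treatments.
DEFAULT_PTM_KEYS = frozenset({"MOD_RES", "CARBOHYD", "LIPID", "CROSSLNK"})

_TRACKED_FEATURE_KEYS = PTM_FEATURE_KEYS | {"VARIANT", "VAR_SEQ"}

_NAMED_ISOFORMS_RE = re.compile(r"Named isoforms=(\d+)")


class FlatfileFormatError(ValueError):
    """Raised when the input cannot be read as Swiss-Prot DAT text at all."""


class MalformedEntryWarning(UserWarning):
    """One entry could not be parsed; the parse continued past it."""


@dataclass(frozen=True)
class FeatureSite:
    """One feature-table line: a located annotation on the sequence.

    Coordinates are 1-based inclusive, as printed in the flat file.
    """

    feature_key: str
    begin: int
    end: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.begin > self.end:
            raise ValueError(f"feature begin {self.begin} > end {self.end}")


class GeneKey(NamedTuple):
    """Identity of a gene: NCBI taxon plus an upper-cased gene label."""

    taxon_id: int
    label: str


@dataclass
class ProteinEntryRecord:
    """One parsed Swiss-Prot entry with the annotation the width models use."""

    primary_accession: str
    secondary_accessions: list[str]
    entry_name: str
    taxon_id: int
    sequence_length: int
    gene_name: str | None = None
    gene_name_source: str = "accession_fallback"
    declared_isoform_count: int = 0
    alternative_splicing_event: bool = False
    variant_features: list[FeatureSite] = field(default_factory=list)
    ptm_features: list[FeatureSite] = field(default_factory=list)
    splice_features: list[FeatureSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence_length <= 0:
            raise ValueError("sequence_length must be positive")
        if self.declared_isoform_count < 0:
            raise ValueError("declared_isoform_count must be >= 0")
        if self.gene_name is None and self.gene_name_source != "accession_fallback":
            raise ValueError("gene_name absent requires accession_fallback source")
        for site in self.variant_features + self.ptm_features + self.splice_features:
            if site.begin < 1:
                raise ValueError(f"feature position {site.begin} < 1")
            # Cross-links may bridge into another chain; only their begin is
            # required to sit on this sequence.
            if site.feature_key != "CROSSLNK" and site.end > self.sequence_length:
                raise ValueError(
                    f"feature end {site.end} beyond sequence length "
                    f"{self.sequence_length}"
                )


@dataclass(frozen=True)
class EntryFeatureCounts:
    """Entry-level counts of splice, SAP and PTM sequence variants."""

    as_sequences: int
    sap_sequences: int
    ptm_sequences: int

    def __post_init__(self) -> None:
        if min(self.as_sequences, self.sap_sequences, self.ptm_sequences) < 0:
            raise ValueError("feature counts must be nonnegative")


def _open_text(source: str | Path | TextIO) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def _iter_entry_chunks(stream: TextIO) -> Iterable[tuple[int, str]]:
    """Yield (start line number, chunk text) per ``//``-terminated entry."""
    lines: list[str] = []
    start = 1
    for lineno, line in enumerate(stream, start=1):
        if not lines:
            start = lineno
        lines.append(line)
        if line.rstrip("\n\r") == "//":
            yield start, "".join(lines)
            lines = []
    if any(line.strip() for line in lines):
        # Trailing text without a terminator: close it so the record is kept.
        yield start, "".join(lines) + "//\n"


def _parse_alternative_products(comments: list[str]) -> tuple[int, bool]:
    for comment in comments:
        if not comment.startswith("ALTERNATIVE PRODUCTS"):
            continue
        match = _NAMED_ISOFORMS_RE.search(comment)
        declared = int(match.group(1)) if match else 0
        has_splicing = "Alternative splicing" in comment
        return declared, has_splicing
    return 0, False


def _parse_gene_name(gene_name_field) -> tuple[str | None, str]:
    """Apply the Name > OrderedLocusNames > ORFNames precedence."""
    if isinstance(gene_name_field, str):  # very old biopython fallback
        match = re.search(r"Name=([^;{ ]+)", gene_name_field)
        if match:
            return match.group(1), "Name"
        return None, "accession_fallback"
    for source in ("Name", "OrderedLocusNames", "ORFNames"):
        for gene in gene_name_field or []:
            value = gene.get(source)
            if not value:
                continue
            if isinstance(value, list):
                value = value[0]
            # Strip evidence tags such as {ECO:...}
            return value.split("{")[0].strip(), source
    return None, "accession_fallback"


def _feature_sites(record) -> tuple[list[FeatureSite], list[FeatureSite], list[FeatureSite]]:
    variants: list[FeatureSite] = []
    ptms: list[FeatureSite] = []
    splices: list[FeatureSite] = []
    for feat in record.features:
        key = feat.type
        if key not in _TRACKED_FEATURE_KEYS:
            continue
        try:
            begin = int(feat.location.start) + 1
            end = int(feat.location.end)
        except (TypeError, ValueError):
            continue  # unknown/uncertain positions carry no countable site
        note = feat.qualifiers.get("note", "") if feat.qualifiers else ""
        site = FeatureSite(key, begin, end, note)
        if key == "VARIANT":
            variants.append(site)
        elif key == "VAR_SEQ":
            splices.append(site)
        else:
            ptms.append(site)
    return variants, ptms, splices


def _record_from_chunk(chunk: str) -> ProteinEntryRecord:
    raw = SwissProt.read(io.StringIO(chunk))
    if not raw.accessions:
        raise ValueError("entry has no AC line")
    taxon_raw = raw.taxonomy_id[0] if raw.taxonomy_id else "0"
    taxon_id = int(re.sub(r"[^\d]", "", taxon_raw) or 0)
    gene_name, source = _parse_gene_name(raw.gene_name)
    declared, has_splicing = _parse_alternative_products(raw.comments)
    variants, ptms, splices = _feature_sites(raw)
    return ProteinEntryRecord(
        primary_accession=raw.accessions[0],
        secondary_accessions=list(raw.accessions[1:]),
        entry_name=raw.entry_name,
        taxon_id=taxon_id,
        sequence_length=raw.sequence_length,
        gene_name=gene_name,
        gene_name_source=source if gene_name else "accession_fallback",
        declared_isoform_count=declared,
        alternative_splicing_event=has_splicing,
        variant_features=variants,
        ptm_features=ptms,
        splice_features=splices,
    )


def parse_flatfile(source: str | Path | TextIO) -> list[ProteinEntryRecord]:
    """Parse Swiss-Prot DAT text into entry records, in file order.

    Parameters
    ----------
    source
        A path (plain or gzip-compressed) or an open text handle.

    Returns
    -------
    list of ProteinEntryRecord
        One record per well-formed entry. A malformed entry raises a
        :class:`MalformedEntryWarning` carrying its starting line number and
        is skipped; parsing continues with the next entry.
    """
    stream = _open_text(source)
    records: list[ProteinEntryRecord] = []
    try:
        for start_line, chunk in _iter_entry_chunks(stream):
            try:
                records.append(_record_from_chunk(chunk))
            except Exception as exc:  # noqa: BLE001 - entry-level recovery
                warnings.warn(
                    f"skipping malformed entry starting at line {start_line}: {exc}",
                    MalformedEntryWarning,
                    stacklevel=2,
                )
    except UnicodeDecodeError as exc:
        raise FlatfileFormatError(f"input is not Swiss-Prot text: {exc}") from exc
    finally:
        if stream is not source:
            stream.close()
    return records


def extract_feature_counts(
    entry: ProteinEntryRecord,
    ptm_keys: frozenset[str] | set[str] = DEFAULT_PTM_KEYS,
    isoform_convention: str = "all_named",
) -> EntryFeatureCounts:
    """Reduce one entry to its AS / SAP / PTM sequence-variant counts.

    ``isoform_convention`` chooses what a "splice sequence" is:

    * ``all_named`` — every declared named isoform counts (so a spliced gene
      contributes at least 2);
    * ``non_canonical`` — the canonical sequence is not counted, i.e.
      ``max(declared - 1, 0)``.

    Either way the count is zero unless the entry's ALTERNATIVE PRODUCTS
    block records an alternative-splicing event.
    """
    unknown = set(ptm_keys) - PTM_FEATURE_KEYS
    if unknown:
        raise ValueError(f"unknown PTM feature keys: {sorted(unknown)}")
    if isoform_convention not in ("all_named", "non_canonical"):
        raise ValueError(f"unknown isoform convention: {isoform_convention!r}")

    if entry.alternative_splicing_event:
        if isoform_convention == "all_named":
            as_sequences = entry.declared_isoform_count
        else:
            as_sequences = max(entry.declared_isoform_count - 1, 0)
    else:
        as_sequences = 0
    sap_sequences = sum(1 for f in entry.variant_features if f.feature_key == "VARIANT")
    ptm_sequences = sum(1 for f in entry.ptm_features if f.feature_key in ptm_keys)
    return EntryFeatureCounts(as_sequences, sap_sequences, ptm_sequences)


def resolve_gene_key(entry: ProteinEntryRecord) -> GeneKey:
    """Map an entry to its gene: (taxon, upper-cased gene label).

    Entries without any GN line become singleton genes keyed by their primary
    accession, so unnamed proteins never deflate the gene count.
    """
    label = entry.gene_name if entry.gene_name is not None else entry.primary_accession
    return GeneKey(entry.taxon_id, label.upper())


def write_entry_audit(
    records: Iterable[ProteinEntryRecord],
    path: str | Path,
    ptm_keys: frozenset[str] | set[str] = DEFAULT_PTM_KEYS,
    isoform_convention: str = "all_named",
) -> None:
    """Emit a per-entry TSV (accession, taxon, gene, isoforms, variants, ptms)."""
    with open(path, "w", encoding="utf-8") as out:
        out.write("accession\ttaxon_id\tgene\tisoforms\tvariants\tptms\n")
        for rec in records:
            counts = extract_feature_counts(rec, ptm_keys, isoform_convention)
            key = resolve_gene_key(rec)
            out.write(
                f"{rec.primary_accession}\t{rec.taxon_id}\t{key.label}\t"
                f"{counts.as_sequences}\t{counts.sap_sequences}\t{counts.ptm_sequences}\n"
            )
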