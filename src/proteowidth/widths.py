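"""Proteome-width models and genome annotation coverage.

The proteome width Np(H) of a species is the number of distinct proteoforms
its genome can encode under an information model H. The models consume a
13-parameter vector per species:

=======  ==========================================================
N        protein-coding genes in the genome
ASg      alternatively spliced genes;       ASd = ASg/N;  ASav = AS/ASg
AS       splice-variant sequences
SAPg     genes carrying SAPs;               SAPd = SAPg/N; SAPav = SAP/SAPg
SAP      SAP-bearing sequence variants
PTMg     genes encoding PTM-modified proteins; PTMd = PTMg/N; PTMav = PTM/PTMg
PTM      PTM-bearing sequence variants
=======  ==========================================================

and compute::

    Nps1 = N * (1 + ASd*ASav + SAPd*SAPav + PTMd*PTMav)
    Nps2 = Nps1 + AS * (SAPav + PTMav)
    Nps3 = Nps2 + N * SAPav*PTMav + AS * SAPav*PTMav

Model 1 lets sequence changes (SAP, PTM) arise only on canonical sequences;
model 2 also on splice variants; model 3 lets SAP and PTM co-occur on any
sequence. The densities are ratios of integers, so all three formulas are
evaluated in exact rational arithmetic; in particular the identity
``Nps1 = N + AS + SAP + PTM`` holds exactly.

Annotation coverage is the companion "exploration degree" statistic: the
percentage of a species' Ensembl genes that carry an expert-reviewed
Swiss-Prot entry (it may exceed 100% when Swiss-Prot is redundant relative
to the Ensembl gene build).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .flatfile import EntryFeatureCounts, GeneKey

__all__ = [
    "GeneFeatureCounts",
    "ProteomeParameters",
    "ProteomeWidths",
    "AnnotationCoverage",
    "aggregate_by_gene",
    "derive_parameters",
    "compute_widths",
    "per_pcg_ratio",
    "per_pcg_ratios",
    "annotation_coverage",
    "format_coverage_percent",
    "format_per_pcg",
    "round_half_up",
    "parameters_from_mapping",
]


@dataclass(frozen=True)
class GeneFeatureCounts:
    """Per-gene totals of splice, SAP and PTM sequence variants."""

    gene_key: GeneKey
    as_sequences: int
    sap_sequences: int
    ptm_sequences: int

    def __post_init__(self) -> None:
        if min(self.as_sequences, self.sap_sequences, self.ptm_sequences) < 0:
            raise ValueError("gene counts must be nonnegative")


@dataclass(frozen=True)
class ProteomeParameters:
    """The 13-parameter vector of one species.

    Only the seven integer counts are stored; the six derived quantities
    (densities ``*d`` and per-gene averages ``*av``) are exposed as exact
    :class:`fractions.Fraction` properties, with the convention that an
    average is 0 when its gene count is 0.
    """

    N: int
    ASg: int = 0
    AS: int = 0
    SAPg: int = 0
    SAP: int = 0
    PTMg: int = 0
    PTM: int = 0

    def __post_init__(self) -> None:
        counts = (self.N, self.ASg, self.AS, self.SAPg, self.SAP, self.PTMg, self.PTM)
        if any(c < 0 for c in counts):
            raise ValueError("all parameter counts must be nonnegative")
        if self.N == 0:
            raise ValueError("undefined parameters: N must be positive")
        for gene_count, seq_count, name in (
            (self.ASg, self.AS, "AS"),
            (self.SAPg, self.SAP, "SAP"),
            (self.PTMg, self.PTM, "PTM"),
        ):
            if gene_count > self.N:
                raise ValueError(f"{name}g exceeds N")
            if gene_count == 0 and seq_count != 0:
                raise ValueError(f"{name} > 0 with {name}g = 0")

    @property
    def ASd(self) -> Fraction:
        return Fraction(self.ASg, self.N)

    @property
    def SAPd(self) -> Fraction:
        return Fraction(self.SAPg, self.N)

    @property
    def PTMd(self) -> Fraction:
        return Fraction(self.PTMg, self.N)

    @property
    def ASav(self) -> Fraction:
        return Fraction(self.AS, self.ASg) if self.ASg else Fraction(0)

    @property
    def SAPav(self) -> Fraction:
        return Fraction(self.SAP, self.SAPg) if self.SAPg else Fraction(0)

    @property
    def PTMav(self) -> Fraction:
        return Fraction(self.PTM, self.PTMg) if self.PTMg else Fraction(0)

    def as_dict(self) -> dict[str, Fraction | int]:
        """All 13 parameters keyed by their conventional names."""
        return {
            "N": self.N,
            "ASg": self.ASg, "ASd": self.ASd, "AS": self.AS, "ASav": self.ASav,
            "SAPg": self.SAPg, "SAPd": self.SAPd, "SAP": self.SAP, "SAPav": self.SAPav,
            "PTMg": self.PTMg, "PTMd": self.PTMd, "PTM": self.PTM, "PTMav": self.PTMav,
        }


@dataclass(frozen=True)
class ProteomeWidths:
    """Proteoform totals under the three models, kept as exact rationals."""

    nps1: Fraction
    nps2: Fraction
    nps3: Fraction

    def per_pcg(self, N: int, decimals: int = 1) -> tuple[float, float, float]:
        return per_pcg_ratios(self, N, decimals)


@dataclass(frozen=True)
class AnnotationCoverage:
    """Annotation coverage of one genome: reviewed genes / Ensembl genes."""

    species: str
    taxon_id: int
    pcg_swissprot: int
    genes_ensembl: int
    percent_annotated: float

    @property
    def printed(self) -> str:
        return format_coverage_percent(self.percent_annotated)


def aggregate_by_gene(
    entries: Iterable[tuple[GeneKey, EntryFeatureCounts]],
) -> list[GeneFeatureCounts]:
    """Sum entry counts per gene; output sorted by (taxon, gene label)."""
    totals: dict[GeneKey, list[int]] = {}
    for key, counts in entries:
        acc = totals.setdefault(key, [0, 0, 0])
        acc[0] += counts.as_sequences
        acc[1] += counts.sap_sequences
        acc[2] += counts.ptm_sequences
    return [
        GeneFeatureCounts(key, *totals[key])
        for key in sorted(totals, key=lambda k: (k.taxon_id, k.label))
    ]


def derive_parameters(
    genes: Sequence[GeneFeatureCounts],
    n_override: int | None = None,
) -> ProteomeParameters:
    """Derive the 13-parameter vector from per-gene counts.

    ``n_override`` substitutes an externally supplied protein-coding gene
    count for N (database releases disagree on N more than on event counts),
    leaving the event totals untouched.
    """
    n = n_override if n_override is not None else len(genes)
    if n <= 0:
        raise ValueError("undefined parameters: no genes and no N override")
    return ProteomeParameters(
        N=n,
        ASg=sum(1 for g in genes if g.as_sequences > 0),
        AS=sum(g.as_sequences for g in genes),
        SAPg=sum(1 for g in genes if g.sap_sequences > 0),
        SAP=sum(g.sap_sequences for g in genes),
        PTMg=sum(1 for g in genes if g.ptm_sequences > 0),
        PTM=sum(g.ptm_sequences for g in genes),
    )


def compute_widths(p: ProteomeParameters) -> ProteomeWidths:
    """Evaluate the three width models exactly on a parameter vector."""
    n = Fraction(p.N)
    nps1 = n * (1 + p.ASd * p.ASav + p.SAPd * p.SAPav + p.PTMd * p.PTMav)
    nps2 = nps1 + p.AS * (p.SAPav + p.PTMav)
    nps3 = nps2 + n * p.SAPav * p.PTMav + p.AS * p.SAPav * p.PTMav
    return ProteomeWidths(nps1, nps2, nps3)


def round_half_up(value: Fraction | float | int, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` places (report convention)."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-decimals)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def per_pcg_ratio(nps: Fraction | float, N: int, decimals: int = 1) -> float:
    """Average proteoforms per protein-coding gene, rounded half-up."""
    if N <= 0:
        raise ValueError("N must be positive")
    ratio = Fraction(nps) / N if isinstance(nps, (Fraction, int)) else nps / N
    return round_half_up(ratio, decimals)


def per_pcg_ratios(w: ProteomeWidths, N: int, decimals: int = 1) -> tuple[float, float, float]:
    return (
        per_pcg_ratio(w.nps1, N, decimals),
        per_pcg_ratio(w.nps2, N, decimals),
        per_pcg_ratio(w.nps3, N, decimals),
    )


def annotation_coverage(
    pcg_swissprot: int,
    genes_ensembl: int,
    species: str = "",
    taxon_id: int = 0,
) -> AnnotationCoverage:
    """Percentage of Ensembl genes with a reviewed Swiss-Prot entry."""
    if genes_ensembl <= 0:
        raise ValueError("genes_ensembl must be positive")
    if pcg_swissprot < 0:
        raise ValueError("pcg_swissprot must be nonnegative")
    percent = 100.0 * pcg_swissprot / genes_ensembl
    return AnnotationCoverage(species, taxon_id, pcg_swissprot, genes_ensembl, percent)


def format_coverage_percent(percent: float) -> str:
    """Report-precision tiers: >=10 integer, 1-10 one decimal, <1 one s.f.

    Rounding is half-up throughout. Note that published coverage tables mix
    truncation with rounding row-by-row; this formatter applies one uniform
    convention and leaves reconciliation of truncated rows to the caller's
    discrepancy log.
    """
    if percent < 0:
        raise ValueError("percent must be nonnegative")
    if percent >= 10:
        return f"{round_half_up(percent, 0):.0f}"
    if percent >= 1:
        return _strip_trailing_zero(f"{round_half_up(percent, 1):.1f}")
    if percent == 0:
        return "0"
    # one significant figure below 1%
    digits = 1
    scaled = percent
    while scaled < 0.1:
        scaled *= 10
        digits += 1
    return _strip_trailing_zero(f"{round_half_up(percent, digits):.{digits}f}")


def format_per_pcg(ratio: float) -> str:
    """Table formatting for a per-PCG ratio: one decimal, trailing .0 dropped."""
    return _strip_trailing_zero(f"{ratio:.1f}")


def _strip_trailing_zero(text: str) -> str:
    return text[:-2] if text.endswith(".0") else text


def parameters_from_mapping(row: Mapping[str, int | str]) -> ProteomeParameters:
    """Build a parameter vector from a table row with the conventional columns."""
    return ProteomeParameters(
        N=int(row["N"]),
        ASg=int(row.get("ASg", 0)), AS=int(row.get("AS", 0)),
        SAPg=int(row.get("SAPg", 0)), SAP=int(row.get("SAP", 0)),
        PTMg=int(row.get("PTMg", 0)), PTM=int(row.get("PTM", 0)),
    )
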