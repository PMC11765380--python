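"""End-to-end orchestration: config -> coverage / widths / overlap reports.

The pipeline stitches the library stages together for a set of species:

1. parse each species' Swiss-Prot DAT file and derive its 13-parameter
   vector (``extract`` stage);
2. evaluate the three width models and the per-PCG ratios (``widths``);
3. compute annotation coverage from an Ensembl gene-count table
   (``coverage``);
4. count aging-gene orthogroup overlap from an orthogroups table or from
   FASTA proteomes via the built-in RBH inferrer (``overlap``).

Reports are plain TSVs with stable ordering and fixed formatting, so a rerun
on identical inputs is byte-identical. Any stage failure aborts the run with
a stage-tagged error and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import flatfile, orthologs, widths as w

__all__ = [
    "SpeciesInput",
    "PipelineConfig",
    "PipelineError",
    "extract_parameters",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class SpeciesInput:
    name: str
    taxon_id: int
    dat_path: str | None = None
    genes_ensembl: int | None = None
    n_override: int | None = None


@dataclass
class PipelineConfig:
    output_dir: str
    species: list[SpeciesInput] = field(default_factory=list)
    aging_list_path: str | None = None
    mapping_path: str | None = None
    orthogroups_path: str | None = None
    fasta_dir: str | None = None
    human_label: str = "human"
    ptm_keys: frozenset[str] = flatfile.DEFAULT_PTM_KEYS
    isoform_convention: str = "all_named"
    seed: int = 0
    sort_overlap_descending: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        species = [SpeciesInput(**s) for s in raw.pop("species", [])]
        ptm_keys = raw.pop("ptm_keys", None)
        cfg = cls(species=species, **raw)
        if ptm_keys is not None:
            cfg.ptm_keys = frozenset(ptm_keys)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["species"] = [dataclasses.asdict(s) for s in self.species]
        raw["ptm_keys"] = sorted(self.ptm_keys)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def validate(self) -> None:
        for sp in self.species:
            if sp.dat_path and not Path(sp.dat_path).exists():
                raise PipelineError("config", f"missing DAT file: {sp.dat_path}")
        for label, path in (
            ("aging list", self.aging_list_path),
            ("mapping", self.mapping_path),
            ("orthogroups", self.orthogroups_path),
            ("FASTA dir", self.fasta_dir),
        ):
            if path is not None and not Path(path).exists():
                raise PipelineError("config", f"missing {label} path: {path}")


def extract_parameters(
    dat_path: str | Path,
    ptm_keys: frozenset[str] = flatfile.DEFAULT_PTM_KEYS,
    isoform_convention: str = "all_named",
    n_override: int | None = None,
) -> tuple[w.ProteomeParameters, int]:
    """Parse a DAT file into its parameter vector; returns (params, n entries)."""
    records = flatfile.parse_flatfile(dat_path)
    pairs = [
        (
            flatfile.resolve_gene_key(rec),
            flatfile.extract_feature_counts(rec, ptm_keys, isoform_convention),
        )
        for rec in records
    ]
    genes = w.aggregate_by_gene(pairs)
    return w.derive_parameters(genes, n_override=n_override), len(records)


def _write_rows(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(header) + "\n")
        for row in rows:
            out.write("\t".join(row) + "\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all configured stages; returns paths of the written reports."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "widths": outdir / "widths.tsv",
        "coverage": outdir / "coverage.tsv",
        "overlap": outdir / "overlap.tsv",
        "log": outdir / "run.log",
    }
    log_lines: list[str] = [f"seed={config.seed}"]
    try:
        _stage_widths(config, outputs["widths"], log_lines)
        _stage_coverage(config, outputs["coverage"], log_lines)
        _stage_overlap(config, outputs["overlap"], outdir, log_lines)
    except PipelineError:
        for path in outputs.values():
            path.unlink(missing_ok=True)
        raise
    outputs["log"].write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return outputs


def _stage_widths(config: PipelineConfig, path: Path, log: list[str]) -> None:
    header = [
        "species", "taxon_id", "PCG",
        "nps1", "per_pcg1", "nps2", "per_pcg2", "nps3", "per_pcg3",
    ]
    rows = []
    for sp in config.species:
        if sp.dat_path is None:
            continue
        try:
            params, n_entries = extract_parameters(
                sp.dat_path, config.ptm_keys, config.isoform_convention,
                sp.n_override,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("widths", f"{sp.name}: {exc}") from exc
        log.append(f"widths: {sp.name} parsed_entries={n_entries} N={params.N}")
        widths = w.compute_widths(params)
        ratios = widths.per_pcg(params.N)
        rows.append([
            sp.name, str(sp.taxon_id), str(params.N),
            f"{w.round_half_up(widths.nps1, 0):.0f}", w.format_per_pcg(ratios[0]),
            f"{w.round_half_up(widths.nps2, 0):.0f}", w.format_per_pcg(ratios[1]),
            f"{w.round_half_up(widths.nps3, 0):.0f}", w.format_per_pcg(ratios[2]),
        ])
    _write_rows(path, header, rows)


def _stage_coverage(config: PipelineConfig, path: Path, log: list[str]) -> None:
    header = [
        "species", "taxon_id", "genes_ensembl", "pcg_swissprot",
        "percent_annotated", "percent_printed",
    ]
    rows = []
    for sp in config.species:
        if sp.genes_ensembl is None or sp.dat_path is None:
            continue
        try:
            params, _ = extract_parameters(
                sp.dat_path, config.ptm_keys, config.isoform_convention,
                sp.n_override,
            )
            cov = w.annotation_coverage(
                params.N, sp.genes_ensembl, sp.name, sp.taxon_id
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("coverage", f"{sp.name}: {exc}") from exc
        rows.append([
            sp.name, str(sp.taxon_id), str(cov.genes_ensembl),
            str(cov.pcg_swissprot), f"{cov.percent_annotated:.4f}", cov.printed,
        ])
    _write_rows(path, header, rows)


def _stage_overlap(
    config: PipelineConfig, path: Path, outdir: Path, log: list[str]
) -> None:
    header = ["species", "n_orthogroups"]
    if config.aging_list_path is None or config.mapping_path is None or (
        config.orthogroups_path is None and config.fasta_dir is None
    ):
        _write_rows(path, header, [])
        return
    try:
        if config.orthogroups_path is not None:
            table = orthologs.read_orthogroups_table(config.orthogroups_path)
        else:
            fasta_dir = Path(config.fasta_dir)
            proteomes = {
                p.stem: p for p in sorted(fasta_dir.glob("*.fasta"))
            }
            if not proteomes:
                raise ValueError(f"no FASTA files in {fasta_dir}")
            table = orthologs.infer_orthogroups_rbh(proteomes)
        symbols = orthologs.read_gene_list(config.aging_list_path)
        mapping = orthologs.read_symbol_mapping(config.mapping_path)
        aging = orthologs.map_aging_genes(symbols, mapping)
        log.append(f"overlap: symbols={len(symbols)} unmapped={len(aging.unmapped)}")
        results = []
        audit_lines = []
        for target in table.species_order:
            if target == config.human_label:
                continue
            count = orthologs.count_overlap(
                table, aging, config.human_label, target
            )
            results.append(count)
            audit_lines.append(f"{target}\t{','.join(count.orthogroup_ids)}")
        if config.sort_overlap_descending:
            results.sort(key=lambda c: (-c.n_orthogroups, c.species))
        (outdir / "overlap_audit.tsv").write_text(
            "\n".join(audit_lines) + ("\n" if audit_lines else ""),
            encoding="utf-8",
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("overlap", str(exc)) from exc
    _write_rows(
        path, header, [[c.species, str(c.n_orthogroups)] for c in results]
    )
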