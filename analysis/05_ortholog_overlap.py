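"""Aging-gene orthogroup overlap on the synthetic ortholog families.

Runs the statistic twice — once on the planted orthogroups table, once on
orthogroups inferred from the FASTA proteomes by reciprocal best hits — and
checks the two routes agree. Writes results/overlap_counts.tsv.
"""

from pathlib import Path

from proteowidth import count_overlap, infer_orthogroups_rbh, map_aging_genes
from proteowidth.orthologs import (
    read_gene_list,
    read_orthogroups_table,
    read_symbol_mapping,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    syn = ROOT / "synthetic"
    if not (syn / "planted_orthogroups.tsv").exists():
        raise SystemExit("run 01_simulate_proteomes.py first")
    planted = read_orthogroups_table(syn / "planted_orthogroups.tsv")
    symbols = read_gene_list(syn / "aging_genes.txt")
    mapping = read_symbol_mapping(syn / "aging_mapping.tsv")
    aging = map_aging_genes(symbols, mapping)
    print(f"aging genes: {len(symbols)} symbols -> {len(aging.accessions)} "
          f"accessions ({len(aging.unmapped)} unmapped)")

    inferred = infer_orthogroups_rbh(
        {p.stem: p for p in sorted(syn.glob("*.fasta"))}
    )
    print(f"RBH inference: {len(inferred.groups)} orthogroups "
          f"(planted {len(planted.groups)})")

    lines = ["species\tn_planted\tn_inferred\tagrees"]
    rows = []
    for target in planted.species_order:
        if target == "human":
            continue
        n_planted = count_overlap(planted, aging, "human", target).n_orthogroups
        n_inferred = count_overlap(inferred, aging, "human", target).n_orthogroups
        rows.append((target, n_planted, n_inferred))
    rows.sort(key=lambda r: (-r[1], r[0]))
    for target, n_planted, n_inferred in rows:
        agrees = n_planted == n_inferred
        lines.append(f"{target}\t{n_planted}\t{n_inferred}\t{agrees}")
        print(f"{target}: planted {n_planted}, RBH-inferred {n_inferred}"
              + ("" if agrees else "  MISMATCH"))
    (ROOT / "overlap_counts.tsv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
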