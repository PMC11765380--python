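"""Generate the synthetic study inputs: Swiss-Prot-like proteomes with
planted AS/SAP/PTM structure, and multi-species ortholog families with a
planted aging-gene subset.

Writes under results/synthetic/: one DAT file per synthetic species, the
planted parameter table, FASTA proteomes, the planted orthogroups table,
the aging-gene list and its symbol->accession mapping.
"""

from pathlib import Path

from proteowidth import (
    OrthologyScenario,
    SyntheticProteomeSpec,
    generate_flatfile,
    generate_ortholog_families,
)
from proteowidth.orthologs import write_orthogroups_table

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

# Three regimes spanning the annotation-density range seen across real
# species: a densely annotated vertebrate-like proteome, a sparsely
# annotated one, and a PTM-only minimal genome.
SPECIES_SPECS = {
    "dense_vertebrate": SyntheticProteomeSpec(
        n_genes=60, as_gene_fraction=0.5, sap_gene_fraction=0.6,
        ptm_gene_fraction=0.9, as_per_gene=3, sap_per_gene=4, ptm_per_gene=5,
        taxon_id=9606, seed=101,
    ),
    "sparse_model": SyntheticProteomeSpec(
        n_genes=40, as_gene_fraction=0.1, sap_gene_fraction=0.2,
        ptm_gene_fraction=0.3, as_per_gene=2, sap_per_gene=1, ptm_per_gene=2,
        taxon_id=7955, seed=102,
    ),
    "ptm_only_minimal": SyntheticProteomeSpec(
        n_genes=6, ptm_gene_fraction=2 / 3, ptm_per_gene=2,
        taxon_id=10181, seed=103,
    ),
}

ORTHOLOGY = OrthologyScenario(
    n_species=4, n_families=8, family_size_per_species=1,
    within_family_identity=0.9, between_family_identity=0.2,
    aging_fraction=0.5, seed=104,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    param_lines = ["species\ttaxon_id\tN\tASg\tAS\tSAPg\tSAP\tPTMg\tPTM"]
    for name, spec in SPECIES_SPECS.items():
        bundle = generate_flatfile(spec)
        (OUT / f"{name}.dat").write_text(bundle.dat_text)
        p = bundle.parameters
        param_lines.append(
            f"{name}\t{spec.taxon_id}\t{p.N}\t{p.ASg}\t{p.AS}\t"
            f"{p.SAPg}\t{p.SAP}\t{p.PTMg}\t{p.PTM}"
        )
        print(f"{name}: {p.N} genes, ASg={p.ASg} SAPg={p.SAPg} PTMg={p.PTMg}")
    (OUT / "planted_parameters.tsv").write_text("\n".join(param_lines) + "\n")

    bundle = generate_ortholog_families(ORTHOLOGY)
    for sp, prot in bundle.proteomes.items():
        with open(OUT / f"{sp}.fasta", "w") as fh:
            for pid, seq in sorted(prot.items()):
                fh.write(f">{pid}\n{seq}\n")
    with open(OUT / "planted_orthogroups.tsv", "w") as fh:
        write_orthogroups_table(bundle.table, fh)
    (OUT / "aging_genes.txt").write_text("\n".join(bundle.aging_symbols) + "\n")
    with open(OUT / "aging_mapping.tsv", "w") as fh:
        for sym, accs in sorted(bundle.mapping.items()):
            fh.write(f"{sym}\t{','.join(accs)}\n")
    print(
        f"orthology: {ORTHOLOGY.n_species} species, "
        f"{len(bundle.table.groups)} planted families, "
        f"{len(bundle.aging_symbols)} aging genes"
    )


if __name__ == "__main__":
    main()
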