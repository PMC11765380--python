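"""Orthogroup tables, overlap counting, alignment scoring and RBH inference."""

import io
import random

import pytest

from proteowidth import (
    AgingGeneSet,
    OrthologyScenario,
    count_overlap,
    generate_ortholog_families,
    infer_orthogroups_rbh,
    map_aging_genes,
    nw_align_score,
    read_orthogroups_table,
)
from proteowidth.orthologs import OrthogroupTable, write_orthogroups_table


def brute_force_overlap(table, accessions, human, target):
    """Independent oracle: exhaustive double loop over groups x accessions."""
    hits = set()
    for og_id, cells in table.groups.items():
        for acc in accessions:
            if acc in cells.get(human, []) and cells.get(target, []):
                hits.add(og_id)
    return len(hits)


def random_toy_table(rng):
    species = ["human"] + [f"sp{i}" for i in range(2, rng.randint(3, 6))]
    table = OrthogroupTable(species_order=species)
    for g in range(rng.randint(0, 15)):
        cells = {}
        for sp in species:
            cells[sp] = [f"{sp}_p{g}_{k}" for k in range(rng.randint(0, 3))]
        if any(cells.values()):
            table.groups[f"OG{g:03d}"] = cells
    return table


class TestReadOrthogroupsTable:
    def test_header_only_file(self):
        table = read_orthogroups_table(io.StringIO("Orthogroup\thuman\tmouse\n"))
        assert table.species_order == ["human", "mouse"]
        assert table.groups == {}

    def test_toy_file_group_sizes(self):
        table = read_orthogroups_table(io.StringIO(
            "Orthogroup\thuman\tmouse\nOG1\th1\tm1\nOG2\th2\t\n"
        ))
        sizes = {og: sum(len(v) for v in cells.values())
                 for og, cells in table.groups.items()}
        assert sizes == {"OG1": 2, "OG2": 1}

    def test_comma_separated_cells(self):
        table = read_orthogroups_table(io.StringIO(
            "Orthogroup\thuman\tmouse\nOG1\th1, h2\tm1,m2\n"
        ))
        assert table.groups["OG1"] == {"human": ["h1", "h2"], "mouse": ["m1", "m2"]}

    def test_round_trip_byte_identical(self, toy_orthogroups_tsv):
        table = read_orthogroups_table(toy_orthogroups_tsv)
        out = io.StringIO()
        write_orthogroups_table(table, out)
        again = io.StringIO()
        write_orthogroups_table(read_orthogroups_table(io.StringIO(out.getvalue())), again)
        assert out.getvalue() == again.getvalue()

    def test_duplicate_group_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate orthogroup id"):
            read_orthogroups_table(io.StringIO(
                "Orthogroup\thuman\nOG1\th1\nOG1\th2\n"
            ))

    def test_ragged_row_rejected_with_row_number(self):
        with pytest.raises(ValueError, match="row 3"):
            read_orthogroups_table(io.StringIO(
                "Orthogroup\thuman\tmouse\nOG1\th1\tm1\nOG2\th2\n"
            ))


class TestMapAgingGenes:
    def test_empty_symbol_list(self):
        aging = map_aging_genes([], {"TP53": ["P04637"]})
        assert aging.symbols == frozenset() and aging.accessions == frozenset()

    def test_case_insensitive_lookup(self):
        mapping = {"TP53": ["P04637"], "EGFR": ["P00533"]}
        aging = map_aging_genes(["TP53", "egfr"], mapping)
        assert aging.accessions == {"P04637", "P00533"}

    def test_unmapped_symbols_reported_not_fatal(self):
        aging = map_aging_genes(["TP53", "NOSUCH"], {"TP53": ["P04637"]})
        assert aging.unmapped == ("NOSUCH",)
        assert aging.accessions == {"P04637"}

    def test_empty_mapping_with_symbols_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            map_aging_genes(["TP53"], {})


class TestCountOverlap:
    def test_empty_aging_set_counts_zero(self, toy_orthogroups_tsv):
        table = read_orthogroups_table(toy_orthogroups_tsv)
        empty = AgingGeneSet(frozenset(), frozenset())
        assert count_overlap(table, empty, "human", "mouse").n_orthogroups == 0

    def test_toy_enumeration(self, toy_orthogroups_tsv):
        table = read_orthogroups_table(toy_orthogroups_tsv)
        aging = AgingGeneSet(frozenset(), frozenset({"h1", "h2"}))
        result = count_overlap(table, aging, "human", "mouse")
        # OG1 has h1 + a mouse protein; OG2 has h2 but no mouse cell.
        assert result.n_orthogroups == 1
        assert result.orthogroup_ids == ("OG1",)

    def test_gene_present_in_two_groups_counts_both(self):
        table = read_orthogroups_table(io.StringIO(
            "Orthogroup\thuman\tmouse\nOG1\th1\tm1\nOG2\th1x, h1\tm2\n"
        ))
        aging = AgingGeneSet(frozenset(), frozenset({"h1"}))
        assert count_overlap(table, aging, "human", "mouse").n_orthogroups == 2

    def test_unknown_species_rejected(self, toy_orthogroups_tsv):
        table = read_orthogroups_table(toy_orthogroups_tsv)
        aging = AgingGeneSet(frozenset(), frozenset({"h1"}))
        with pytest.raises(KeyError):
            count_overlap(table, aging, "human", "rat")

    def test_matches_brute_force_on_random_tables(self):
        rng = random.Random(20240)
        for _ in range(200):
            table = random_toy_table(rng)
            all_human = sorted(table.species_proteins("human"))
            chosen = frozenset(rng.sample(all_human, rng.randint(0, len(all_human))))
            aging = AgingGeneSet(frozenset(), chosen)
            for target in table.species_order:
                got = count_overlap(table, aging, "human", target).n_orthogroups
                assert got == brute_force_overlap(table, chosen, "human", target)

    def test_monotone_in_aging_set(self):
        rng = random.Random(7)
        table = random_toy_table(rng)
        human = sorted(table.species_proteins("human"))
        small = frozenset(human[: len(human) // 2])
        large = frozenset(human)
        for target in table.species_order:
            lo = count_overlap(table, AgingGeneSet(frozenset(), small), "human", target)
            hi = count_overlap(table, AgingGeneSet(frozenset(), large), "human", target)
            assert hi.n_orthogroups >= lo.n_orthogroups

    def test_human_against_itself_counts_every_aging_group(self, toy_orthogroups_tsv):
        table = read_orthogroups_table(toy_orthogroups_tsv)
        aging = AgingGeneSet(frozenset(), frozenset({"h1", "h2"}))
        assert count_overlap(table, aging, "human", "human").n_orthogroups == 2


class TestAlignmentScore:
    def test_identical_short_sequence(self):
        assert nw_align_score("ACD", "ACD") == 19  # 4 + 9 + 6 on the diagonal

    def test_empty_pair_scores_zero(self):
        assert nw_align_score("", "") == 0

    def test_single_mismatch(self):
        assert nw_align_score("A", "D") == -2

    def test_gap_cost_convention(self):
        # Aligning "AA" vs "A": one residue gap costs open + extend = 11.
        assert nw_align_score("AA", "A") == 4 - 11

    def test_illegal_character_named_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            nw_align_score("AX", "ACD")


class TestRBHInference:
    def test_single_species_yields_empty_table(self):
        table = infer_orthogroups_rbh({"human": {"p1": "ACDEFGHIKL"}})
        assert table.groups == {}

    def test_identical_pair_forms_one_group(self):
        table = infer_orthogroups_rbh({
            "human": {"h1": "ACDEFGHIKLMNPQRSTVWY"},
            "mouse": {"m1": "ACDEFGHIKLMNPQRSTVWY"},
        })
        assert len(table.groups) == 1
        (cells,) = table.groups.values()
        assert cells == {"human": ["h1"], "mouse": ["m1"]}

    def test_recovers_planted_families(self):
        scn = OrthologyScenario(
            n_species=2, n_families=2, family_size_per_species=1,
            within_family_identity=0.85, between_family_identity=0.25, seed=11,
        )
        bundle = generate_ortholog_families(scn)
        inferred = infer_orthogroups_rbh(bundle.proteomes)
        def partition(t):
            return sorted(
                sorted((sp, p) for sp, ids in cells.items() for p in ids)
                for cells in t.groups.values()
            )
        assert partition(inferred) == partition(bundle.table)

    def test_permutation_invariant(self):
        scn = OrthologyScenario(
            n_species=2, n_families=3, family_size_per_species=1,
            within_family_identity=0.9, between_family_identity=0.2, seed=3,
        )
        bundle = generate_ortholog_families(scn)
        shuffled = {
            sp: dict(sorted(prot.items(), reverse=True))
            for sp, prot in bundle.proteomes.items()
        }
        a = infer_orthogroups_rbh(bundle.proteomes)
        b = infer_orthogroups_rbh(shuffled)
        assert a.groups == b.groups

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty sequence"):
            infer_orthogroups_rbh({"human": {"h1": ""}, "mouse": {"m1": "ACD"}})

    def test_duplicate_fasta_ids_rejected(self, tmp_path):
        fasta = tmp_path / "dup.fasta"
        fasta.write_text(">p1\nACDE\n>p1\nACDF\n")
        with pytest.raises(ValueError, match="duplicate protein id"):
            infer_orthogroups_rbh({"human": fasta, "mouse": {"m1": "ACDE"}})
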