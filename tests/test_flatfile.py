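"""Swiss-Prot flat-file parsing and entry-level event counting."""

import gzip
import io

import pytest

from proteowidth import (
    DEFAULT_PTM_KEYS,
    EntryFeatureCounts,
    FeatureSite,
    ProteinEntryRecord,
    extract_feature_counts,
    generate_flatfile,
    parse_flatfile,
    resolve_gene_key,
)
from proteowidth.flatfile import MalformedEntryWarning, write_entry_audit
from proteowidth.synthetic import SyntheticProteomeSpec

from conftest import HAND_WRITTEN_ENTRY


def make_record(**kwargs):
    base = dict(
        primary_accession="P00001",
        secondary_accessions=[],
        entry_name="TEST_HUMAN",
        taxon_id=9606,
        sequence_length=100,
    )
    base.update(kwargs)
    return ProteinEntryRecord(**base)


class TestParseFlatfile:
    def test_empty_stream_gives_empty_collection(self):
        assert parse_flatfile(io.StringIO("")) == []

    def test_hand_written_entry_fields(self, hand_written_record):
        rec = hand_written_record
        assert rec.primary_accession == "P04637"
        assert rec.secondary_accessions == ["Q15086"]
        assert rec.taxon_id == 9606
        assert rec.gene_name == "TP53"
        assert rec.gene_name_source == "Name"
        assert rec.declared_isoform_count == 3
        assert rec.alternative_splicing_event
        assert len(rec.variant_features) == 2
        assert len(rec.ptm_features) == 1
        assert rec.sequence_length == 120

    def test_feature_positions_are_one_based_inclusive(self, hand_written_record):
        positions = sorted(f.begin for f in hand_written_record.variant_features)
        assert positions == [12, 47]
        (mod,) = hand_written_record.ptm_features
        assert (mod.begin, mod.end) == (30, 30)

    def test_gzip_input_accepted(self, tmp_path):
        path = tmp_path / "sprot.dat.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(HAND_WRITTEN_ENTRY)
        records = parse_flatfile(path)
        assert len(records) == 1 and records[0].gene_name == "TP53"

    def test_malformed_entry_warns_with_line_number_and_parse_continues(self):
        bad = "ID   BROKEN\nnot a swissprot line\n//\n"
        stream = io.StringIO(bad + HAND_WRITTEN_ENTRY)
        with pytest.warns(MalformedEntryWarning, match="line 1"):
            records = parse_flatfile(stream)
        assert [r.entry_name for r in records] == ["TP53_HUMAN"]

    def test_parse_matches_generator_truth(self):
        spec = SyntheticProteomeSpec(
            n_genes=2, sap_gene_fraction=1.0, sap_per_gene=2, seed=1
        )
        bundle = generate_flatfile(spec)
        records = parse_flatfile(io.StringIO(bundle.dat_text))
        assert len(records) == 2
        for rec, truth in zip(records, bundle.entries):
            counts = extract_feature_counts(rec)
            assert counts.sap_sequences == truth.sap_sequences
            assert counts.as_sequences == truth.as_sequences
            assert counts.ptm_sequences == truth.ptm_sequences

    def test_sap_total_equals_variant_line_total(self):
        spec = SyntheticProteomeSpec(
            n_genes=30, sap_gene_fraction=0.5, sap_per_gene=3, seed=5
        )
        bundle = generate_flatfile(spec)
        n_variant_lines = sum(
            1 for line in bundle.dat_text.splitlines()
            if line.startswith("FT   VARIANT")
        )
        records = parse_flatfile(io.StringIO(bundle.dat_text))
        total = sum(extract_feature_counts(r).sap_sequences for r in records)
        assert total == n_variant_lines == 45

    def test_order_preserving(self):
        spec = SyntheticProteomeSpec(n_genes=10, seed=3)
        bundle = generate_flatfile(spec)
        records = parse_flatfile(io.StringIO(bundle.dat_text))
        assert [r.primary_accession for r in records] == [
            e.accession for e in bundle.entries
        ]


class TestExtractFeatureCounts:
    def test_no_features_no_isoforms_gives_zeros(self):
        rec = make_record()
        assert extract_feature_counts(rec) == EntryFeatureCounts(0, 0, 0)

    def test_default_ptm_keys_exclude_disulfid(self):
        rec = make_record(
            ptm_features=[
                FeatureSite("MOD_RES", 1, 1),
                FeatureSite("MOD_RES", 2, 2),
                FeatureSite("CARBOHYD", 3, 3),
                FeatureSite("DISULFID", 4, 10),
            ]
        )
        assert extract_feature_counts(rec).ptm_sequences == 3
        with_ss = extract_feature_counts(
            rec, ptm_keys=DEFAULT_PTM_KEYS | {"DISULFID"}
        )
        assert with_ss.ptm_sequences == 4

    @pytest.mark.parametrize(
        "convention,expected", [("all_named", 4), ("non_canonical", 3)]
    )
    def test_isoform_conventions(self, convention, expected):
        rec = make_record(declared_isoform_count=4, alternative_splicing_event=True)
        counts = extract_feature_counts(rec, isoform_convention=convention)
        assert counts.as_sequences == expected

    def test_isoforms_without_splicing_event_do_not_count(self):
        rec = make_record(declared_isoform_count=2, alternative_splicing_event=False)
        assert extract_feature_counts(rec).as_sequences == 0

    def test_unknown_ptm_key_rejected(self):
        rec = make_record()
        with pytest.raises(ValueError, match="unknown PTM"):
            extract_feature_counts(rec, ptm_keys={"MOD_RES", "HELIX"})


class TestResolveGeneKey:
    def test_gene_name_upper_cased(self):
        rec = make_record(gene_name="Trp53", gene_name_source="Name", taxon_id=10090)
        assert resolve_gene_key(rec) == (10090, "TRP53")

    def test_accession_fallback_without_gn_line(self):
        rec = make_record(primary_accession="P99999", gene_name=None)
        assert resolve_gene_key(rec) == (9606, "P99999")
        assert rec.gene_name_source == "accession_fallback"

    def test_ordered_locus_name_precedence(self):
        entry = (
            "ID   YAAA_ECOLI              Reviewed;         50 AA.\n"
            "AC   P0A8I3;\n"
            "OX   NCBI_TaxID=83333;\n"
            "GN   OrderedLocusNames=b0001; ORFNames=ECK0001;\n"
            "SQ   SEQUENCE   50 AA;  5000 MW;  0000000000000000 CRC64;\n"
            "     MKTAYIAKQR QISFVKSHFS RQLEERLGLI EVQAPILSRV GDGTQDNLSG\n"
            "//\n"
        )
        (rec,) = parse_flatfile(io.StringIO(entry))
        assert rec.gene_name == "b0001"
        assert rec.gene_name_source == "OrderedLocusNames"
        assert resolve_gene_key(rec) == (83333, "B0001")


class TestRecordInvariants:
    def test_feature_beyond_sequence_rejected(self):
        with pytest.raises(ValueError, match="beyond sequence length"):
            make_record(ptm_features=[FeatureSite("MOD_RES", 150, 150)])

    def test_crosslink_may_extend_past_chain_end(self):
        rec = make_record(ptm_features=[FeatureSite("CROSSLNK", 90, 400)])
        assert rec.ptm_features[0].end == 400

    def test_inverted_feature_rejected(self):
        with pytest.raises(ValueError, match="begin"):
            FeatureSite("VARIANT", 10, 2)


def test_entry_audit_tsv(tmp_path, hand_written_record):
    path = tmp_path / "audit.tsv"
    write_entry_audit([hand_written_record], path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t") == [
        "accession", "taxon_id", "gene", "isoforms", "variants", "ptms"
    ]
    assert lines[1].split("\t") == ["P04637", "9606", "TP53", "3", "2", "1"]
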