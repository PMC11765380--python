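import io
import textwrap

import pytest

from proteowidth import parse_flatfile

HAND_WRITTEN_ENTRY = textwrap.dedent("""\
    ID   TP53_HUMAN              Reviewed;         120 AA.
    AC   P04637; Q15086;
    OX   NCBI_TaxID=9606;
    GN   Name=TP53; Synonyms=P53;
    CC   -!- ALTERNATIVE PRODUCTS:
    CC       Event=Alternative splicing; Named isoforms=3;
    CC       Name=1;
    CC         IsoId=P04637-1; Sequence=Displayed;
    FT   VARIANT         12
    FT                   /note="A -> G (in a tumor)"
    FT   VARIANT         47
    FT                   /note="P -> S (polymorphism)"
    FT   MOD_RES         30
    FT                   /note="Phosphoserine"
    SQ   SEQUENCE   120 AA;  13000 MW;  ABCDEF0123456789 CRC64;
         MKTAYIAKQR QISFVKSHFS RQLEERLGLI EVQAPILSRV GDGTQDNLSG AEKAVQVKVK
         ALPDAQFEVV HSLAKWKRQT LGQHDFSAGE GLYTHMKALR PDEDRLSPLH SVYVDQWDWE
    //
    """)


@pytest.fixture
def hand_written_record():
    """The spliced, SAP- and PTM-bearing entry written out line by line."""
    (record,) = parse_flatfile(io.StringIO(HAND_WRITTEN_ENTRY))
    return record


@pytest.fixture
def toy_orthogroups_tsv():
    """Three groups over human and mouse: OG1 shared, OG2 human-only,
    OG3 shared but its human protein is not an aging gene."""
    return io.StringIO(
        "Orthogroup\thuman\tmouse\n"
        "OG1\th1\tm1\n"
        "OG2\th2\t\n"
        "OG3\th3\tm2\n"
    )
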