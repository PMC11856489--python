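import warnings

import pytest

from mitodyn.synthetic_data import make_fixture

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def conserved7():
    return make_fixture("conserved7")


@pytest.fixture(scope="session")
def transposed():
    return make_fixture("transposed")


@pytest.fixture(scope="session")
def two_leaf():
    return make_fixture("two_leaf")


@pytest.fixture(scope="session")
def intron_cohort():
    rich, truth_rich = make_fixture("intron_rich")
    poor, truth_poor = make_fixture("intron_poor")
    return rich + poor, truth_rich, truth_poor


def _gb_seq_lines(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks.lower()}")
    return "\n".join(lines)


@pytest.fixture(scope="session")
def handwritten_genbank(tmp_path_factory):
    """A small hand-built GenBank file with foreign-style labels, a join()
    CDS with an intron gap, and a minus-strand tRNA."""
    seq = ("ATG" + "GCT" * 99 + "TAA")  # filler; coordinates are what matter
    seq = (seq * 8)[:2000]
    text = f"""LOCUS       TESTREC1                2000 bp    DNA     circular FUN 01-JAN-2025
DEFINITION  synthetic parser fixture.
ACCESSION   TESTREC1
SOURCE      synthetic construct
  ORGANISM  synthetic construct
FEATURES             Location/Qualifiers
     source          1..2000
                     /organism="synthetic construct"
     CDS             join(101..300,1501..1900)
                     /gene="COX1"
                     /product="cytochrome c oxidase subunit 1"
     CDS             351..401
                     /gene="ND4L"
                     /product="NADH dehydrogenase subunit 4L"
     CDS             421..480
                     /gene="orf19"
                     /product="hypothetical protein"
     tRNA            complement(501..572)
                     /gene="trnM"
     rRNA            601..900
                     /gene="rrnS"
ORIGIN
{_gb_seq_lines(seq)}
//
"""
    path = tmp_path_factory.mktemp("gb") / "hand.gb"
    path.write_text(text)
    return path
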