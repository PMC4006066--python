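import pytest

from sxrna.fixtures import SplintDesign, make_splint
from sxrna.motif import builtin_descriptor, match_motif
from sxrna.seqio import Transcript

#: 30-nt message with one HSL: AA bulge at [6,8), 6-bp stem, 4-nt loop.
WORKED_SEQ = "GAGAGAAAGGCUCUUUUCAGAGCCCACACC"
#: splint for it: arms 6/6, ncRNA-side junction of 2
WORKED_NCRNA = "GGUGUGAAUCUCUC"
#: its designed joint structure (30-nt mRNA & 14-nt ncRNA)
WORKED_DB = "((((((..((((((....))))))((((((&))))))..))))))"


@pytest.fixture(scope="session")
def hsl():
    return builtin_descriptor("hsl")


@pytest.fixture(scope="session")
def worked_transcript():
    return Transcript(id="worked", sequence=WORKED_SEQ)


@pytest.fixture(scope="session")
def worked_motif(hsl, worked_transcript):
    matches = match_motif(hsl, worked_transcript)
    assert len(matches) == 1
    return matches[0]


@pytest.fixture(scope="session")
def worked_splint(worked_transcript, worked_motif):
    return make_splint(
        worked_transcript, worked_motif, SplintDesign(arm5_len=6, arm3_len=6, gap=2)
    )
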