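import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from sxrna.motif import (
    DescriptorError,
    MotifDescriptor,
    SeqElement,
    StemClose,
    StemOpen,
    builtin_descriptor,
    descriptor_from_toml,
    match_motif,
)
from sxrna.seqio import Transcript

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "R": "AG", "Y": "CU", "S": "CG",
    "W": "AU", "K": "GU", "M": "AC", "B": "CGU", "D": "AGU", "H": "ACU",
    "V": "ACG", "N": "ACGU",
}
PAIRS_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
PAIRS_WOBBLE = PAIRS_WC | {("G", "U"), ("U", "G")}


def brute_force_matches(descriptor, seq):
    """Enumerate all (start, element-length assignment) combinations."""
    elements = descriptor.elements
    ranges = []
    for el in elements:
        if isinstance(el, StemClose):
            ranges.append((None,))  # length taken from its opener
        else:
            ranges.append(tuple(range(el.min_len, el.max_len + 1)))
    found = []
    for start in range(len(seq) + 1):
        for combo in itertools.product(*ranges):
            pos = start
            spans = []
            open_spans = {}
            ok = True
            for el, ln in zip(elements, combo):
                if isinstance(el, StemClose):
                    ln = open_spans[el.tag][1] - open_spans[el.tag][0]
                if pos + ln > len(seq):
                    ok = False
                    break
                span = (pos, pos + ln)
                if isinstance(el, SeqElement):
                    for i in range(ln):
                        base = seq[pos + i]
                        allowed = IUPAC[el.iupac[i]]
                        if base == "N":
                            if allowed != "ACGU":
                                ok = False
                                break
                        elif base not in allowed:
                            ok = False
                            break
                    if not ok:
                        break
                elif isinstance(el, StemOpen):
                    open_spans[el.tag] = span
                else:
                    opener = next(
                        e for e in elements
                        if isinstance(e, StemOpen) and e.tag == el.tag
                    )
                    o0, o1 = open_spans[el.tag]
                    allowed = PAIRS_WOBBLE if opener.allow_wobble else PAIRS_WC
                    mism = sum(
                        (seq[o0 + k], seq[span[1] - 1 - k]) not in allowed
                        for k in range(ln)
                    )
                    if mism > opener.max_mismatch:
                        ok = False
                        break
                spans.append(span)
                pos += ln
            if ok and len(spans) == len(elements):
                found.append((start, pos))
    return sorted(set(found), key=lambda t: (t[0], t[1] - t[0]))


class TestBuiltins:
    def test_hsl_stemloop_span_is_16(self, worked_motif):
        s, e = worked_motif.stemloop_span
        assert e - s == 16

    def test_hsl_anatomy_on_worked_transcript(self, worked_motif):
        m = worked_motif
        assert m.bulge_positions == (6, 7)
        assert m.stem5 == (8, 14)
        assert m.loop == (14, 18)
        assert m.stem3 == (18, 24)
        assert m.span == (6, 24)

    def test_ire_loop_pattern(self):
        ire = builtin_descriptor("ire")
        # CAGUGU satisfies CAGUGH; stem GGGGC / GCCCC
        tx = Transcript("t", "AAGGGGCCAGUGUGCCCCAA")
        (m,) = match_motif(ire, tx)
        assert tx.sequence[slice(*m.loop)] == "CAGUGU"
        assert m.stemloop_span[1] - m.stemloop_span[0] == 16

    def test_unknown_descriptor_lists_available(self):
        with pytest.raises(DescriptorError, match="hsl, ire"):
            builtin_descriptor("xyz")


class TestMatching:
    def test_all_a_transcript_has_no_match(self, hsl):
        assert match_motif(hsl, Transcript("t", "A" * 40)) == []

    def test_tandem_copies_reported_in_start_order(self, hsl, worked_transcript):
        double = Transcript("t2", worked_transcript.sequence * 2)
        starts = [m.span[0] for m in match_motif(hsl, double)]
        assert 6 in starts and 36 in starts
        assert starts == sorted(starts)

    def test_matches_shift_with_prefix(self, hsl, worked_transcript):
        prefix = "CCCC"
        shifted = Transcript("t", prefix + worked_transcript.sequence)
        base = match_motif(hsl, worked_transcript)
        moved = match_motif(hsl, shifted)
        assert [m.span[0] + len(prefix) for m in base] == [m.span[0] for m in moved]

    def test_returned_matches_satisfy_invariants(self, hsl):
        rng = random.Random(5)
        for _ in range(20):
            seq = "".join(rng.choice("ACGU") for _ in range(60))
            for m in match_motif(hsl, Transcript("t", seq)):
                assert m.stem5[1] == m.loop[0] and m.loop[1] == m.stem3[0]
                stem5 = seq[slice(*m.stem5)]
                stem3 = seq[slice(*m.stem3)]
                assert all(
                    (a, b) in PAIRS_WOBBLE
                    for a, b in zip(stem5, reversed(stem3))
                )

    @pytest.mark.parametrize("seed", range(8))
    def test_equivalence_with_bruteforce_oracle(self, hsl, seed):
        rng = random.Random(seed)
        # AU-biased alphabet raises the motif hit rate
        seq = "".join(rng.choice("AACGUU") for _ in range(120))
        got = [(m.span[0], m.span[1]) for m in match_motif(hsl, Transcript("t", seq))]
        assert got == brute_force_matches(hsl, seq)

    def test_wobble_stem_matches_and_is_flagged(self):
        d = builtin_descriptor("hsl")
        # stem5 GGGGGU vs stem3 GCCCCC: U·G wobble at the bottom pair
        tx = Transcript("t", "AAGGGGGUCCCCGCCCCC")
        (m,) = match_motif(d, tx)
        assert m.wobble_count == 1
        strict = MotifDescriptor(
            name="strict",
            elements=(
                SeqElement("AA", 2, 2),
                StemOpen("s", 6, 6, allow_wobble=False),
                SeqElement("NNNN", 4, 4),
                StemClose("s"),
            ),
            anchors5=(0,),
        )
        assert match_motif(strict, tx) == []

    def test_stem_mismatch_budget(self):
        lax = MotifDescriptor(
            name="lax",
            elements=(
                StemOpen("s", 6, 6, allow_wobble=True, max_mismatch=1),
                SeqElement("NNNN", 4, 4),
                StemClose("s"),
            ),
        )
        # one mismatch in the stem (A opposite C at the bottom pair)
        tx = Transcript("t", "GGCUCUUUUCAGAGCA")
        assert len(match_motif(lax, tx)) >= 1
        strict = MotifDescriptor(
            name="strict",
            elements=(
                StemOpen("s", 6, 6, allow_wobble=True, max_mismatch=0),
                SeqElement("NNNN", 4, 4),
                StemClose("s"),
            ),
        )
        assert all(
            m.span != (0, 16) for m in match_motif(strict, tx)
        )


class TestDescriptorConfig:
    TOML = """
name = "custom_hsl"
anchors5 = [0]
[[elements]]
kind = "seq"
iupac = "AA"
min_len = 2
max_len = 2
[[elements]]
kind = "stem_open"
tag = "s"
min_len = 6
max_len = 6
allow_wobble = true
max_mismatch = 0
[[elements]]
kind = "seq"
iupac = "NNNN"
min_len = 4
max_len = 4
[[elements]]
kind = "stem_close"
tag = "s"
"""

    def test_toml_descriptor_equivalent_to_builtin(self, worked_transcript, hsl):
        d = descriptor_from_toml(self.TOML)
        got = match_motif(d, worked_transcript)
        ref = match_motif(hsl, worked_transcript)
        assert [(m.span, m.stem5, m.stem3) for m in got] == [
            (m.span, m.stem5, m.stem3) for m in ref
        ]

    def test_toml_file_loading(self, tmp_path, worked_transcript):
        p = tmp_path / "d.toml"
        p.write_text(self.TOML)
        d = descriptor_from_toml(p)
        assert d.name == "custom_hsl"
        assert len(match_motif(d, worked_transcript)) == 1

    def test_malformed_descriptors_rejected(self):
        with pytest.raises(DescriptorError):
            MotifDescriptor("x", (StemOpen("s", 2, 6), SeqElement("NNNN", 4, 4)))
        with pytest.raises(DescriptorError):
            MotifDescriptor("x", (StemClose("s"),))
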