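import dataclasses
import random

import pytest

from sxrna.fold import parse_dotbracket
from sxrna.junction import (
    JunctionError,
    Thresholds,
    ablation_pairs,
    annotate_junction,
    motif_intact,
    score_and_classify,
    splints_base,
)
from sxrna.motif import MotifMatch
from tests.conftest import WORKED_DB
from tests.helpers import oracle_anchors, random_pair_table


@pytest.fixture()
def worked_pt():
    return parse_dotbracket(WORKED_DB, 30, 14)


def _motif_for(spans, tid="t"):
    return MotifMatch(
        transcript_id=tid,
        span=(spans["bulge"][0], spans["stem3"][1]),
        stem5=spans["stem5"],
        loop=spans["loop"],
        stem3=spans["stem3"],
        bulge_positions=tuple(range(*spans["bulge"])),
        descriptor_name="hsl",
    )


class TestMotifIntact:
    def test_worked_structure_all_stem_pairs(self, worked_pt, worked_motif):
        ok, diag = motif_intact(worked_pt, worked_motif, Thresholds())
        assert ok and diag == "6/6 stem pairs"

    def test_open_structure_reports_zero(self, worked_motif):
        pt = parse_dotbracket("." * 30 + "&" + "." * 14, 30, 14)
        ok, diag = motif_intact(pt, worked_motif, Thresholds())
        assert not ok and diag == "0/6 stem pairs"

    def test_loop_trans_pairing_gated_by_flag(self, worked_pt, worked_motif):
        # motif stem intact but one loop base pairs the ncRNA (crossing pair,
        # expressible only as a raw pair table)
        partner = list(worked_pt.partner)
        partner[15], partner[36] = 36, 15
        pt = dataclasses.replace(worked_pt, partner=tuple(partner))
        assert motif_intact(pt, worked_motif, Thresholds())[0] is False
        lax = Thresholds(require_loop_unpaired_trans=False)
        assert motif_intact(pt, worked_motif, lax)[0] is True

    def test_partial_stem_with_relaxed_fraction(self, worked_motif):
        # five of six stem pairs: bottom pair removed
        db = ".........(((((....))))).......&.............."
        pt = parse_dotbracket(db, 30, 14)
        assert motif_intact(pt, worked_motif, Thresholds())[0] is False
        assert motif_intact(pt, worked_motif, Thresholds(min_stem_frac=0.8))[0]

    def test_motif_outside_strand_is_error(self, worked_pt, worked_motif):
        bad = worked_motif.shifted(20)
        with pytest.raises(JunctionError):
            motif_intact(worked_pt, bad, Thresholds())


class TestSplintsBase:
    def test_worked_structure_splinted(self, worked_pt, worked_motif):
        assert splints_base(worked_pt, worked_motif, Thresholds())

    def test_one_sided_binding_is_not_splinting(self, worked_motif):
        db = "((((((..((((((....))))))......&........))))))"
        pt = parse_dotbracket(db, 30, 14)
        assert not splints_base(pt, worked_motif, Thresholds())

    def test_reach_bound(self, worked_pt, worked_motif):
        # nearest intermolecular pairs sit 3 (5') and 1 (3') bases from the
        # stem; max_reach=2 hides the 5' side
        assert not splints_base(worked_pt, worked_motif, Thresholds(max_reach=2))
        assert splints_base(worked_pt, worked_motif, Thresholds(max_reach=3))


class TestAnnotateJunction:
    def test_worked_anchor_positions_and_segments(self, worked_pt, worked_motif):
        ann = annotate_junction(worked_pt, worked_motif)
        assert (ann.purple5, ann.purple3) == (8, 23)
        assert (ann.blue5, ann.blue3) == (5, 24)
        assert (ann.orange5, ann.orange3) == (0, 29)
        assert (ann.green5, ann.green3) == (8, 5)
        assert (ann.mJ5, ann.mJ3, ann.nJ) == (2, 0, 2)
        assert (ann.h5_pairs, ann.h3_pairs) == (6, 6)
        assert ann.flank5_paired_frac == 1.0 and ann.flank3_paired_frac == 1.0
        assert ann.ncrna_paired_frac == pytest.approx(12 / 14)
        assert ann.bulge_unpaired
        assert ann.arm_order_ok

    def test_removing_terminal_flank_pair_moves_orange_only(
        self, worked_pt, worked_motif
    ):
        partner = list(worked_pt.partner)
        j = partner[0]
        partner[0] = partner[j] = None
        pt = dataclasses.replace(worked_pt, partner=tuple(partner))
        ann = annotate_junction(pt, worked_motif)
        assert ann.orange5 == 1 and ann.h5_pairs == 5
        assert (ann.mJ5, ann.mJ3, ann.nJ) == (2, 0, 2)

    def test_single_pair_helix_degenerate_case(self, worked_motif):
        # only 5'-flank pair is adjacent to the stem at position 7... the
        # bulge boundary: use position 5 (blue5 == orange5)
        db = ".....(..((((((....))))))(.....&.........)...)"
        pt = parse_dotbracket(db, 30, 14)
        ann = annotate_junction(pt, worked_motif)
        assert ann.blue5 == ann.orange5 == 5
        assert ann.mJ5 == 2 and ann.h5_span == 1 and ann.h5_pairs == 1

    def test_precondition_violation_raises(self, worked_motif):
        pt = parse_dotbracket("." * 30 + "&" + "." * 14, 30, 14)
        with pytest.raises(JunctionError):
            annotate_junction(pt, worked_motif)

    @pytest.mark.parametrize("seed", range(4))
    def test_anchors_agree_with_bruteforce_oracle(self, seed):
        rng = random.Random(seed)
        checked = 0
        for _ in range(300):
            pt, spans = random_pair_table(rng)
            motif = _motif_for(spans)
            expected = oracle_anchors(pt, motif.stem5[0], motif.stem3[1] - 1)
            if expected is None:
                continue
            ann = annotate_junction(pt, motif)
            got = {
                "blue5": ann.blue5,
                "orange5": ann.orange5,
                "blue3": ann.blue3,
                "orange3": ann.orange3,
                "green5": ann.green5,
                "green3": ann.green3,
            }
            assert got == expected
            checked += 1
        assert checked > 200


class TestScoreAndClassify:
    def test_worked_structure_is_inducer(self, worked_pt, worked_motif):
        cls, passed, ann, reasons = score_and_classify(
            worked_pt, worked_motif, Thresholds()
        )
        assert (cls, passed, reasons) == ("inducer", True, ())
        assert ann is not None

    def test_tight_njunction_threshold_fails_with_reason(
        self, worked_pt, worked_motif
    ):
        cls, passed, ann, reasons = score_and_classify(
            worked_pt, worked_motif, Thresholds(max_nJ=1)
        )
        assert cls == "none" and not passed
        assert "nJ 2 > 1" in reasons

    def test_ablation_is_repressor(self, worked_motif):
        # ncRNA pairs 10 bases across loop+stem3; no motif stem
        db = "..............((((((((((......&....))))))))))"
        pt = parse_dotbracket(db, 30, 14)
        assert ablation_pairs(pt, worked_motif) == 10
        cls, passed, ann, _ = score_and_classify(pt, worked_motif, Thresholds())
        assert cls == "repressor" and not passed and ann is None

    def test_weak_ablation_is_none(self, worked_motif):
        db = "..............((..............&............))"
        pt = parse_dotbracket(db, 30, 14)
        assert ablation_pairs(pt, worked_motif) == 2
        cls, *_ = score_and_classify(pt, worked_motif, Thresholds())
        assert cls == "none"

    def test_junction_bases_unpaired_to_other_strand(self, worked_pt, worked_motif):
        ann = annotate_junction(worked_pt, worked_motif)
        for p in range(ann.blue5 + 1, ann.purple5):
            assert not worked_pt.is_intermolecular(p)
        for p in range(ann.purple3 + 1, ann.blue3):
            assert not worked_pt.is_intermolecular(p)
        n0 = min(ann.green3, ann.green5)
        n1 = max(ann.green3, ann.green5)
        for q in range(n0 + 1, n1):
            assert not worked_pt.is_intermolecular(worked_pt.len_m + q)


RELAXATIONS = [
    dict(max_mJ5=12),
    dict(max_mJ3=12),
    dict(max_nJ=12),
    dict(min_helix_pairs=2),
    dict(min_flank_paired_frac=0.3),
    dict(min_ncrna_paired_frac=0.2),
    dict(min_stem_frac=0.5),
]


@pytest.mark.parametrize("relax", RELAXATIONS)
def test_threshold_monotonicity(relax, worked_pt, worked_motif):
    """Relaxing any single threshold never turns an inducer into a non-inducer."""
    base = Thresholds()
    relaxed = Thresholds(**relax)
    assert score_and_classify(worked_pt, worked_motif, base)[0] == "inducer"
    assert score_and_classify(worked_pt, worked_motif, relaxed)[0] == "inducer"
    rng = random.Random(101)
    for _ in range(300):
        pt, spans = random_pair_table(rng)
        motif = _motif_for(spans)
        before, *_ = score_and_classify(pt, motif, base)
        if before == "inducer":
            after, *_ = score_and_classify(pt, motif, relaxed)
            assert after == "inducer"


def test_thresholds_validation():
    with pytest.raises(ValueError):
        Thresholds(max_nJ=-1)
    with pytest.raises(ValueError):
        Thresholds(min_flank_paired_frac=1.5)
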