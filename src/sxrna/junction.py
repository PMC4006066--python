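"""Trans three-way-junction detection, annotation, scoring and classification.

Given the pair table of a cofolded (mRNA segment, ncRNA) complex and the
location of a stem-loop motif on the mRNA strand, decide whether the complex
is a *trans* three-way junction: the motif's own stem is intact (one helix),
and the ncRNA splints the two mRNA flanks at the motif's base (the two trans
helices), enclosing a junction of unpaired bases.

Anchor bookkeeping (all on the mRNA strand unless noted):

* **purple5 / purple3** — the bottom bases of the motif stem (first base of
  the 5′ arm, last base of the 3′ arm).
* **blue5 / blue3** — the first intermolecularly paired mRNA base 5′ / 3′ of
  the motif, i.e. nearest the motif base.
* **orange5 / orange3** — the last such bases, farthest from the motif base.
* **green5 / green3** — the ncRNA-local partners of blue5 / blue3.

Segments: purple→blue gaps are the mRNA-side junction lengths (mJ5, mJ3);
the gap between the green anchors is the ncRNA-side junction length (nJ);
blue→orange extents are the two trans helices.

Classification: **inducer** — motif intact, ncRNA splints both flanks, and
all thresholds hold (the ncRNA stabilizes the RBP motif); **repressor** —
the ncRNA hybridizes onto the motif's own stem/loop and the motif is not
intact (the ncRNA ablates the motif); **none** otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from sxrna.fold import PairTable
from sxrna.motif import MotifMatch


class JunctionError(ValueError):
    """Raised when junction operations are called outside their contract."""


@dataclass(frozen=True)
class Thresholds:
    """Acceptance thresholds for calling an inducer sxRNA.

    Junction-size bounds follow the sizes tolerated by cis three-way
    junctions; hybridization-quality bounds cap how sparse the trans helices
    may be.  All values are policy, exposed as configuration.
    """

    #: max unpaired mRNA bases between the motif base and each trans helix
    max_mJ5: int = 8
    max_mJ3: int = 8
    #: max unpaired ncRNA bases between the two trans helix arms
    max_nJ: int = 8
    #: min intermolecular pairs per trans helix
    min_helix_pairs: int = 4
    #: min fraction of mRNA bases paired within each trans-helix extent
    min_flank_paired_frac: float = 0.6
    #: min fraction of ncRNA bases intermolecularly paired
    min_ncrna_paired_frac: float = 0.5
    #: fraction of motif stem pairs that must be present intramolecularly
    min_stem_frac: float = 1.0
    #: forbid the motif loop from pairing with the ncRNA
    require_loop_unpaired_trans: bool = True
    #: min trans pairs on stem∪loop for a repressor verdict
    min_ablation_pairs: int = 3
    #: how far (mRNA bases) from the motif base a splinting pair may sit;
    #: the scan pipeline sets this to the window flank
    max_reach: int = 25

    def __post_init__(self) -> None:
        for name in ("max_mJ5", "max_mJ3", "max_nJ", "min_helix_pairs",
                     "min_ablation_pairs", "max_reach"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("min_flank_paired_frac", "min_ncrna_paired_frac",
                     "min_stem_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass(frozen=True)
class JunctionAnnotation:
    """Anchors, segment lengths and pairing fractions of one trans 3WJ."""

    purple5: int
    purple3: int
    blue5: int
    blue3: int
    orange5: int
    orange3: int
    green5: int  # ncRNA-local
    green3: int  # ncRNA-local
    mJ5: int
    mJ3: int
    nJ: int
    h5_pairs: int
    h3_pairs: int
    h5_span: int
    h3_span: int
    flank5_paired_frac: float
    flank3_paired_frac: float
    ncrna_paired_frac: float
    bulge_unpaired: bool

    def __post_init__(self) -> None:
        if not (self.orange5 <= self.blue5 < self.purple5
                <= self.purple3 < self.blue3 <= self.orange3):
            raise ValueError("anchor ordering violated")
        if self.mJ5 != self.purple5 - self.blue5 - 1:
            raise ValueError("mJ5 inconsistent with anchors")
        if self.mJ3 != self.blue3 - self.purple3 - 1:
            raise ValueError("mJ3 inconsistent with anchors")
        if self.nJ != abs(self.green5 - self.green3) - 1:
            raise ValueError("nJ inconsistent with green anchors")

    @property
    def arm_order_ok(self) -> bool:
        """Antiparallel splint geometry: the 5′ flank helix must engage the
        ncRNA 3′ arm and vice versa, so green5 lies 3′ of green3 on the
        ncRNA."""
        return self.green5 > self.green3

    def shifted(self, offset: int) -> "JunctionAnnotation":
        """mRNA-side anchors shifted by *offset* (window → transcript
        coordinates); ncRNA-local anchors unchanged."""
        return replace(
            self,
            purple5=self.purple5 + offset,
            purple3=self.purple3 + offset,
            blue5=self.blue5 + offset,
            blue3=self.blue3 + offset,
            orange5=self.orange5 + offset,
            orange3=self.orange3 + offset,
        )


@dataclass(frozen=True)
class SxRNACandidate:
    """One scored (transcript × motif × ncRNA × mode) combination."""

    transcript_id: str
    ncrna_id: str
    descriptor_name: str
    motif: MotifMatch
    mode: str
    annotation: Optional[JunctionAnnotation]
    classification: str  # inducer | repressor | none
    passed: bool
    fail_reasons: tuple[str, ...]
    backend_score: float = 0.0


def _check_motif_in_strand(pt: PairTable, motif: MotifMatch) -> None:
    if not (0 <= motif.span[0] and motif.span[1] <= pt.len_m):
        raise JunctionError(
            f"motif span {motif.span} outside mRNA strand of length {pt.len_m}"
        )


def stem_pairs_present(pt: PairTable, motif: MotifMatch) -> int:
    """Count of motif stem pairs present as intramolecular pairs.

    Stem pair k joins position ``stem5.start + k`` with ``stem3.end − 1 − k``.
    """
    count = 0
    for k in range(motif.stem_len):
        i = motif.stem5[0] + k
        j = motif.stem3[1] - 1 - k
        if pt.partner[i] == j:
            count += 1
    return count


def motif_intact(
    pt: PairTable, motif: MotifMatch, th: Thresholds
) -> tuple[bool, str]:
    """Is the motif's own stem-loop present in the joint structure?

    Returns (flag, diagnostic).  True iff at least ``min_stem_frac`` of the
    stem pairs are formed intramolecularly and — when
    ``require_loop_unpaired_trans`` — no loop base pairs with the ncRNA.
    """
    _check_motif_in_strand(pt, motif)
    present = stem_pairs_present(pt, motif)
    need = th.min_stem_frac * motif.stem_len
    if present < need:
        return False, f"{present}/{motif.stem_len} stem pairs"
    if th.require_loop_unpaired_trans:
        for p in range(*motif.loop):
            if pt.is_intermolecular(p):
                return False, f"loop position {p} paired to ncRNA"
    return True, f"{present}/{motif.stem_len} stem pairs"


def splints_base(pt: PairTable, motif: MotifMatch, th: Thresholds) -> bool:
    """Does the ncRNA bind across the motif's base?

    True iff some intermolecular pair lands within ``max_reach`` bases 5′ of
    the stem and another within ``max_reach`` bases 3′ of it.
    """
    _check_motif_in_strand(pt, motif)
    purple5 = motif.stem5[0]
    purple3 = motif.stem3[1] - 1
    has5 = any(
        pt.is_intermolecular(p)
        for p in range(max(0, purple5 - th.max_reach), purple5)
    )
    has3 = any(
        pt.is_intermolecular(p)
        for p in range(purple3 + 1, min(pt.len_m, purple3 + 1 + th.max_reach))
    )
    return has5 and has3


def annotate_junction(pt: PairTable, motif: MotifMatch) -> JunctionAnnotation:
    """Locate the anchors and measure all junction/helix segments.

    Contract: call only when :func:`motif_intact` and :func:`splints_base`
    are both true (there must be intermolecular pairs on both sides of the
    motif); otherwise :class:`JunctionError` is raised.
    """
    _check_motif_in_strand(pt, motif)
    purple5 = motif.stem5[0]
    purple3 = motif.stem3[1] - 1
    inter5 = [p for p in range(0, purple5) if pt.is_intermolecular(p)]
    inter3 = [p for p in range(purple3 + 1, pt.len_m) if pt.is_intermolecular(p)]
    if not inter5 or not inter3:
        raise JunctionError(
            "annotate_junction requires intermolecular pairs on both sides "
            "of the motif (splints_base precondition)"
        )
    blue5, orange5 = max(inter5), min(inter5)
    blue3, orange3 = min(inter3), max(inter3)
    green5 = pt.to_n_local(pt.partner[blue5])
    green3 = pt.to_n_local(pt.partner[blue3])

    h5_positions = range(orange5, blue5 + 1)
    h3_positions = range(blue3, orange3 + 1)
    h5_pairs = sum(1 for p in h5_positions if pt.is_intermolecular(p))
    h3_pairs = sum(1 for p in h3_positions if pt.is_intermolecular(p))
    h5_span = blue5 - orange5 + 1
    h3_span = orange3 - blue3 + 1
    n_inter_total = sum(
        1 for p in range(pt.len_m, pt.length) if pt.is_intermolecular(p)
    )
    return JunctionAnnotation(
        purple5=purple5,
        purple3=purple3,
        blue5=blue5,
        blue3=blue3,
        orange5=orange5,
        orange3=orange3,
        green5=green5,
        green3=green3,
        mJ5=purple5 - blue5 - 1,
        mJ3=blue3 - purple3 - 1,
        nJ=abs(green5 - green3) - 1,
        h5_pairs=h5_pairs,
        h3_pairs=h3_pairs,
        h5_span=h5_span,
        h3_span=h3_span,
        flank5_paired_frac=h5_pairs / h5_span,
        flank3_paired_frac=h3_pairs / h3_span,
        ncrna_paired_frac=n_inter_total / pt.len_n,
        bulge_unpaired=all(
            not pt.is_paired(p) for p in motif.bulge_positions
        ),
    )


def ablation_pairs(pt: PairTable, motif: MotifMatch) -> int:
    """Intermolecular pairs landing on the motif's stem or loop positions."""
    return sum(
        1
        for p in range(motif.stem5[0], motif.stem3[1])
        if pt.is_intermolecular(p)
    )


def score_and_classify(
    pt: PairTable,
    motif: MotifMatch,
    th: Thresholds,
) -> tuple[str, bool, Optional[JunctionAnnotation], tuple[str, ...]]:
    """Score one joint structure against the thresholds.

    Returns ``(classification, passed, annotation, fail_reasons)``:

    * ``inducer`` — motif intact, flanks splinted, every threshold met;
    * ``repressor`` — motif NOT intact and ≥ ``min_ablation_pairs``
      intermolecular pairs sit on the motif (positive ablation evidence);
    * ``none`` — anything else, with each failed requirement recorded.
    """
    intact, diag = motif_intact(pt, motif, th)
    reasons: list[str] = []
    if not intact:
        if ablation_pairs(pt, motif) >= th.min_ablation_pairs:
            return "repressor", False, None, (f"motif not intact: {diag}",)
        return "none", False, None, (f"motif not intact: {diag}",)
    if not splints_base(pt, motif, th):
        return "none", False, None, ("ncRNA does not splint the motif base",)

    ann = annotate_junction(pt, motif)
    if not ann.arm_order_ok:
        reasons.append("arm-order")
    if ann.mJ5 > th.max_mJ5:
        reasons.append(f"mJ5 {ann.mJ5} > {th.max_mJ5}")
    if ann.mJ3 > th.max_mJ3:
        reasons.append(f"mJ3 {ann.mJ3} > {th.max_mJ3}")
    if ann.nJ > th.max_nJ:
        reasons.append(f"nJ {ann.nJ} > {th.max_nJ}")
    if ann.h5_pairs < th.min_helix_pairs:
        reasons.append(f"h5_pairs {ann.h5_pairs} < {th.min_helix_pairs}")
    if ann.h3_pairs < th.min_helix_pairs:
        reasons.append(f"h3_pairs {ann.h3_pairs} < {th.min_helix_pairs}")
    if ann.flank5_paired_frac < th.min_flank_paired_frac:
        reasons.append(
            f"flank5_frac {ann.flank5_paired_frac:.2f} < {th.min_flank_paired_frac:.2f}"
        )
    if ann.flank3_paired_frac < th.min_flank_paired_frac:
        reasons.append(
            f"flank3_frac {ann.flank3_paired_frac:.2f} < {th.min_flank_paired_frac:.2f}"
        )
    if ann.ncrna_paired_frac < th.min_ncrna_paired_frac:
        reasons.append(
            f"ncrna_frac {ann.ncrna_paired_frac:.2f} < {th.min_ncrna_paired_frac:.2f}"
        )
    if reasons:
        return "none", False, ann, tuple(reasons)
    return "inducer", True, ann, ()
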