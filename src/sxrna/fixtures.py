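"""Seeded synthetic fixtures: motif-bearing transcripts, designed splint
ncRNAs with known junction geometry, and negative controls.

The generator emulates the inputs of a motif-centric cofold scan:

* :func:`make_motif_transcript` embeds exactly one motif instance in random
  flanks, rejection-sampling the flanks so they carry no complementarity run
  of ≥ 4 bases against each other or against the motif (such runs would let
  the fold maximizer build competing helices).
* :func:`make_splint` builds an ncRNA that is the reverse complement of the
  two flank segments abutting the motif base, separated by a designed
  junction gap — a guaranteed inducer geometry whose junction parameters
  (mJ5, mJ3, nJ, helix pair counts) are known by construction.
* :func:`make_negatives` builds repressor-style ablators (reverse complement
  of the motif's loop+stem) and dinucleotide-shuffled decoys.

What this does **not** emulate: real miRNA biology (seed regions, expression,
conservation) and real transcript context (long-range structure, proteins).
Passing recovery tests show the detector's bookkeeping is exact on designed
geometries, not that real sxRNAs are common.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from sxrna.fold import PairTable, pair_weight
from sxrna.junction import JunctionAnnotation
from sxrna.motif import (
    MotifDescriptor,
    MotifMatch,
    SeqElement,
    StemClose,
    StemOpen,
    match_motif,
)
from sxrna.rna import IUPAC, can_pair, revcomp
from sxrna.seqio import SmallRNA, Transcript

_BASES = "ACGU"


class FixtureError(RuntimeError):
    """Raised when fixture construction cannot satisfy its constraints."""


def max_complement_run(a: str, b: str, wobble: bool = True) -> int:
    """Longest antiparallel complementary run between strings *a* and *b*.

    A run of length k means a[i..i+k) can helix with b[j-k+1..j+1) reversed.
    """
    best = 0
    prev = [0] * (len(b) + 2)
    # run[i][j]: length of complementary run ending at (a[i], b[j]) with the
    # next pair being (a[i+1], b[j-1])
    for i in range(len(a)):
        cur = [0] * (len(b) + 2)
        for j in range(len(b)):
            if can_pair(a[i], b[j], wobble):
                cur[j] = prev[j + 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _sample_iupac(code: str, rng: random.Random) -> str:
    return rng.choice(IUPAC[code])


def _has_slippage(seq: str, match) -> bool:
    """True when an equal-weight alternative pairing can displace a designed
    helix end (a degeneracy of any base-pair-count fold model).

    Three local degeneracies matter: the first/last loop base stealing the
    bottom stem pair, and — when a bulge abuts the 5' arm target — the bulge
    base stealing the flank base's intermolecular pair.  Rejecting them makes
    the designed splint structure dominant rather than merely tied.
    """
    s5_last = seq[match.stem5[1] - 1]
    s3_first = seq[match.stem3[0]]
    loop_first = seq[match.loop[0]]
    loop_last = seq[match.loop[1] - 1]
    w_bottom = pair_weight(s5_last, s3_first)
    if pair_weight(loop_first, s3_first) >= w_bottom:
        return True
    if pair_weight(s5_last, loop_last) >= w_bottom:
        return True
    if match.bulge_positions:
        first_bulge = min(match.bulge_positions)
        if first_bulge > 0:
            flank_last = seq[first_bulge - 1]
            bulge_base = seq[max(match.bulge_positions)]
            # the ncRNA base designed to pair flank_last is its WC complement
            partner = revcomp(flank_last)
            if pair_weight(bulge_base, partner) >= pair_weight(flank_last, partner):
                return True
            # with a zero-length ncRNA junction the base adjacent to the 3'
            # arm block is comp(flank_last); it must not steal the bottom
            # stem pair (purple5-purple3)
            purple3_base = seq[match.stem3[1] - 1]
            if pair_weight(purple3_base, partner) >= pair_weight(
                seq[match.stem5[0]], purple3_base
            ):
                return True
        # a bulge base pairing cis with the first bases 3' of the stem would
        # merge bulge and flank into one extended stem, displacing the
        # designed 3' trans helix
        bulge_bases = {seq[q] for q in match.bulge_positions}
        for k in (1, 2):
            p = match.stem3[1] - 1 + k
            if p < len(seq) and any(can_pair(b, seq[p]) for b in bulge_bases):
                return True
    return False


def _instantiate_motif(descriptor: MotifDescriptor, rng: random.Random) -> str:
    """One concrete sequence realization of a descriptor (minimum lengths,
    pure Watson-Crick stem)."""
    parts: list[str] = []
    arms: dict[str, str] = {}
    for el in descriptor.elements:
        if isinstance(el, SeqElement):
            parts.append("".join(_sample_iupac(c, rng) for c in el.iupac[: el.min_len]))
        elif isinstance(el, StemOpen):
            arm = "".join(rng.choice(_BASES) for _ in range(el.min_len))
            arms[el.tag] = arm
            parts.append(arm)
        elif isinstance(el, StemClose):
            parts.append(revcomp(arms[el.tag]))
    return "".join(parts)


def _clean_against(s: str, other: str) -> bool:
    """No ≥4 complementary run between *s* and *other* in either
    orientation (direct pairing, or pairing of *other* with s's reverse
    complement — the orientation a designed splint arm would present)."""
    return (
        max_complement_run(s, other) < 4
        and max_complement_run(other, revcomp(s)) < 4
    )


def _grow_flank(
    length: int, others: tuple[str, ...], rng: random.Random
) -> Optional[str]:
    """Sample a flank of *length* bases with no ≥4 complementary run against
    any of *others* (either orientation), extending one base at a time."""
    s = ""
    for _ in range(length):
        order = list(_BASES)
        rng.shuffle(order)
        for base in order:
            cand = s + base
            if all(_clean_against(cand, other) for other in others):
                s = cand
                break
        else:
            return None
    return s


def make_motif_transcript(
    descriptor: MotifDescriptor,
    flank5_len: int,
    flank3_len: int,
    seed: int,
    max_tries: int = 500,
) -> tuple[Transcript, MotifMatch]:
    """A random transcript containing exactly one occurrence of *descriptor*.

    Flanks are rejection-sampled (seeded) so that no complementarity run of
    ≥ 4 bases exists between the two flanks or between either flank and the
    motif region, and so the descriptor matches the transcript exactly once.
    """
    if flank5_len < 0 or flank3_len < 0:
        raise ValueError("flank lengths must be >= 0")
    rng = random.Random(seed)
    tid = f"{descriptor.name}_tx_s{seed}"
    for _ in range(max_tries):
        core = _instantiate_motif(descriptor, rng)
        # grow each flank base by base, rejecting any base that completes a
        # ≥4 complementary run against the motif or the other flank, in
        # either orientation — splint arms are flank reverse complements, so
        # a run between the motif and a flank's reverse complement would let
        # the designed arm helix relocate onto the motif (trans competition);
        # sequential construction keeps the joint constraint satisfiable
        # where independent whole-flank resampling is hopeless
        flank5 = _grow_flank(flank5_len, (core,), rng)
        if flank5 is None:
            continue
        flank3 = _grow_flank(flank3_len, (core, flank5), rng)
        if flank3 is None:
            continue
        tx = Transcript(id=tid, sequence=flank5 + core + flank3)
        matches = match_motif(descriptor, tx)
        if len(matches) != 1:
            continue
        if matches[0].span[0] != flank5_len:
            continue
        # the stem pair closing the junction is constrained to G·C, as in
        # the natural histone stem-loop; a weakly closed junction lets a
        # splint arm trade the bottom stem pair for junction pairing
        mm = matches[0]
        if pair_weight(tx.sequence[mm.stem5[0]], tx.sequence[mm.stem3[1] - 1]) != 3:
            continue
        if _has_slippage(tx.sequence, mm):
            continue
        return tx, mm
    raise FixtureError(
        f"could not build a clean motif transcript in {max_tries} tries; "
        "try another seed or longer flanks"
    )


@dataclass(frozen=True)
class SplintDesign:
    """Geometry of a designed inducer ncRNA."""

    arm5_len: int  # trans helix on the 5' flank
    arm3_len: int  # trans helix on the 3' flank
    gap: int  # designed ncRNA-side junction (nJ)
    bulge: str = "AA"  # mRNA bases left unpaired 5' of the stem (mJ5)
    mJ3_gap: int = 0  # mRNA bases left unpaired 3' of the stem (mJ3)
    mismatch_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm5_len < 1 or self.arm3_len < 1:
            raise ValueError("arm lengths must be >= 1")
        if self.gap < 0 or self.mJ3_gap < 0:
            raise ValueError("gaps must be >= 0")
        if not 0.0 <= self.mismatch_rate <= 1.0:
            raise ValueError("mismatch_rate must be in [0,1]")


@dataclass(frozen=True)
class SplintResult:
    smallrna: SmallRNA
    #: junction parameters implied by the design; None when mismatches were
    #: introduced (the designed structure is then no longer valid)
    truth: Optional[JunctionAnnotation]
    #: the designed joint structure (transcript & ncRNA dot-bracket), or None
    dotbracket: Optional[str]


def _gap_fill(length: int, avoid: str) -> str:
    """Deterministic junction filler.

    Prefers, in order A/U/G/C (weight-3-capable bases last), the first base
    that cannot pair (wobble included) with any base in *avoid*; if every
    base is blocked, falls back to the one with the smallest worst-case pair
    weight against *avoid*.
    """
    order = "AUGC"
    choice = None
    for cand in order:
        if not any(can_pair(cand, b) for b in avoid):
            choice = cand
            break
    if choice is None:
        choice = min(
            order, key=lambda c: max(pair_weight(c, b) for b in avoid)
        )
    return choice * length


def make_splint(
    transcript: Transcript, motif: MotifMatch, design: SplintDesign
) -> SplintResult:
    """Design an ncRNA that splints the motif's flanks.

    5'→3' the ncRNA reads: reverse complement of the ``arm3_len`` mRNA bases
    starting ``mJ3_gap`` bases 3' of the stem, then ``gap`` junction bases
    chosen not to pair with the mRNA-side junction, then the reverse
    complement of the ``arm5_len`` mRNA bases ending immediately 5' of the
    bulge.  With ``mismatch_rate`` 0 the designed structure is a valid
    nested trans 3WJ with mJ5 = len(bulge), mJ3 = mJ3_gap, nJ = gap,
    h5_pairs = arm5_len, h3_pairs = arm3_len.
    """
    seq = transcript.sequence
    purple5 = motif.stem5[0]
    purple3 = motif.stem3[1] - 1
    bulge_len = len(design.bulge)
    if motif.bulge_positions:
        if tuple(range(purple5 - len(motif.bulge_positions), purple5)) != tuple(
            motif.bulge_positions
        ):
            raise ValueError("motif bulge is not flush with the 5' stem base")
        bulge_len = len(motif.bulge_positions)

    start5 = purple5 - bulge_len - design.arm5_len
    blue3 = purple3 + 1 + design.mJ3_gap
    if start5 < 0:
        raise ValueError("arm5_len longer than available 5' flank")
    if blue3 + design.arm3_len > transcript.length:
        raise ValueError("arm3_len longer than available 3' flank")

    target5 = seq[start5 : start5 + design.arm5_len]
    target3 = seq[blue3 : blue3 + design.arm3_len]
    # junction filler must not pair the mRNA-side junction bases, nor the
    # bottom stem bases: a filler base pairing purple5/purple3 trades the
    # bottom stem pair for an arm extension at equal weight (stem slippage)
    junction_m = (
        seq[start5 + design.arm5_len : purple5]
        + seq[purple3 + 1 : blue3]
        + seq[purple5]
        + seq[purple3]
    )
    arm_n3 = revcomp(target3)  # ncRNA 5' arm, pairs the mRNA 3' flank
    arm_n5 = revcomp(target5)  # ncRNA 3' arm, pairs the mRNA 5' flank

    rng = random.Random(design.seed)
    mismatched = False
    if design.mismatch_rate > 0:
        def scramble(arm: str) -> str:
            nonlocal mismatched
            out = []
            for c in arm:
                if rng.random() < design.mismatch_rate:
                    mismatched = True
                    out.append(rng.choice([b for b in _BASES if b != c]))
                else:
                    out.append(c)
            return "".join(out)

        arm_n3 = scramble(arm_n3)
        arm_n5 = scramble(arm_n5)

    ncrna_seq = arm_n3 + _gap_fill(design.gap, junction_m) + arm_n5
    nc_len = len(ncrna_seq)
    smallrna = SmallRNA(
        id=f"splint_{transcript.id}_a{design.arm5_len}_{design.arm3_len}"
        f"_g{design.gap}_s{design.seed}",
        sequence=ncrna_seq,
    )
    if mismatched:
        return SplintResult(smallrna=smallrna, truth=None, dotbracket=None)

    len_m = transcript.length
    partner: list[Optional[int]] = [None] * (len_m + nc_len)

    def pair(i: int, j: int) -> None:
        partner[i], partner[j] = j, i

    for k in range(motif.stem_len):
        pair(motif.stem5[0] + k, motif.stem3[1] - 1 - k)
    for k in range(design.arm3_len):  # mRNA 3' flank vs ncRNA 5' arm
        pair(blue3 + k, len_m + design.arm3_len - 1 - k)
    for k in range(design.arm5_len):  # mRNA 5' flank vs ncRNA 3' arm
        pair(start5 + k, len_m + nc_len - 1 - k)
    pt = PairTable(len_m=len_m, len_n=nc_len, partner=tuple(partner))

    blue5 = start5 + design.arm5_len - 1
    truth = JunctionAnnotation(
        purple5=purple5,
        purple3=purple3,
        blue5=blue5,
        blue3=blue3,
        orange5=start5,
        orange3=blue3 + design.arm3_len - 1,
        green5=nc_len - 1 - design.arm5_len + 1,
        green3=design.arm3_len - 1,
        mJ5=bulge_len,
        mJ3=design.mJ3_gap,
        nJ=design.gap,
        h5_pairs=design.arm5_len,
        h3_pairs=design.arm3_len,
        h5_span=design.arm5_len,
        h3_span=design.arm3_len,
        flank5_paired_frac=1.0,
        flank3_paired_frac=1.0,
        ncrna_paired_frac=(design.arm5_len + design.arm3_len) / nc_len,
        bulge_unpaired=True,
    )
    return SplintResult(smallrna=smallrna, truth=truth, dotbracket=pt.render())


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Shuffle *seq* preserving its exact dinucleotide counts
    (Altschul-Erickson Eulerian-walk shuffle)."""
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = set(edges) | {last}
    # choose a random final out-edge per vertex such that every vertex can
    # still reach `last` through the chosen final edges
    while True:
        final: dict[str, str] = {}
        for v in edges:
            if v != last:
                final[v] = rng.choice(edges[v])
        ok = True
        for v in final:
            u, seen = v, set()
            while u != last and u in final and u not in seen:
                seen.add(u)
                u = final[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    walk_edges: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in final:
            rest.remove(final[v])
        rng.shuffle(rest)
        walk_edges[v] = rest + ([final[v]] if v in final else [])
    out = [seq[0]]
    cur = seq[0]
    while walk_edges.get(cur):
        cur = walk_edges[cur].pop(0)
        out.append(cur)
    return "".join(out)


def make_negatives(
    transcript: Transcript, motif: MotifMatch, n: int, seed: int
) -> list[SmallRNA]:
    """Negative/repressor controls for one (transcript, motif).

    The first ``ceil(n/2)`` records are **ablators** — reverse complements of
    the motif's loop+stem3 (extended 0-2 bases into stem5) that hybridize
    onto the conserved motif and destroy it (expected classification:
    repressor).  The rest are **decoys** — dinucleotide-shuffled versions of
    the designed splint (expected classification: none).  The id prefix
    (``ablator``/``decoy``) carries the expected label.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    out: list[SmallRNA] = []
    n_ablators = (n + 1) // 2
    for i in range(n_ablators):
        ext = i % 3
        start = motif.loop[0] - ext
        segment = transcript.sequence[start : motif.stem3[1]]
        out.append(
            SmallRNA(id=f"ablator_{transcript.id}_{i}", sequence=revcomp(segment))
        )
    if n - n_ablators > 0:
        # decoys shuffle a splint-like sequence (same length/composition as a
        # genuine inducer for this motif)
        purple5 = motif.stem5[0]
        bulge_len = len(motif.bulge_positions)
        arm5 = min(6, purple5 - bulge_len)
        arm3 = min(6, transcript.length - motif.stem3[1])
        if arm5 >= 1 and arm3 >= 1:
            base = make_splint(
                transcript, motif, SplintDesign(arm5, arm3, gap=2, seed=seed)
            ).smallrna.sequence
        else:  # motif flush with transcript ends: shuffle the ablator instead
            base = out[0].sequence
        for i in range(n - n_ablators):
            # a shuffle of a short arm sequence can retain functional runs by
            # chance; redraw until the decoy has no ≥4 complementary run
            # against the transcript (else keep the cleanest draw), so the
            # "expected none" label holds by construction
            best = None
            best_run = 10**9
            for _ in range(20):
                cand = dinucleotide_shuffle(base, rng)
                run = max_complement_run(cand, transcript.sequence)
                if run < best_run:
                    best, best_run = cand, run
                if run < 4:
                    break
            out.append(SmallRNA(id=f"decoy_{transcript.id}_{i}", sequence=best))
    return out
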