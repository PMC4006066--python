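"""Independent oracles used by the test suite.

These deliberately re-derive results by the dumbest correct route — direct
enumeration and linear scans — and share no code with the implementation
paths they check.
"""

from __future__ import annotations

import functools
import random
from typing import Optional

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}
WEIGHT = {**{p: 3 for p in (("G", "C"), ("C", "G"))},
          **{p: 2 for p in (("A", "U"), ("U", "A"))},
          **{p: 1 for p in (("G", "U"), ("U", "G"))}}


def oracle_max_weight(seq_m: str, seq_n: str) -> int:
    """Maximum total pair weight over all nested structures of the
    concatenated two-strand sequence, by memoized interval recursion."""
    seq = seq_m + seq_n
    len_m = len(seq_m)

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i >= j:
            return 0
        top = best(i + 1, j)
        for k in range(i + 1, j + 1):
            w = WEIGHT.get((seq[i], seq[k]), 0)
            if w == 0:
                continue
            if (i < len_m) == (k < len_m) and k - i - 1 < 3:
                continue
            top = max(top, w + best(i + 1, k - 1) + best(k + 1, j))
        return top

    return best(0, len(seq) - 1)


def enumerate_structures(seq_m: str, seq_n: str):
    """Yield every nested structure (as frozenset of pairs) — tiny inputs only."""
    seq = seq_m + seq_n
    len_m = len(seq_m)

    def gen(i: int, j: int):
        if i > j:
            yield frozenset()
            return
        # position i unpaired
        for rest in gen(i + 1, j):
            yield rest
        for k in range(i + 1, j + 1):
            if (seq[i], seq[k]) not in WEIGHT:
                continue
            if (i < len_m) == (k < len_m) and k - i - 1 < 3:
                continue
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield inner | outer | {(i, k)}

    yield from gen(0, len(seq) - 1)


def oracle_anchors(pt, purple5: int, purple3: int):
    """Extremal intermolecularly paired mRNA positions on each side of the
    motif base, straight from the full pair list."""
    inter = [
        i
        for i in range(pt.len_m)
        if pt.partner[i] is not None and pt.partner[i] >= pt.len_m
    ]
    left = [p for p in inter if p < purple5]
    right = [p for p in inter if p > purple3]
    if not left or not right:
        return None
    return {
        "blue5": max(left),
        "orange5": min(left),
        "blue3": min(right),
        "orange3": max(right),
        "green5": pt.partner[max(left)] - pt.len_m,
        "green3": pt.partner[min(right)] - pt.len_m,
    }


def random_pair_table(rng: random.Random):
    """A random two-strand involution with an intact embedded stem and
    intermolecular pairs on both flanks (not necessarily nested).

    Returns (PairTable, MotifMatch-like spans dict).
    """
    from sxrna.fold import PairTable

    f5 = rng.randint(3, 10)
    stem = rng.randint(3, 6)
    loop = 4
    f3 = rng.randint(3, 10)
    len_m = f5 + 2 + 2 * stem + loop + f3
    len_n = rng.randint(6, 20)
    partner: list[Optional[int]] = [None] * (len_m + len_n)
    stem5_start = f5 + 2
    stem3_end = stem5_start + 2 * stem + loop
    for k in range(stem):
        i, j = stem5_start + k, stem3_end - 1 - k
        partner[i], partner[j] = j, i
    free_n = list(range(len_m, len_m + len_n))
    rng.shuffle(free_n)
    left = list(range(0, f5))
    right = list(range(stem3_end, len_m))
    rng.shuffle(left)
    rng.shuffle(right)
    for side in (left, right):
        n_pairs = rng.randint(1, len(side))
        for p in side[:n_pairs]:
            if not free_n:
                break
            q = free_n.pop()
            partner[p], partner[q] = q, p
    pt = PairTable(len_m=len_m, len_n=len_n, partner=tuple(partner))
    spans = {
        "stem5": (stem5_start, stem5_start + stem),
        "loop": (stem5_start + stem, stem5_start + stem + loop),
        "stem3": (stem3_end - stem, stem3_end),
        "bulge": (f5, f5 + 2),
    }
    return pt, spans
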