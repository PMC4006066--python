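"""Joint secondary structure of an mRNA segment and one ncRNA.

The two strands are concatenated (mRNA first) and folded as a single nested
structure, the standard trick for cofolding: intermolecular pairs are
ordinary pairs that happen to cross the strand break, and the minimum
hairpin-loop constraint (≥ 3 unpaired bases) does not apply across the break.
Pseudoknots — including "kissing" topologies that crossing intermolecular
pairs would create — are outside the model; dot-bracket input uses a single
bracket family.

Two backends satisfy the same contract:

``reference``
    A deterministic weighted base-pair maximizer (G·C = 3, A·U = 2, G·U = 1)
    by Nussinov-style dynamic programming.  Ties are broken exactly: prefer
    leaving position *i* unpaired, else pair *i* with the smallest admissible
    *j*.  No external dependency; every example is bit-reproducible.

``external``
    The ViennaRNA ``RNAcofold`` executable (minimum-free-energy, full
    nearest-neighbor thermodynamics).  Unavailability raises
    :class:`BackendError`; there is never a silent fallback.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass
from typing import Optional

from sxrna.rna import can_pair

#: Pair weights of the reference backend (hydrogen-bond counts; G·U wobble
#: counts one).
PAIR_WEIGHTS = {
    ("G", "C"): 3,
    ("C", "G"): 3,
    ("A", "U"): 2,
    ("U", "A"): 2,
    ("G", "U"): 1,
    ("U", "G"): 1,
}

#: Minimum unpaired bases in an intramolecular hairpin loop.
MIN_HAIRPIN = 3


class DotBracketError(ValueError):
    """Raised for malformed dot-bracket strings."""


class BackendError(RuntimeError):
    """Raised when the requested fold backend is unavailable or fails."""


@dataclass(frozen=True)
class PairTable:
    """Position→partner map over the combined (mRNA + ncRNA) coordinate axis.

    Combined positions ``0 .. len_m-1`` are the mRNA strand, ``len_m ..
    len_m+len_n-1`` the ncRNA strand.  ``partner[i]`` is the combined partner
    position or ``None``.
    """

    len_m: int
    len_n: int
    partner: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.partner) != self.len_m + self.len_n:
            raise ValueError("partner table length mismatch")
        for i, j in enumerate(self.partner):
            if j is None:
                continue
            if j == i:
                raise ValueError(f"position {i} pairs with itself")
            if self.partner[j] != i:
                raise ValueError(f"pairing not an involution at {i}<->{j}")

    @property
    def length(self) -> int:
        return self.len_m + self.len_n

    def strand_of(self, i: int) -> str:
        return "m" if i < self.len_m else "n"

    def to_n_local(self, i: int) -> int:
        """Combined → ncRNA-local coordinate."""
        if i < self.len_m:
            raise ValueError(f"combined position {i} is on the mRNA strand")
        return i - self.len_m

    def is_paired(self, i: int) -> bool:
        return self.partner[i] is not None

    def is_intermolecular(self, i: int) -> bool:
        j = self.partner[i]
        return j is not None and self.strand_of(i) != self.strand_of(j)

    def pairs(self) -> list[tuple[int, int]]:
        """All pairs as (i, j) with i < j, ascending in i."""
        return [
            (i, j) for i, j in enumerate(self.partner) if j is not None and i < j
        ]

    def inter_pairs(self) -> list[tuple[int, int]]:
        """Intermolecular pairs as (mRNA position, ncRNA-local position)."""
        return [
            (i, self.to_n_local(j))
            for i, j in self.pairs()
            if i < self.len_m <= j
        ]

    def render(self) -> str:
        """Dot-bracket string with '&' at the strand break."""
        chars = ["."] * self.length
        for i, j in self.pairs():
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars[: self.len_m]) + "&" + "".join(chars[self.len_m :])


@dataclass(frozen=True)
class JointStructure:
    """A two-strand structure in dot-bracket notation plus a backend score."""

    seq_m: str
    seq_n: str
    dotbracket: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.dotbracket.count("&") != 1:
            raise DotBracketError("dot-bracket must contain exactly one '&'")
        stripped = self.dotbracket.replace("&", "")
        if len(stripped) != len(self.seq_m) + len(self.seq_n):
            raise DotBracketError(
                f"dot-bracket length {len(stripped)} != sequence lengths "
                f"{len(self.seq_m)}+{len(self.seq_n)}"
            )

    def pair_table(self) -> PairTable:
        return parse_dotbracket(self.dotbracket, len(self.seq_m), len(self.seq_n))


def parse_dotbracket(db: str, len_m: int, len_n: int) -> PairTable:
    """Parse a two-strand dot-bracket string into a :class:`PairTable`.

    Stack-based matching of '(' with ')'; '&' marks the strand break and
    consumes no position.  Only the nested single-family alphabet '(', ')',
    '.' is accepted — pseudoknot families ('[', '{', …) are rejected.
    """
    if db.count("&") != 1:
        raise DotBracketError("expected exactly one '&' strand separator")
    amp = db.index("&")
    if amp != len_m:
        raise DotBracketError(
            f"strand separator at position {amp}, expected {len_m}"
        )
    stripped = db.replace("&", "")
    if len(stripped) != len_m + len_n:
        raise DotBracketError(
            f"structure length {len(stripped)} != len_m+len_n = {len_m + len_n}"
        )
    partner: list[Optional[int]] = [None] * (len_m + len_n)
    stack: list[int] = []
    for i, c in enumerate(stripped):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise DotBracketError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[i] = j
            partner[j] = i
        elif c != ".":
            raise DotBracketError(
                f"invalid character {c!r} at position {i} "
                "(single nested bracket family only)"
            )
    if stack:
        raise DotBracketError(f"unbalanced '(' at position {stack[-1]}")
    return PairTable(len_m=len_m, len_n=len_n, partner=tuple(partner))


def _check_seq(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(
            f"{label} sequence contains {sorted(bad)}; normalize to A/C/G/U/N first"
        )


def pair_weight(a: str, b: str) -> int:
    """Reference-backend weight of pairing bases *a* and *b* (0 if forbidden)."""
    return PAIR_WEIGHTS.get((a, b), 0)


def _admissible(seq: str, len_m: int, i: int, j: int) -> int:
    """Weight of pair (i,j) if admissible, else 0.

    Intramolecular pairs need a hairpin loop of ≥ MIN_HAIRPIN unpaired bases;
    pairs across the strand break have no distance constraint.
    """
    w = PAIR_WEIGHTS.get((seq[i], seq[j]), 0)
    if w == 0:
        return 0
    same_strand = (i < len_m) == (j < len_m)
    if same_strand and j - i - 1 < MIN_HAIRPIN:
        return 0
    return w


#: Lexicographic packing: primary objective is total pair weight, secondary
#: is the number of stacked pairs (pair (i,j) with (i+1,j-1) also paired).
#: Stacking only resolves weight ties — real helices are contiguous, and an
#: unguided tie-break fragments them.  SHIFT exceeds any possible stack count.
_SHIFT = 12


def _cofold_reference(seq_m: str, seq_n: str) -> JointStructure:
    seq = seq_m + seq_n
    len_m = len(seq_m)
    n = len(seq)
    NEG = -1
    # F[i][j]: best packed (weight, stacks) on interval [i, j], inclusive.
    # P[i][j]: best packed value given that (i, j) is a pair (NEG if i,j
    # cannot pair).
    F = [[0] * n for _ in range(n)]
    P = [[NEG] * n for _ in range(n)]
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            w = _admissible(seq, len_m, i, j)
            if w:
                if i + 1 <= j - 1:
                    interior = F[i + 1][j - 1]
                    if P[i + 1][j - 1] >= 0 and P[i + 1][j - 1] + 1 > interior:
                        interior = P[i + 1][j - 1] + 1  # stacked on (i+1,j-1)
                else:
                    interior = 0
                P[i][j] = (w << _SHIFT) + interior
            best = F[i + 1][j]
            row_p = P[i]
            for k in range(i + 1, j + 1):
                pk = row_p[k]
                if pk < 0:
                    continue
                cand = pk + (F[k + 1][j] if k + 1 <= j else 0)
                if cand > best:
                    best = cand
            F[i][j] = best

    partner: list[Optional[int]] = [None] * n
    # Traceback on the packed score; residual ties: prefer i unpaired, else
    # pair i with the smallest admissible j.
    stack = [(0, n - 1, False)]
    while stack:
        i, j, paired = stack.pop()
        if paired:
            partner[i], partner[j] = j, i
            if i + 1 <= j - 1:
                interior = F[i + 1][j - 1]
                if P[i + 1][j - 1] >= 0 and P[i + 1][j - 1] + 1 > interior:
                    stack.append((i + 1, j - 1, True))
                else:
                    stack.append((i + 1, j - 1, False))
            continue
        if i >= j:
            continue
        best = F[i][j]
        if best == F[i + 1][j]:
            stack.append((i + 1, j, False))
            continue
        for k in range(i + 1, j + 1):
            if P[i][k] < 0:
                continue
            if P[i][k] + (F[k + 1][j] if k + 1 <= j else 0) == best:
                stack.append((i, k, True))
                stack.append((k + 1, j, False))
                break
    pt = PairTable(len_m=len_m, len_n=len(seq_n), partner=tuple(partner))
    score = sum(pair_weight(seq[i], seq[j]) for i, j in pt.pairs())
    return JointStructure(
        seq_m=seq_m, seq_n=seq_n, dotbracket=pt.render(), score=float(score)
    )


def _cofold_external(seq_m: str, seq_n: str) -> JointStructure:
    try:
        proc = subprocess.run(
            ["RNAcofold", "--noPS"],
            input=f"{seq_m}&{seq_n}\n",
            capture_output=True,
            text=True,
            check=True,
        )
    except FileNotFoundError as exc:
        raise BackendError(
            "external backend requested but RNAcofold is not on PATH"
        ) from exc
    except subprocess.CalledProcessError as exc:
        raise BackendError(f"RNAcofold failed: {exc.stderr}") from exc
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise BackendError(f"unexpected RNAcofold output: {proc.stdout!r}")
    tokens = lines[1].split(None, 1)
    structure = tokens[0]
    try:
        energy = float(tokens[1].strip().strip("()").strip())
    except (IndexError, ValueError) as exc:
        raise BackendError(f"cannot parse RNAcofold energy: {lines[1]!r}") from exc
    return JointStructure(
        seq_m=seq_m, seq_n=seq_n, dotbracket=structure, score=energy
    )


def cofold(seq_m: str, seq_n: str, backend: str = "reference") -> JointStructure:
    """Joint structure of mRNA segment *seq_m* and ncRNA *seq_n*.

    The reference backend maximizes total pair weight; its ``score`` is that
    weight (higher = more pairing).  The external backend reports a free
    energy in kcal/mol (lower = more stable).  Downstream junction analysis
    uses only the pairing pattern, never the score's units.
    """
    _check_seq(seq_m, "mRNA")
    _check_seq(seq_n, "ncRNA")
    if backend == "reference":
        return _cofold_reference(seq_m, seq_n)
    if backend == "external":
        return _cofold_external(seq_m, seq_n)
    raise ValueError(f"unknown backend {backend!r}; use 'reference' or 'external'")
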