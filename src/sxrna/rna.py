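"""Base-pairing rules and IUPAC matching shared across modules."""

from __future__ import annotations

#: Watson-Crick pairs.
WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
#: G·U wobble pairs.
WOBBLE = {("G", "U"), ("U", "G")}

#: Complement used for reverse-complement construction (WC only; N→N).
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "U": "U",
    "R": "AG",
    "Y": "CU",
    "S": "CG",
    "W": "AU",
    "K": "GU",
    "M": "AC",
    "B": "CGU",
    "D": "AGU",
    "H": "ACU",
    "V": "ACG",
    "N": "ACGU",
}


def can_pair(a: str, b: str, wobble: bool = True) -> bool:
    """True if bases *a* and *b* can form a pair.  N never pairs."""
    if (a, b) in WC:
        return True
    return wobble and (a, b) in WOBBLE


def revcomp(seq: str) -> str:
    """Reverse Watson-Crick complement of an RNA string."""
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def iupac_match(code: str, base: str) -> bool:
    """True if *base* (A/C/G/U) is allowed by IUPAC *code*.  N in the subject
    matches only an N-code (an ambiguous base satisfies no constraint)."""
    allowed = IUPAC[code]
    if base == "N":
        return allowed == "ACGU"
    return base in allowed
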