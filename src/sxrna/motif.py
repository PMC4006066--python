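"""Structured stem-loop pattern matching.

A :class:`MotifDescriptor` is an ordered list of pattern elements — literal
IUPAC sequence elements and tagged stem open/close pairs — in the spirit of
structured-pattern search tools used for RNA motifs.  Only the structured
subset needed for stem-loop RBP motifs (histone stem-loop, iron-response
element) is implemented: no insertion/deletion wildcards, no pseudoknots.

Built-in descriptors:

``hsl``
    Two adenosines (a must-stay-unpaired bulge, essential for SLBP binding)
    followed by a 16-base stem-loop: 6-bp stem, 4-nt loop.  Primary-sequence
    consensus letters are deliberately not hard-coded beyond the adenosines;
    supply a custom descriptor to constrain them.
``ire``
    Iron-response element: 5-bp stem enclosing the canonical CAGUGH apical
    loop.

Matching reports **all** positions (overlaps included) where every sequence
element matches and every stem's two arms are reverse-complementary under
Watson-Crick pairing, plus G·U wobble when the stem allows it.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

from sxrna.rna import can_pair, iupac_match, IUPAC
from sxrna.seqio import Transcript


class DescriptorError(ValueError):
    """Raised for ill-formed motif descriptors."""


@dataclass(frozen=True)
class SeqElement:
    """A literal sequence element.

    ``iupac`` must have length ``max_len``; a match of length ``k`` (with
    ``min_len <= k <= max_len``) uses the first ``k`` codes.
    """

    iupac: str
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not 0 <= self.min_len <= self.max_len:
            raise DescriptorError("SeqElement requires 0 <= min_len <= max_len")
        if len(self.iupac) != self.max_len:
            raise DescriptorError(
                f"SeqElement iupac {self.iupac!r} must have length max_len={self.max_len}"
            )
        bad = set(self.iupac) - set(IUPAC)
        if bad:
            raise DescriptorError(f"invalid IUPAC codes {sorted(bad)}")


@dataclass(frozen=True)
class StemOpen:
    """Opens a stem arm; the matching :class:`StemClose` arm must be its
    reverse complement (up to ``max_mismatch`` positions)."""

    tag: str
    min_len: int
    max_len: int
    allow_wobble: bool = True
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.min_len <= self.max_len:
            raise DescriptorError("StemOpen requires 1 <= min_len <= max_len")
        if self.max_mismatch < 0:
            raise DescriptorError("max_mismatch must be >= 0")


@dataclass(frozen=True)
class StemClose:
    tag: str


Element = Union[SeqElement, StemOpen, StemClose]


@dataclass(frozen=True)
class MotifDescriptor:
    name: str
    elements: tuple[Element, ...]
    #: indices of elements whose matched bases must stay unpaired in any
    #: accepted joint structure (the HSL adenosine bulge lives here)
    anchors5: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        opens: list[str] = []
        n_stems = 0
        for el in self.elements:
            if isinstance(el, StemOpen):
                if el.tag in opens:
                    raise DescriptorError(f"stem tag {el.tag!r} opened twice")
                opens.append(el.tag)
                n_stems += 1
            elif isinstance(el, StemClose):
                if not opens or opens[-1] != el.tag:
                    raise DescriptorError(
                        f"StemClose {el.tag!r} does not close the innermost open stem"
                    )
                opens.pop()
        if opens:
            raise DescriptorError(f"unclosed stem tags {opens}")
        if n_stems != 1:
            raise DescriptorError(
                "descriptors must contain exactly one stem (stem5/loop/stem3 anatomy)"
            )
        for idx in self.anchors5:
            if not 0 <= idx < len(self.elements) or not isinstance(
                self.elements[idx], SeqElement
            ):
                raise DescriptorError(
                    f"anchors5 index {idx} does not reference a SeqElement"
                )


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence; all spans are 0-based half-open transcript coords."""

    transcript_id: str
    span: tuple[int, int]
    stem5: tuple[int, int]
    loop: tuple[int, int]
    stem3: tuple[int, int]
    bulge_positions: tuple[int, ...]
    descriptor_name: str
    #: number of G·U pairs used in the stem (0 means pure Watson-Crick)
    wobble_count: int = 0

    def __post_init__(self) -> None:
        if self.stem5[1] != self.loop[0] or self.loop[1] != self.stem3[0]:
            raise ValueError("stem5/loop/stem3 must be contiguous")
        if self.stem5[1] - self.stem5[0] != self.stem3[1] - self.stem3[0]:
            raise ValueError("stem arms must have equal length")
        if not (self.span[0] <= self.stem5[0] and self.stem3[1] <= self.span[1]):
            raise ValueError("span must cover stem5+loop+stem3")

    @property
    def stem_len(self) -> int:
        return self.stem5[1] - self.stem5[0]

    @property
    def stemloop_span(self) -> tuple[int, int]:
        """The stem-loop proper (bulge excluded); 16 bases for the default HSL."""
        return (self.stem5[0], self.stem3[1])

    def shifted(self, offset: int) -> "MotifMatch":
        """The same match with all coordinates shifted by *offset*."""

        def sh(span: tuple[int, int]) -> tuple[int, int]:
            return (span[0] + offset, span[1] + offset)

        return MotifMatch(
            transcript_id=self.transcript_id,
            span=sh(self.span),
            stem5=sh(self.stem5),
            loop=sh(self.loop),
            stem3=sh(self.stem3),
            bulge_positions=tuple(p + offset for p in self.bulge_positions),
            descriptor_name=self.descriptor_name,
            wobble_count=self.wobble_count,
        )


def builtin_descriptor(name: str) -> MotifDescriptor:
    """Return a built-in descriptor (``hsl`` or ``ire``)."""
    if name == "hsl":
        return MotifDescriptor(
            name="hsl",
            elements=(
                SeqElement("AA", 2, 2),
                StemOpen("stem", 6, 6, allow_wobble=True, max_mismatch=0),
                SeqElement("NNNN", 4, 4),
                StemClose("stem"),
            ),
            anchors5=(0,),
        )
    if name == "ire":
        return MotifDescriptor(
            name="ire",
            elements=(
                StemOpen("stem", 5, 5, allow_wobble=True, max_mismatch=0),
                SeqElement("CAGUGH", 6, 6),
                StemClose("stem"),
            ),
        )
    raise DescriptorError(
        f"unknown descriptor {name!r}; available built-ins: hsl, ire"
    )


def descriptor_from_toml(source: Union[str, Path]) -> MotifDescriptor:
    """Load a custom descriptor from a TOML file (or TOML text).

    Schema::

        name = "my_motif"
        anchors5 = [0]           # optional
        [[elements]]
        kind = "seq"             # iupac, min_len, max_len
        ...
        [[elements]]
        kind = "stem_open"       # tag, min_len, max_len, allow_wobble, max_mismatch
        ...
        [[elements]]
        kind = "stem_close"      # tag
    """
    if isinstance(source, Path) or "\n" not in str(source) and Path(source).exists():
        data = tomllib.loads(Path(source).read_text())
    else:
        data = tomllib.loads(str(source))
    elements: list[Element] = []
    for spec in data.get("elements", []):
        kind = spec.get("kind")
        if kind == "seq":
            elements.append(
                SeqElement(spec["iupac"], spec["min_len"], spec["max_len"])
            )
        elif kind == "stem_open":
            elements.append(
                StemOpen(
                    spec["tag"],
                    spec["min_len"],
                    spec["max_len"],
                    allow_wobble=spec.get("allow_wobble", True),
                    max_mismatch=spec.get("max_mismatch", 0),
                )
            )
        elif kind == "stem_close":
            elements.append(StemClose(spec["tag"]))
        else:
            raise DescriptorError(f"unknown element kind {kind!r}")
    return MotifDescriptor(
        name=data["name"],
        elements=tuple(elements),
        anchors5=tuple(data.get("anchors5", ())),
    )


def _stem_mismatches(
    seq: str, open_span: tuple[int, int], close_span: tuple[int, int], wobble: bool
) -> tuple[int, int]:
    """(mismatches, wobble pairs) for arm ``open_span`` vs arm ``close_span``."""
    o0, o1 = open_span
    c0, c1 = close_span
    length = o1 - o0
    mism = 0
    wob = 0
    for k in range(length):
        a, b = seq[o0 + k], seq[c1 - 1 - k]
        if (a, b) in {("G", "U"), ("U", "G")}:
            if wobble:
                wob += 1
            else:
                mism += 1
        elif not can_pair(a, b, wobble=False):
            mism += 1
    return mism, wob


def _assignments(
    seq: str, pos: int, elements: tuple[Element, ...], idx: int, spans: list
) -> Iterator[list[tuple[int, int]]]:
    """Yield every element→span assignment starting the remaining elements at *pos*."""
    if idx == len(elements):
        yield list(spans)
        return
    el = elements[idx]
    if isinstance(el, SeqElement):
        for k in range(el.min_len, el.max_len + 1):
            if pos + k > len(seq):
                break
            if all(iupac_match(el.iupac[i], seq[pos + i]) for i in range(k)):
                spans.append((pos, pos + k))
                yield from _assignments(seq, pos + k, elements, idx + 1, spans)
                spans.pop()
    elif isinstance(el, StemOpen):
        for k in range(el.min_len, el.max_len + 1):
            if pos + k > len(seq):
                break
            spans.append((pos, pos + k))
            yield from _assignments(seq, pos + k, elements, idx + 1, spans)
            spans.pop()
    else:  # StemClose — length forced by its StemOpen; complementarity checked
        open_idx = _open_index(elements, idx, el.tag)
        open_span = spans[open_idx]
        k = open_span[1] - open_span[0]
        if pos + k > len(seq):
            return
        opener = elements[open_idx]
        assert isinstance(opener, StemOpen)
        mism, _ = _stem_mismatches(
            seq, open_span, (pos, pos + k), opener.allow_wobble
        )
        if mism <= opener.max_mismatch:
            spans.append((pos, pos + k))
            yield from _assignments(seq, pos + k, elements, idx + 1, spans)
            spans.pop()


def _open_index(elements: tuple[Element, ...], close_idx: int, tag: str) -> int:
    for i in range(close_idx - 1, -1, -1):
        el = elements[i]
        if isinstance(el, StemOpen) and el.tag == tag:
            return i
    raise DescriptorError(f"no StemOpen for tag {tag!r}")  # pragma: no cover


def match_motif(descriptor: MotifDescriptor, transcript: Transcript) -> list[MotifMatch]:
    """All occurrences of *descriptor* in *transcript*, overlaps included.

    Deterministic order: ascending start position, then ascending total match
    length.  A transcript with no occurrence yields an empty list.
    """
    seq = transcript.sequence
    elements = descriptor.elements
    stem_open_idx = next(
        i for i, el in enumerate(elements) if isinstance(el, StemOpen)
    )
    stem_close_idx = next(
        i for i, el in enumerate(elements) if isinstance(el, StemClose)
    )
    opener = elements[stem_open_idx]
    assert isinstance(opener, StemOpen)

    matches: list[MotifMatch] = []
    for start in range(len(seq) + 1):
        for spans in _assignments(seq, start, elements, 0, []):
            stem5 = spans[stem_open_idx]
            stem3 = spans[stem_close_idx]
            loop = (stem5[1], stem3[0])
            bulge: list[int] = []
            for aidx in descriptor.anchors5:
                bulge.extend(range(*spans[aidx]))
            _, wob = _stem_mismatches(seq, stem5, stem3, opener.allow_wobble)
            matches.append(
                MotifMatch(
                    transcript_id=transcript.id,
                    span=(spans[0][0], spans[-1][1]),
                    stem5=stem5,
                    loop=loop,
                    stem3=stem3,
                    bulge_positions=tuple(sorted(bulge)),
                    descriptor_name=descriptor.name,
                    wobble_count=wob,
                )
            )
    matches.sort(key=lambda m: (m.span[0], m.span[1] - m.span[0]))
    return matches
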