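"""Sequence and table I/O.

Reads transcript and small-ncRNA FASTA files into normalized RNA records
(T→U, uppercase), writes candidate reports as TSV and motif matches as GFF3.

All coordinates inside the package are 0-based, half-open, on the sense
strand.  GFF3 output converts to the 1-based inclusive convention required by
the format.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence, Union

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from sxrna.junction import SxRNACandidate
    from sxrna.motif import MotifMatch

#: Characters allowed in a normalized transcript.  N is tolerated (real
#: transcript dumps contain it) but never pairs.
TRANSCRIPT_ALPHABET = frozenset("ACGUN")
#: Small ncRNAs must be fully specified.
SMALLRNA_ALPHABET = frozenset("ACGUN")


class FastaError(ValueError):
    """Raised for malformed FASTA input or invariant violations."""


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert DNA T to RNA U.

    Idempotent: ``normalize_rna(normalize_rna(s)) == normalize_rna(s)``.
    """
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class Transcript:
    """An mRNA (or any message) with a normalized A/C/G/U/N sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("transcript id must be non-empty")
        bad = set(self.sequence) - TRANSCRIPT_ALPHABET
        if bad:
            raise FastaError(
                f"transcript {self.id!r}: invalid characters {sorted(bad)} "
                "(normalize with normalize_rna first)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SmallRNA:
    """A small non-coding RNA (miRNA-sized, but any length ≥ 1 is accepted)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("ncRNA id must be non-empty")
        if len(self.sequence) < 1:
            raise FastaError(f"ncRNA {self.id!r}: empty sequence")
        bad = set(self.sequence) - SMALLRNA_ALPHABET
        if bad:
            raise FastaError(f"ncRNA {self.id!r}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


Record = Union[Transcript, SmallRNA]


def read_fasta(path: Union[str, Path], kind: str = "transcript") -> list[Record]:
    """Read a FASTA file into normalized :class:`Transcript` or :class:`SmallRNA` records.

    Parameters
    ----------
    path
        FASTA file.  An empty file yields an empty list.
    kind
        ``"transcript"`` or ``"smallrna"``.

    Raises
    ------
    FastaError
        On duplicate record ids or invalid characters.
    """
    if kind not in ("transcript", "smallrna"):
        raise ValueError(f"kind must be 'transcript' or 'smallrna', got {kind!r}")
    cls = Transcript if kind == "transcript" else SmallRNA
    records: list[Record] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(cls(id=rec.id, sequence=normalize_rna(str(rec.seq))))
    return records


def write_fasta(records: Iterable[Record], path: Union[str, Path]) -> None:
    """Write records as FASTA, 60 columns per line."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


#: Fixed column order of the candidate report.
REPORT_COLUMNS = [
    "transcript_id",
    "ncrna_id",
    "descriptor",
    "mode",
    "motif_start",
    "motif_end",
    "classification",
    "pass",
    "mJ5",
    "mJ3",
    "nJ",
    "h5_pairs",
    "h3_pairs",
    "flank5_frac",
    "flank3_frac",
    "ncrna_frac",
    "bulge_unpaired",
    "backend_score",
    "fail_reasons",
]


def candidate_row(cand: "SxRNACandidate") -> dict[str, object]:
    """Flatten one candidate into a report row (annotation fields blank if absent)."""
    ann = cand.annotation
    row: dict[str, object] = {
        "transcript_id": cand.transcript_id,
        "ncrna_id": cand.ncrna_id,
        "descriptor": cand.descriptor_name,
        "mode": cand.mode,
        "motif_start": cand.motif.span[0],
        "motif_end": cand.motif.span[1],
        "classification": cand.classification,
        "pass": str(cand.passed).lower(),
        "backend_score": f"{cand.backend_score:g}",
        "fail_reasons": ";".join(cand.fail_reasons),
    }
    if ann is None:
        for col in ("mJ5", "mJ3", "nJ", "h5_pairs", "h3_pairs"):
            row[col] = ""
        for col in ("flank5_frac", "flank3_frac", "ncrna_frac", "bulge_unpaired"):
            row[col] = ""
    else:
        row.update(
            mJ5=ann.mJ5,
            mJ3=ann.mJ3,
            nJ=ann.nJ,
            h5_pairs=ann.h5_pairs,
            h3_pairs=ann.h3_pairs,
            flank5_frac=f"{ann.flank5_paired_frac:.4f}",
            flank3_frac=f"{ann.flank3_paired_frac:.4f}",
            ncrna_frac=f"{ann.ncrna_paired_frac:.4f}",
            bulge_unpaired=str(ann.bulge_unpaired).lower(),
        )
    return row


def write_report(rows: Sequence["SxRNACandidate"], path: Union[str, Path]) -> None:
    """Write candidates as a TSV report.

    Rows are sorted by (transcript id, motif start, ncRNA id, mode) so reruns
    are byte-identical regardless of input iteration order.
    """
    ordered = sorted(
        rows, key=lambda c: (c.transcript_id, c.motif.span[0], c.ncrna_id, c.mode)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS, delimiter="\t")
        writer.writeheader()
        for cand in ordered:
            writer.writerow(candidate_row(cand))


def write_matches_gff3(
    matches: Sequence["MotifMatch"], path: Union[str, Path]
) -> None:
    """Write motif matches as GFF3 ``stem_loop`` features with sub-features.

    Internal 0-based half-open spans are converted to GFF3's 1-based
    inclusive convention here and nowhere else.
    """

    def g(span: tuple[int, int]) -> tuple[int, int]:
        return span[0] + 1, span[1]

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, m in enumerate(
            sorted(matches, key=lambda m: (m.transcript_id, m.span[0]))
        ):
            fid = f"motif{i:05d}"
            start, end = g(m.span)
            fh.write(
                f"{m.transcript_id}\tsxrna\tstem_loop\t{start}\t{end}\t.\t+\t.\t"
                f"ID={fid};Name={m.descriptor_name}\n"
            )
            for part, span in (
                ("stem5", m.stem5),
                ("loop", m.loop),
                ("stem3", m.stem3),
            ):
                s, e = g(span)
                fh.write(
                    f"{m.transcript_id}\tsxrna\tsequence_feature\t{s}\t{e}\t.\t+\t.\t"
                    f"ID={fid}.{part};Parent={fid};Name={part}\n"
                )
            for j, pos in enumerate(m.bulge_positions):
                fh.write(
                    f"{m.transcript_id}\tsxrna\tsequence_feature\t{pos + 1}\t{pos + 1}"
                    f"\t.\t+\t.\tID={fid}.bulge{j};Parent={fid};Name=bulge\n"
                )
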