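"""Scan orchestration and command-line interface.

The scan runs, for every (transcript × motif match × ncRNA × mode)
combination: cofold the motif region (a ±``window_flank`` base window and/or
the whole message) against the ncRNA, map the joint structure back to
transcript coordinates, detect/score the trans three-way junction, and emit
one report row.  Rerunning with identical inputs and configuration produces
byte-identical output under the reference backend.

CLI::

    sxrna find-motifs TRANSCRIPTS.fa --motif hsl --gff matches.gff3
    sxrna scan TRANSCRIPTS.fa NCRNAS.fa -o report.tsv [--mode window] [--window 25]
    sxrna fixtures --out-dir DIR --seed 1 [--n-transcripts 5]
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import click

from sxrna.fold import BackendError, cofold
from sxrna.junction import (
    SxRNACandidate,
    Thresholds,
    score_and_classify,
)
from sxrna.motif import (
    MotifDescriptor,
    MotifMatch,
    builtin_descriptor,
    descriptor_from_toml,
    match_motif,
)
from sxrna.seqio import (
    SmallRNA,
    Transcript,
    read_fasta,
    write_fasta,
    write_matches_gff3,
    write_report,
)

logger = logging.getLogger("sxrna")

#: O(n^3) reference folding makes whole-message mode impractical above this.
DEFAULT_WHOLE_GUARD = 5000


@dataclass(frozen=True)
class Window:
    """A motif-centered subsequence plus the bookkeeping to map back."""

    sequence: str
    offset: int  # transcript position of window start
    clamped: bool  # True when the transcript end truncated a flank


def extract_window(transcript: Transcript, motif: MotifMatch, flank: int) -> Window:
    """The motif span extended by *flank* bases on each side, clamped to the
    transcript; ``offset`` converts window-local to transcript coordinates."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start, end = motif.span
    if not (0 <= start <= end <= transcript.length):
        raise ValueError(
            f"motif span {motif.span} out of bounds for transcript "
            f"{transcript.id!r} (length {transcript.length})"
        )
    wstart = max(0, start - flank)
    wend = min(transcript.length, end + flank)
    clamped = wstart != start - flank or wend != end + flank
    return Window(
        sequence=transcript.sequence[wstart:wend], offset=wstart, clamped=clamped
    )


@dataclass(frozen=True)
class ScanConfig:
    window_flank: int = 25
    mode: str = "window"  # window | whole | both
    thresholds: Optional[Thresholds] = None
    backend: str = "reference"
    descriptors: tuple[MotifDescriptor, ...] = ()
    whole_length_guard: int = DEFAULT_WHOLE_GUARD
    hits_only: bool = False

    def __post_init__(self) -> None:
        if self.window_flank < 0:
            raise ValueError("window_flank must be >= 0")
        if self.mode not in ("window", "whole", "both"):
            raise ValueError("mode must be window, whole or both")
        if self.thresholds is None:
            # splinting pairs may sit anywhere inside the cofold window
            object.__setattr__(
                self, "thresholds", Thresholds(max_reach=self.window_flank)
            )
        if not self.descriptors:
            object.__setattr__(self, "descriptors", (builtin_descriptor("hsl"),))

    @property
    def modes(self) -> tuple[str, ...]:
        return ("window", "whole") if self.mode == "both" else (self.mode,)


def _scan_one(
    transcript: Transcript,
    motif: MotifMatch,
    ncrna: SmallRNA,
    mode: str,
    config: ScanConfig,
) -> Optional[SxRNACandidate]:
    th = config.thresholds
    assert th is not None
    if mode == "window":
        window = extract_window(transcript, motif, config.window_flank)
        seq_m = window.sequence
        offset = window.offset
    else:
        if transcript.length > config.whole_length_guard:
            logger.warning(
                "skipping whole-message mode for %s: length %d exceeds guard %d",
                transcript.id,
                transcript.length,
                config.whole_length_guard,
            )
            return None
        seq_m = transcript.sequence
        offset = 0
    motif_local = motif.shifted(-offset)
    try:
        joint = cofold(seq_m, ncrna.sequence, backend=config.backend)
    except BackendError as exc:
        raise BackendError(
            f"cofold failed for transcript {transcript.id!r} x ncRNA "
            f"{ncrna.id!r} ({mode} mode): {exc}"
        ) from exc
    pt = joint.pair_table()
    classification, passed, ann, reasons = score_and_classify(pt, motif_local, th)
    if ann is not None:
        ann = ann.shifted(offset)
    return SxRNACandidate(
        transcript_id=transcript.id,
        ncrna_id=ncrna.id,
        descriptor_name=motif.descriptor_name,
        motif=motif,
        mode=mode,
        annotation=ann,
        classification=classification,
        passed=passed,
        fail_reasons=reasons,
        backend_score=joint.score,
    )


def scan(
    transcripts: Sequence[Transcript],
    smallrnas: Sequence[SmallRNA],
    config: ScanConfig,
) -> list[SxRNACandidate]:
    """Run the full scan; one candidate row per (transcript, motif, ncRNA,
    mode) combination, in deterministic order."""
    results: list[SxRNACandidate] = []
    any_motif = False
    for transcript in transcripts:
        matches: list[MotifMatch] = []
        for descriptor in config.descriptors:
            matches.extend(match_motif(descriptor, transcript))
        matches.sort(key=lambda m: (m.span[0], m.span[1] - m.span[0]))
        logger.info(
            "transcript %s: %d motif match(es)", transcript.id, len(matches)
        )
        any_motif = any_motif or bool(matches)
        for motif in matches:
            for ncrna in smallrnas:
                for mode in config.modes:
                    cand = _scan_one(transcript, motif, ncrna, mode, config)
                    if cand is None:
                        continue
                    if config.hits_only and cand.classification == "none":
                        continue
                    results.append(cand)
    if not any_motif:
        logger.warning("no motifs found in %d transcript(s)", len(transcripts))
    return results


# ---------------------------------------------------------------------------
# configuration loading


def _thresholds_from_dict(data: dict) -> Thresholds:
    valid = {f.name for f in dataclasses.fields(Thresholds)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown threshold keys {sorted(unknown)}")
    return Thresholds(**data)


def load_config(path: Path, **overrides) -> ScanConfig:
    """Build a :class:`ScanConfig` from a TOML file plus keyword overrides."""
    data = tomllib.loads(Path(path).read_text())
    kwargs: dict = {}
    if "window_flank" in data:
        kwargs["window_flank"] = int(data["window_flank"])
    if "mode" in data:
        kwargs["mode"] = data["mode"]
    if "backend" in data:
        kwargs["backend"] = data["backend"]
    if "whole_length_guard" in data:
        kwargs["whole_length_guard"] = int(data["whole_length_guard"])
    if "thresholds" in data:
        kwargs["thresholds"] = _thresholds_from_dict(data["thresholds"])
    kwargs.update(overrides)
    return ScanConfig(**kwargs)


def _resolve_descriptor(motif: str) -> MotifDescriptor:
    if motif in ("hsl", "ire"):
        return builtin_descriptor(motif)
    return descriptor_from_toml(Path(motif))


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option(
    "--log-level",
    default="WARNING",
    type=click.Choice(["DEBUG", "INFO", "WARNING", "ERROR"]),
)
def cli(log_level: str) -> None:
    """sxRNA: scan mRNAs for stem-loop motifs splinted by small ncRNAs."""
    logging.basicConfig(level=getattr(logging, log_level), format="%(message)s")


@cli.command("find-motifs")
@click.argument("fasta", type=click.Path(exists=True))
@click.option("--motif", default="hsl", help="hsl, ire, or a descriptor TOML file")
@click.option("--gff", type=click.Path(), default=None, help="GFF3 output path")
@click.option("--tsv", type=click.Path(), default=None, help="TSV output path")
def find_motifs_cmd(fasta: str, motif: str, gff: Optional[str], tsv: Optional[str]):
    """Locate stem-loop motif matches in transcript FASTA."""
    descriptor = _resolve_descriptor(motif)
    transcripts = read_fasta(fasta, kind="transcript")
    matches: list[MotifMatch] = []
    for tx in transcripts:
        matches.extend(match_motif(descriptor, tx))
    if gff:
        write_matches_gff3(matches, gff)
    if tsv or not gff:
        lines = ["transcript_id\tdescriptor\tstart\tend\tstem5\tloop\tstem3\tbulge"]
        for m in sorted(matches, key=lambda m: (m.transcript_id, m.span[0])):
            lines.append(
                f"{m.transcript_id}\t{m.descriptor_name}\t{m.span[0]}\t{m.span[1]}"
                f"\t{m.stem5[0]}-{m.stem5[1]}\t{m.loop[0]}-{m.loop[1]}"
                f"\t{m.stem3[0]}-{m.stem3[1]}"
                f"\t{','.join(map(str, m.bulge_positions)) or '-'}"
            )
        text = "\n".join(lines) + "\n"
        if tsv:
            Path(tsv).write_text(text)
        else:
            click.echo(text, nl=False)


@cli.command("scan")
@click.argument("mrna_fasta", type=click.Path(exists=True))
@click.argument("ncrna_fasta", type=click.Path(exists=True))
@click.option("-o", "--output", type=click.Path(), required=True)
@click.option("--motif", default="hsl", help="hsl, ire, or a descriptor TOML file")
@click.option("--window", default=25, show_default=True)
@click.option(
    "--mode",
    default="window",
    type=click.Choice(["window", "whole", "both"]),
    show_default=True,
)
@click.option(
    "--backend",
    default="reference",
    type=click.Choice(["reference", "external"]),
    show_default=True,
)
@click.option("--hits-only", is_flag=True, help="omit classification-none rows")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def scan_cmd(
    mrna_fasta: str,
    ncrna_fasta: str,
    output: str,
    motif: str,
    window: int,
    mode: str,
    backend: str,
    hits_only: bool,
    config_path: Optional[str],
):
    """Cofold transcripts against ncRNAs and report trans-3WJ candidates."""
    descriptor = _resolve_descriptor(motif)
    overrides = dict(
        window_flank=window,
        mode=mode,
        backend=backend,
        hits_only=hits_only,
        descriptors=(descriptor,),
    )
    if config_path:
        config = load_config(Path(config_path), **overrides)
    else:
        config = ScanConfig(**overrides)
    transcripts = read_fasta(mrna_fasta, kind="transcript")
    smallrnas = read_fasta(ncrna_fasta, kind="smallrna")
    candidates = scan(transcripts, smallrnas, config)
    write_report(candidates, output)
    n_ind = sum(1 for c in candidates if c.classification == "inducer")
    n_rep = sum(1 for c in candidates if c.classification == "repressor")
    click.echo(
        f"{len(candidates)} rows written to {output} "
        f"({n_ind} inducer, {n_rep} repressor)"
    )


@cli.command("fixtures")
@click.option("--out-dir", type=click.Path(), required=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--n-transcripts", default=5, show_default=True)
@click.option("--motif", default="hsl", type=click.Choice(["hsl", "ire"]))
@click.option("--negatives-per-transcript", default=2, show_default=True)
def fixtures_cmd(
    out_dir: str, seed: int, n_transcripts: int, motif: str, negatives_per_transcript: int
):
    """Emit synthetic transcripts, splint/negative ncRNAs, and a truth TSV."""
    import random

    from sxrna.fixtures import SplintDesign, make_motif_transcript, make_negatives, make_splint

    descriptor = builtin_descriptor(motif)
    rng = random.Random(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    transcripts: list[Transcript] = []
    ncrnas: list[SmallRNA] = []
    truth_lines = [
        "transcript_id\tncrna_id\texpected\tmJ5\tmJ3\tnJ\th5_pairs\th3_pairs"
    ]
    for i in range(n_transcripts):
        sub = rng.randrange(2**31)
        arm5, arm3 = rng.randint(4, 8), rng.randint(4, 8)
        gap = rng.randint(0, 4)
        tx, m = make_motif_transcript(
            descriptor, flank5_len=arm5 + 2, flank3_len=arm3 + 2, seed=sub
        )
        tx = Transcript(id=f"{tx.id}_{i}", sequence=tx.sequence)
        m = dataclasses.replace(m, transcript_id=tx.id)
        transcripts.append(tx)
        res = make_splint(tx, m, SplintDesign(arm5, arm3, gap, seed=sub))
        ncrnas.append(res.smallrna)
        t = res.truth
        assert t is not None
        truth_lines.append(
            f"{tx.id}\t{res.smallrna.id}\tinducer\t{t.mJ5}\t{t.mJ3}\t{t.nJ}"
            f"\t{t.h5_pairs}\t{t.h3_pairs}"
        )
        for neg in make_negatives(tx, m, negatives_per_transcript, seed=sub):
            ncrnas.append(neg)
            expected = "repressor" if neg.id.startswith("ablator") else "none"
            truth_lines.append(f"{tx.id}\t{neg.id}\t{expected}\t\t\t\t\t")
    write_fasta(transcripts, out / "transcripts.fasta")
    write_fasta(ncrnas, out / "ncrnas.fasta")
    (out / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    click.echo(
        f"wrote {len(transcripts)} transcripts, {len(ncrnas)} ncRNAs to {out}"
    )


if __name__ == "__main__":  # pragma: no cover
    cli()
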