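"""Stranded transcription of the ground-truth annotation into cDNA sequences."""

from __future__ import annotations

import csv
import os
import re
from dataclasses import dataclass

from .annotation import AnnotationSet, GenomeSequence
from .as_events import GroundTruth

__all__ = [
    "TranscriptSeq",
    "transcribe",
    "isoform_stats",
    "write_fasta",
    "write_per_isoform_fasta",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptSeq:
    """The mRNA-sense sequence of one isoform."""

    transcript_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        # G and C only in the numerator; ambiguity codes count toward length
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


def transcribe(
    gt: GroundTruth | AnnotationSet,
    genome: GenomeSequence,
    poly_a: int = 0,
) -> list[TranscriptSeq]:
    """Concatenate stranded exonic sequence per isoform.

    Plus-strand transcripts are the genomic-order concatenation of their exon
    substrings; minus-strand transcripts are the reverse complement of that
    concatenation. ``poly_a`` appends that many A bases (default none).
    """
    ann = gt.annotation if isinstance(gt, GroundTruth) else gt
    ann.validate_against_genome(genome)
    out: list[TranscriptSeq] = []
    for tid in sorted(ann.transcripts):
        t = ann.transcripts[tid]
        seq = "".join(genome.fetch(t.contig, e.start, e.end) for e in t.exons)
        if t.strand == "-":
            seq = reverse_complement(seq)
        if poly_a:
            seq += "A" * poly_a
        out.append(TranscriptSeq(transcript_id=tid, sequence=seq))
    return out


def isoform_stats(seqs: list[TranscriptSeq], ann: AnnotationSet | None = None, path=None):
    """Per-isoform statistics (length, GC content, exon count); optionally TSV.

    Returns a list of row dicts; writes a tab-separated file when ``path`` is
    given, GC content at 6 decimal places.
    """
    rows = []
    for s in seqs:
        n_exons = ann.transcripts[s.transcript_id].n_exons if ann else None
        rows.append(
            {
                "transcript_id": s.transcript_id,
                "length": s.length,
                "gc_content": round(s.gc_content, 6),
                "exon_count": n_exons,
            }
        )
    if path is not None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["transcript_id", "length", "gc_content", "exon_count"])
            for r in rows:
                w.writerow(
                    [
                        r["transcript_id"],
                        r["length"],
                        f"{r['gc_content']:.6f}",
                        "" if r["exon_count"] is None else r["exon_count"],
                    ]
                )
    return rows


def write_fasta(seqs: list[TranscriptSeq], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.transcript_id}\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i : i + width] + "\n")


def _sanitize(name: str) -> str:
    return re.sub(r"[/\\\0]", "_", name)


def write_per_isoform_fasta(seqs: list[TranscriptSeq], directory) -> str:
    """One FASTA per isoform plus a combined FASTA; returns the combined path."""
    os.makedirs(directory, exist_ok=True)
    for s in seqs:
        write_fasta([s], os.path.join(directory, f"{_sanitize(s.transcript_id)}.fa"))
    combined = os.path.join(directory, "combined.fa")
    write_fasta(seqs, combined)
    return combined
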