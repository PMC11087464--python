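"""Gene-model containers and FASTA/GTF I/O.

The simulator and the evaluator both operate on :class:`AnnotationSet`, a
validated in-memory gene model (genes -> transcripts -> ordered exons with
strand). Coordinates are stored 0-based half-open internally; GTF I/O converts
to/from the format's 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pyfaidx

__all__ = [
    "Exon",
    "Transcript",
    "AnnotationSet",
    "GenomeSequence",
    "GtfError",
    "read_genome",
    "read_gtf",
    "write_gtf",
    "sample_transcripts",
]

_VALID_STRANDS = ("+", "-")


class GtfError(ValueError):
    """Raised when a GTF file violates the gene-model contract."""


@dataclass(frozen=True, order=True)
class Exon:
    """A stranded exonic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid exon interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """One isoform: an ordered chain of non-overlapping exons on one strand.

    The *intron chain* — the ordered (donor, acceptor) coordinate pairs between
    consecutive exons — is the unit of exact isoform matching: two transcripts
    are considered the same splice structure iff their intron chains are equal,
    regardless of where their terminal exons start or end.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for e in self.exons:
            if e.contig != self.contig or e.strand != self.strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {e.contig}({e.strand}) "
                    f"does not match transcript {self.contig}({self.strand})"
                )
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"transcript {self.transcript_id}: exons not sorted by start")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (donor, acceptor) = (exon_i.end, exon_{i+1}.start) pairs."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def transcribed_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class AnnotationSet:
    """A set of transcripts grouped by gene.

    ``genes`` maps gene_id to the (sorted) list of its transcript ids; every
    transcript's gene_id is guaranteed to appear there.
    """

    transcripts: dict[str, Transcript] = field(default_factory=dict)
    genes: dict[str, list[str]] = field(default_factory=dict)
    source_dialect: str = "ensembl"

    @classmethod
    def from_transcripts(
        cls, transcripts: list[Transcript] | tuple[Transcript, ...],
        source_dialect: str = "ensembl",
    ) -> "AnnotationSet":
        tmap: dict[str, Transcript] = {}
        genes: dict[str, list[str]] = {}
        for t in transcripts:
            if t.transcript_id in tmap:
                raise ValueError(f"duplicate transcript_id {t.transcript_id}")
            tmap[t.transcript_id] = t
            genes.setdefault(t.gene_id, []).append(t.transcript_id)
        for tids in genes.values():
            tids.sort()
        return cls(transcripts=tmap, genes=genes, source_dialect=source_dialect)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.transcripts == other.transcripts and self.genes == other.genes

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        """(contig, min start, max end) over the gene's transcripts."""
        ts = [self.transcripts[tid] for tid in self.genes[gene_id]]
        contigs = {t.contig for t in ts}
        if len(contigs) != 1:
            raise ValueError(f"gene {gene_id} spans multiple contigs: {sorted(contigs)}")
        return ts[0].contig, min(t.start for t in ts), max(t.end for t in ts)

    def subset(self, transcript_ids) -> "AnnotationSet":
        """New AnnotationSet restricted to the given transcripts; empty genes dropped."""
        keep = set(transcript_ids)
        missing = keep - self.transcripts.keys()
        if missing:
            raise KeyError(f"unknown transcript ids: {sorted(missing)[:5]}")
        return AnnotationSet.from_transcripts(
            [self.transcripts[tid] for tid in sorted(keep)],
            source_dialect=self.source_dialect,
        )

    def validate_against_genome(self, genome: "GenomeSequence") -> None:
        for t in self.transcripts.values():
            if t.contig not in genome.contigs:
                raise ValueError(f"transcript {t.transcript_id}: unknown contig {t.contig}")
            clen = len(genome.contigs[t.contig])
            if t.end > clen:
                raise ValueError(
                    f"transcript {t.transcript_id} exceeds contig {t.contig} "
                    f"length {clen}"
                )


@dataclass
class GenomeSequence:
    """Uppercased genome sequences keyed by contig name."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        bad = set()
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("empty contig name")
            bad |= set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"unexpected characters in genome: {sorted(bad)}")

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_genome(path) -> GenomeSequence:
    """Load a FASTA file; sequences are uppercased (soft-masking discarded)."""
    try:
        fa = pyfaidx.Fasta(str(path), sequence_always_upper=True, rebuild=True)
    except (pyfaidx.FastaIndexingError, ValueError) as exc:
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    contigs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return GenomeSequence(contigs=contigs)


# -- GTF ----------------------------------------------------------------------

# accepts Ensembl (`key "value";`) and UCSC spacing variants
_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"\s*;?')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path) -> AnnotationSet:
    """Parse a GTF into an :class:`AnnotationSet`.

    Transcript models are assembled from ``exon`` features only; other feature
    types (gene, transcript, CDS, ...) are ignored for model building. GTF's
    1-based inclusive coordinates are converted to 0-based half-open.
    """
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfError(f"{path}:{lineno}: expected 9 tab-separated fields")
            contig, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            gid = attributes.get("gene_id")
            if not tid:
                raise GtfError(f"{path}:{lineno}: exon feature missing transcript_id")
            if not gid:
                raise GtfError(f"{path}:{lineno}: exon feature missing gene_id")
            try:
                exon = Exon(contig=contig, start=int(start) - 1, end=int(end), strand=strand)
            except ValueError as exc:
                raise GtfError(f"{path}:{lineno}: {exc}") from exc
            rec = per_tx.setdefault(tid, {"gene_id": gid, "exons": []})
            if rec["gene_id"] != gid:
                raise GtfError(
                    f"{path}:{lineno}: transcript {tid} assigned to both "
                    f"{rec['gene_id']} and {gid}"
                )
            rec["exons"].append(exon)

    transcripts = []
    for tid, rec in per_tx.items():
        exons = tuple(sorted(rec["exons"], key=lambda e: e.start))
        try:
            transcripts.append(
                Transcript(
                    transcript_id=tid,
                    gene_id=rec["gene_id"],
                    contig=exons[0].contig,
                    strand=exons[0].strand,
                    exons=exons,
                )
            )
        except ValueError as exc:
            raise GtfError(f"transcript {tid}: {exc}") from exc
    return AnnotationSet.from_transcripts(transcripts)


def write_gtf(ann: AnnotationSet, path) -> None:
    """Write gene, transcript and exon features in Ensembl attribute style.

    Round-trip safe: ``read_gtf(write_gtf(ann))`` reproduces the model content.
    """
    lines = ["#!gtf produced by splicesim"]
    for gid in sorted(ann.genes):
        contig, gstart, gend = ann.gene_span(gid)
        strand = ann.transcripts[ann.genes[gid][0]].strand
        lines.append(
            "\t".join(
                [contig, "splicesim", "gene", str(gstart + 1), str(gend), ".",
                 strand, ".", f'gene_id "{gid}";']
            )
        )
        for tid in sorted(ann.genes[gid]):
            t = ann.transcripts[tid]
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            lines.append(
                "\t".join(
                    [t.contig, "splicesim", "transcript", str(t.start + 1),
                     str(t.end), ".", t.strand, ".", attrs]
                )
            )
            for i, e in enumerate(t.exons, start=1):
                eattrs = attrs + f' exon_number "{i}";'
                lines.append(
                    "\t".join(
                        [e.contig, "splicesim", "exon", str(e.start + 1),
                         str(e.end), ".", e.strand, ".", eattrs]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def sample_transcripts(ann: AnnotationSet, percent: float, seed: int) -> AnnotationSet:
    """Random annotation-completeness subsampling.

    Retains exactly ``round(percent * N)`` transcripts chosen uniformly without
    replacement; genes left with no transcripts are dropped, so incomplete
    annotation reduces both isoform- and gene-level knowledge.
    """
    if not 0 < percent <= 1:
        raise ValueError(f"percent must be in (0, 1], got {percent}")
    if not ann.transcripts:
        raise ValueError("cannot subsample an empty annotation")
    if percent == 1.0:
        return ann.subset(ann.transcripts)
    tids = sorted(ann.transcripts)
    n_keep = int(round(percent * len(tids)))
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(tids), size=n_keep, replace=False)
    return ann.subset([tids[i] for i in keep])
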