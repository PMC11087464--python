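"""Synthetic toy genomes and annotations with known structure.

Every other module is exercisable on these fixtures without any download: a
random genome with a controllable GC fraction, and non-overlapping multi-exon
genes laid left to right with >= 500 bp intergenic gaps (so intergenic
classification is testable), alternating +/- strand to exercise stranded
code paths. Isoforms of a gene share a common exon scaffold and differ by
dropped terminal exons and shifted terminal ends, so their intron chains are
distinct by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import AnnotationSet, Exon, GenomeSequence, Transcript

__all__ = ["FixtureSpec", "make_fixture"]

MIN_GENE_SPACING = 500


@dataclass
class FixtureSpec:
    n_contigs: int = 1
    contig_length: int = 100_000
    n_genes: int = 10
    exons_per_transcript: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 400)
    isoforms_per_gene: tuple[int, int] = (1, 3)
    gc_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exons_per_transcript", "exon_length", "intron_length", "isoforms_per_gene"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.exons_per_transcript[0] < 1:
            raise ValueError("need at least one exon per transcript")
        if not 0 < self.gc_bias < 1:
            raise ValueError("gc_bias must be in (0, 1)")
        if self.n_contigs < 1 or self.n_genes < 1 or self.contig_length < 1:
            raise ValueError("counts and lengths must be positive")


def _random_genome(spec: FixtureSpec, rng: np.random.Generator) -> GenomeSequence:
    p = np.array(
        [(1 - spec.gc_bias) / 2, spec.gc_bias / 2, spec.gc_bias / 2, (1 - spec.gc_bias) / 2]
    )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    contigs = {}
    for i in range(spec.n_contigs):
        draw = rng.choice(4, size=spec.contig_length, p=p)
        contigs[f"chr{i + 1}"] = bases[draw].tobytes().decode("ascii")
    return GenomeSequence(contigs=contigs)


def _gene_scaffold(spec: FixtureSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Exon intervals of one gene, relative to its own start."""
    n_exons = int(rng.integers(spec.exons_per_transcript[0], spec.exons_per_transcript[1] + 1))
    pos = 0
    exons = []
    for i in range(n_exons):
        if i > 0:
            pos += int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1))
        elen = int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
        exons.append((pos, pos + elen))
        pos += elen
    return exons


def make_fixture(spec: FixtureSpec) -> tuple[GenomeSequence, AnnotationSet]:
    """Deterministic toy genome + annotation for the given spec."""
    rng = np.random.default_rng(spec.seed)
    genome = _random_genome(spec, rng)

    # lay out scaffolds first so infeasibility is reported before placement
    scaffolds = [_gene_scaffold(spec, rng) for _ in range(spec.n_genes)]
    spans = [sc[-1][1] for sc in scaffolds]
    per_contig = -(-spec.n_genes // spec.n_contigs)  # ceil division
    required = max(
        sum(spans[i : i + per_contig]) + MIN_GENE_SPACING * (per_contig + 1)
        for i in range(0, spec.n_genes, per_contig)
    )
    if required > spec.contig_length:
        raise ValueError(
            f"genes do not fit: need a contig of >= {required} bp, have {spec.contig_length}"
        )

    transcripts: list[Transcript] = []
    for g in range(spec.n_genes):
        contig = f"chr{g // per_contig + 1}"
        idx_on_contig = g % per_contig
        offset = MIN_GENE_SPACING
        for j in range(idx_on_contig):
            offset += spans[g - idx_on_contig + j] + MIN_GENE_SPACING
        strand = "+" if g % 2 == 0 else "-"
        gid = f"gene{g + 1}"
        scaffold = scaffolds[g]
        n_iso = int(rng.integers(spec.isoforms_per_gene[0], spec.isoforms_per_gene[1] + 1))
        # each extra isoform drops one more terminal exon, so at most
        # len(scaffold) - 1 distinct chains exist per gene
        n_iso = min(n_iso, max(1, len(scaffold) - 1))
        for k in range(n_iso):
            exon_ivals = list(scaffold)
            # terminal variation: isoform k drops k terminal exons (alternating
            # ends) while keeping >= 2 exons, giving distinct intron chains
            drop = k
            side = 0
            while drop > 0 and len(exon_ivals) > 2:
                if side == 0:
                    exon_ivals = exon_ivals[1:]
                else:
                    exon_ivals = exon_ivals[:-1]
                side ^= 1
                drop -= 1
            # jitter the outermost ends without touching internal junctions
            if k > 0:
                s0, e0 = exon_ivals[0]
                shrink = int(rng.integers(0, min(20, e0 - s0 - 1) + 1))
                exon_ivals[0] = (s0 + shrink, e0)
            exons = tuple(
                Exon(contig=contig, start=offset + s, end=offset + e, strand=strand)
                for s, e in exon_ivals
            )
            transcripts.append(
                Transcript(
                    transcript_id=f"{gid}.t{k + 1}",
                    gene_id=gid,
                    contig=contig,
                    strand=strand,
                    exons=exons,
                )
            )
    ann = AnnotationSet.from_transcripts(transcripts)
    ann.validate_against_genome(genome)
    return genome, ann
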