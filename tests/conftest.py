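import numpy as np
import pytest

from splicesim import (
    AnnotationSet,
    Exon,
    FixtureSpec,
    Transcript,
    make_fixture,
)


def tx(tid, gene, exon_ivals, contig="chr1", strand="+"):
    """Shorthand transcript builder for hand-written cases."""
    return Transcript(
        transcript_id=tid,
        gene_id=gene,
        contig=contig,
        strand=strand,
        exons=tuple(Exon(contig=contig, start=s, end=e, strand=strand) for s, e in exon_ivals),
    )


@pytest.fixture(scope="session")
def toy():
    """Small deterministic genome + annotation used across modules."""
    return make_fixture(FixtureSpec(n_genes=10, contig_length=100_000, seed=11))


@pytest.fixture(scope="session")
def toy200():
    """200-gene fixture for depth-calibration style checks."""
    return make_fixture(FixtureSpec(n_genes=200, contig_length=2_000_000, seed=11))


def random_annotation(rng: np.random.Generator, n_transcripts=20, contig="chr1"):
    """Random multi-exon annotation on a small coordinate space.

    Junction coordinates are drawn from a coarse grid so that chain
    collisions, subchains and shared splice sites actually occur.
    """
    transcripts = []
    for i in range(n_transcripts):
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 5))
        # boundaries on a grid of step 10 to provoke shared sites
        cuts = np.sort(rng.choice(np.arange(1, 400), size=2 * n_exons, replace=False)) * 10
        exons = [(int(cuts[2 * j]), int(cuts[2 * j + 1])) for j in range(n_exons)]
        transcripts.append(
            tx(f"t{i}", f"g{int(rng.integers(0, max(2, n_transcripts // 3)))}",
               exons, contig=contig, strand=strand)
        )
    # gene ids must map to consistent contigs; single contig here, fine
    return AnnotationSet.from_transcripts(transcripts)
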