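import shutil
import subprocess

import numpy as np
import pytest

from splicesim import (
    AnnotationSet,
    GroundTruth,
    classify,
    filter_mono_exonic,
    jaccard_similarity,
    match_exact,
    realized_depth_report,
)

from conftest import random_annotation, tx


# ---------------------------------------------------------------- oracles --

def oracle_match(query, reference):
    """All-pairs exact intron-chain matching with one-to-one assignment."""
    available = {
        rid: (t.contig, t.strand, t.intron_chain())
        for rid, t in reference.transcripts.items()
    }
    tp = 0
    for qid in sorted(query.transcripts):
        q = query.transcripts[qid]
        key = (q.contig, q.strand, q.intron_chain())
        for rid in sorted(available):
            if available[rid] == key:
                del available[rid]
                tp += 1
                break
    return tp, len(query.transcripts) - tp, len(reference.transcripts) - tp


def oracle_classify_one(q, reference):
    """Explicit enumeration of the five-way cascade for one query transcript."""
    chain = q.intron_chain()
    same = [
        t for t in reference.transcripts.values()
        if t.contig == q.contig and t.strand == q.strand
    ]
    if any(t.intron_chain() == chain for t in same):
        return "FSM"
    for t in same:
        c = t.intron_chain()
        if len(c) > len(chain) and chain and any(
            c[i : i + len(chain)] == chain for i in range(len(c) - len(chain) + 1)
        ):
            return "ISM"
    overlaps = False
    for gid in reference.genes:
        contig, s, e = reference.gene_span(gid)
        if contig == q.contig and q.start < e and s < q.end:
            overlaps = True
            break
    if not overlaps:
        return "INTERGENIC"
    donors = {d for t in same for d, _ in t.intron_chain()}
    acceptors = {a for t in same for _, a in t.intron_chain()}
    if all(d in donors for d, _ in chain) and all(a in acceptors for _, a in chain):
        return "NIC"
    return "NNC"


def oracle_jaccard(a, b):
    """Per-base set arithmetic on exonic positions."""
    def bases(ann):
        s = set()
        for t in ann.transcripts.values():
            for e in t.exons:
                s.update((e.contig, p) for p in range(e.start, e.end))
        return s

    A, B = bases(a), bases(b)
    return len(A & B), len(A | B)


# ------------------------------------------------------------------ tests --

class TestFilterMonoExonic:
    def test_multi_exonic_input_unchanged(self, toy):
        _, ann = toy
        multi = filter_mono_exonic(ann)
        assert set(multi.transcripts) == {
            t for t, v in ann.transcripts.items() if v.n_exons > 1
        }

    def test_counts(self):
        ann = AnnotationSet.from_transcripts(
            [
                tx("m1", "g1", [(0, 100)]),
                tx("m2", "g2", [(500, 600)]),
                tx("s1", "g3", [(1000, 1100), (1200, 1300)]),
                tx("s2", "g3", [(1000, 1100), (1250, 1300)]),
                tx("s3", "g4", [(2000, 2100), (2200, 2300)]),
            ]
        )
        out = filter_mono_exonic(ann)
        assert len(out) == 3
        assert "g1" not in out.genes and "g2" not in out.genes


class TestMatchExact:
    def test_self_comparison_is_perfect(self, toy):
        _, ann = toy
        res = match_exact(ann, ann)
        assert res.FP == 0 and res.FN == 0
        assert res.precision == 1.0 and res.sensitivity == 1.0

    def test_printed_formula_example(self):
        ref = AnnotationSet.from_transcripts(
            [tx(f"r{i}", f"g{i}", [(i * 1000, i * 1000 + 100), (i * 1000 + 200, i * 1000 + 300)])
             for i in range(1, 6)]
        )
        query = AnnotationSet.from_transcripts(
            [tx(f"q{i}", f"g{i}", [(i * 1000 - 10, i * 1000 + 100), (i * 1000 + 200, i * 1000 + 350)])
             for i in range(1, 4)]
            + [tx("q_novel", "gx", [(50_000, 50_100), (50_200, 50_300)])]
        )
        res = match_exact(query, ref)
        assert (res.TP, res.FP, res.FN) == (3, 1, 2)
        assert res.precision == pytest.approx(0.75)
        assert res.sensitivity == pytest.approx(0.6)

    def test_terminal_ends_free_to_differ(self):
        ref = AnnotationSet.from_transcripts([tx("r", "g", [(100, 200), (300, 400)])])
        query = AnnotationSet.from_transcripts([tx("q", "g", [(50, 200), (300, 450)])])
        assert match_exact(query, ref).TP == 1

    def test_strand_specific(self):
        ref = AnnotationSet.from_transcripts([tx("r", "g", [(100, 200), (300, 400)])])
        query = AnnotationSet.from_transcripts(
            [tx("q", "g", [(100, 200), (300, 400)], strand="-")]
        )
        assert match_exact(query, ref).TP == 0

    def test_duplicate_reference_matched_once_each(self):
        ref = AnnotationSet.from_transcripts(
            [tx("r1", "g", [(100, 200), (300, 400)]), tx("r2", "g", [(120, 200), (300, 380)])]
        )
        query = AnnotationSet.from_transcripts([tx("q1", "g", [(100, 200), (300, 400)])])
        res = match_exact(query, ref)
        assert (res.TP, res.FP, res.FN) == (1, 0, 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        query = filter_mono_exonic(random_annotation(rng, n_transcripts=25))
        reference = filter_mono_exonic(random_annotation(rng, n_transcripts=25))
        res = match_exact(query, reference)
        assert (res.TP, res.FP, res.FN) == oracle_match(query, reference)

    def test_empty_denominators_flagged(self):
        empty = AnnotationSet()
        ref = AnnotationSet.from_transcripts([tx("r", "g", [(0, 10), (20, 30)])])
        res = match_exact(empty, ref)
        assert res.precision is None
        assert res.sensitivity == 0.0


@pytest.fixture(scope="module")
def reference():
    return AnnotationSet.from_transcripts(
        [
            tx("r1", "gA", [(100, 150), (200, 300), (400, 500)]),
            tx("r2", "gA", [(100, 150), (200, 300)]),
            tx("r3", "gB", [(5000, 5100), (5200, 5300)]),
        ]
    )


class TestClassify:

    def test_fsm_with_shifted_terminal_ends(self, reference):
        q = AnnotationSet.from_transcripts([tx("q", "gA", [(50, 150), (200, 350)])])
        (rec,) = classify(q, reference)
        assert rec.category == "FSM" and rec.matched_reference_id == "r2"

    def test_ism_contiguous_subchain(self, reference):
        # chain ((200,300),) is a terminal run of r1's ((150,200),(300,400))... use r1 junctions
        q = AnnotationSet.from_transcripts([tx("q", "gA", [(160, 300), (400, 480)])])
        (rec,) = classify(q, reference)
        assert rec.category == "ISM" and rec.matched_reference_id == "r1"

    def test_nic_known_sites_new_combination(self, reference):
        # donor 150 (r1/r2) combined with acceptor 400 (r1) skips exon 2
        q = AnnotationSet.from_transcripts([tx("q", "gA", [(100, 150), (400, 500)])])
        (rec,) = classify(q, reference)
        assert rec.category == "NIC"

    def test_nnc_unannotated_site(self, reference):
        q = AnnotationSet.from_transcripts([tx("q", "gA", [(100, 150), (401, 500)])])
        (rec,) = classify(q, reference)
        assert rec.category == "NNC"

    def test_intergenic_no_gene_overlap(self, reference):
        q = AnnotationSet.from_transcripts([tx("q", "gX", [(10_000, 10_100), (10_200, 10_300)])])
        (rec,) = classify(q, reference)
        assert rec.category == "INTERGENIC"

    def test_antisense_falls_to_nnc_not_fsm(self, reference):
        q = AnnotationSet.from_transcripts(
            [tx("q", "gA", [(100, 150), (200, 300)], strand="-")]
        )
        (rec,) = classify(q, reference)
        assert rec.category == "NNC"

    def test_internal_exon_skip_is_not_ism(self, reference):
        # subset of r1's junctions but not a contiguous run -> NIC
        q = AnnotationSet.from_transcripts([tx("q", "gA", [(100, 150), (200, 300), (400, 500)])])
        ref2 = AnnotationSet.from_transcripts(
            [tx("r", "gA", [(100, 150), (200, 300), (320, 360), (400, 500)])]
        )
        (rec,) = classify(q, ref2)
        assert rec.category == "NIC"

    @pytest.mark.parametrize("seed", range(20))
    def test_cascade_agrees_with_enumeration_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        query = filter_mono_exonic(random_annotation(rng, n_transcripts=30))
        reference = filter_mono_exonic(random_annotation(rng, n_transcripts=30))
        records = {r.query_id: r.category for r in classify(query, reference)}
        assert set(records) == set(query.transcripts)  # totality
        for qid, t in query.transcripts.items():
            assert records[qid] == oracle_classify_one(t, reference), qid


class TestJaccard:
    def test_identity(self, toy):
        _, ann = toy
        assert jaccard_similarity(ann, ann).jaccard == 1.0

    def test_disjoint(self):
        a = AnnotationSet.from_transcripts([tx("a", "g", [(0, 100), (200, 300)])])
        b = AnnotationSet.from_transcripts([tx("b", "g", [(1000, 1100), (1200, 1300)])])
        assert jaccard_similarity(a, b).jaccard == 0.0

    def test_half_overlap_hand_case(self):
        a = AnnotationSet.from_transcripts([tx("a", "g", [(0, 100)])])
        b = AnnotationSet.from_transcripts([tx("b", "g", [(50, 150)])])
        res = jaccard_similarity(a, b)
        assert (res.intersection_bp, res.union_bp) == (50, 150)
        assert res.jaccard == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(15))
    def test_agrees_with_per_base_oracle_and_symmetry(self, seed):
        rng = np.random.default_rng(2000 + seed)
        a = random_annotation(rng, n_transcripts=15)
        b = random_annotation(rng, n_transcripts=15)
        res = jaccard_similarity(a, b)
        assert (res.intersection_bp, res.union_bp) == oracle_jaccard(a, b)
        rev = jaccard_similarity(b, a)
        assert res.intersection_bp == rev.intersection_bp
        assert res.union_bp == rev.union_bp

    @pytest.mark.skipif(shutil.which("bedtools") is None, reason="bedtools not on PATH")
    def test_agrees_with_bedtools_jaccard(self, tmp_path):
        rng = np.random.default_rng(77)
        a = random_annotation(rng, n_transcripts=20)
        b = random_annotation(rng, n_transcripts=20)

        def to_bed(ann, path):
            ivals = sorted(
                (e.contig, e.start, e.end)
                for t in ann.transcripts.values()
                for e in t.exons
            )
            path.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in ivals))

        pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
        to_bed(a, pa)
        to_bed(b, pb)
        out = subprocess.run(
            ["bedtools", "jaccard", "-a", str(pa), "-b", str(pb)],
            capture_output=True, text=True, check=True,
        )
        inter, union = out.stdout.splitlines()[1].split("\t")[:2]
        res = jaccard_similarity(a, b)
        assert res.intersection_bp == int(inter)
        assert res.union_bp == int(union)


class TestDepthReport:
    def test_full_length_reads_recover_depth(self):
        from splicesim import ReadSimConfig, simulate_sample
        from splicesim.transcribe import TranscriptSeq

        ann = AnnotationSet.from_transcripts([tx("t1", "g1", [(0, 500), (600, 1100)])])
        gt = GroundTruth(annotation=ann)
        from splicesim import ExpressionProfile

        profile = ExpressionProfile(
            isoform_depth={"t1": 20.0}, gene_of={"t1": "g1"}, expressed={"t1": True}
        )
        seqs = [TranscriptSeq("t1", "A" * 1000)]
        reads, _ = simulate_sample(
            seqs, profile, ReadSimConfig(accuracy_mean=1.0, strand_symmetric=False, seed=0)
        )
        report = realized_depth_report(reads, gt)
        assert report.isoform_depth["t1"] == 20.0
        assert report.sample_depth == 20.0

    def test_gene_depth_is_mean_of_zipf_pair(self, tmp_path):
        # isoform depths 640/17 and 40/17 average to gene depth 20
        from splicesim.reads import SimulatedRead, format_read_id, write_fastq

        ann = AnnotationSet.from_transcripts(
            [tx("tA", "g1", [(0, 50), (100, 150)]), tx("tB", "g1", [(0, 50), (120, 150)])]
        )
        gt = GroundTruth(annotation=ann)
        reads = []
        for tid, depth in (("tA", 640 / 17), ("tB", 40 / 17)):
            L = 100 if tid == "tA" else 80
            total = int(round(depth * L))
            reads.append(
                SimulatedRead(
                    read_id=format_read_id(tid, 1, "+"), sequence="A" * total,
                    quality="I" * total, origin=tid, strand="+", template_span=(0, total),
                )
            )
        p = tmp_path / "r.fq"
        write_fastq(reads, p)
        report = realized_depth_report(p, gt)
        gene_depth = report.gene_depth["g1"]
        assert gene_depth == pytest.approx(20.0, abs=0.01)

    def test_empty_input_gives_zero_depths(self, tmp_path):
        ann = AnnotationSet.from_transcripts([tx("t1", "g1", [(0, 100), (200, 300)])])
        gt = GroundTruth(annotation=ann)
        report = realized_depth_report([], gt)
        assert report.isoform_depth["t1"] == 0.0
        assert report.sample_depth == 0.0

    def test_unparseable_reads_counted_and_skipped(self, tmp_path):
        p = tmp_path / "r.fq"
        p.write_text("@garbage\nACGT\n+\nIIII\n")
        ann = AnnotationSet.from_transcripts([tx("t1", "g1", [(0, 100), (200, 300)])])
        report = realized_depth_report(p, GroundTruth(annotation=ann))
        assert report.skipped_reads == 1
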