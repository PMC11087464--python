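"""Isoform-set benchmarking: exact matching, classification, base-pair Jaccard.

A query transcript counts as a true positive when some reference transcript on
the same contig and strand carries an identical intron chain — i.e. it "shares
all splice site boundaries exactly" — with terminal exon ends free to differ.
Each reference transcript can absorb at most one query toward TP/FN
accounting. Queries are additionally classified into the five standard
categories: FSM (full splice match), ISM (incomplete splice match: a
contiguous terminal subchain of a longer reference chain), NIC (novel in
catalog: only annotated donor/acceptor sites, in a new combination), NNC
(novel not in catalog: at least one unannotated site), and intergenic (no
overlap with any annotated gene span). Mono-exonic transcripts carry no splice
junctions and are excluded by default.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

from .annotation import AnnotationSet
from .as_events import GroundTruth

__all__ = [
    "EvalResult",
    "ClassificationRecord",
    "SimilarityResult",
    "DepthReport",
    "filter_mono_exonic",
    "match_exact",
    "classify",
    "jaccard_similarity",
    "realized_depth_report",
    "write_metrics",
    "write_classification",
]

CATEGORIES = ("FSM", "ISM", "NIC", "NNC", "INTERGENIC")


@dataclass
class EvalResult:
    """TP/FP/FN counts with the derived precision and sensitivity."""

    TP: int
    FP: int
    FN: int
    matches: dict[str, str]

    @property
    def precision(self) -> float | None:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN > 0 else None


@dataclass(frozen=True)
class ClassificationRecord:
    query_id: str
    category: str
    matched_reference_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in ("FSM", "ISM") and self.matched_reference_id is None:
            raise ValueError(f"{self.category} requires a matched reference id")


@dataclass(frozen=True)
class SimilarityResult:
    intersection_bp: int
    union_bp: int

    @property
    def jaccard(self) -> float:
        return self.intersection_bp / self.union_bp if self.union_bp else 0.0


def filter_mono_exonic(ann: AnnotationSet) -> AnnotationSet:
    """Drop single-exon transcripts (they carry no splice junctions)."""
    keep = [tid for tid, t in ann.transcripts.items() if t.n_exons > 1]
    return ann.subset(keep)


def _warn_orphan_contigs(query: AnnotationSet, reference: AnnotationSet) -> None:
    qc = {t.contig for t in query.transcripts.values()}
    rc = {t.contig for t in reference.transcripts.values()}
    orphans = qc ^ rc
    if orphans and qc and rc:
        warnings.warn(
            f"contigs present in only one annotation: {sorted(orphans)}", stacklevel=3
        )


def match_exact(
    query: AnnotationSet, reference: AnnotationSet, keep_mono: bool = False
) -> EvalResult:
    """Exact intron-chain matching with one-to-one reference assignment.

    precision = TP / (TP + FP), sensitivity = TP / (TP + FN). Because matching
    is equality on (contig, strand, intron chain), the maximum bipartite
    assignment reduces to pairing equal-key groups; ties are broken by
    lexicographic id so reports are deterministic.
    """
    if not keep_mono:
        query = filter_mono_exonic(query)
        reference = filter_mono_exonic(reference)
    _warn_orphan_contigs(query, reference)

    ref_by_key: dict[tuple, list[str]] = {}
    for tid in sorted(reference.transcripts):
        t = reference.transcripts[tid]
        ref_by_key.setdefault((t.contig, t.strand, t.intron_chain()), []).append(tid)

    matches: dict[str, str] = {}
    used: set[str] = set()
    for qid in sorted(query.transcripts):
        t = query.transcripts[qid]
        for rid in ref_by_key.get((t.contig, t.strand, t.intron_chain()), []):
            if rid not in used:
                matches[qid] = rid
                used.add(rid)
                break
    tp = len(matches)
    return EvalResult(
        TP=tp,
        FP=len(query.transcripts) - tp,
        FN=len(reference.transcripts) - tp,
        matches=matches,
    )


def _is_contiguous_subchain(
    sub: tuple[tuple[int, int], ...], chain: tuple[tuple[int, int], ...]
) -> bool:
    if not sub or len(sub) >= len(chain):
        return False
    for i in range(len(chain) - len(sub) + 1):
        if chain[i : i + len(sub)] == sub:
            return True
    return False


def classify(
    query: AnnotationSet, reference: AnnotationSet, keep_mono: bool = False
) -> list[ClassificationRecord]:
    """Assign each query transcript exactly one of the five categories.

    Decision cascade (all chain/site comparisons on the same contig+strand):
    FSM on chain equality; ISM when the chain is a contiguous run inside a
    longer reference chain; otherwise NIC/NNC by donor+acceptor site-set
    membership when the transcript overlaps any gene span (any strand), or
    INTERGENIC when it overlaps none.
    """
    if not keep_mono:
        query = filter_mono_exonic(query)

    chain_to_ref: dict[tuple, str] = {}
    long_chains: dict[tuple[str, str], list[tuple[str, tuple]]] = {}
    donors: dict[tuple[str, str], set[int]] = {}
    acceptors: dict[tuple[str, str], set[int]] = {}
    for rid in sorted(reference.transcripts):
        t = reference.transcripts[rid]
        key = (t.contig, t.strand)
        chain = t.intron_chain()
        chain_to_ref.setdefault((t.contig, t.strand, chain), rid)
        if chain:
            long_chains.setdefault(key, []).append((rid, chain))
            donors.setdefault(key, set()).update(d for d, _ in chain)
            acceptors.setdefault(key, set()).update(a for _, a in chain)

    spans: list[tuple[str, int, int]] = [
        reference.gene_span(gid) for gid in sorted(reference.genes)
    ]

    records: list[ClassificationRecord] = []
    for qid in sorted(query.transcripts):
        t = query.transcripts[qid]
        key = (t.contig, t.strand)
        chain = t.intron_chain()

        rid = chain_to_ref.get((t.contig, t.strand, chain))
        if rid is not None:
            records.append(ClassificationRecord(qid, "FSM", rid))
            continue

        ism_ref = None
        for cand_rid, cand_chain in long_chains.get(key, []):
            if _is_contiguous_subchain(chain, cand_chain):
                ism_ref = cand_rid
                break
        if ism_ref is not None:
            records.append(ClassificationRecord(qid, "ISM", ism_ref))
            continue

        overlaps_gene = any(
            c == t.contig and t.start < e and s < t.end for c, s, e in spans
        )
        if not overlaps_gene:
            records.append(ClassificationRecord(qid, "INTERGENIC"))
            continue

        known_d = donors.get(key, set())
        known_a = acceptors.get(key, set())
        all_known = all(d in known_d for d, _ in chain) and all(
            a in known_a for _, a in chain
        )
        records.append(ClassificationRecord(qid, "NIC" if all_known else "NNC"))
    return records


def _merged_intervals(ann: AnnotationSet) -> dict[str, list[tuple[int, int]]]:
    """Union of exonic intervals per contig, strand-agnostic."""
    raw: dict[str, list[tuple[int, int]]] = {}
    for t in ann.transcripts.values():
        for e in t.exons:
            raw.setdefault(e.contig, []).append((e.start, e.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig, ivals in raw.items():
        ivals.sort()
        out = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = [(s, e) for s, e in out]
    return merged


def _interval_ops(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> tuple[int, int]:
    """(intersection bp, union bp) of two merged, sorted interval lists."""
    inter = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            inter += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    len_a = sum(e - s for s, e in a)
    len_b = sum(e - s for s, e in b)
    return inter, len_a + len_b - inter


def jaccard_similarity(a: AnnotationSet, b: AnnotationSet) -> SimilarityResult:
    """Base-pair Jaccard of two isoform sets' merged exonic intervals."""
    ma, mb = _merged_intervals(a), _merged_intervals(b)
    inter = union = 0
    for contig in sorted(ma.keys() | mb.keys()):
        ia, ib = ma.get(contig, []), mb.get(contig, [])
        ci, cu = _interval_ops(ia, ib)
        inter += ci
        union += cu
    return SimilarityResult(intersection_bp=inter, union_bp=union)


@dataclass
class DepthReport:
    """Alignment-free realized depths recovered from read provenance."""

    isoform_depth: dict[str, float]
    gene_depth: dict[str, float]
    sample_depth: float
    skipped_reads: int


def realized_depth_report(reads, gt: GroundTruth) -> DepthReport:
    """Realized depth per isoform/gene/sample from provenance-tagged reads.

    ``reads`` is a path to a FASTQ file or an iterable of
    :class:`~splicesim.reads.SimulatedRead`. depth_i = emitted bases assigned
    to isoform i divided by its transcribed length; gene and sample depths are
    arithmetic means over isoforms with nonzero depth.
    """
    from .reads import SimulatedRead, parse_read_id  # avoid import cycle

    ann = gt.annotation
    bases: dict[str, int] = {tid: 0 for tid in ann.transcripts}
    skipped = 0

    def _records():
        if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
            import pysam

            with pysam.FastxFile(str(reads)) as fx:
                for rec in fx:
                    yield rec.name, len(rec.sequence)
        else:
            for r in reads:
                assert isinstance(r, SimulatedRead)
                yield r.read_id, len(r.sequence)

    for name, length in _records():
        try:
            tid, _, _ = parse_read_id(name)
        except ValueError:
            skipped += 1
            continue
        if tid not in bases:
            skipped += 1
            continue
        bases[tid] += length

    isoform_depth = {
        tid: bases[tid] / ann.transcripts[tid].transcribed_length for tid in bases
    }
    gene_depth: dict[str, float] = {}
    for gid, tids in ann.genes.items():
        expressed = [isoform_depth[t] for t in tids if isoform_depth[t] > 0]
        gene_depth[gid] = sum(expressed) / len(expressed) if expressed else 0.0
    expressed_all = [d for d in isoform_depth.values() if d > 0]
    sample = sum(expressed_all) / len(expressed_all) if expressed_all else 0.0
    return DepthReport(
        isoform_depth=isoform_depth,
        gene_depth=gene_depth,
        sample_depth=sample,
        skipped_reads=skipped,
    )


def write_metrics(result: EvalResult, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["TP", "FP", "FN", "precision", "sensitivity"])
        fmt = lambda x: "NA" if x is None else f"{x:.6f}"
        w.writerow([result.TP, result.FP, result.FN, fmt(result.precision), fmt(result.sensitivity)])


def write_classification(records: list[ClassificationRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["query_id", "category", "matched_reference_id"])
        for r in records:
            w.writerow([r.query_id, r.category, r.matched_reference_id or "NA"])
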