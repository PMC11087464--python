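"""Novel alternative-splicing isoform generation.

Starting from a reference annotation restricted to expressed genes, novel
isoforms are derived from existing ones by applying one of four event
operators — exon skipping (ES), intron retention (IR), alternative 5' donor
(A5) and alternative 3' acceptor (A3) — until each gene reaches a target
isoform count drawn from the transcriptome complexity index. The result is
the ground-truth annotation from which reads are simulated.

The per-gene isoform target is ``min(cap, 1 + Poisson(complexity - 1))``, so
complexity 1 leaves single-isoform genes untouched and the realized mean
isoforms/gene grows with the index.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationSet, Exon, Transcript

__all__ = [
    "ASEventConfig",
    "GroundTruth",
    "select_expressed_genes",
    "apply_event",
    "generate_ground_truth",
    "write_provenance",
]

EVENT_TYPES = ("ES", "IR", "A5", "A3")

DEFAULT_EVENT_WEIGHTS = {"ES": 0.4, "IR": 0.2, "A5": 0.2, "A3": 0.2}


@dataclass
class ASEventConfig:
    """Parameters of the AS-event generator.

    complexity_index
        Target isoform count per gene (the ``--complexity`` knob); the
        realized mean isoforms/gene is positively correlated with it but
        saturates at the number of distinct legal intron chains.
    event_weights
        Sampling probability per event type; must sum to 1.
    shift_range
        Inclusive (min, max) shift in bp for A5/A3 donor/acceptor moves.
    """

    complexity_index: float = 2.0
    event_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_WEIGHTS)
    )
    shift_range: tuple[int, int] = (3, 30)
    max_attempts_per_isoform: int = 100
    expressed_gene_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.complexity_index <= 0:
            raise ValueError("complexity_index must be positive")
        if set(self.event_weights) - set(EVENT_TYPES):
            raise ValueError(f"unknown event types: {set(self.event_weights) - set(EVENT_TYPES)}")
        total = sum(self.event_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event weights must sum to 1, got {total}")
        if any(w < 0 for w in self.event_weights.values()):
            raise ValueError("event weights must be non-negative")
        lo, hi = self.shift_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid shift_range {self.shift_range}")
        if not 0 < self.expressed_gene_fraction <= 1:
            raise ValueError("expressed_gene_fraction must be in (0, 1]")
        if self.max_attempts_per_isoform < 1:
            raise ValueError("max_attempts_per_isoform must be >= 1")


@dataclass
class GroundTruth:
    """Expressed reference isoforms plus generated novel isoforms (the gtGTF).

    ``provenance`` maps each novel transcript id to its parent id and the
    ordered list of events applied along its derivation chain.
    """

    annotation: AnnotationSet
    novel_ids: set[str] = field(default_factory=set)
    provenance: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = self.novel_ids - self.annotation.transcripts.keys()
        if missing:
            raise ValueError(f"novel ids absent from annotation: {sorted(missing)[:5]}")


def select_expressed_genes(ann: AnnotationSet, fraction: float, seed: int) -> AnnotationSet:
    """Uniformly choose round(fraction * N_genes) genes with all their isoforms."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not ann.genes:
        raise ValueError("empty annotation")
    if fraction == 1.0:
        return ann.subset(ann.transcripts)
    gids = sorted(ann.genes)
    n_keep = int(round(fraction * len(gids)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(gids), size=n_keep, replace=False)
    keep_tids: list[str] = []
    for i in chosen:
        keep_tids.extend(ann.genes[gids[i]])
    return ann.subset(keep_tids)


def _replace_exons(t: Transcript, exons: tuple[Exon, ...], new_id: str) -> Transcript:
    return Transcript(
        transcript_id=new_id,
        gene_id=t.gene_id,
        contig=t.contig,
        strand=t.strand,
        exons=exons,
    )


def legal_shift_placements(
    t: Transcript, event: str, shift_range: tuple[int, int]
) -> list[tuple[int, int]]:
    """All legal (intron index, signed delta) moves for an A5 or A3 event.

    A5 moves the donor (upstream exon end); A3 moves the acceptor (downstream
    exon start). Negative delta shrinks the exon, positive extends it into the
    intron. A move is legal when the affected exon keeps >= 1 bp and the
    intron keeps >= 1 bp.
    """
    lo, hi = shift_range
    placements: list[tuple[int, int]] = []
    for i in range(t.n_exons - 1):
        up, down = t.exons[i], t.exons[i + 1]
        for delta in range(lo, hi + 1):
            if event == "A5":
                # donor = up.end; shrink keeps exon non-empty, extend keeps intron
                if up.end - delta > up.start:
                    placements.append((i, -delta))
                if up.end + delta < down.start:
                    placements.append((i, +delta))
            else:  # A3: acceptor = down.start
                if down.start - delta > up.end:
                    placements.append((i, -delta))  # extend exon into intron
                if down.start + delta < down.end:
                    placements.append((i, +delta))  # shrink exon
    return placements


def apply_event(
    t: Transcript,
    event: str,
    rng: np.random.Generator,
    shift_range: tuple[int, int] = (3, 30),
    new_id: str = "novel",
) -> Transcript | None:
    """Apply one AS event to a transcript; None when no legal placement exists.

    ES removes one uniformly chosen internal exon (needs >= 3 exons); IR merges
    one uniformly chosen adjacent exon pair across their intron (needs >= 2);
    A5/A3 move one uniformly chosen donor/acceptor by a uniform shift in
    ``shift_range``, direction uniform, rejecting moves that would empty an
    exon or erase an intron.
    """
    if event not in EVENT_TYPES:
        raise ValueError(f"unknown event code {event!r}")
    exons = t.exons
    if event == "ES":
        if t.n_exons < 3:
            return None
        i = int(rng.integers(1, t.n_exons - 1))  # internal exon
        return _replace_exons(t, exons[:i] + exons[i + 1 :], new_id)
    if event == "IR":
        if t.n_exons < 2:
            return None
        i = int(rng.integers(0, t.n_exons - 1))
        merged = Exon(
            contig=t.contig,
            start=exons[i].start,
            end=exons[i + 1].end,
            strand=t.strand,
        )
        return _replace_exons(t, exons[:i] + (merged,) + exons[i + 2 :], new_id)

    # A5 / A3: rejection-sample (intron, direction, delta) uniformly, falling
    # back to enumeration so "no legal placement" is decided exactly.
    if t.n_exons < 2:
        return None
    lo, hi = shift_range
    placement: tuple[int, int] | None = None
    for _ in range(32):
        i = int(rng.integers(0, t.n_exons - 1))
        delta = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)
        if (i, delta) in set(legal_shift_placements(t, event, shift_range)):
            placement = (i, delta)
            break
    if placement is None:
        legal = legal_shift_placements(t, event, shift_range)
        if not legal:
            return None
        placement = legal[int(rng.integers(0, len(legal)))]
    i, delta = placement
    up, down = exons[i], exons[i + 1]
    if event == "A5":
        new_up = Exon(contig=t.contig, start=up.start, end=up.end + delta, strand=t.strand)
        new_exons = exons[:i] + (new_up,) + exons[i + 1 :]
    else:
        new_down = Exon(
            contig=t.contig, start=down.start + delta, end=down.end, strand=t.strand
        )
        new_exons = exons[: i + 1] + (new_down,) + exons[i + 2 :]
    return _replace_exons(t, new_exons, new_id)


def generate_ground_truth(
    ann: AnnotationSet, cfg: ASEventConfig, seed: int
) -> GroundTruth:
    """Generate novel isoforms per gene up to the complexity target.

    For each gene a target isoform count ``n_g = 1 + Poisson(complexity - 1)``
    is drawn; parents and event types are then sampled repeatedly, and a
    candidate is accepted only if its intron chain is new within the gene.
    All reference isoforms of expressed genes are retained.
    """
    cfg.__post_init__()  # re-validate in case fields were mutated
    rng = np.random.default_rng(seed)
    event_names = sorted(cfg.event_weights)
    event_probs = np.array([cfg.event_weights[e] for e in event_names])

    all_transcripts: list[Transcript] = []
    novel_ids: set[str] = set()
    provenance: dict[str, tuple[str, tuple[str, ...]]] = {}

    lam = max(cfg.complexity_index - 1.0, 0.0)
    for gid in sorted(ann.genes):
        members = [ann.transcripts[tid] for tid in sorted(ann.genes[gid])]
        chains = {t.intron_chain() for t in members}
        target = 1 + int(rng.poisson(lam)) if lam > 0 else 1
        needed = max(0, target - len(members))
        serial = 1
        attempts_left = cfg.max_attempts_per_isoform * max(needed, 1)
        # event history per transcript id, so chained derivations are recorded
        history: dict[str, tuple[str, ...]] = {t.transcript_id: () for t in members}
        while needed > 0 and attempts_left > 0:
            attempts_left -= 1
            parent = members[int(rng.integers(0, len(members)))]
            event = event_names[int(rng.choice(len(event_names), p=event_probs))]
            new_id = f"{parent.transcript_id}.novel{serial}"
            candidate = apply_event(
                parent, event, rng, shift_range=cfg.shift_range, new_id=new_id
            )
            if candidate is None:
                continue
            chain = candidate.intron_chain()
            if chain in chains:
                continue
            chains.add(chain)
            members.append(candidate)
            novel_ids.add(new_id)
            history[new_id] = history[parent.transcript_id] + (event,)
            provenance[new_id] = (parent.transcript_id, history[new_id])
            serial += 1
            needed -= 1
        all_transcripts.extend(members)

    gt_ann = AnnotationSet.from_transcripts(all_transcripts, source_dialect=ann.source_dialect)
    return GroundTruth(annotation=gt_ann, novel_ids=novel_ids, provenance=provenance)


def write_provenance(gt: GroundTruth, path) -> None:
    """TSV of (novel_id, parent_id, comma-joined events)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["novel_id", "parent_id", "events"])
        for nid in sorted(gt.provenance):
            parent, events = gt.provenance[nid]
            w.writerow([nid, parent, ",".join(events)])
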