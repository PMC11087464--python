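"""Error- and truncation-aware long-read generation ("sequencing" + "assembling").

Each expressed isoform contributes ``round(depth)`` template copies; every copy
is optionally clipped at the 5'/3' end (uniform truncation fractions, the read
completeness model), passed through a per-base substitution/insertion/deletion
error channel calibrated to ``1 - accuracy``, optionally reverse-complemented
(cDNA strand symmetry), and written to a single provenance-tagged FASTQ. Read
ids encode the origin isoform, a serial, and the emitted strand, so realized
depth and per-isoform accounting are recoverable without alignment.

The built-in generator fulfils the low-level read generator (LLRG) adapter
contract — template sequence plus depth in, reads out — so an external
sequencer-specific engine can be substituted via :class:`LLRGAdapter`.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Protocol

import numpy as np

from .expression import ExpressionProfile
from .transcribe import TranscriptSeq, reverse_complement

__all__ = [
    "ReadSimConfig",
    "SimulatedRead",
    "SimStats",
    "LLRGAdapter",
    "reads_per_isoform",
    "clip_template",
    "introduce_errors",
    "simulate_sample",
    "write_fastq",
    "format_read_id",
    "parse_read_id",
]

_BASES = "ACGT"


@dataclass
class ReadSimConfig:
    """Read-generation parameters.

    accuracy_mean
        Expected per-base identity; the error channel introduces edits with
        total probability 1 - accuracy, split by ``error_mix``.
    error_mix
        (substitution, insertion, deletion) fractions summing to 1.
    truncate_ratio_5p / truncate_ratio_3p
        Fraction of each template removed from the mRNA 5' / 3' end before
        sequencing (read-completeness model; uniform across reads).
    strand_symmetric
        When True each read is independently reverse-complemented with
        probability 1/2, as for double-stranded cDNA libraries.
    """

    accuracy_mean: float = 0.85
    accuracy_sd: float = 0.0
    error_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    truncate_ratio_5p: float = 0.0
    truncate_ratio_3p: float = 0.0
    strand_symmetric: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.accuracy_mean <= 1:
            raise ValueError("accuracy_mean must be in (0, 1]")
        if self.accuracy_sd < 0:
            raise ValueError("accuracy_sd must be >= 0")
        if abs(sum(self.error_mix) - 1.0) > 1e-9 or any(x < 0 for x in self.error_mix):
            raise ValueError("error_mix must be non-negative and sum to 1")
        r5, r3 = self.truncate_ratio_5p, self.truncate_ratio_3p
        if not (0 <= r5 < 1 and 0 <= r3 < 1 and r5 + r3 < 1):
            raise ValueError("truncation ratios must lie in [0, 1) with sum < 1")


@dataclass(frozen=True)
class SimulatedRead:
    """One FASTQ record with provenance back to its origin isoform."""

    read_id: str
    sequence: str
    quality: str
    origin: str
    strand: str
    template_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")
        if len(self.sequence) != len(self.quality):
            raise ValueError("quality length does not match sequence length")


@dataclass
class SimStats:
    """Realized per-isoform and sample-level sequencing statistics."""

    per_isoform: dict[str, dict] = field(default_factory=dict)
    total_reads: int = 0
    total_bases: int = 0
    total_edits: int = 0
    total_template_bases: int = 0

    @property
    def realized_sample_depth(self) -> float:
        """Arithmetic mean of realized depth over the expressed isoforms."""
        depths = [
            rec["depth"] for rec in self.per_isoform.values() if rec["target_depth"] > 0
        ]
        return float(np.mean(depths)) if depths else 0.0

    @property
    def realized_error_rate(self) -> float:
        if self.total_template_bases == 0:
            return 0.0
        return self.total_edits / self.total_template_bases


class LLRGAdapter(Protocol):
    """Contract for a pluggable low-level read generator.

    An adapter receives one template (mRNA-sense cDNA) with its target depth
    and configuration, and yields finished reads; it owns any temporary files
    and cleans them up. The built-in error channel is the default adapter.
    """

    def generate(
        self, template: TranscriptSeq, depth: float, cfg: ReadSimConfig,
        rng: np.random.Generator,
    ) -> Iterable[SimulatedRead]: ...


def reads_per_isoform(depth: float) -> int:
    """Number of full-length template copies for a target depth.

    Each full-length read contributes exactly 1x depth before truncation, so
    the read count is depth rounded to the nearest integer.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    return int(round(depth))


def clip_template(template: str, r5: float, r3: float) -> tuple[str, tuple[int, int]]:
    """Remove floor(r5*L) bases from the 5' end and floor(r3*L) from the 3' end.

    Returns the remaining substring and its (start, end) span on the template.
    A clip that would leave nothing yields a 1-base read with a warning.
    """
    if not template:
        raise ValueError("empty template")
    if r5 + r3 >= 1:
        raise ValueError("r5 + r3 must be < 1")
    L = len(template)
    start = math.floor(r5 * L)
    end = L - math.floor(r3 * L)
    if end <= start:
        warnings.warn(
            f"clipping left no bases of a {L} bp template; emitting 1 base",
            stacklevel=2,
        )
        end = start + 1
    return template[start:end], (start, end)


def _phred_char(accuracy: float) -> str:
    q = min(41, round(-10 * math.log10(max(1 - accuracy, 1e-5))))
    return chr(q + 33)


def introduce_errors(
    template: str,
    accuracy: float,
    error_mix: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[str, str, int]:
    """Pass a template through the per-base error channel.

    Each base independently suffers an edit with probability ``1 - accuracy``:
    a substitution (uniform different base), an insertion (base emitted, then
    one uniform random base), or a deletion (base skipped), partitioned by
    ``error_mix``. Returns (sequence, phred+33 quality, number of edits).
    """
    if not 0 < accuracy <= 1:
        raise ValueError("accuracy must be in (0, 1]")
    if accuracy == 1.0:
        return template, _phred_char(accuracy) * len(template), 0

    e = 1.0 - accuracy
    sub_f, ins_f, _del_f = error_mix
    codes = np.frombuffer(template.encode("ascii"), dtype=np.uint8).copy()
    L = codes.size
    u = rng.random(L)
    err = u < e
    # partition errors by type using the same uniform draw (keeps one stream)
    sub_mask = err & (u < e * sub_f)
    ins_mask = err & (u >= e * sub_f) & (u < e * (sub_f + ins_f))
    del_mask = err & ~sub_mask & ~ins_mask

    base_codes = np.frombuffer(_BASES.encode("ascii"), dtype=np.uint8)
    # substitution: uniform over the three other bases; N -> uniform ACGT
    n_sub = int(sub_mask.sum())
    if n_sub:
        orig = codes[sub_mask]
        # map ascii code -> 0..3 (N and other codes -> 4)
        lut = np.full(256, 4, dtype=np.int8)
        for i, b in enumerate(_BASES.encode("ascii")):
            lut[b] = i
        orig_idx = lut[orig].astype(np.int64)
        offset = rng.integers(1, 4, size=n_sub)
        new_idx = (orig_idx + offset) % 4
        is_n = orig_idx == 4
        if is_n.any():
            new_idx[is_n] = rng.integers(0, 4, size=int(is_n.sum()))
        codes[sub_mask] = base_codes[new_idx]

    counts = np.ones(L, dtype=np.int64)
    counts[del_mask] = 0
    counts[ins_mask] = 2
    out = codes[np.repeat(np.arange(L), counts)]
    # the second slot of every insertion position receives a random base
    starts = np.cumsum(counts) - counts
    extra_slots = starts[ins_mask] + 1
    if extra_slots.size:
        out[extra_slots] = base_codes[rng.integers(0, 4, size=extra_slots.size)]

    seq = out.tobytes().decode("ascii")
    n_edits = int(err.sum())
    return seq, _phred_char(accuracy) * len(seq), n_edits


def format_read_id(transcript_id: str, serial: int, strand: str) -> str:
    # escape '%' before ':' so the encoding is bijective
    tid = transcript_id.replace("%", "%25").replace(":", "%3A")
    return f"{tid}:{serial}:{strand}"


def parse_read_id(read_id: str) -> tuple[str, int, str]:
    """Recover (origin transcript id, serial, strand) from a read id."""
    try:
        tid, serial, strand = read_id.rsplit(":", 2)
    except ValueError:
        raise ValueError(f"unparseable read id {read_id!r}") from None
    if strand not in "+-" or not serial.isdigit():
        raise ValueError(f"unparseable read id {read_id!r}")
    return tid.replace("%3A", ":").replace("%25", "%"), int(serial), strand


def _draw_accuracy(cfg: ReadSimConfig, rng: np.random.Generator) -> float:
    if cfg.accuracy_sd == 0:
        return cfg.accuracy_mean
    while True:  # truncated normal on (0, 1]
        a = rng.normal(cfg.accuracy_mean, cfg.accuracy_sd)
        if 0 < a <= 1:
            return a


def simulate_sample(
    seqs: list[TranscriptSeq],
    profile: ExpressionProfile,
    cfg: ReadSimConfig,
) -> tuple[list[SimulatedRead], SimStats]:
    """Sequence every expressed isoform and assemble one read collection.

    Deterministic for a fixed (seqs, profile, cfg): isoforms are processed in
    sorted id order with a single seeded random stream.
    """
    seq_by_id = {s.transcript_id: s for s in seqs}
    missing = [t for t in profile.isoform_depth if t not in seq_by_id]
    if missing:
        raise ValueError(f"profile isoforms missing from sequences: {missing[:5]}")

    rng = np.random.default_rng(cfg.seed)
    reads: list[SimulatedRead] = []
    stats = SimStats()
    for tid in sorted(seq_by_id):
        template_seq = seq_by_id[tid]
        depth = profile.effective_depth(tid) if tid in profile.isoform_depth else 0.0
        n = reads_per_isoform(depth)
        bases = 0
        for serial in range(1, n + 1):
            clipped, span = clip_template(
                template_seq.sequence, cfg.truncate_ratio_5p, cfg.truncate_ratio_3p
            )
            accuracy = _draw_accuracy(cfg, rng)
            seq, qual, edits = introduce_errors(clipped, accuracy, cfg.error_mix, rng)
            strand = "+"
            if cfg.strand_symmetric and rng.random() < 0.5:
                seq = reverse_complement(seq)
                qual = qual[::-1]
                strand = "-"
            reads.append(
                SimulatedRead(
                    read_id=format_read_id(tid, serial, strand),
                    sequence=seq,
                    quality=qual,
                    origin=tid,
                    strand=strand,
                    template_span=span,
                )
            )
            bases += len(seq)
            stats.total_edits += edits
            stats.total_template_bases += len(clipped)
        stats.per_isoform[tid] = {
            "n_reads": n,
            "bases": bases,
            "depth": bases / template_seq.length,
            "target_depth": depth,
        }
        stats.total_reads += n
        stats.total_bases += bases
    return reads, stats


def write_fastq(reads: Iterable[SimulatedRead], path) -> None:
    """Write phred+33 FASTQ; gzip-compressed when the path ends in .gz."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_sim_stats(stats: SimStats, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["transcript_id", "n_reads", "bases", "realized_depth", "target_depth"])
        for tid in sorted(stats.per_isoform):
            rec = stats.per_isoform[tid]
            w.writerow(
                [tid, rec["n_reads"], rec["bases"],
                 f"{rec['depth']:.6f}", f"{rec['target_depth']:.6f}"]
            )
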