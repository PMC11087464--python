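"""Expression-profile generation: GMM gene depths, Zipf isoform depths.

Gene-level sequencing depth is drawn from a Gaussian mixture in log10 space,
rejection-restricted to [low_cutoff, high_cutoff_ratio * mu] and rescaled so
the gene-level arithmetic mean hits the targeted sample depth mu. Within a
gene, isoform depths follow deterministic Zipf rank weights r^(-alpha)
rescaled so their arithmetic mean equals the gene depth, with ranks assigned
to isoforms by a seeded random permutation. With the default alpha = 4 a gene
with k isoforms spans a k^4-fold expression range (2401-fold at k = 7), i.e.
>= 1000-fold inequality in most multi-isoform genes without moving the mean.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .as_events import GroundTruth

__all__ = [
    "GMMSpec",
    "DepthConfig",
    "ExpressionProfile",
    "default_gmm",
    "draw_gene_depths",
    "zipf_isoform_depths",
    "build_profile",
    "write_profile",
    "read_profile",
]


@dataclass
class GMMSpec:
    """Gaussian mixture over log10(depth): list of (weight, mean, sd)."""

    components: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("GMM needs at least one component")
        total = sum(w for w, _, _ in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"GMM weights must sum to 1, got {total}")
        for w, _, sd in self.components:
            if not 0 < w <= 1:
                raise ValueError("GMM weights must lie in (0, 1]")
            if sd <= 0:
                raise ValueError("GMM sds must be positive")

    def sample_log10(self, n: int, rng: np.random.Generator) -> np.ndarray:
        weights = np.array([w for w, _, _ in self.components])
        means = np.array([m for _, m, _ in self.components])
        sds = np.array([s for _, _, s in self.components])
        comp = rng.choice(len(weights), size=n, p=weights)
        return rng.normal(means[comp], sds[comp])


def default_gmm(mu: float) -> GMMSpec:
    """Two-component mixture centred on log10(mu) with a heavy right tail.

    Produces the ~1e5-fold dynamic range of gene expression typical of bulk
    RNA-seq once combined with the rejection window and Zipf inequality.
    """
    base = math.log10(mu)
    return GMMSpec(components=[(0.7, base - 0.5, 0.6), (0.3, base + 0.5, 0.4)])


@dataclass
class DepthConfig:
    """Depth-model parameters.

    mu
        Targeted mean sample depth (reads-equivalent coverage per isoform).
    alpha
        Zipf exponent controlling within-gene isoform inequality.
    low_cutoff
        Minimum isoform depth; isoforms below it are flagged unexpressed.
    high_cutoff_ratio
        Gene depths are capped at this multiple of mu.
    """

    mu: float = 20.0
    alpha: float = 4.0
    low_cutoff: float = 0.01
    high_cutoff_ratio: float = 200.0
    gmm: GMMSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.low_cutoff < 0:
            raise ValueError("low_cutoff must be >= 0")
        if self.high_cutoff_ratio <= 1:
            raise ValueError("high_cutoff_ratio must be > 1")
        if self.gmm is None:
            self.gmm = default_gmm(self.mu)


@dataclass
class ExpressionProfile:
    """Per-isoform target depth with gene and sample roll-ups.

    ``isoform_depth`` stores the assigned depth for every isoform; isoforms
    whose depth fell below ``low_cutoff`` have ``expressed`` False and are
    treated as silent (effective depth 0) downstream, but remain present so a
    benchmark can distinguish "annotated but silent".
    """

    isoform_depth: dict[str, float]
    gene_of: dict[str, str]
    expressed: dict[str, bool]

    def effective_depth(self, tid: str) -> float:
        return self.isoform_depth[tid] if self.expressed[tid] else 0.0

    def gene_depth(self, gene_id: str) -> float:
        """Arithmetic mean of the gene's expressed isoform depths."""
        depths = [
            self.isoform_depth[t]
            for t, g in self.gene_of.items()
            if g == gene_id and self.expressed[t]
        ]
        return float(np.mean(depths)) if depths else 0.0

    def sample_depth(self) -> float:
        """Arithmetic mean over all expressed isoforms."""
        depths = [d for t, d in self.isoform_depth.items() if self.expressed[t]]
        return float(np.mean(depths)) if depths else 0.0


def draw_gene_depths(genes: list[str], cfg: DepthConfig) -> dict[str, float]:
    """Sample one depth per gene from the range-restricted GMM.

    After rejection sampling into [low_cutoff, high_cutoff_ratio * mu] the
    values are rescaled by a common factor so the arithmetic mean equals mu,
    re-clipped to the range, and the rescale/clip pass repeated (<= 5 times)
    until the mean is within 1% of mu.
    """
    if not genes:
        raise ValueError("empty gene list")
    hi = cfg.high_cutoff_ratio * cfg.mu
    lo = cfg.low_cutoff
    if lo > hi:
        raise ValueError(f"infeasible depth range [{lo}, {hi}]")
    rng = np.random.default_rng(cfg.seed)
    n = len(genes)
    depths = np.empty(0)
    while depths.size < n:
        draw = 10.0 ** cfg.gmm.sample_log10(2 * n, rng)
        depths = np.concatenate([depths, draw[(draw >= lo) & (draw <= hi)]])
    depths = depths[:n]
    for _ in range(5):
        depths = depths * (cfg.mu / depths.mean())
        depths = np.clip(depths, lo, hi)
        if abs(depths.mean() - cfg.mu) <= 0.01 * cfg.mu:
            break
    return {g: float(d) for g, d in zip(sorted(genes), depths)}


def zipf_isoform_depths(
    gene_depth: float, k: int, alpha: float, rng: np.random.Generator
) -> list[float]:
    """Mean-preserving Zipf depths for the k isoforms of one gene.

    Rank r carries unnormalized weight r^(-alpha); weights are rescaled so
    their arithmetic mean equals ``gene_depth`` and shuffled onto isoform
    positions. The max/min ratio is exactly k^alpha.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if gene_depth <= 0:
        raise ValueError("gene_depth must be positive")
    ranks = np.arange(1, k + 1, dtype=float)
    weights = ranks ** (-alpha)
    depths = weights * (gene_depth * k / weights.sum())
    rng.shuffle(depths)
    return depths.tolist()


def build_profile(gt: GroundTruth, cfg: DepthConfig) -> ExpressionProfile:
    """Assign a depth to every isoform of the ground truth.

    Composes :func:`draw_gene_depths` and :func:`zipf_isoform_depths`; isoforms
    landing below ``low_cutoff`` are flagged unexpressed.
    """
    ann = gt.annotation
    gene_depths = draw_gene_depths(sorted(ann.genes), cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    isoform_depth: dict[str, float] = {}
    gene_of: dict[str, str] = {}
    expressed: dict[str, bool] = {}
    for gid in sorted(ann.genes):
        tids = sorted(ann.genes[gid])
        depths = zipf_isoform_depths(gene_depths[gid], len(tids), cfg.alpha, rng)
        for tid, d in zip(tids, depths):
            isoform_depth[tid] = d
            gene_of[tid] = gid
            expressed[tid] = d >= cfg.low_cutoff
    return ExpressionProfile(
        isoform_depth=isoform_depth, gene_of=gene_of, expressed=expressed
    )


def write_profile(profile: ExpressionProfile, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["transcript_id", "gene_id", "depth", "expressed"])
        for tid in sorted(profile.isoform_depth):
            w.writerow(
                [
                    tid,
                    profile.gene_of[tid],
                    repr(profile.isoform_depth[tid]),
                    int(profile.expressed[tid]),
                ]
            )


def read_profile(path) -> ExpressionProfile:
    isoform_depth: dict[str, float] = {}
    gene_of: dict[str, str] = {}
    expressed: dict[str, bool] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            tid = row["transcript_id"]
            isoform_depth[tid] = float(row["depth"])
            gene_of[tid] = row["gene_id"]
            expressed[tid] = bool(int(row["expressed"]))
    return ExpressionProfile(
        isoform_depth=isoform_depth, gene_of=gene_of, expressed=expressed
    )
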