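"""End-to-end simulation driver and evaluation driver.

``run_end_to_end`` chains annotation subsampling, expressed-gene selection,
AS-event generation, expression profiling, transcription and read simulation
into one artifact bundle ({prefix}.gt.gtf, .expression.tsv, .fq, .stats.tsv,
.provenance.tsv, .manifest.json). A single master seed deterministically
derives every module seed, so identical configurations reproduce outputs
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np

from . import __version__
from .annotation import read_genome, read_gtf, sample_transcripts, write_gtf
from .as_events import ASEventConfig, generate_ground_truth, select_expressed_genes, write_provenance
from .evaluate import (
    classify,
    jaccard_similarity,
    match_exact,
    write_classification,
    write_metrics,
)
from .expression import DepthConfig, build_profile, write_profile
from .reads import ReadSimConfig, simulate_sample, write_fastq, write_sim_stats
from .transcribe import transcribe

__all__ = ["SimulationConfig", "run_end_to_end", "run_evaluate"]


@dataclass
class SimulationConfig:
    """Full parameter set of one simulation run."""

    genome_path: str
    gtf_path: str
    output_prefix: str
    complexity: float = 2.0
    mu: float = 20.0
    alpha: float = 4.0
    accuracy_mean: float = 0.85
    truncate_ratio_5p: float = 0.0
    truncate_ratio_3p: float = 0.0
    percent: float = 1.0
    low_cutoff: float = 0.01
    high_cutoff_ratio: float = 200.0
    expressed_gene_fraction: float = 1.0
    strand_symmetric: bool = True
    seed: int = 0

    def module_seeds(self) -> dict[str, int]:
        """Derive one deterministic sub-seed per stochastic stage."""
        ss = np.random.SeedSequence(self.seed)
        names = ("sample", "select", "as", "profile", "reads")
        children = ss.spawn(len(names))
        return {
            n: int(c.generate_state(1, dtype=np.uint32)[0]) for n, c in zip(names, children)
        }


def run_end_to_end(cfg: SimulationConfig) -> dict[str, str]:
    """Run the whole simulator; returns a mapping of artifact name -> path.

    Any stage failure removes partial outputs and re-raises with the stage
    named.
    """
    seeds = cfg.module_seeds()
    prefix = cfg.output_prefix
    outputs = {
        "gt_gtf": f"{prefix}.gt.gtf",
        "expression": f"{prefix}.expression.tsv",
        "fastq": f"{prefix}.fq",
        "stats": f"{prefix}.stats.tsv",
        "provenance": f"{prefix}.provenance.tsv",
        "manifest": f"{prefix}.manifest.json",
    }
    stage = "setup"
    try:
        stage = "read inputs"
        genome = read_genome(cfg.genome_path)
        ann = read_gtf(cfg.gtf_path)

        stage = "sample_transcripts"
        if cfg.percent < 1.0:
            ann = sample_transcripts(ann, cfg.percent, seeds["sample"])

        stage = "select_expressed_genes"
        expressed = select_expressed_genes(
            ann, cfg.expressed_gene_fraction, seeds["select"]
        )

        stage = "generate_ground_truth"
        as_cfg = ASEventConfig(complexity_index=cfg.complexity)
        gt = generate_ground_truth(expressed, as_cfg, seeds["as"])

        stage = "build_profile"
        depth_cfg = DepthConfig(
            mu=cfg.mu,
            alpha=cfg.alpha,
            low_cutoff=cfg.low_cutoff,
            high_cutoff_ratio=cfg.high_cutoff_ratio,
            seed=seeds["profile"],
        )
        profile = build_profile(gt, depth_cfg)

        stage = "transcribe"
        seqs = transcribe(gt, genome)

        stage = "simulate_sample"
        read_cfg = ReadSimConfig(
            accuracy_mean=cfg.accuracy_mean,
            truncate_ratio_5p=cfg.truncate_ratio_5p,
            truncate_ratio_3p=cfg.truncate_ratio_3p,
            strand_symmetric=cfg.strand_symmetric,
            seed=seeds["reads"],
        )
        reads, stats = simulate_sample(seqs, profile, read_cfg)

        stage = "write outputs"
        write_gtf(gt.annotation, outputs["gt_gtf"])
        write_profile(profile, outputs["expression"])
        write_fastq(reads, outputs["fastq"])
        write_sim_stats(stats, outputs["stats"])
        write_provenance(gt, outputs["provenance"])
        manifest = {
            "tool": "splicesim",
            "version": __version__,
            "parameters": dataclasses.asdict(cfg),
            "derived_seeds": seeds,
            "n_transcripts_gt": len(gt.annotation),
            "n_novel": len(gt.novel_ids),
            "n_reads": stats.total_reads,
        }
        with open(outputs["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        for path in outputs.values():
            if os.path.exists(path):
                os.remove(path)
        raise RuntimeError(f"simulation failed at stage '{stage}': {exc}") from exc
    return outputs


def run_evaluate(
    query_gtf: str,
    reference_gtf: str,
    output_prefix: str,
    keep_mono: bool = False,
    with_jaccard: bool = False,
) -> dict[str, str]:
    """Compare a query isoform GTF against a reference GTF; write reports."""
    query = read_gtf(query_gtf)
    reference = read_gtf(reference_gtf)
    outputs = {"metrics": f"{output_prefix}.metrics.tsv",
               "classification": f"{output_prefix}.classification.tsv"}
    result = match_exact(query, reference, keep_mono=keep_mono)
    write_metrics(result, outputs["metrics"])
    records = classify(query, reference, keep_mono=keep_mono)
    write_classification(records, outputs["classification"])
    if with_jaccard:
        sim = jaccard_similarity(query, reference)
        outputs["jaccard"] = f"{output_prefix}.jaccard.tsv"
        with open(outputs["jaccard"], "w") as fh:
            fh.write("intersection_bp\tunion_bp\tjaccard\n")
            fh.write(f"{sim.intersection_bp}\t{sim.union_bp}\t{sim.jaccard:.6f}\n")
    return outputs
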