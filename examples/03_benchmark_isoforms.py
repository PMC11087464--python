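"""Benchmark an isoform set against simulated ground truth.

Simulates with 60% annotation completeness, then evaluates the incomplete
annotation (playing the role of a detection tool's output) against the
ground-truth GTF: exact splice-boundary precision/sensitivity, the five-way
FSM/ISM/NIC/NNC/intergenic classification, and base-pair Jaccard similarity.
Precision is 1 because every retained isoform is a true ground-truth isoform;
sensitivity is below 1 because the simulator added novel splice variants the
incomplete annotation cannot know about.
"""

import tempfile
from collections import Counter
from pathlib import Path

from splicesim import (
    ASEventConfig,
    FixtureSpec,
    classify,
    filter_mono_exonic,
    generate_ground_truth,
    jaccard_similarity,
    make_fixture,
    match_exact,
    sample_transcripts,
)

workdir = Path(tempfile.mkdtemp(prefix="splicesim_"))
_, ann = make_fixture(FixtureSpec(n_genes=30, contig_length=400_000, seed=5))

incomplete = sample_transcripts(ann, percent=0.6, seed=6)
gt = generate_ground_truth(incomplete, ASEventConfig(complexity_index=3), seed=7)

query = filter_mono_exonic(incomplete)
reference = filter_mono_exonic(gt.annotation)

res = match_exact(query, reference)
print(f"TP={res.TP} FP={res.FP} FN={res.FN}")
print(f"precision  = {res.precision:.3f}")
print(f"sensitivity = {res.sensitivity:.3f}")

counts = Counter(r.category for r in classify(query, reference))
print("classification of query isoforms:", dict(counts))

sim = jaccard_similarity(query, reference)
print(f"base-pair Jaccard = {sim.jaccard:.3f} "
      f"({sim.intersection_bp}/{sim.union_bp} bp)")
# All query isoforms classify as FSM (they ARE ground-truth isoforms); the
# missed sensitivity counts the simulator's novel isoforms as false negatives.
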