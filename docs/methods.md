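# Methods

## Overview

`splicesim` is a two-level simulator of long-read RNA-seq experiments plus an
evaluator for isoform-detection output. The simulator works top-down:

1. **Annotation completeness** (`sample_transcripts`): a fraction `percent` of
   reference transcripts is retained, chosen uniformly without replacement;
   genes left empty are dropped. Exact-count sampling (round(p·N) retained)
   is used instead of per-transcript Bernoulli so a completeness level is an
   exact dataset size, reproducible under one seed.
2. **Expressed-gene selection** (`select_expressed_genes`): a uniform gene
   subset, all isoforms kept.
3. **Novel AS generation** (`generate_ground_truth`): per gene, a target
   isoform count n_g = 1 + Poisson(complexity − 1); candidate isoforms are
   produced by one of four event operators applied to a uniformly chosen
   parent (which may itself be novel, so derivation chains occur) and
   accepted only when the intron chain is new within the gene. The loop stops
   at n_g isoforms or after max_attempts, so the realized mean isoforms/gene
   saturates below the index on genes with few legal distinct chains — which
   is also why the realized mean is monotone rather than equal to the index.
4. **Expression profile** (`build_profile`): see below.
5. **Transcription** (`transcribe`): stranded exon concatenation; minus-strand
   isoforms are the reverse complement of the genomic-order concatenation.
   N passes through unchanged. No poly(A) tail is appended by default
   (`poly_a=0` exposes one).
6. **Read generation** (`simulate_sample`): see below.

All stage seeds are spawned from one master seed via `numpy.random
.SeedSequence`, so a `SimulationConfig` determines every output byte.

## AS event operators

* **ES** removes one uniformly chosen internal exon (needs ≥ 3 exons).
* **IR** merges one uniformly chosen adjacent exon pair across their intron;
  on a 2-exon transcript this yields a mono-exonic isoform, which the
  evaluator's default mono-exon filter later excludes — intentional, as
  retained introns are a known source of mono-exon calls.
* **A5/A3** move one donor (upstream exon end) or acceptor (downstream exon
  start) by a uniform δ ∈ [3, 30] bp in a uniform direction, rejecting moves
  that would empty an exon or erase an intron. Donor/acceptor are genomic
  notions here (left/right intron boundary); strand only affects
  transcription. The lower bound 3 avoids sub-codon jitter; the upper bound
  30 keeps events inside typical exon scale. Sampling is rejection-based
  (32 tries) with exhaustive enumeration as fallback, so "no legal placement"
  is decided exactly and `apply_event` returns None rather than looping.

Event-type weights default to ES 0.4, IR 0.2, A5 0.2, A3 0.2 — exon skipping
is the most common event class in animal transcriptomes; the weights are
plain config and fully overridable. The operator set is limited to these
four: terminal-site variation is produced downstream by read truncation, and
mutually-exclusive-exon events are not modelled.

Novel ids are `{parent_id}.novel{serial}`; provenance (parent id plus the
ordered event list along the derivation chain) is written as TSV.

## Expression model

Gene-level depth: x ~ GMM over log₁₀(depth), accepted when
10^x ∈ [low_cutoff, high_cutoff_ratio·μ]; the accepted vector is rescaled by
a common factor so its arithmetic mean equals the targeted sample depth μ,
re-clipped to the window, and the rescale/clip pass repeated up to 5 times
(tolerance 1 % of μ; in practice 1–2 passes suffice because the clip moves
little mass). Defaults μ = 20, low_cutoff = 0.01, high_cutoff_ratio = 200.
The default mixture has two components in log₁₀ space —
(w 0.7, m log₁₀μ − 0.5, s 0.6) and (w 0.3, m log₁₀μ + 0.5, s 0.4) — chosen to
give a heavy right tail and a ≥ 10⁴–10⁵-fold dynamic range across a few
hundred genes; any fitted `GMMSpec` can be substituted.

Isoform-level depth: deterministic Zipf rank weights r^(−α) rescaled so the
arithmetic mean equals the gene depth, with ranks shuffled onto isoforms by a
seeded permutation. The ranks are deterministic rather than sampled so the
inequality is exact and checkable in closed form: max/min = k^α, e.g.
7⁴ = 2401 at the default α = 4. Isoforms falling below low_cutoff are flagged
unexpressed (silent) but kept in the ground-truth GTF, so an evaluation can
distinguish "annotated but silent" from "absent".

Because the sample-level mean is an isoform-weighted mean of gene depths, it
carries sampling scatter around μ that shrinks with gene count; at ≥ 100
genes it sits within ~10 % of μ (verified in the tests at 200 genes), while
the gene-level mean is pinned within 1 % by construction.

## Read model

* Read count per isoform = round(depth): one full-length read contributes
  exactly 1× depth, matching the definition of isoform depth as emitted
  bases divided by transcribed length. This inversion (depth → count) is the
  package's own convention.
* Truncation removes floor(r₅·L) bases from the 5′ and floor(r₃·L) from the
  3′ end of every read — a deliberately uniform completeness model (every
  read of an isoform is clipped identically). With r₅ + r₃ < 1 enforced, the
  floor arithmetic always leaves ≥ 1 base; a defensive 1-base floor with a
  warning guards the degenerate path.
* The error channel edits each base independently with probability
  1 − accuracy, split sub:ins:del = 0.4:0.3:0.3 by default (indel-heavy,
  ONT-like; overridable). Substitutions draw a uniform *different* base;
  insertions emit the base plus one uniform base; deletions skip. Quality is
  a uniform phred char q = min(41, round(−10·log₁₀(1 − accuracy))). Per-read
  accuracy can be drawn from a truncated Normal(accuracy_mean, accuracy_sd);
  the default sd 0 uses the mean for every read. Context-dependent
  (homopolymer/k-mer) error structure is not modelled.
* With `strand_symmetric` (default on, modelling double-stranded cDNA) each
  read is reverse-complemented with probability ½; the emitted strand is
  recorded in the read id `{transcript_id}:{serial}:{+|-}` (':' and '%' in
  ids escaped bijectively).
* An `LLRGAdapter` protocol (template + depth in, reads out) documents how an
  external sequencer-specific read generator can replace the built-in
  channel.

## Evaluator

* **Matching**: TP iff identical (contig, strand, intron chain); terminal
  exon ends are free. Each reference isoform absorbs at most one query;
  because the criterion is equality, maximum bipartite matching reduces to
  per-key pairing, with lexicographic tie-breaks for deterministic reports.
  precision = TP/(TP+FP), sensitivity = TP/(TP+FN); undefined denominators
  are reported as None/NA rather than 0.
* **Classification cascade** (per query, same contig+strand throughout):
  FSM on chain equality → ISM when the chain is a *contiguous* run inside a
  longer reference chain (internal-exon-skipping subsets are NOT ISM; they
  fall through to NIC/NNC) → if the transcript overlaps any gene span
  (any strand; intergenic is a positional notion) NIC when every donor and
  acceptor it uses is annotated on that contig+strand, else NNC → INTERGENIC
  when no gene span overlaps. Classification is strand-specific, so an
  antisense copy of an annotated isoform lands in NNC (or INTERGENIC), by
  design; finer antisense/genic sub-categories are deliberately collapsed
  into these five. Mono-exonic queries are excluded by default (`keep_mono`
  disables the filter; an empty chain then matches only a mono-exonic
  reference for FSM, is never ISM, and is vacuously NIC when genic).
* **Jaccard**: strand-agnostic union of exonic intervals per set, then
  intersection-bp / union-bp over merged intervals; 0/0 → 0 by convention.
  Cross-checked in the tests against a per-base set oracle and against
  `bedtools jaccard`.
* **Depth report**: alignment-free — read ids are parsed back to origin
  isoforms; depth_i = Σ emitted read lengths / transcribed length, gene and
  sample depths are arithmetic means over isoforms with nonzero depth.
  Unparseable ids are counted and skipped.

## Synthetic fixtures

`make_fixture` generates i.i.d. random genomes at a target GC fraction and
places non-overlapping genes left-to-right with ≥ 500 bp gaps (guaranteeing
intergenic space for classification tests), alternating +/− strand to
exercise stranded paths. A gene's isoforms share one exon scaffold and differ
by dropped terminal exons plus jittered terminal ends, so intron chains are
distinct by construction (isoform count is capped at n_exons − 1
accordingly). The fixtures deliberately omit realistic base composition,
repeats, splice-site motifs and overlapping genes: passing tests demonstrate
the simulator's and evaluator's *accounting* is correct, not that the reads
fool an aligner trained on real data.

## Problem sizes and numerical choices

Tests run on fixtures of 10–200 genes (≈ 18–460 isoforms) and error-channel
calibrations on 10⁶-base templates; these sizes make every distributional
check statistically comfortable (binomial sd ≪ tolerance) while the whole
suite completes in seconds. Tolerances asserted: gene-mean within 1 % of μ
(the rescale loop's own stopping rule), sample depth within 10 % of μ,
realized error rate within 0.5 percentage points at 10⁶ bases, Zipf ratios
exact to 1e-9 relative. Dataclass validation re-runs in
`generate_ground_truth` so mutated configs fail loudly. GTF coordinates
convert 1-based inclusive ↔ 0-based half-open only at the I/O boundary.

## Known limitations

* Depth-to-read-count rounding makes isoforms with depth < 0.5 silent even
  when flagged expressed; the realized sample depth therefore dips slightly
  under μ when many minor isoforms exist.
* Truncation is uniform per dataset, not a per-read completeness
  distribution.
* The evaluator's ISM/NIC/NNC semantics operate purely on splice-site
  coordinates; no reference-coverage or expression-aware matching.
* Single-sample simulation only; no replicate covariance or differential
  isoform usage modelling.
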