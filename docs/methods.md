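# Methods

## The signal being modeled

N1-methyladenosine (m¹A) carries its methyl group on the Watson–Crick
face, so a reverse transcriptase (RT) that encounters it either stalls or
reads through with a misincorporation. Chemical reduction of m¹A (NaBH₄)
strengthens both readthrough and the misincorporation signature —
dominantly A→T with a minor A→G component — while alkaline-driven Dimroth
rearrangement (m¹A→m⁶A, RT-silent) or pNTP treatment suppresses it,
yielding matched control libraries. A site is called m¹A when two treated
libraries made with different RTs (ProtoScript II and SuperScript IV)
concordantly show an elevated mutation ratio that the controls lack.

This package implements the computational side of that design end to end:
a generative simulator of the libraries, read preprocessing, alignment,
pileup/mutation statistics, and the site-calling cascade.

## Simulator

Each molecule is a fragment of a reference (full-length for spike-in
oligos and tRNA-length references; uniform-length random fragments
otherwise). Copying proceeds 3′→5′ along the template. At a modified
position with signature `(emit_probs, trunc_prob)`:

* with probability `residual_factor × trunc_prob` the product terminates
  immediately before the site — its last copied template base is the one
  3′ of the site, so the product's reference span starts at `site + 1`;
* otherwise the emitted base is drawn from the residual-scaled
  `emit_probs` (A→T, A→G, A→C), with the remaining mass emitting A.

Every product base then miscalls uniformly at `error_rate`
(default 0.001, matching a sub-1% observed background floor). Errors are
applied once per molecule, so PCR duplicates share them — they stand for
RT/PCR-stage errors; independent per-read sequencer noise is not
modeled, nor are position-dependent quality profiles or
structure-dependent truncation.

**Control chemistries** are a single multiplicative `residual_factor` on
the whole signature: 16/65 (pNTP) and 7/65 (Tris/Dimroth) by default, the
ratios of the observed spike-in control rates (~16%, ~7%) to the ~65%
treated rate. A one-parameter model is the most transparent mechanism
that reproduces those observations; whether truncation scales identically
in real controls is unknown, and we scale it by the same factor.

**Library layout** mirrors the protocol: R2 =
`[5-nt random end][6-nt in-line barcode][product][5-nt random end]` plus
3′ adapter, clipped to the read length (PE63 default); R1 reads the
opposite strand (`revcomp`), with the two 5-nt random ends acting as a
10-nt UMI. PCR duplication is geometric (mean reads/molecule 1.5 by
default) — the simplest memoryless choice. Qualities are constant Q40;
no downstream step is quality-aware. A truth table records each
molecule's covered span, emitted base per site, and copy number, so
every downstream stage is testable exactly.

**Spike-ins.** The 43-mer fixed-context oligo (m¹A at the 18th
nucleotide, AA-m¹A-GC context) and the 45-mer oligo with the modified A
flanked by four degenerate positions (NN-m¹A-NN, 256 motifs) are built
in as references; the N-containing template is a first-class reference
whose N positions score as matches during alignment and are excluded
from mutation counting.

## Preprocessing

Stage order: 3′ adapter trim → minimum-length filter (30 nt, boundary
inclusive) → exact-sequence collapsing → blind end trim (R1 5+5, R2
11+5). Collapsing precedes end trimming deliberately: with the random
ends still attached, identical full sequences are PCR duplicates, not
biological duplicates. Adapter matching is exact (full occurrence
anywhere, or a suffix/prefix overlap of ≥ 5 nt); no error-tolerant or
quality trimming is performed — a divergence from production trimmers,
chosen for desk-scale determinism. Paired reads collapse on
`R1 + "|" + R2`.

A consequence worth knowing: at 50,000 molecules, 10-nt UMIs collide at
the birthday rate (~10³ collisions), and collisions are more frequent
within the majority base class at a strongly modified site, so the
post-collapse rate sits a couple of tenths of a percentage point below
the emission parameter. Real collapsing-based pipelines share this
artifact.

## Alignment

Full Smith–Waterman–Gotoh (affine gaps; match +1, mismatch −4, gap open
−6, extend −1 — a common short-read-mapper scheme) with no seeding: the
references are at most a few kb. Cigars use =/X plus S. Perfect
occurrences take the leftmost position; among other co-optimal
alignments the latest-ending cell wins, so a mismatch at the read end is
retained rather than soft-clipped — the effect a mapper's clip penalty
has, and essential for sites a few bases from a read end. The traceback
prefers diagonal over deletion over insertion.

A read is assigned uniquely when its best score reaches `min_score`
(20) and exceeds the second-best candidate by `unique_margin` (4);
otherwise it is ambiguous (the stand-in for a MAPQ ≥ 10 filter — exact
MAPQ reproduction is not attempted because mapper MAPQ formulas are
heuristic and version-dependent) or unmapped. Identical reference
sequences (tRNA isodecoders) can be merged first so their shared reads
are not all discarded. The stranded protocol is honored by
reverse-complementing R1 payloads to reference sense instead of
searching both orientations.

## Pileups and statistics

A column tallies base calls from =/X/M ops, deletions spanning the
position, and RT stops. Because RT runs 3′→5′, `stop_count` at `pos`
counts alignments whose reference span starts at `pos + 1`; the
readthrough/truncation ratio is covering reads over stops, `inf` when no
stops are seen. For fragmented references a genuine fragment start is
indistinguishable from an RT stop — the same ambiguity real RT-stop
analyses carry.

Mutation ratio = non-reference fraction of base calls; deletions are
excluded from numerator and denominator (the pattern of interest is
substitution) but reported. Significance is a two-sided Fisher's exact
test of each treated library against the two controls pooled; the
reported p is the worse of the two treated tests, so "significant" means
both RTs are. The test is validated against an exact hypergeometric
enumeration oracle to 1e−10. No multiple-testing correction is applied
by default (matching the bare p < 0.05 rule); Benjamini–Hochberg can be
layered on by the user. Technical replicates are merged by summing
counts before rates are computed.

## Calling cascade

A candidate is every reference A with any coverage; each is emitted with
per-filter flags so the cascade is auditable. Pass requires: coverage
≥ 50 in all four libraries (controls included — a site without control
coverage is never "pass"); ratio ≥ 5% and mutant support ≥ 2 in both
treated libraries; p < 0.05; ratio < 5% in both controls; and each
treated ratio ≥ 2× each control ratio (pairwise-all, the strictest
reading; a zero control ratio passes with an `inf` fold sentinel).
Raising any threshold can only shrink the passing set (tested).

## Numerical and degenerate-input choices

* Coordinates: 0-based half-open internally, 1-based inclusive in all
  output tables.
* Zero-coverage columns are undefined for rates and skipped; a
  zero-coverage margin in the Fisher test returns p = 1 with a warning.
* The site table serializes rates as percentages with two decimals,
  p-values as `%.4e`, folds as `%.3f`/`inf`; re-serializing a parsed
  table is byte-identical.
* All randomness flows from one user-supplied seed through a named
  `numpy` generator; identical seeds give identical FASTQ bytes.

## Problem sizes and what the tests show

The acceptance computations are sized for a desk: 50,000 spike-in
molecules for the fixed-context rate recovery (~64.4% observed vs the
64.5% emission total and the printed ~65%; A→T ~57.6% vs 57.7%), and
10,000 molecules per library for the near-3′-end tRNA regime (treated
9%, controls 1%/0%), where sampling error on the treated rate is ~0.3
percentage points and the site must also pass the full cascade.
Specificity (no passing sites across 20 null simulations of 2,000 A
positions at coverage 500) and boundary sensitivity (≥95/100 passes in
the 9%/1%/0% regime at coverage 200) are evaluated on binomially
simulated pileups, since the cascade consumes pileups.

Passing these tests shows the pipeline recovers the parameters its
generator encodes and that the cascade behaves as specified at its
boundaries. It does not certify performance on real libraries: the
simulator has no position-dependent error structure, no RT sequence
preferences away from the modified site, no isodecoder families beyond
what the user supplies, and a one-parameter control model. Genome-scale
alignment, canonical tRNA numbering, and stoichiometry calibration are
out of scope.
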