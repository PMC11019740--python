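"""Per-position pileups, mutation rates and the treated-vs-control test.

A pileup column tallies aligned read bases (from =/X/M cigar ops),
deletions spanning the position, and RT stops.  Because the reverse
transcriptase copies the template 3'->5', a product truncated at a
modified site begins one base 3' of it; ``stop_count`` at a column
therefore counts alignments whose reference start is ``pos + 1``.

The mutation ratio at a column is the non-reference fraction of base
calls; deletions are excluded from both numerator and denominator (the
signature of interest is base substitution) but reported separately.

Treated-vs-control significance uses a two-sided Fisher's exact test on
mutant/non-mutant counts, with the two control libraries pooled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from scipy.stats import fisher_exact

from m1aseq.io_formats import AlignmentRecord, ReferenceSet


@dataclass
class PileupColumn:
    ref_name: str
    pos: int  # 0-based
    ref_base: str
    counts: dict = field(default_factory=lambda: {"A": 0, "C": 0, "G": 0, "T": 0})
    del_count: int = 0
    stop_count: int = 0

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MutationSummary:
    """Non-reference fraction and its per-alt decomposition at a column."""

    rate: float
    pattern: dict  # alt base -> fraction of coverage
    alt_support: int
    coverage: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")


def build_pileup(alignments: list[AlignmentRecord], refs: ReferenceSet) -> dict:
    """Tally base calls per reference position from unique alignments.

    Returns ``{ref_name: [PileupColumn, ...]}`` covering every position
    of every reference.  Soft-clipped bases are never counted; deletions
    increment ``del_count`` over the deleted positions; an alignment
    starting at ``pos + 1`` increments ``stop_count`` at ``pos`` (the RT
    stop signal).  Ambiguous/unmapped records are ignored.
    """
    pileups = {
        name: [PileupColumn(name, p, seq[p]) for p in range(len(seq))]
        for name, seq in refs.items()
    }
    for aln in alignments:
        if aln.status != "unique":
            continue
        aln.validate(refs)
        if aln.seq is None:
            raise ValueError(f"alignment {aln.read_id!r} carries no read sequence")
        cols = pileups[aln.ref_name]
        w = aln.weight
        i, j = 0, aln.ref_start
        for op, n in aln.cigar:
            if op in ("M", "=", "X"):
                for k in range(n):
                    base = aln.seq[i + k]
                    if base != "N":
                        cols[j + k].counts[base] += w
                i += n
                j += n
            elif op == "D":
                for k in range(n):
                    cols[j + k].del_count += w
                j += n
            elif op in ("I", "S"):
                i += n
            else:  # pragma: no cover
                raise ValueError(f"unsupported cigar op {op!r}")
        if aln.ref_start >= 1:
            cols[aln.ref_start - 1].stop_count += w
    return pileups


def mutation_rate(column: PileupColumn) -> MutationSummary:
    """Mutation ratio and pattern decomposition at one column.

    rate = (coverage - ref-base count) / coverage; each pattern component
    is counts[alt] / coverage.  Zero coverage is undefined: the caller
    must skip such columns.
    """
    cov = column.coverage
    if cov == 0:
        raise ValueError(
            f"zero coverage at {column.ref_name}:{column.pos}; column must be skipped"
        )
    if column.ref_base not in "ACGT":
        raise ValueError(f"reference base {column.ref_base!r} is not a concrete base")
    ref_n = column.counts[column.ref_base]
    pattern = {
        alt: column.counts[alt] / cov for alt in "ACGT" if alt != column.ref_base
    }
    return MutationSummary((cov - ref_n) / cov, pattern, cov - ref_n, cov)


def site_test(treated_mut: int, treated_cov: int,
              control_mut: int, control_cov: int) -> float:
    """Two-sided Fisher's exact test of treated vs (pooled) control.

    The 2x2 table is [[treated_mut, treated_cov - treated_mut],
    [control_mut, control_cov - control_mut]].  A zero-coverage margin
    is degenerate and returns p = 1 with a warning.
    """
    if min(treated_mut, treated_cov, control_mut, control_cov) < 0:
        raise ValueError("counts must be non-negative")
    if treated_mut > treated_cov or control_mut > control_cov:
        raise ValueError("mutant count exceeds coverage")
    if treated_cov == 0 or control_cov == 0:
        warnings.warn("zero coverage in site test; p = 1", stacklevel=2)
        return 1.0
    table = [
        [treated_mut, treated_cov - treated_mut],
        [control_mut, control_cov - control_mut],
    ]
    return float(fisher_exact(table, alternative="two-sided")[1])


def truncation_ratio(alignments: list[AlignmentRecord], ref_name: str, pos: int) -> float:
    """Readthrough/truncation ratio at a site.

    readthrough = unique alignments covering ``pos``; stops = unique
    alignments starting exactly at ``pos + 1`` (RT terminated just before
    copying the site).  Returns ``inf`` when no stops are seen and
    ``nan`` when no reads are informative at all.
    """
    covers = 0
    stops = 0
    for aln in alignments:
        if aln.status != "unique" or aln.ref_name != ref_name:
            continue
        if aln.ref_start <= pos < aln.ref_end():
            covers += aln.weight
        elif aln.ref_start == pos + 1:
            stops += aln.weight
    if covers == 0 and stops == 0:
        return math.nan
    if stops == 0:
        return math.inf
    return covers / stops
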