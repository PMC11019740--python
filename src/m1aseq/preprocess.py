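"""Read preprocessing: adapter trim, length filter, duplicate collapse, end trim.

Stage order follows the library design: 3' adapter removal and a 30-bp
minimum-length filter first, then exact-sequence collapsing of identical
reads (the 5-nt random ends still attached act as UMIs, so collapsing
removes PCR duplicates without destroying biological duplicates), and
finally blind end-trimming that strips the random ends and the in-line
barcode: 5+5 nt from R1, 11+5 nt from R2.

Adapter trimming is exact-match prefix/suffix (no error tolerance); the
pipeline has no quality-aware step downstream, so qualities are only
carried along in lock-step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from m1aseq._seq import revcomp
from m1aseq.io_formats import ReadRecord

logger = logging.getLogger(__name__)

ReadPair = tuple[ReadRecord, ReadRecord]


@dataclass(frozen=True)
class PreprocessConfig:
    adapter3: str = "AGATCGGAAGAGC"
    min_len: int = 30
    min_overlap: int = 5
    r1_trim: tuple[int, int] = (5, 5)
    r2_trim: tuple[int, int] = (11, 5)
    collapse: bool = True

    def __post_init__(self) -> None:
        if self.min_len <= 0:
            raise ValueError("min_len must be positive")
        if any(t < 0 for t in self.r1_trim + self.r2_trim):
            raise ValueError("trims must be non-negative")
        if not self.adapter3:
            raise ValueError("adapter3 must be non-empty")


def trim_adapter3(read: ReadRecord, adapter3: str, min_overlap: int = 5) -> ReadRecord:
    """Remove the leftmost 3'-adapter match and everything 3' of it.

    A match is either a full occurrence of the adapter anywhere in the
    read, or a read suffix equal to an adapter prefix of length at least
    ``min_overlap``.  No match leaves the read unchanged.
    """
    if not adapter3:
        raise ValueError("adapter must be non-empty")
    seq = read.seq
    n, la = len(seq), len(adapter3)
    cut = seq.find(adapter3)
    if cut == -1:
        cut = n
    # suffix/adapter-prefix overlaps, longest (leftmost) first
    lo = max(0, n - la + 1)
    for i in range(lo, n - min_overlap + 1):
        if i >= cut:
            break
        if seq.startswith(adapter3[: n - i], i):
            cut = i
            break
    if cut == n:
        return read
    return ReadRecord(read.id, seq[:cut], read.qual[:cut], read.role)


def length_filter(reads: list, min_len: int = 30) -> list:
    """Drop reads shorter than ``min_len`` (30-nt reads are retained).

    For paired input, a pair is dropped when either mate is too short.
    """
    out = []
    for item in reads:
        if isinstance(item, tuple):
            if all(len(r) >= min_len for r in item):
                out.append(item)
        elif len(item) >= min_len:
            out.append(item)
    return out


def _collapse_key(item) -> str:
    if isinstance(item, tuple):
        return "|".join(r.seq for r in item)
    return item.seq


def collapse_identical(reads: list) -> list[tuple[object, int]]:
    """Exact-sequence deduplication with multiplicity.

    Paired reads collapse on the concatenation R1 + "|" + R2.  One
    representative (the first occurrence) is kept per distinct sequence,
    annotated with its count; output order is first-occurrence order.
    """
    seen: dict[str, int] = {}
    reps: list = []
    counts: list[int] = []
    for item in reads:
        key = _collapse_key(item)
        idx = seen.get(key)
        if idx is None:
            seen[key] = len(reps)
            reps.append(item)
            counts.append(1)
        else:
            counts[idx] += 1
    return list(zip(reps, counts))


def trim_fixed_ends(read: ReadRecord, role: str | None = None,
                    r1_trim: tuple[int, int] = (5, 5),
                    r2_trim: tuple[int, int] = (11, 5)) -> ReadRecord | None:
    """Blind end trim: R1 loses 5+5 nt, R2 loses 11+5 nt (head+tail).

    Qualities are trimmed in lock-step.  A read too short to trim is
    dropped (returns None) with a logged warning: it signals
    over-trimmed input.
    """
    role = role or read.role
    head, tail = r2_trim if role == "R2" else r1_trim
    if len(read) <= head + tail:
        logger.warning("read %s too short (%d nt) for %d+%d end trim; dropped",
                       read.id, len(read), head, tail)
        return None
    end = len(read) - tail
    return ReadRecord(read.id, read.seq[head:end], read.qual[head:end], read.role)


def preprocess_pipeline(reads: list, config: PreprocessConfig = PreprocessConfig()
                        ) -> tuple[list, dict]:
    """Run adapter trim -> length filter -> collapse -> end trim.

    ``reads`` is a list of ReadRecord (single-end) or of (R1, R2) pairs.
    Returns the processed reads and a per-stage count dict.  Collapse
    multiplicities are folded into the stage counts; each distinct
    molecule proceeds once.
    """
    stats = {"input": len(reads)}

    def _trim(item):
        if isinstance(item, tuple):
            return tuple(trim_adapter3(r, config.adapter3, config.min_overlap)
                         for r in item)
        return trim_adapter3(item, config.adapter3, config.min_overlap)

    trimmed = [_trim(item) for item in reads]
    stats["adapter_trimmed"] = len(trimmed)

    kept = length_filter(trimmed, config.min_len)
    stats["length_filtered"] = len(kept)

    if config.collapse:
        collapsed = collapse_identical(kept)
        stats["collapsed_unique"] = len(collapsed)
        stats["collapsed_duplicates_removed"] = len(kept) - len(collapsed)
        kept = [item for item, _count in collapsed]

    out = []
    for item in kept:
        if isinstance(item, tuple):
            pair = tuple(
                trim_fixed_ends(r, r.role, config.r1_trim, config.r2_trim)
                for r in item
            )
            if all(p is not None for p in pair):
                out.append(pair)
        else:
            rec = trim_fixed_ends(item, item.role, config.r1_trim, config.r2_trim)
            if rec is not None:
                out.append(rec)
    stats["end_trimmed"] = len(out)
    logger.info("preprocess: %s", stats)
    return out, stats


def sense_payloads(processed: list) -> list[ReadRecord]:
    """Orient processed reads to reference sense for alignment.

    R1 reads the cDNA strand, i.e. the reverse complement of the insert,
    so mapping uses revcomp(R1); this honors the stranded protocol
    without searching both orientations.  Pairs contribute their R1.
    """
    out = []
    for item in processed:
        if isinstance(item, tuple):
            r1 = next((r for r in item if r.role == "R1"), item[0])
        else:
            r1 = item
        seq = revcomp(r1.seq) if r1.role in ("R1", "single") else r1.seq
        out.append(ReadRecord(r1.id, seq, r1.qual[::-1], "single"))
    return out
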