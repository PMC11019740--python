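"""Affine-gap local alignment of processed reads to small reference sets.

The references here are tiny (spike-in oligos, mature tRNAs, at most a
few kb of rRNA), so a full Smith-Waterman-Gotoh dynamic program is used
without seeding heuristics: correctness over speed.  Scoring defaults
mirror a widely used short-read mapper (match +1, mismatch -4, gap open
-6, gap extend -1).

Read assignment keeps the best hit only when it clears a minimum score
and beats the second-best reference by a uniqueness margin; everything
else is flagged ambiguous (the effect of a MAPQ >= 10 filter) or
unmapped and excluded downstream.

An exact N in the reference (the degenerate positions of the randomized
spike-in) scores as a match against any read base.
"""

from __future__ import annotations

from dataclasses import dataclass

from m1aseq._seq import revcomp
from m1aseq.io_formats import AlignmentRecord, ReadRecord, ReferenceSet

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_score: int = 20
    unique_margin: int = 4

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")


def _exact_find(read: str, ref: str) -> int:
    """Leftmost exact occurrence of read in ref; ref N matches anything."""
    if "N" not in ref:
        return ref.find(read)
    n, m = len(read), len(ref)
    for o in range(m - n + 1):
        ok = True
        for k in range(n):
            rb = ref[o + k]
            if rb != "N" and rb != read[k]:
                ok = False
                break
        if ok:
            return o
    return -1


def local_align(read: str | ReadRecord, ref: str, scoring: ScoringScheme = ScoringScheme()
                ) -> tuple[int, AlignmentRecord]:
    """Maximal-scoring local alignment (Smith-Waterman-Gotoh).

    Returns ``(score, record)``; the record's cigar uses =/X (never M)
    plus S for soft-clipped read ends, and ``ref_start`` is 0-based.
    Ties are resolved deterministically: a perfect occurrence takes the
    leftmost position; otherwise the latest-ending co-optimal cell wins,
    so a mismatch at the read end is kept rather than silently
    soft-clipped (the effect a mapper's clip penalty has), and the
    traceback prefers diagonal moves over deletions over insertions.
    A read sharing nothing with the reference yields score 0 and an
    empty alignment.
    """
    read_id = "read"
    if isinstance(read, ReadRecord):
        read_id, read = read.id, read.seq
    if not read or not ref:
        raise ValueError("empty sequence")

    # fast path: perfect occurrence is provably optimal (match is the
    # per-column maximum), and the leftmost one ends earliest
    pos = _exact_find(read, ref)
    if pos >= 0:
        n = len(read)
        rec = AlignmentRecord(read_id, "", pos, [("=", n)], "+",
                              n * scoring.match, "unique", seq=read)
        return n * scoring.match, rec

    n, m = len(read), len(ref)
    ma, mi = scoring.match, scoring.mismatch
    go = scoring.gap_open + scoring.gap_extend  # cost of opening a length-1 gap
    ge = scoring.gap_extend

    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in read (D: consumes ref)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in ref (I: consumes read)

    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        rb = read[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            cb = ref[j - 1]
            s = ma if (cb == rb or cb == "N") else mi
            e = max(Hi[j - 1] + go, Ei[j - 1] + ge)
            f = max(Hi1[j] + go, Fi1[j] + ge)
            h = Hi1[j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
            if h >= best and h > 0:  # ties extend: keep the latest-ending
                best, bi, bj = h, i, j  # maximum so end mismatches are not
                # silently clipped (the effect of a mapper's clip penalty)
    if best == 0:
        return 0, AlignmentRecord(read_id, "", 0, [("S", n)], "+", 0, "unmapped", seq=read)

    # traceback
    ops: list[str] = []
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        rb, cb = read[i - 1], ref[j - 1]
        s = ma if (cb == rb or cb == "N") else mi
        if H[i][j] == H[i - 1][j - 1] + s:
            ops.append("=" if (cb == rb or cb == "N") else "X")
            i -= 1
            j -= 1
        elif H[i][j] == E[i][j]:
            while True:
                ops.append("D")
                if E[i][j] == H[i][j - 1] + go:
                    j -= 1
                    break
                j -= 1
        elif H[i][j] == F[i][j]:
            while True:
                ops.append("I")
                if F[i][j] == H[i - 1][j] + go:
                    i -= 1
                    break
                i -= 1
        else:  # pragma: no cover - unreachable by construction
            raise AssertionError("traceback failed")
    ops.reverse()

    cigar: list[tuple[str, int]] = []
    if i > 0:
        cigar.append(("S", i))
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    if bi < n:
        cigar.append(("S", n - bi))
    rec = AlignmentRecord(read_id, "", j, cigar, "+", best, "unique", seq=read)
    return best, rec


def assign_reads(
    reads: list[ReadRecord],
    refs: ReferenceSet,
    scoring: ScoringScheme = ScoringScheme(),
    search_rc: bool = False,
    collapse_identical_refs: bool = False,
) -> list[AlignmentRecord]:
    """Align every read to every reference; keep unique confident hits.

    The best hit survives when its score reaches ``min_score`` AND beats
    the second-best candidate by ``unique_margin``; otherwise the read is
    ambiguous (multi-mapping, e.g. across identical tRNA isodecoders) or
    unmapped.  ``collapse_identical_refs`` merges duplicate reference
    sequences first, so shared-sequence isodecoders do not discard all
    their reads.
    """
    if len(refs) == 0:
        raise ValueError("empty reference set")
    entries = list(refs.items())
    if collapse_identical_refs:
        by_seq: dict[str, str] = {}
        for name, seq in entries:
            by_seq.setdefault(seq, name)
        entries = [(name, seq) for seq, name in by_seq.items()]

    cache: dict[str, tuple] = {}
    out: list[AlignmentRecord] = []
    for read in reads:
        hit = cache.get(read.seq)
        if hit is None:
            candidates = []
            for name, refseq in entries:
                score, rec = local_align(read.seq, refseq, scoring)
                candidates.append((score, "+", name, rec))
                if search_rc:
                    score_rc, rec_rc = local_align(revcomp(read.seq), refseq, scoring)
                    candidates.append((score_rc, "-", name, rec_rc))
            candidates.sort(key=lambda c: -c[0])
            best_score, strand, ref_name, rec = candidates[0]
            second = candidates[1][0] if len(candidates) > 1 else 0
            if best_score < scoring.min_score:
                status = "unmapped"
            elif best_score - second < scoring.unique_margin:
                status = "ambiguous"
            else:
                status = "unique"
            hit = (best_score, strand, ref_name, rec.ref_start, rec.cigar, status,
                   rec.seq)
            cache[read.seq] = hit
        best_score, strand, ref_name, ref_start, cigar, status, oriented = hit
        if status == "unmapped":
            out.append(AlignmentRecord(read.id, "*", 0, [], "+", best_score,
                                       "unmapped", seq=read.seq))
        else:
            out.append(AlignmentRecord(read.id, ref_name, ref_start, list(cigar),
                                       strand, best_score, status, seq=oriented))
    return out
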