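"""Readers/writers for the formats the pipeline touches.

FASTA references (rRNA, mature tRNA, spike-in oligos), FASTQ reads,
SAM import for externally produced alignments, and the TSV site-call
table that is the pipeline's primary output.  All sequences are held in
DNA space: RNA inputs are transliterated U->T on load, because the
sequencer reports cDNA space and the reference FASTAs are DNA.

Coordinates are 0-based half-open internally; every user-facing table
is 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: cigar operations the pipeline understands (query-consuming, ref-consuming)
_CIGAR_CONSUMES = {
    "M": (True, True),
    "=": (True, True),
    "X": (True, True),
    "I": (True, False),
    "D": (False, True),
    "S": (True, False),
}

_PYSAM_OPS = {0: "M", 1: "I", 2: "D", 4: "S", 7: "=", 8: "X"}


class FormatError(ValueError):
    """Raised on malformed input files or invariant violations."""


def _clean_seq(seq: str, where: str = "") -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise FormatError(f"invalid characters {sorted(bad)} in sequence {where}")
    return s


class ReferenceSet:
    """Ordered, named nucleotide sequences the pipeline aligns to.

    Names are unique and non-empty; sequences are non-empty strings over
    {A, C, G, T, N}.  ``N`` is permitted so that the randomized spike-in
    template (four degenerate positions around the modified A) can be a
    first-class reference.
    """

    def __init__(self, entries: Iterable[tuple[str, str]] = ()):
        self.entries: dict[str, str] = {}
        for name, seq in entries:
            self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if not name:
            raise FormatError("empty reference name")
        if name in self.entries:
            raise FormatError(f"duplicate reference name {name!r}")
        s = _clean_seq(seq, where=name)
        if not s:
            raise FormatError(f"empty sequence for reference {name!r}")
        self.entries[name] = s

    def __getitem__(self, name: str) -> str:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def items(self) -> Iterable[tuple[str, str]]:
        return self.entries.items()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ReferenceSet) and self.entries == other.entries

    def __repr__(self) -> str:
        return f"ReferenceSet({len(self.entries)} entries)"


@dataclass
class ReadRecord:
    """A sequencing read: identifier, bases, per-base qualities and role."""

    id: str
    seq: str
    qual: str
    role: str = "single"  # one of {"R1", "R2", "single"}

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FormatError(
                f"read {self.id!r}: seq length {len(self.seq)} != qual length {len(self.qual)}"
            )
        if self.role not in ("R1", "R2", "single"):
            raise FormatError(f"read {self.id!r}: bad role {self.role!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentRecord:
    """One read-to-reference alignment.

    ``cigar`` is a list of ``(op, length)`` with op in {M, X, =, I, D, S};
    ``ref_start`` is 0-based.  ``seq`` carries the read bases in reference
    orientation so pileups can be built without a side lookup.
    """

    read_id: str
    ref_name: str
    ref_start: int
    cigar: list[tuple[str, int]]
    strand: str = "+"
    score: int = 0
    status: str = "unique"  # unique | ambiguous | unmapped
    seq: str | None = None
    weight: int = 1  # multiplicity carried through from read collapsing

    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if _CIGAR_CONSUMES[op][0])

    def ref_length(self) -> int:
        return sum(n for op, n in self.cigar if _CIGAR_CONSUMES[op][1])

    def ref_end(self) -> int:
        """0-based exclusive end of the reference span."""
        return self.ref_start + self.ref_length()

    def validate(self, refs: ReferenceSet | None = None) -> None:
        for op, n in self.cigar:
            if op not in _CIGAR_CONSUMES:
                raise FormatError(f"unsupported cigar op {op!r}")
            if n <= 0:
                raise FormatError("cigar op length must be positive")
        if self.seq is not None and self.query_length() != len(self.seq):
            raise FormatError(
                f"alignment {self.read_id!r}: cigar consumes {self.query_length()} "
                f"query bases but read has {len(self.seq)}"
            )
        if refs is not None and self.status != "unmapped":
            if self.ref_name not in refs:
                raise FormatError(f"unknown reference {self.ref_name!r}")
            if self.ref_end() > len(refs[self.ref_name]):
                raise FormatError(
                    f"alignment {self.read_id!r} overruns reference {self.ref_name!r}"
                )


def cigar_to_string(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def cigar_from_string(s: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    num = ""
    for ch in s:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise FormatError(f"bad cigar string {s!r}")
            out.append((ch, int(num)))
            num = ""
    if num:
        raise FormatError(f"bad cigar string {s!r}")
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ReferenceSet:
    """Load a FASTA file into a :class:`ReferenceSet` (U -> T applied).

    The header token before the first whitespace is the reference name.
    Duplicate names and empty files are hard errors.
    """
    refs = ReferenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        refs.add(rec.id, str(rec.seq))
    if len(refs) == 0:
        raise FormatError(f"no FASTA records in {path}")
    return refs


def write_fasta(refs: ReferenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in refs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path, role: str = "single") -> list[ReadRecord]:
    """Read 4-line FASTQ records; seq/qual length mismatches are hard errors."""
    out: list[ReadRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            qual = "".join(chr(q + 33) for q in quals)
            out.append(ReadRecord(rec.id, _clean_seq(str(rec.seq), rec.id), qual, role))
    except ValueError as exc:  # Biopython signals truncated/mismatched records
        raise FormatError(f"malformed FASTQ {path}: {exc}") from exc
    return out


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# SAM import / export
# ---------------------------------------------------------------------------

def read_sam(
    path: str | Path, refs: ReferenceSet, min_mapq: int = 10
) -> list[AlignmentRecord]:
    """Import alignments from a SAM file produced by an external aligner.

    Records with mapping quality below ``min_mapq`` (default 10, the
    samtools ``-q 10`` uniqueness filter) come back with status
    ``ambiguous``; unmapped-flagged reads with status ``unmapped``.
    A reference name absent from ``refs`` is a hard error.
    """
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for name in sam.references:
            if name not in refs:
                raise FormatError(f"SAM reference {name!r} not in reference set")
        for rec in sam:
            if rec.is_unmapped:
                out.append(
                    AlignmentRecord(
                        rec.query_name, "*", 0, [], "+", 0, "unmapped",
                        seq=rec.query_sequence,
                    )
                )
                continue
            cigar = []
            for code, n in rec.cigartuples or []:
                if code not in _PYSAM_OPS:
                    raise FormatError(
                        f"cigar op code {code} in read {rec.query_name!r} unsupported"
                    )
                cigar.append((_PYSAM_OPS[code], n))
            status = "unique" if rec.mapping_quality >= min_mapq else "ambiguous"
            aln = AlignmentRecord(
                rec.query_name,
                rec.reference_name,
                rec.reference_start,
                cigar,
                "-" if rec.is_reverse else "+",
                rec.get_tag("AS") if rec.has_tag("AS") else 0,
                status,
                seq=rec.query_sequence,
            )
            aln.validate(refs)
            out.append(aln)
    return out


def write_sam(
    alignments: Iterable[AlignmentRecord], refs: ReferenceSet, path: str | Path
) -> None:
    """Export internal alignments as SAM (for IGV-style inspection)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in refs.items()],
    }
    mapq = {"unique": 60, "ambiguous": 0}
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for aln in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = aln.read_id
            if aln.status == "unmapped":
                rec.is_unmapped = True
                rec.query_sequence = aln.seq or ""
                sam.write(rec)
                continue
            rec.reference_name = aln.ref_name
            rec.reference_start = aln.ref_start
            rec.cigarstring = cigar_to_string(aln.cigar)
            rec.mapping_quality = mapq[aln.status]
            rec.is_reverse = aln.strand == "-"
            if aln.seq is not None:
                rec.query_sequence = aln.seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(aln.seq))
            rec.set_tag("AS", int(aln.score))
            sam.write(rec)


# ---------------------------------------------------------------------------
# Site table (primary tabular output)
# ---------------------------------------------------------------------------

LIBRARIES = ("psii", "ssiv", "pntp", "tris")

SITE_TABLE_COLUMNS = (
    ["ref_name", "pos_1based", "ref_base"]
    + [f"cov_{lib}" for lib in LIBRARIES]
    + [f"rate_{lib}" for lib in LIBRARIES]
    + [f"{mut}_{lib}" for lib in LIBRARIES for mut in ("a_to_t", "a_to_g", "a_to_c")]
    + ["p_value", "fold_vs_pntp", "fold_vs_tris"]
    + [
        "flag_ref_a",
        "flag_coverage",
        "flag_treated_rate",
        "flag_alt_support",
        "flag_p_value",
        "flag_control_rate",
        "flag_fold",
    ]
    + ["verdict"]
)


def _fmt_rate(x: float) -> str:
    """Rates are printed as percentages with two decimals."""
    return f"{100.0 * x:.2f}"


def _fmt_fold(x: float) -> str:
    if math.isinf(x):
        return "inf"
    if math.isnan(x):
        return "NA"
    return f"{x:.3f}"


def _fmt_p(x: float) -> str:
    if math.isnan(x):
        return "NA"
    return f"{x:.4e}"


def site_call_to_row(call) -> list[str]:
    row = [call.ref_name, str(call.pos_1based), call.ref_base]
    row += [str(call.coverage[lib]) for lib in LIBRARIES]
    row += [_fmt_rate(call.rate[lib]) for lib in LIBRARIES]
    for lib in LIBRARIES:
        for alt in "TGC":
            row.append(_fmt_rate(call.pattern[lib].get(alt, 0.0)))
    row += [_fmt_p(call.p_value), _fmt_fold(call.fold_vs_pntp), _fmt_fold(call.fold_vs_tris)]
    row += [str(int(call.flags[k])) for k in (
        "ref_a", "coverage", "treated_rate", "alt_support",
        "p_value", "control_rate", "fold",
    )]
    row.append("pass" if call.verdict else "fail")
    return row


def write_site_table(calls: Iterable, path: str | Path) -> None:
    """Serialize site calls as TSV, sorted by (ref name, position).

    The format is deterministic: re-serializing a parsed table is
    byte-identical.
    """
    calls = sorted(calls, key=lambda c: (c.ref_name, c.pos_1based))
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_TABLE_COLUMNS) + "\n")
        for call in calls:
            fh.write("\t".join(site_call_to_row(call)) + "\n")


def read_site_table(path: str | Path) -> list:
    """Parse a site-call TSV back into :class:`~m1aseq.calling.SiteCall` rows."""
    from m1aseq.calling import SiteCall  # deferred; calling imports this module

    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(SITE_TABLE_COLUMNS):
            raise FormatError(f"unexpected site-table header in {path}")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            coverage = {lib: int(f[f"cov_{lib}"]) for lib in LIBRARIES}
            rate = {lib: float(f[f"rate_{lib}"]) / 100.0 for lib in LIBRARIES}
            pattern = {
                lib: {
                    alt: float(f[f"a_to_{alt.lower()}_{lib}"]) / 100.0
                    for alt in "TGC"
                }
                for lib in LIBRARIES
            }
            flags = {
                k: bool(int(f[f"flag_{k}"]))
                for k in (
                    "ref_a", "coverage", "treated_rate", "alt_support",
                    "p_value", "control_rate", "fold",
                )
            }
            calls.append(
                SiteCall(
                    ref_name=f["ref_name"],
                    pos_1based=int(f["pos_1based"]),
                    ref_base=f["ref_base"],
                    coverage=coverage,
                    rate=rate,
                    pattern=pattern,
                    p_value=float("nan") if f["p_value"] == "NA" else float(f["p_value"]),
                    fold_vs_pntp=_parse_fold(f["fold_vs_pntp"]),
                    fold_vs_tris=_parse_fold(f["fold_vs_tris"]),
                    flags=flags,
                    verdict=f["verdict"] == "pass",
                )
            )
    return calls


def _parse_fold(s: str) -> float:
    if s == "inf":
        return math.inf
    if s == "NA":
        return math.nan
    return float(s)


def write_bed(calls: Iterable, path: str | Path, passing_only: bool = True) -> None:
    """Minimal BED export: ref, 0-based start, end, verdict."""
    calls = sorted(calls, key=lambda c: (c.ref_name, c.pos_1based))
    with open(path, "w") as fh:
        for c in calls:
            if passing_only and not c.verdict:
                continue
            fh.write(
                f"{c.ref_name}\t{c.pos_1based - 1}\t{c.pos_1based}\t"
                f"{'pass' if c.verdict else 'fail'}\n"
            )
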