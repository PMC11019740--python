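"""Synthetic sequencing libraries with an m1A reverse-transcription signature.

The generator emulates what the wet protocol produces:

* RT copies each RNA template 3'->5'.  At a reduced m1A it either stops
  just before the modified base (truncation) or reads through and
  misincorporates, dominantly A->T with a minor A->G component.
* Control chemistries (pNTP and Tris-driven Dimroth rearrangement to
  RT-silent m6A) do not remove the signal completely; the residue is
  modeled as a single multiplicative ``residual_factor`` on the treated
  site signature.  Defaults are 16/65 (pNTP) and 7/65 (Tris), the ratios
  of the observed spike-in control rates (~16% and ~7%) to the ~65%
  treated rate.
* Library layout: the cDNA insert is flanked by 5-nt random ends (which
  act as UMIs), a 6-nt in-line barcode on the R2 side, and a 3' adapter;
  reads are clipped to a fixed length (PE63 by default).  PCR duplicates
  are geometric; duplicates share their molecule's RT product (RT/PCR
  errors propagate, per-duplicate sequencer noise is not modeled).

Every downstream stage of the pipeline is testable against the truth
table this module emits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from m1aseq._seq import revcomp
from m1aseq.io_formats import ReadRecord, ReferenceSet

BASES = "ACGT"

#: residual signal left by each control chemistry, as a fraction of the
#: treated signature (observed control rate / observed treated rate on the
#: fixed spike-in: 16/65 for pNTP, 7/65 for the Tris Dimroth condition)
RESIDUAL_PNTP = 16.0 / 65.0
RESIDUAL_TRIS = 7.0 / 65.0

DEFAULT_ADAPTER3 = "AGATCGGAAGAGC"
DEFAULT_BARCODE = "CAGTAC"


@dataclass(frozen=True)
class SiteSignature:
    """Per-site RT signature of a reduced m1A.

    ``emit_probs`` are the probabilities of reading T, G or C at the site
    (the remaining mass emits the reference A); ``trunc_prob`` is the
    probability that RT terminates immediately before copying the site.
    """

    ref_name: str
    pos: int  # 0-based
    emit_probs: dict = field(default_factory=dict)
    trunc_prob: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.emit_probs) - {"T", "G", "C"}
        if bad:
            raise ValueError(f"emit_probs keys must be alt bases, got {sorted(bad)}")
        probs = list(self.emit_probs.values()) + [self.trunc_prob]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(self.emit_probs.values()) > 1 + 1e-12:
            raise ValueError("emit_probs must sum to at most 1")


@dataclass(frozen=True)
class ModificationProfile:
    """The set of modified sites simulated on a reference set."""

    sites: tuple = ()

    def __post_init__(self) -> None:
        keys = [(s.ref_name, s.pos) for s in self.sites]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (ref_name, pos) in profile")

    def for_ref(self, ref_name: str) -> list[SiteSignature]:
        return [s for s in self.sites if s.ref_name == ref_name]

    def validate_against(self, refs: ReferenceSet) -> None:
        for s in self.sites:
            if s.ref_name not in refs:
                raise ValueError(f"profile site on unknown reference {s.ref_name!r}")
            ref_base = refs[s.ref_name][s.pos]
            if ref_base not in ("A", "N"):
                raise ValueError(
                    f"modified position {s.ref_name}:{s.pos} is {ref_base}, not A"
                )


@dataclass(frozen=True)
class LibraryCondition:
    """One of the four library chemistries.

    ``residual_factor`` scales every site's emission and truncation
    probabilities (1.0 for the NaBH4-reduced treated libraries, <1 for
    the converted controls); ``error_rate`` is the uniform per-base
    miscall floor.
    """

    name: str
    residual_factor: float = 1.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_factor <= 1.0:
            raise ValueError("residual_factor must lie in [0, 1]")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")


def standard_conditions(error_rate: float = 0.001,
                        residual_pntp: float = RESIDUAL_PNTP,
                        residual_tris: float = RESIDUAL_TRIS) -> dict:
    """The four libraries the caller expects, with default residuals."""
    return {
        "psii": LibraryCondition("NaBH4_PSII", 1.0, error_rate),
        "ssiv": LibraryCondition("NaBH4_SSIV", 1.0, error_rate),
        "pntp": LibraryCondition("pNTP_ctrl", residual_pntp, error_rate),
        "tris": LibraryCondition("Tris_ctrl", residual_tris, error_rate),
    }


@dataclass(frozen=True)
class LibraryLayout:
    """Read structure of the small-RNA libraries (PE63 by default)."""

    umi_len: int = 5
    barcode: str = DEFAULT_BARCODE
    adapter3: str = DEFAULT_ADAPTER3
    read_len: int = 63
    pcr_duplication: float = 1.5  # mean reads per molecule (geometric)

    def __post_init__(self) -> None:
        if len(self.barcode) != 6:
            raise ValueError("in-line barcode must be 6 nt")
        if self.umi_len != 5:
            raise ValueError("random ends are 5 nt in this protocol")
        if self.read_len <= 30:
            raise ValueError("read_len must exceed 30")
        if self.pcr_duplication < 1.0:
            raise ValueError("pcr_duplication is a mean >= 1")

    @property
    def r2_overhead(self) -> int:
        return 2 * self.umi_len + len(self.barcode)


# ---------------------------------------------------------------------------
# Spike-in references
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeIn:
    """A spike-in oligo: sequence (DNA space), its m1A index, N positions."""

    name: str
    seq: str
    site: int  # 0-based index of the modified A
    n_positions: tuple = ()


_FIXED43_RNA = "CCUACCUCCCUCACCAAAGCCCAUAAAAAUAAAAAAUUAUAAC"
_RANDOM45_RNA = "GUAAUUAUACNNANNAUUCGUUGUACGUGAUGCCUAAUGCCUGAA"


def fixed_spikein_reference() -> SpikeIn:
    """The 43-mer spike-in with a fixed m1A context (AAm1AGC).

    The modified A is the 18th nucleotide (0-based index 17).
    """
    seq = _FIXED43_RNA.replace("U", "T")
    assert len(seq) == 43 and seq[17] == "A"
    return SpikeIn("spikein_fixed43", seq, 17)


def random_spikein_template() -> SpikeIn:
    """The 45-mer NN-m1A-NN spike-in template with degenerate N positions."""
    seq = _RANDOM45_RNA.replace("U", "T")
    assert len(seq) == 45 and seq[12] == "A"
    return SpikeIn("spikein_random45", seq, 12, (10, 11, 13, 14))


def concrete_random_spikein(motif: str) -> SpikeIn:
    """Instantiate the 45-mer with a concrete 4-letter motif (NN + NN)."""
    if len(motif) != 4 or set(motif) - set(BASES):
        raise ValueError(f"motif must be 4 letters over ACGT, got {motif!r}")
    tpl = random_spikein_template()
    seq = list(tpl.seq)
    for base, pos in zip(motif, tpl.n_positions):
        seq[pos] = base
    return SpikeIn(f"{tpl.name}_{motif}", "".join(seq), tpl.site, tpl.n_positions)


def all_random_spikein_motifs() -> list[str]:
    """All 4^4 = 256 motifs of the randomized spike-in."""
    return [a + b + c + d for a in BASES for b in BASES for c in BASES for d in BASES]


# A synthetic 76-nt tRNA-like reference (CCA 3' end) used for the
# near-3'-end low-stoichiometry calling regime; the modified A sits at
# 1-based position 72, mirroring an acceptor-stem m1A.
TOY_TRNA_SEQ = "TAGACCCCCGACAAATACTAACGCTCAACATAGTCGTACGTGGTGTCGGCGCCTAATGTTCCCCTTAGCTAATCCA"
TOY_TRNA_SITE = 71  # 0-based


def toy_trna_reference() -> SpikeIn:
    """Synthetic tRNA-length reference with a single m1A anchor at 1-based 72."""
    assert len(TOY_TRNA_SEQ) == 76 and TOY_TRNA_SEQ[TOY_TRNA_SITE] == "A"
    return SpikeIn("toy_tRNA", TOY_TRNA_SEQ, TOY_TRNA_SITE)


def randomized_spikein_reference(seed: int) -> tuple[SpikeIn, str]:
    """Draw one concrete 45-mer: N positions i.i.d. uniform over ACGT."""
    rng = np.random.default_rng(seed)
    motif = "".join(rng.choice(list(BASES), size=4))
    return concrete_random_spikein(motif), motif


# ---------------------------------------------------------------------------
# RT product simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RTProduct:
    """One cDNA product in reference-sense orientation.

    ``start``/``end`` are the 0-based half-open reference coordinates the
    product covers (``start`` moves 3' of a site when RT truncates);
    ``emitted`` maps each covered modified position to the base the RT
    wrote there (before sequencer noise).
    """

    start: int
    end: int
    seq: str
    truncated_at: int | None = None
    emitted: tuple = ()  # tuple of (pos, base)


def _draw_fragment(rng, ref_len: int, frag_model) -> tuple[int, int]:
    if frag_model == "full":
        return 0, ref_len
    kind, lo, hi = frag_model
    if kind != "uniform":
        raise ValueError(f"unknown fragment model {frag_model!r}")
    lo = min(lo, ref_len)
    hi = min(hi, ref_len)
    length = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(0, ref_len - length + 1))
    return start, start + length


def simulate_rt_products(
    ref_seq: str,
    sites: list[SiteSignature],
    condition: LibraryCondition,
    n: int,
    frag_model="full",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[RTProduct]:
    """Simulate ``n`` cDNA products from one reference.

    Copying proceeds 3'->5' along the template.  At each modified
    position, with probability ``residual_factor * trunc_prob`` the
    product terminates just before the site (its last copied template
    base is the one 3' of the site); otherwise the emitted base is drawn
    from the residual-scaled emission probabilities, with the remaining
    mass emitting the reference A.  Every product base then miscalls
    uniformly at ``error_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    for s in sites:
        if not 0 <= s.pos < len(ref_seq):
            raise ValueError(f"site position {s.pos} outside reference")
    r = condition.residual_factor
    err = condition.error_rate
    site_order = sorted(sites, key=lambda s: -s.pos)  # 3' -> 5' encounter order
    products: list[RTProduct] = []
    for _ in range(n):
        fs, fe = _draw_fragment(rng, len(ref_seq), frag_model)
        cov_start = fs
        truncated_at: int | None = None
        emitted: list[tuple[int, str]] = []
        for s in site_order:
            if not fs <= s.pos < fe:
                continue  # site outside the fragment: simply not covered
            if r * s.trunc_prob > 0 and rng.random() < r * s.trunc_prob:
                cov_start = s.pos + 1
                truncated_at = s.pos
                emitted = [e for e in emitted if e[0] > s.pos]
                break
            u = rng.random()
            base = ref_seq[s.pos]
            acc = 0.0
            for alt in ("T", "G", "C"):
                acc += r * s.emit_probs.get(alt, 0.0)
                if u < acc:
                    base = alt
                    break
            emitted.append((s.pos, base))
        seq = list(ref_seq[cov_start:fe])
        for pos, base in emitted:
            seq[pos - cov_start] = base
        if err > 0 and seq:
            hits = np.flatnonzero(rng.random(len(seq)) < err)
            for i in hits:
                seq[i] = rng.choice([b for b in BASES if b != seq[i]])
        products.append(
            RTProduct(cov_start, fe, "".join(seq), truncated_at, tuple(emitted))
        )
    return products


# ---------------------------------------------------------------------------
# Library construction
# ---------------------------------------------------------------------------

def apply_conversion(
    profile: ModificationProfile, condition: LibraryCondition
) -> ModificationProfile:
    """Residual profile of a control library: every site scaled by
    ``residual_factor``."""
    r = condition.residual_factor
    sites = tuple(
        replace(
            s,
            emit_probs={k: v * r for k, v in s.emit_probs.items()},
            trunc_prob=s.trunc_prob * r,
        )
        for s in profile.sites
    )
    return ModificationProfile(sites)


def _random_umi(rng, k: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=k))


def simulate_library(
    refs: ReferenceSet,
    profile: ModificationProfile,
    condition: LibraryCondition,
    layout: LibraryLayout,
    n_molecules: int,
    seed: int,
    frag_model="full",
) -> tuple[list[ReadRecord], list[ReadRecord], pd.DataFrame]:
    """Simulate one paired-end library (``n_molecules`` per reference).

    R2 reads the insert in reference sense: [5-nt UMI][6-nt barcode]
    [product][5-nt UMI], 3' adapter appended, clipped to ``read_len``.
    R1 reads the opposite strand: [5-nt UMI][revcomp(product)][5-nt UMI],
    adapter appended, clipped likewise.  Each molecule is emitted
    ``k ~ 1 + extra`` times with geometric ``extra`` of mean
    ``pcr_duplication - 1``.  The truth table records, per molecule, the
    covered fragment coordinates, the emitted base at every modified
    site, and the number of PCR copies.
    """
    if layout.read_len <= layout.r2_overhead:
        raise ValueError("read_len does not exceed the UMI/barcode overhead")
    profile.validate_against(refs)
    rng = np.random.default_rng(seed)
    extra_mean = layout.pcr_duplication - 1.0
    r1_out: list[ReadRecord] = []
    r2_out: list[ReadRecord] = []
    truth_rows = []
    qual = "I"
    for ref_name, ref_seq in refs.items():
        sites = profile.for_ref(ref_name)
        products = simulate_rt_products(
            ref_seq, sites, condition, n_molecules, frag_model, rng=rng
        )
        for mi, prod in enumerate(products):
            umi1 = _random_umi(rng, layout.umi_len)
            umi2 = _random_umi(rng, layout.umi_len)
            r2 = (umi1 + layout.barcode + prod.seq + umi2 + layout.adapter3)[: layout.read_len]
            r1 = (revcomp(umi2) + revcomp(prod.seq) + revcomp(umi1) + layout.adapter3)[
                : layout.read_len
            ]
            if extra_mean > 0:
                k = int(rng.geometric(1.0 / (1.0 + extra_mean)))
            else:
                k = 1
            mol_id = f"{condition.name}:{ref_name}:mol{mi}"
            for j in range(k):
                r1_out.append(ReadRecord(f"{mol_id}:dup{j}", r1, qual * len(r1), "R1"))
                r2_out.append(ReadRecord(f"{mol_id}:dup{j}", r2, qual * len(r2), "R2"))
            truth_rows.append(
                {
                    "molecule": mol_id,
                    "ref": ref_name,
                    "cov_start": prod.start,
                    "cov_end": prod.end,
                    "truncated_at": -1 if prod.truncated_at is None else prod.truncated_at,
                    "emitted": ";".join(f"{p}:{b}" for p, b in prod.emitted),
                    "n_copies": k,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "molecule", "ref", "cov_start", "cov_end",
            "truncated_at", "emitted", "n_copies",
        ],
    )
    return r1_out, r2_out, truth


def truth_site_counts(truth: pd.DataFrame, ref_name: str, pos: int) -> dict:
    """Per-base molecule counts the truth table implies at one site."""
    counts: dict[str, int] = {}
    tag = f"{pos}:"
    for _, row in truth[truth["ref"] == ref_name].iterrows():
        if not row["emitted"]:
            continue
        for item in row["emitted"].split(";"):
            if item.startswith(tag):
                base = item.split(":")[1]
                counts[base] = counts.get(base, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Profile TSV (CLI surface)
# ---------------------------------------------------------------------------

def read_profile(path: str | Path) -> ModificationProfile:
    """Profile TSV columns: ref, pos_1based, p_T, p_G, p_C, trunc_prob."""
    df = pd.read_csv(path, sep="\t")
    sites = tuple(
        SiteSignature(
            row["ref"],
            int(row["pos_1based"]) - 1,
            {
                k: float(row[f"p_{k}"])
                for k in ("T", "G", "C")
                if float(row.get(f"p_{k}", 0.0)) > 0
            },
            float(row.get("trunc_prob", 0.0)),
        )
        for _, row in df.iterrows()
    )
    return ModificationProfile(sites)


def write_profile(profile: ModificationProfile, path: str | Path) -> None:
    rows = [
        {
            "ref": s.ref_name,
            "pos_1based": s.pos + 1,
            "p_T": s.emit_probs.get("T", 0.0),
            "p_G": s.emit_probs.get("G", 0.0),
            "p_C": s.emit_probs.get("C", 0.0),
            "trunc_prob": s.trunc_prob,
        }
        for s in profile.sites
    ]
    pd.DataFrame(
        rows, columns=["ref", "pos_1based", "p_T", "p_G", "p_C", "trunc_prob"]
    ).to_csv(path, sep="\t", index=False)
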