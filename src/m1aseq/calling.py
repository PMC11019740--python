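"""m1A site calling: the coverage/rate/significance/fold filter cascade.

A candidate site (any reference adenosine with coverage) passes when,
and only when, all of the following hold:

* coverage >= 50 in all four libraries (two NaBH4-reduced treated
  libraries made with different RTs, PSII and SSIV, plus the pNTP and
  Tris/Dimroth controls);
* mutation ratio >= 5% and mutant-read support >= 2 in BOTH treated
  libraries;
* two-sided Fisher's exact p < 0.05 for each treated library against
  the pooled controls (the reported p is the worse of the two);
* mutation ratio < 5% in BOTH control libraries;
* each treated ratio at least twofold the ratio of EACH control
  (a zero control ratio passes the fold rule; the fold column then
  carries an ``inf`` sentinel).

Every candidate is emitted with its per-filter flags, pass or fail, so
the cascade is auditable.  Requiring concordance between two different
reverse transcriptases is what suppresses enzyme-specific artifacts.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import pandas as pd

from m1aseq.align import ScoringScheme, assign_reads
from m1aseq.io_formats import (
    LIBRARIES,
    AlignmentRecord,
    ReadRecord,
    ReferenceSet,
    read_fasta,
    read_fastq,
    write_fasta,
    write_site_table,
)
from m1aseq.mutations import (
    MutationSummary,
    build_pileup,
    mutation_rate,
    site_test,
)
from m1aseq.preprocess import PreprocessConfig, preprocess_pipeline, sense_payloads
from m1aseq.simulate import (
    LibraryLayout,
    ModificationProfile,
    SiteSignature,
    SpikeIn,
    fixed_spikein_reference,
    simulate_library,
    standard_conditions,
)

logger = logging.getLogger(__name__)

TREATED = ("psii", "ssiv")
CONTROLS = ("pntp", "tris")


@dataclass(frozen=True)
class Thresholds:
    min_cov: int = 50
    min_treated_rate: float = 0.05
    max_control_rate: float = 0.05
    min_fold: float = 2.0
    alpha: float = 0.05
    min_alt_support: int = 2

    def __post_init__(self) -> None:
        if self.min_cov <= 0 or self.min_fold <= 0 or self.min_alt_support <= 0:
            raise ValueError("thresholds must be positive")
        for r in (self.min_treated_rate, self.max_control_rate, self.alpha):
            if not 0.0 < r < 1.0:
                raise ValueError("rates/alpha must lie in (0, 1)")


@dataclass
class SiteCall:
    """One candidate m1A site with rates across the four libraries."""

    ref_name: str
    pos_1based: int
    ref_base: str
    coverage: dict
    rate: dict
    pattern: dict
    p_value: float
    fold_vs_pntp: float
    fold_vs_tris: float
    flags: dict
    verdict: bool

    def __post_init__(self) -> None:
        if self.pos_1based < 1:
            raise ValueError("pos_1based must be >= 1")
        if self.verdict != all(self.flags.values()):
            raise ValueError("verdict must equal the conjunction of the flags")


# identical 2x2 tables recur constantly across candidate sites
_site_test_cached = lru_cache(maxsize=1 << 16)(site_test)


def _fold(treated_min: float, control: float) -> float:
    if control == 0.0:
        return math.inf
    return treated_min / control


def call_m1a_sites(pileups_by_library: dict, thresholds: Thresholds = Thresholds()
                   ) -> list[SiteCall]:
    """Run the filter cascade over every reference A position with coverage.

    ``pileups_by_library`` maps the keys psii/ssiv/pntp/tris to pileup
    dicts (as from :func:`m1aseq.mutations.build_pileup`) built on the
    same reference set.  Missing libraries or mismatched references are
    hard errors.
    """
    missing = [lib for lib in LIBRARIES if lib not in pileups_by_library]
    if missing:
        raise ValueError(f"missing libraries: {missing}")
    ref_names = sorted(pileups_by_library["psii"])
    for lib in LIBRARIES:
        if sorted(pileups_by_library[lib]) != ref_names:
            raise ValueError(f"library {lib!r} pileup covers different references")

    calls: list[SiteCall] = []
    zero = MutationSummary(0.0, {"T": 0.0, "G": 0.0, "C": 0.0}, 0, 0)
    for ref in ref_names:
        n_pos = len(pileups_by_library["psii"][ref])
        for pos in range(n_pos):
            cols = {lib: pileups_by_library[lib][ref][pos] for lib in LIBRARIES}
            ref_base = cols["psii"].ref_base
            if ref_base != "A":
                continue
            if all(c.coverage == 0 for c in cols.values()):
                continue
            summ = {
                lib: (mutation_rate(c) if c.coverage > 0 else zero)
                for lib, c in cols.items()
            }
            cov = {lib: c.coverage for lib, c in cols.items()}
            rate = {lib: summ[lib].rate for lib in LIBRARIES}
            ctrl_mut = sum(summ[lib].alt_support for lib in CONTROLS)
            ctrl_cov = sum(cov[lib] for lib in CONTROLS)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # degenerate margins handled by flags
                p_value = max(
                    _site_test_cached(summ[t].alt_support, cov[t], ctrl_mut, ctrl_cov)
                    for t in TREATED
                )
            flags = {
                "ref_a": True,
                "coverage": all(cov[lib] >= thresholds.min_cov for lib in LIBRARIES),
                "treated_rate": all(
                    rate[t] >= thresholds.min_treated_rate for t in TREATED
                ),
                "alt_support": all(
                    summ[t].alt_support >= thresholds.min_alt_support for t in TREATED
                ),
                "p_value": p_value < thresholds.alpha,
                "control_rate": all(
                    rate[c] < thresholds.max_control_rate for c in CONTROLS
                ),
                "fold": all(
                    rate[c] == 0.0 or rate[t] >= thresholds.min_fold * rate[c]
                    for t in TREATED
                    for c in CONTROLS
                ),
            }
            treated_min = min(rate[t] for t in TREATED)
            calls.append(
                SiteCall(
                    ref_name=ref,
                    pos_1based=pos + 1,
                    ref_base=ref_base,
                    coverage=cov,
                    rate=rate,
                    pattern={lib: dict(summ[lib].pattern) for lib in LIBRARIES},
                    p_value=p_value,
                    fold_vs_pntp=_fold(treated_min, rate["pntp"]),
                    fold_vs_tris=_fold(treated_min, rate["tris"]),
                    flags=flags,
                    verdict=all(flags.values()),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Spike-in analyses
# ---------------------------------------------------------------------------

def spikein_fixed_rate(pileup, spikein: SpikeIn) -> MutationSummary | None:
    """Mutation summary at the recorded m1A position of a spike-in.

    ``pileup`` is either a pileup dict or the column list of the
    spike-in reference.  Zero coverage returns None with a warning.
    """
    cols = pileup[spikein.name] if isinstance(pileup, dict) else pileup
    col = cols[spikein.site]
    if col.coverage == 0:
        warnings.warn(f"no coverage at spike-in site {spikein.name}:{spikein.site}")
        return None
    return mutation_rate(col)


@dataclass(frozen=True)
class MotifRate:
    coverage: int
    mut_count: int
    rate: float
    low_confidence: bool


def _bases_at(aln: AlignmentRecord, positions: list[int]) -> list[str | None]:
    """Read base at each requested reference position (None if not an =/X/M op)."""
    want = {p: None for p in positions}
    i, j = 0, aln.ref_start
    for op, n in aln.cigar:
        if op in ("M", "=", "X"):
            for p in positions:
                if j <= p < j + n:
                    want[p] = aln.seq[i + (p - j)]
            i += n
            j += n
        elif op == "D":
            j += n
        elif op in ("I", "S"):
            i += n
    return [want[p] for p in positions]


def motif_rates(
    alignments: list[AlignmentRecord],
    spikein: SpikeIn | None = None,
    site_pos: int | None = None,
    min_motif_cov: int = 20,
) -> dict[str, MotifRate]:
    """Per-motif mutation rates at the randomized spike-in m1A site.

    Each unique read's motif is the four bases it shows at the N
    positions of the NN-m1A-NN reference; reads not covering all four N
    positions and the site are skipped.  Motifs with coverage below
    ``min_motif_cov`` are flagged low-confidence.
    """
    from m1aseq.simulate import random_spikein_template

    if spikein is None:
        spikein = random_spikein_template()
    site = spikein.site if site_pos is None else site_pos
    positions = list(spikein.n_positions) + [site]
    acc: dict[str, list[int]] = {}
    for aln in alignments:
        if aln.status != "unique":
            continue
        bases = _bases_at(aln, positions)
        if any(b is None or b == "N" for b in bases):
            continue
        motif = "".join(bases[:-1])
        site_base = bases[-1]
        cov_mut = acc.setdefault(motif, [0, 0])
        cov_mut[0] += aln.weight
        if site_base != "A":
            cov_mut[1] += aln.weight
    return {
        motif: MotifRate(cov, mut, mut / cov, cov < min_motif_cov)
        for motif, (cov, mut) in sorted(acc.items())
    }


def motif_matrix_to_frame(matrix: dict) -> pd.DataFrame:
    rows = [
        {
            "motif": motif,
            "coverage": mr.coverage,
            "mut_count": mr.mut_count,
            "rate_percent": round(100.0 * mr.rate, 2),
            "low_confidence": int(mr.low_confidence),
        }
        for motif, mr in sorted(matrix.items())
    ]
    return pd.DataFrame(
        rows, columns=["motif", "coverage", "mut_count", "rate_percent", "low_confidence"]
    )


def fold_reduction(level_before: float, level_after: float) -> float:
    """Fold reduction of a modification level (e.g. an m1A/A ratio) after
    a conversion treatment: before / after.

    A zero post-treatment level yields the ``inf`` sentinel (complete
    conversion at the measurement's resolution).
    """
    if level_before <= 0 or level_after < 0:
        raise ValueError("levels must be positive (after may be zero)")
    if level_after == 0:
        return math.inf
    return level_before / level_after


# ---------------------------------------------------------------------------
# End-to-end orchestration
# ---------------------------------------------------------------------------

def _library_pileup(
    r1: list[ReadRecord],
    r2: list[ReadRecord] | None,
    refs: ReferenceSet,
    pre_config: PreprocessConfig,
    scoring: ScoringScheme,
) -> tuple[dict, dict, list[AlignmentRecord]]:
    """preprocess -> orient -> align -> pileup for one library."""
    items = list(zip(r1, r2)) if r2 is not None else list(r1)
    processed, stats = preprocess_pipeline(items, pre_config)
    payloads = sense_payloads(processed)
    alignments = assign_reads(payloads, refs, scoring)
    stats["aligned_unique"] = sum(1 for a in alignments if a.status == "unique")
    stats["ambiguous"] = sum(1 for a in alignments if a.status == "ambiguous")
    stats["unmapped"] = sum(1 for a in alignments if a.status == "unmapped")
    return build_pileup(alignments, refs), stats, alignments


def run_pipeline(config: dict) -> dict:
    """Execute the full pipeline from a config mapping.

    Two input modes:

    * ``simulate``: a block with n_molecules, seed, error_rate, profile
      (list of site dicts: ref, pos_1based, p_T/p_G/p_C, trunc_prob),
      optional residual_pntp/residual_tris, layout overrides and
      frag_model; all four libraries are generated.
    * ``libraries``: per-library FASTQ paths
      ``{psii: {"r1": ..., "r2": ...}, ...}``.

    References come from ``refs_fasta`` and/or ``include_fixed_spikein``.
    Returns a dict with calls, pileups, per-stage stats and (when a
    spike-in is present) the spike-in mutation summaries; writes the
    site table and run log under ``out_dir`` when given.
    """
    refs = ReferenceSet()
    spike = None
    if config.get("refs_fasta"):
        for name, seq in read_fasta(config["refs_fasta"]).items():
            refs.add(name, seq)
    if config.get("include_fixed_spikein"):
        spike = fixed_spikein_reference()
        refs.add(spike.name, spike.seq)
    if len(refs) == 0:
        raise ValueError("pipeline config names no references")

    pre_config = PreprocessConfig(**config.get("preprocess", {}))
    scoring = ScoringScheme(**config.get("scoring", {}))
    thresholds = Thresholds(**config.get("thresholds", {}))

    pileups: dict = {}
    stats: dict = {}
    alignments: dict = {}
    if "simulate" in config:
        sim = config["simulate"]
        layout = LibraryLayout(**sim.get("layout", {}))
        profile = ModificationProfile(
            tuple(
                SiteSignature(
                    s["ref"],
                    int(s["pos_1based"]) - 1,
                    {k: s[f"p_{k}"] for k in ("T", "G", "C") if s.get(f"p_{k}", 0.0) > 0},
                    s.get("trunc_prob", 0.0),
                )
                for s in sim.get("profile", [])
            )
        )
        conditions = standard_conditions(
            error_rate=sim.get("error_rate", 0.001),
            **{
                k: sim[k]
                for k in ("residual_pntp", "residual_tris")
                if k in sim
            },
        )
        base_seed = int(sim["seed"])
        for k, lib in enumerate(LIBRARIES):
            r1, r2, _truth = simulate_library(
                refs,
                profile,
                conditions[lib],
                layout,
                int(sim["n_molecules"]),
                seed=base_seed + 1000 * (k + 1),
                frag_model=sim.get("frag_model", "full"),
            )
            pileups[lib], stats[lib], alignments[lib] = _library_pileup(
                r1, r2, refs, pre_config, scoring
            )
    elif "libraries" in config:
        for lib in LIBRARIES:
            if lib not in config["libraries"]:
                raise ValueError(f"missing library {lib!r} in config")
            paths = config["libraries"][lib]
            r1 = read_fastq(paths["r1"], role="R1")
            r2 = read_fastq(paths["r2"], role="R2") if paths.get("r2") else None
            pileups[lib], stats[lib], alignments[lib] = _library_pileup(
                r1, r2, refs, pre_config, scoring
            )
    else:
        raise ValueError("config must contain a 'simulate' or 'libraries' block")

    calls = call_m1a_sites(pileups, thresholds)

    spikein_report = None
    spike_cfg = config.get("spikein_site")
    if spike_cfg:
        spike = SpikeIn(
            spike_cfg["ref"], refs[spike_cfg["ref"]], int(spike_cfg["pos_1based"]) - 1
        )
    if spike is not None:
        spikein_report = {
            lib: spikein_fixed_rate(pileups[lib], spike) for lib in LIBRARIES
        }

    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_site_table(calls, out / "sites.tsv")
        write_fasta(refs, out / "references.fa")
        with open(out / "run_log.txt", "w") as fh:
            fh.write(f"thresholds: {thresholds}\n")
            fh.write(f"scoring: {scoring}\n")
            for lib in LIBRARIES:
                fh.write(f"{lib}: {stats[lib]}\n")
            if spikein_report is not None:
                for lib, summ in spikein_report.items():
                    if summ is not None:
                        fh.write(
                            f"spikein {lib}: rate={100 * summ.rate:.2f}% "
                            f"cov={summ.coverage}\n"
                        )
    return {
        "calls": calls,
        "pileups": pileups,
        "alignments": alignments,
        "stats": stats,
        "spikein_report": spikein_report,
        "thresholds": thresholds,
        "references": refs,
    }
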