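"""The filter cascade, spike-in analyses and end-to-end orchestration."""

from __future__ import annotations

import math

import numpy as np
import pytest

from m1aseq.calling import (
    SiteCall,
    Thresholds,
    call_m1a_sites,
    fold_reduction,
    motif_rates,
    run_pipeline,
    spikein_fixed_rate,
)
from m1aseq.io_formats import LIBRARIES, AlignmentRecord, ReferenceSet, write_fasta
from m1aseq.mutations import PileupColumn, build_pileup
from m1aseq.simulate import (
    LibraryCondition,
    SiteSignature,
    concrete_random_spikein,
    all_random_spikein_motifs,
    fixed_spikein_reference,
    random_spikein_template,
    simulate_rt_products,
    standard_conditions,
    toy_trna_reference,
)

REF = "site"


def _columns(cov, mut, n_pos=1, pos=0):
    cols = []
    for p in range(n_pos):
        c = PileupColumn(REF, p, "A")
        m = mut if p == pos else 0
        c.counts = {"A": cov - m, "T": m, "G": 0, "C": 0}
        cols.append(c)
    return cols


def _pileups(counts_by_lib):
    """counts_by_lib: {lib: (coverage, mutant_count)} at a single A site."""
    return {lib: {REF: _columns(cov, mut)} for lib, (cov, mut) in counts_by_lib.items()}


class TestCascade:
    def test_low_stoichiometry_site_passes(self):
        # the near-3'-end tRNA regime: 9% treated, 1%/0% controls, cov 200
        pile = _pileups({
            "psii": (200, 18), "ssiv": (200, 18), "pntp": (200, 2), "tris": (200, 0),
        })
        (call,) = call_m1a_sites(pile)
        assert call.verdict
        assert call.rate["psii"] == pytest.approx(0.09)
        assert call.fold_vs_tris == math.inf
        assert call.p_value < 0.05

    def test_coverage_boundary_49_fails(self):
        pile = _pileups({
            "psii": (200, 18), "ssiv": (200, 18), "pntp": (49, 0), "tris": (200, 0),
        })
        (call,) = call_m1a_sites(pile)
        assert not call.flags["coverage"] and not call.verdict

    def test_coverage_boundary_50_passes(self):
        pile = _pileups({
            "psii": (200, 18), "ssiv": (200, 18), "pntp": (50, 0), "tris": (200, 0),
        })
        (call,) = call_m1a_sites(pile)
        assert call.flags["coverage"] and call.verdict

    def test_fold_below_two_fails(self):
        # 8% treated vs 4.5% control: 1.78-fold, below the twofold rule
        pile = _pileups({
            "psii": (200, 16), "ssiv": (200, 16), "pntp": (200, 9), "tris": (200, 2),
        })
        (call,) = call_m1a_sites(pile)
        assert not call.flags["fold"]
        assert call.flags["control_rate"]  # 4.5% is still under 5%
        assert not call.verdict

    def test_min_alt_support(self):
        pile = _pileups({
            "psii": (200, 1), "ssiv": (200, 18), "pntp": (200, 0), "tris": (200, 0),
        })
        (call,) = call_m1a_sites(pile)
        assert not call.flags["alt_support"]

    def test_missing_library_hard_error(self):
        pile = _pileups({"psii": (200, 18), "ssiv": (200, 18), "pntp": (200, 0),
                         "tris": (200, 0)})
        del pile["tris"]
        with pytest.raises(ValueError, match="missing"):
            call_m1a_sites(pile)

    def test_mismatched_references_hard_error(self):
        pile = _pileups({"psii": (200, 18), "ssiv": (200, 18), "pntp": (200, 0),
                         "tris": (200, 0)})
        pile["tris"] = {"other": _columns(200, 0)}
        with pytest.raises(ValueError, match="different references"):
            call_m1a_sites(pile)

    def test_verdict_is_conjunction_of_flags(self):
        pile = _pileups({
            "psii": (200, 18), "ssiv": (200, 18), "pntp": (200, 2), "tris": (200, 0),
        })
        for call in call_m1a_sites(pile):
            assert call.verdict == all(call.flags.values())
        with pytest.raises(ValueError, match="conjunction"):
            SiteCall("r", 1, "A", {}, {}, {}, 1.0, 1.0, 1.0,
                     {"coverage": False}, True)

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(51)
        pile = {lib: {REF: []} for lib in LIBRARIES}
        for p in range(40):
            for lib in LIBRARIES:
                cov = int(rng.integers(30, 400))
                frac = 0.12 if lib in ("psii", "ssiv") else 0.02
                mut = rng.binomial(cov, frac)
                c = PileupColumn(REF, p, "A")
                c.counts = {"A": cov - mut, "T": int(mut), "G": 0, "C": 0}
                pile[lib][REF].append(c)
        base = Thresholds()
        n_base = sum(c.verdict for c in call_m1a_sites(pile, base))
        tighter = [
            Thresholds(min_cov=100),
            Thresholds(min_treated_rate=0.10),
            Thresholds(max_control_rate=0.01),
            Thresholds(min_fold=5.0),
            Thresholds(alpha=0.001),
            Thresholds(min_alt_support=10),
        ]
        for t in tighter:
            assert sum(c.verdict for c in call_m1a_sites(pile, t)) <= n_base

    def test_null_specificity_zero_passing(self):
        """No modified sites, 0.1% error floor, cov 500, 2000 A positions,
        20 seeds: the cascade must emit zero passing sites."""
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            pile = {}
            for lib in LIBRARIES:
                muts = rng.binomial(500, 0.001, size=2000)
                cols = []
                for p, mut in enumerate(muts):
                    c = PileupColumn(REF, p, "A")
                    c.counts = {"A": 500 - int(mut), "T": int(mut), "G": 0, "C": 0}
                    cols.append(c)
                pile[lib] = {REF: cols}
            total += sum(c.verdict for c in call_m1a_sites(pile))
        assert total == 0

    def test_boundary_sensitivity(self):
        """The 9%/1%/0% regime at coverage 200 passes in >= 95/100 draws."""
        passed = 0
        for seed in range(100):
            rng = np.random.default_rng(2000 + seed)
            pile = _pileups({
                "psii": (200, int(rng.binomial(200, 0.09))),
                "ssiv": (200, int(rng.binomial(200, 0.09))),
                "pntp": (200, int(rng.binomial(200, 0.01))),
                "tris": (200, 0),
            })
            (call,) = call_m1a_sites(pile)
            passed += call.verdict
        assert passed >= 95

    def test_identical_treated_and_control_never_pass(self):
        cols = {REF: _columns(300, 45)}  # 15% everywhere
        pile = {lib: cols for lib in LIBRARIES}
        calls = call_m1a_sites(pile)
        assert sum(c.verdict for c in calls) == 0


def _products_to_alignments(spikein, prods):
    return [
        AlignmentRecord(f"p{i}", spikein.name, p.start, [("=", len(p.seq))],
                        "+", len(p.seq), "unique", seq=p.seq)
        for i, p in enumerate(prods)
    ]


class TestSpikeinAnalyses:
    def test_null_profile_background_below_one_percent(self):
        sp = fixed_spikein_reference()
        cond = LibraryCondition("x", 1.0, 0.001)
        prods = simulate_rt_products(sp.seq, [], cond, 4000, seed=61)
        refs = ReferenceSet([(sp.name, sp.seq)])
        pile = build_pileup(_products_to_alignments(sp, prods), refs)
        summ = spikein_fixed_rate(pile, sp)
        assert summ.rate < 0.01

    def test_tris_control_near_seven_percent(self):
        sp = fixed_spikein_reference()
        sites = [SiteSignature(sp.name, sp.site, {"T": 0.577, "G": 0.068}, 0.0)]
        cond = standard_conditions(error_rate=0.001)["tris"]
        prods = simulate_rt_products(sp.seq, sites, cond, 6000, seed=62)
        refs = ReferenceSet([(sp.name, sp.seq)])
        pile = build_pileup(_products_to_alignments(sp, prods), refs)
        summ = spikein_fixed_rate(pile, sp)
        assert summ.rate == pytest.approx(0.07, abs=0.012)

    def test_zero_coverage_flagged(self):
        sp = fixed_spikein_reference()
        refs = ReferenceSet([(sp.name, sp.seq)])
        pile = build_pileup([], refs)
        with pytest.warns(UserWarning):
            assert spikein_fixed_rate(pile, sp) is None

    def test_single_motif_populates_one_key(self):
        tpl = random_spikein_template()
        concrete = concrete_random_spikein("ACGT")
        cond = LibraryCondition("x", 1.0, 0.0)
        prods = simulate_rt_products(concrete.seq, [], cond, 50, seed=63)
        alns = _products_to_alignments(tpl, prods)
        matrix = motif_rates(alns, tpl)
        assert list(matrix) == ["ACGT"]
        assert matrix["ACGT"].coverage == 50
        assert matrix["ACGT"].rate == 0.0

    def test_uniform_emission_gives_consistent_motif_rates(self):
        tpl = random_spikein_template()
        cond = LibraryCondition("x", 1.0, 0.0)
        alns = []
        k = 60
        for i, motif in enumerate(all_random_spikein_motifs()):
            concrete = concrete_random_spikein(motif)
            sites = [SiteSignature(concrete.name, concrete.site, {"T": 0.5}, 0.0)]
            prods = simulate_rt_products(concrete.seq, sites, cond, k, seed=7000 + i)
            alns.extend(_products_to_alignments(tpl, prods))
        matrix = motif_rates(alns, tpl)
        assert len(matrix) == 256
        se = math.sqrt(0.5 * 0.5 / k)
        for mr in matrix.values():
            assert mr.coverage == k
            assert abs(mr.rate - 0.5) < 4 * se


class TestFoldReduction:
    def test_printed_worked_examples(self):
        assert fold_reduction(0.055, 0.0023) == pytest.approx(23.91, abs=0.01)
        assert fold_reduction(0.03, 0.0029) == pytest.approx(10.34, abs=0.01)

    def test_identity(self):
        assert fold_reduction(0.5, 0.5) == 1.0

    def test_complete_conversion_sentinel(self):
        assert fold_reduction(0.1, 0.0) == math.inf

    def test_invalid_levels(self):
        with pytest.raises(ValueError):
            fold_reduction(0.0, 0.1)


@pytest.fixture(scope="module")
def toy_config(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("pipe")
    trna = toy_trna_reference()
    refs = ReferenceSet([(trna.name, trna.seq)])
    write_fasta(refs, tmp / "refs.fa")
    return {
        "refs_fasta": str(tmp / "refs.fa"),
        "simulate": {
            "n_molecules": 600,
            "seed": 21,
            "error_rate": 0.001,
            "profile": [
                {"ref": trna.name, "pos_1based": 72, "p_T": 0.13, "p_G": 0.02}
            ],
        },
        "out_dir": str(tmp / "out"),
    }


@pytest.fixture(scope="module")
def toy_result(toy_config):
    return run_pipeline(toy_config)


class TestRunPipeline:
    def test_single_true_site_passes_alone(self, toy_result):
        passing = [c for c in toy_result["calls"] if c.verdict]
        assert [(c.ref_name, c.pos_1based) for c in passing] == [("toy_tRNA", 72)]
        (call,) = passing
        assert call.rate["psii"] == pytest.approx(0.15, abs=0.05)

    def test_site_table_written(self, toy_config, toy_result):
        from pathlib import Path

        out = Path(toy_config["out_dir"])
        assert (out / "sites.tsv").exists()
        assert (out / "run_log.txt").exists()

    def test_absurd_coverage_threshold_blocks_everything(self, toy_config):
        config = dict(toy_config, thresholds={"min_cov": 10 ** 9}, out_dir=None)
        result = run_pipeline(config)
        assert sum(c.verdict for c in result["calls"]) == 0

    def test_config_without_inputs_rejected(self):
        with pytest.raises(ValueError):
            run_pipeline({"include_fixed_spikein": True})
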