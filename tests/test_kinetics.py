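"""Renaturation kinetics, DSN digestion and parameter recovery."""

import numpy as np
import pytest

from dsnnorm.kinetics import (KineticsParams, NormalizationCollapseError,
                              apply_dsn, duplex_fraction,
                              expected_depletion_table, fit_kinetics)
from dsnnorm.synth import Fragment, FragmentPool, Read, ReadLibrary


def _flat_params(kct_unit: float, t: float = 1.0) -> KineticsParams:
    """GC-independent params with k0 chosen so k*c*t = kct_unit at c=1."""
    return KineticsParams(t=t, mode="NaCl", k0=kct_unit / t, alpha_gc=0.0)


def _pool(specs):
    """specs: list of (n_fragments, conc, gc)."""
    frags = []
    total = sum(n for n, _, _ in specs)
    for ci, (n, conc, gc) in enumerate(specs):
        seq = "ACGT" * 25
        frags += [Fragment(seq, gc, f"class{ci}", 1.0 / total, conc)
                  for _ in range(n)]
    return FragmentPool(frags, 100)


def _library(pool, n_per_class):
    reads = []
    for i, f in enumerate(pool.fragments):
        reads.append(Read(f"r{i}", f.seq, "F" * len(f.seq), frag=i))
    return ReadLibrary(reads)


class TestDuplexFraction:
    def test_no_renaturation_at_cot_zero(self):
        assert duplex_fraction(0.0, 0.5, _flat_params(1.0)) == 0.0
        assert duplex_fraction(1.0, 0.5, KineticsParams(t=0.0)) == 0.0

    def test_half_renatured_at_unit_cot(self):
        assert duplex_fraction(1.0, 0.5, _flat_params(1.0)) == pytest.approx(0.5)

    def test_three_quarters_at_cot_three(self):
        assert duplex_fraction(1.0, 0.5, _flat_params(3.0)) == pytest.approx(0.75)

    def test_monotone_in_concentration_time_and_gc(self):
        p = KineticsParams(t=10.0, mode="NaCl")
        c = np.linspace(0, 1, 50)
        f = duplex_fraction(c, 0.4, p)
        assert np.all(np.diff(f) >= 0)
        gc = np.linspace(0, 1, 50)
        fg = duplex_fraction(0.1, gc, p)
        assert np.all(np.diff(fg) >= 0)  # alpha_gc > 0 in NaCl
        f1 = duplex_fraction(0.1, 0.4, KineticsParams(t=5.0))
        f2 = duplex_fraction(0.1, 0.4, KineticsParams(t=50.0))
        assert f2 > f1

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            duplex_fraction(-0.1, 0.5, _flat_params(1.0))
        with pytest.raises(ValueError):
            KineticsParams(t=-1.0)


class TestApplyDsn:
    def test_zero_time_resamples_unchanged_composition(self):
        pool = _pool([(500, 0.9, 0.4), (500, 0.001, 0.4)])
        lib = _library(pool, None)
        params = KineticsParams(t=0.0, mode="NaCl", target_depth=4000)
        out = apply_dsn(lib, pool, params, seed=1)
        assert len(out) == 4000
        share = np.mean([pool.fragments[r.frag].origin == "class0"
                         for r in out.reads])
        sigma = (0.5 * 0.5 / 4000) ** 0.5
        assert abs(share - 0.5) < 3 * sigma
        assert out.treatment == "dsn" and out.salt == "NaCl"

    def test_high_copy_class_survives_ten_percent(self):
        # repeat at k*c*t = 9 -> survival 0.1; single copy k*c*t = 0.009
        c_rep, c_one = 1000 / 1001, 1 / 1001
        kct = 9.0 / c_rep
        pool = _pool([(5000, c_rep, 0.5), (5000, c_one, 0.5)])
        lib = _library(pool, None)
        params = _flat_params(kct)
        params.target_depth = 10_000
        out = apply_dsn(lib, pool, params, seed=2)
        surv_rep = 1 / (1 + 9.0)
        surv_one = 1 / (1 + kct * c_one)
        exp_share = surv_rep / (surv_rep + surv_one)
        share = np.mean([pool.fragments[r.frag].origin == "class0"
                         for r in out.reads])
        sigma = (exp_share * (1 - exp_share) / len(out)) ** 0.5
        assert abs(share - exp_share) < 4 * sigma

    def test_gc_bias_in_nacl_but_not_tmac(self):
        # equal concentration classes at 30% vs 60% GC
        pool = _pool([(4000, 0.05, 0.30), (4000, 0.05, 0.60)])
        lib = _library(pool, None)
        out_n = apply_dsn(lib, pool,
                          KineticsParams(t=22.0, mode="NaCl",
                                         target_depth=8000), seed=3)
        out_t = apply_dsn(lib, pool,
                          KineticsParams(t=22.0, mode="TMAC",
                                         target_depth=8000), seed=4)

        def share_high_gc(out):
            return np.mean([pool.fragments[r.frag].origin == "class1"
                            for r in out.reads])

        assert share_high_gc(out_n) < 0.4  # high-GC depleted in NaCl
        assert abs(share_high_gc(out_t) - 0.5) < 0.02  # TMAC equalized

    def test_collapse_when_everything_is_digested(self):
        pool = _pool([(100, 1.0, 0.5)])
        lib = _library(pool, None)
        with pytest.raises(NormalizationCollapseError):
            apply_dsn(lib, pool, _flat_params(1e9), seed=5)

    def test_output_depth_is_exact(self):
        pool = _pool([(1000, 0.01, 0.4)])
        lib = _library(pool, None)
        out = apply_dsn(lib, pool, _flat_params(0.5, t=2.0), seed=6)
        assert len(out) == len(lib)


class TestExpectedDepletion:
    def test_identical_classes_all_ratio_one(self):
        tab = expected_depletion_table([(10, 0.4)] * 5,
                                       KineticsParams(t=22.0))
        assert np.allclose(tab["ratio"], 1.0)

    def test_high_copy_ratio_grows_then_saturates(self):
        classes = [(1000, 0.4), (1, 0.4)]
        ratios = [expected_depletion_table(
            classes, KineticsParams(t=t))["ratio"].iloc[0]
            for t in (22.0, 46.0, 70.0, 94.0)]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))
        increments = np.diff(ratios)
        assert increments[-1] < increments[0]  # saturation

    def test_low_copy_class_apparently_enriched(self):
        tab = expected_depletion_table([(1000, 0.4), (1, 0.4)],
                                       KineticsParams(t=22.0))
        assert tab["ratio"].iloc[1] < 1.0

    def test_depletion_nondecreasing_in_copy_number(self):
        copies = [1, 5, 20, 100, 500, 2000]
        for mode in ("NaCl", "TMAC"):
            tab = expected_depletion_table([(c, 0.42) for c in copies],
                                           KineticsParams(t=22.0, mode=mode))
            assert np.all(np.diff(tab["ratio"]) >= 0)

    def test_empty_class_list_rejected(self):
        with pytest.raises(ValueError):
            expected_depletion_table([], KineticsParams(t=1.0))


class TestParameterRecovery:
    def test_alpha_and_k0t_recovered_within_ten_percent(self, rng):
        classes = [(c, gc) for c in (1, 10, 50, 200, 1000)
                   for gc in (0.3, 0.4, 0.5, 0.6)]
        true_k0t, true_alpha = 110.0, 8.0
        p = KineticsParams(t=1.0, mode="NaCl", k0=true_k0t,
                           alpha_gc=true_alpha)
        tab = expected_depletion_table(classes, p)
        n = 100_000  # reads per library
        ctrl = rng.multinomial(n, tab["control_share"])
        trt = rng.multinomial(n, tab["treated_share"])
        obs_ratio = (ctrl / n) / np.maximum(trt / n, 1e-9)
        fit = fit_kinetics(classes, obs_ratio, counts=(ctrl, trt))
        assert abs(fit.k0t - true_k0t) / true_k0t < 0.10
        assert abs(fit.alpha_gc - true_alpha) / true_alpha < 0.10
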