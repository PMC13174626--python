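import math

import numpy as np
import pytest

from funcbench.benchmarks import BenchmarkSet
from funcbench.metrics import (coverage, fmax, smin, summarize, sweep,
                               write_curve)
from funcbench.ontology import TermInformation
from funcbench.predictions import PredictionSet

from _oracles import make_bench_pred


def _at(curve, tau):
    idx = int(np.argmin(np.abs(curve.thresholds - tau)))
    assert math.isclose(curve.thresholds[idx], tau)
    return idx


IA1 = TermInformation(ia={"A": 1.0, "B": 1.0, "C": 1.0}, reference_size=0)


class TestSweepWorkedExamples:
    def test_single_protein_flat_truth(self):
        # truth {A, C}; scored A:0.8, C:0.5 and a false positive B:0.3
        bench, pred = make_bench_pred(
            prior={"P1": set()}, gained={"P1": {"A", "C"}},
            scores={"P1": {"A": 0.8, "C": 0.5, "B": 0.3}})
        curve = sweep(pred, bench, IA1)
        i = _at(curve, 0.3)
        assert curve.pr_macro[i] == pytest.approx(2 / 3) and curve.rc_macro[i] == 1.0
        i = _at(curve, 0.5)
        assert curve.pr_macro[i] == 1.0 and curve.rc_macro[i] == 1.0
        i = _at(curve, 0.8)
        assert curve.pr_macro[i] == 1.0 and curve.rc_macro[i] == 0.5
        assert fmax(curve, "macro") == (1.0, 0.5)

    def test_partial_knowledge_prior_subtraction(self):
        # prior {A}, full truth {A, C}: predicting A again is neither rewarded
        # nor punished; at tau=0.7 the effective set is {C}
        bench, pred = make_bench_pred(
            prior={"P1": {"A"}}, gained={"P1": {"C"}},
            scores={"P1": {"A": 0.9, "C": 0.7}})
        curve = sweep(pred, bench, IA1)
        i = _at(curve, 0.7)
        assert curve.pr_macro[i] == 1.0 and curve.rc_macro[i] == 1.0
        assert curve.m[i] == 1
        i = _at(curve, 0.9)  # only the prior term remains -> empty effective set
        assert curve.m[i] == 0 and curve.rc_macro[i] == 0.0

    def test_empty_predictor(self):
        bench, _ = make_bench_pred(
            prior={"P1": set(), "P2": set()},
            gained={"P1": {"A"}, "P2": {"B", "C"}}, scores={})
        pred = PredictionSet("empty", {}, propagated=True)
        curve = sweep(pred, bench, IA1)
        assert list(curve.m) == [0]
        assert curve.rc_macro[0] == curve.rc_micro[0] == 0.0
        assert curve.mi[0] == 0.0
        # ru is the mean total information of the gained truth: (1 + 2) / 2
        assert curve.ru[0] == 1.5

    def test_misinformation_counts_only_terms_outside_full_truth(self):
        bench, pred = make_bench_pred(
            prior={"P1": {"A"}}, gained={"P1": {"C"}},
            scores={"P1": {"A": 0.9, "B": 0.9}})
        curve = sweep(pred, bench, IA1)
        i = _at(curve, 0.9)
        assert curve.mi[i] == 1.0  # B only; re-predicting the prior A is free
        assert curve.ru[i] == 1.0  # C missed


class TestFmaxSmin:
    def test_perfect_predictor_is_exactly_one(self):
        bench, pred = make_bench_pred(
            prior={"P1": set(), "P2": set()},
            gained={"P1": {"A"}, "P2": {"B", "C"}},
            scores={"P1": {"A": 1.0}, "P2": {"B": 1.0, "C": 1.0}})
        curve = sweep(pred, bench, IA1)
        assert fmax(curve, "macro")[0] == 1.0
        assert fmax(curve, "micro")[0] == 1.0
        assert smin(curve)[0] == 0.0

    def test_all_wrong_predictor_is_zero(self):
        bench, pred = make_bench_pred(
            prior={"P1": set()}, gained={"P1": {"A"}},
            scores={"P1": {"B": 0.9, "C": 0.2}})
        curve = sweep(pred, bench, IA1)
        assert fmax(curve, "macro")[0] == 0.0
        assert fmax(curve, "micro")[0] == 0.0

    def test_macro_equals_micro_for_single_protein(self):
        bench, pred = make_bench_pred(
            prior={"P1": set()}, gained={"P1": {"A", "B"}},
            scores={"P1": {"A": 0.8, "C": 0.6, "B": 0.4}})
        curve = sweep(pred, bench, IA1)
        assert np.allclose(curve.pr_macro, curve.pr_micro)
        assert np.allclose(curve.rc_macro, curve.rc_micro)
        assert fmax(curve, "macro")[0] == fmax(curve, "micro")[0]

    def test_smin_of_empty_predictor_single_protein(self):
        bench, _ = make_bench_pred(prior={"P1": set()}, gained={"P1": {"C"}},
                                   scores={})
        pred = PredictionSet("empty", {}, propagated=True)
        curve = sweep(pred, bench, TermInformation(ia={"C": 1.0}, reference_size=0))
        assert smin(curve)[0] == 1.0

    def test_argmax_prefers_smallest_threshold_on_ties(self):
        bench, pred = make_bench_pred(
            prior={"P1": set()}, gained={"P1": {"A"}},
            scores={"P1": {"A": 0.4}})
        curve = sweep(pred, bench, IA1)
        # F = 1 at tau = 0.4 only; grid also holds 1.0 where F = 0
        assert fmax(curve, "macro") == (1.0, 0.4)

    def test_fmax_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(5)
        from _oracles import random_raw_fixture
        for _ in range(20):
            _, prior, gained, scores, ia = random_raw_fixture(rng)
            bench, pred = make_bench_pred(prior, gained, scores)
            f0 = fmax(sweep(pred, bench, None), "macro")[0]
            warped = {p: {t: s ** 3 for t, s in d.items()}
                      for p, d in scores.items()}
            bench2, pred2 = make_bench_pred(prior, gained, warped)
            f1 = fmax(sweep(pred2, bench2, None), "macro")[0]
            assert math.isclose(f0, f1, rel_tol=1e-12, abs_tol=1e-12)


class TestModesAndCoverage:
    def _partial(self):
        return make_bench_pred(
            prior={"P1": set(), "P2": set(), "P3": set()},
            gained={"P1": {"A"}, "P2": {"B"}, "P3": {"C"}},
            scores={"P1": {"A": 0.8}, "P2": {"B": 0.6}})  # P3 unpredicted

    def test_coverage_ratio(self):
        bench, pred = self._partial()
        assert coverage(pred, bench) == pytest.approx(2 / 3)
        assert coverage(PredictionSet("e", {}), bench) == 0.0

    def test_incomplete_recall_dominates_complete(self):
        bench, pred = self._partial()
        complete = sweep(pred, bench, IA1, mode="complete")
        incomplete = sweep(pred, bench, IA1, mode="incomplete")
        assert complete.ne == 3 and incomplete.ne == 2
        assert np.all(complete.rc_macro <= incomplete.rc_macro + 1e-15)
        # equality at full coverage
        bench2, pred2 = make_bench_pred(
            prior={"P1": set()}, gained={"P1": {"A"}}, scores={"P1": {"A": 0.5}})
        c = sweep(pred2, bench2, IA1, mode="complete")
        i = sweep(pred2, bench2, IA1, mode="incomplete")
        assert np.array_equal(c.rc_macro, i.rc_macro)

    def test_fixed_grid_option(self):
        bench, pred = self._partial()
        grid = np.linspace(0.0, 1.0, 101)
        curve = sweep(pred, bench, IA1, thresholds=grid)
        assert len(curve.thresholds) == 101
        exact = fmax(sweep(pred, bench, IA1), "macro")[0]
        gridded = fmax(curve, "macro")[0]
        assert gridded <= exact + 1e-12

    def test_aspect_and_emptiness_guards(self):
        bench, pred = self._partial()
        with pytest.raises(ValueError):
            sweep(pred, bench, IA1, mode="bogus")
        empty = BenchmarkSet(aspect="MF", setting="NK")
        with pytest.raises(ValueError, match="empty"):
            sweep(pred, empty, IA1)


def test_curve_writer_emits_parseable_rows(tmp_path):
    bench, pred = make_bench_pred(
        prior={"P1": set()}, gained={"P1": {"A"}}, scores={"P1": {"A": 0.5, "B": 0.25}})
    curve = sweep(pred, bench, IA1)
    path = tmp_path / "curve.tsv"
    write_curve(curve, path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t")[0] == "tau"
    assert len(lines) == 1 + len(curve.thresholds)
    tau, *rest = lines[1].split("\t")
    assert float(tau) == curve.thresholds[0]


def test_summarize_consistency():
    bench, pred = make_bench_pred(
        prior={"P1": set()}, gained={"P1": {"A", "B"}},
        scores={"P1": {"A": 0.9, "B": 0.2, "C": 0.5}})
    curve = sweep(pred, bench, IA1)
    res = summarize(curve, pred, bench)
    assert res.fmax_macro == fmax(curve, "macro")[0]
    assert res.smin == smin(curve)[0]
    assert res.coverage == 1.0
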