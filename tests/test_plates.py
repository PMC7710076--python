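"""Standard curves, LOQ, sample calls, panel metrics, quantification."""

import math

import numpy as np
import pytest
from scipy import stats

from ednaqpcr.plates import (
    LoqResult,
    PanelResult,
    Reaction,
    StandardCurve,
    call_sample,
    determine_loq,
    efficiency_from_slope,
    fit_standard_curve,
    panel_metrics,
    quantify_environmental,
)

PERFECT_SLOPE = -1.0 / math.log10(2.0)  # -3.3219...: exact doubling per cycle


def standards(slope, intercept, concs, reps=3, sigma=0.0, rng=None, dropout_below=None):
    out = []
    for conc in concs:
        for rep in range(1, reps + 1):
            if dropout_below is not None and conc < dropout_below and (
                rng is None or rng.random() < 0.6
            ):
                cq = None
            else:
                cq = intercept + slope * math.log10(conc)
                if sigma and rng is not None:
                    cq += rng.normal(0, sigma)
                if cq > 40.0:  # beyond the run length: never reported
                    cq = None
            out.append(
                Reaction("std_%g" % conc, "standard", rep, cq=cq, known_conc_pg_per_ul=conc)
            )
    return out


class TestStandardCurve:
    def test_noiseless_recovery_and_perfect_efficiency(self):
        curve = fit_standard_curve(
            standards(PERFECT_SLOPE, 38.0, [1000, 100, 10, 1])
        )
        assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-6)
        assert curve.intercept == pytest.approx(38.0, abs=1e-6)
        assert curve.efficiency_pct == pytest.approx(100.0, abs=0.01)
        assert curve.r_squared == pytest.approx(1.0)

    def test_efficiency_closed_form(self):
        assert efficiency_from_slope(-3.3219) == pytest.approx(100.0, abs=0.01)
        assert efficiency_from_slope(-3.6) < 100.0 < efficiency_from_slope(-3.1)

    def test_below_loq_standards_excluded_from_fit(self):
        rng = np.random.default_rng(4)
        reactions = standards(-3.5, 36.0, [100, 10, 1, 0.1, 0.01], rng=rng, dropout_below=0.05)
        curve = fit_standard_curve(reactions)
        assert curve.loq.concentration == pytest.approx(0.1)
        assert 0.01 not in curve.concentrations

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_standard_curve(standards(-3.3, 38.0, [10, 1]))

    def test_all_nd_standards_rejected(self):
        rxns = [
            Reaction("s", "standard", i, cq=None, known_conc_pg_per_ul=1.0)
            for i in range(1, 4)
        ]
        with pytest.raises(ValueError):
            fit_standard_curve(rxns)

    def test_slope_recovery_within_own_ci(self):
        # seeded Monte-Carlo: true slope inside the fitted 95% CI >= 90% of runs
        rng = np.random.default_rng(2024)
        true_slope, hits, runs = -3.6, 0, 200
        concs = [100, 10, 1, 0.1, 0.01, 0.001]
        for _ in range(runs):
            rxns = standards(true_slope, 28.0, concs, sigma=0.15, rng=rng)
            x = np.log10([r.known_conc_pg_per_ul for r in rxns])
            y = [r.cq for r in rxns]
            fit = stats.linregress(x, y)
            half = stats.t.ppf(0.975, len(x) - 2) * fit.stderr
            hits += abs(fit.slope - true_slope) <= half
        assert hits / runs >= 0.90


class TestDetermineLoq:
    def test_planted_dropout_threshold(self):
        rng = np.random.default_rng(8)
        rxns = standards(-3.4, 34.5, [100, 10, 1, 0.1, 0.01], rng=rng, dropout_below=0.05)
        loq = determine_loq(rxns)
        assert loq.concentration == pytest.approx(0.1)
        assert loq.cq == pytest.approx(34.5 - 3.4 * math.log10(0.1))

    def test_fully_detected_series_gives_lowest_concentration(self):
        rxns = standards(-3.4, 30.0, [100, 10, 1])
        assert determine_loq(rxns).concentration == pytest.approx(1.0)

    def test_nothing_fully_detected_is_flagged_undefined(self):
        rxns = [
            Reaction("s", "standard", i, cq=None if i == 1 else 30.0, known_conc_pg_per_ul=c)
            for c in (10.0, 1.0)
            for i in range(1, 4)
        ]
        loq = determine_loq(rxns)
        assert not loq.defined and loq.concentration is None

    def test_matches_brute_force_scan_on_random_dropout_patterns(self):
        rng = np.random.default_rng(55)
        concs = [10.0 ** -i for i in range(6)]
        for _ in range(1000):
            detected = {c: rng.random(3) < rng.uniform(0.2, 1.0) for c in concs}
            rxns = [
                Reaction("s%g" % c, "standard", i + 1,
                         cq=25.0 + i if det else None, known_conc_pg_per_ul=c)
                for c in concs
                for i, det in enumerate(detected[c])
            ]
            # brute force: lowest conc with all replicates detected such that
            # every higher conc is also fully detected
            expected = None
            for c in sorted(concs, reverse=True):
                if all(detected[c]):
                    expected = c
                else:
                    break
            loq = determine_loq(rxns)
            assert loq.concentration == expected


def make_curve(slope=-3.4, intercept=34.5, loq_conc=0.1):
    loq_cq = intercept + slope * math.log10(loq_conc)
    return StandardCurve(
        slope=slope, intercept=intercept, r_squared=0.999,
        efficiency_pct=efficiency_from_slope(slope),
        loq=LoqResult(loq_conc, loq_cq), n_points=12,
        concentrations=(100, 10, 1, 0.1),
    )


class TestCallSample:
    curve = make_curve()  # LOQ Cq ~ 37.9

    def r(self, sid, rep, cq):
        return Reaction(sid, "environmental", rep, cq=cq)

    def test_below_loq_cq_positive_all_replicates_quantified(self):
        calls = call_sample([self.r("a", 1, 30.0), self.r("a", 2, 30.2), self.r("a", 3, 29.8)], self.curve)
        assert calls["a"].status == "quantified"

    def test_nd_replicates_negative(self):
        calls = call_sample([self.r("a", i, None) for i in (1, 2, 3)], self.curve)
        assert calls["a"].status == "ND" and calls["a"].n_detects == 0

    def test_mixed_detection_is_bloq(self):
        calls = call_sample(
            [self.r("a", 1, 30.0), self.r("a", 2, 30.5), self.r("a", 3, None)], self.curve
        )
        assert calls["a"].status == "BLOQ"

    def test_above_loq_cq_configurable(self):
        reps = [self.r("a", 1, 39.0), self.r("a", 2, None), self.r("a", 3, None)]
        assert call_sample(reps, self.curve)["a"].status == "BLOQ"
        assert call_sample(reps, self.curve, above_loq="negative")["a"].status == "ND"

    def test_undefined_loq_rejected(self):
        curve = make_curve()
        bad = StandardCurve(
            slope=curve.slope, intercept=curve.intercept, r_squared=1.0,
            efficiency_pct=curve.efficiency_pct, loq=LoqResult(None, None),
            n_points=0, concentrations=(),
        )
        with pytest.raises(ValueError, match="LOQ"):
            call_sample([self.r("a", 1, 30.0)], bad)


class TestPanelMetrics:
    def test_printed_validation_counts(self):
        assert PanelResult(tp=4, fn=0, tn=21, fp=5).sensitivity_pct == 100
        assert PanelResult(tp=4, fn=0, tn=21, fp=5).specificity_pct == 81
        assert PanelResult(tp=3, fn=0, tn=29, fp=8).specificity_pct == 78
        assert PanelResult(tp=3, fn=0, tn=9, fp=0).specificity_pct == 100

    def test_counts_from_labeled_calls(self):
        detected = {"t1": True, "t2": False, "n1": True, "n2": False, "n3": False}
        labels = {"t1": "target", "t2": "target", "n1": "non-target",
                  "n2": "non-target", "n3": "non-target"}
        pm = panel_metrics(detected, labels)
        assert (pm.tp, pm.fn, pm.fp, pm.tn) == (1, 1, 1, 2)
        assert pm.sensitivity_pct == 50 and pm.specificity_pct == 67

    def test_degenerate_cases(self):
        assert PanelResult(tp=1, fn=0, tn=5, fp=0).specificity_pct == 100
        assert PanelResult(tp=1, fn=0, tn=5, fp=0).sensitivity_pct == 100
        with pytest.raises(ValueError, match="empty"):
            panel_metrics({}, {})
        with pytest.raises(ValueError, match="label"):
            panel_metrics({"x": True}, {})


class TestQuantifyEnvironmental:
    curve = make_curve(slope=-3.4, intercept=34.5)

    def forward_model(self, conc_pg_per_ml, dilution=5.0, extract_ul=100.0,
                      filtered_ml=1000.0, template_ul=2.0):
        """Invert the dimensional chain to produce the Cq for a water conc."""
        pg_extract = conc_pg_per_ml * filtered_ml
        pg_per_ul_template = pg_extract / (dilution * extract_ul)
        return self.curve.intercept + self.curve.slope * math.log10(pg_per_ul_template)

    def test_noiseless_round_trip(self):
        true_conc = 0.06
        cq = self.forward_model(true_conc)
        rxns = [Reaction("w", "environmental", i, cq=cq, template_ul=2.0) for i in (1, 2, 3)]
        (est,) = quantify_environmental(rxns, self.curve, 5.0, 100.0, 1000.0)
        assert est.status == "quantified"
        assert est.mean_pg_per_ml == pytest.approx(true_conc, rel=1e-9)
        assert est.ci95_half_width == pytest.approx(0.0, abs=1e-12)

    def test_t_interval_matches_direct_formula(self):
        rng = np.random.default_rng(99)
        cqs = [self.forward_model(0.5) + rng.normal(0, 0.2) for _ in range(3)]
        rxns = [Reaction("w", "environmental", i + 1, cq=c) for i, c in enumerate(cqs)]
        (est,) = quantify_environmental(rxns, self.curve, 5.0, 100.0, 1000.0)
        per_rep = [
            10 ** ((c - self.curve.intercept) / self.curve.slope) * 2.0 * 5.0 * (100.0 / 2.0) / 1000.0
            for c in cqs
        ]
        mean = np.mean(per_rep)
        half = stats.t.ppf(0.975, 2) * np.std(per_rep, ddof=1) / math.sqrt(3)
        assert est.mean_pg_per_ml == pytest.approx(mean)
        assert est.ci95_half_width == pytest.approx(half)

    def test_bloq_and_nd_propagate_without_numbers(self):
        rxns = [
            Reaction("b", "environmental", 1, cq=30.0),
            Reaction("b", "environmental", 2, cq=None),
            Reaction("b", "environmental", 3, cq=30.5),
            Reaction("n", "environmental", 1, cq=None),
            Reaction("n", "environmental", 2, cq=None),
            Reaction("n", "environmental", 3, cq=None),
        ]
        by_id = {e.sample_id: e for e in quantify_environmental(rxns, self.curve, 5, 100, 1000)}
        assert by_id["b"].status == "BLOQ" and by_id["b"].mean_pg_per_ml is None
        assert by_id["n"].status == "ND" and by_id["n"].mean_pg_per_ml is None

    def test_bad_volumes_rejected(self):
        with pytest.raises(ValueError):
            quantify_environmental([], self.curve, 0.0, 100.0, 1000.0)
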