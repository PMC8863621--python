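"""Contingency tests, correlations and the association battery."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

import beamaudit as ba
from beamaudit.stats import ScoredAudit


def fisher_oracle_p(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration.

    With margins fixed, sum the probabilities of every table whose
    probability does not exceed the observed one (up to a small relative
    tolerance for ties).
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def table(a, b, c, d):
    return ba.ContingencyTable2x2(a, b, c, d)


class TestBuildTable:
    def test_balanced_tally(self):
        t = ba.build_table([(True, True), (True, False), (False, True),
                            (False, False)])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_degenerate_tally(self):
        t = ba.build_table([(True, True)] * 5)
        assert (t.a, t.b, t.c, t.d) == (5, 0, 0, 0)

    def test_counts_match_brute_force(self, rng):
        flags = rng.random(200) < 0.3
        outcomes = rng.random(200) < 0.1
        t = ba.build_table(zip(flags, outcomes))
        assert t.a == int(np.sum(flags & outcomes))
        assert t.d == int(np.sum(~flags & ~outcomes))
        assert t.total == 200

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ba.build_table([])


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert ba.fisher_exact(table(5, 5, 5, 5)).p_value == pytest.approx(1.0)

    def test_two_by_two_diagonal(self):
        # enumeration by hand: extreme tables each carry probability 1/6
        assert ba.fisher_exact(table(2, 0, 0, 2)).p_value == pytest.approx(1 / 3)

    def test_three_one_table(self):
        # 34 of the C(8,4)=70 margin-fixed tables are at most as probable
        assert ba.fisher_exact(table(3, 1, 1, 3)).p_value == pytest.approx(34 / 70)

    def test_zero_cell_flagged(self):
        res = ba.fisher_exact(table(4, 0, 1, 5))
        assert math.isinf(res.estimate)
        assert "infinite" in res.note

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10),
           st.integers(0, 10))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        res = ba.fisher_exact(table(a, b, c, d))
        assert res.p_value == pytest.approx(fisher_oracle_p(a, b, c, d),
                                            rel=1e-9, abs=1e-12)

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_invariant_under_row_and_column_swap(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = ba.fisher_exact(table(a, b, c, d)).p_value
        assert ba.fisher_exact(table(d, c, b, a)).p_value == pytest.approx(p)


class TestChiSquare:
    def test_hand_computed_statistic(self):
        res = ba.chi_square(table(30, 20, 20, 30))
        assert res.statistic == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.0455, abs=0.0005)

    def test_independent_table_statistic_zero(self):
        res = ba.chi_square(table(10, 10, 10, 10))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            ba.chi_square(table(0, 0, 5, 5))

    def test_continuity_correction_shrinks_statistic(self):
        plain = ba.chi_square(table(12, 5, 6, 14)).statistic
        corrected = ba.chi_square(table(12, 5, 6, 14),
                                  continuity_correction=True).statistic
        assert corrected < plain

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30),
           st.integers(1, 30))
    def test_transposition_invariance(self, a, b, c, d):
        assert ba.chi_square(table(a, b, c, d)).statistic == \
            pytest.approx(ba.chi_square(table(a, c, b, d)).statistic)


class TestPearsonCorrelation:
    def test_perfect_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = ba.pearson_correlation(x, [2 * v + 1 for v in x])
        assert res.statistic == pytest.approx(1.0)

    def test_hand_computed_half(self):
        assert ba.pearson_correlation([1, 2, 3], [6, 4, 5]).statistic == \
            pytest.approx(-0.5)

    def test_perfect_inversion(self):
        assert ba.pearson_correlation([1, 2, 3, 4], [4, 3, 2, 1]).statistic == \
            pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ba.pearson_correlation([1, 2, 3], [5, 5, 5])

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_invariant_under_positive_affine_transform(self, scale, shift):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        base = ba.pearson_correlation(x, y).statistic
        assert ba.pearson_correlation(scale * x + shift, y).statistic == \
            pytest.approx(base, rel=1e-9)


def scored(inst, atypical, failing, poor=None, mean_err=0.0, est=None,
           excluded=False, tps="Eclipse AAA", param="Dosimetric Leaf Gap",
           pct=None):
    if poor is None:
        poor = failing
    if pct is None:
        pct = 95.0 if atypical else 50.0
    score = ba.PercentileScore(parameter_name=param, value=0.0,
                               percentile=pct, atypical=atypical)
    return ScoredAudit(institution_id=inst, tps_name=tps,
                       scores={param: score}, failing=failing, poor=poor,
                       excluded_for_localization=excluded,
                       mean_tld_error_pct=mean_err, estimated_error_pct=est)


class TestRunAssociationAnalysis:
    def test_single_record_marks_all_not_computed(self):
        report = ba.run_association_analysis([scored("i1", True, True)])
        assert not report["computed"].any()

    def test_tabulates_counts_and_tests(self, rng):
        records = []
        for i in range(120):
            atypical = bool(rng.random() < 0.3)
            failing = bool(rng.random() < (0.4 if atypical else 0.05))
            err = float(rng.normal(2.0 if atypical else 0.0, 1.0))
            records.append(scored(f"i{i}", atypical, failing, mean_err=err,
                                  est=err + float(rng.normal(0, 0.5))))
        report = ba.run_association_analysis(
            records, impactful={"Dosimetric Leaf Gap"})
        ids = set(report["test_id"])
        assert {"overall_any_atypical", "impactful_any_atypical",
                "per_parameter_atypical", "percentile_vs_tld_error",
                "estimated_vs_measured"} <= ids
        fisher_fail = report[(report.test_id == "per_parameter_atypical")
                             & (report.outcome == "failing")].iloc[0]
        assert fisher_fail["a"] + fisher_fail["b"] + fisher_fail["c"] + \
            fisher_fail["d"] == 120
        assert fisher_fail["computed"]
        assert fisher_fail["p_value"] < 0.05  # strong planted signal

    def test_null_cohort_type_one_error_controlled(self):
        # flags independent of outcomes: Fisher rejects at most ~alpha
        root = np.random.SeedSequence(1234)
        rejections = 0
        n_reps = 200
        for child in root.spawn(n_reps):
            r = np.random.default_rng(child)
            flags = r.random(80) < 0.2
            outcomes = r.random(80) < 0.15
            t = ba.build_table(zip(flags, outcomes))
            if ba.fisher_exact(t).p_value < 0.05:
                rejections += 1
        margin = 2 * math.sqrt(0.05 * 0.95 / n_reps)
        assert rejections / n_reps <= 0.05 + margin

    def test_planted_dose_signal_detected(self, eclipse_community, effect_models):
        # leaf gap drives the error with little residual noise: the
        # percentile-vs-error correlation is positive and significant
        reports = ba.sample_institutions(eclipse_community, 150, seed=55)
        cfg = ba.CohortConfig(n_institutions=150, sigma_residual_pct=0.3,
                              tld_noise_pct=0.3, n_tld_per_phantom=4)
        samples = ba.sample_community(eclipse_community, 4000, seed=56)
        dist = ba.fit_distribution(samples["Dosimetric Leaf Gap"],
                                   eclipse_community.stratum,
                                   "Dosimetric Leaf Gap")
        records = []
        for i, (rep, child) in enumerate(
                zip(reports, np.random.SeedSequence(57).spawn(len(reports)))):
            sim = ba.simulate_audit(rep, effect_models, cfg, seed=child)
            label = ba.classify_outcome(sim.record)
            pct = ba.percentile_of(dist, rep.parameters["Dosimetric Leaf Gap"])
            score = ba.PercentileScore("Dosimetric Leaf Gap",
                                       rep.parameters["Dosimetric Leaf Gap"],
                                       pct, ba.classify_atypical(pct))
            records.append(ScoredAudit(
                institution_id=rep.institution_id, tps_name="Eclipse AAA",
                scores={"Dosimetric Leaf Gap": score}, failing=label.failing,
                poor=label.poor, mean_tld_error_pct=label.mean_tld_error_pct,
                estimated_error_pct=sim.predicted_error_pct))
        report = ba.run_association_analysis(records)
        row = report[report.test_id == "percentile_vs_tld_error"].iloc[0]
        assert row["computed"] and row["statistic"] > 0.5 and row["p_value"] < 1e-6
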