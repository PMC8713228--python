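"""Score fitting, patient scoring, classification, and their invariants."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clnmscore import (
    ClassConditionalFrequencyTable,
    ClassLabel,
    Factor,
    PatientProfile,
    RiskFactorScheme,
    ScoringError,
    classify,
    fit_score_table,
    log_joint_probability,
    round_half_away,
    score_from_probability,
    score_patient,
)

P, N = ClassLabel.POSITIVE, ClassLabel.NEGATIVE


class TestScoreTransform:
    def test_anchor_points(self):
        """P = 1 scores 10, P = 0.1 scores 0, P < 0.1 goes negative."""
        assert score_from_probability(1.0) == pytest.approx(10.0)
        assert score_from_probability(0.1) == pytest.approx(0.0)
        assert score_from_probability(0.05) < 0

    def test_zero_probability_rejected(self):
        with pytest.raises(ScoringError, match="zero probability"):
            score_from_probability(0.0)


class TestFitScoreTable:
    def test_reproduces_published_table_every_cell(self, fitted_results, published_scores):
        """All 34 fitted cells match the printed score table at 1 dp."""
        fitted = fitted_results.score_table
        for key, printed in published_scores.scores.items():
            assert round_half_away(fitted.scores[key]) == pytest.approx(printed), key

    @pytest.mark.parametrize(
        "factor, category, g, printed",
        [
            ("Multifocality", "Y", P, -1.8),
            ("TL", "Upper pole", P, 1.2),
            ("Sex", "Male", P, 4.3),
            ("TD", "≥2.0 cm", N, -4.3),
        ],
    )
    def test_spot_cells(self, fitted_results, factor, category, g, printed):
        cell = fitted_results.score_table.score(factor, category, g)
        assert round_half_away(cell) == pytest.approx(printed)

    def test_zero_count_requires_smoothing(self):
        scheme = RiskFactorScheme((Factor("A", ("a1", "a2")),))
        counts = {("A", "a1", P): 5, ("A", "a2", P): 0,
                  ("A", "a1", N): 2, ("A", "a2", N): 3}
        table = ClassConditionalFrequencyTable.from_counts(scheme, counts)
        with pytest.raises(ScoringError, match="a2"):
            fit_score_table(table)
        smoothed = fit_score_table(table, smoothing=0.5)
        assert math.isfinite(smoothed.score("A", "a2", P))

    def test_smoothing_continuity(self, retro_table):
        """On a strictly positive table, scores converge to the unsmoothed
        fit as the smoothing constant goes to zero."""
        base = fit_score_table(retro_table)
        deviations = [
            fit_score_table(retro_table, smoothing=alpha).max_abs_difference(base)
            for alpha in (1.0, 0.1, 0.01, 0.001)
        ]
        assert deviations == sorted(deviations, reverse=True)
        assert deviations[-1] < 0.01


class TestScorePatient:
    def test_worked_example(self, fitted_results, worked_example_profile):
        """The published example patient scores 37.0 vs 30.2 → metastatic."""
        r = score_patient(worked_example_profile, fitted_results.score_table)
        assert round_half_away(r.s_positive) == pytest.approx(37.0)
        assert round_half_away(r.s_negative) == pytest.approx(30.2)
        assert r.predicted is P
        assert not r.tie_broken
        assert r.margin == pytest.approx(r.s_positive - r.s_negative)

    def test_hand_summed_low_risk_profile(self, fitted_results):
        """Six printed cells summed by hand for an older female with a
        small upper-pole tumor: 8.6+6.4−0.4+8.4+9.7+1.2 = 33.9 vs
        9.2+7.5+5.4+9.6+9.8+3.5 = 45.0 → not metastatic."""
        profile = PatientProfile(categories={
            "Sex": "Female", "Age": "≥45 yrs", "TD": "<0.7 cm",
            "CI": "N", "Multifocality": "N", "TL": "Upper pole",
        })
        r = score_patient(profile, fitted_results.score_table)
        assert round_half_away(r.s_positive) == pytest.approx(33.9)
        assert round_half_away(r.s_negative) == pytest.approx(45.0)
        assert r.predicted is N

    def test_full_precision_mode_differs_only_in_rounding(self, fitted_results, worked_example_profile):
        r = score_patient(worked_example_profile, fitted_results.score_table,
                          precision="full")
        # full-precision sums: 37.011… / 30.125…
        assert r.s_positive == pytest.approx(37.0110112282041)
        assert r.s_negative == pytest.approx(30.1252889802515)
        assert r.predicted is P

    def test_all_flat_profile_ties(self):
        """If every category has P = 0.1 in both classes, both totals are 0
        and the tie goes to positive under the default policy."""
        scheme = RiskFactorScheme((Factor("A", tuple(f"a{i}" for i in range(10))),))
        counts = {("A", f"a{i}", g): 1 for i in range(10) for g in (P, N)}
        table = ClassConditionalFrequencyTable.from_counts(scheme, counts)
        scores = fit_score_table(table)
        profile = PatientProfile(categories={"A": "a0"})
        r = score_patient(profile, scores)
        assert r.s_positive == pytest.approx(0.0)
        assert r.s_negative == pytest.approx(0.0)
        assert r.tie_broken and r.predicted is P

    def test_prior_term_shifts_totals(self, fitted_results, worked_example_profile):
        r0 = score_patient(worked_example_profile, fitted_results.score_table)
        r1 = score_patient(worked_example_profile, fitted_results.score_table,
                           prior=197 / 412)
        assert r1.s_positive - r0.s_positive == pytest.approx(10 * math.log10(197 / 412))
        assert r1.s_negative - r0.s_negative == pytest.approx(10 * math.log10(215 / 412))

    def test_unknown_category_is_lookup_error(self, fitted_results):
        profile = PatientProfile(categories={
            "Sex": "Female", "Age": "≥45 yrs", "TD": "4 cm",
            "CI": "N", "Multifocality": "N", "TL": "Upper pole",
        })
        with pytest.raises(Exception):
            score_patient(profile, fitted_results.score_table)


class TestClassify:
    @pytest.mark.parametrize(
        "sp, sn, expected, tie",
        [(37.0, 30.2, P, False), (34.5, 45.0, N, False), (0.0, 0.0, P, True)],
    )
    def test_decisions(self, sp, sn, expected, tie):
        label, tie_broken = classify(sp, sn)
        assert label is expected and tie_broken is tie

    def test_tie_policy_negative(self):
        label, tie_broken = classify(5.0, 5.0, tie_policy="negative")
        assert label is N and tie_broken

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ScoringError):
            classify(bad, 0.0)


class TestLogJointProbability:
    def test_affine_relation_on_worked_example(self, retro_table, fitted_results,
                                               worked_example_profile):
        """S_g equals (lg P_g + #factors) × 10 at full precision."""
        lg = log_joint_probability(worked_example_profile, retro_table, P)
        r = score_patient(worked_example_profile, fitted_results.score_table,
                          precision="full")
        assert (lg + 6) * 10 == pytest.approx(r.s_positive)
        assert round_half_away((lg + 6) * 10) == pytest.approx(37.0)

    def test_single_factor_certainty_scores_zero(self):
        scheme = RiskFactorScheme((Factor("A", ("a1", "a2")),))
        counts = {("A", "a1", P): 5, ("A", "a2", P): 0,
                  ("A", "a1", N): 0, ("A", "a2", N): 3}
        table = ClassConditionalFrequencyTable.from_counts(scheme, counts)
        profile = PatientProfile(categories={"A": "a1"})
        assert log_joint_probability(profile, table, P) == pytest.approx(0.0)
        with pytest.raises(ScoringError):
            log_joint_probability(profile, table, N)

    def test_decision_agreement_on_all_320_profiles(self, retro_table, fitted_results):
        """argmax over S_g (full precision) equals argmax over lg P_g for
        every complete category combination of the six-factor scheme."""
        scheme = retro_table.scheme
        n_checked = 0
        for combo in itertools.product(*(f.categories for f in scheme.factors)):
            profile = PatientProfile(categories=dict(zip(scheme.factor_names, combo)))
            r = score_patient(profile, fitted_results.score_table, precision="full")
            lg_p = log_joint_probability(profile, retro_table, P)
            lg_n = log_joint_probability(profile, retro_table, N)
            by_lg = P if lg_p > lg_n else N if lg_n > lg_p else P
            assert r.predicted is by_lg, combo
            n_checked += 1
        assert n_checked == 320


@settings(derandomize=True, max_examples=50)
@given(data=st.data())
def test_permutation_stability(data, retro_table, fitted_results):
    """Reordering factors in the scheme leaves every patient's totals
    unchanged up to round-off."""
    scheme = retro_table.scheme
    order = data.draw(st.permutations(range(len(scheme.factors))))
    permuted_scheme = RiskFactorScheme(tuple(scheme.factors[i] for i in order))
    permuted_table = ClassConditionalFrequencyTable(
        scheme=permuted_scheme, counts=retro_table.counts,
        class_totals=retro_table.class_totals,
    )
    permuted_scores = fit_score_table(permuted_table)
    combo = {
        f.name: data.draw(st.sampled_from(f.categories), label=f.name)
        for f in scheme.factors
    }
    profile = PatientProfile(categories=combo)
    r0 = score_patient(profile, fitted_results.score_table, precision="full")
    r1 = score_patient(profile, permuted_scores, precision="full")
    assert abs(r0.s_positive - r1.s_positive) < 1e-9
    assert abs(r0.s_negative - r1.s_negative) < 1e-9
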