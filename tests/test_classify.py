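"""Platt calibration, MVP scoring and one-vs-rest training."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import episig as ep
from episig.errors import (
    BetaRangeError,
    CalibrationError,
    FoldError,
    TrainingError,
)


class TestFitPlatt:
    def test_symmetric_decisions_give_centered_link(self):
        platt = ep.fit_platt([-1.0] * 20 + [1.0] * 20,
                             [False] * 20 + [True] * 20)
        assert platt.A < 0
        assert abs(platt.B) < 1e-3
        assert float(ep.mvp_from_decision(0.0, platt)) == pytest.approx(0.5,
                                                                        abs=1e-3)

    def test_uninformative_decisions_give_flat_link(self):
        platt = ep.fit_platt([0.0] * 10 + [0.0] * 10,
                             [True] * 10 + [False] * 10)
        assert abs(platt.A) < 1e-3
        # balanced classes: the smoothed prior is one half
        assert float(ep.mvp_from_decision(0.0, platt)) == pytest.approx(0.5,
                                                                        abs=1e-3)

    def test_label_swap_flips_slope_sign(self):
        decisions = [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]
        labels = [False, False, False, True, True, True]
        a = ep.fit_platt(decisions, labels)
        b = ep.fit_platt(decisions, [not x for x in labels])
        assert a.A < 0 < b.A
        assert b.A == pytest.approx(-a.A, rel=1e-3, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            ep.fit_platt([0.1, 0.2], [True, True])


class TestMvpFromDecision:
    @pytest.mark.parametrize("A,B,f,expected,tol", [
        (-2.0, 0.0, 0.0, 0.5, 1e-12),
        (-1.5, 0.2, 1.0, 0.7858349830425586, 1e-9),
    ])
    def test_closed_form(self, A, B, f, expected, tol):
        platt = ep.PlattParams(A=A, B=B)
        assert float(ep.mvp_from_decision(f, platt)) == pytest.approx(expected,
                                                                      abs=tol)

    def test_asymptotes_without_overflow(self):
        platt = ep.PlattParams(A=-2.0, B=0.0)
        with np.errstate(over="raise"):
            high = float(ep.mvp_from_decision(10.0, platt))
            extreme = float(ep.mvp_from_decision(1e6, platt))
            low = float(ep.mvp_from_decision(-1e6, platt))
        assert high > 0.999
        assert 0 < low < 1e-12 + 1e-15 or low < extreme  # inside open interval
        assert 0 < extreme < 1 and 0 < low < 1

    @given(f1=st.floats(-1e6, 1e6), f2=st.floats(-1e6, 1e6))
    def test_monotone_when_slope_negative(self, f1, f2):
        platt = ep.PlattParams(A=-1.3, B=0.4)
        lo, hi = sorted([f1, f2])
        assert ep.mvp_from_decision(lo, platt) <= ep.mvp_from_decision(hi, platt)

    @given(f=st.floats(allow_nan=False, allow_infinity=False),
           A=st.floats(-50, 50), B=st.floats(-50, 50))
    def test_score_always_in_unit_interval(self, f, A, B):
        score = float(ep.mvp_from_decision(f, ep.PlattParams(A, B)))
        assert 0 < score < 1


class TestCallCategory:
    @pytest.mark.parametrize("score,expected", [
        (0.0, "negative"),
        (0.05, "negative"),
        (0.1, "inconclusive"),   # closed band includes both cutoffs
        (0.2, "inconclusive"),
        (0.5, "inconclusive"),
        (0.51, "positive"),
        (0.9, "positive"),
        (1.0, "positive"),
    ])
    def test_bands(self, score, expected):
        assert ep.call_category(score) == expected

    def test_score_out_of_range(self):
        with pytest.raises(BetaRangeError):
            ep.call_category(1.5)


def _truth_groups(cohort, *groups):
    t = cohort.truth
    return t[t["group"].isin(groups)]


class TestTrainClassifiers:
    def test_holdout_separation_on_small_panel(self, small_cohort, small_kdb):
        classifiers = small_kdb.classifiers
        for _, row in _truth_groups(small_cohort, "test_case").iterrows():
            res = ep.score_sample(classifiers,
                                  small_cohort.beta.sample(row["sample_id"]))
            assert res.scores[row["disorder_id"]] > 0.5
            for d, score in res.scores.items():
                if d != row["disorder_id"]:
                    assert score < 0.1
        for _, row in _truth_groups(small_cohort, "test_control").iterrows():
            res = ep.score_sample(classifiers,
                                  small_cohort.beta.sample(row["sample_id"]))
            assert all(score < 0.1 for score in res.scores.values())

    def test_platt_slope_negative_for_real_signal(self, small_kdb):
        for clf in small_kdb.classifiers.values():
            assert clf.platt.A < 0

    def test_single_class_training_error(self, small_cohort, small_kdb):
        sheet = small_cohort.sheet
        cases_only = ep.SampleSheet(
            sheet.data[(sheet.data["role"] == "reference_case")
                       & (sheet.data["disorder_label"] == "SYND_A")]
        )
        sig = small_kdb.signatures["SYND_A"]
        with pytest.raises(TrainingError):
            ep.train_classifiers(small_cohort.beta, cases_only,
                                 {"SYND_A": sig}, cv_folds=2)

    def test_fold_count_exceeding_positives(self, small_cohort, small_kdb):
        sig = small_kdb.signatures["SYND_A"]
        with pytest.raises(FoldError):
            ep.train_classifiers(small_cohort.beta, small_cohort.sheet,
                                 {"SYND_A": sig}, cv_folds=50)

    def test_permuted_labels_show_no_separation(self, small_cohort, small_kdb):
        """Out-of-fold calibration keeps label-noise models uninformative."""
        sheet_df = small_cohort.sheet.data.copy()
        ref_mask = sheet_df["role"].isin(["reference_case", "reference_control"])
        shuffled = sheet_df.loc[ref_mask, ["role", "disorder_label"]].sample(
            frac=1.0, random_state=17
        ).to_numpy()
        sheet_df.loc[ref_mask, ["role", "disorder_label"]] = shuffled
        permuted = ep.SampleSheet(sheet_df)
        sig = small_kdb.signatures["SYND_A"]
        clfs = ep.train_classifiers(small_cohort.beta, permuted,
                                    {"SYND_A": sig}, cv_folds=5, seed=1)
        truth = small_cohort.truth
        case_ids = truth.loc[(truth["group"] == "test_case")
                             & (truth["disorder_id"] == "SYND_A"), "sample_id"]
        ctrl_ids = truth.loc[truth["group"] == "test_control", "sample_id"]
        case_scores = [ep.score_sample(clfs, small_cohort.beta.sample(s)).scores["SYND_A"]
                       for s in case_ids]
        ctrl_scores = [ep.score_sample(clfs, small_cohort.beta.sample(s)).scores["SYND_A"]
                       for s in ctrl_ids]
        assert abs(np.mean(case_scores) - np.mean(ctrl_scores)) < 0.2


class TestScoreSample:
    def test_control_profile_scores_negative(self, small_cohort, small_kdb):
        baseline = small_cohort.baseline
        res = ep.score_sample(small_kdb.classifiers, baseline, "baseline")
        assert all(score < 0.1 for score in res.scores.values())

    def test_coverage_error_recorded_not_raised(self, small_cohort, small_kdb):
        sample = small_cohort.beta.sample(
            small_cohort.sheet.control_ids()[0]
        ).copy()
        sig_a = small_kdb.signatures["SYND_A"].probe_ids
        sample.loc[sig_a[: int(len(sig_a) * 0.95)]] = np.nan
        res = ep.score_sample(small_kdb.classifiers, sample, "masked")
        assert "SYND_A" in res.coverage_errors
        assert "SYND_B" in res.scores

    def test_few_missing_probes_are_imputed(self, small_cohort, small_kdb):
        sid = small_cohort.sheet.control_ids()[1]
        sample = small_cohort.beta.sample(sid).copy()
        sig_a = small_kdb.signatures["SYND_A"].probe_ids
        sample.loc[sig_a[:3]] = np.nan  # well under the 10% floor
        res = ep.score_sample(small_kdb.classifiers, sample, sid)
        assert "SYND_A" in res.scores
        assert res.scores["SYND_A"] < 0.1

    def test_score_matrix_long_format(self, small_cohort, small_kdb):
        ids = small_cohort.sheet.control_ids()[:3]
        table = ep.score_matrix(small_kdb.classifiers, small_cohort.beta, ids)
        assert set(table.columns) == {"sample_id", "disorder_id", "mvp",
                                      "category", "coverage_flag"}
        assert len(table) == 3 * len(small_kdb.classifiers)
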