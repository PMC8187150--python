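"""Report composition, replicate concordance and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import episig as ep
from episig.classify import MVPResult
from episig.errors import ComparisonError, CompositionError
from episig.evidence import ClusterEvidence
from episig.loci import LocusResult


def _mvp(sample_id="S1", **scores):
    res = MVPResult(sample_id=sample_id)
    for d, s in scores.items():
        res.scores[d] = s
        res.categories[d] = ep.call_category(s)
    return res


def _ev(disorder, call, margin, sample_id="S1"):
    assignment = {"with_cases": "case_side",
                  "with_controls": "control_side"}.get(
        call, "case_side" if margin >= 0 else "control_side")
    return ClusterEvidence(
        disorder_id=disorder, sample_id=sample_id,
        embedding=pd.DataFrame(columns=["dim1", "dim2"]),
        assignment=assignment, margin=margin, call=call,
    )


def _locus(call="normal", z=0.0, fraction=None, name="ICR_A"):
    return LocusResult(
        locus=name, locus_type="imprinted_dmr", observed_mean=0.5,
        control_mean=0.5, control_sd=0.02, z=z,
        estimated_aberrant_fraction=fraction, call=call,
    )


class TestComposeReport:
    def test_confirmed_positive(self):
        rep = ep.compose_report(
            _mvp(D1=0.95, D2=0.01),
            {"D1": _ev("D1", "with_cases", 0.8)},
        )
        assert rep.final_status == "positive"
        assert rep.matched_disorders == ["D1"]

    def test_score_cluster_discordance_is_inconclusive(self):
        rep = ep.compose_report(
            _mvp(D1=0.95), {"D1": _ev("D1", "with_controls", -0.6)},
        )
        assert rep.final_status == "inconclusive"
        assert any("discordant" in f for f in rep.review_flags)

    def test_inconclusive_band_score(self):
        # a mildly elevated score below the positive cutoff, everything
        # else negative: reported inconclusive, flag cites the band
        rep = ep.compose_report(_mvp(D1=0.2, D2=0.02, D3=0.0))
        assert rep.final_status == "inconclusive"
        assert any("inconclusive band" in f for f in rep.review_flags)

    def test_negative_scores_with_caseward_cluster_trend(self):
        # near-zero scores but the sample plots between cases and controls
        rep = ep.compose_report(
            _mvp(D1=0.03, D2=0.0),
            {"D1": _ev("D1", "intermediate", 0.1)},
        )
        assert rep.final_status == "inconclusive"
        assert any("between" in f for f in rep.review_flags)

    def test_all_negative_everywhere_is_negative(self):
        rep = ep.compose_report(
            _mvp(D1=0.02, D2=0.05),
            {"D1": _ev("D1", "with_controls", -0.9)},
            [_locus("normal")],
        )
        assert rep.final_status == "negative"
        assert rep.matched_disorders == []

    def test_locus_aberration_is_positive(self):
        rep = ep.compose_report(
            _mvp(D1=0.01),
            loci=[_locus("hypomethylated", z=-20.0, fraction=0.9)],
        )
        assert rep.final_status == "positive"
        assert rep.matched_disorders == ["ICR_A"]

    def test_multiple_positives_all_reported_with_flag(self):
        rep = ep.compose_report(
            _mvp(D1=0.95, D2=0.9),
            {"D1": _ev("D1", "with_cases", 0.7),
             "D2": _ev("D2", "with_cases", 0.6)},
        )
        assert rep.final_status == "positive"
        assert rep.matched_disorders == ["D1", "D2"]
        assert any("multiple" in f for f in rep.review_flags)

    def test_sample_mismatch_rejected(self):
        with pytest.raises(CompositionError):
            ep.compose_report(
                _mvp(D1=0.95), {"D1": _ev("D1", "with_cases", 0.8,
                                          sample_id="OTHER")},
            )

    def test_deterministic_content(self):
        kwargs = dict(
            evidence={"D1": _ev("D1", "with_cases", 0.8)},
            loci=[_locus()], timestamp="fixed",
        )
        a = ep.compose_report(_mvp(D1=0.95), **kwargs)
        b = ep.compose_report(_mvp(D1=0.95), **kwargs)
        assert (a.final_status, a.matched_disorders, a.review_flags,
                a.timestamp) == \
               (b.final_status, b.matched_disorders, b.review_flags,
                b.timestamp)

    @pytest.mark.parametrize("score", [0.03, 0.3, 0.9])
    @pytest.mark.parametrize("cluster", [None, "with_cases", "with_controls",
                                         "intermediate+", "intermediate-"])
    @pytest.mark.parametrize("locus_call", ["normal", "hypermethylated"])
    def test_rule_table_is_exhaustive(self, score, cluster, locus_call):
        """Every score band x cluster call x locus call maps to one status."""
        evidence = {}
        if cluster is not None:
            call = cluster.rstrip("+-")
            margin = {"with_cases": 0.8, "with_controls": -0.8,
                      "intermediate": 0.1 if cluster.endswith("+") else -0.1}[call]
            evidence = {"D1": _ev("D1", call, margin)}
        rep = ep.compose_report(
            _mvp(D1=score), evidence,
            [_locus(locus_call, z=20.0 if locus_call != "normal" else 0.0,
                    fraction=0.9 if locus_call != "normal" else None)],
        )
        assert rep.final_status in {"positive", "negative", "inconclusive"}
        assert (rep.final_status == "positive") == bool(rep.matched_disorders)


class TestReplicateConcordance:
    def test_within_tolerance_concordant(self):
        r1 = _mvp("rep1", D1=0.93, D2=0.01)
        r2 = _mvp("rep2", D1=0.90, D2=0.005)
        out = ep.check_replicate_concordance(r1, r2)
        assert out.concordant
        assert out.max_delta == pytest.approx(0.03)

    def test_identical_results_concordant(self):
        r = _mvp("rep", D1=0.5, D2=0.0)
        assert ep.check_replicate_concordance(r, r).concordant

    def test_score_shift_and_category_flip_discordant(self):
        out = ep.check_replicate_concordance(_mvp("a", D1=0.52),
                                             _mvp("b", D1=0.45))
        assert not out.concordant
        assert out.discordant_disorders == ["D1"]

    def test_panel_mismatch(self):
        with pytest.raises(ComparisonError):
            ep.check_replicate_concordance(_mvp("a", D1=0.5),
                                           _mvp("b", D2=0.5))


class TestSummaries:
    @pytest.mark.parametrize("k,n,expected", [
        (48, 136, 35.3),
        (8, 71, 11.3),
        (4, 207, 1.9),
        (134, 136, 98.5),
    ])
    def test_percent_half_up(self, k, n, expected):
        assert ep.percent(k, n) == expected

    def test_percent_rounds_half_up_not_bankers(self):
        assert ep.percent(1, 8) == 12.5
        assert ep.percent(25, 1000) == 2.5
        assert ep.percent(45, 1000) == 4.5  # 4.5 stays 4.5, not 4 or 5

    def test_summarize_counts(self):
        out = ep.summarize_counts(positive=48, negative=86, inconclusive=2)
        assert out["n"] == 136
        assert out["pct_positive"] == 35.3
        assert out["pct_conclusive"] == 98.5

    @given(pos=st.integers(0, 500), neg=st.integers(0, 500),
           inc=st.integers(0, 500))
    def test_percentages_sum_to_hundred(self, pos, neg, inc):
        if pos + neg + inc == 0:
            return
        out = ep.summarize_counts(pos, neg, inc)
        total = out["pct_positive"] + out["pct_negative"] + out["pct_inconclusive"]
        assert total == pytest.approx(100.0, abs=0.1 + 1e-9)

    def test_empty_report_list(self):
        table = ep.summarize_cohort([])
        assert table.empty

    def test_cohort_breakdown(self):
        reports = []
        sheet_rows = []
        for i, (status, cohort) in enumerate(
            [("positive", "targeted")] * 2 + [("negative", "targeted")]
            + [("inconclusive", "screening")]
        ):
            sid = f"s{i}"
            rep = ep.compose_report(_mvp(sid, D1=0.95 if status == "positive"
                                         else 0.3 if status == "inconclusive"
                                         else 0.01),
                                    {"D1": _ev("D1", "with_cases", 0.8,
                                               sample_id=sid)}
                                    if status == "positive" else {},
                                    timestamp="t")
            reports.append(rep)
            sheet_rows.append({"sample_id": sid, "sex": "F",
                               "role": "test", "cohort": cohort})
        sheet = ep.sheet_from_records(sheet_rows)
        table = ep.summarize_cohort(reports, sheet).set_index("cohort")
        assert table.loc["all", "n"] == 4
        assert table.loc["targeted", "pct_positive"] == pytest.approx(66.7)
        assert table.loc["screening", "pct_inconclusive"] == 100.0

    def test_kdb_version_propagates_to_report(self, small_cohort, small_kdb):
        sid = small_cohort.sheet.control_ids()[0]
        rep = ep.analyze_sample(small_cohort.beta, small_cohort.sheet,
                                small_kdb, sid,
                                annotation=small_cohort.annotation)
        assert rep.kdb_version == small_kdb.version
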