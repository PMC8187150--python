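"""MDS embedding and clustering evidence."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

import episig as ep
from episig.errors import CohortSizeError, EmbeddingError, SeparabilityError

from conftest import make_beta


@pytest.fixture(scope="module")
def panel(small_cohort, small_kdb):
    """SYND_A signature-restricted views shared by the evidence tests."""
    sig = small_kdb.signatures["SYND_A"]
    beta = small_cohort.beta.restrict(sig.probe_ids)
    case_ids = small_cohort.sheet.case_ids("SYND_A")
    control_ids = small_cohort.sheet.control_ids()
    return beta, case_ids, control_ids, sig


class TestMdsEmbed:
    def test_equilateral_configuration_preserved(self):
        beta = make_beta(np.eye(3))  # three pairwise-equidistant samples
        emb = ep.mds_embed(beta)
        dists = pdist(emb.to_numpy())
        assert np.ptp(dists) < 1e-6

    def test_duplicated_sample_coincides(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(size=(10, 4))
        values = np.column_stack([values, values[:, 1]])  # s4 duplicates s1
        emb = ep.mds_embed(make_beta(values))
        np.testing.assert_allclose(emb.iloc[1], emb.iloc[4], atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(EmbeddingError):
            ep.mds_embed(make_beta(np.full((4, 2), 0.5)))

    def test_case_like_sample_lands_near_cases(self, panel, small_cohort):
        beta, case_ids, control_ids, _ = panel
        test_id = small_cohort.truth.loc[
            (small_cohort.truth["group"] == "test_case")
            & (small_cohort.truth["disorder_id"] == "SYND_A"), "sample_id"
        ].iloc[0]
        sub = beta.subset_samples(case_ids + control_ids + [test_id])
        emb = ep.mds_embed(sub, case_ids=case_ids)
        case_centroid = emb.loc[case_ids].mean()
        ctrl_centroid = emb.loc[control_ids].mean()
        test_pt = emb.loc[test_id]
        assert (np.linalg.norm(test_pt - case_centroid)
                < np.linalg.norm(test_pt - ctrl_centroid))
        # sign convention: case centroid forced to non-negative first axis
        assert case_centroid["dim1"] >= 0

    def test_distance_rank_order_preserved(self, panel):
        beta, case_ids, control_ids, _ = panel
        sub = beta.subset_samples(case_ids + control_ids)
        emb = ep.mds_embed(sub, case_ids=case_ids)
        orig = pdist(sub.data.to_numpy().T)
        embedded = pdist(emb.to_numpy())
        # large distances (between the case and control clouds) carry the
        # structure; tiny within-cloud distances are noise-dominated
        large = orig > np.median(orig)
        rho = spearmanr(orig[large], embedded[large]).statistic
        assert rho >= 0.9


class TestClusterAssign:
    def test_reference_case_copy_called_with_cases(self, panel, small_cohort):
        beta, case_ids, control_ids, sig = panel
        full = small_cohort.beta.restrict(sig.probe_ids)
        copy_of_case = full.data[case_ids[0]].rename("query")
        augmented = ep.BetaMatrix(
            pd.concat([full.data, copy_of_case], axis=1)
        )
        ev = ep.cluster_assign(augmented, case_ids, control_ids, "query",
                               disorder_id="SYND_A")
        assert ev.assignment == "case_side"
        assert ev.call == "with_cases"
        assert ev.margin > 0.5

    def test_control_mean_profile_called_with_controls(self, panel, small_cohort):
        beta, case_ids, control_ids, sig = panel
        full = small_cohort.beta.restrict(sig.probe_ids)
        ctrl_mean = full.data[control_ids].mean(axis=1).rename("query")
        augmented = ep.BetaMatrix(pd.concat([full.data, ctrl_mean], axis=1))
        ev = ep.cluster_assign(augmented, case_ids, control_ids, "query")
        assert ev.call == "with_controls"
        assert ev.margin < -0.5

    def test_half_mosaic_is_intermediate(self, panel, small_cohort):
        """A 50/50 case/control mixture plots between the references."""
        beta, case_ids, control_ids, sig = panel
        mosaic_id = small_cohort.truth.loc[
            small_cohort.truth["group"] == "mosaic", "sample_id"
        ].iloc[0]
        full = small_cohort.beta.restrict(sig.probe_ids)
        ev = ep.cluster_assign(full, case_ids, control_ids, mosaic_id,
                               disorder_id="SYND_A")
        assert ev.call == "intermediate"
        assert abs(ev.margin) < 0.2

    def test_margin_monotone_in_mosaic_fraction(self, panel, small_cohort):
        beta, case_ids, control_ids, sig = panel
        full = small_cohort.beta.restrict(sig.probe_ids)
        case_prof = small_cohort.case_profiles["SYND_A"].loc[sig.probe_ids]
        ctrl_prof = small_cohort.baseline.loc[sig.probe_ids]
        margins = []
        for frac in np.linspace(0, 1, 11):
            mixed = pd.Series(
                ep.mix_mosaic(case_prof.to_numpy(), ctrl_prof.to_numpy(), frac),
                index=sig.probe_ids, name="query",
            )
            augmented = ep.BetaMatrix(pd.concat([full.data, mixed], axis=1))
            ev = ep.cluster_assign(augmented, case_ids, control_ids, "query")
            margins.append(ev.margin)
        assert all(b >= a - 1e-9 for a, b in zip(margins, margins[1:]))
        assert margins[0] < -0.2 and margins[-1] > 0.2

    def test_order_invariance(self, panel, small_cohort):
        beta, case_ids, control_ids, sig = panel
        test_id = small_cohort.truth.loc[
            small_cohort.truth["group"] == "test_case", "sample_id"
        ].iloc[0]
        full = small_cohort.beta.restrict(sig.probe_ids)
        ev1 = ep.cluster_assign(full, case_ids, control_ids, test_id)
        rng = np.random.default_rng(5)
        shuffled_probes = list(rng.permutation(sig.probe_ids))
        shuffled = ep.BetaMatrix(
            full.data.loc[shuffled_probes,
                          list(rng.permutation(full.sample_ids))]
        )
        ev2 = ep.cluster_assign(shuffled, list(reversed(case_ids)),
                                list(reversed(control_ids)), test_id)
        assert ev1.call == ev2.call
        assert ev1.margin == pytest.approx(ev2.margin, abs=1e-9)

    def test_min_reference_sizes(self, panel):
        beta, case_ids, control_ids, _ = panel
        with pytest.raises(CohortSizeError):
            ep.cluster_assign(beta, case_ids[:2], control_ids, case_ids[0])

    def test_degenerate_signature_raises_separability(self):
        rng = np.random.default_rng(8)
        refs = 0.5 + rng.normal(0, 0.002, size=(30, 10))
        outlier = np.full((30, 1), 0.95)
        values = np.clip(np.column_stack([refs, outlier]), 0, 1)
        samples = [f"case{i}" for i in range(5)] \
            + [f"ctrl{i}" for i in range(5)] + ["far"]
        beta = make_beta(values, samples=samples)
        with pytest.raises(SeparabilityError):
            ep.cluster_assign(beta, samples[:5], samples[5:10], "far")
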