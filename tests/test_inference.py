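"""Coding, FDR, responders, marginal means and Steiger's Z oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest

import pupilpipe as pp
from pupilpipe.inference import (
    bh_adjust,
    bin_epochs,
    classify_responders,
    code_design,
    estimate_marginal_means,
    fit_main_model,
    fit_meta_models,
    fit_timecourse,
    steiger_z,
)
from pupilpipe.lmm import FitResult


def _tiny_tables():
    """Two participants, one trial per condition, hand-set metadata.

    [DERIVED] coding oracle: rating differences are 24-20=4 and 10-10=0;
    centered (mean 2) and divided by 100 they code to +0.02 and -0.02.
    Amplitudes 1, 3, 1, 3 have mean 2 and population SD 1, so they code to
    -1, +1, -1, +1.
    """
    trials = pd.DataFrame(
        {
            "participant": [0, 0, 1, 1],
            "condition": [pp.SHAM, pp.TAVNS, pp.SHAM, pp.TAVNS],
            "block": [0, 1, 2, 0],
            "trial_index": [0, 0, 0, 0],
            "excluded": [False, False, False, False],
            "max_dilation": [1.0, 2.0, 3.0, 4.0],
        }
    )
    meta = pd.DataFrame(
        {
            "participant": [0, 0, 1, 1],
            "condition": [pp.SHAM, pp.TAVNS, pp.SHAM, pp.TAVNS],
            "mean_rating": [20.0, 24.0, 10.0, 10.0],
            "amplitude_ma": [1.0, 3.0, 1.0, 3.0],
            "order_code": [-0.5, -0.5, 0.5, 0.5],
        }
    )
    return trials, meta


class TestCodeDesign:
    def test_worked_example(self):
        trials, meta = _tiny_tables()
        frame = code_design(trials, meta)
        by = frame.set_index(["participant", "condition"])
        assert by.loc[(0, pp.SHAM), "stimulation"] == -0.5
        assert by.loc[(0, pp.TAVNS), "stimulation"] == 0.5
        assert by.loc[(0, pp.SHAM), "rating_diff"] == pytest.approx(0.02)
        assert by.loc[(1, pp.TAVNS), "rating_diff"] == pytest.approx(-0.02)
        assert list(frame["block_code"]) == [0.0, 1.0, 2.0, 0.0]
        assert by.loc[(0, pp.SHAM), "amplitude_z"] == pytest.approx(-1.0)
        assert by.loc[(1, pp.TAVNS), "amplitude_z"] == pytest.approx(1.0)
        assert set(frame["order"]) == {-0.5, 0.5}

    def test_amplitude_z_standardized(self):
        trials, meta = _tiny_tables()
        frame = code_design(trials, meta)
        assert frame["amplitude_z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert frame["amplitude_z"].std(ddof=0) == pytest.approx(1.0)

    def test_excluded_trials_dropped(self):
        trials, meta = _tiny_tables()
        extra = trials.iloc[[0]].assign(trial_index=1, excluded=True)
        trials = pd.concat([trials, extra], ignore_index=True)
        frame = code_design(trials, meta)
        assert len(frame) == 4
        assert not frame["excluded"].any()

    def test_excluding_a_whole_condition_drops_the_participant(self):
        trials, meta = _tiny_tables()
        trials.loc[0, "excluded"] = True  # participant 0 loses its only sham
        with pytest.warns(UserWarning, match="missing a condition"):
            frame = code_design(trials, meta)
        assert set(frame["participant"]) == {1}

    def test_participant_missing_condition_dropped_with_warning(self):
        trials, meta = _tiny_tables()
        trials = trials[~((trials.participant == 1) & (trials.condition == pp.TAVNS))]
        with pytest.warns(UserWarning, match="missing a condition"):
            frame = code_design(trials, meta)
        assert set(frame["participant"]) == {0}


class TestBHAdjust:
    def test_worked_example(self):
        # [DERIVED] step-up: p_(i) * m / i = 0.04, 0.04, 0.04, 0.04
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_hand_coded_step_up(self, rng):
        def naive_bh(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), naive_bh(p), atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2])) == pytest.approx([0.2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([]))


class TestResponders:
    def test_classification_and_tie(self):
        table = pd.DataFrame(
            {
                "participant": [0, 0, 1, 1, 2, 2],
                "condition": [pp.SHAM, pp.TAVNS] * 3,
                "max_dilation": [1.0, 2.0, 3.0, 1.0, 2.0, 2.0],
                "excluded": [False] * 6,
            }
        )
        lab = classify_responders(table).set_index("participant")
        assert lab.loc[0, "responder"] == 1
        assert lab.loc[1, "responder"] == 0
        assert lab.loc[2, "responder"] == 0  # tie counts as non-responder

    def test_excluded_trials_ignored(self):
        table = pd.DataFrame(
            {
                "participant": [0, 0, 0],
                "condition": [pp.SHAM, pp.TAVNS, pp.TAVNS],
                "max_dilation": [1.0, 0.5, 9.0],
                "excluded": [False, False, True],
            }
        )
        lab = classify_responders(table)
        assert lab.loc[0, "responder"] == 0


def _toy_fit(beta, terms=None, cov=None):
    terms = terms or ["Intercept", "stimulation", "rating_diff", "stimulation:rating_diff"]
    beta = np.asarray(beta, float)
    cov = np.eye(len(terms)) if cov is None else np.asarray(cov, float)
    return FitResult(
        table=pd.DataFrame({"term": terms, "estimate": beta}),
        terms=terms,
        fe_params=beta,
        fe_cov=cov,
        cov_re=np.eye(1),
        scale=1.0,
        converged=True,
        singular=False,
        re_structure="correlated",
        df_method="satterthwaite",
        frame_means={"rating_diff": 0.0},
        frame_ranges={"rating_diff": (-0.1, 0.1)},
    )


class TestMarginalMeans:
    def test_contrast_algebra(self):
        # [DERIVED] with beta = [1, 2, 3, 4] the taVNS - sham contrast at
        # coded rating difference v is beta_stim + beta_int * v = 2 + 4 v
        fit = _toy_fit([1.0, 2.0, 3.0, 4.0])
        emm = estimate_marginal_means(fit, [-0.1, 0.0, 0.1])
        assert emm["contrast"].to_numpy() == pytest.approx([1.6, 2.0, 2.4])
        # predictions: 1 + 2 s + 3 v + 4 s v at s = -/+ 0.5
        assert emm.loc[1, "pred_sham"] == pytest.approx(0.0)
        assert emm.loc[1, "pred_tavns"] == pytest.approx(2.0)

    def test_zero_interaction_contrast_constant(self):
        fit = _toy_fit([1.0, 2.0, 3.0, 0.0])
        emm = estimate_marginal_means(fit, [-0.1, 0.05])
        assert emm["contrast"].to_numpy() == pytest.approx([2.0, 2.0])

    def test_delta_method_se_identity_cov(self):
        # contrast vector d = (0, 1, 0, v): with identity covariance the
        # SE is sqrt(1 + v^2)
        fit = _toy_fit([0.0, 0.0, 0.0, 0.0])
        emm = estimate_marginal_means(fit, [0.1])
        assert emm.loc[0, "contrast_se"] == pytest.approx(np.sqrt(1.0 + 0.01))

    def test_out_of_range_warns(self):
        fit = _toy_fit([0.0, 0.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="outside the observed range"):
            estimate_marginal_means(fit, [0.5])


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        z, p = steiger_z(0.4, 0.4, 0.3, 50)
        assert z == 0.0
        assert p == 1.0

    def test_sign_convention(self):
        z_pos, _ = steiger_z(0.6, 0.2, 0.1, 60)
        z_neg, _ = steiger_z(0.2, 0.6, 0.1, 60)
        assert z_pos > 0 > z_neg
        assert z_pos == pytest.approx(-z_neg)

    def test_worked_example(self):
        # [DERIVED] r1=0.5, r2=0.3, r12=0.2, n=103: rbar=0.4,
        # psi = 0.2*0.68 - 0.08*0.64 = 0.0848, sbar = 0.0848/0.84^2 =
        # 0.120181..., Z = (atanh(0.5)-atanh(0.3)) * sqrt(100/(2*0.879819))
        # = 1.8076, p = 0.0706
        z, p = steiger_z(0.5, 0.3, 0.2, 103)
        assert z == pytest.approx(1.8076, abs=2e-4)
        assert p == pytest.approx(0.0706, abs=2e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            steiger_z(1.0, 0.3, 0.2, 50)
        with pytest.raises(ValueError):
            steiger_z(0.5, 0.3, 0.2, 3)


@pytest.fixture(scope="module")
def fitted():
    design = pp.StudyDesign(n_participants=10)
    table, meta = pp.simulate_trial_table(
        design, pp.EffectSpec(seed=17, stimulation_effect=2.0)
    )
    frame = code_design(table, meta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_main_model(frame)
    return table, meta, fit


class TestModelsEndToEnd:
    def test_main_model_recovers_effect(self, fitted):
        _, _, fit = fitted
        assert fit.coef("stimulation") == pytest.approx(2.0, abs=1.0)
        assert set(fit.table["term"]) >= {"stimulation", "amplitude_z", "rating_diff"}

    def test_main_model_input_validation(self, fitted):
        table, meta, _ = fitted
        frame = code_design(table, meta)
        with pytest.raises(ValueError, match="participants"):
            fit_main_model(frame[frame.participant == 0])
        with pytest.raises(ValueError, match="conditions"):
            fit_main_model(frame[frame.condition == pp.SHAM])

    def test_meta_models_have_expected_keys(self, fitted):
        table, meta, _ = fitted
        labels = classify_responders(table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = fit_meta_models(meta, labels)
        assert set(fits) == {
            "amplitude_by_responder",
            "amplitude_by_order",
            "rating_by_responder",
            "rating_by_order",
        }
        f = fits["amplitude_by_responder"]
        assert {"stimulation", "responder", "stimulation:responder"} <= set(
            f.table["term"]
        )


class TestTimecourse:
    def test_bins_and_joint_fdr(self, small_design):
        from pupilpipe.trials import apply_exclusions, baseline_correct, segment

        e = pp.EffectSpec(seed=8, stimulation_effect=6.0)
        meta = pp.study_meta_table(small_design, e)
        groups = []
        for rec, _ in pp.simulate_study(small_design, e):
            eps = segment(pp.preprocess_recording(rec))
            for ep in eps:
                if not ep.excluded:
                    baseline_correct(ep)
            apply_exclusions(eps)
            groups.append(eps)
        binned = bin_epochs(groups, bin_ms=100.0)
        # 26 s of 100 ms bins per retained trial
        assert binned.groupby(
            ["participant", "condition", "block", "trial_index"]
        ).size().eq(260).all()
        sub = binned[binned.bin_time.isin([-0.5, 1.5])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tc = fit_timecourse(sub, meta, df_method="residual")
        assert set(tc["bin_time"]) == {-0.5, 1.5}
        mask = tc["term"] != "Intercept"
        # BH is joint across bins and terms: one common rank ordering
        np.testing.assert_allclose(
            tc.loc[mask, "p_fdr"].to_numpy(),
            bh_adjust(tc.loc[mask, "p"].to_numpy()),
        )
        assert not tc.loc[~mask, "significant"].any()
        sig = tc.loc[mask, "significant"].to_numpy()
        np.testing.assert_array_equal(sig, tc.loc[mask, "p_fdr"].to_numpy() < 0.05)
        # the stimulation estimate is large post-onset, near zero pre-onset
        stim = tc[(tc.term == "stimulation")].set_index("bin_time")
        assert stim.loc[1.5, "estimate"] > 3.0
        assert abs(stim.loc[-0.5, "estimate"]) < 2.0
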