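"""Behavioral curves, posterior predictive checks, recovery, mixed models."""

import numpy as np
import pandas as pd
import pytest

from nedpd import io as nio
from nedpd.cognitive_model import MODEL_SPECS, ParameterSet
from nedpd.evaluation import (
    empirical_curves,
    fit_behavioral_glmm,
    posterior_predictive,
    recovery_study,
)
from nedpd.inference import fit_model
from nedpd.synthetic_cohort import CohortConfig, generate_cohort, _shapes
from nedpd.cognitive_model import PARAM_BOUNDS
from nedpd.task_env import RandomPolicy, SessionConfig, run_session


def _hand_built_log():
    """Ten trials, two partners, with known per-bin tallies."""
    rows = []
    cum = 0
    seq = [
        # (partner, gs, id, newcomer, mine, theirs, prev)
        (0, 1, None, True, "C", "D", None),
        (0, 1, 1, False, "C", "C", "D"),
        (1, 2, None, True, "D", "C", None),
        (0, 2, 2, False, "C", "C", "C"),
        (1, 2, 2, False, "C", "D", "C"),
        (0, 2, 2, False, "D", "C", "C"),
        (1, 2, 2, False, "D", "D", "D"),
        (0, 2, 2, False, "C", "C", "C"),
        (1, 2, 2, False, "D", "D", "D"),
        (0, 2, 2, False, "C", "C", "C"),
    ]
    from nedpd.task_env import payoff
    for t, (pid, gs, idist, newc, mine, theirs, prev) in enumerate(seq):
        pay = payoff(mine, theirs)
        cum += pay
        rows.append({
            "participant_id": 0, "trial_index": t, "partner_id": pid,
            "group_size": gs, "interaction_distance": idist,
            "is_newcomer": newc, "is_switch_opportunity": False,
            "is_pause": False, "participant_choice": mine,
            "partner_choice": theirs, "partner_prev_choice": prev,
            "participant_payoff": pay, "cumulative_score": cum,
            "link_broken": False})
    return pd.DataFrame(rows)


class TestEmpiricalCurves:
    def test_all_cooperation_gives_unit_rates(self):
        df = _hand_built_log()
        df["participant_choice"] = "C"
        curves = empirical_curves(df, by="GS", n_boot=10)
        assert (curves.coop_rate == 1.0).all()

    def test_manual_tally_oracle(self):
        df = _hand_built_log()
        curves = empirical_curves(df, by="GS", n_boot=0).set_index("bin")
        # GS=1: trials 0-1, both C -> coop 1.0; GS=2: 8 trials, 4 C
        assert curves.loc[1.0, "coop_rate"] == 1.0
        assert curves.loc[2.0, "coop_rate"] == pytest.approx(4 / 8)
        # reciprocity defined on 8 trials; GS=1: trial 1 (C after D -> 0)
        assert curves.loc[1.0, "recip_rate"] == 0.0
        # GS=2 reciprocity over trials 3-9: matches on all but trial 5
        recip_gs2 = np.mean([1, 1, 0, 1, 1, 1, 1])
        assert curves.loc[2.0, "recip_rate"] == pytest.approx(recip_gs2)

    def test_first_encounters_excluded_from_reciprocity(self):
        df = _hand_built_log()
        curves = empirical_curves(df, by="ID", n_boot=0)
        # 10 trials, 2 first encounters -> 8 distance-defined trials
        assert curves.n_trials.sum() == 8

    def test_rejects_unknown_axis(self):
        with pytest.raises(ValueError):
            empirical_curves(_hand_built_log(), by="trial")

    def test_bootstrap_bands_bracket_the_rate(self, tiny_cohort):
        records, _, _ = tiny_cohort
        curves = empirical_curves(records, by="GS", n_boot=200, seed=1)
        ok = curves.dropna(subset=["coop_lo", "coop_hi"])
        assert ((ok.coop_lo <= ok.coop_rate + 1e-9)
                & (ok.coop_rate <= ok.coop_hi + 1e-9)).all()


@pytest.fixture(scope="module")
def small_fit():
    cfg = CohortConfig(n_participants=12, n_trials=180, rng_seed=13)
    records, truths = generate_cohort(cfg)
    fit = fit_model(records, "M3", chains=2, draws=800, warmup=400, seed=2,
                    refit_on_rhat=False)
    return records, truths, fit


class TestPosteriorPredictive:
    def test_predictions_track_choices_above_shuffled_null(self, small_fit):
        records, _, fit = small_fit
        res = posterior_predictive(fit, records, n_sim=4, seed=0)
        rs = res["per_participant"]["r"].dropna()
        assert rs.median() > 0.2
        # shuffled-choice null: same predictions, permuted outcomes
        rng = np.random.default_rng(0)
        null_rs = []
        from nedpd.cognitive_model import compute_latents
        pm = fit.participant_posterior_means().set_index("participant_id")
        for pid, g in records.groupby("participant_id"):
            row = pm.loc[pid]
            params = ParameterSet(V0C=row.V0C, VRD=row.VRD, VP=row.VP,
                                  alpha=row.alpha, k=row.k)
            lat = compute_latents(g.sort_values("trial_index"), params,
                                  MODEL_SPECS["M3"])
            y = (g.loc[~g.is_pause].sort_values("trial_index")
                 .participant_choice == "C").to_numpy(dtype=float)
            p = lat["p_coop"].to_numpy()
            y_shuf = rng.permutation(y)
            if y_shuf.std() > 0:
                null_rs.append(np.corrcoef(p, y_shuf)[0, 1])
        assert rs.median() > np.median(null_rs) + 0.2

    def test_ribbons_have_both_axes(self, small_fit):
        records, _, fit = small_fit
        res = posterior_predictive(fit, records, n_sim=3, seed=1)
        assert {"coop_mean", "recip_mean"} <= set(res["sim_curves_gs"].columns)
        assert len(res["sim_curves_id"]) > 0

    def test_rejects_unknown_participant(self, small_fit):
        records, _, fit = small_fit
        alien = records.copy()
        alien["participant_id"] = alien["participant_id"] + 100
        with pytest.raises(ValueError, match="absent"):
            posterior_predictive(fit, alien)


class TestRecovery:
    def test_shuffled_truths_destroy_correlation(self, small_fit):
        records, truths, fit = small_fit
        pm = fit.participant_posterior_means().set_index("participant_id")
        t = truths.set_index("participant_id").loc[pm.index]
        params = fit.free_names

        def mean_r(order):
            return np.mean([np.corrcoef(t[n].to_numpy()[order], pm[n])[0, 1]
                            for n in params])

        real = mean_r(np.arange(len(pm)))
        rng = np.random.default_rng(3)
        shuffled = [mean_r(rng.permutation(len(pm))) for _ in range(200)]
        assert real > np.percentile(shuffled, 97.5)

    def test_report_structure(self):
        cfg = CohortConfig(n_participants=4, n_trials=80, rng_seed=17)
        report = recovery_study(cfg, n_simulations=1, seed=5, chains=2,
                                draws=250, warmup=125, refit_on_rhat=False,
                                exclude_nonconverged=False)
        assert set(report.group_level.param) == set(
            MODEL_SPECS["M3"].free_parameters())
        assert report.group_level.covered.isin([True, False]).all()
        assert ((report.participant_level.r >= -1)
                & (report.participant_level.r <= 1)).all()


class TestBehavioralGlmm:
    def test_null_group_size_effect_covers_zero(self):
        # choices from a policy with no group-size dependence at all
        frames = []
        for pid in range(12):
            recs = run_session(SessionConfig(n_trials=120, rng_seed=pid),
                               RandomPolicy(0.6), participant_id=pid)
            frames.append(nio.records_to_frame(recs))
        records = pd.concat(frames, ignore_index=True)
        tab = fit_behavioral_glmm(records, 1).set_index("term")
        assert tab.loc["GS", "ci_lo"] < 0 < tab.loc["GS", "ci_hi"]

    def test_planted_group_size_effect_is_recovered(self):
        prior = dict(
            V0C=_shapes(0.5, PARAM_BOUNDS["V0C"], 8.0),
            VRD=_shapes(1.0, PARAM_BOUNDS["VRD"], 8.0),
            VGS=_shapes(2.0, PARAM_BOUNDS["VGS"], 20.0),
            VP=_shapes(1.0, PARAM_BOUNDS["VP"], 8.0),
            k=_shapes(0.638, PARAM_BOUNDS["k"], 8.0),
            alpha=_shapes(0.567, PARAM_BOUNDS["alpha"], 8.0),
        )
        cfg = CohortConfig(n_participants=15, n_trials=150,
                           spec=MODEL_SPECS["M6"], group_prior=prior,
                           rng_seed=19)
        records, _ = generate_cohort(cfg)
        tab = fit_behavioral_glmm(records, 1).set_index("term")
        assert tab.loc["GS", "estimate"] > 0
        assert tab.loc["GS", "p"] < 0.05

    def test_rt_structures_require_rt_column(self, tiny_cohort):
        records, _, _ = tiny_cohort
        with pytest.raises(ValueError, match="response times"):
            fit_behavioral_glmm(records, 5)

    def test_rt_structure_runs_with_rt_column(self, tiny_cohort):
        records, _, _ = tiny_cohort
        rng = np.random.default_rng(0)
        df = records.copy()
        df["rt"] = 700 + 30 * df["group_size"].astype(float) \
            + rng.normal(0, 50, len(df))
        tab = fit_behavioral_glmm(df, 5).set_index("term")
        assert tab.loc["GS", "estimate"] == pytest.approx(30, abs=10)
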