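"""Valuation/choice model: elementary ops, likelihood oracle, regressors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nedpd import io as nio
from nedpd._fastlik import CohortArrays, cohort_pointwise_loglik
from nedpd.cognitive_model import (
    MODEL_SPECS,
    ModelSpec,
    ParameterSet,
    choice_probability,
    compute_latents,
    cooperation_value,
    derive_regressors,
    memory_retention,
    prediction_update,
    prev_choice_probabilities,
    reciprocity_value,
    session_loglik,
    standardize_group_size,
    standardize_prediction,
)


class TestMemoryRetention:
    def test_perfect_memory(self):
        assert memory_retention(1.0, 7) == 1.0

    def test_no_memory(self):
        assert memory_retention(0.0, 3) == 0.0

    def test_fitted_decay_at_distance_two(self):
        assert memory_retention(0.638, 2) == pytest.approx(0.407, abs=5e-4)

    def test_rejects_distance_below_one(self):
        with pytest.raises(ValueError):
            memory_retention(0.5, 0)

    @given(k=st.floats(0.01, 0.99), d=st.integers(1, 20))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_distance(self, k, d):
        assert memory_retention(k, d + 1) < memory_retention(k, d)


class TestPrevChoiceProbabilities:
    def test_perfect_memory_of_cooperation(self):
        assert prev_choice_probabilities("C", 1.0) == (1.0, 0.0)

    def test_first_encounter_is_uninformative(self):
        assert prev_choice_probabilities(None, 0.0) == (0.5, 0.5)
        assert prev_choice_probabilities(None, 1.0) == (0.5, 0.5)

    def test_partial_memory_of_defection(self):
        p_c, p_d = prev_choice_probabilities("D", 0.638)
        assert p_d == pytest.approx(0.819, abs=1e-3)
        assert p_c == pytest.approx(0.181, abs=1e-3)

    @given(mr=st.floats(0.0, 1.0), prev=st.sampled_from(["C", "D"]))
    @settings(max_examples=50, deadline=None)
    def test_normalization_and_floor(self, mr, prev):
        p_c, p_d = prev_choice_probabilities(prev, mr)
        assert p_c + p_d == pytest.approx(1.0, abs=1e-12)
        p_true = p_c if prev == "C" else p_d
        assert p_true >= 0.5  # remembered choice never decays below chance


class TestReciprocityValue:
    def test_symmetric_cancellation(self):
        assert reciprocity_value(1.0, 1.0, 0.5, 0.5) == 0.0

    def test_fitted_group_means(self):
        p_c, p_d = prev_choice_probabilities("C", 0.638)
        assert reciprocity_value(1.0, 3.481, p_c, p_d) == pytest.approx(0.189, abs=1e-3)

    def test_memoryless_regime_is_constant(self, mid_params):
        # MR = 0 on every remembered trial: VR = (VRC - VRD) / 2 throughout
        p_c, p_d = prev_choice_probabilities("C", 0.0)
        vr_after_c = reciprocity_value(1.0, 3.481, p_c, p_d)
        p_c, p_d = prev_choice_probabilities("D", 0.0)
        vr_after_d = reciprocity_value(1.0, 3.481, p_c, p_d)
        assert vr_after_c == pytest.approx(vr_after_d)
        assert vr_after_c == pytest.approx(0.5 * (1.0 - 3.481))


class TestPredictionUpdate:
    def test_fitted_learning_rate(self):
        pred, pe = prediction_update(0.5, "C", 0.567)
        assert pe == 0.5
        assert pred == pytest.approx(0.7835)

    def test_no_learning(self):
        pred, _ = prediction_update(0.3, "C", 0.0)
        assert pred == 0.3

    def test_full_update_tracks_last_observation(self):
        pred = 0.5
        for obs in ["C", "D"] * 10:
            pred, _ = prediction_update(pred, obs, 1.0)
            assert pred == (1.0 if obs == "C" else 0.0)

    @given(pred=st.floats(0.0, 1.0), alpha=st.floats(0.0, 1.0),
           obs=st.sampled_from([0, 1]))
    @settings(max_examples=50, deadline=None)
    def test_update_stays_in_unit_interval(self, pred, alpha, obs):
        new, _ = prediction_update(pred, obs, alpha)
        assert 0.0 <= new <= 1.0


class TestChoiceProbability:
    def test_indifference(self):
        assert choice_probability(0.0) == 0.5

    def test_saturation(self):
        assert choice_probability(100.0) == pytest.approx(1.0, abs=1e-9)
        assert choice_probability(-100.0) == pytest.approx(0.0, abs=1e-9)

    def test_fitted_intrinsic_value(self):
        assert choice_probability(1.366) == pytest.approx(0.797, abs=1e-3)

    def test_strictly_increasing_in_value(self):
        vals = [choice_probability(v) for v in np.linspace(-5, 5, 41)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestCooperationValue:
    def test_constant_model(self):
        p = ParameterSet(V0C=2.0, VRD=0.5, VP=0.0, alpha=0.5, VRC=1.0)
        # zero reciprocity input and zero slopes leave only the intercept
        assert cooperation_value(p, MODEL_SPECS["M1"], 1.3, -0.7, 0.0) == 2.0

    def test_group_term_absent_without_group_effect(self, mid_params):
        with_gs = ParameterSet(V0C=1.366, VRD=3.481, VP=2.536, alpha=0.567,
                               k=0.638, VGS=2.0)
        v_m3 = cooperation_value(with_gs, MODEL_SPECS["M3"], 1.5, 0.2, 0.1)
        v_m6 = cooperation_value(with_gs, MODEL_SPECS["M6"], 1.5, 0.2, 0.1)
        assert v_m6 == pytest.approx(v_m3 + 2.0 * 1.5)


class TestNestedModelConsistency:
    def test_perfect_memory_equals_decay_at_k_one(self, tiny_cohort):
        records, _, _ = tiny_cohort
        g = records[records.participant_id == 0]
        p = ParameterSet(V0C=1.0, VRD=2.0, VP=1.5, alpha=0.6, k=1.0)
        ll_perfect, pw_perfect = session_loglik(g, p, MODEL_SPECS["M2"])
        ll_decay, pw_decay = session_loglik(g, p, MODEL_SPECS["M3"])
        np.testing.assert_allclose(pw_perfect, pw_decay, atol=1e-12)

    def test_absent_group_effect_equals_zero_weight(self, tiny_cohort):
        records, _, _ = tiny_cohort
        g = records[records.participant_id == 1]
        p = ParameterSet(V0C=1.0, VRD=2.0, VP=1.5, alpha=0.6, k=0.5, VGS=0.0)
        _, pw_m3 = session_loglik(g, p, MODEL_SPECS["M3"])
        _, pw_m6 = session_loglik(g, p, MODEL_SPECS["M6"])
        np.testing.assert_allclose(pw_m3, pw_m6, atol=1e-12)


def _brute_force_loglik(records: pd.DataFrame, p: ParameterSet,
                        spec: ModelSpec) -> np.ndarray:
    """Naive trial loop written independently of the library internals."""
    out = []
    preds: dict[int, float] = {}
    k = {"none": 0.0, "perfect": 1.0, "decay": p.k}[spec.memory]
    for row in records.sort_values("trial_index").itertuples():
        if row.is_pause:
            continue
        pid = int(row.partner_id)
        pred = preds.get(pid, 0.5)
        if pd.isna(row.interaction_distance):
            pc = 0.5
        else:
            mr = k ** int(row.interaction_distance)
            ptrue = 0.5 * mr + 0.5
            pc = ptrue if row.partner_prev_choice == "C" else 1.0 - ptrue
        vc = (p.V0C + (p.VRC * pc - p.VRD * (1.0 - pc))
              + p.VP * standardize_prediction(pred))
        if spec.group_effect:
            vc += p.VGS * standardize_group_size(row.group_size)
        prob = 1.0 / (1.0 + math.exp(-vc))
        y = row.participant_choice == "C"
        out.append(math.log(prob if y else 1.0 - prob))
        obs = 1.0 if row.partner_choice == "C" else 0.0
        preds[pid] = pred + p.alpha * (obs - pred)
    return np.array(out)


class TestSessionLoglik:
    def test_single_indifferent_trial(self):
        rec = nio.records_to_frame([])
        df = pd.DataFrame([{
            "participant_id": 0, "trial_index": 0, "partner_id": 0,
            "group_size": 1, "interaction_distance": None, "is_newcomer": True,
            "is_switch_opportunity": False, "is_pause": False,
            "participant_choice": "C", "partner_choice": "D",
            "partner_prev_choice": None, "participant_payoff": -30,
            "cumulative_score": -30, "link_broken": False}])
        p = ParameterSet(V0C=0.0, VRD=1.0, VP=0.0, alpha=0.5, VRC=1.0)
        total, pw = session_loglik(df, p, MODEL_SPECS["M2"])
        assert total == pytest.approx(math.log(0.5))

    def test_pointwise_sums_to_total(self, tiny_cohort, mid_params):
        records, _, _ = tiny_cohort
        g = records[records.participant_id == 2]
        total, pw = session_loglik(g, mid_params, MODEL_SPECS["M3"])
        assert total == pytest.approx(pw.sum(), abs=1e-10)

    @pytest.mark.parametrize("draw", range(10))
    def test_matches_independent_brute_force(self, tiny_cohort, draw, any_spec):
        records, _, _ = tiny_cohort
        rng = np.random.default_rng(100 + draw)
        p = ParameterSet(
            V0C=rng.uniform(-5, 5), VRD=rng.uniform(-5, 5),
            VGS=rng.uniform(-2, 2), VP=rng.uniform(-2, 2),
            k=rng.uniform(0.05, 0.95), alpha=rng.uniform(0.05, 0.95))
        g = records[records.participant_id == draw % 5]
        _, pw = session_loglik(g, p, any_spec)
        np.testing.assert_allclose(
            pw, _brute_force_loglik(g, p, any_spec), atol=1e-10)

    def test_compiled_kernel_matches_reference(self, tiny_cohort):
        records, _, _ = tiny_cohort
        data = CohortArrays.from_dataframe(records)
        rng = np.random.default_rng(0)
        for spec in (MODEL_SPECS["M3"], MODEL_SPECS["M6"]):
            params = {
                "V0C": rng.uniform(-5, 5, 5), "VRD": rng.uniform(-5, 5, 5),
                "VGS": rng.uniform(-2, 2, 5), "VP": rng.uniform(-2, 2, 5),
                "k": rng.uniform(0.05, 0.95, 5),
                "alpha": rng.uniform(0.05, 0.95, 5)}
            pw = cohort_pointwise_loglik(data, params, spec.group_effect)
            for i, pid in enumerate(data.participant_ids):
                ps = ParameterSet(**{n: params[n][i] for n in params})
                _, ref = session_loglik(
                    records[records.participant_id == pid], ps, spec)
                np.testing.assert_allclose(pw[i][data.valid[i]], ref, atol=1e-12)

    def test_rejects_unsorted_records(self, tiny_cohort, mid_params):
        records, _, _ = tiny_cohort
        g = records[records.participant_id == 0].iloc[::-1]
        with pytest.raises(ValueError):
            session_loglik(g, mid_params, MODEL_SPECS["M3"])


class TestDeriveRegressors:
    @pytest.fixture()
    def latents_and_records(self, tiny_cohort, mid_params):
        records, _, _ = tiny_cohort
        g = records[records.participant_id == 0].sort_values("trial_index")
        lat = compute_latents(g, mid_params, MODEL_SPECS["M3"])
        return g, lat, derive_regressors(g, lat)

    def test_betrayal_zero_after_partner_defection(self, latents_and_records):
        g, lat, reg = latents_and_records
        modeled = g[~g.is_pause].reset_index(drop=True)
        after_d = modeled.partner_prev_choice == "D"
        assert (reg.loc[after_d.to_numpy(), "NRbarB"] == 0.0).all()

    def test_forgiveness_zero_after_partner_cooperation(self, latents_and_records):
        g, lat, reg = latents_and_records
        modeled = g[~g.is_pause].reset_index(drop=True)
        after_c = modeled.partner_prev_choice == "C"
        assert (reg.loc[after_c.to_numpy(), "NRbarF"] == 0.0).all()

    def test_signed_reciprocity_value(self, latents_and_records):
        g, lat, reg = latents_and_records
        modeled = g[~g.is_pause].reset_index(drop=True)
        after_c = (modeled.partner_prev_choice == "C").to_numpy()
        after_d = (modeled.partner_prev_choice == "D").to_numpy()
        vc = lat["VC"].to_numpy()
        np.testing.assert_allclose(reg.loc[after_c, "Rbar"], vc[after_c])
        np.testing.assert_allclose(reg.loc[after_d, "Rbar"], -vc[after_d])

    def test_first_encounters_are_missing(self, latents_and_records):
        g, lat, reg = latents_and_records
        modeled = g[~g.is_pause].reset_index(drop=True)
        first = modeled.partner_prev_choice.isna().to_numpy()
        assert reg.loc[first, "Rbar"].isna().all()
        assert reg.loc[first, "CG"].isna().all()

    def test_congruence_matches_social_tendency(self, latents_and_records):
        g, lat, reg = latents_and_records
        modeled = g[~g.is_pause].reset_index(drop=True)
        st_val = reg["ST"].iloc[0]
        coop_frac = (modeled.participant_choice == "C").mean()
        assert st_val == (1 if coop_frac > 0.5 else 0)
        prev_c = modeled.partner_prev_choice == "C"
        defined = modeled.partner_prev_choice.notna()
        expect = (prev_c.astype(int) == st_val).astype(float)
        np.testing.assert_allclose(
            reg.loc[defined.to_numpy(), "CG"],
            expect[defined].to_numpy())

    def test_distance_binarization(self, latents_and_records):
        g, lat, reg = latents_and_records
        modeled = g[~g.is_pause].reset_index(drop=True)
        idist = modeled.interaction_distance.astype(float)
        short = (idist == 1).to_numpy()
        longd = (idist > 1).to_numpy()
        assert (reg.loc[short, "ID_binary"] == "short").all()
        assert (reg.loc[longd, "ID_binary"] == "long").all()
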