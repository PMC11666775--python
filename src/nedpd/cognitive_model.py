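"""Trial-wise valuation/choice model with exponential memory decay.

On every trial the latent value of cooperating is

    V_t^C = V_0^C + V_t^R + V_t^GS + V_t^P

where ``V_0^C`` is the intrinsic (social-tendency) value of cooperation,
``V_t^R`` the reciprocity value, ``V_t^GS`` a linear group-size term and
``V_t^P`` a linear term in the delta-rule prediction of the partner's
cooperation.  Memory of the current partner's previous choice decays
exponentially with interaction distance, ``MR_t = k^ID``, and is mapped to a
subjective probability that never falls below 0.5 for the true choice:
``p(true) = 0.5*MR + 0.5``.  Defection has fixed value 0, so the choice rule
is a logistic in V_t^C (inverse temperature fixed to 1).

Six model variants cross a group-size effect (absent/present) with a memory
regime (none: k=0, perfect: k=1, decay: k free).

Linear predictors (group size and the cooperation prediction) enter the
value function standardized with fixed reference moments rather than
per-session empirical moments, so that exactly the same transform applies
when the model generates behavior forward and when it is fitted to data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .task_env import COOPERATE, DEFECT, ParticipantPolicy, TrialContext

__all__ = [
    "PARAM_BOUNDS",
    "FIXED_PARAMS",
    "ParameterSet",
    "ModelSpec",
    "MODEL_SPECS",
    "memory_retention",
    "prev_choice_probabilities",
    "reciprocity_value",
    "prediction_update",
    "cooperation_value",
    "choice_probability",
    "compute_latents",
    "session_loglik",
    "derive_regressors",
    "ModelAgent",
    "standardize_group_size",
    "standardize_prediction",
]

# Parameter ranges (native space); VRC and tau are fixed for identifiability.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "V0C": (-10.0, 10.0),
    "VRD": (-10.0, 10.0),
    "VGS": (-5.0, 5.0),
    "VP": (-5.0, 5.0),
    "k": (0.0, 1.0),
    "alpha": (0.0, 1.0),
}
FIXED_PARAMS: dict[str, float] = {"VRC": 1.0, "tau": 1.0}

# Fixed reference moments for predictor standardization (see module
# docstring).  GS moments approximate the stationary group-size distribution
# of the default environment; the prediction is centred at its 0.5 prior.
GS_REF_MEAN = 3.0
GS_REF_SD = 1.4
PRED_REF_MEAN = 0.5
PRED_REF_SD = 0.25

PRED_INIT = 0.5
_PCLIP = 1e-12


def standardize_group_size(gs):
    return (np.asarray(gs, dtype=float) - GS_REF_MEAN) / GS_REF_SD


def standardize_prediction(pred):
    return (np.asarray(pred, dtype=float) - PRED_REF_MEAN) / PRED_REF_SD


@dataclass(frozen=True)
class ModelSpec:
    """A point in the 2x3 factorial model space (group effect x memory)."""

    group_effect: bool
    memory: str  # "none" | "perfect" | "decay"

    def __post_init__(self) -> None:
        if self.memory not in ("none", "perfect", "decay"):
            raise ValueError(f"unknown memory regime {self.memory!r}")

    @property
    def name(self) -> str:
        order = {("none", False): "M1", ("perfect", False): "M2",
                 ("decay", False): "M3", ("none", True): "M4",
                 ("perfect", True): "M5", ("decay", True): "M6"}
        return order[(self.memory, self.group_effect)]

    def effective_k(self, k: float) -> float:
        if self.memory == "none":
            return 0.0
        if self.memory == "perfect":
            return 1.0
        return k

    def free_parameters(self) -> list[str]:
        names = ["V0C", "VRD", "VP", "alpha"]
        if self.group_effect:
            names.insert(2, "VGS")
        if self.memory == "decay":
            names.append("k")
        return names


MODEL_SPECS: dict[str, ModelSpec] = {
    "M1": ModelSpec(group_effect=False, memory="none"),
    "M2": ModelSpec(group_effect=False, memory="perfect"),
    "M3": ModelSpec(group_effect=False, memory="decay"),
    "M4": ModelSpec(group_effect=True, memory="none"),
    "M5": ModelSpec(group_effect=True, memory="perfect"),
    "M6": ModelSpec(group_effect=True, memory="decay"),
}


@dataclass(frozen=True)
class ParameterSet:
    """One participant's model parameters (native space).

    ``VRC`` and ``tau`` are fixed to 1 for identifiability; the others are
    free within :data:`PARAM_BOUNDS` (``k`` and ``alpha`` admit their closed
    endpoints, which the fixed-memory regimes use).
    """

    V0C: float
    VRD: float
    VP: float
    alpha: float
    k: float = 0.5
    VGS: float = 0.0
    VRC: float = field(default=FIXED_PARAMS["VRC"])
    tau: float = field(default=FIXED_PARAMS["tau"])

    def __post_init__(self) -> None:
        for name in ("V0C", "VRD", "VGS", "VP"):
            lb, ub = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not (lb < v < ub):
                raise ValueError(f"{name}={v} outside ({lb}, {ub})")
        for name in ("k", "alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in
                ("V0C", "VRD", "VGS", "VP", "k", "alpha", "VRC", "tau")}


# ---------------------------------------------------------------------------
# Elementary operations


def memory_retention(k: float, interaction_distance: int) -> float:
    """MR = k^ID: fidelity of the memory of the partner's previous choice."""
    if interaction_distance < 1 or int(interaction_distance) != interaction_distance:
        raise ValueError(f"interaction distance must be an integer >= 1, got "
                         f"{interaction_distance}")
    if not (0.0 <= k <= 1.0):
        raise ValueError(f"k must lie in [0, 1], got {k}")
    return float(k) ** int(interaction_distance)


def prev_choice_probabilities(prev_choice: Optional[str], mr: float
                              ) -> tuple[float, float]:
    """(p_C, p_D) for the partner's previous choice given memory retention.

    The remembered (true) choice gets ``0.5*MR + 0.5``; the probability of
    the true choice never decays below 0.5.  With no previous encounter both
    probabilities are 0.5.
    """
    if prev_choice is None:
        return 0.5, 0.5
    p_true = 0.5 * (mr - 1.0) + 1.0
    if prev_choice == COOPERATE:
        return p_true, 1.0 - p_true
    if prev_choice == DEFECT:
        return 1.0 - p_true, p_true
    raise ValueError(f"invalid previous choice {prev_choice!r}")


def reciprocity_value(vrc: float, vrd: float, p_c: float, p_d: float) -> float:
    """V^R = V^RC * p(C) - V^RD * p(D)."""
    return vrc * p_c - vrd * p_d


def prediction_update(pred: float, observed, alpha: float
                      ) -> tuple[float, float]:
    """Delta-rule update of the partner-cooperation estimate.

    ``observed`` may be "C"/"D" or 1/0.  Returns (updated estimate, PE).
    """
    if isinstance(observed, str):
        obs = 1.0 if observed == COOPERATE else 0.0
    else:
        obs = float(observed)
    pe = obs - pred
    return pred + alpha * pe, pe


def cooperation_value(params: ParameterSet, spec: ModelSpec,
                      z_gs: float, z_pred: float, vr: float) -> float:
    """V^C = V0C + V^R + [VGS * z(GS)] + VP * z(pred)."""
    vc = params.V0C + vr + params.VP * z_pred
    if spec.group_effect:
        vc += params.VGS * z_gs
    return vc


def choice_probability(vc: float, tau: float = 1.0) -> float:
    """Logistic choice rule against a defection value fixed at 0."""
    x = tau * vc
    if x >= 0:
        p = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        p = e / (1.0 + e)
    return min(1.0 - _PCLIP, max(_PCLIP, p))


# ---------------------------------------------------------------------------
# Session-level computation


def _check_session(records: pd.DataFrame) -> pd.DataFrame:
    if records["participant_id"].nunique() > 1:
        raise ValueError("expected records of a single participant")
    t = records["trial_index"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("records must be sorted by trial_index")
    return records


def compute_latents(records: pd.DataFrame, params: ParameterSet,
                    spec: ModelSpec) -> pd.DataFrame:
    """Per-trial latent quantities of the model for one participant.

    ``records`` is a trial-record table (one participant, sorted by trial);
    pause slots are skipped.  Returns one row per modeled trial with columns
    MR, pC, pD, VR, VGS_t, VP_t, pred, PE, VC, p_coop, F (forgetting
    ``1 - k^ID``; NaN with MR on first encounters where ID is undefined).
    """
    _check_session(records)
    k = spec.effective_k(params.k)
    preds: dict[int, float] = {}
    rows = []
    for rec in records.itertuples(index=False):
        if rec.is_pause:
            continue
        pid = int(rec.partner_id)
        pred = preds.get(pid, PRED_INIT)
        idist = rec.interaction_distance
        first = pd.isna(idist)
        prev = None if (rec.partner_prev_choice is None
                        or (isinstance(rec.partner_prev_choice, float)
                            and pd.isna(rec.partner_prev_choice))) \
            else rec.partner_prev_choice
        if first:
            mr = math.nan
            p_c, p_d = 0.5, 0.5
        else:
            mr = memory_retention(k, int(idist))
            p_c, p_d = prev_choice_probabilities(prev, mr)
        vr = reciprocity_value(params.VRC, params.VRD, p_c, p_d)
        z_gs = float(standardize_group_size(rec.group_size))
        z_pred = float(standardize_prediction(pred))
        vc = cooperation_value(params, spec, z_gs, z_pred, vr)
        p_coop = choice_probability(vc, params.tau)
        obs = 1.0 if rec.partner_choice == COOPERATE else 0.0
        new_pred, pe = prediction_update(pred, obs, params.alpha)
        preds[pid] = new_pred
        rows.append({
            "trial_index": rec.trial_index,
            "partner_id": pid,
            "MR": mr,
            "pC": p_c,
            "pD": p_d,
            "VR": vr,
            "VGS_t": params.VGS * z_gs if spec.group_effect else 0.0,
            "VP_t": params.VP * z_pred,
            "pred": pred,
            "PE": pe,
            "VC": vc,
            "p_coop": p_coop,
            "F": math.nan if first else 1.0 - mr,
        })
    return pd.DataFrame(rows)


def session_loglik(records: pd.DataFrame, params: ParameterSet,
                   spec: ModelSpec) -> tuple[float, np.ndarray]:
    """Bernoulli log-likelihood of one participant's choices under the model.

    Returns (total, pointwise vector over modeled trials).  This is the
    readable reference path; inference uses a numerically identical compiled
    kernel (see ``nedpd._fastlik``).
    """
    latents = compute_latents(records, params, spec)
    modeled = records.loc[~records["is_pause"].astype(bool)]
    if len(modeled) != len(latents):
        raise ValueError("latents/records length mismatch")
    choices = (modeled["participant_choice"] == COOPERATE).to_numpy()
    vc = latents["VC"].to_numpy()
    # stable log-logistic: log p(C) = -log1p(exp(-VC)), log p(D) = -log1p(exp(VC))
    x = np.where(choices, vc, -vc)
    pointwise = -np.log1p(np.exp(-np.abs(x))) + np.where(x < 0, x, 0.0)
    return float(pointwise.sum()), pointwise


# ---------------------------------------------------------------------------
# Derived trial-wise regressors


def derive_regressors(records: pd.DataFrame, latents: pd.DataFrame
                      ) -> pd.DataFrame:
    """Trial-wise derived regressors under a fitted model.

    Adds the signed integrated reciprocity value (Rbar), forgiveness and
    betrayal values (NRbarF / NRbarB), the participant's binary social
    tendency (ST: cooperates on more than half of all trials), congruence of
    ST with the partner's previous choice (CG), and a short/long interaction
    distance split (ID = 1 vs ID > 1).  Regressors that condition on the
    partner's previous choice are missing (NaN) on first encounters.
    """
    modeled = records.loc[~records["is_pause"].astype(bool)].reset_index(drop=True)
    if len(modeled) != len(latents):
        raise ValueError("latents must align with the non-pause records")
    coop_frac = float((modeled["participant_choice"] == COOPERATE).mean())
    st = 1 if coop_frac > 0.5 else 0
    vc = latents["VC"].to_numpy()
    prev = modeled["partner_prev_choice"]
    prev_c = (prev == COOPERATE).to_numpy()
    prev_d = (prev == DEFECT).to_numpy()
    defined = prev_c | prev_d

    rbar = np.where(prev_c, vc, np.where(prev_d, -vc, np.nan))
    nrbar_f = np.where(prev_d, vc, np.where(prev_c, 0.0, np.nan))
    nrbar_b = np.where(prev_c, -vc, np.where(prev_d, 0.0, np.nan))
    prev_code = np.where(prev_c, 1.0, np.where(prev_d, 0.0, np.nan))
    cg = np.where(defined, (prev_code == st).astype(float), np.nan)
    idist = modeled["interaction_distance"].astype(float).to_numpy()
    id_binary = np.where(np.isnan(idist), None,
                         np.where(idist == 1, "short", "long"))
    return pd.DataFrame({
        "trial_index": modeled["trial_index"],
        "Rbar": rbar,
        "NRbarF": nrbar_f,
        "NRbarB": nrbar_b,
        "ST": st,
        "CG": cg,
        "ID_binary": id_binary,
    })


# ---------------------------------------------------------------------------
# Generative agent (the model as a participant policy)


class ModelAgent(ParticipantPolicy):
    """Participant policy that chooses by the valuation/choice model.

    Used by the synthetic-cohort generator and for posterior predictive
    simulation, so generation and likelihood evaluation share one code path
    through the same elementary operations.
    """

    def __init__(self, params: ParameterSet, spec: ModelSpec,
                 rng: Optional[np.random.Generator] = None):
        self.params = params
        self.spec = spec
        self._preds: dict[int, float] = {}

    def coop_probability(self, ctx: TrialContext) -> float:
        k = self.spec.effective_k(self.params.k)
        pred = self._preds.get(ctx.partner_id, PRED_INIT)
        if ctx.interaction_distance is None:
            p_c, p_d = 0.5, 0.5
        else:
            mr = memory_retention(k, ctx.interaction_distance)
            p_c, p_d = prev_choice_probabilities(ctx.partner_prev_choice, mr)
        vr = reciprocity_value(self.params.VRC, self.params.VRD, p_c, p_d)
        vc = cooperation_value(
            self.params, self.spec,
            float(standardize_group_size(ctx.group_size)),
            float(standardize_prediction(pred)), vr)
        return choice_probability(vc, self.params.tau)

    def choose(self, ctx: TrialContext, rng: np.random.Generator) -> str:
        return COOPERATE if rng.random() < self.coop_probability(ctx) else DEFECT

    def observe(self, ctx: TrialContext, participant_choice: str,
                partner_choice: str, payoff_value: int) -> None:
        pred = self._preds.get(ctx.partner_id, PRED_INIT)
        new_pred, _ = prediction_update(pred, partner_choice, self.params.alpha)
        self._preds[ctx.partner_id] = new_pred
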