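"""Compiled fast path for the cohort likelihood.

The MCMC sampler evaluates the Bernoulli log-likelihood of every
participant's choice sequence tens of thousands of times; this module
provides a numba kernel that computes the full pointwise log-likelihood
matrix for a whole cohort in one call.  It must stay numerically identical
to :func:`nedpd.cognitive_model.session_loglik` (asserted by tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .cognitive_model import (
    COOPERATE,
    GS_REF_MEAN,
    GS_REF_SD,
    PRED_INIT,
    PRED_REF_MEAN,
    PRED_REF_SD,
)

__all__ = ["CohortArrays", "cohort_pointwise_loglik"]


@dataclass
class CohortArrays:
    """Dense (participants x trials) arrays of modeled (non-pause) trials."""

    participant_ids: np.ndarray      # (P,)
    prev_code: np.ndarray            # (P, T) int8: -1 none, 0 D, 1 C
    idist: np.ndarray                # (P, T) int32 (0 where undefined)
    partner_local: np.ndarray        # (P, T) int32 dense per-participant ids
    obs: np.ndarray                  # (P, T) int8 partner choice (C=1)
    choice: np.ndarray               # (P, T) int8 participant choice (C=1)
    z_gs: np.ndarray                 # (P, T) float64 standardized group size
    valid: np.ndarray                # (P, T) bool
    n_partners_max: int

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_obs(self) -> int:
        return int(self.valid.sum())

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame) -> "CohortArrays":
        df = records.loc[~records["is_pause"].astype(bool)]
        pids = np.sort(df["participant_id"].unique())
        groups = [df.loc[df["participant_id"] == p].sort_values("trial_index")
                  for p in pids]
        T = max(len(g) for g in groups)
        P = len(groups)
        prev_code = np.full((P, T), -1, dtype=np.int8)
        idist = np.zeros((P, T), dtype=np.int32)
        partner_local = np.zeros((P, T), dtype=np.int32)
        obs = np.zeros((P, T), dtype=np.int8)
        choice = np.zeros((P, T), dtype=np.int8)
        z_gs = np.zeros((P, T), dtype=np.float64)
        valid = np.zeros((P, T), dtype=bool)
        n_partners_max = 1
        for i, g in enumerate(groups):
            n = len(g)
            local: dict[int, int] = {}
            pl = np.empty(n, dtype=np.int32)
            for j, pid in enumerate(g["partner_id"].to_numpy()):
                pl[j] = local.setdefault(int(pid), len(local))
            n_partners_max = max(n_partners_max, len(local))
            partner_local[i, :n] = pl
            prev = g["partner_prev_choice"]
            prev_code[i, :n] = np.where(
                prev.isna(), -1, (prev == COOPERATE).astype(int)).astype(np.int8)
            d = pd.to_numeric(g["interaction_distance"], errors="coerce")
            idist[i, :n] = d.fillna(0).astype(int).to_numpy()
            obs[i, :n] = (g["partner_choice"] == COOPERATE).to_numpy()
            choice[i, :n] = (g["participant_choice"] == COOPERATE).to_numpy()
            z_gs[i, :n] = (g["group_size"].to_numpy(dtype=float)
                           - GS_REF_MEAN) / GS_REF_SD
            valid[i, :n] = True
        return cls(participant_ids=pids, prev_code=prev_code, idist=idist,
                   partner_local=partner_local, obs=obs, choice=choice,
                   z_gs=z_gs, valid=valid, n_partners_max=n_partners_max)

    def flatten(self, pointwise: np.ndarray) -> np.ndarray:
        """(P, T) matrix -> participant-major vector over valid trials."""
        return pointwise[self.valid]


@njit(cache=True)
def _kernel(v0c, vrd, vgs, vp, k, alpha, prev_code, idist, partner_local,
            obs, choice, z_gs, valid, n_partners_max, group_on,
            pred_init, pred_mean, pred_sd, out):  # pragma: no cover - compiled
    P, T = choice.shape
    for i in range(P):
        preds = np.full(n_partners_max, pred_init)
        for t in range(T):
            if not valid[i, t]:
                out[i, t] = 0.0
                continue
            j = partner_local[i, t]
            pred = preds[j]
            if prev_code[i, t] >= 0:
                mr = k[i] ** idist[i, t]
                p_true = 0.5 * mr + 0.5
                p_c = p_true if prev_code[i, t] == 1 else 1.0 - p_true
            else:
                p_c = 0.5
            vr = p_c - vrd[i] * (1.0 - p_c)  # VRC fixed to 1
            vc = v0c[i] + vr + vp[i] * (pred - pred_mean) / pred_sd
            if group_on:
                vc = vc + vgs[i] * z_gs[i, t]
            x = vc if choice[i, t] == 1 else -vc
            if x < 0.0:
                out[i, t] = x - np.log1p(np.exp(x))
            else:
                out[i, t] = -np.log1p(np.exp(-x))
            preds[j] = pred + alpha[i] * (obs[i, t] - pred)


@njit(cache=True)
def _kernel_grad(v0c, vrd, vgs, vp, k, alpha, prev_code, idist, partner_local,
                 obs, choice, z_gs, valid, n_partners_max, group_on,
                 pred_init, pred_mean, pred_sd, out, grad):  # pragma: no cover
    """Pointwise log-likelihood plus its gradient in the native parameters.

    ``grad`` has shape (P, 6) ordered (V0C, VRD, VGS, VP, k, alpha).  The
    learning-rate gradient propagates through the delta-rule recursion by
    forward accumulation: d pred'/d alpha = (1-alpha) d pred/d alpha +
    (obs - pred).
    """
    P, T = choice.shape
    for i in range(P):
        preds = np.full(n_partners_max, pred_init)
        dpreds = np.zeros(n_partners_max)
        for t in range(T):
            if not valid[i, t]:
                out[i, t] = 0.0
                continue
            j = partner_local[i, t]
            pred = preds[j]
            dpc_dk = 0.0
            if prev_code[i, t] >= 0:
                d = idist[i, t]
                mr = k[i] ** d
                dmr = d * k[i] ** (d - 1)
                p_true = 0.5 * mr + 0.5
                if prev_code[i, t] == 1:
                    p_c = p_true
                    dpc_dk = 0.5 * dmr
                else:
                    p_c = 1.0 - p_true
                    dpc_dk = -0.5 * dmr
            else:
                p_c = 0.5
            vr = p_c - vrd[i] * (1.0 - p_c)
            zp = (pred - pred_mean) / pred_sd
            vc = v0c[i] + vr + vp[i] * zp
            if group_on:
                vc = vc + vgs[i] * z_gs[i, t]
            x = vc if choice[i, t] == 1 else -vc
            if x < 0.0:
                out[i, t] = x - np.log1p(np.exp(x))
            else:
                out[i, t] = -np.log1p(np.exp(-x))
            # d loglik / d VC = y - sigmoid(VC)
            if vc < 0.0:
                p_coop = np.exp(vc) / (1.0 + np.exp(vc))
            else:
                p_coop = 1.0 / (1.0 + np.exp(-vc))
            resid = (1.0 if choice[i, t] == 1 else 0.0) - p_coop
            grad[i, 0] += resid
            grad[i, 1] += resid * (-(1.0 - p_c))
            if group_on:
                grad[i, 2] += resid * z_gs[i, t]
            grad[i, 3] += resid * zp
            grad[i, 4] += resid * (1.0 + vrd[i]) * dpc_dk
            grad[i, 5] += resid * vp[i] / pred_sd * dpreds[j]
            dpreds[j] = (1.0 - alpha[i]) * dpreds[j] + (obs[i, t] - pred)
            preds[j] = pred + alpha[i] * (obs[i, t] - pred)


def cohort_loglik_grad(data: CohortArrays, params: dict[str, np.ndarray],
                       group_on: bool) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise log-likelihood (P, T) and its native-space gradient (P, 6).

    Gradient columns are ordered (V0C, VRD, VGS, VP, k, alpha) and hold the
    derivative of each participant's summed log-likelihood.
    """
    P, T = data.choice.shape
    out = np.empty((P, T), dtype=np.float64)
    grad = np.zeros((P, 6), dtype=np.float64)
    _kernel_grad(
        np.ascontiguousarray(params["V0C"], dtype=np.float64),
        np.ascontiguousarray(params["VRD"], dtype=np.float64),
        np.ascontiguousarray(params["VGS"], dtype=np.float64),
        np.ascontiguousarray(params["VP"], dtype=np.float64),
        np.ascontiguousarray(params["k"], dtype=np.float64),
        np.ascontiguousarray(params["alpha"], dtype=np.float64),
        data.prev_code, data.idist, data.partner_local, data.obs,
        data.choice, data.z_gs, data.valid, data.n_partners_max,
        group_on, PRED_INIT, PRED_REF_MEAN, PRED_REF_SD, out, grad,
    )
    return out, grad


def cohort_pointwise_loglik(data: CohortArrays, params: dict[str, np.ndarray],
                            group_on: bool) -> np.ndarray:
    """Pointwise log-likelihood matrix (P, T) for per-participant parameters.

    ``params`` maps names to (P,) vectors; ``k`` must already reflect the
    memory regime (0, 1, or the free value).  Entries outside ``valid`` are 0.
    """
    P, T = data.choice.shape
    out = np.empty((P, T), dtype=np.float64)
    _kernel(
        np.ascontiguousarray(params["V0C"], dtype=np.float64),
        np.ascontiguousarray(params["VRD"], dtype=np.float64),
        np.ascontiguousarray(params["VGS"], dtype=np.float64),
        np.ascontiguousarray(params["VP"], dtype=np.float64),
        np.ascontiguousarray(params["k"], dtype=np.float64),
        np.ascontiguousarray(params["alpha"], dtype=np.float64),
        data.prev_code, data.idist, data.partner_local, data.obs,
        data.choice, data.z_gs, data.valid, data.n_partners_max,
        group_on, PRED_INIT, PRED_REF_MEAN, PRED_REF_SD, out,
    )
    return out
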