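"""Behavioral summaries, posterior predictive checks, parameter recovery.

Cooperation is the fraction of C choices; reciprocity is the fraction of
trials on which the participant repeats the current partner's previous
choice (undefined, and excluded, on first encounters).  Curve confidence
bands are nonparametric bootstraps over participants.  The recovery study
simulates cohorts with known truths through the task environment, refits
the generating model and scores highest-density-interval coverage of the
group-level means plus truth/estimate correlations at the participant
level.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cognitive_model import (
    COOPERATE,
    PARAM_BOUNDS,
    ModelAgent,
    ModelSpec,
    ParameterSet,
    compute_latents,
)
from .inference import FitResult, fit_model, group_mean, hdi
from .synthetic_cohort import CohortConfig, generate_cohort, sample_parameters
from .task_env import SessionConfig, run_session
from . import io as nio

__all__ = [
    "empirical_curves",
    "posterior_predictive",
    "RecoveryReport",
    "recovery_study",
    "fit_behavioral_glmm",
    "GLMM_STRUCTURES",
]

DEFAULT_ID_BINS = (0, 1, 2, 3, 5, 8, np.inf)
N_BOOTSTRAP = 1000


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    m = records.loc[~records["is_pause"].astype(bool)].copy()
    m["coop"] = (m["participant_choice"] == COOPERATE).astype(float)
    m["recip"] = np.where(
        m["partner_prev_choice"].isna(), np.nan,
        (m["participant_choice"] == m["partner_prev_choice"]).astype(float))
    return m


def empirical_curves(records: pd.DataFrame, by: str = "GS",
                     id_bins: Sequence[float] = DEFAULT_ID_BINS,
                     n_boot: int = N_BOOTSTRAP,
                     seed: int = 0) -> pd.DataFrame:
    """Cooperation and reciprocity rates by group size or distance bin.

    Returns one row per bin with trial counts, pooled rates and bootstrap
    (over participants) 95% intervals.  Empty bins are omitted.
    """
    if by not in ("GS", "ID"):
        raise ValueError("by must be 'GS' or 'ID'")
    m = _prepare(records)
    if by == "GS":
        m["bin"] = m["group_size"].astype(float)
    else:
        idist = m["interaction_distance"].astype(float)
        m = m.loc[idist.notna()].copy()
        labels = [f"{int(lo) + 1}" if hi - lo == 1 else
                  (f"{int(lo) + 1}-{int(hi)}" if np.isfinite(hi) else f"{int(lo) + 1}+")
                  for lo, hi in zip(id_bins[:-1], id_bins[1:])]
        m["bin"] = pd.cut(m["interaction_distance"].astype(float),
                          list(id_bins), labels=labels)

    rng = np.random.default_rng(seed)
    pids = m["participant_id"].unique()
    rows = []
    for b, g in m.groupby("bin", observed=True):
        if not len(g):
            continue
        boot_c, boot_r = [], []
        by_pid = {p: gg for p, gg in g.groupby("participant_id")}
        for _ in range(n_boot):
            sel = rng.choice(pids, size=len(pids), replace=True)
            frames = [by_pid[p] for p in sel if p in by_pid]
            if not frames:
                continue
            gg = pd.concat(frames)
            boot_c.append(gg["coop"].mean())
            boot_r.append(gg["recip"].mean())
        c_lo, c_hi = np.nanpercentile(boot_c, [2.5, 97.5]) if boot_c else (np.nan,) * 2
        r_lo, r_hi = np.nanpercentile(boot_r, [2.5, 97.5]) if boot_r else (np.nan,) * 2
        rows.append({
            "bin": b, "n_trials": len(g),
            "coop_rate": g["coop"].mean(),
            "coop_lo": c_lo, "coop_hi": c_hi,
            "recip_rate": g["recip"].mean(),
            "recip_lo": r_lo, "recip_hi": r_hi,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Posterior predictive


def posterior_predictive(fit: FitResult, records: pd.DataFrame,
                         n_sim: int = 20, seed: int = 0) -> dict:
    """Model predictions against observed choices, plus simulated ribbons.

    Per participant: the Pearson correlation between the trial-wise
    predicted cooperation probability (at the participant's posterior-mean
    parameters) and the 0/1 choices; missing when the choice sequence is
    constant.  Cohort level: fresh sessions simulated from posterior draws
    through the task environment (the same code path that generates data),
    summarized as cooperation/reciprocity curves with 95% ribbons.
    """
    pm = fit.participant_posterior_means().set_index("participant_id")
    missing = set(records["participant_id"].unique()) - set(pm.index)
    if missing:
        raise ValueError(f"participants absent from fit: {sorted(missing)}")

    rows = []
    for pid, g in records.groupby("participant_id"):
        params = _params_from_row(pm.loc[pid], fit.spec)
        lat = compute_latents(g.sort_values("trial_index"), params, fit.spec)
        modeled = g.loc[~g["is_pause"].astype(bool)].sort_values("trial_index")
        y = (modeled["participant_choice"] == COOPERATE).to_numpy(dtype=float)
        p = lat["p_coop"].to_numpy()
        if np.std(y) == 0 or np.std(p) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(p, y)[0, 1])
        rows.append({"participant_id": pid, "r": r, "n_trials": len(y)})
    per_participant = pd.DataFrame(rows)

    post = fit.idata.posterior
    n_chains = post.sizes["chain"]
    n_draws = post.sizes["draw"]
    rng = np.random.default_rng(seed)
    sims_gs, sims_id = [], []
    for s in range(n_sim):
        c = int(rng.integers(n_chains))
        d = int(rng.integers(n_draws))
        frames = []
        for i, pid in enumerate(fit.participant_ids):
            vals = {n: float(post[n].isel(chain=c, draw=d, participant=i))
                    for n in fit.free_names}
            params = _params_from_dict(vals, fit.spec)
            agent = ModelAgent(params, fit.spec)
            recs = run_session(SessionConfig(), agent,
                               rng=np.random.default_rng(rng.integers(2 ** 31)),
                               participant_id=int(pid))
            frames.append(nio.records_to_frame(recs))
        sim = pd.concat(frames, ignore_index=True)
        sims_gs.append(empirical_curves(sim, by="GS", n_boot=0))
        sims_id.append(empirical_curves(sim, by="ID", n_boot=0))

    def _ribbon(sims: list[pd.DataFrame]) -> pd.DataFrame:
        allsim = pd.concat(sims)
        out = allsim.groupby("bin", observed=True).agg(
            coop_mean=("coop_rate", "mean"),
            coop_lo=("coop_rate", lambda v: np.nanpercentile(v, 2.5)),
            coop_hi=("coop_rate", lambda v: np.nanpercentile(v, 97.5)),
            recip_mean=("recip_rate", "mean"),
            recip_lo=("recip_rate", lambda v: np.nanpercentile(v, 2.5)),
            recip_hi=("recip_rate", lambda v: np.nanpercentile(v, 97.5)),
            n_sims=("coop_rate", "size"),
        ).reset_index()
        return out

    return {
        "per_participant": per_participant,
        "sim_curves_gs": _ribbon(sims_gs),
        "sim_curves_id": _ribbon(sims_id),
    }


def _params_from_row(row: pd.Series, spec: ModelSpec) -> ParameterSet:
    return _params_from_dict({n: float(row[n]) for n in row.index if n != "participant_id"}, spec)


def _params_from_dict(vals: dict, spec: ModelSpec) -> ParameterSet:
    d = dict(vals)
    d.setdefault("VGS", 0.0)
    d["k"] = spec.effective_k(d.get("k", 0.0))
    return ParameterSet(**d)


# ---------------------------------------------------------------------------
# Parameter recovery


@dataclass
class RecoveryReport:
    """Coverage and correlation summary of a simulate-and-refit study."""

    group_level: pd.DataFrame         # simulation, param, truth, mean, hdi, covered
    participant_level: pd.DataFrame   # simulation, param, pearson r
    hdi_prob: float
    n_simulations: int
    excluded_simulations: list[int] = field(default_factory=list)

    @property
    def coverage_rate(self) -> float:
        return float(self.group_level["covered"].mean())

    @property
    def median_correlation(self) -> float:
        return float(self.participant_level["r"].median())


def recovery_study(config: CohortConfig, n_simulations: int = 3,
                   hdi_prob: float = 0.9, seed: int = 0,
                   exclude_nonconverged: bool = True,
                   **fit_kwargs) -> RecoveryReport:
    """Simulate cohorts from known truths, refit, and score recovery.

    Group-level: whether the ``hdi_prob`` highest-density interval of each
    group mean contains the generating population mean.  Participant-level:
    Pearson correlation of true parameter values with posterior means.
    Non-converged fits are flagged and excluded from the coverage tally.
    """
    spec = config.spec
    free = spec.free_parameters()
    truth_mu = {n: group_mean(*config.group_prior[n], *PARAM_BOUNDS[n])
                for n in free}

    g_rows, p_rows, excluded = [], [], []
    for s in range(n_simulations):
        sim_cfg = replace(config, rng_seed=config.rng_seed + 1000 * (s + 1))
        records, truths = generate_cohort(sim_cfg)
        fit = fit_model(records, spec, seed=seed + s, **fit_kwargs)
        if exclude_nonconverged and not fit.converged:
            excluded.append(s)
        hdis = fit.group_hdi(hdi_prob)
        post_mu = fit.group_posterior_mean()
        for n in free:
            lo, hi = hdis[n]
            g_rows.append({
                "simulation": s, "param": n, "truth": truth_mu[n],
                "truth_sample_mean": float(truths[n].mean()),
                "post_mean": post_mu[n], "hdi_lo": lo, "hdi_hi": hi,
                "covered": bool(lo <= truth_mu[n] <= hi),
                "converged": fit.converged,
            })
        pm = fit.participant_posterior_means().set_index("participant_id")
        for n in free:
            t = truths.set_index("participant_id")[n]
            r = float(np.corrcoef(t.loc[pm.index], pm[n])[0, 1])
            p_rows.append({"simulation": s, "param": n, "r": r})

    g = pd.DataFrame(g_rows)
    if exclude_nonconverged:
        g_cov = g[~g["simulation"].isin(excluded)]
        g = g.assign(in_tally=~g["simulation"].isin(excluded))
    return RecoveryReport(
        group_level=g, participant_level=pd.DataFrame(p_rows),
        hdi_prob=hdi_prob, n_simulations=n_simulations,
        excluded_simulations=excluded)


# ---------------------------------------------------------------------------
# Mixed-model wrappers (delegated to lme4/lmerTest through Rscript)

GLMM_STRUCTURES = {
    1: ("coop ~ GS + (GS | participant_id)", "binomial"),
    2: ("recip ~ GS + (GS | participant_id)", "binomial"),
    3: ("coop ~ ID + (ID | participant_id)", "binomial"),
    4: ("recip ~ ID + (ID | participant_id)", "binomial"),
    5: ("rt ~ GS * coop + (1 | participant_id)", "gaussian"),
    6: ("rt ~ GS * recip + (1 | participant_id)", "gaussian"),
    7: ("rt ~ ID * coop + (1 | participant_id)", "gaussian"),
    8: ("rt ~ ID * recip + (1 | participant_id)", "gaussian"),
}

_R_TEMPLATE = """
suppressMessages({{ library(lme4); library(lmerTest) }})
d <- read.csv("{data}")
fit_one <- function(formula_str, family) {{
  f <- as.formula(formula_str)
  if (family == "binomial") {{
    m <- suppressWarnings(glmer(f, data = d, family = binomial))
  }} else {{
    m <- suppressWarnings(lmer(f, data = d, REML = FALSE))
  }}
  m
}}
ok <- TRUE
m <- tryCatch(fit_one("{formula}", "{family}"), error = function(e) {{ ok <<- FALSE; NULL }})
if (ok && "{family}" == "binomial" && !is.null(m@optinfo$conv$lme4$messages)) ok <- FALSE
if (ok && isSingular(m)) ok <- FALSE
simplified <- FALSE
if (!ok) {{
  simplified <- TRUE
  m <- fit_one("{fallback}", "{family}")
}}
s <- summary(m)
co <- as.data.frame(coef(s))
co$term <- rownames(co)
co$simplified <- simplified
write.csv(co, "{out}", row.names = FALSE)
"""


def fit_behavioral_glmm(records: pd.DataFrame, structure: int,
                        rt_column: str = "rt") -> pd.DataFrame:
    """Fit one of the eight mixed-model structures with lme4/lmerTest.

    Binary outcomes (cooperation, reciprocity) use a logit link with random
    slopes per participant; response-time structures (5-8) require an
    ``rt`` column on the records and use identity-link linear mixed models
    with random intercepts.  On non-convergence or a singular fit the random
    structure is simplified to intercepts only (``simplified`` column).
    Returns a coefficient table with estimates, Wald 95% CIs and p values.
    """
    if structure not in GLMM_STRUCTURES:
        raise ValueError(f"unknown structure {structure}; choose 1-8")
    formula, family = GLMM_STRUCTURES[structure]
    m = _prepare(records)
    m["GS"] = m["group_size"].astype(float)
    m["ID"] = m["interaction_distance"].astype(float)
    if family == "gaussian":
        if rt_column not in records.columns:
            raise ValueError(
                f"structure {structure} models response times, but the "
                f"records carry no {rt_column!r} column")
        m["rt"] = records.loc[m.index, rt_column].astype(float)
    import re
    tokens = set(re.findall(r"[A-Za-z_]+", formula))
    need = [c for c in ("coop", "recip", "GS", "ID", "rt") if c in tokens]
    sub = m.dropna(subset=need)[need + ["participant_id"]]

    dep = formula.split("~")[0].strip()
    fallback = formula.split("+ (")[0].strip() + " + (1 | participant_id)"
    with tempfile.TemporaryDirectory() as td:
        data = Path(td) / "data.csv"
        out = Path(td) / "coef.csv"
        script = Path(td) / "fit.R"
        sub.to_csv(data, index=False)
        script.write_text(_R_TEMPLATE.format(
            data=data, out=out, formula=formula, fallback=fallback,
            family=family))
        res = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True)
        if res.returncode != 0 or not out.exists():
            raise RuntimeError(
                f"mixed-model fit failed (structure {structure}):\n{res.stderr}")
        co = pd.read_csv(out)

    est = co["Estimate"]
    se = co[next(c for c in co.columns if c.startswith("Std."))]
    pcol = next((c for c in co.columns if c.startswith("Pr(")), None)
    return pd.DataFrame({
        "term": co["term"],
        "estimate": est,
        "se": se,
        "ci_lo": est - 1.96 * se,
        "ci_hi": est + 1.96 * se,
        "p": co[pcol] if pcol else np.nan,
        "simplified": co["simplified"],
    })
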