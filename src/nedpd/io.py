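"""Trial-record file I/O, schema validation and dataset manifests.

One canonical dialect: comma-separated UTF-8 with a header row, one row per
trial slot, empty field = missing, choices encoded "C"/"D", booleans 0/1.
Trial indices are 1-based on disk and 0-based in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .task_env import COOPERATE, DEFECT, PayoffMatrix, SessionConfig, TrialRecord, payoff

__all__ = [
    "SCHEMA_COLUMNS",
    "records_to_frame",
    "write_trial_records",
    "read_trial_records",
    "ValidationReport",
    "validate_dataset",
    "map_osf_columns",
    "DatasetManifest",
    "session_config_to_dict",
    "session_config_from_dict",
    "load_config",
    "dump_config",
    "config_hash",
]

SCHEMA_COLUMNS = [
    "participant_id", "trial_index", "partner_id", "group_size",
    "interaction_distance", "is_newcomer", "is_switch_opportunity",
    "is_pause", "participant_choice", "partner_choice",
    "partner_prev_choice", "participant_payoff", "cumulative_score",
    "link_broken",
]
_BOOL_COLUMNS = ["is_newcomer", "is_switch_opportunity", "is_pause", "link_broken"]
_SCHEMA_VERSION = "1"
EXCLUSION_DEFECTION_THRESHOLD = 0.95


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Internal canonical DataFrame (0-based trial index, NaN = missing)."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records],
                      columns=SCHEMA_COLUMNS)
    for col in ("partner_id", "interaction_distance"):
        df[col] = df[col].astype("Int64")
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    return df


def write_trial_records(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["trial_index"] = out["trial_index"].astype(int) + 1  # 1-based on disk
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, na_rep="")


def read_trial_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial-record file {path} lacks columns: {missing}")
    df = df[SCHEMA_COLUMNS].copy()
    df["trial_index"] = df["trial_index"].astype(int) - 1
    for col in ("partner_id", "interaction_distance"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    for col in _BOOL_COLUMNS:
        df[col] = df[col].fillna(0).astype(int).astype(bool)
    return df


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    violations: list[tuple[int, str]] = field(default_factory=list)
    exclusion_flags: dict[int, float] = field(default_factory=dict)
    n_records: int = 0

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_on_error(self) -> None:
        if not self.ok:
            head = "; ".join(f"row {r}: {m}" for r, m in self.violations[:5])
            raise ValueError(
                f"dataset failed validation with {len(self.violations)} "
                f"violation(s): {head}")


def validate_dataset(data: pd.DataFrame | str | Path,
                     payoffs: Optional[PayoffMatrix] = None,
                     max_partners: int = 5) -> ValidationReport:
    """Check every trial-record invariant; report violations by row.

    Re-derives interaction distance and the partner's previous choice from
    the partner-id sequence, recomputes payoffs and the cumulative score,
    and checks newcomer spacing and group-size bounds.  Participants who
    defect on more than 95% of their choice trials are flagged (reported,
    never dropped).
    """
    df = read_trial_records(data) if not isinstance(data, pd.DataFrame) else data
    payoffs = payoffs if payoffs is not None else PayoffMatrix()
    rep = ValidationReport(n_records=len(df))
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"schema mismatch, missing columns: {missing}")

    for pid, g in df.groupby("participant_id", sort=True):
        g = g.sort_values("trial_index")
        last_seen: dict[int, int] = {}
        last_choice: dict[int, str] = {}
        cum = 0
        prev_newcomer = False
        n_def = 0
        n_choice = 0
        for row in g.itertuples():
            i = row.Index
            if row.is_pause:
                if row.group_size != 0:
                    rep.violations.append((i, "pause trial with nonzero group size"))
                prev_newcomer = False
                continue
            t = int(row.trial_index)
            partner = int(row.partner_id)
            if row.group_size < 1:
                rep.violations.append((i, "group_size < 1 on a non-pause trial"))
            if row.group_size > max_partners:
                rep.violations.append((i, f"group_size exceeds cap {max_partners}"))
            if row.is_newcomer and prev_newcomer:
                rep.violations.append((i, "two consecutive newcomer trials"))
            expected_id = t - last_seen[partner] if partner in last_seen else None
            stored_id = None if pd.isna(row.interaction_distance) \
                else int(row.interaction_distance)
            if stored_id != expected_id:
                rep.violations.append(
                    (i, f"interaction_distance {stored_id} != recount {expected_id}"))
            if row.is_newcomer and stored_id is not None:
                rep.violations.append((i, "newcomer trial with defined distance"))
            expected_prev = last_choice.get(partner)
            stored_prev = None if pd.isna(row.partner_prev_choice) \
                else row.partner_prev_choice
            if stored_prev != expected_prev:
                rep.violations.append(
                    (i, f"partner_prev_choice {stored_prev} != recount {expected_prev}"))
            try:
                pay = payoff(row.participant_choice, row.partner_choice, payoffs)
            except ValueError as exc:
                rep.violations.append((i, str(exc)))
                pay = 0
            if pay != row.participant_payoff:
                rep.violations.append(
                    (i, f"payoff {row.participant_payoff} != {pay} for joint outcome"))
            cum += pay
            if cum != row.cumulative_score:
                rep.violations.append(
                    (i, f"cumulative_score {row.cumulative_score} != running sum {cum}"))
            last_seen[partner] = t
            last_choice[partner] = row.partner_choice
            prev_newcomer = bool(row.is_newcomer)
            n_choice += 1
            n_def += row.participant_choice == DEFECT
        if n_choice:
            frac = n_def / n_choice
            if frac > EXCLUSION_DEFECTION_THRESHOLD:
                rep.exclusion_flags[int(pid)] = frac
    return rep


# ---------------------------------------------------------------------------
# Column-mapping adapter for externally deposited tables

_REQUIRED_FIELDS = ["participant_id", "trial_index", "partner_id",
                    "group_size", "participant_choice", "partner_choice"]


def map_osf_columns(raw: pd.DataFrame, mapping: dict[str, str],
                    choice_codes: Optional[dict[Any, str]] = None,
                    one_based_trials: bool = True) -> pd.DataFrame:
    """Adapt an externally deposited table to the trial-record schema.

    ``mapping`` maps schema field -> raw column name.  Fields absent from
    the mapping are re-derived where possible (interaction distance,
    partner's previous choice, payoff, cumulative score) and defaulted
    otherwise.  Missing required fields raise with the offending names.
    ``choice_codes`` converts raw choice encodings to "C"/"D".
    """
    missing = [f for f in _REQUIRED_FIELDS if f not in mapping]
    if missing:
        raise ValueError(f"mapping lacks required fields: {missing}")
    absent = [c for c in mapping.values() if c not in raw.columns]
    if absent:
        raise ValueError(f"mapped columns not in table: {absent}")

    df = pd.DataFrame({f: raw[c] for f, c in mapping.items()})
    if choice_codes:
        for col in ("participant_choice", "partner_choice", "partner_prev_choice"):
            if col in df.columns:
                df[col] = df[col].map(lambda v: choice_codes.get(v, v))
    df["trial_index"] = df["trial_index"].astype(int) - (1 if one_based_trials else 0)
    for col in _BOOL_COLUMNS:
        if col not in df.columns:
            df[col] = False
        df[col] = df[col].astype(bool)

    out = []
    for pid, g in df.groupby("participant_id", sort=True):
        g = g.sort_values("trial_index").copy()
        last_seen: dict[int, int] = {}
        last_choice: dict[int, str] = {}
        idist, prev, pays, cums = [], [], [], []
        cum = 0
        for row in g.itertuples():
            partner = int(row.partner_id)
            t = int(row.trial_index)
            idist.append(t - last_seen[partner] if partner in last_seen else None)
            prev.append(last_choice.get(partner))
            pay = payoff(row.participant_choice, row.partner_choice)
            cum += pay
            pays.append(pay)
            cums.append(cum)
            last_seen[partner] = t
            last_choice[partner] = row.partner_choice
        if "interaction_distance" not in mapping:
            g["interaction_distance"] = idist
        if "partner_prev_choice" not in mapping:
            g["partner_prev_choice"] = prev
        if "participant_payoff" not in mapping:
            g["participant_payoff"] = pays
        if "cumulative_score" not in mapping:
            g["cumulative_score"] = cums
        out.append(g)
    result = pd.concat(out, ignore_index=True)[
        [c for c in SCHEMA_COLUMNS]]
    for col in ("partner_id", "interaction_distance"):
        result[col] = pd.to_numeric(result[col], errors="coerce").astype("Int64")
    return result


# ---------------------------------------------------------------------------
# Manifests and configs


@dataclass
class DatasetManifest:
    files: list[str]
    seed: Optional[int]
    config_hash: str
    provenance: str = "synthetic"  # synthetic | osf | user
    schema_version: str = _SCHEMA_VERSION

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "DatasetManifest":
        return cls(**json.loads(Path(path).read_text()))


def session_config_to_dict(cfg: SessionConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["payoffs"] = dataclasses.asdict(cfg.payoffs)
    return d


def session_config_from_dict(d: dict) -> SessionConfig:
    d = dict(d)
    if "payoffs" in d and isinstance(d["payoffs"], dict):
        d["payoffs"] = PayoffMatrix(**d["payoffs"])
    return SessionConfig(**d)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
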