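"""Simulator for the network-embedded-dyad prisoner's dilemma (NEDPD) task.

The participant sits inside a dynamic group of up to five computer partners.
On each trial they play one pairwise prisoner's dilemma round with either a
newly introduced partner (~10% of trials) or a uniformly chosen current group
member.  At the end of ~20% of trials both sides may unilaterally break the
social link.  Partner agents mix a delta-rule reciprocation estimate of the
participant with a slow sinusoidal "mood" cycle and a constant defection
bias, so unconditioned partners defect slightly more often than they
cooperate.

The partner-algorithm constants below are reconstructions calibrated against
the task's published summary statistics (58.2% partner defection on newcomer
trials), not a copy of the original task script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

__all__ = [
    "COOPERATE",
    "DEFECT",
    "PayoffMatrix",
    "PartnerState",
    "SessionConfig",
    "TrialRecord",
    "TrialContext",
    "ParticipantPolicy",
    "AlwaysCooperate",
    "AlwaysDefect",
    "RandomPolicy",
    "payoff",
    "schedule_next_event",
    "select_partner",
    "partner_decide",
    "partner_observe",
    "partner_switch_decide",
    "run_session",
]

COOPERATE = "C"
DEFECT = "D"
_CHOICES = (COOPERATE, DEFECT)

# ---------------------------------------------------------------------------
# Partner-agent constants (reconstruction; see module docstring).
# The defection bias is the root of logistic(w_m*sin(theta) + b) averaged over
# a uniform mood phase theta equalling 0.418, i.e. 58.2% defection by an
# unconditioned (newcomer) partner.
PARTNER_RECIP_WEIGHT = 8.0
PARTNER_MOOD_WEIGHT = 1.0
PARTNER_DEFECT_BIAS = -0.3719
PARTNER_LEARNING_RATE = 0.5
DEFAULT_MOOD_PERIOD = 22.0

# Partner stay/switch rule: logistic in the participant's defection count over
# the last (up to) 3 interactions with that partner, with a floor.
SWITCH_WINDOW = 3
PARTNER_SWITCH_INTERCEPT = -2.6
PARTNER_SWITCH_SLOPE = 1.1
SWITCH_FLOOR = 0.05

# Default participant-side stay/switch rule (used when a policy does not
# override it): more likely to drop a partner the more that partner defected
# recently.  Calibrated jointly with the partner rule so link-break outflow
# roughly balances newcomer inflow and group size keeps spanning 1..5.
PARTICIPANT_SWITCH_INTERCEPT = -3.8
PARTICIPANT_SWITCH_SLOPE = 1.1


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class PayoffMatrix:
    """Participant-side payoffs; defaults are the task's point values."""

    mutual_coop: int = 30
    temptation: int = 60
    sucker: int = -30
    mutual_defect: int = 0

    def __post_init__(self) -> None:
        if not (self.temptation > self.mutual_coop > self.mutual_defect > self.sucker):
            raise ValueError(
                "payoffs must satisfy the PD ordering "
                "temptation > mutual_coop > mutual_defect > sucker"
            )


@dataclass
class PartnerState:
    """A simulated partner: mood cycle, reciprocation estimate, link status."""

    partner_id: int
    avatar_id: int
    mood_phase: float
    mood_period: float = DEFAULT_MOOD_PERIOD
    recip_estimate: float = 0.5
    active: bool = True
    last_interaction_trial: Optional[int] = None

    def mood(self, trial_index: int) -> float:
        """Sinusoidal mood sampled by the absolute trial number."""
        return math.sin(2.0 * math.pi * trial_index / self.mood_period + self.mood_phase)


@dataclass(frozen=True)
class SessionConfig:
    n_trials: int = 180
    newcomer_rate: float = 0.10
    switch_rate: float = 0.20
    max_partners: int = 5
    partner_pool_size: int = 30
    payoffs: PayoffMatrix = field(default_factory=PayoffMatrix)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("newcomer_rate", "switch_rate"):
            r = getattr(self, name)
            if not (0.0 < r < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1), got {r}")
        if self.max_partners < 1:
            raise ValueError("max_partners must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.partner_pool_size < 1:
            raise ValueError("partner_pool_size must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    """One emitted PD trial (or pause slot) with every model covariate.

    ``trial_index`` is 0-based here; the file format writes it 1-based.
    ``interaction_distance`` is ``None`` on first encounters (including every
    newcomer trial).  On pause slots all choice fields are ``None``.
    """

    participant_id: int
    trial_index: int
    partner_id: Optional[int]
    group_size: int
    interaction_distance: Optional[int]
    is_newcomer: bool
    is_switch_opportunity: bool
    is_pause: bool
    participant_choice: Optional[str]
    partner_choice: Optional[str]
    partner_prev_choice: Optional[str]
    participant_payoff: int
    cumulative_score: int
    link_broken: bool


@dataclass(frozen=True)
class TrialContext:
    """Covariates visible to the participant when choosing."""

    trial_index: int
    partner_id: int
    group_size: int
    interaction_distance: Optional[int]
    partner_prev_choice: Optional[str]
    is_newcomer: bool
    is_switch_opportunity: bool


class ParticipantPolicy:
    """Base participant policy: choose, observe the outcome, decide switches.

    ``decide_switch`` defaults to a logistic rule in the partner's recent
    defection count (participants tend to drop defectors).
    """

    def choose(self, ctx: TrialContext, rng: np.random.Generator) -> str:
        raise NotImplementedError

    def observe(self, ctx: TrialContext, participant_choice: str,
                partner_choice: str, payoff_value: int) -> None:
        pass

    def decide_switch(self, ctx: TrialContext, recent_partner_choices: list[str],
                      rng: np.random.Generator) -> bool:
        d = sum(1 for c in recent_partner_choices[-SWITCH_WINDOW:] if c == DEFECT)
        p = _logistic(PARTICIPANT_SWITCH_INTERCEPT + PARTICIPANT_SWITCH_SLOPE * d)
        return bool(rng.random() < p)


class AlwaysCooperate(ParticipantPolicy):
    def choose(self, ctx: TrialContext, rng: np.random.Generator) -> str:
        return COOPERATE

    def decide_switch(self, ctx, recent_partner_choices, rng) -> bool:
        return False


class AlwaysDefect(ParticipantPolicy):
    def choose(self, ctx: TrialContext, rng: np.random.Generator) -> str:
        return DEFECT


class RandomPolicy(ParticipantPolicy):
    def __init__(self, p_coop: float = 0.5):
        self.p_coop = p_coop

    def choose(self, ctx: TrialContext, rng: np.random.Generator) -> str:
        return COOPERATE if rng.random() < self.p_coop else DEFECT


# ---------------------------------------------------------------------------
# Operations


def payoff(participant_choice: str, partner_choice: str,
           matrix: PayoffMatrix | None = None) -> int:
    """Participant-side payoff for a joint PD outcome."""
    matrix = matrix if matrix is not None else PayoffMatrix()
    if participant_choice not in _CHOICES or partner_choice not in _CHOICES:
        raise ValueError(
            f"choices must be 'C' or 'D', got ({participant_choice!r}, {partner_choice!r})"
        )
    if participant_choice == COOPERATE:
        return matrix.mutual_coop if partner_choice == COOPERATE else matrix.sucker
    return matrix.temptation if partner_choice == COOPERATE else matrix.mutual_defect


def schedule_next_event(
    group_size: int,
    prev_was_newcomer: bool,
    last_two_choices: tuple[Optional[str], Optional[str]],
    config: SessionConfig,
    rng: np.random.Generator,
) -> tuple[bool, bool]:
    """Draw the (is_newcomer, is_switch_opportunity) flags for the next trial.

    The newcomer probability is the base rate, forced to zero after a
    newcomer trial or at the group-size cap, and halved if the participant
    defected on both immediately preceding trials.  The switch-opportunity
    draw is independent of the defection rule.
    """
    p_new = config.newcomer_rate
    if prev_was_newcomer or group_size >= config.max_partners:
        p_new = 0.0
    elif last_two_choices[0] == DEFECT and last_two_choices[1] == DEFECT:
        p_new = p_new / 2.0
    is_newcomer = bool(rng.random() < p_new)
    is_switch = bool(rng.random() < config.switch_rate)
    return is_newcomer, is_switch


def select_partner(active_partners: dict[int, PartnerState], is_newcomer: bool,
                   rng: np.random.Generator,
                   newcomer: Optional[PartnerState] = None) -> int:
    """Uniform draw over active partners; newcomers are the current partner."""
    if is_newcomer:
        if newcomer is None:
            raise ValueError("newcomer trial requires the newly introduced partner")
        return newcomer.partner_id
    if not active_partners:
        raise LookupError("no active partners on a non-newcomer trial (pause handling)")
    ids = sorted(active_partners)
    return ids[rng.integers(len(ids))]


def partner_decide(partner: PartnerState, trial_index: int,
                   rng: np.random.Generator) -> str:
    """Partner's C/D choice from reciprocation estimate + mood + bias."""
    p_coop = partner_coop_probability(partner, trial_index)
    return COOPERATE if rng.random() < p_coop else DEFECT


def partner_coop_probability(partner: PartnerState, trial_index: int) -> float:
    """Deterministic part of :func:`partner_decide` (exposed for testing)."""
    x = (
        PARTNER_RECIP_WEIGHT * (partner.recip_estimate - 0.5)
        + PARTNER_MOOD_WEIGHT * partner.mood(trial_index)
        + PARTNER_DEFECT_BIAS
    )
    return _logistic(x)


def partner_observe(partner: PartnerState, participant_choice: str) -> None:
    """Delta-rule update of the partner's estimate of the participant."""
    target = 1.0 if participant_choice == COOPERATE else 0.0
    partner.recip_estimate += PARTNER_LEARNING_RATE * (target - partner.recip_estimate)


def partner_switch_probability(recent_participant_choices: list[str]) -> float:
    d = sum(1 for c in recent_participant_choices[-SWITCH_WINDOW:] if c == DEFECT)
    p = _logistic(PARTNER_SWITCH_INTERCEPT + PARTNER_SWITCH_SLOPE * d)
    return max(SWITCH_FLOOR, p)


def partner_switch_decide(partner: PartnerState,
                          recent_participant_choices: list[str],
                          rng: np.random.Generator) -> str:
    """Partner's stay/switch decision on a switch-opportunity trial.

    P(switch) is non-decreasing in the participant's recent defection count
    toward this partner, with a floor probability.
    """
    p = partner_switch_probability(recent_participant_choices)
    return "switch" if rng.random() < p else "stay"


# ---------------------------------------------------------------------------
# Session loop


def run_session(
    config: SessionConfig,
    participant_policy: ParticipantPolicy,
    rng: Optional[np.random.Generator] = None,
    participant_id: int = 0,
) -> list[TrialRecord]:
    """Run one full session and emit one :class:`TrialRecord` per trial slot.

    All stochastic draws flow from a single generator seeded by
    ``config.rng_seed`` (unless an explicit ``rng`` is passed), so sessions
    are bit-reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    # Pre-initialized partner pool: each has a fixed uniform mood phase.
    pool = [
        PartnerState(
            partner_id=i,
            avatar_id=i,
            mood_phase=float(rng.uniform(0.0, 2.0 * math.pi)),
        )
        for i in range(config.partner_pool_size)
    ]
    next_pool_idx = 0

    active: dict[int, PartnerState] = {}
    partner_choice_hist: dict[int, list[str]] = {}       # partner's choices
    participant_choice_hist: dict[int, list[str]] = {}   # toward each partner

    records: list[TrialRecord] = []
    cumulative = 0
    last_two: list[Optional[str]] = [None, None]  # participant's last 2 choices
    prev_was_newcomer = False
    force_newcomer = True  # first trial starts with a newcomer

    for t in range(config.n_trials):
        if force_newcomer:
            is_newcomer, is_switch = True, bool(rng.random() < config.switch_rate)
        elif not active:
            # Zero partners: one pause slot, then a forced newcomer.
            records.append(TrialRecord(
                participant_id=participant_id, trial_index=t, partner_id=None,
                group_size=0, interaction_distance=None, is_newcomer=False,
                is_switch_opportunity=False, is_pause=True,
                participant_choice=None, partner_choice=None,
                partner_prev_choice=None, participant_payoff=0,
                cumulative_score=cumulative, link_broken=False,
            ))
            force_newcomer = True
            prev_was_newcomer = False
            continue
        else:
            is_newcomer, is_switch = schedule_next_event(
                len(active), prev_was_newcomer, (last_two[0], last_two[1]),
                config, rng,
            )
        force_newcomer = False

        newcomer_state: Optional[PartnerState] = None
        if is_newcomer:
            if next_pool_idx >= len(pool):
                # Pre-initialized pool exhausted (possible under extreme
                # defection): extend with fresh partners, new avatars.
                pool.append(PartnerState(
                    partner_id=len(pool), avatar_id=len(pool),
                    mood_phase=float(rng.uniform(0.0, 2.0 * math.pi))))
            newcomer_state = pool[next_pool_idx]
            next_pool_idx += 1
            active[newcomer_state.partner_id] = newcomer_state
            partner_choice_hist[newcomer_state.partner_id] = []
            participant_choice_hist[newcomer_state.partner_id] = []

        pid = select_partner(active, is_newcomer, rng, newcomer=newcomer_state)
        partner = active[pid]
        group_size = len(active)

        if partner.last_interaction_trial is None:
            idist = None
            prev_choice = None
        else:
            idist = t - partner.last_interaction_trial
            prev_choice = partner_choice_hist[pid][-1]

        ctx = TrialContext(
            trial_index=t, partner_id=pid, group_size=group_size,
            interaction_distance=idist, partner_prev_choice=prev_choice,
            is_newcomer=is_newcomer, is_switch_opportunity=is_switch,
        )

        part_choice = participant_policy.choose(ctx, rng)
        if part_choice not in _CHOICES:
            raise ValueError(f"participant policy returned invalid choice {part_choice!r}")
        p_choice = partner_decide(partner, t, rng)

        pay = payoff(part_choice, p_choice, config.payoffs)
        cumulative += pay

        partner_observe(partner, part_choice)
        participant_choice_hist[pid].append(part_choice)
        partner_choice_hist[pid].append(p_choice)
        participant_policy.observe(ctx, part_choice, p_choice, pay)

        link_broken = False
        if is_switch:
            partner_says = partner_switch_decide(
                partner, participant_choice_hist[pid], rng)
            participant_says = participant_policy.decide_switch(
                ctx, partner_choice_hist[pid], rng)
            if partner_says == "switch" or participant_says:
                link_broken = True
                partner.active = False  # avatar retired, never re-used
                del active[pid]

        partner.last_interaction_trial = t

        records.append(TrialRecord(
            participant_id=participant_id, trial_index=t, partner_id=pid,
            group_size=group_size, interaction_distance=idist,
            is_newcomer=is_newcomer, is_switch_opportunity=is_switch,
            is_pause=False, participant_choice=part_choice,
            partner_choice=p_choice, partner_prev_choice=prev_choice,
            participant_payoff=pay, cumulative_score=cumulative,
            link_broken=link_broken,
        ))

        last_two = [last_two[1], part_choice]
        prev_was_newcomer = is_newcomer

    return records
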