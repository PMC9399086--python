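"""Choice-set and session construction for the risky-choice task.

Each participant faces the same 90-gamble choice set three times: once for
themselves (always first), once for another person, and once with outcomes
shared with that person, the latter two in counterbalanced order.  Social
context is carried by three signed indicator variables (other / sharing /
identity) attached to every trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CodingError, ConfigurationError, DesignError

__all__ = [
    "GambleSpec",
    "IndicatorTriple",
    "TrialRecord",
    "SessionDesign",
    "DesignConfig",
    "generate_choice_set",
    "build_session",
    "build_cohort",
    "encode_social_indicators",
    "sessions_to_table",
    "MIXED_GAINS",
    "CONDITIONS",
    "GROUPS",
    "TRIAL_COLUMNS",
]

MIXED_GAINS = (2.0, 4.0, 5.0, 6.0, 8.0, 9.0, 10.0, 12.0)
CONDITIONS = ("self", "other", "shared")
GROUPS = ("friend", "stranger")

# stimulus timing is recorded as metadata only; nothing downstream uses it
TIMING_SECONDS = {"options": 2.0, "response_window": 2.0}

TRIAL_COLUMNS = [
    "participant_id", "group", "trial_index", "condition", "block",
    "trial_type", "gain", "loss", "guaranteed", "other", "sharing", "identity",
]


@dataclass(frozen=True)
class GambleSpec:
    """One risky option vs. a sure option, both branches at 50%.

    mixed: 50% gain / 50% loss against a guaranteed $0.
    gain_only: 50% gain / 50% $0 against a smaller guaranteed gain.
    """

    trial_type: str
    gain: float
    loss: float
    guaranteed: float
    p_gain: float = 0.5
    p_loss_or_zero: float = 0.5

    def __post_init__(self) -> None:
        if self.trial_type not in ("mixed", "gain_only"):
            raise DesignError(f"unknown trial_type {self.trial_type!r}")
        if abs(self.p_gain + self.p_loss_or_zero - 1.0) > 1e-12:
            raise DesignError("branch probabilities must sum to 1")
        if self.gain <= 0:
            raise DesignError(f"gain must be > 0, got {self.gain}")
        if self.trial_type == "mixed":
            if not (self.loss < 0 and self.guaranteed == 0):
                raise DesignError("mixed trials need loss < 0 and guaranteed = 0")
        else:
            if not (self.loss == 0 and 0 < self.guaranteed < self.gain):
                raise DesignError(
                    "gain_only trials need loss = 0 and 0 < guaranteed < gain"
                )


@dataclass(frozen=True)
class IndicatorTriple:
    other: int
    sharing: int
    identity: int

    def __post_init__(self) -> None:
        if self.other not in (0, 1):
            raise CodingError(f"other must be 0 or 1, got {self.other}")
        if self.other == 0:
            if self.sharing != 0 or self.identity != 0:
                raise CodingError("self trials must be coded (0, 0, 0)")
        else:
            if self.sharing not in (-1, 1) or self.identity not in (-1, 1):
                raise CodingError(
                    "social trials need sharing and identity in {-1, +1}"
                )


_INDICATOR_TABLE = {
    ("self", "friend"): (0, 0, 0),
    ("self", "stranger"): (0, 0, 0),
    ("other", "stranger"): (1, +1, +1),
    ("other", "friend"): (1, +1, -1),
    ("shared", "stranger"): (1, -1, +1),
    ("shared", "friend"): (1, -1, -1),
}


def encode_social_indicators(condition: str, group: str) -> IndicatorTriple:
    """Signed contrast coding: self (0,0,0); other-only sharing=+1, shared -1;
    stranger identity=+1, friend -1."""
    try:
        return IndicatorTriple(*_INDICATOR_TABLE[(condition, group)])
    except KeyError:
        raise CodingError(f"unknown condition/group pair ({condition!r}, {group!r})")


@dataclass(frozen=True)
class TrialRecord:
    spec: GambleSpec
    indicators: IndicatorTriple
    condition: str
    block: int          # 1-based mini-block within condition
    trial_index: int    # 1-based within the session
    choice: int | None = None
    true_p: float | None = None


@dataclass(frozen=True)
class SessionDesign:
    participant_id: str
    group: str
    condition_order: tuple
    trials: tuple

    def __post_init__(self) -> None:
        if self.condition_order[0] != "self":
            raise DesignError("the self condition must come first")


@dataclass(frozen=True)
class DesignConfig:
    """Choice-set sizes and value grids.

    The per-condition set defaults to 54 mixed + 36 gain-only = 90 trials.
    Loss factors span [-2, -0.25] (loss = gain x factor); gain-only risky
    gains span [3.25, 30] with guaranteed = gain x fraction.
    """

    n_mixed: int = 54
    n_gain_only: int = 36
    mixed_gains: Sequence[float] = MIXED_GAINS
    loss_factor_range: tuple = (-0.25, -2.0)
    gain_only_range: tuple = (3.25, 30.0)
    guaranteed_fractions: Sequence[float] = (0.35, 0.4, 0.45, 0.5, 0.55, 0.6)
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if self.n_mixed < 0 or self.n_gain_only < 0:
            raise ConfigurationError("trial counts must be >= 0")
        lo, hi = sorted(self.loss_factor_range)
        if lo < -2.0 - 1e-12 or hi > -0.25 + 1e-12:
            raise ConfigurationError("loss factors must lie within [-2, -0.25]")
        g_lo, g_hi = self.gain_only_range
        if not (0 < g_lo < g_hi):
            raise ConfigurationError("invalid gain-only value range")
        if any(not (0 < f < 1) for f in self.guaranteed_fractions):
            raise ConfigurationError("guaranteed fractions must lie in (0, 1)")
        n = self.n_mixed + self.n_gain_only
        if n > 0 and self.n_blocks > 0 and n % self.n_blocks != 0:
            raise ConfigurationError(
                f"{n} trials cannot be split into {self.n_blocks} equal blocks"
            )

    @property
    def n_per_condition(self) -> int:
        return self.n_mixed + self.n_gain_only


def _round_cents(x: float) -> float:
    return float(np.round(x, 2))


def generate_choice_set(config: DesignConfig = DesignConfig(), seed: int = 0) -> list:
    """Build the per-condition choice set; deterministic given ``seed``.

    Mixed trials cycle through the gain grid while the loss factor sweeps the
    configured range; gain-only risky gains are evenly spaced with guaranteed
    amounts cycling through the fraction grid.  The final ordering is a
    seeded shuffle.
    """
    specs: list[GambleSpec] = []
    if config.n_mixed > 0:
        factors = np.linspace(*config.loss_factor_range, config.n_mixed)
        gains = list(config.mixed_gains)
        for i, f in enumerate(factors):
            gain = gains[i % len(gains)]
            specs.append(GambleSpec("mixed", gain, _round_cents(gain * f), 0.0))
    if config.n_gain_only > 0:
        risky = np.linspace(*config.gain_only_range, config.n_gain_only)
        fracs = list(config.guaranteed_fractions)
        for i, g in enumerate(risky):
            g = _round_cents(g)
            specs.append(
                GambleSpec("gain_only", g, 0.0, _round_cents(g * fracs[i % len(fracs)]))
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


def build_session(
    participant_id: str,
    group: str,
    counterbalance_flag: str,
    choice_set: Sequence[GambleSpec],
    seed: int = 0,
    n_blocks: int = 3,
) -> SessionDesign:
    """Assemble one participant's 3-condition session from a choice set.

    The self condition always comes first; flag ``AB`` runs other then
    shared, ``BA`` the reverse.  The identical choice set is reshuffled
    independently within each condition (seeded) and split into equal
    mini-blocks.
    """
    if group not in GROUPS:
        raise CodingError(f"unknown group {group!r}")
    if counterbalance_flag not in ("AB", "BA"):
        raise DesignError(f"counterbalance flag must be AB or BA, got {counterbalance_flag!r}")
    n = len(choice_set)
    if n == 0 or n % n_blocks != 0:
        raise DesignError(f"choice set of {n} cannot form {n_blocks} equal mini-blocks")
    block_size = n // n_blocks

    order = ("self", "other", "shared") if counterbalance_flag == "AB" else ("self", "shared", "other")
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    t = 0
    for condition in order:
        perm = rng.permutation(n)
        ind = encode_social_indicators(condition, group)
        for j, k in enumerate(perm):
            t += 1
            trials.append(
                TrialRecord(
                    spec=choice_set[k],
                    indicators=ind,
                    condition=condition,
                    block=j // block_size + 1,
                    trial_index=t,
                )
            )
    return SessionDesign(participant_id, group, order, tuple(trials))


def build_cohort(
    n_stranger: int = 29,
    n_friend: int = 28,
    config: DesignConfig = DesignConfig(),
    seed: int = 0,
) -> list:
    """Sessions for a full cohort, alternating the counterbalance flag
    within each group.  All participants share one choice set."""
    choice_set = generate_choice_set(config, seed=seed)
    sessions = []
    i = 0
    for group, count in (("stranger", n_stranger), ("friend", n_friend)):
        for j in range(count):
            i += 1
            flag = "AB" if j % 2 == 0 else "BA"
            child_seed = np.random.SeedSequence([seed, 1, i]).generate_state(1)[0]
            sessions.append(
                build_session(f"p{i:03d}", group, flag, choice_set, seed=int(child_seed),
                              n_blocks=config.n_blocks)
            )
    return sessions


def sessions_to_table(sessions) -> pd.DataFrame:
    """Long-format trial table, one row per (participant, trial)."""
    if isinstance(sessions, SessionDesign):
        sessions = [sessions]
    rows = []
    for s in sessions:
        for tr in s.trials:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "group": s.group,
                    "trial_index": tr.trial_index,
                    "condition": tr.condition,
                    "block": tr.block,
                    "trial_type": tr.spec.trial_type,
                    "gain": tr.spec.gain,
                    "loss": tr.spec.loss,
                    "guaranteed": tr.spec.guaranteed,
                    "other": tr.indicators.other,
                    "sharing": tr.indicators.sharing,
                    "identity": tr.indicators.identity,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
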