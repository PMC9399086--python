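"""Generative cohort with the statistical structure the hierarchical model assumes.

Subject-level log parameters are drawn around configurable group log-means;
each agent also receives subject-level 'other' shifts (for mixed-effects
style generation) and trait scores constructed to correlate with a chosen
shift via a Gaussian-copula-style latent construction.

Seed-splitting rule: with master seed ``s``, the population draw uses
``default_rng(SeedSequence([s, 0]))`` and the choice simulation for agent
``i`` (0-based) uses ``default_rng(SeedSequence([s, 2, i]))``, so any single
agent can be re-simulated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DesignError
from .prospect_model import ParameterSet, SocialEffects, utilities
from .task_design import DesignConfig, SessionDesign, build_cohort, sessions_to_table
from scipy.special import expit

__all__ = [
    "TraitSpec",
    "PopulationConfig",
    "AgentRecord",
    "default_population",
    "draw_population",
    "simulate_choices",
    "simulate_cohort",
    "agents_to_table",
]

_SUBJECT_EFFECTS = ("d_rho_other", "d_lam_other", "d_mu_other")


@dataclass(frozen=True)
class TraitSpec:
    """A questionnaire-like covariate tied to one subject-level 'other' shift."""

    name: str
    mean: float
    sd: float
    target_corr: float
    linked_effect: str  # one of d_rho_other / d_lam_other / d_mu_other

    def __post_init__(self) -> None:
        if not abs(self.target_corr) < 1:
            raise ConfigurationError("|target correlation| must be < 1")
        if self.sd <= 0:
            raise ConfigurationError("trait sd must be > 0")
        if self.linked_effect not in _SUBJECT_EFFECTS:
            raise ConfigurationError(
                f"linked_effect must be one of {_SUBJECT_EFFECTS}, got {self.linked_effect!r}"
            )


@dataclass(frozen=True)
class PopulationConfig:
    group_log_means: tuple  # (log rho, log lam, log mu)
    group_log_sds: tuple
    true_social_effects: SocialEffects
    subject_effect_sd: float
    traits: tuple = ()
    n_friend: int = 28
    n_stranger: int = 29
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_log_means) != 3 or len(self.group_log_sds) != 3:
            raise ConfigurationError("group means/sds must each have 3 entries")
        if any(s < 0 for s in self.group_log_sds) or self.subject_effect_sd < 0:
            raise ConfigurationError("spreads must be >= 0")
        if self.n_friend < 0 or self.n_stranger < 0:
            raise ConfigurationError("group sizes must be >= 0")


def default_population(seed: int = 0, **overrides) -> PopulationConfig:
    """Demo/test defaults: group means at published point estimates; the
    group-level log-sds and subject-effect sd are free choices of this
    artifact (the source estimates do not pin them down)."""
    cfg = dict(
        group_log_means=(math.log(1.07), math.log(1.78), math.log(18.0)),
        group_log_sds=(0.25, 0.35, 0.4),
        true_social_effects=SocialEffects(
            d_rho_other=-0.11, d_rho_sharing=0.016, d_rho_identity=-0.05,
            d_lam_other=0.06, d_lam_sharing=0.0, d_lam_identity=0.02,
            d_mu_other=0.45, d_mu_sharing=0.0, d_mu_identity=-0.18,
        ),
        subject_effect_sd=0.15,
        traits=(
            TraitSpec("social_risk", 25.0, 7.0, 0.30, "d_lam_other"),
            TraitSpec("empathy", 70.0, 10.0, -0.25, "d_rho_other"),
        ),
        n_friend=28,
        n_stranger=29,
        seed=seed,
    )
    cfg.update(overrides)
    return PopulationConfig(**cfg)


@dataclass(frozen=True)
class AgentRecord:
    participant_id: str
    group: str
    params: ParameterSet                    # true baseline, natural + log scale
    subject_other_effects: tuple            # (d rho, d lam, d mu) for this agent
    traits: dict
    population_effects: SocialEffects       # group-level truth this agent came from


def _population_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 0]))


def agent_choice_rng(seed: int, agent_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 2, agent_index]))


def draw_population(config: PopulationConfig) -> list:
    """Draw agents: log params ~ N(group means, group sds); subject 'other'
    shifts ~ N(group shifts, subject_effect_sd); traits correlated with the
    latent z-score of their linked shift."""
    rng = _population_rng(config.seed)
    means = np.asarray(config.group_log_means, dtype=float)
    sds = np.asarray(config.group_log_sds, dtype=float)
    group_other = np.array(
        [getattr(config.true_social_effects, n) for n in _SUBJECT_EFFECTS]
    )
    agents = []
    i = 0
    for group, count in (("stranger", config.n_stranger), ("friend", config.n_friend)):
        for _ in range(count):
            i += 1
            z = rng.standard_normal(3)
            logs = means + sds * z
            w = rng.standard_normal(3)  # latent z-scores of the subject shifts
            subject_other = group_other + config.subject_effect_sd * w
            traits = {}
            for ts in config.traits:
                k = _SUBJECT_EFFECTS.index(ts.linked_effect)
                eps = rng.standard_normal()
                latent = ts.target_corr * w[k] + math.sqrt(1 - ts.target_corr**2) * eps
                traits[ts.name] = ts.mean + ts.sd * latent
            agents.append(
                AgentRecord(
                    participant_id=f"p{i:03d}",
                    group=group,
                    params=ParameterSet.from_log(*logs),
                    subject_other_effects=tuple(subject_other.tolist()),
                    traits=traits,
                    population_effects=config.true_social_effects,
                )
            )
    return agents


def _agent_effects(agent: AgentRecord, effects_mode: str) -> SocialEffects:
    if effects_mode == "model1_fixed":
        return agent.population_effects
    if effects_mode == "model2_mixed":
        d_rho, d_lam, d_mu = agent.subject_other_effects
        return replace(
            agent.population_effects,
            d_rho_other=d_rho, d_lam_other=d_lam, d_mu_other=d_mu,
        )
    raise ConfigurationError(f"unknown effects_mode {effects_mode!r}")


def simulate_choices(
    session: SessionDesign,
    agent: AgentRecord,
    effects_mode: str = "model1_fixed",
    seed: int = 0,
    agent_index: int = 0,
) -> pd.DataFrame:
    """One Bernoulli accept/reject per trial; the generating probability is
    retained in ``true_p`` alongside the draw."""
    if session.group != agent.group:
        raise DesignError(
            f"session group {session.group!r} does not match agent group {agent.group!r}"
        )
    table = sessions_to_table(session)
    eff = _agent_effects(agent, effects_mode).as_array().reshape(3, 3)
    ix = table[["other", "sharing", "identity"]].to_numpy(dtype=float)
    shifts = ix @ eff.T  # (n, 3): per-trial log shifts of rho, lam, mu
    logs = agent.params.as_log_array()[None, :] + shifts
    rho, lam, mu = np.exp(logs).T
    u_g, u_s = utilities(
        table["gain"].to_numpy(), table["loss"].to_numpy(),
        table["guaranteed"].to_numpy(), rho, lam,
    )
    p = expit(mu * (u_g - u_s))
    rng = agent_choice_rng(seed, agent_index)
    table["choice"] = (rng.random(len(p)) < p).astype(int)
    table["true_p"] = p
    return table


def simulate_cohort(
    config: PopulationConfig,
    design: DesignConfig = DesignConfig(),
    effects_mode: str = "model1_fixed",
) -> tuple:
    """Full pipeline from population truth to a long choice table.

    Returns ``(agents, trials)`` where trials stacks every agent's simulated
    session.  All randomness descends from ``config.seed``.
    """
    agents = draw_population(config)
    sessions = build_cohort(
        n_stranger=config.n_stranger, n_friend=config.n_friend,
        config=design, seed=config.seed,
    )
    frames = []
    for idx, (agent, session) in enumerate(zip(agents, sessions)):
        frames.append(
            simulate_choices(session, agent, effects_mode, seed=config.seed,
                             agent_index=idx)
        )
    trials = pd.concat(frames, ignore_index=True)
    return agents, trials


def agents_to_table(agents) -> pd.DataFrame:
    """Ground-truth agents file: true parameters, subject shifts, traits."""
    rows = []
    for a in agents:
        row = {
            "participant_id": a.participant_id,
            "group": a.group,
            "rho": a.params.rho,
            "lam": a.params.lam,
            "mu": a.params.mu,
            "log_rho": a.params.log_rho,
            "log_lam": a.params.log_lam,
            "log_mu": a.params.log_mu,
            "d_rho_other_subject": a.subject_other_effects[0],
            "d_lam_other_subject": a.subject_other_effects[1],
            "d_mu_other_subject": a.subject_other_effects[2],
        }
        row.update(a.traits)
        rows.append(row)
    return pd.DataFrame(rows)
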