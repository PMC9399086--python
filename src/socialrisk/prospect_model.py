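"""Valuation and choice equations for 50/50 risky gambles.

The model has three behavioural parameters: a curvature exponent ``rho``
(risk attitude), a multiplicative loss weight ``lam`` (loss aversion), and a
softmax inverse temperature ``mu`` (choice consistency).  All three are
strictly positive and are represented internally on an unconstrained log
scale; social context shifts act additively on that log scale and are mapped
back through ``exp``, which doubles as the parameter bound.

Sign convention for losses: a loss branch with face value ``x < 0``
contributes ``-lam * |x| ** rho`` to the gamble's utility (a single ``rho``
is shared between gains and losses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.special import expit, log_expit

from .exceptions import DataValidationError

__all__ = [
    "ParameterSet",
    "SocialEffects",
    "gamble_utility",
    "guaranteed_utility",
    "choice_probability",
    "compose_trial_parameters",
    "trial_loglik",
    "dataset_loglik",
    "utilities",
]


@dataclass(frozen=True)
class ParameterSet:
    """(rho, lam, mu) on the natural scale plus their log-scale counterparts.

    ``rho = 1`` is risk neutral and ``lam = 1`` gain-loss neutral; larger
    ``mu`` means more deterministic choices.  Use :meth:`from_natural` or
    :meth:`from_log` rather than the raw constructor.
    """

    rho: float
    lam: float
    mu: float
    log_rho: float
    log_lam: float
    log_mu: float

    @classmethod
    def from_natural(cls, rho: float, lam: float, mu: float) -> "ParameterSet":
        if rho <= 0 or lam <= 0:
            raise ValueError(f"rho and lam must be > 0, got rho={rho}, lam={lam}")
        if mu < 0:
            raise ValueError(f"mu must be >= 0, got {mu}")
        log_mu = math.log(mu) if mu > 0 else -math.inf
        return cls(rho, lam, mu, math.log(rho), math.log(lam), log_mu)

    @classmethod
    def from_log(cls, log_rho: float, log_lam: float, log_mu: float) -> "ParameterSet":
        return cls(
            math.exp(log_rho), math.exp(log_lam), math.exp(log_mu),
            log_rho, log_lam, log_mu,
        )

    def as_log_array(self) -> np.ndarray:
        return np.array([self.log_rho, self.log_lam, self.log_mu])


#: canonical ordering of the nine additive social terms: for each behavioural
#: parameter (rho, lam, mu), the (other, sharing, identity) factors in turn.
EFFECT_NAMES = (
    "d_rho_other", "d_rho_sharing", "d_rho_identity",
    "d_lam_other", "d_lam_sharing", "d_lam_identity",
    "d_mu_other", "d_mu_sharing", "d_mu_identity",
)


@dataclass(frozen=True)
class SocialEffects:
    """Additive log-scale shifts of (rho, lam, mu) by social context.

    A zero vector makes every social condition behave exactly like the self
    condition.
    """

    d_rho_other: float = 0.0
    d_rho_sharing: float = 0.0
    d_rho_identity: float = 0.0
    d_lam_other: float = 0.0
    d_lam_sharing: float = 0.0
    d_lam_identity: float = 0.0
    d_mu_other: float = 0.0
    d_mu_sharing: float = 0.0
    d_mu_identity: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")

    def as_array(self) -> np.ndarray:
        """Length-9 vector in :data:`EFFECT_NAMES` order."""
        return np.array([getattr(self, n) for n in EFFECT_NAMES])

    @classmethod
    def from_array(cls, arr) -> "SocialEffects":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (9,):
            raise ValueError(f"expected 9 effects, got shape {arr.shape}")
        return cls(**dict(zip(EFFECT_NAMES, arr.tolist())))


def _check_params(params: ParameterSet) -> None:
    if params.rho <= 0 or params.lam <= 0:
        raise ValueError("rho and lam must be strictly positive")


def gamble_utility(spec, params: ParameterSet) -> float:
    """Utility of the risky option: ``p+ * gain**rho - p- * lam * |loss|**rho``.

    For gain-only gambles the 50% zero branch contributes exactly 0.
    """
    _check_params(params)
    u = spec.p_gain * spec.gain ** params.rho
    if spec.loss < 0:
        u -= spec.p_loss_or_zero * params.lam * abs(spec.loss) ** params.rho
    return u


def guaranteed_utility(amount: float, params: ParameterSet) -> float:
    """Utility of the sure option, ``amount ** rho`` (0 maps to 0)."""
    _check_params(params)
    if amount < 0:
        raise ValueError(f"guaranteed amount must be >= 0, got {amount}")
    if amount == 0:
        return 0.0
    return amount ** params.rho


def choice_probability(u_gamble: float, u_guaranteed: float, mu: float) -> float:
    """Softmax probability of accepting the gamble, ``expit(mu * du)``."""
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    return float(expit(mu * (u_gamble - u_guaranteed)))


def compose_trial_parameters(baseline: ParameterSet, effects: SocialEffects, ind) -> ParameterSet:
    """Per-trial parameters: baseline log values plus indicator-weighted shifts.

    For each parameter ``theta``::

        theta_trial = exp(log theta + other*d_other + sharing*d_sharing
                          + identity*d_identity)

    Self trials (all-zero indicators) return the baseline exactly.
    """
    ix = np.array([ind.other, ind.sharing, ind.identity], dtype=float)
    d = effects.as_array().reshape(3, 3)  # rows: rho, lam, mu
    shift = d @ ix
    return ParameterSet.from_log(
        baseline.log_rho + shift[0],
        baseline.log_lam + shift[1],
        baseline.log_mu + shift[2],
    )


def trial_loglik(trial, params: ParameterSet) -> float:
    """Log-likelihood of the observed accept(1)/reject(0) on one trial."""
    choice = getattr(trial, "choice", None)
    if choice is None or (isinstance(choice, float) and math.isnan(choice)):
        raise DataValidationError("trial has no observed choice")
    spec = getattr(trial, "spec", trial)
    du = gamble_utility(spec, params) - guaranteed_utility(spec.guaranteed, params)
    s = params.mu * du
    return float(log_expit(s) if choice else log_expit(-s))


# ---------------------------------------------------------------------------
# vectorized forms (shared by the simulator and the inference backend)
# ---------------------------------------------------------------------------

def utilities(gain, loss, guaranteed, rho, lam):
    """Vectorized (u_gamble, u_guaranteed); inputs broadcast elementwise."""
    gain = np.asarray(gain, dtype=float)
    loss = np.asarray(loss, dtype=float)
    guaranteed = np.asarray(guaranteed, dtype=float)
    u_g = 0.5 * gain ** rho - 0.5 * lam * np.abs(loss) ** rho
    u_s = np.where(guaranteed > 0, guaranteed, 1.0) ** rho
    u_s = np.where(guaranteed > 0, u_s, 0.0)
    return u_g, u_s


def dataset_loglik(gain, loss, guaranteed, choice, rho, lam, mu):
    """Vector of per-trial log-likelihoods; total is their sum (independent trials)."""
    u_g, u_s = utilities(gain, loss, guaranteed, rho, lam)
    s = mu * (u_g - u_s)
    choice = np.asarray(choice)
    return np.where(choice == 1, log_expit(s), log_expit(-s))
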