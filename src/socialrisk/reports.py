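"""Result objects built from posteriors: implied per-condition parameter
means, parameter-recovery diagnostics, and trait correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import AlignmentError, DataValidationError
from .inference.diagnostics import hdi
from .prospect_model import EFFECT_NAMES, ParameterSet, SocialEffects
from .task_design import encode_social_indicators

__all__ = [
    "CONDITION_CELLS",
    "implied_condition_means",
    "implied_condition_means_from_draws",
    "implied_other_means",
    "RecoveryReport",
    "recovery_report",
    "trait_correlations",
    "group_difference_ttests",
    "condition_means_markdown",
]

# the four social cells of the 2 (other-only/shared) x 2 (stranger/friend) design
CONDITION_CELLS = (
    ("other", "stranger"), ("other", "friend"),
    ("shared", "stranger"), ("shared", "friend"),
)

_PARAMS = ("rho", "lam", "mu")


def _cell_values(log_baseline, deltas, condition, group):
    """Natural-scale (rho, lam, mu) for one cell; inputs may be draw arrays.

    log_baseline: (..., 3); deltas: (..., 9) in EFFECT_NAMES order.
    """
    ind = encode_social_indicators(condition, group)
    ix = np.array([ind.other, ind.sharing, ind.identity], dtype=float)
    d = np.asarray(deltas).reshape(*np.shape(deltas)[:-1], 3, 3)
    shift = d @ ix
    return np.exp(np.asarray(log_baseline) + shift)


def implied_condition_means(baselines: ParameterSet, effects: SocialEffects) -> pd.DataFrame:
    """Point version: compose posterior-mean baselines with posterior-mean
    social terms for each of the four social cells (plus the self row)."""
    rows = [{"condition": "self", "group": "-",
             **dict(zip(_PARAMS, (baselines.rho, baselines.lam, baselines.mu)))}]
    logs = baselines.as_log_array()
    d = effects.as_array()
    for condition, group in CONDITION_CELLS:
        vals = _cell_values(logs, d, condition, group)
        rows.append({"condition": condition, "group": group,
                     **dict(zip(_PARAMS, vals.tolist()))})
    return pd.DataFrame(rows)


def implied_condition_means_from_draws(
    log_baseline_draws: np.ndarray,
    delta_draws: np.ndarray,
    mass: float = 0.95,
) -> pd.DataFrame:
    """Draw-wise composition (exponentiating each draw, then averaging),
    with HDIs per cell.  Note the Jensen gap: this is not the same as
    exponentiating the posterior means unless the draws are tightly
    concentrated; the draw-wise version is always reported."""
    log_baseline_draws = np.asarray(log_baseline_draws, dtype=float)
    delta_draws = np.asarray(delta_draws, dtype=float)
    if log_baseline_draws.shape[-1] != 3 or delta_draws.shape[-1] != 9:
        raise AlignmentError("expected (n, 3) baselines and (n, 9) deltas")
    rows = []
    self_vals = np.exp(log_baseline_draws)
    row = {"condition": "self", "group": "-"}
    for k, p in enumerate(_PARAMS):
        iv = hdi(self_vals[:, k], mass)
        row[p] = float(self_vals[:, k].mean())
        row[f"{p}_lower"], row[f"{p}_upper"] = iv.lower, iv.upper
    rows.append(row)
    for condition, group in CONDITION_CELLS:
        vals = _cell_values(log_baseline_draws, delta_draws, condition, group)
        row = {"condition": condition, "group": group}
        for k, p in enumerate(_PARAMS):
            iv = hdi(vals[:, k], mass)
            row[p] = float(vals[:, k].mean())
            row[f"{p}_lower"], row[f"{p}_upper"] = iv.lower, iv.upper
        rows.append(row)
    return pd.DataFrame(rows)


def implied_other_means(baselines: ParameterSet, effects: SocialEffects) -> tuple:
    """(rho, lam, mu) implied for 'another person is involved', ignoring the
    sharing and identity terms (their deltas zeroed, indicator other=1)."""
    logs = baselines.as_log_array()
    d = np.zeros(9)
    for i, name in enumerate(EFFECT_NAMES):
        if name.endswith("_other"):
            d[i] = getattr(effects, name)
    vals = np.exp(logs + d.reshape(3, 3)[:, 0])
    return tuple(vals.tolist())


def condition_means_markdown(table: pd.DataFrame) -> str:
    """Render a condition-means table (point or draw-wise) to markdown."""
    lines = ["| condition | group | rho | lambda | mu |",
             "|---|---|---|---|---|"]
    has_hdi = "rho_lower" in table.columns
    for _, row in table.iterrows():
        cells = []
        for p in _PARAMS:
            if has_hdi:
                cells.append(f"{row[p]:.2f} [{row[p + '_lower']:.2f}, {row[p + '_upper']:.2f}]")
            else:
                cells.append(f"{row[p]:.2f}")
        lines.append(f"| {row['condition']} | {row['group']} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    table: pd.DataFrame     # per-parameter truth / posterior mean / bias / coverage
    coverage_rate: float

    def to_dict(self) -> dict:
        return {"coverage_rate": self.coverage_rate,
                "parameters": self.table.to_dict(orient="records")}


def recovery_report(population, posterior, agents=None, mass: float = 0.95) -> RecoveryReport:
    """Compare group-level posterior blocks against the generating truth.

    ``population`` is the generating :class:`PopulationConfig`; ``agents``
    (optional, for mixed-effect fits) supplies per-subject truth for the
    subject-level 'other' shifts.
    """
    rows = []

    def add(name, truth, draws):
        draws = np.asarray(draws, dtype=float).ravel()
        iv = hdi(draws, mass)
        mean = float(draws.mean())
        rows.append({
            "parameter": name, "truth": float(truth), "posterior_mean": mean,
            "bias": mean - float(truth), "abs_error": abs(mean - float(truth)),
            "hdi_lower": iv.lower, "hdi_upper": iv.upper,
            "covered": bool(iv.contains(float(truth))),
        })

    gm = posterior.get("group_mean")
    for k, p in enumerate(_PARAMS):
        add(f"group_mean[{p}]", population.group_log_means[k], gm[:, :, k])
    gsd = np.exp(posterior.get("group_log_sd"))
    for k, p in enumerate(_PARAMS):
        add(f"group_sd[{p}]", population.group_log_sds[k], gsd[:, :, k])

    truth_eff = population.true_social_effects
    if "delta" in posterior.registry:
        d = posterior.get("delta")
        for i, name in enumerate(EFFECT_NAMES):
            add(name, getattr(truth_eff, name), d[:, :, i])
    if "delta_other_subject" in posterior.registry:
        dm = posterior.get("delta_other_mean")
        for k, p in enumerate(_PARAMS):
            add(f"d_{p}_other", getattr(truth_eff, f"d_{p}_other"), dm[:, :, k])
        if agents is not None:
            subj = subject_other_effect_draws(posterior)
            if len(agents) != subj.shape[1]:
                raise AlignmentError(
                    f"{len(agents)} truth agents vs {subj.shape[1]} fitted subjects"
                )
            for s, agent in enumerate(agents):
                if agent.participant_id != posterior.participants[s]:
                    raise AlignmentError("agent order does not match posterior registry")
                for k, p in enumerate(_PARAMS):
                    add(f"d_{p}_other[{agent.participant_id}]",
                        agent.subject_other_effects[k], subj[:, s, k])

    table = pd.DataFrame(rows)
    return RecoveryReport(table=table, coverage_rate=float(table["covered"].mean()))


def subject_other_effect_draws(posterior) -> np.ndarray:
    """Mixed-model subject-level 'other' shifts, (draws, subjects, 3)."""
    if "delta_other_subject" not in posterior.registry:
        raise AlignmentError("posterior has no subject-level 'other' terms (need an M2 fit)")
    return posterior.flat("delta_other_subject")


def subject_other_effect_means(posterior, point: str = "mean") -> pd.DataFrame:
    """Per-subject point estimates (posterior mean, or median by flag) of the
    'other' shifts from a mixed-effects fit."""
    draws = subject_other_effect_draws(posterior)
    agg = np.mean if point == "mean" else np.median
    vals = agg(draws, axis=0)
    return pd.DataFrame(
        vals, columns=["d_rho_other", "d_lam_other", "d_mu_other"],
    ).assign(participant_id=posterior.participants)


# ---------------------------------------------------------------------------
# individual differences
# ---------------------------------------------------------------------------

def trait_correlations(subject_effects: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (two-sided, df = n - 2) between each trait column and each
    subject-level effect column, pairwise-complete, with a Benjamini-Hochberg
    adjusted column alongside the unadjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    merged = subject_effects.merge(traits, on="participant_id", how="inner")
    effect_cols = [c for c in subject_effects.columns if c != "participant_id"]
    trait_cols = [c for c in traits.columns if c not in ("participant_id", "group")]
    rows = []
    for t in trait_cols:
        for e in effect_cols:
            pair = merged[[t, e]].dropna()
            n = len(pair)
            if n < 3:
                raise DataValidationError(f"need >= 3 complete pairs for ({t}, {e}), got {n}")
            x, y = pair[t].to_numpy(), pair[e].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                raise DataValidationError(f"zero-variance vector in ({t}, {e})")
            r, p = sps.pearsonr(x, y)
            rows.append({"trait": t, "effect": e, "r": float(r), "p": float(p), "n": n})
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def group_difference_ttests(subject_effects: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Two-sample t-tests of subject-level 'other' shift point estimates
    between stranger- and friend-group participants."""
    merged = subject_effects.merge(groups[["participant_id", "group"]], on="participant_id")
    rows = []
    for e in [c for c in subject_effects.columns if c != "participant_id"]:
        a = merged.loc[merged["group"] == "stranger", e]
        b = merged.loc[merged["group"] == "friend", e]
        t, p = sps.ttest_ind(a, b)
        rows.append({"effect": e, "t": float(t), "p": float(p),
                     "n_stranger": len(a), "n_friend": len(b)})
    return pd.DataFrame(rows)
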