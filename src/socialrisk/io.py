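"""Plain-text file formats: trial tables, agents, posteriors, summaries.

Money columns are serialized with exactly two decimals; indicators as signed
integers.  All tables are comma-separated with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataValidationError
from .task_design import TRIAL_COLUMNS

__all__ = ["write_trials", "load_choice_table", "write_agents",
           "write_posterior", "write_json"]

_MONEY_COLS = ("gain", "loss", "guaranteed")
_INDICATOR_SETS = {"other": {0, 1}, "sharing": {-1, 0, 1}, "identity": {-1, 0, 1}}


def write_trials(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for c in _MONEY_COLS:
        out[c] = out[c].map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)


def load_choice_table(path) -> pd.DataFrame:
    """Read and validate a long trial table.

    Checks: required columns present, money parses as decimal, indicators in
    their legal sets and jointly consistent (self trials all-zero), choice in
    {0, 1} when present, and no duplicate (participant, trial) keys.  Raises
    :class:`DataValidationError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise DataValidationError(f"missing required columns: {missing}")

    for c in _MONEY_COLS:
        table[c] = pd.to_numeric(table[c], errors="coerce")
        bad = table.index[table[c].isna()]
        if len(bad):
            raise DataValidationError(f"non-numeric {c!r} at row {bad[0]}")
    for c, legal in _INDICATOR_SETS.items():
        vals = table[c]
        bad = table.index[~vals.isin(list(legal))]
        if len(bad):
            raise DataValidationError(
                f"illegal {c!r} value {vals.loc[bad[0]]!r} at row {bad[0]}"
            )
    selfish = table["other"] == 0
    bad = table.index[selfish & ((table["sharing"] != 0) | (table["identity"] != 0))]
    if len(bad):
        raise DataValidationError(f"self trial with non-zero social coding at row {bad[0]}")
    bad = table.index[~selfish & ((table["sharing"] == 0) | (table["identity"] == 0))]
    if len(bad):
        raise DataValidationError(f"social trial with zero sharing/identity at row {bad[0]}")

    if "choice" in table.columns:
        obs = table["choice"].dropna()
        if not obs.isin([0, 1]).all():
            bad = obs.index[~obs.isin([0, 1])]
            raise DataValidationError(f"choice outside {{0,1}} at row {bad[0]}")

    dup = table.duplicated(subset=["participant_id", "trial_index"])
    if dup.any():
        row = table.index[dup][0]
        key = (table.loc[row, "participant_id"], table.loc[row, "trial_index"])
        raise DataValidationError(f"duplicate (participant, trial) key {key} at row {row}")
    return table


def write_agents(agents_table: pd.DataFrame, path) -> None:
    agents_table.to_csv(path, index=False)


def write_posterior(posterior, out_dir) -> None:
    """Serialize a fit: long draws table plus a JSON summary with means, sds,
    HDIs, and convergence diagnostics."""
    from .inference.diagnostics import check_convergence, hdi

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    posterior.to_frame().to_csv(out_dir / "draws.csv", index=False)

    diag = check_convergence(posterior)
    flat = posterior.flat_all()
    summary = {}
    for j, name in enumerate(posterior.parameter_names):
        x = flat[:, j]
        iv = hdi(x)
        summary[name] = {
            "mean": float(x.mean()), "sd": float(x.std(ddof=1)),
            "hdi_lower": iv.lower, "hdi_upper": iv.upper,
            "rhat": None if np.isnan(diag.loc[j, "rhat"]) else float(diag.loc[j, "rhat"]),
            "ess": float(diag.loc[j, "ess"]),
        }
    write_json({"meta": posterior.meta, "parameters": summary},
               out_dir / "summary.json")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
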