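"""Run configuration and the end-to-end pipeline:
generate -> simulate -> fit -> report.

The YAML/JSON config schema is documented in ``config_schema.md`` at the
repository root; every run re-serializes its config (with a content hash)
into the output directory for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .inference import MCMCConfig, ModelSpec, fit_model
from .io import write_agents, write_json, write_posterior, write_trials
from .prospect_model import SocialEffects
from .synthetic_cohort import (PopulationConfig, TraitSpec, agents_to_table,
                               default_population, simulate_cohort)
from .task_design import DesignConfig

__all__ = ["RunConfig", "load_run_config", "run_pipeline"]

log = logging.getLogger("socialrisk")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "out"
    design: DesignConfig = field(default_factory=DesignConfig)
    population: PopulationConfig | None = None
    models: tuple = ("M1",)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    effects_mode: str = "model1_fixed"

    def __post_init__(self) -> None:
        for m in self.models:
            ModelSpec(m)  # validates
        if self.effects_mode not in ("model1_fixed", "model2_mixed"):
            raise ConfigurationError(f"unknown effects_mode {self.effects_mode!r}")

    def resolved_population(self) -> PopulationConfig:
        if self.population is not None:
            return self.population
        return default_population(seed=self.seed)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "design": asdict(self.design),
            "models": list(self.models),
            "mcmc": asdict(self.mcmc),
            "effects_mode": self.effects_mode,
        }
        pop = self.resolved_population()
        d["population"] = {
            "group_log_means": list(pop.group_log_means),
            "group_log_sds": list(pop.group_log_sds),
            "true_social_effects": {
                k: getattr(pop.true_social_effects, k)
                for k in pop.true_social_effects.__dataclass_fields__
            },
            "subject_effect_sd": pop.subject_effect_sd,
            "traits": [asdict(t) for t in pop.traits],
            "n_friend": pop.n_friend,
            "n_stranger": pop.n_stranger,
            "seed": pop.seed,
        }
        return d


def _tupled(d, keys):
    return {k: (tuple(v) if k in keys and isinstance(v, list) else v)
            for k, v in d.items()}


def load_run_config(path) -> RunConfig:
    """Load a YAML (or JSON) run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    known = {"seed", "out_dir", "design", "population", "models", "mcmc",
             "effects_mode"}
    extra = set(raw) - known
    if extra:
        raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
    kwargs = {}
    for k in ("seed", "out_dir", "effects_mode"):
        if k in raw:
            kwargs[k] = raw[k]
    if "models" in raw:
        kwargs["models"] = tuple(raw["models"])
    if "design" in raw:
        d = _tupled(raw["design"], {"loss_factor_range", "gain_only_range",
                                    "mixed_gains", "guaranteed_fractions"})
        kwargs["design"] = DesignConfig(**d)
    if "mcmc" in raw:
        kwargs["mcmc"] = MCMCConfig(**raw["mcmc"])
    if "population" in raw:
        p = dict(raw["population"])
        eff = p.get("true_social_effects", {})
        p["true_social_effects"] = SocialEffects(**eff)
        p["traits"] = tuple(TraitSpec(**t) for t in p.get("traits", []))
        p["group_log_means"] = tuple(p["group_log_means"])
        p["group_log_sds"] = tuple(p["group_log_sds"])
        kwargs["population"] = PopulationConfig(**p)
    try:
        return RunConfig(**kwargs)
    except TypeError as e:
        raise ConfigurationError(str(e)) from e


def _config_hash(config_dict: dict) -> str:
    canon = json.dumps(config_dict, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage, persisting each output before the next starts.

    Stage failures abort with the stage name; partial outputs are left in
    place.  Returns the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    cfg_dict = config.to_dict()
    cfg_hash = _config_hash(cfg_dict)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    log.info("config hash %s, master seed %d", cfg_hash, config.seed)

    stage = "simulate"
    try:
        pop = config.resolved_population()
        agents, trials = simulate_cohort(pop, config.design, config.effects_mode)
        write_trials(trials, out / "trials.csv")
        write_agents(agents_to_table(agents), out / "agents.csv")
        log.info("simulate: %d agents, %d trials", len(agents), len(trials))

        stage = "fit"
        posteriors = {}
        for model_id in config.models:
            post = fit_model(trials, model_id, config.mcmc)
            posteriors[model_id] = post
            write_posterior(post, out / f"posterior_{model_id}")
            log.info("fit %s: %d divergences, %.1fs", model_id,
                     post.meta["divergences"], post.meta["runtime_seconds"])

        stage = "report"
        from .reports import (implied_condition_means_from_draws,
                              condition_means_markdown, recovery_report)
        reports = {}
        for model_id, post in posteriors.items():
            rec = recovery_report(pop, post,
                                  agents=agents if model_id == "M2" else None)
            reports[model_id] = {"recovery": rec.to_dict()}
            if model_id == "M1":
                logs = post.flat("group_mean")
                deltas = post.flat("delta")
                cm = implied_condition_means_from_draws(logs, deltas)
                (out / "condition_means.md").write_text(condition_means_markdown(cm))
                reports[model_id]["condition_means"] = cm.to_dict(orient="records")
        if len(posteriors) > 1:
            from .inference import compare_waic, waic
            wtab = {m: waic(p.loglik).to_dict() for m, p in posteriors.items()}
            ids = list(posteriors)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    wtab[f"{ids[i]}_vs_{ids[j]}"] = compare_waic(
                        posteriors[ids[i]].loglik, posteriors[ids[j]].loglik)
            write_json(wtab, out / "waic.json")
        write_json({"config_hash": cfg_hash, "reports": reports},
                   out / "reports.json")
        log.info("pipeline complete")
    except Exception:
        log.exception("pipeline failed in stage %s", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
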