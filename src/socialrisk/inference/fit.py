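"""Model fitting: run chains, collect draws, pointwise log-likelihood."""

from __future__ import annotations

import time
import warnings

import numpy as np
import pandas as pd

from ..exceptions import InitializationError
from .hmc import MCMCConfig, run_chain
from .model import HierarchicalModel, ModelSpec, PriorConfig

__all__ = ["PosteriorSamples", "fit_model"]

_DIVERGENCE_WARN_FRACTION = 0.02


class PosteriorSamples:
    """Draws indexed by (chain, iteration, parameter) plus the pointwise
    log-likelihood matrix and sampler metadata."""

    def __init__(self, draws, registry, parameter_names, participants,
                 loglik=None, meta=None):
        self.draws = draws                    # (chains, iters, dim)
        self.registry = registry              # name -> (offset, shape)
        self.parameter_names = parameter_names
        self.participants = participants
        self.loglik = loglik                  # (chains*iters, n_trials) or None
        self.meta = meta or {}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Block draws shaped (chains, iters, *block_shape)."""
        off, shape = self.registry[name]
        size = int(np.prod(shape))
        block = self.draws[:, :, off:off + size]
        return block.reshape(self.draws.shape[0], self.draws.shape[1], *shape)

    def flat(self, name: str) -> np.ndarray:
        """Block draws with chains stacked: (chains*iters, *block_shape)."""
        off, shape = self.registry[name]
        size = int(np.prod(shape))
        flat = self.draws.reshape(-1, self.draws.shape[2])[:, off:off + size]
        return flat.reshape(-1, *shape)

    def flat_all(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_frame(self) -> pd.DataFrame:
        """Long format (chain, iteration, parameter, value) for serialization."""
        chains, iters, dim = self.draws.shape
        chain_col = np.repeat(np.arange(chains), iters * dim)
        iter_col = np.tile(np.repeat(np.arange(iters), dim), chains)
        param_col = np.tile(np.asarray(self.parameter_names, dtype=object),
                            chains * iters)
        return pd.DataFrame({
            "chain": chain_col,
            "iteration": iter_col,
            "parameter": param_col,
            "value": self.draws.ravel(),
        })


def fit_model(
    table: pd.DataFrame,
    model_spec: ModelSpec | str,
    mcmc_config: MCMCConfig = MCMCConfig(),
    priors: PriorConfig = PriorConfig(),
    compute_loglik: bool = True,
) -> PosteriorSamples:
    """Fit one model to a long trial table by HMC.

    All randomness descends from ``mcmc_config.seed``; chains are run
    sequentially with independent child seeds.  Raises
    :class:`InitializationError` if no finite starting point is found, and
    records (plus warns about) an elevated divergence fraction.
    """
    if isinstance(model_spec, str):
        model_spec = ModelSpec(model_spec)
    model = HierarchicalModel(table, model_spec, priors)

    ss = np.random.SeedSequence(mcmc_config.seed)
    children = ss.spawn(mcmc_config.chains)
    all_draws = np.empty((mcmc_config.chains, mcmc_config.draws, model.n_params))
    chain_stats = []
    t0 = time.time()
    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        theta0 = None
        for attempt, jitter in enumerate((0.1, 0.05, 0.02, 0.01, 0.0)):
            cand = model.initial_point(rng, jitter=jitter)
            lp, _ = model.logp_grad(cand)
            if np.isfinite(lp):
                theta0 = cand
                break
        if theta0 is None:
            raise InitializationError(
                f"chain {c}: log density non-finite at every candidate start "
                f"(last lp={lp}); check data scaling"
            )
        draws, stats = run_chain(model.logp_grad, theta0, mcmc_config, rng)
        all_draws[c] = draws
        chain_stats.append(stats)

    total_iters = mcmc_config.chains * (mcmc_config.warmup + mcmc_config.draws)
    n_div = sum(s["divergences"] for s in chain_stats)
    meta = {
        "model_id": model_spec.model_id,
        "chains": mcmc_config.chains,
        "warmup": mcmc_config.warmup,
        "draws_per_chain": mcmc_config.draws,
        "seed": mcmc_config.seed,
        "scaled_down": mcmc_config.scaled_down,
        "priors": priors.to_dict(),
        "divergences": n_div,
        "divergence_fraction": n_div / total_iters,
        "step_sizes": [s["step_size"] for s in chain_stats],
        "mean_accept": [s["mean_accept"] for s in chain_stats],
        "runtime_seconds": time.time() - t0,
        "warnings": [],
    }
    if meta["divergence_fraction"] > _DIVERGENCE_WARN_FRACTION:
        msg = (f"{n_div} divergent transitions "
               f"({100 * meta['divergence_fraction']:.1f}% of iterations)")
        meta["warnings"].append(msg)
        warnings.warn(msg, stacklevel=2)

    loglik = None
    if compute_loglik:
        flat = all_draws.reshape(-1, model.n_params)
        loglik = np.empty((flat.shape[0], model.n_trials), dtype=np.float32)
        for i in range(flat.shape[0]):
            loglik[i] = model.pointwise_loglik(flat[i])

    return PosteriorSamples(
        draws=all_draws,
        registry=dict(model.registry),
        parameter_names=model.parameter_names(),
        participants=list(model.participants),
        loglik=loglik,
        meta=meta,
    )
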