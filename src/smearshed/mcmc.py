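"""Adaptive Metropolis-within-Gibbs engine and posterior containers.

All models in this package are sampled with componentwise random-walk
Metropolis inside a Gibbs sweep, vectorised across chains and across the
components of each parameter block. Proposal step sizes are tuned during
warmup by Robbins-Monro stochastic approximation toward a target acceptance
rate, then frozen for the sampling phase.

Convergence is summarised by split-R̂ and bulk effective sample size
(computed with arviz) for every stored parameter; fits fail loudly when any
R̂ reaches 1.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import arviz as az
import numpy as np
import pandas as pd

from .errors import ConfigError, ConvergenceError

RHAT_THRESHOLD = 1.05


@dataclass
class McmcConfig:
    """Sampler settings shared by all model fits.

    ``n_iterations`` is the total per chain including warmup; the retained
    sample has ``n_iterations - n_warmup`` draws per chain.
    """

    n_chains: int = 4
    n_iterations: int = 5000
    n_warmup: int = 2500
    seed: int = 0
    target_accept: float = 0.35

    def validate(self) -> None:
        if self.n_chains < 2:
            raise ConfigError("at least 2 chains are required for split-R-hat")
        if not 0 < self.n_warmup < self.n_iterations:
            raise ConfigError("need 0 < n_warmup < n_iterations")
        if not 0 < self.target_accept < 1:
            raise ConfigError("target_accept must lie in (0, 1)")

    @property
    def n_draws(self) -> int:
        return self.n_iterations - self.n_warmup


def half_cauchy_logpdf(x, gamma: float):
    """Log density of the half-Cauchy(0, gamma) prior used for all scales."""
    x = np.asarray(x, dtype=float)
    return math.log(2.0 / (math.pi * gamma)) - np.log1p((x / gamma) ** 2)


class StepAdapter:
    """Robbins-Monro adaptation of log step sizes toward a target acceptance.

    One step size per proposal component (vectorised); adaptation happens
    only while ``adapting`` is true, with gain decaying as t^-0.6.
    """

    def __init__(self, shape, init_step: float, target: float):
        self.log_step = np.full(shape, math.log(init_step))
        self.target = target
        self.t = 0

    @property
    def step(self) -> np.ndarray:
        return np.exp(self.log_step)

    def update(self, accept_prob: np.ndarray) -> None:
        self.t += 1
        gain = self.t ** -0.6
        self.log_step += gain * (accept_prob - self.target)
        np.clip(self.log_step, -12.0, 6.0, out=self.log_step)


def mh_accept(log_ratio: np.ndarray, rng: np.random.Generator):
    """Vectorised Metropolis accept step.

    Returns (accept mask, acceptance probability) for adaptation.
    """
    log_ratio = np.where(np.isnan(log_ratio), -np.inf, log_ratio)
    accept_prob = np.exp(np.minimum(0.0, log_ratio))
    u = rng.random(size=log_ratio.shape)
    return np.log(u) < log_ratio, accept_prob


def segment_layout(idx: np.ndarray, n_levels: int):
    """Sorting order and segment starts for per-level sums via reduceat.

    Every level must be non-empty (guaranteed upstream where levels are
    derived from the data).
    """
    order = np.argsort(idx, kind="stable")
    starts = np.searchsorted(idx[order], np.arange(n_levels))
    return order, starts


def segment_sums(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Per-segment sums along the last axis of a (chains, n) array."""
    return np.add.reduceat(values, starts, axis=-1)


@dataclass
class PosteriorSamples:
    """Labelled posterior draws with convergence metadata.

    ``draws`` maps parameter name to an array of shape (chain, draw) for
    scalars or (chain, draw, k) for vector blocks, with ``coords`` giving
    the trailing-dimension labels. ``rhat`` / ``ess`` are flattened per
    scalar component, keyed like ``"mu[aBV]"``.
    """

    draws: dict
    coords: dict = field(default_factory=dict)
    model: Optional[object] = None  # the generating ModelSpec
    mcmc: Optional[McmcConfig] = None
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rhat:
            self._compute_diagnostics()

    def _compute_diagnostics(self) -> None:
        idata = az.from_dict(posterior=self.draws)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        for name, arr in self.draws.items():
            r = np.atleast_1d(np.asarray(rhat[name]))
            e = np.atleast_1d(np.asarray(ess[name]))
            labels = self._labels(name, arr)
            for lab, rv, ev in zip(labels, r.ravel(), e.ravel()):
                self.rhat[lab] = float(rv)
                self.ess[lab] = float(ev)

    def _labels(self, name: str, arr: np.ndarray) -> list[str]:
        if arr.ndim == 2:
            return [name]
        labels = self.coords.get(name)
        if labels is None:
            labels = [str(i) for i in range(arr.shape[2])]
        return [f"{name}[{lab}]" for lab in labels]

    # -- access -------------------------------------------------------------
    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def extract(self, name: str, level: Optional[str] = None) -> np.ndarray:
        """All draws of one scalar component, chains concatenated."""
        arr = self.draws[name]
        if arr.ndim == 2:
            return arr.reshape(-1)
        if level is None:
            return arr.reshape(-1, arr.shape[2])
        labels = self.coords.get(name)
        if labels is None or level not in labels:
            raise KeyError(f"unknown level {level!r} for parameter {name!r}")
        return arr[:, :, labels.index(level)].reshape(-1)

    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            labels = self._labels(name, arr)
            flat = arr.reshape(-1, 1) if arr.ndim == 2 else arr.reshape(-1, arr.shape[2])
            for j, lab in enumerate(labels):
                d = flat[:, j]
                rows.append(
                    {
                        "parameter": lab,
                        "mean": float(np.mean(d)),
                        "sd": float(np.std(d, ddof=1)),
                        "q2.5": float(np.quantile(d, 0.025)),
                        "median": float(np.median(d)),
                        "q97.5": float(np.quantile(d, 0.975)),
                        "rhat": self.rhat[lab],
                        "ess_bulk": self.ess[lab],
                    }
                )
        return pd.DataFrame(rows)

    def permute_chains(self, order) -> "PosteriorSamples":
        """Same posterior with chains reordered (diagnostics recomputed)."""
        draws = {k: v[list(order)] for k, v in self.draws.items()}
        return PosteriorSamples(draws=draws, coords=dict(self.coords),
                                model=self.model, mcmc=self.mcmc)


def require_converged(posterior: PosteriorSamples,
                      threshold: float = RHAT_THRESHOLD) -> PosteriorSamples:
    """Raise :class:`ConvergenceError` if any split-R̂ is at/above threshold."""
    bad = {k: v for k, v in posterior.rhat.items() if v >= threshold}
    if bad:
        worst = max(bad, key=bad.get)
        raise ConvergenceError(
            f"{len(bad)} parameter(s) with split-R-hat >= {threshold} "
            f"(worst {worst}: {bad[worst]:.3f})",
            rhat=posterior.rhat,
        )
    return posterior
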