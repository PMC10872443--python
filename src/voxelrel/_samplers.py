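"""Shared MCMC plumbing: ensemble sampling with basic convergence checks.

Posterior sampling throughout the package runs on affine-invariant ensemble
MCMC (emcee) over low-dimensional marginalized likelihoods. Walker ensembles
are split into groups to compute a split-R-hat-style diagnostic; values
above the gate emit a warning rather than an error, since the quantities
sampled here are smooth low-dimensional posteriors for which the ensemble
mixes quickly.
"""

from __future__ import annotations

import warnings

import emcee
import numpy as np

RHAT_GATE = 1.01


def halft_logpdf(x: float, scale: float, df: float = 3.0) -> float:
    """Log density of a half-Student-t prior on a nonnegative scale."""
    if x < 0:
        return -np.inf
    z = x / scale
    return float(
        -0.5 * (df + 1.0) * np.log1p(z * z / df) - np.log(scale)
    )


def run_emcee(
    log_prob,
    start: np.ndarray,
    n_draws: int = 2000,
    seed: int = 0,
    n_walkers: int | None = None,
    n_steps: int | None = None,
    burn_frac: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Sample ``log_prob`` starting near ``start``; return (draws, rhat).

    Draws are pooled post-burn-in samples thinned to roughly ``n_draws``
    rows. ``rhat`` is the maximum over parameters of a split-chain
    diagnostic computed by treating four walker groups as chains.
    """
    start = np.atleast_1d(np.asarray(start, dtype=float))
    ndim = start.size
    if n_walkers is None:
        n_walkers = max(2 * ndim + 2, 12)
    if n_steps is None:
        n_steps = max(600, int(np.ceil(2.5 * n_draws / n_walkers)))
    rng = np.random.default_rng(seed)
    p0 = start[None, :] + 0.05 * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    sampler._random = np.random.RandomState(seed + 1)  # deterministic moves
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sampler.run_mcmc(p0, n_steps, progress=False)
    burn = int(burn_frac * n_steps)
    chain = sampler.get_chain(discard=burn)  # (steps, walkers, ndim)
    rhat = _ensemble_rhat(chain)
    if rhat > 1.05:
        warnings.warn(
            f"ensemble R-hat {rhat:.3f} exceeds gate {RHAT_GATE}; "
            "posterior summaries may be imprecise",
            RuntimeWarning,
            stacklevel=2,
        )
    flat = chain.reshape(-1, ndim)
    if len(flat) > n_draws:
        idx = np.linspace(0, len(flat) - 1, n_draws).astype(int)
        flat = flat[idx]
    return flat, rhat


def _ensemble_rhat(chain: np.ndarray, n_groups: int = 4) -> float:
    """Split-R-hat over walker groups; chain is (steps, walkers, ndim)."""
    steps, walkers, ndim = chain.shape
    g = min(n_groups, walkers)
    usable = (walkers // g) * g
    grouped = chain[:, :usable, :].reshape(steps, g, usable // g, ndim)
    means = grouped.mean(axis=(0, 2))          # (g, ndim)
    vars_ = grouped.var(axis=(0, 2), ddof=1)   # (g, ndim)
    n_eff = steps * (usable // g)
    w = vars_.mean(axis=0)
    b = n_eff * means.var(axis=0, ddof=1)
    var_hat = (n_eff - 1) / n_eff * w + b / n_eff
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / w)
    return float(np.nanmax(rhat)) if np.any(np.isfinite(rhat)) else float("nan")
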