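"""Variance-component reliability statistics for voxel contrast panels.

Three statistics are implemented, all defined as variance-share ratios of a
Gaussian multilevel model:

* **Pairwise test-retest ICC** — for each pair of adjacent sessions, a
  two-level model ``y_ij = b0 + b_i + pi_j + eps_ij`` (session fixed effects,
  participant random intercept) gives ``ICC_pair = s_pi^2 / (s_pi^2 +
  s_eps^2)``, the ICC(3,1) "consistent agreement" coefficient. Pair
  posteriors are logit-transformed and pooled with a normal-normal
  hierarchical meta-analysis whose back-transformed mean is the latent
  test-retest reliability.
* **Internal consistency** — a three-level model ``y_ijk = b0 + b_i +
  lambda_j + pi_jk + eps_ijk`` over all voxels and sessions gives
  ``ICC_within = s_pi^2 / (s_lambda^2 + s_pi^2 + s_eps^2)``, the share of
  variance carried by participant-session means (voxel-to-voxel coherence
  within a scan).
* **Multilevel alpha** — the same ratio with the error variance divided by
  the number of items, ``alpha = s_pi^2 / (s_lambda^2 + s_pi^2 +
  s_eps^2/k)``, the generalizability-theory analogue of Cronbach's alpha.

Backends
--------
``backend="mcmc"`` (default) samples the variance components with emcee from
the restricted likelihood — for balanced designs the fixed effects integrate
out exactly and the likelihood reduces to independent scaled-chi-square
sufficient statistics, so sampling is fast and exact. Priors are
half-Student-t(3, 2.5 * sd(y)) on component SDs. ``backend="reml"`` returns
the classical mean-squares (ANOVA/REML) point estimates; on balanced data
the two agree closely and the REML route doubles as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._samplers import halft_logpdf, run_emcee

__all__ = [
    "ICCEstimate",
    "PooledICC",
    "ICCWithinEstimate",
    "AlphaEstimate",
    "fit_variance_components_2level",
    "icc_pair_from_components",
    "pool_icc_meta",
    "fit_internal_consistency",
    "multilevel_alpha",
    "icc_oneway",
    "adjacent_pairs",
    "retest_reliability",
]

LOGIT_CLAMP = 1e-6  # boundary clamp applied to ICC draws before logit


@dataclass
class ICCEstimate:
    """Posterior summary of one session pair's test-retest ICC."""

    pair: tuple[int, int]
    icc_median: float
    logit_median: float
    logit_sd: float
    sigma_pi2: float
    sigma_eps2: float
    draws: np.ndarray | None = None
    rhat: float = float("nan")


@dataclass
class PooledICC:
    """Meta-analytic pooled test-retest ICC (latent-mean posterior)."""

    icc_median: float
    icc_ci: tuple[float, float]
    mu_median: float
    tau_median: float
    draws_mu: np.ndarray | None = None


@dataclass
class ICCWithinEstimate:
    """Posterior summary of a parcel's internal consistency."""

    parcel: int | str
    icc_median: float
    icc_ci: tuple[float, float]
    sigma_lambda2: float
    sigma_pi2: float
    sigma_eps2: float
    n_voxels: int
    draws: np.ndarray | None = None
    rhat: float = float("nan")


@dataclass
class AlphaEstimate:
    alpha: float
    k: int


def icc_pair_from_components(sigma_pi2, sigma_eps2):
    """``ICC_pair = s_pi^2 / (s_pi^2 + s_eps^2)``; applied draw-wise."""
    sigma_pi2 = np.asarray(sigma_pi2, dtype=float)
    sigma_eps2 = np.asarray(sigma_eps2, dtype=float)
    if np.any(sigma_pi2 < 0) or np.any(sigma_eps2 < 0):
        raise ValueError("variances must be >= 0")
    total = sigma_pi2 + sigma_eps2
    if np.any(total == 0):
        raise ZeroDivisionError("ICC undefined when both variances are zero")
    out = sigma_pi2 / total
    return float(out) if out.ndim == 0 else out


def multilevel_alpha(
    sigma_lambda2: float, sigma_pi2: float, sigma_eps2: float, k: int
) -> AlphaEstimate:
    """Generalizability-theory alpha: error variance scaled by item count."""
    if k < 1:
        raise ValueError("item count k must be >= 1")
    denom = sigma_lambda2 + sigma_pi2 + sigma_eps2 / k
    if denom == 0:
        raise ZeroDivisionError("alpha undefined for all-zero components")
    return AlphaEstimate(alpha=sigma_pi2 / denom, k=k)


# ---------------------------------------------------------------------------
# Two-level test-retest fit
# ---------------------------------------------------------------------------

def _pair_sufficient_stats(df: pd.DataFrame, sessions: tuple[int, int]):
    sub = df[df["session"].isin(sessions)]
    wide = sub.pivot_table(
        index="participant", columns="session", values="value", aggfunc="mean"
    ).dropna()
    n = len(wide)
    if n < 3:
        raise ValueError(
            f"need >= 3 participants with both sessions {sessions}, got {n}"
        )
    y = wide.to_numpy()  # n x 2
    # remove session means (fixed effects); remaining SS are the REML stats
    r = y - y.mean(axis=0, keepdims=True)
    row = r.mean(axis=1, keepdims=True)
    ssp = 2.0 * float(np.sum((row - row.mean()) ** 2))  # E = eps2 + 2 pi2
    sse = float(np.sum((r - row) ** 2))  # interaction SS, E = eps2
    dfp = n - 1
    dfe = n - 1  # (n-1)(S-1) with S=2
    return n, y, ssp, sse, dfp, dfe


def fit_variance_components_2level(
    df: pd.DataFrame,
    sessions: tuple[int, int],
    backend: str = "mcmc",
    n_draws: int = 2000,
    seed: int = 0,
    keep_draws: bool = True,
) -> ICCEstimate:
    """Fit the two-level test-retest model for one pair of sessions.

    ``df`` holds one value per (participant, session) for a single parcel
    (columns ``participant, session, value``). Participants missing either
    session are dropped. Returns an :class:`ICCEstimate` whose posterior
    draws (mcmc backend) or point estimate (reml backend) summarize
    ``ICC_pair``.
    """
    n, y, ssp, sse, dfp, dfe = _pair_sufficient_stats(df, tuple(sessions))
    sd_y = float(np.std(y)) or 1.0

    # REML / ANOVA closed form (two-way mean squares, k = 2 sessions)
    msr, mse = ssp / dfp, sse / dfe
    eps2_hat = mse
    pi2_hat = max(0.0, (msr - mse) / 2.0)

    if backend == "reml":
        icc = icc_pair_from_components(pi2_hat, eps2_hat) if (pi2_hat + eps2_hat) else 0.0
        il = _logit(np.clip(icc, LOGIT_CLAMP, 1 - LOGIT_CLAMP))
        return ICCEstimate(
            pair=tuple(sessions), icc_median=float(icc), logit_median=float(il),
            logit_sd=float("nan"), sigma_pi2=pi2_hat, sigma_eps2=eps2_hat,
        )
    if backend != "mcmc":
        raise ValueError(f"unknown backend {backend!r}")

    prior_scale = 2.5 * sd_y

    def logpost(theta):
        log_sp, log_se = theta
        sp, se = np.exp(log_sp), np.exp(log_se)
        pi2, eps2 = sp * sp, se * se
        v = eps2 + 2.0 * pi2
        ll = -0.5 * (dfe * np.log(eps2) + sse / eps2 + dfp * np.log(v) + ssp / v)
        lp = halft_logpdf(sp, prior_scale) + halft_logpdf(se, prior_scale)
        return ll + lp + log_sp + log_se  # Jacobian of log parametrization

    start = np.log([np.sqrt(max(pi2_hat, 1e-3 * sd_y**2)),
                    np.sqrt(max(eps2_hat, 1e-3 * sd_y**2))])
    draws, rhat = run_emcee(logpost, start, n_draws=n_draws, seed=seed)
    pi2 = np.exp(2 * draws[:, 0])
    eps2 = np.exp(2 * draws[:, 1])
    icc = icc_pair_from_components(pi2, eps2)
    icc_cl = np.clip(icc, LOGIT_CLAMP, 1 - LOGIT_CLAMP)
    logit = _logit(icc_cl)
    return ICCEstimate(
        pair=tuple(sessions),
        icc_median=float(np.median(icc)),
        logit_median=float(np.median(logit)),
        logit_sd=float(np.std(logit, ddof=1)),
        sigma_pi2=float(np.median(pi2)),
        sigma_eps2=float(np.median(eps2)),
        draws=icc if keep_draws else None,
        rhat=rhat,
    )


def adjacent_pairs(sessions: list[int] | np.ndarray, disjoint: bool = False):
    """Overlapping adjacent pairs (1,2),(2,3),... or disjoint (1,2),(3,4),..."""
    s = sorted(set(int(v) for v in sessions))
    step = 2 if disjoint else 1
    return [(s[i], s[i + 1]) for i in range(0, len(s) - 1, step)]


def retest_reliability(
    df: pd.DataFrame,
    backend: str = "mcmc",
    disjoint: bool = False,
    seed: int = 0,
    n_draws: int = 2000,
) -> tuple[list[ICCEstimate], PooledICC]:
    """Pairwise ICCs across adjacent sessions plus the pooled estimate."""
    pairs = adjacent_pairs(df["session"].unique(), disjoint=disjoint)
    ests = [
        fit_variance_components_2level(
            df, p, backend=backend, seed=seed + 1000 * i, n_draws=n_draws,
            keep_draws=False,
        )
        for i, p in enumerate(pairs)
    ]
    if backend == "reml":
        # point estimates carry no posterior SD; use a jackknife-free normal
        # approx from the logit point spread for pooling weights
        for e in ests:
            e.logit_sd = 1.0
    pooled = pool_icc_meta(ests, seed=seed + 99991)
    return ests, pooled


# ---------------------------------------------------------------------------
# Meta-analytic pooling
# ---------------------------------------------------------------------------

def pool_icc_meta(
    estimates: list[ICCEstimate],
    seed: int = 0,
    n_draws: int = 2000,
    fixed_effect: bool = False,
) -> PooledICC:
    """Pool logit-scale pair ICCs with a normal-normal hierarchical model.

    Observed ``logit(ICC_pair) ~ Normal(latent_i, SE_i)``; ``latent_i ~
    Normal(mu, tau)``. The latent means marginalize out, leaving ``d_i ~
    Normal(mu, sqrt(tau^2 + SE_i^2))``. The report is the inverse-logit of
    the ``mu`` posterior (median and central 95% interval). With
    ``fixed_effect=True`` tau is pinned at 0, giving the closed-form
    inverse-variance weighted mean.
    """
    if len(estimates) < 2:
        raise ValueError("need >= 2 pair estimates to pool")
    d = np.array([e.logit_median for e in estimates], dtype=float)
    s = np.array([e.logit_sd for e in estimates], dtype=float)
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(s)) and np.all(s >= 0)):
        raise ValueError("non-finite logit summaries in meta-analysis input")
    s = np.maximum(s, 1e-6)

    if fixed_effect:
        w = 1.0 / s**2
        mu = float(np.sum(w * d) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        lo, hi = mu - 1.96 * se, mu + 1.96 * se
        return PooledICC(
            icc_median=float(_inv_logit(mu)),
            icc_ci=(float(_inv_logit(lo)), float(_inv_logit(hi))),
            mu_median=mu, tau_median=0.0,
        )

    prior_scale = 2.5 * max(float(np.std(d, ddof=1)), 0.1)

    def logpost(theta):
        mu, log_tau = theta
        tau = np.exp(log_tau)
        var = tau * tau + s * s
        ll = -0.5 * np.sum(np.log(var) + (d - mu) ** 2 / var)
        return ll + halft_logpdf(tau, prior_scale) + log_tau

    start = np.array([float(np.mean(d)), np.log(max(np.std(d, ddof=1), 1e-3))])
    draws, _ = run_emcee(logpost, start, n_draws=n_draws, seed=seed)
    mu_draws = draws[:, 0]
    icc_draws = _inv_logit(mu_draws)
    lo, hi = np.quantile(icc_draws, [0.025, 0.975])
    return PooledICC(
        icc_median=float(np.median(icc_draws)),
        icc_ci=(float(lo), float(hi)),
        mu_median=float(np.median(mu_draws)),
        tau_median=float(np.median(np.exp(draws[:, 1]))),
        draws_mu=mu_draws,
    )


# ---------------------------------------------------------------------------
# Three-level internal consistency
# ---------------------------------------------------------------------------

def _three_level_stats(panel: pd.DataFrame):
    """Balanced-design sufficient statistics for the three-level model."""
    counts = panel.groupby(["participant", "session"])["value"].count()
    if counts.nunique() != 1:
        raise ValueError("panel must be balanced (equal voxels per cell)")
    v = int(counts.iloc[0])
    if v < 2:
        raise ValueError("need >= 2 voxels per cell for internal consistency")
    cells = panel.groupby(["participant", "session"])["value"].mean().unstack()
    n, s = cells.shape
    if n < 3 or s < 2:
        raise ValueError("need >= 3 participants and >= 2 sessions")
    m = cells.to_numpy()
    gm = m.mean()
    row = m.mean(axis=1, keepdims=True)
    col = m.mean(axis=0, keepdims=True)
    ssp = s * float(np.sum((row - gm) ** 2))                # df n-1
    sse = float(np.sum((m - row - col + gm) ** 2))          # df (n-1)(s-1)
    cell_sq = panel.groupby(["participant", "session"])["value"].var(ddof=0)
    ssw = float((cell_sq * v).sum())                        # df n*s*(v-1)
    return n, s, v, ssp, sse, ssw, float(np.std(panel["value"])) or 1.0


def fit_internal_consistency(
    panel: pd.DataFrame,
    backend: str = "mcmc",
    n_draws: int = 2000,
    seed: int = 0,
    keep_draws: bool = False,
) -> ICCWithinEstimate:
    """Fit the three-level model to one parcel's full voxel panel.

    Sessions enter as fixed effects (conditioned out via the REML
    projection); participant and participant-session intercepts are random.
    Reports the posterior (or REML point) of ``ICC_within`` as the raw
    variance share, without the /k item scaling.
    """
    n, s, v, ssp, sse, ssw, sd_y = _three_level_stats(panel)
    dfp, dfe, dfw = n - 1, (n - 1) * (s - 1), n * s * (v - 1)
    parcel = panel["parcel"].iloc[0] if "parcel" in panel else 0

    # moment / REML closed form
    eps2_hat = ssw / dfw
    cell_var_hat = sse / dfe                       # = pi2 + eps2/v
    pi2_hat = max(0.0, cell_var_hat - eps2_hat / v)
    lam2_hat = max(0.0, (ssp / dfp - cell_var_hat) / s)

    if backend == "reml":
        tot = lam2_hat + pi2_hat + eps2_hat
        icc = pi2_hat / tot if tot > 0 else 0.0
        return ICCWithinEstimate(
            parcel=parcel, icc_median=float(icc), icc_ci=(float("nan"),) * 2,
            sigma_lambda2=lam2_hat, sigma_pi2=pi2_hat, sigma_eps2=eps2_hat,
            n_voxels=v,
        )
    if backend != "mcmc":
        raise ValueError(f"unknown backend {backend!r}")

    prior_scale = 2.5 * sd_y

    def logpost(theta):
        log_sl, log_sp, log_se = theta
        sl, sp, se = np.exp(theta)
        lam2, pi2, eps2 = sl * sl, sp * sp, se * se
        cell = pi2 + eps2 / v
        btw = cell + s * lam2
        ll = -0.5 * (
            dfw * np.log(eps2) + ssw / eps2
            + dfe * np.log(cell) + sse / cell
            + dfp * np.log(btw) + ssp / btw
        )
        lp = (
            halft_logpdf(sl, prior_scale)
            + halft_logpdf(sp, prior_scale)
            + halft_logpdf(se, prior_scale)
        )
        return ll + lp + log_sl + log_sp + log_se

    start = np.log(
        np.sqrt(
            np.maximum([lam2_hat, pi2_hat, eps2_hat], 1e-4 * sd_y**2)
        )
    )
    draws, rhat = run_emcee(logpost, start, n_draws=n_draws, seed=seed)
    lam2 = np.exp(2 * draws[:, 0])
    pi2 = np.exp(2 * draws[:, 1])
    eps2 = np.exp(2 * draws[:, 2])
    icc = pi2 / (lam2 + pi2 + eps2)
    lo, hi = np.quantile(icc, [0.025, 0.975])
    return ICCWithinEstimate(
        parcel=parcel,
        icc_median=float(np.median(icc)),
        icc_ci=(float(lo), float(hi)),
        sigma_lambda2=float(np.median(lam2)),
        sigma_pi2=float(np.median(pi2)),
        sigma_eps2=float(np.median(eps2)),
        n_voxels=v,
        draws=icc if keep_draws else None,
        rhat=rhat,
    )


# ---------------------------------------------------------------------------
# One-way ICC for behavioral predictors
# ---------------------------------------------------------------------------

def icc_oneway(df: pd.DataFrame, value_col: str = "x") -> float:
    """One-way random-effects ICC(1,1): between / (between + within).

    Works on a tidy panel with ``participant`` and a value column; handles
    unbalanced groups with the standard ANOVA group-size correction and
    truncates a negative between-variance at zero.
    """
    g = df.groupby("participant")[value_col]
    sizes = g.count().to_numpy(dtype=float)
    if len(sizes) < 3 or np.any(sizes < 1) or (sizes >= 2).sum() < 1:
        raise ValueError("need >= 3 participants with repeated measures")
    means = g.mean().to_numpy()
    gm = float(df[value_col].mean())
    ssb = float(np.sum(sizes * (means - gm) ** 2))
    ssw = float(((df[value_col] - g.transform("mean")) ** 2).sum())
    n_tot = sizes.sum()
    k = len(sizes)
    dfw = n_tot - k
    if dfw <= 0 or ssw + ssb == 0:
        raise ValueError("degenerate data: no within-participant variation")
    msb = ssb / (k - 1)
    msw = ssw / dfw
    k0 = (n_tot - np.sum(sizes**2) / n_tot) / (k - 1)
    b2 = max(0.0, (msb - msw) / k0)
    if b2 + msw == 0:
        raise ValueError("degenerate data: all values constant")
    return b2 / (b2 + msw)


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
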