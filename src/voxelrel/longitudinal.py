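"""Longitudinal within-person inference for dense-sampling fMRI designs.

The analysis chain implemented here:

1. **Predictor scoring** — two-week actigraphy sleep aggregation over
   19:00->19:00 windows, episodic stress sum scores and chronic stress
   maxima on the 1-5 half-point severity grid.
2. **Within/between centering** — each monthly predictor is split into a
   within-person component ``x_w`` (deviation from the person mean) and a
   between-person component ``x_b`` (person mean centered at the grand
   mean), so that ``x = grand_mean + x_b + x_w`` exactly.
3. **Group-level model** — a random-intercept linear mixed model
   ``y ~ 1 + time + x_b + x_w`` fit by REML, with CR2 cluster-robust
   (sandwich) standard errors clustered by participant and Bell-McCaffrey
   Satterthwaite degrees of freedom; the coefficient p-value is converted
   to a signed Z test statistic.
4. **Freedman-Lane permutation** — outcomes are residualized on the
   nuisance covariates (time, x_b) under the same random-intercept GLS,
   residuals are permuted only within participants, reconstructed outcomes
   are refit with the full robust pipeline, yielding an exchangeable null
   distribution of Z.
5. **Cluster-extent FWE** — permutation Z volumes are thresholded at a
   two-sided cluster-forming p, 6-connectivity clusters are extracted, and
   the null distribution of the maximum cluster extent calibrates a
   familywise-error-controlled extent threshold.
6. **Parcel posteriors and sign-error selection** — a parcel-level
   Bayesian model with participant and participant-session intercepts
   yields posterior draws of the within-person slope; parcels are ranked by
   sign-agreement probability and selected while the cumulative product
   (the probability of no sign error) stays above 1 - budget.
7. **Design power simulation** — Monte-Carlo power of the within-person
   coefficient test for a standardized effect under the study design.

Implementation notes: the mixed-model fit profiles the REML criterion over
the variance ratio ``rho = tau^2/sigma^2`` in closed form (balanced or
unbalanced clusters), then applies the CR2 adjustment and Satterthwaite df
on the GLS-whitened regression, following the working-model construction of
cluster-robust small-sample corrections. Permutation statistics hold the
whitening fixed at the observed-data estimate, so the identity permutation
reproduces the observed Z exactly.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special, stats

from ._samplers import halft_logpdf, run_emcee
from .synthetic import SEVERITY_GRID

__all__ = [
    "LongitudinalFit",
    "ParcelPosterior",
    "SleepAggregate",
    "center_within_between",
    "aggregate_sleep",
    "sle_sum_score",
    "chronic_score",
    "fit_longitudinal_model",
    "make_within_permutations",
    "freedman_lane_null",
    "voxelwise_freedman_lane",
    "cluster_fwe_threshold",
    "fit_parcel_posterior",
    "sign_error_select",
    "estimate_power",
]


# ---------------------------------------------------------------------------
# Predictor operations
# ---------------------------------------------------------------------------

def center_within_between(raw: pd.DataFrame, value_col: str = "x") -> pd.DataFrame:
    """Decompose a longitudinal predictor into within/between components.

    ``x_w = x - person mean``; ``x_b = person mean - grand mean`` where the
    grand mean is the mean of person means (so person-level contributions
    sum to zero even on unbalanced panels). The reconstruction
    ``x = grand_mean + x_b + x_w`` is exact.
    """
    out = raw.copy()
    person_mean = out.groupby("participant")[value_col].transform("mean")
    grand = out.groupby("participant")[value_col].mean().mean()
    out["x_w"] = out[value_col] - person_mean
    out["x_b"] = person_mean - grand
    out.attrs = dict(raw.attrs)
    out.attrs["grand_mean"] = float(grand)
    return out


@dataclass(frozen=True)
class SleepAggregate:
    """Two-week sleep-duration summary prior to a scan."""

    mean_hours: float
    n_windows_observed: int
    reason: str = ""

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.mean_hours)


def aggregate_sleep(
    events: pd.DataFrame,
    scan_date,
    min_windows: int = 7,
    n_windows: int = 14,
) -> SleepAggregate:
    """Mean nightly sleep hours over the two weeks before a scan.

    Days are 24-hour windows from 19:00 to 19:00; the most recent window
    ends at 19:00 on ``scan_date``. A window's duration is the total time of
    all sleep events intersected with it (naps included, awake gaps between
    events excluded; events spanning the 19:00 boundary are split across
    windows). Windows with no overlapping event count as unobserved; fewer
    than ``min_windows`` observed windows yields a missing-value sentinel.

    ``events`` holds one participant's records with ``onset``/``offset``
    timestamp columns.
    """
    if (pd.to_datetime(events["offset"]) <= pd.to_datetime(events["onset"])).any():
        raise ValueError("every sleep offset must be after its onset")
    end0 = pd.Timestamp(scan_date).normalize() + pd.Timedelta(hours=19)
    onsets = pd.to_datetime(events["onset"]).to_numpy()
    offsets = pd.to_datetime(events["offset"]).to_numpy()
    durations = []
    for d in range(n_windows):
        w_end = end0 - pd.Timedelta(days=d)
        w_start = w_end - pd.Timedelta(days=1)
        lo = np.maximum(onsets, np.datetime64(w_start))
        hi = np.minimum(offsets, np.datetime64(w_end))
        overlap = (hi - lo) / np.timedelta64(1, "h")
        overlap = overlap[overlap > 0]
        if overlap.size:
            durations.append(float(overlap.sum()))
    if len(durations) < min_windows:
        return SleepAggregate(
            float("nan"),
            len(durations),
            reason=f"only {len(durations)} of {n_windows} windows observed "
            f"(need >= {min_windows})",
        )
    return SleepAggregate(float(np.mean(durations)), len(durations))


def _validate_severities(sev: np.ndarray) -> None:
    if sev.size and not np.all(np.isin(np.round(sev, 6), np.round(SEVERITY_GRID, 6))):
        bad = sev[~np.isin(np.round(sev, 6), np.round(SEVERITY_GRID, 6))]
        raise ValueError(f"severities off the 1-5 half-point grid: {bad[:5]}")


def sle_sum_score(events: pd.DataFrame) -> float:
    """Episodic stress score: sum of severities of all episodic events in
    one participant-month; no events scores zero."""
    ep = events[events["type"] == "episodic"] if len(events) else events
    sev = np.asarray(ep["severity"], dtype=float) if len(ep) else np.array([])
    _validate_severities(sev)
    return float(sev.sum()) if sev.size else 0.0


def chronic_score(events: pd.DataFrame) -> float:
    """Chronic stress score: the severity of the domain with the highest
    ongoing stress in one participant-month (zero if none reported)."""
    ch = events[events["type"] == "chronic"] if len(events) else events
    sev = np.asarray(ch["severity"], dtype=float) if len(ch) else np.array([])
    _validate_severities(sev)
    return float(sev.max()) if sev.size else 0.0


# ---------------------------------------------------------------------------
# Random-intercept REML + CR2 cluster-robust inference (array core)
# ---------------------------------------------------------------------------

def _cluster_slices(sizes: np.ndarray):
    ends = np.cumsum(sizes)
    starts = ends - sizes
    return [slice(int(a), int(b)) for a, b in zip(starts, ends)]


def _whiten(M: np.ndarray, rho: float, sizes: np.ndarray) -> np.ndarray:
    """Apply the GLS whitening transform row-block-wise: within each cluster
    of size m, subtract ``a * cluster mean`` with ``a = 1 - (1+m rho)^-1/2``."""
    out = M.astype(float).copy()
    for sl, m in zip(_cluster_slices(sizes), sizes):
        a = 1.0 - 1.0 / np.sqrt(1.0 + m * rho)
        out[sl] -= a * out[sl].mean(axis=0, keepdims=True)
    return out


def _reml_rho(X: np.ndarray, y: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """Profile the REML criterion of the random-intercept model over
    ``rho = tau^2 / sigma^2``. Returns (rho_hat, sigma2_hat)."""
    n, p = X.shape

    def neg2_reml(log_rho: float) -> float:
        rho = np.exp(log_rho)
        Xw = _whiten(X, rho, sizes)
        yw = _whiten(y[:, None], rho, sizes)[:, 0]
        xtx = Xw.T @ Xw
        beta = np.linalg.solve(xtx, Xw.T @ yw)
        rss = float(np.sum((yw - Xw @ beta) ** 2))
        logdet_v = float(np.sum(np.log1p(sizes * rho)))
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        return (n - p) * np.log(rss / (n - p)) + logdet_v + logdet_xtx

    res = optimize.minimize_scalar(
        neg2_reml, bounds=(-12.0, 8.0), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(np.exp(res.x))
    # compare against the no-random-intercept boundary
    if neg2_reml(-30.0) < res.fun:
        rho = 0.0
    Xw = _whiten(X, rho, sizes)
    yw = _whiten(y[:, None], rho, sizes)[:, 0]
    beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
    sigma2 = float(np.sum((yw - Xw @ beta) ** 2) / (n - p))
    return rho, sigma2


def _cr2_shared(Xw: np.ndarray, sizes: np.ndarray):
    """Design-only CR2 pieces shared across coefficients: ``(X'X)^-1`` and
    the per-cluster adjusted matrices ``A_j X_j (X'X)^-1``."""
    B = np.linalg.inv(Xw.T @ Xw)
    slices = _cluster_slices(sizes)
    axb = []
    for sl in slices:
        Xj = Xw[sl]
        Hjj = Xj @ B @ Xj.T
        evals, evecs = np.linalg.eigh(np.eye(Xj.shape[0]) - Hjj)
        evals = np.clip(evals, 1e-12, None)
        Aj = (evecs / np.sqrt(evals)) @ evecs.T
        axb.append(Aj @ (Xj @ B))
    return B, slices, axb


def _cr2_precompute(
    Xw: np.ndarray,
    sizes: np.ndarray,
    coef_idx: int,
    shared=None,
):
    """CR2/Satterthwaite pieces for one coefficient: the extractor row ``w``
    (``beta_k = w @ y``), the per-cluster meat rows folded with the
    residual maker (``G_M``; the robust variance is ``sum_j (G_M[:,j]'y)^2``)
    and the Bell-McCaffrey Satterthwaite df."""
    n, p = Xw.shape
    B, slices, axb = shared if shared is not None else _cr2_shared(Xw, sizes)
    w = (B @ Xw.T)[coef_idx]
    G = np.zeros((n, len(slices)))
    for j, sl in enumerate(slices):
        G[sl, j] = axb[j][:, coef_idx]
    # G_M = (I - H)' G computed without forming H
    G_M = G - Xw @ (B @ (Xw.T @ G))
    # Satterthwaite df from the quadratic form B_q = G_M G_M'
    gram = G_M.T @ G_M
    tr = float(np.trace(gram))
    tr2 = float(np.sum(gram * gram))
    df = tr * tr / tr2 if tr2 > 0 else float(n - p)
    return w, G_M, df


def _z_from_t(t, df):
    t = np.asarray(t, dtype=float)
    p_half = special.stdtr(df, -np.abs(t))  # upper-tail t probability
    p_half = np.clip(p_half, 1e-300, 0.5)
    z = -special.ndtri(p_half)
    return np.sign(t) * z, 2.0 * p_half


@dataclass
class LongitudinalFit:
    """Robust mixed-model fit of ``y ~ 1 + time + x_b + x_w``."""

    params: dict[str, float]
    se: dict[str, float]
    df: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    zvalues: dict[str, float]
    rho: float
    sigma2: float
    tau2: float
    n_obs: int
    n_clusters: int

    @property
    def beta_within(self) -> float:
        return self.params["x_w"]


def _design_from_frame(data: pd.DataFrame, terms: list[str]):
    data = data.sort_values(["participant", "session"], kind="mergesort")
    sizes = data.groupby("participant", sort=False).size().to_numpy()
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for t in terms:
        cols.append(data[t].to_numpy(dtype=float))
        names.append(t)
    X = np.column_stack(cols)
    return data, X, names, sizes


def fit_longitudinal_model(
    y: pd.DataFrame | pd.Series,
    panel: pd.DataFrame | None = None,
    time: np.ndarray | None = None,
) -> LongitudinalFit:
    """Fit the group-level longitudinal model for one outcome series.

    ``y`` is a tidy frame with ``participant, session, value`` (one row per
    participant-session); ``panel`` a predictor frame with ``participant,
    session`` and either raw ``x`` (centered here) or precomputed
    ``x_w``/``x_b``. ``time`` defaults to months since the first session
    (``session - min(session)``). Inference: REML random intercept, CR2
    cluster-robust SE, Satterthwaite df, two-sided p, signed Z.
    """
    df = y.copy()
    if panel is not None:
        if "x_w" not in panel.columns:
            panel = center_within_between(panel)
        df = df.merge(
            panel[["participant", "session", "x_w", "x_b"]],
            on=["participant", "session"],
            validate="1:1",
        )
    if time is None:
        df["time"] = df["session"] - df["session"].min()
    else:
        df["time"] = np.asarray(time, dtype=float)
    terms = ["time"] + (["x_b", "x_w"] if panel is not None else [])
    df, X, names, sizes = _design_from_frame(df, terms)
    yv = df["value"].to_numpy(dtype=float)
    return _fit_array(X, yv, sizes, names)


def _fit_array(
    X: np.ndarray,
    yv: np.ndarray,
    sizes: np.ndarray,
    names: list[str],
    coef_names: list[str] | None = None,
) -> LongitudinalFit:
    n, p = X.shape
    if len(sizes) < 5:
        raise ValueError("need >= 5 participants")
    if np.linalg.matrix_rank(X) < p:
        r = np.linalg.qr(X, mode="r")
        bad = [names[i] for i in range(p) if abs(r[i, i]) < 1e-8 * abs(r[0, 0])]
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear columns: {bad}"
        )
    rho, sigma2 = _reml_rho(X, yv, sizes)
    Xw = _whiten(X, rho, sizes)
    yw = _whiten(yv[:, None], rho, sizes)[:, 0]
    shared = _cr2_shared(Xw, sizes)
    B = shared[0]
    beta = B @ (Xw.T @ yw)
    wanted = names if coef_names is None else coef_names
    params, se, dfs, tvals, pvals, zvals = {}, {}, {}, {}, {}, {}
    for k, name in enumerate(names):
        params[name] = float(beta[k])
        if name not in wanted:
            continue
        w, G_M, dfk = _cr2_precompute(Xw, sizes, k, shared=shared)
        var = float(np.sum((G_M.T @ yw) ** 2))
        t = beta[k] / np.sqrt(var) if var > 0 else np.inf * np.sign(beta[k])
        z, pv = _z_from_t(t, dfk)
        se[name] = float(np.sqrt(var))
        dfs[name] = float(dfk)
        tvals[name] = float(t)
        pvals[name] = float(pv)
        zvals[name] = float(z)
    return LongitudinalFit(
        params=params, se=se, df=dfs, tvalues=tvals, pvalues=pvals,
        zvalues=zvals, rho=rho, sigma2=sigma2, tau2=rho * sigma2,
        n_obs=n, n_clusters=len(sizes),
    )


# ---------------------------------------------------------------------------
# Within-participant permutations
# ---------------------------------------------------------------------------

def make_within_permutations(
    blocks: list[np.ndarray] | list[list[int]],
    n_perm: int,
    seed: int,
    exhaustive: bool = False,
    max_tries_factor: int = 20,
) -> np.ndarray:
    """Generate permutation rows that shuffle indexes only within blocks.

    ``blocks`` lists each participant's global observation indexes. Row 0 is
    always the identity; the remaining rows are distinct random
    within-block permutations (duplicates and the identity are rejected).
    With ``exhaustive=True`` (or when the block structure admits no more
    than ``n_perm`` distinct non-identity rows) all distinct permutations
    are enumerated instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    blocks = [np.asarray(b, dtype=int) for b in blocks]
    n = sum(len(b) for b in blocks)
    identity = np.arange(n)
    flat = np.concatenate(blocks)
    if sorted(flat.tolist()) != list(range(n)):
        raise ValueError("blocks must partition 0..n-1")

    log_total = sum(math.lgamma(len(b) + 1) for b in blocks)
    small = log_total <= math.log(5e6)
    total = int(round(math.exp(log_total))) if small else None

    if exhaustive or (small and total <= n_perm + 1):
        rows = []
        per_block = [list(itertools.permutations(b.tolist())) for b in blocks]
        for combo in itertools.product(*per_block):
            row = identity.copy()
            for b, perm in zip(blocks, combo):
                row[b] = np.asarray(perm)
            rows.append(row)
        mat = np.unique(np.stack(rows), axis=0)
        # put identity first
        is_id = np.all(mat == identity, axis=1)
        mat = np.concatenate([identity[None, :], mat[~is_id]], axis=0)
        return mat

    rng = np.random.default_rng(seed)
    seen = {identity.tobytes()}
    rows = [identity]
    tries = 0
    while len(rows) < n_perm + 1:
        tries += 1
        if tries > max_tries_factor * (n_perm + 10):
            raise RuntimeError("could not generate enough distinct permutations")
        row = identity.copy()
        for b in blocks:
            row[b] = rng.permutation(b)
        key = row.tobytes()
        if key in seen:
            continue
        seen.add(key)
        rows.append(row)
    return np.stack(rows)


def blocks_from_participants(participants: np.ndarray) -> list[np.ndarray]:
    """Index blocks for each participant, rows assumed sorted by participant."""
    participants = np.asarray(participants)
    _, starts = np.unique(participants, return_index=True)
    starts = np.sort(starts)
    ends = np.append(starts[1:], len(participants))
    return [np.arange(a, b) for a, b in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Freedman-Lane permutation null (vectorized over permutations and voxels)
# ---------------------------------------------------------------------------

def _fl_zstats(
    X_full: np.ndarray,
    reduced_cols: list[int],
    coef_idx: int,
    Y: np.ndarray,
    sizes: np.ndarray,
    perms: np.ndarray,
    rho: float | None = None,
    chunk: int = 128,
    single_precision: bool | None = None,
) -> tuple[np.ndarray, float]:
    """Z statistics of the target coefficient for every permutation row and
    every outcome column. Returns (Z of shape (n_perm_rows, V), df).

    The whitening ratio ``rho`` is estimated once from the observed data
    (mean outcome column) and held fixed across permutations; within-block
    permutation commutes with the block whitening transform, so the whole
    computation runs on the whitened scale. For wide outcome matrices the
    batched permutation algebra runs in single precision (relative error
    ~1e-7 on Z, far below Monte-Carlo noise); the single-column path stays
    in double precision.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, V = Y.shape
    if single_precision is None:
        single_precision = V * perms.shape[0] > 1_000_000
    if rho is None:
        rho, _ = _reml_rho(X_full, Y.mean(axis=1), sizes)
    Xw = _whiten(X_full, rho, sizes)
    Yw = _whiten(Y, rho, sizes)
    Xr = Xw[:, reduced_cols]
    Br = np.linalg.inv(Xr.T @ Xr)
    F = Xr @ (Br @ (Xr.T @ Yw))  # reduced-model fitted values
    E = Yw - F                   # exchangeable residuals
    w, G_M, df = _cr2_precompute(Xw, sizes, coef_idx)
    J = G_M.shape[1]
    wF = w @ F                   # (V,)
    GF = G_M.T @ F               # (J, V)
    fdtype = np.float32 if single_precision else np.float64
    E = E.astype(fdtype)
    G_Mf = G_M.astype(fdtype)
    R = perms.shape[0]
    Z = np.empty((R, V))
    for a in range(0, R, chunk):
        b = min(a + chunk, R)
        pr = perms[a:b]
        r = b - a
        Wmat = np.zeros((r, n), dtype=fdtype)
        np.put_along_axis(Wmat, pr, np.broadcast_to(w.astype(fdtype), (r, n)), axis=1)
        betas = wF[None, :] + Wmat @ E  # (r, V)
        Gbig = np.zeros((r, n, J), dtype=fdtype)
        Gbig[np.arange(r)[:, None], pr, :] = G_Mf[None, :, :]
        S = (Gbig.transpose(0, 2, 1).reshape(r * J, n) @ E).reshape(r, J, V)
        S += GF[None, :, :].astype(fdtype)
        var = np.einsum("rjv,rjv->rv", S, S)
        t = betas / np.sqrt(np.maximum(var, 1e-30))
        Z[a:b], _ = _z_from_t(t, df)
    return Z, df


def freedman_lane_null(
    y: pd.DataFrame,
    panel: pd.DataFrame,
    perms: np.ndarray | None = None,
    n_perm: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Permutation null distribution of the within-person coefficient Z.

    Residualizes the outcome on (intercept, time, x_b) under the
    random-intercept GLS, permutes residuals within participants according
    to each permutation row, reconstructs outcomes and recomputes the full
    robust Z. Returns the vector of Z values; element 0 corresponds to the
    identity permutation and therefore equals the observed statistic.
    """
    df = y.copy()
    if "x_w" not in panel.columns:
        panel = center_within_between(panel)
    df = df.merge(
        panel[["participant", "session", "x_w", "x_b"]],
        on=["participant", "session"], validate="1:1",
    )
    df["time"] = df["session"] - df["session"].min()
    df, X, names, sizes = _design_from_frame(df, ["time", "x_b", "x_w"])
    if perms is None:
        blocks = blocks_from_participants(df["participant"].to_numpy())
        perms = make_within_permutations(blocks, n_perm, seed)
    Z, _ = _fl_zstats(
        X, reduced_cols=[0, 1, 2], coef_idx=3,
        Y=df["value"].to_numpy(), sizes=sizes, perms=perms,
    )
    return Z[:, 0]


def voxelwise_freedman_lane(
    Y: np.ndarray,
    design: pd.DataFrame,
    mask: np.ndarray,
    n_perm: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Voxel-wise observed and permutation Z volumes for the within-person
    coefficient.

    ``Y`` is (n_obs, V) with columns matching the True voxels of ``mask``
    in C order; ``design`` has ``participant, session, x_w, x_b`` rows
    aligned with ``Y`` and sorted by participant. Returns
    ``(observed Z volume, null Z volumes (n_perm, *mask.shape), df)``.
    """
    design = design.reset_index(drop=True)
    t = (design["session"] - design["session"].min()).to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(design)), t, design["x_b"].to_numpy(), design["x_w"].to_numpy()]
    )
    sizes = design.groupby("participant", sort=False).size().to_numpy()
    blocks = blocks_from_participants(design["participant"].to_numpy())
    perms = make_within_permutations(blocks, n_perm, seed)
    Z, df = _fl_zstats(X, [0, 1, 2], 3, Y, sizes, perms)
    obs = np.full(mask.shape, 0.0)
    obs[mask] = Z[0]
    nulls = np.zeros((Z.shape[0] - 1,) + mask.shape)
    nulls[:, mask] = Z[1:]
    return obs, nulls, df


# ---------------------------------------------------------------------------
# Cluster-extent familywise-error control
# ---------------------------------------------------------------------------

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def _max_cluster_extent(volume: np.ndarray, zthr: float, mask: np.ndarray) -> int:
    binary = (np.abs(volume) > zthr) & mask
    if not binary.any():
        return 0
    labeled, nlab = ndimage.label(binary, structure=_SIX_CONN)
    return int(np.max(ndimage.sum_labels(np.ones_like(volume), labeled,
                                         index=np.arange(1, nlab + 1))))


def cluster_fwe_threshold(
    observed: np.ndarray,
    nulls: np.ndarray,
    cluster_forming_p: float = 0.01,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Max-cluster-extent permutation correction of a Z volume.

    Both the observed volume and each null volume are binarized at the
    two-sided cluster-forming threshold ``|Z| > Phi^-1(1 - p/2)`` and
    decomposed into 6-connectivity components. Observed clusters survive if
    their extent strictly exceeds the ``1 - alpha`` quantile of the null
    distribution of maximum extents (so a null set identical to the
    observed volume yields no survivors). Returns a table with columns
    ``cluster_id, extent, peak_z, peak_i, peak_j, peak_k, survives``.
    """
    nulls = np.asarray(nulls)
    if nulls.ndim == 3:
        nulls = nulls[None, ...]
    if len(nulls) == 0:
        raise ValueError("at least one null volume is required")
    if len(nulls) < 100:
        warnings.warn(
            f"only {len(nulls)} null volumes; the FWE threshold quantile is "
            "imprecise below ~100",
            RuntimeWarning, stacklevel=2,
        )
    if nulls.shape[1:] != observed.shape:
        raise ValueError("observed and null volumes must share shape")
    if mask is None:
        mask = np.ones(observed.shape, dtype=bool)
    zthr = float(stats.norm.isf(cluster_forming_p / 2.0))
    null_max = np.array([_max_cluster_extent(v, zthr, mask) for v in nulls])
    crit = float(np.quantile(null_max, 1.0 - alpha, method="higher"))

    binary = (np.abs(observed) > zthr) & mask
    labeled, nlab = ndimage.label(binary, structure=_SIX_CONN)
    rows = []
    for lab in range(1, nlab + 1):
        where = labeled == lab
        extent = int(where.sum())
        vals = observed[where]
        peak_flat = np.argmax(np.abs(vals))
        coords = np.argwhere(where)[peak_flat]
        rows.append(
            {
                "cluster_id": lab,
                "extent": extent,
                "peak_z": float(vals[peak_flat]),
                "peak_i": int(coords[0]),
                "peak_j": int(coords[1]),
                "peak_k": int(coords[2]),
                "survives": extent > crit,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster_id", "extent", "peak_z", "peak_i", "peak_j",
                 "peak_k", "survives"],
    )
    table.attrs["critical_extent"] = crit
    table.attrs["z_threshold"] = zthr
    table.attrs["null_max_extents"] = null_max
    return table


def spherical_mask(grid: int = 24, radius: float = 9.5) -> np.ndarray:
    """Brain-like spherical analysis mask centered in a cubic grid."""
    g = np.indices((grid,) * 3)
    c = (grid - 1) / 2.0
    return ((g - c) ** 2).sum(axis=0) <= radius**2


def fwe_null_calibration(
    n_datasets: int = 200,
    n_perm: int = 500,
    grid: int = 24,
    mask_radius: float = 9.5,
    n_participants: int = 30,
    n_sessions: int = 10,
    tau2: float = 0.07,
    cluster_forming_p: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
    signal_extent: int = 0,
    signal_beta: float = 0.0,
) -> dict:
    """Familywise-error calibration of the permutation cluster pipeline.

    Simulates null longitudinal datasets (random-intercept share ``tau2``,
    no within-person effect) on a masked cubic grid, runs the full
    Freedman-Lane + max-cluster-extent correction on each, and reports the
    fraction of datasets with any surviving cluster together with its
    binomial Monte-Carlo SE. With ``signal_extent > 0`` a contiguous block
    of voxels receives a within-person effect ``signal_beta`` (in residual
    SD units), turning the run into a detection-power check whose
    ``detection_rate`` counts datasets with a surviving cluster overlapping
    the planted block.
    """
    from .synthetic import generate_predictor_panel

    mask = spherical_mask(grid, mask_radius)
    V = int(mask.sum())
    n, s = n_participants, n_sessions
    part = np.repeat(np.arange(n), s)
    eps_sd = np.sqrt(1.0 - tau2)
    signal_cols = np.arange(min(signal_extent, V)) if signal_extent else np.array([], int)
    rng = np.random.default_rng(seed)
    any_cluster = 0
    detected = 0
    for d in range(n_datasets):
        pred = generate_predictor_panel(1.0, 1.0, n, s, seed=int(rng.integers(2**31)))
        cp = center_within_between(pred)
        design = cp.sort_values(["participant", "session"]).reset_index(drop=True)
        lam = rng.normal(0, np.sqrt(tau2), (n, 1))
        Y = lam[part] + rng.normal(0, eps_sd, (n * s, V))
        if signal_cols.size:
            xw = design["x_w"].to_numpy()[:, None]
            Y[:, signal_cols] += signal_beta * xw
        obs, nulls, _ = voxelwise_freedman_lane(
            Y, design, mask, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = cluster_fwe_threshold(
                obs, nulls, cluster_forming_p=cluster_forming_p,
                alpha=alpha, mask=mask,
            )
        surv = table[table["survives"]]
        if len(surv):
            any_cluster += 1
            if signal_cols.size:
                coords = np.argwhere(mask)[signal_cols]
                sig_set = set(map(tuple, coords))
                labeled, nlab = ndimage.label(
                    (np.abs(obs) > table.attrs["z_threshold"]) & mask,
                    structure=_SIX_CONN,
                )
                for _, row in surv.iterrows():
                    lab = labeled[row["peak_i"], row["peak_j"], row["peak_k"]]
                    cl = set(map(tuple, np.argwhere(labeled == lab)))
                    if cl & sig_set:
                        detected += 1
                        break
    rate = any_cluster / n_datasets
    mc_se = float(np.sqrt(max(rate, 1.0 / n_datasets) * (1 - rate) / n_datasets))
    out = {
        "fwe_rate": rate,
        "mc_se": mc_se,
        "n_datasets": n_datasets,
        "n_perm": n_perm,
        "n_voxels": V,
    }
    if signal_cols.size:
        out["detection_rate"] = detected / n_datasets
    return out


# ---------------------------------------------------------------------------
# Parcel-level posterior and sign-error selection
# ---------------------------------------------------------------------------

@dataclass
class ParcelPosterior:
    """Posterior of a parcel's within-person slope."""

    parcel: int | str
    draws: np.ndarray
    median: float = field(init=False)
    p_sign: float = field(init=False)

    def __post_init__(self) -> None:
        self.median = float(np.median(self.draws))
        sgn = np.sign(self.median) if self.median != 0 else 1.0
        agree = float(np.mean(np.sign(self.draws) == sgn))
        self.p_sign = max(agree, 1.0 - agree)


def fit_parcel_posterior(
    panel: pd.DataFrame,
    pred: pd.DataFrame,
    n_draws: int = 2000,
    seed: int = 0,
) -> ParcelPosterior:
    """Posterior draws of the within-person slope for one parcel.

    The model has the longitudinal mean structure (intercept, time, x_b,
    x_w) with participant and participant-session random intercepts over
    the voxel-level rows. On a voxel-balanced panel the voxel dimension
    collapses exactly onto participant-session cell means plus a
    within-cell sum of squares informing the voxel error variance, which is
    how the likelihood is evaluated. Sampling: emcee on the marginalized
    likelihood (participant intercepts integrated analytically).
    """
    counts = panel.groupby(["participant", "session"])["value"].count()
    if counts.nunique() != 1:
        raise ValueError("panel must be voxel-balanced")
    v = int(counts.iloc[0])
    if v < 2:
        raise ValueError("need >= 2 voxels in the parcel")
    cells = (
        panel.groupby(["participant", "session"])["value"].mean().reset_index()
    )
    ssw = float(
        (panel.groupby(["participant", "session"])["value"].var(ddof=0) * v).sum()
    )
    dfw = len(cells) * (v - 1)
    if "x_w" not in pred.columns:
        pred = center_within_between(pred)
    df = cells.merge(
        pred[["participant", "session", "x_w", "x_b"]],
        on=["participant", "session"], validate="1:1",
    )
    df["time"] = df["session"] - df["session"].min()
    df, X, names, sizes = _design_from_frame(df, ["time", "x_b", "x_w"])
    yv = df["value"].to_numpy(dtype=float)
    if len(sizes) < 5:
        raise ValueError("need >= 5 participants")
    slices = _cluster_slices(sizes)
    sd_y = float(np.std(yv)) or 1.0
    prior_scale = 2.5 * sd_y
    p = X.shape[1]
    coef_idx = names.index("x_w")

    # starting values from the REML fit on cell means
    warm = _fit_array(X, yv, sizes, names)
    beta0 = np.array([warm.params[n] for n in names])
    cell_var0 = max(warm.sigma2, 1e-4 * sd_y**2)
    lam0 = max(warm.tau2, 1e-4 * sd_y**2)
    eps0 = max(ssw / dfw, 1e-6)
    pi0 = max(cell_var0 - eps0 / v, 1e-4 * sd_y**2)

    def logpost(theta):
        beta = theta[:p]
        sl, sp_, se_ = np.exp(theta[p:])
        lam2, pi2, eps2 = sl * sl, sp_ * sp_, se_ * se_
        cell = pi2 + eps2 / v
        r = yv - X @ beta
        ll = -0.5 * (dfw * np.log(eps2) + ssw / eps2)
        for sl_idx, m in zip(slices, sizes):
            rj = r[sl_idx]
            tot = cell + m * lam2
            q = (rj @ rj - (lam2 / tot) * rj.sum() ** 2) / cell
            ll += -0.5 * ((m - 1) * np.log(cell) + np.log(tot) + q)
        lp = (
            halft_logpdf(sl, prior_scale)
            + halft_logpdf(sp_, prior_scale)
            + halft_logpdf(se_, prior_scale)
        )
        return ll + lp + float(np.sum(theta[p:]))

    start = np.concatenate([beta0, 0.5 * np.log([lam0, pi0, eps0])])
    draws, _ = run_emcee(logpost, start, n_draws=n_draws, seed=seed)
    parcel = panel["parcel"].iloc[0] if "parcel" in panel else 0
    return ParcelPosterior(parcel=parcel, draws=draws[:, coef_idx])


def sign_error_select(
    parcels: list[ParcelPosterior], error_budget: float = 0.05
) -> pd.DataFrame:
    """Select parcels whose joint probability of any sign error stays below
    the budget.

    Parcels are sorted by sign-agreement probability descending (ties by
    parcel id ascending); the cumulative product of sign-agreement
    probabilities is the probability of no sign error in the prefix; the
    maximal prefix with cumulative product >= 1 - budget is selected.
    Returns the full ranked table with ``p_sign, cum_prod, selected``.
    """
    if not 0 < error_budget < 1:
        raise ValueError("error_budget must be in (0, 1)")
    rows = sorted(parcels, key=lambda pp: (-pp.p_sign, pp.parcel))
    p_s = np.array([r.p_sign for r in rows])
    c_s = np.cumprod(p_s)
    selected = c_s >= 1.0 - error_budget
    # maximal prefix: stop at the first failure
    if not selected.all():
        first_bad = int(np.argmin(selected))
        selected[first_bad:] = False
    return pd.DataFrame(
        {
            "parcel": [r.parcel for r in rows],
            "median": [r.median for r in rows],
            "p_sign": p_s,
            "cum_prod": c_s,
            "selected": selected,
        }
    )


# ---------------------------------------------------------------------------
# Design power simulation
# ---------------------------------------------------------------------------

def estimate_power(
    beta_within_std: float = 0.17,
    n_participants: int = 30,
    n_sessions: int = 10,
    tau2: float = 0.07,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo power of the within-person coefficient test.

    The standardized generative model: monthly predictor ``x = mu_j +
    d_js`` with unit between- and within-person SDs; outcome ``y =
    beta * d + lambda_j + eps`` with random-intercept share ``tau2`` and
    residual variance ``1 - tau2 - beta^2`` (unit total variance). Each
    replicate is fit with the full REML + CR2 + Satterthwaite pipeline and
    the rejection of ``H0: beta_w = 0`` at ``alpha`` recorded. Returns
    (power, binomial MC standard error).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    n, s = n_participants, n_sessions
    eps_var = 1.0 - tau2 - beta_within_std**2
    if eps_var <= 0:
        raise ValueError("beta and tau2 imply non-positive residual variance")
    t = np.tile(np.arange(s, dtype=float), n)
    part = np.repeat(np.arange(n), s)
    sizes = np.full(n, s)
    names = ["intercept", "time", "x_b", "x_w"]
    rejections = 0
    for _ in range(n_sim):
        mu = rng.normal(0, 1, n)
        d = rng.normal(0, 1, (n, s))
        x = (mu[:, None] + d).ravel()
        lam = rng.normal(0, np.sqrt(tau2), n)
        y = (
            beta_within_std * d.ravel()
            + lam[part]
            + rng.normal(0, np.sqrt(eps_var), n * s)
        )
        xm = x.reshape(n, s).mean(axis=1)
        x_w = x - xm[part]
        x_b = xm[part] - xm.mean()
        X = np.column_stack([np.ones(n * s), t, x_b, x_w])
        fit = _fit_array(X, y, sizes, names, coef_names=["x_w"])
        if fit.pvalues["x_w"] < alpha:
            rejections += 1
    power = rejections / n_sim
    mc_se = float(np.sqrt(power * (1 - power) / n_sim))
    return power, mc_se
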