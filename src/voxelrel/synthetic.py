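"""Synthetic data generators for densely sampled task-fMRI reliability studies.

This module generates inputs with the exact statistical structure the
downstream estimators assume, so every stage of the pipeline can be tested
against known ground truth without any imaging data:

* long-format voxel contrast panels with a three-level Gaussian variance
  decomposition (participant mean, participant-session mean, voxel error),
* longitudinal behavioral predictors with separable between- and
  within-person variance,
* 3-D integer label volumes for region-of-interest operations,
* daily sleep-event records and monthly stress-event lists mimicking
  actigraphy and life-stress-interview outputs.

The default study design is 30 participants scanned at 10 monthly sessions,
matching a year-long dense-sampling protocol for an emotional-faces contrast.
All random draws go through a :class:`numpy.random.Generator` seeded from the
caller, and identical configuration + seed always reproduces identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "StudyConfig",
    "generate_parcel_voxels",
    "generate_predictor_panel",
    "inject_within_effect",
    "generate_label_volume",
    "generate_sleep_and_stress",
    "generate_consistency_records",
    "inject_mcar_missingness",
    "write_panel",
    "read_panel",
]

#: Allowed stress-severity grid: a 1–5 scale in half-point steps.
SEVERITY_GRID = np.arange(1.0, 5.01, 0.5)

#: Chronic-stress interview domains.
STRESS_DOMAINS = (
    "peer", "parent", "family", "neighborhood", "school",
    "academic", "health", "finance", "discrimination",
)


@dataclass(frozen=True)
class VarianceComponents:
    """Ground-truth variance decomposition of a voxel contrast panel.

    Parameters
    ----------
    grand_mean
        Overall mean contrast value (beta_0).
    session_effects
        Fixed session offsets (beta_i), one per session. The default study
        uses a weak linear habituation trend.
    sigma_lambda2
        Variance of participant means (sigma_lambda^2).
    sigma_pi2
        Variance of participant-session means around the participant mean
        (sigma_pi^2); this is the internally consistent within-person signal.
    sigma_eps2
        Voxel-level error variance (sigma_eps^2).
    """

    grand_mean: float
    session_effects: tuple[float, ...]
    sigma_lambda2: float
    sigma_pi2: float
    sigma_eps2: float

    def __post_init__(self) -> None:
        for name in ("sigma_lambda2", "sigma_pi2", "sigma_eps2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not np.all(np.isfinite(self.session_effects)):
            raise ValueError("session_effects must be finite")
        if not np.isfinite(self.grand_mean):
            raise ValueError("grand_mean must be finite")

    @property
    def n_sessions(self) -> int:
        return len(self.session_effects)

    @staticmethod
    def linear_habituation(
        n_sessions: int,
        grand_mean: float = 0.5,
        slope: float = -0.02,
        sigma_lambda2: float = 0.02,
        sigma_pi2: float = 0.12,
        sigma_eps2: float = 0.18,
    ) -> "VarianceComponents":
        """Default components: weak linear habituation across sessions and a
        variance mix dominated by within-person signal and voxel error, the
        regime observed for emotion-task contrasts (test-retest share small,
        within-session share moderate)."""
        effects = tuple(slope * np.arange(n_sessions, dtype=float))
        return VarianceComponents(
            grand_mean, effects, sigma_lambda2, sigma_pi2, sigma_eps2
        )


@dataclass(frozen=True)
class StudyConfig:
    """Full design of a simulated dense-sampling study.

    Defaults mirror the motivating design: 30 participants, 10 monthly scan
    sessions, parcels of ~50 voxels each.
    """

    n_participants: int = 30
    n_sessions: int = 10
    parcel_voxels: tuple[int, ...] = (50,) * 20
    components: VarianceComponents | None = None
    predictor_between_sd: float = 1.0
    predictor_within_sd: float = 1.0
    beta_within: float = 0.0
    beta_between: float = 0.0
    beta_time: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.n_sessions < 2:
            raise ValueError("need at least 2 sessions")
        if any(v < 1 for v in self.parcel_voxels):
            raise ValueError("every parcel needs at least 1 voxel")

    def resolved_components(self) -> VarianceComponents:
        if self.components is not None:
            return self.components
        return VarianceComponents.linear_habituation(self.n_sessions)

    def to_json(self) -> str:
        vc = self.resolved_components()
        payload = {
            "n_participants": self.n_participants,
            "n_sessions": self.n_sessions,
            "parcel_voxels": list(self.parcel_voxels),
            "components": {
                "grand_mean": vc.grand_mean,
                "session_effects": list(vc.session_effects),
                "sigma_lambda2": vc.sigma_lambda2,
                "sigma_pi2": vc.sigma_pi2,
                "sigma_eps2": vc.sigma_eps2,
            },
            "predictor_between_sd": self.predictor_between_sd,
            "predictor_within_sd": self.predictor_within_sd,
            "beta_within": self.beta_within,
            "beta_between": self.beta_between,
            "beta_time": self.beta_time,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Voxel contrast panels
# ---------------------------------------------------------------------------

def generate_parcel_voxels(
    vc: VarianceComponents,
    n_participants: int,
    n_sessions: int,
    n_voxels: int,
    seed: int,
    parcel_id: int = 1,
) -> pd.DataFrame:
    """Generate a long-format voxel panel for one parcel.

    Each value is ``beta_0 + beta_i + lambda_j + pi_jk + eps_ijk`` with
    ``lambda_j ~ N(0, sigma_lambda^2)``, ``pi_jk ~ N(0, sigma_pi^2)`` and
    ``eps_ijk ~ N(0, sigma_eps^2)``: a participant random intercept, a
    participant-session random intercept, and iid voxel error.

    Returns a DataFrame with columns ``participant, session, parcel, voxel,
    value`` (sessions 1-based) and ground truth recorded in ``df.attrs``.
    """
    if n_sessions != vc.n_sessions:
        raise ValueError(
            f"session_effects has length {vc.n_sessions}, requested {n_sessions}"
        )
    if n_participants < 1 or n_voxels < 1:
        raise ValueError("n_participants and n_voxels must be >= 1")
    rng = np.random.default_rng(seed)
    lam = rng.normal(0.0, np.sqrt(vc.sigma_lambda2), size=n_participants)
    pi = rng.normal(0.0, np.sqrt(vc.sigma_pi2), size=(n_participants, n_sessions))
    eps = rng.normal(
        0.0, np.sqrt(vc.sigma_eps2), size=(n_participants, n_sessions, n_voxels)
    )
    sess = np.asarray(vc.session_effects, dtype=float)
    values = (
        vc.grand_mean
        + sess[None, :, None]
        + lam[:, None, None]
        + pi[:, :, None]
        + eps
    )
    idx = pd.MultiIndex.from_product(
        [
            np.arange(1, n_participants + 1),
            np.arange(1, n_sessions + 1),
            np.arange(1, n_voxels + 1),
        ],
        names=["participant", "session", "voxel"],
    )
    df = pd.DataFrame({"value": values.ravel()}, index=idx).reset_index()
    df.insert(2, "parcel", parcel_id)
    df.attrs["ground_truth"] = {
        "grand_mean": vc.grand_mean,
        "session_effects": list(vc.session_effects),
        "sigma_lambda2": vc.sigma_lambda2,
        "sigma_pi2": vc.sigma_pi2,
        "sigma_eps2": vc.sigma_eps2,
        "seed": seed,
    }
    return df


def generate_predictor_panel(
    between_sd: float,
    within_sd: float,
    n_participants: int,
    n_sessions: int,
    seed: int,
) -> pd.DataFrame:
    """Generate a monthly predictor with separable between/within variance.

    ``x_js = mu_j + d_js`` with ``mu_j ~ N(0, between_sd^2)`` and
    ``d_js ~ N(0, within_sd^2)``. Returns columns ``participant, session, x``
    plus the generating person means in ``df.attrs["person_means"]``.
    """
    if between_sd < 0 or within_sd < 0:
        raise ValueError("SDs must be >= 0")
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, between_sd, size=n_participants)
    dev = rng.normal(0.0, within_sd, size=(n_participants, n_sessions))
    x = mu[:, None] + dev
    idx = pd.MultiIndex.from_product(
        [np.arange(1, n_participants + 1), np.arange(1, n_sessions + 1)],
        names=["participant", "session"],
    )
    df = pd.DataFrame({"x": x.ravel()}, index=idx).reset_index()
    df.attrs["person_means"] = mu.tolist()  # plain list: ndarray attrs break concat
    df.attrs["seed"] = seed
    return df


def inject_within_effect(
    panel: pd.DataFrame,
    pred: pd.DataFrame,
    beta_within: float,
    beta_between: float,
    beta_time: float,
) -> pd.DataFrame:
    """Add predictor and time effects into a voxel panel.

    Every voxel value is incremented by ``beta_time * t + beta_between * x_b
    + beta_within * x_w`` where ``t`` is months since the first session
    (``session - 1``), ``x_w`` is the person-mean-centered predictor and
    ``x_b`` the person mean centered at the grand mean. Ground-truth slopes
    are recorded in ``attrs``.
    """
    from .longitudinal import center_within_between

    centered = center_within_between(pred)
    key = ["participant", "session"]
    merged = panel.merge(
        centered[key + ["x_w", "x_b"]], on=key, how="left", validate="m:1"
    )
    if merged["x_w"].isna().any():
        missing = merged.loc[merged["x_w"].isna(), key].drop_duplicates()
        raise ValueError(
            "predictor panel is missing participant/session keys present in "
            f"the voxel panel: {missing.to_records(index=False)[:5]}"
        )
    out = panel.copy()
    t = (merged["session"] - 1).to_numpy(dtype=float)
    out["value"] = (
        merged["value"].to_numpy()
        + beta_time * t
        + beta_between * merged["x_b"].to_numpy()
        + beta_within * merged["x_w"].to_numpy()
    )
    out.attrs = dict(panel.attrs)
    out.attrs["injected_effects"] = {
        "beta_within": beta_within,
        "beta_between": beta_between,
        "beta_time": beta_time,
    }
    return out


def inject_mcar_missingness(
    panel: pd.DataFrame, rate: float, seed: int
) -> pd.DataFrame:
    """Drop participant-sessions completely at random at the given rate."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cells = panel[["participant", "session"]].drop_duplicates()
    keep = rng.random(len(cells)) >= rate
    kept = cells[keep]
    out = panel.merge(kept, on=["participant", "session"], how="inner")
    out.attrs = dict(panel.attrs)
    out.attrs["mcar_rate"] = rate
    return out


# ---------------------------------------------------------------------------
# Label volumes
# ---------------------------------------------------------------------------

def generate_label_volume(
    shape: tuple[int, int, int],
    region_specs: list[tuple[int, dict]],
) -> np.ndarray:
    """Build an int16 label volume from geometric region specifications.

    Each spec is ``(label, geometry)`` where geometry is either
    ``{"kind": "block", "corner": (i,j,k), "size": (di,dj,dk)}`` or
    ``{"kind": "sphere", "center": (i,j,k), "radius": r}`` (membership rule:
    voxel-center distance <= r). Labels must be positive; 0 is background.
    Overlapping regions raise ``ValueError``.
    """
    vol = np.zeros(shape, dtype=np.int16)
    for label, geom in region_specs:
        if label <= 0:
            raise ValueError(f"labels must be positive integers, got {label}")
        mask = np.zeros(shape, dtype=bool)
        if geom["kind"] == "block":
            c = geom["corner"]
            s = geom["size"]
            hi = tuple(c[a] + s[a] for a in range(3))
            if any(c[a] < 0 or hi[a] > shape[a] for a in range(3)):
                raise ValueError(f"block for label {label} does not fit in {shape}")
            mask[c[0]:hi[0], c[1]:hi[1], c[2]:hi[2]] = True
        elif geom["kind"] == "sphere":
            center = np.asarray(geom["center"], dtype=float)
            r = float(geom["radius"])
            grids = np.indices(shape, dtype=float)
            d2 = sum((grids[a] - center[a]) ** 2 for a in range(3))
            mask = d2 <= r * r + 1e-12
            lo = center - r
            hi = center + r
            if np.any(lo < -0.5) or np.any(hi > np.asarray(shape) - 0.5):
                raise ValueError(f"sphere for label {label} does not fit in {shape}")
        else:
            raise ValueError(f"unknown geometry kind {geom['kind']!r}")
        if np.any(vol[mask] != 0):
            raise ValueError(f"region {label} overlaps an existing region")
        vol[mask] = label
    return vol


# ---------------------------------------------------------------------------
# Behavioral records: sleep events and stress events
# ---------------------------------------------------------------------------

def generate_sleep_and_stress(
    n_participants: int,
    n_days: int,
    seed: int,
    nap_probability: float = 0.25,
    start_date: str = "2016-09-01",
    monthly_event_rate: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate actigraphy-like sleep events and interview-like stress events.

    Sleep: one nocturnal event per day with onset near 23:00 (SD 1 h) and
    duration near 8 h (SD 0.75 h), so events routinely span midnight; with
    probability ``nap_probability`` an afternoon nap of 20–90 minutes is
    added. Stress: per participant-month, a Poisson number of episodic
    events (rate ``monthly_event_rate``) with severities on the 1–5
    half-point grid (geometric-ish decay over severity), plus one chronic
    severity per active domain.

    Distributional details are conventions of this generator; only the grid,
    the event/window structure and the scoring rules downstream are contract.
    """
    if n_days < 14:
        raise ValueError("need at least 14 days of sleep records")
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(start_date)
    sleep_rows = []
    for p in range(1, n_participants + 1):
        for d in range(n_days):
            day = t0 + pd.Timedelta(days=d)
            onset = (
                day
                + pd.Timedelta(hours=23)
                + pd.Timedelta(hours=float(rng.normal(0, 1.0)))
            )
            dur = max(3.0, float(rng.normal(8.0, 0.75)))
            sleep_rows.append(
                {
                    "participant": p,
                    "onset": onset,
                    "offset": onset + pd.Timedelta(hours=dur),
                    "kind": "night",
                }
            )
            if nap_probability > 0 and rng.random() < nap_probability:
                nap_on = day + pd.Timedelta(hours=float(rng.uniform(13, 17)))
                nap_dur = float(rng.uniform(1 / 3, 1.5))
                sleep_rows.append(
                    {
                        "participant": p,
                        "onset": nap_on,
                        "offset": nap_on + pd.Timedelta(hours=nap_dur),
                        "kind": "nap",
                    }
                )
    sleep = pd.DataFrame(sleep_rows)

    n_months = max(1, n_days // 30)
    sev_p = 0.55 ** np.arange(len(SEVERITY_GRID))
    sev_p /= sev_p.sum()
    stress_rows = []
    for p in range(1, n_participants + 1):
        for m in range(1, n_months + 1):
            k = rng.poisson(monthly_event_rate)
            for _ in range(k):
                stress_rows.append(
                    {
                        "participant": p,
                        "month": m,
                        "severity": float(rng.choice(SEVERITY_GRID, p=sev_p)),
                        "domain": str(rng.choice(STRESS_DOMAINS)),
                        "type": "episodic",
                    }
                )
            n_chronic = rng.integers(1, 4)
            domains = rng.choice(STRESS_DOMAINS, size=n_chronic, replace=False)
            for dom in domains:
                stress_rows.append(
                    {
                        "participant": p,
                        "month": m,
                        "severity": float(rng.choice(SEVERITY_GRID, p=sev_p)),
                        "domain": str(dom),
                        "type": "chronic",
                    }
                )
    stress = pd.DataFrame(
        stress_rows,
        columns=["participant", "month", "severity", "domain", "type"],
    )
    sleep.attrs["seed"] = stress.attrs["seed"] = seed
    return sleep, stress


# ---------------------------------------------------------------------------
# Consistency-record sampler (for the smoothness/anatomy regression stage)
# ---------------------------------------------------------------------------

def generate_consistency_records(
    seed: int,
    n_cortex: int = 400,
    n_subcortex: int = 14,
    n_control: int = 24,
    anatomy_means: dict[str, float] | None = None,
    size_logit_slope: float = 0.0,
    smooth_logit_slope: float = 0.0,
    phi: float = 50.0,
    median_size: int = 312,
) -> pd.DataFrame:
    """Sample parcel-level internal-consistency records from a beta model.

    The mean structure is ``logit(mu) = logit(anatomy mean) +
    size_logit_slope * (n_voxels - median_size)/100 + smooth_logit_slope *
    (smoothness - 3)`` and responses are Beta(mu*phi, (1-mu)*phi). Parcel
    sizes are lognormal around the median size; smoothness is ~N(3, 0.5) mm.
    Default anatomy means follow the regime seen for emotion-contrast data:
    cortex 0.44, subcortex 0.36, control 0.35.
    """
    if anatomy_means is None:
        anatomy_means = {"cortex": 0.44, "subcortex": 0.36, "control": 0.35}
    rng = np.random.default_rng(seed)
    rows = []
    counts = {"cortex": n_cortex, "subcortex": n_subcortex, "control": n_control}
    pid = 0
    for anatomy, n in counts.items():
        base = np.log(anatomy_means[anatomy] / (1 - anatomy_means[anatomy]))
        sizes = np.maximum(
            8, np.round(np.exp(rng.normal(np.log(median_size), 0.45, size=n)))
        ).astype(int)
        smooth = np.maximum(1.0, rng.normal(3.0, 0.5, size=n))
        eta = (
            base
            + size_logit_slope * (sizes - median_size) / 100.0
            + smooth_logit_slope * (smooth - 3.0)
        )
        mu = 1.0 / (1.0 + np.exp(-eta))
        icc = rng.beta(mu * phi, (1 - mu) * phi)
        for s, f, v in zip(sizes, smooth, icc):
            pid += 1
            rows.append(
                {
                    "parcel_id": pid,
                    "anatomy": anatomy,
                    "n_voxels": int(s),
                    "smoothness_mm": float(f),
                    "icc_within": float(np.clip(v, 1e-4, 1 - 1e-4)),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = {
        "anatomy_means": anatomy_means,
        "size_logit_slope": size_logit_slope,
        "smooth_logit_slope": smooth_logit_slope,
        "phi": phi,
    }
    return df


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_panel(df: pd.DataFrame, path: str | Path, sidecar: dict | None = None) -> None:
    """Write a tidy panel as CSV with an optional JSON sidecar carrying the
    seed and ground truth (``<path>.json``)."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta = dict(df.attrs)
    if sidecar:
        meta.update(sidecar)
    if meta:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(meta, fh, indent=2, default=_json_default)


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a tidy panel written by :func:`write_panel`, restoring attrs."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            df.attrs.update(json.load(fh))
    return df


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
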