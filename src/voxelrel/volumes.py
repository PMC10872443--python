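"""Volume-domain utilities: control spheres, parcel extraction, smoothness.

Coordinates are 0-based integer voxel indices throughout; physical units
enter only through the per-axis voxel size in mm. NIfTI affines are passed
through unmodified on read/write — no reorientation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SmoothnessEstimate",
    "sphere_radius_for_volume",
    "match_control_sphere",
    "extract_parcel_values",
    "subsample_voxels",
    "estimate_fwhm",
    "panel_to_volume",
    "read_label_volume",
    "write_label_volume",
    "write_voxel_set",
    "read_voxel_set",
]


@dataclass(frozen=True)
class SmoothnessEstimate:
    """Residual smoothness as per-axis and combined FWHM in mm."""

    fwhm: tuple[float, float, float]
    combined: float


def sphere_radius_for_volume(target_voxels: float) -> float:
    """Radius (in voxel units) of a sphere whose continuous volume equals
    ``target_voxels``: ``r = (3 V / 4 pi)^(1/3)``."""
    if target_voxels <= 0:
        raise ValueError(f"target volume must be positive, got {target_voxels}")
    return float((3.0 * target_voxels / (4.0 * np.pi)) ** (1.0 / 3.0))


def match_control_sphere(
    labels: np.ndarray,
    control_label: int,
    target_voxels: int,
    seed: int,
    max_tries: int = 1000,
) -> np.ndarray:
    """Place a size-matched sphere inside a control region.

    A center voxel is drawn uniformly from the control region; a discretized
    sphere (voxel-center distance <= r, starting from the equal-volume
    radius and grown until at least ``target_voxels`` members lie inside the
    volume bounds) is accepted only if every member carries
    ``control_label``. On containment failure a new center is drawn, up to
    ``max_tries`` attempts. The accepted set is trimmed to exactly
    ``target_voxels`` voxels by dropping the farthest voxels, ties broken by
    lexicographic (i, j, k) order, so a fixed seed gives a fixed set.

    Returns an ``(target_voxels, 3)`` int array of coordinates.
    """
    labels = np.asarray(labels)
    coords = np.argwhere(labels == control_label)
    if coords.size == 0:
        raise ValueError(f"label {control_label} not present in volume")
    if target_voxels < 1:
        raise ValueError("target_voxels must be >= 1")
    if target_voxels > len(coords):
        raise ValueError(
            f"cannot place a {target_voxels}-voxel sphere: label "
            f"{control_label} has only {len(coords)} voxels"
        )
    rng = np.random.default_rng(seed)
    shape = np.asarray(labels.shape)
    for _ in range(max_tries):
        center = coords[rng.integers(len(coords))]
        r = sphere_radius_for_volume(target_voxels)
        members, contained = _sphere_members(center, r, shape)
        while contained and len(members) < target_voxels:
            r *= 1.12
            members, contained = _sphere_members(center, r, shape)
        if not contained:
            continue  # sphere leaves the volume: containment failure, retry
        vals = labels[members[:, 0], members[:, 1], members[:, 2]]
        if not np.all(vals == control_label):
            continue
        d2 = np.sum((members - center) ** 2, axis=1)
        order = np.lexsort((members[:, 2], members[:, 1], members[:, 0], d2))
        chosen = members[order[:target_voxels]]
        # containment re-check after trimming is vacuous (subset), keep sorted
        final = chosen[np.lexsort((chosen[:, 2], chosen[:, 1], chosen[:, 0]))]
        return final
    raise RuntimeError(
        f"could not place a {target_voxels}-voxel sphere inside label "
        f"{control_label} after {max_tries} tries"
    )


def _sphere_members(
    center: np.ndarray, r: float, shape: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Lattice voxels within distance r of center, plus an in-bounds flag
    (False when the ideal sphere pokes out of the volume)."""
    lo = np.floor(center - r).astype(int)
    hi = np.ceil(center + r).astype(int)
    axes = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    gi, gj, gk = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gi.ravel(), gj.ravel(), gk.ravel()], axis=1)
    d2 = np.sum((pts - center) ** 2, axis=1)
    members = pts[d2 <= r * r + 1e-12]
    contained = bool(
        np.all(members >= 0) and np.all(members < shape[None, :])
    )
    return members, contained


def extract_parcel_values(
    contrast_volume: np.ndarray, labels: np.ndarray, parcel_id: int
) -> np.ndarray:
    """Extract the contrast values of one parcel in stable voxel order.

    Values come back in lexicographic (i, j, k) order, so repeated calls on
    the same volumes give identical vectors.
    """
    contrast_volume = np.asarray(contrast_volume)
    labels = np.asarray(labels)
    if contrast_volume.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: contrast {contrast_volume.shape} vs labels {labels.shape}"
        )
    mask = labels == parcel_id
    if not mask.any():
        raise KeyError(f"parcel {parcel_id} not present in label volume")
    # np.argwhere + advanced indexing preserves C (lexicographic) order
    return contrast_volume[mask]


def subsample_voxels(parcel_voxels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Uniformly sample ``k`` voxels without replacement from a voxel set.

    Input is an ``(n, 3)`` coordinate array; output is ``(k, 3)``,
    order-normalized lexicographically.
    """
    parcel_voxels = np.asarray(parcel_voxels)
    n = len(parcel_voxels)
    if k > n:
        raise ValueError(f"cannot sample {k} voxels from a parcel of {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    chosen = parcel_voxels[idx]
    order = np.lexsort((chosen[:, 2], chosen[:, 1], chosen[:, 0]))
    return chosen[order]


def estimate_fwhm(
    residuals: np.ndarray,
    mask: np.ndarray | None = None,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SmoothnessEstimate:
    """Estimate residual smoothness with the Gaussian-autocorrelation model.

    For each axis ``a`` the ratio ``rho_a = var(first differences) /
    (2 var(values))`` determines ``FWHM_a = delta_a * sqrt(-2 ln 2 /
    ln(1 - rho_a))``; for iid noise ``rho_a -> 1`` and the FWHM is clamped
    to 0. The combined estimate is the geometric mean over axes with a
    finite estimate. Accepts a 3-D volume or a 4-D stack (last axis stacks
    volumes; moments pool across the stack). ``mask`` may be a boolean
    volume or an ``(n, 3)`` coordinate array.

    This is the classical fixed-Gaussian-shape estimator; mixed
    Gaussian/exponential ACF models fit by some external tools will differ
    on heavy-tailed autocorrelation (comparability caveat).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim == 3:
        residuals = residuals[..., None]
    if residuals.ndim != 4:
        raise ValueError("residuals must be a 3-D volume or 4-D stack")
    shape3 = residuals.shape[:3]
    if mask is None:
        bmask = np.ones(shape3, dtype=bool)
    else:
        mask = np.asarray(mask)
        if mask.ndim == 2 and mask.shape[1] == 3:
            bmask = np.zeros(shape3, dtype=bool)
            bmask[mask[:, 0], mask[:, 1], mask[:, 2]] = True
        else:
            bmask = mask.astype(bool)

    vals = residuals[bmask]
    v0 = float(np.var(vals))
    if v0 <= 0:
        raise ValueError("zero variance inside mask: smoothness is undefined")

    fwhms = []
    for axis in range(3):
        pair = bmask & np.roll(bmask, -1, axis=axis)
        idx = [slice(None)] * 3
        idx[axis] = slice(0, shape3[axis] - 1)
        pair = pair[tuple(idx)]
        if pair.sum() < 1:
            fwhms.append(np.nan)
            continue
        diffs = np.diff(residuals, axis=axis)
        dvals = diffs[pair]
        rho = float(np.var(dvals)) / (2.0 * v0)
        if rho >= 1.0 or rho <= 0.0:
            fwhms.append(0.0 if rho >= 1.0 else np.inf)
            continue
        fwhms.append(
            voxel_size_mm[axis] * np.sqrt(-2.0 * np.log(2.0) / np.log1p(-rho))
        )
    arr = np.asarray(fwhms, dtype=float)
    finite = arr[np.isfinite(arr)]
    combined = float(np.exp(np.mean(np.log(np.maximum(finite, 1e-300))))) if len(finite) else float("nan")
    if len(finite) and np.any(finite == 0.0):
        combined = 0.0
    return SmoothnessEstimate(fwhm=tuple(arr), combined=combined)


# ---------------------------------------------------------------------------
# Panel <-> volume round trips and NIfTI IO
# ---------------------------------------------------------------------------

def panel_to_volume(
    panel: pd.DataFrame,
    labels: np.ndarray,
    parcel_id: int,
    participant: int,
    session: int,
) -> np.ndarray:
    """Write one participant-session of a voxel panel into a 3-D volume.

    Voxel ids map to the parcel's voxels in lexicographic coordinate order,
    the same order :func:`extract_parcel_values` reads them back, so
    write-then-extract is an exact round trip.
    """
    sub = panel[
        (panel["parcel"] == parcel_id)
        & (panel["participant"] == participant)
        & (panel["session"] == session)
    ].sort_values("voxel")
    mask = np.asarray(labels) == parcel_id
    if int(mask.sum()) != len(sub):
        raise ValueError(
            f"parcel {parcel_id} has {int(mask.sum())} voxels in the label "
            f"volume but {len(sub)} rows in the panel"
        )
    vol = np.zeros(np.asarray(labels).shape, dtype=float)
    vol[mask] = sub["value"].to_numpy()
    return vol


def write_label_volume(
    labels: np.ndarray, path: str | Path, voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine)
    nib.save(img, str(path))


def write_value_volume(
    values: np.ndarray, path: str | Path, voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
) -> None:
    """Write a float volume (e.g., a Z map) as NIfTI-1."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def read_value_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def read_label_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (integer label array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj).astype(np.int16), img.affine


def write_voxel_set(voxels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(voxels), columns=["i", "j", "k"]).to_csv(
        path, sep="\t", index=False
    )


def read_voxel_set(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")[["i", "j", "k"]].to_numpy()
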