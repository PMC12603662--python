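"""Streamline bundles: density maps, cleaning, profiles, yield, WMH overlap.

Bundles hold streamlines in world (mm) coordinates, read and written as TCK
files through nibabel.  A tract-density (visitation) map counts the number
of distinct streamlines touching each voxel.  Tract profiles summarize a
scalar map at 100 equidistant nodes along the bundle, weighting each
streamline's contribution inversely to its node's Mahalanobis distance
from the node-wise bundle center, so stray trajectories count less.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import nibabel as nib
from nibabel import streamlines as nib_streamlines

from .reliability import weighted_dice

logger = logging.getLogger(__name__)

__all__ = [
    "TractBundle",
    "TractDensityMap",
    "TractProfile",
    "load_tck",
    "save_tck",
    "resample_streamline",
    "density_map",
    "clean_bundle",
    "tract_profile",
    "tract_yield",
    "wmh_overlap",
]

N_PROFILE_NODES = 100


@dataclass(frozen=True)
class TractBundle:
    """A named collection of streamlines in world coordinates (mm)."""

    streamlines: tuple[np.ndarray, ...]
    name: str = ""

    def __post_init__(self) -> None:
        sl = tuple(np.asarray(s, dtype=float) for s in self.streamlines)
        for i, s in enumerate(sl):
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(
                    f"streamline {i} must be an (n>=2, 3) point array"
                )
            if not np.all(np.isfinite(s)):
                raise ValueError(f"streamline {i} has non-finite coordinates")
        object.__setattr__(self, "streamlines", sl)

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass(frozen=True)
class TractDensityMap:
    """Per-voxel streamline visitation counts on a grid."""

    counts: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(int))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))


@dataclass(frozen=True)
class TractProfile:
    """A 100-node along-tract profile of a scalar metric."""

    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_PROFILE_NODES,):
            raise ValueError(f"profile must have exactly {N_PROFILE_NODES} nodes")
        object.__setattr__(self, "values", values)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


def load_tck(path: str | os.PathLike, name: str = "") -> TractBundle:
    """Read a TCK streamline file (world/RAS mm coordinates)."""
    tck = nib_streamlines.load(os.fspath(path))
    return TractBundle(
        streamlines=tuple(np.asarray(s) for s in tck.streamlines),
        name=name or os.path.splitext(os.path.basename(os.fspath(path)))[0],
    )


def save_tck(bundle: TractBundle, path: str | os.PathLike) -> None:
    tractogram = nib_streamlines.Tractogram(
        list(bundle.streamlines), affine_to_rasmm=np.eye(4)
    )
    nib_streamlines.save(tractogram, os.fspath(path))


def resample_streamline(points: np.ndarray, n: int = N_PROFILE_NODES) -> np.ndarray:
    """Resample a polyline to ``n`` points at equal arc-length spacing.

    Endpoints are preserved exactly; interior points are linearly
    interpolated along the cumulative arc length.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need at least 2 points to resample")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] == 0:
        raise ValueError("zero-length streamline cannot be resampled")
    targets = np.linspace(0.0, arc[-1], n)
    out = np.column_stack(
        [np.interp(targets, arc, points[:, i]) for i in range(3)]
    )
    out[0], out[-1] = points[0], points[-1]
    return out


def _voxel_visits(
    points: np.ndarray, inv_affine: np.ndarray, shape: tuple[int, ...],
    max_step: float,
) -> np.ndarray:
    """Unique voxel indices visited by a polyline.

    Segments are subdivided to at most ``max_step`` (mm) so corner-cutting
    segments still register the voxels they pass through.
    """
    pts = [points[0]]
    for p0, p1 in zip(points[:-1], points[1:]):
        length = np.linalg.norm(p1 - p0)
        n_sub = max(int(np.ceil(length / max_step)), 1)
        ts = np.linspace(0.0, 1.0, n_sub + 1)[1:]
        pts.extend(p0 + ts[:, None] * (p1 - p0))
    pts = np.asarray(pts)
    ijk = nib.affines.apply_affine(inv_affine, pts)
    ijk = np.round(ijk).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.asarray(shape)), axis=1)
    if not np.all(inside):
        logger.warning(
            "%d streamline sample(s) outside the grid were dropped",
            int(np.count_nonzero(~inside)),
        )
    return np.unique(ijk[inside], axis=0)


def density_map(
    bundle: TractBundle, shape: tuple[int, int, int], affine: np.ndarray
) -> TractDensityMap:
    """Count distinct streamlines visiting each voxel.

    Each streamline increments a voxel at most once, regardless of how many
    of its points fall inside (visitation, not point count).
    """
    counts = np.zeros(shape, dtype=int)
    if len(bundle) == 0:
        logger.warning("density_map: empty bundle, returning all-zero map")
        return TractDensityMap(counts=counts, affine=affine)
    inv = np.linalg.inv(affine)
    voxel_size = np.abs(np.linalg.eigvals(affine[:3, :3])).min()
    max_step = max(voxel_size / 2.0, 1e-6)
    for s in bundle.streamlines:
        visited = _voxel_visits(s, inv, shape, max_step)
        counts[visited[:, 0], visited[:, 1], visited[:, 2]] += 1
    return TractDensityMap(counts=counts, affine=affine)


def _median_trajectory(resampled: np.ndarray) -> np.ndarray:
    """Node-wise coordinate-wise median, (n_nodes, 3)."""
    return np.median(resampled, axis=0)


def clean_bundle(
    bundle: TractBundle,
    sd_threshold: float = 5.0,
    min_streamlines: int = 20,
    max_rounds: int = 10,
) -> TractBundle:
    """Iteratively drop streamlines far from the median trajectory.

    Every streamline is resampled to 100 nodes; its deviation is the mean
    node-wise distance to the bundle's median trajectory.  Streamlines whose
    deviation z-score — relative to the median deviation, in robust SD units
    (1.4826 x MAD, falling back to the plain SD when the MAD is zero) —
    exceeds ``sd_threshold`` are removed, and the criterion is recomputed
    until no streamline is removed.  Bundles smaller than
    ``min_streamlines`` pass through untouched.
    """
    if len(bundle) < min_streamlines:
        logger.warning(
            "clean_bundle: %d streamlines < minimum %d, passing through",
            len(bundle), min_streamlines,
        )
        return bundle
    resampled = np.stack(
        [resample_streamline(s) for s in bundle.streamlines]
    )  # (S, nodes, 3)
    keep = np.arange(len(bundle))
    for _ in range(max_rounds):
        if len(keep) < min_streamlines:
            break
        median = _median_trajectory(resampled[keep])
        dev = np.linalg.norm(resampled[keep] - median, axis=2).mean(axis=1)
        center = np.median(dev)
        sigma = 1.4826 * np.median(np.abs(dev - center))
        if sigma == 0:
            sigma = dev.std()
        if sigma == 0:
            break  # perfectly coherent bundle
        z = (dev - center) / sigma
        bad = z > sd_threshold
        if not np.any(bad):
            break
        keep = keep[~bad]
    return TractBundle(
        streamlines=tuple(bundle.streamlines[i] for i in keep), name=bundle.name
    )


def tract_profile(
    bundle: TractBundle,
    scalar_map: np.ndarray,
    affine: np.ndarray,
    mask: np.ndarray | None = None,
    weighting: str = "mahalanobis",
) -> TractProfile:
    """100-node distance-weighted mean of a scalar along the bundle.

    At each node, every streamline contributes the scalar sampled (nearest
    voxel) at its own node position, weighted by the inverse of its node's
    distance from the node-wise bundle center: Mahalanobis distance under
    the node's coordinate covariance by default, Euclidean with
    ``weighting="euclidean"``.  Weights are normalized to sum to one per
    node.  Nodes whose contributing points all fall outside the map (or the
    optional mask) are flagged missing (NaN).
    """
    if len(bundle) == 0:
        raise ValueError("cannot profile an empty bundle")
    if weighting not in ("mahalanobis", "euclidean"):
        raise ValueError(f"unknown weighting {weighting!r}")
    resampled = np.stack([resample_streamline(s) for s in bundle.streamlines])
    n_sl, n_nodes, _ = resampled.shape
    inv = np.linalg.inv(affine)
    ijk = nib.affines.apply_affine(inv, resampled.reshape(-1, 3))
    ijk = np.round(ijk).astype(int).reshape(n_sl, n_nodes, 3)
    shape = np.asarray(scalar_map.shape)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=2)
    if mask is not None:
        in_mask = np.zeros((n_sl, n_nodes), dtype=bool)
        ok = inside
        idx = ijk[ok]
        in_mask[ok] = mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        inside = inside & in_mask

    values = np.full((n_sl, n_nodes), np.nan)
    ok_idx = ijk[inside]
    values[inside] = scalar_map[ok_idx[:, 0], ok_idx[:, 1], ok_idx[:, 2]]

    mean = resampled.mean(axis=0)  # (nodes, 3)
    centered = resampled - mean
    if weighting == "mahalanobis" and n_sl > 3:
        cov = np.einsum("snk,snl->nkl", centered, centered) / max(n_sl - 1, 1)
        cov += 1e-6 * np.eye(3)  # regularize degenerate node clouds
        cov_inv = np.linalg.inv(cov)
        d2 = np.einsum("snk,nkl,snl->sn", centered, cov_inv, centered)
        dist = np.sqrt(np.maximum(d2, 0.0))
    else:
        dist = np.linalg.norm(centered, axis=2)

    weights = 1.0 / (dist + 1e-6)
    weights = np.where(inside & np.isfinite(values), weights, 0.0)
    wsum = weights.sum(axis=0)
    profile = np.full(n_nodes, np.nan)
    good = wsum > 0
    vals = np.where(np.isfinite(values), values, 0.0)
    profile[good] = (weights * vals).sum(axis=0)[good] / wsum[good]
    return TractProfile(values=profile, name=bundle.name)


def tract_yield(bundles: list[TractBundle], min_streamlines: int = 10) -> int:
    """Number of bundles with at least ``min_streamlines`` streamlines."""
    return sum(1 for b in bundles if len(b) >= min_streamlines)


def wmh_overlap(density: TractDensityMap, wmh_mask: np.ndarray) -> float:
    """Weighted Dice between a tract density map and a binary lesion mask.

    The mask enters as a uniformly weighted density; an empty mask gives 0
    with a warning.
    """
    wmh_mask = np.asarray(wmh_mask).astype(bool)
    if wmh_mask.shape != density.counts.shape:
        raise ValueError("mask and density map must share a grid")
    return weighted_dice(density.counts, wmh_mask.astype(float))
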