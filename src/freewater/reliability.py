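"""Split-half reliability statistics.

Four statistics quantify how well a processing pipeline reproduces its
outputs across two random halves of an acquisition:

* per-voxel squared Pearson correlation (r²) between discretized spherical
  functions (fODFs or tensor ODFs) sampled on a common sphere grid;
* the symmetric percent change of r² between two pipelines,
  100 (r² - r²_ref) / (0.5 (r² + r²_ref));
* the Dice overlap of two tract-density maps, weighted by normalized
  streamline visitation counts;
* ICC(2,1) — the two-way random-effects, absolute-agreement, single-rater
  intraclass correlation — between paired tract-profile readings.

Undefined values (constant ODF vectors, empty maps, degenerate ANOVA
tables) propagate as NaN and are counted, never silently zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sphere import SphereGrid

logger = logging.getLogger(__name__)

__all__ = [
    "SphericalFieldPair",
    "fodf_r2",
    "percent_change",
    "weighted_dice",
    "icc_2_1",
    "mean_sem",
]


@dataclass(frozen=True)
class SphericalFieldPair:
    """Two per-voxel spherical functions sampled on the same grid."""

    field_a: np.ndarray  # (..., N)
    field_b: np.ndarray
    sphere: SphereGrid
    sphere_b: SphereGrid | None = None  # defaults to `sphere`

    def __post_init__(self) -> None:
        a = np.asarray(self.field_a, dtype=float)
        b = np.asarray(self.field_b, dtype=float)
        sphere_b = self.sphere_b if self.sphere_b is not None else self.sphere
        if sphere_b != self.sphere:
            raise ValueError(
                f"sphere grids differ: {self.sphere.version} vs {sphere_b.version}"
            )
        if a.shape != b.shape:
            raise ValueError(f"field shapes differ: {a.shape} vs {b.shape}")
        if a.shape[-1] != len(self.sphere):
            raise ValueError(
                f"fields sample {a.shape[-1]} directions but the sphere has "
                f"{len(self.sphere)} vertices"
            )
        object.__setattr__(self, "field_a", a)
        object.__setattr__(self, "field_b", b)
        object.__setattr__(self, "sphere_b", sphere_b)


def fodf_r2(pair: SphericalFieldPair) -> np.ndarray:
    """Squared Pearson correlation of the two spherical functions per voxel.

    Voxels where either vector is constant (zero variance) or contains
    non-finite values get NaN.
    """
    a, b = pair.field_a, pair.field_b
    am = a - a.mean(axis=-1, keepdims=True)
    bm = b - b.mean(axis=-1, keepdims=True)
    va = np.sum(am * am, axis=-1)
    vb = np.sum(bm * bm, axis=-1)
    cov = np.sum(am * bm, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (cov * cov) / (va * vb)
    finite = np.isfinite(a).all(axis=-1) & np.isfinite(b).all(axis=-1)
    defined = finite & (va > 0) & (vb > 0)
    r2 = np.where(defined, r2, np.nan)
    n_undef = int(np.count_nonzero(finite & ~defined))
    if n_undef:
        logger.info("r²: %d voxels undefined (constant spherical function)", n_undef)
    return r2


def percent_change(r2: np.ndarray | float, r2_reference: np.ndarray | float):
    """Symmetric percent change of r² relative to a reference pipeline.

        100 (r² - r²_ref) / (0.5 (r² + r²_ref))

    Antisymmetric under argument swap; NaN where both inputs are zero.
    """
    r2 = np.asarray(r2, dtype=float)
    ref = np.asarray(r2_reference, dtype=float)
    if np.any((r2 < -1e-12) | (r2 > 1 + 1e-12)) or np.any(
        (ref < -1e-12) | (ref > 1 + 1e-12)
    ):
        raise ValueError("r² values must lie in [0, 1]")
    denom = 0.5 * (r2 + ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * (r2 - ref) / denom
    out = np.where(denom > 0, out, np.nan)
    return out if out.ndim else float(out)


def _normalized_weights(counts: np.ndarray) -> tuple[np.ndarray, float]:
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("density counts must be non-negative")
    total = counts.sum()
    if total == 0:
        return counts, 0.0
    return counts / total, total


def weighted_dice(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Dice overlap of two density maps weighted by normalized visitation.

    With per-map weights w = counts / sum(counts),

        wDice = sum_{v in supp(a) ∩ supp(b)} (w_a(v) + w_b(v))
                / (sum_v w_a(v) + sum_v w_b(v))

    which is symmetric, 1 for identical supports/weights, 0 for disjoint
    supports, and 0 (with a warning) when either map is empty.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.shape != counts_b.shape:
        raise ValueError("density maps must share a grid")
    w_a, tot_a = _normalized_weights(counts_a)
    w_b, tot_b = _normalized_weights(counts_b)
    if tot_a == 0 or tot_b == 0:
        logger.warning("weighted_dice: empty density map, returning 0")
        return 0.0
    overlap = (counts_a > 0) & (counts_b > 0)
    return float((w_a[overlap].sum() + w_b[overlap].sum()) / (w_a.sum() + w_b.sum()))


def icc_2_1(ratings_a: np.ndarray, ratings_b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    The two halves are treated as k=2 raters scoring n targets (profile
    nodes, possibly concatenated across tracts/participants).  Pairs with a
    missing value in either vector are dropped (listwise deletion).  From
    the two-way ANOVA mean squares,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Returns NaN when fewer than 3 complete pairs remain or the total
    variance is zero.
    """
    a = np.asarray(ratings_a, dtype=float).ravel()
    b = np.asarray(ratings_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = len(a)
    k = 2
    if n < 3:
        return float("nan")
    table = np.column_stack([a, b])  # (n targets, k raters)
    grand = table.mean()
    if np.allclose(table, grand):
        return float("nan")  # zero total variance
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def mean_sem(values: np.ndarray) -> tuple[float, float]:
    """Mean ± standard error of the mean over the defined (finite) entries."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return float("nan"), float("nan")
    if len(v) == 1:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))
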