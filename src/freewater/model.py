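"""The two-compartment free-water diffusion tensor model (FWDTI).

Each white-matter voxel is modeled as a mixture of an anisotropic tissue
compartment, described by a symmetric diffusion tensor Q, and an isotropic
free-water compartment with fixed diffusivity ``D_ISO``:

    S(theta, b) = S0 (1 - f) exp(-b theta' Q theta) + S0 f exp(-b D_ISO)

where f is the free-water volume fraction.  Once (Q, f, S0) are known the
free-water contribution can be subtracted from each measurement:

    S_fwe(theta, b) = S(theta, b) - S0 f exp(-b D_ISO)

leaving a tissue-only residual signal ("free-water eliminated", FWE).

Tensors are stored as 6 unique elements in lower-triangular order
(xx, xy, yy, xz, yz, zz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .acquisition import DWIDataset, GradientScheme
from .sphere import SphereGrid

logger = logging.getLogger(__name__)

__all__ = [
    "D_ISO",
    "FreeWaterTensorField",
    "predict_signal",
    "eliminate_free_water",
    "tensor_scalars",
    "tensor_odf",
    "tensor_to_matrix",
    "matrix_to_tensor",
    "design_quadratic",
]

#: Diffusivity of free water at body temperature, mm²/s.
D_ISO = 3.0e-3

#: Index order of the 6 unique tensor elements.
TENSOR_ELEMENT_ORDER = ("xx", "xy", "yy", "xz", "yz", "zz")

# (row, col) of each unique element in the 3x3 matrix
_LT_IDX = ((0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2))


def tensor_to_matrix(q6: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular elements -> (..., 3, 3) symmetric matrices."""
    q6 = np.asarray(q6, dtype=float)
    m = np.zeros(q6.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_LT_IDX):
        m[..., i, j] = q6[..., k]
        m[..., j, i] = q6[..., k]
    return m


def matrix_to_tensor(m: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) lower-triangular elements."""
    m = np.asarray(m, dtype=float)
    return np.stack([m[..., i, j] for (i, j) in _LT_IDX], axis=-1)


def design_quadratic(scheme: GradientScheme) -> np.ndarray:
    """Per-measurement coefficients c such that b·thetaᵀQtheta = c @ q6.

    Returns an (M, 6) array in the package's element order; off-diagonal
    coefficients carry the symmetry factor 2.
    """
    g = scheme.bvecs
    b = scheme.bvals
    cols = [
        g[:, 0] * g[:, 0],
        2 * g[:, 0] * g[:, 1],
        g[:, 1] * g[:, 1],
        2 * g[:, 0] * g[:, 2],
        2 * g[:, 1] * g[:, 2],
        g[:, 2] * g[:, 2],
    ]
    out = b[:, None] * np.stack(cols, axis=1)
    out[scheme.b0_mask] = 0.0  # b0 directions are undefined
    return out


@dataclass(frozen=True)
class FreeWaterTensorField:
    """Per-voxel bi-tensor model parameters on a 3-D grid.

    Attributes
    ----------
    q : (..., 6) array
        Tissue tensor unique elements (mm²/s), order (xx, xy, yy, xz, yz, zz).
    f : (...) array
        Free-water volume fraction in [0, 1].
    s0 : (...) array
        Non-diffusion-weighted signal.
    d_iso : float
        Free-water diffusivity (mm²/s).
    mask : (...) bool array or None
        Voxels on which the invariants are enforced; None = everywhere.
    """

    q: np.ndarray
    f: np.ndarray
    s0: np.ndarray
    d_iso: float = D_ISO
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        f = np.asarray(self.f, dtype=float)
        s0 = np.asarray(self.s0, dtype=float)
        if q.shape[-1] != 6:
            raise ValueError("q must have 6 tensor elements on the last axis")
        if q.shape[:-1] != f.shape or f.shape != s0.shape:
            raise ValueError("q, f, s0 spatial shapes must agree")
        mask = self.mask
        if mask is None:
            mask = np.ones(f.shape, dtype=bool)
        else:
            mask = np.asarray(mask).astype(bool)
            if mask.shape != f.shape:
                raise ValueError("mask shape must match field shape")
        if np.any(f[mask] < -1e-12) or np.any(f[mask] > 1 + 1e-12):
            raise ValueError("free-water fraction must lie in [0, 1] in mask")
        if np.any(s0[mask] <= 0):
            raise ValueError("S0 must be positive in mask")
        evals = np.linalg.eigvalsh(tensor_to_matrix(q[mask]))
        if evals.size and evals.min() < -1e-9:
            raise ValueError(
                "tissue tensor must be positive semi-definite in mask "
                f"(min eigenvalue {evals.min():.3e})"
            )
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "f", np.clip(f, 0.0, 1.0))
        object.__setattr__(self, "s0", s0)
        object.__setattr__(self, "mask", mask)

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.f.shape


def predict_signal(field: FreeWaterTensorField, scheme: GradientScheme) -> np.ndarray:
    """Forward bi-tensor signal for every voxel and measurement.

    Returns an array of shape ``field.spatial_shape + (len(scheme),)``.
    """
    design = design_quadratic(scheme)  # (M, 6)
    bqb = np.einsum("...k,mk->...m", field.q, design)
    e_tissue = np.exp(-bqb)
    e_water = np.exp(-scheme.bvals * field.d_iso)
    f = field.f[..., None]
    return field.s0[..., None] * ((1.0 - f) * e_tissue + f * e_water)


def eliminate_free_water(ds: DWIDataset, field: FreeWaterTensorField) -> DWIDataset:
    """Subtract the modeled free-water signal from every measurement.

    Negative corrected values (possible under noise) are clipped to zero;
    the number of clipped in-mask samples is logged at INFO level for QC.
    """
    if field.spatial_shape != ds.spatial_shape:
        raise ValueError(
            f"field grid {field.spatial_shape} != data grid {ds.spatial_shape}"
        )
    e_water = np.exp(-ds.scheme.bvals * field.d_iso)
    water = field.s0[..., None] * field.f[..., None] * e_water
    corrected = ds.data - water
    n_clipped = int(np.count_nonzero(corrected[ds.mask] < 0))
    if n_clipped:
        logger.info("free-water elimination clipped %d negative samples", n_clipped)
    corrected = np.clip(corrected, 0.0, None)
    return DWIDataset(
        data=corrected, scheme=ds.scheme, mask=ds.mask, affine=ds.affine
    )


def tensor_scalars(field: FreeWaterTensorField) -> dict[str, np.ndarray]:
    """Standard tensor-derived maps: MD, FA, eigenvalues, principal direction.

    Voxels with non-finite tensors are flagged (``valid`` map) and excluded:
    their scalar values are NaN.
    """
    q = tensor_to_matrix(field.q)
    finite = np.all(np.isfinite(field.q), axis=-1)
    evals = np.full(field.spatial_shape + (3,), np.nan)
    evecs = np.full(field.spatial_shape + (3, 3), np.nan)
    if np.any(finite):
        w, v = np.linalg.eigh(q[finite])
        evals[finite] = w
        evecs[finite] = v
    md = evals.mean(axis=-1)
    # FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||
    dev = evals - md[..., None]
    denom = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * (dev**2).sum(axis=-1)) / denom
    fa = np.where(denom > 0, fa, 0.0)
    fa = np.where(finite, fa, np.nan)
    principal = evecs[..., :, 2]  # eigh sorts ascending
    return {
        "md": md,
        "fa": fa,
        "evals": evals[..., ::-1],  # descending, conventional
        "principal_direction": principal,
        "valid": finite,
    }


def tensor_odf(
    field: FreeWaterTensorField, sphere: SphereGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Discretized tensor orientation distribution function per voxel.

    The standard DTI ODF, ODF(u) ∝ (uᵀ Q⁻¹ u)^(-3/2), evaluated on the
    sphere grid and normalized to sum to 1 over the vertices.  Singular or
    non-finite tensors are flagged invalid and their ODF left as NaN.

    Returns
    -------
    odf : (..., N) array
    valid : (...) bool array
    """
    q = tensor_to_matrix(field.q)
    flat = q.reshape(-1, 3, 3)
    n_vox = flat.shape[0]
    u = sphere.vertices  # (N, 3)
    odf = np.full((n_vox, len(u)), np.nan)
    finite = np.all(np.isfinite(flat), axis=(1, 2))
    # positive determinant + positive diagonal is cheap; eigh confirms PD
    valid = finite.copy()
    if np.any(finite):
        evals = np.linalg.eigvalsh(flat[finite])
        valid[finite] = evals[:, 0] > 1e-12 * np.maximum(evals[:, -1], 1e-300)
    if np.any(valid):
        qinv = np.linalg.inv(flat[valid])
        quad = np.einsum("nk,vkl,nl->vn", u, qinv, u)  # (V, N)
        vals = quad ** (-1.5)
        odf[valid] = vals / vals.sum(axis=1, keepdims=True)
    shape = field.spatial_shape
    return odf.reshape(shape + (len(u),)), valid.reshape(shape)
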