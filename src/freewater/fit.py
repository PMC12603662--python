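"""Estimating the free-water tensor model from data.

Two fitting regimes, wrapped as scikit-learn style estimators:

``MultiShellFreeWaterModel``
    Voxel-wise non-linear least squares.  With two or more non-zero shells
    the bi-tensor model is well-posed and each voxel can be fit
    independently.  The tensor is parameterized through its Cholesky-like
    factor so the optimizer cannot leave the positive semi-definite cone,
    and the free-water fraction is box-constrained to [0, 1].

``SingleShellFreeWaterModel``
    With a single shell the per-voxel problem is ill-posed (free-water
    fraction and mean diffusivity trade off), so the whole field is fit
    jointly by gradient descent on a cost combining per-voxel squared
    residuals with a spatial-regularity penalty on neighboring tensors, and
    the fraction is confined to a per-voxel feasibility interval derived
    from the observed attenuation under physiological tissue-diffusivity
    bounds.

Both expose ``fit(dataset)`` -> self with a fitted ``field_`` attribute and
``transform(dataset)`` = free-water elimination with the fitted field.
Internally diffusivities are scaled to µm²/ms (x1000) and b-values to
ms/µm² so all optimization variables are O(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as splinalg
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, TransformerMixin

from .acquisition import DWIDataset, GradientScheme
from .model import (
    D_ISO,
    FreeWaterTensorField,
    design_quadratic,
    eliminate_free_water,
    matrix_to_tensor,
    tensor_to_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "fit_tensor_lls",
    "fit_tensor_wls",
    "initialize_fit",
    "MultiShellFreeWaterModel",
    "SingleShellFreeWaterModel",
    "fit_multishell",
    "fit_singleshell",
]

_SCALE = 1e3  # mm²/s -> µm²/ms
# Upper-typical white-matter MD (mm²/s), used only to seed the f estimate:
# voxels whose apparent MD does not exceed plausible tissue MD start at the
# lower clamp rather than at a spurious positive fraction.
_TYPICAL_TISSUE_MD = 0.9e-3


def fit_tensor_lls(
    data: np.ndarray, scheme: GradientScheme, min_signal: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary log-linear diffusion tensor fit, vectorized over voxels.

    Parameters
    ----------
    data : (..., M) array
        Signals; values below ``min_signal`` are floored before the log.
    scheme : GradientScheme

    Returns
    -------
    q6 : (..., 6) tensor elements (mm²/s) and s0 : (...) array.
    """
    design = design_quadratic(scheme)  # (M, 6)
    x = np.column_stack([np.ones(len(scheme)), -design])
    y = np.log(np.maximum(data, min_signal))
    beta = np.linalg.lstsq(x, y.reshape(-1, len(scheme)).T, rcond=None)[0]
    beta = beta.T.reshape(data.shape[:-1] + (7,))
    return beta[..., 1:], np.exp(beta[..., 0])


def fit_tensor_wls(
    data: np.ndarray, scheme: GradientScheme, min_signal: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted log-linear tensor fit (weights = observed signal).

    The log transform turns multiplicative signal noise into additive noise
    with variance ~ 1/S²; weighting each sample by its signal restores the
    correct relative weighting and stops heavily attenuated measurements
    from dominating the fit.  Vectorized over voxels via per-voxel normal
    equations.
    """
    design = design_quadratic(scheme)
    x = np.column_stack([np.ones(len(scheme)), -design])  # (M, 7)
    flat = np.maximum(data.reshape(-1, len(scheme)), min_signal)
    y = np.log(flat)
    w2 = flat**2  # squared weights in the normal equations
    xtw = x.T[None] * w2[:, None, :]  # (V, 7, M)
    lhs = xtw @ x
    rhs = np.einsum("vpm,vm->vp", xtw, y)
    lhs += 1e-12 * np.eye(7)
    beta = np.linalg.solve(lhs, rhs[..., None])[..., 0]
    beta = beta.reshape(data.shape[:-1] + (7,))
    return beta[..., 1:], np.exp(beta[..., 0])


def _psd_project(q6: np.ndarray, floor: float = 1e-7) -> np.ndarray:
    """Clip tensor eigenvalues at ``floor`` (mm²/s) to enforce PSD."""
    m = tensor_to_matrix(q6)
    w, v = np.linalg.eigh(m)
    w = np.maximum(w, floor)
    m = np.einsum("...ij,...j,...kj->...ik", v, w, v)
    return matrix_to_tensor(m)


def _mixture_f_estimate(
    md: np.ndarray, b: float, d_iso: float, tissue_md: float = _TYPICAL_TISSUE_MD
) -> np.ndarray:
    """Map an apparent MD to a free-water fraction via the mixture relation.

    Solves (1-f) exp(-b D_t) + f exp(-b D_iso) = exp(-b MD) for f with a
    typical tissue diffusivity D_t; a crude but serviceable starting point.
    """
    a_obs = np.exp(-b * md)
    a_tis = np.exp(-b * tissue_md)
    a_w = np.exp(-b * d_iso)
    return (a_obs - a_tis) / (a_w - a_tis)


def initialize_fit(ds: DWIDataset, d_iso: float = D_ISO) -> FreeWaterTensorField:
    """Initial (Q, f, S0) field for either fitting regime.

    S0 is the mean of the b=0 measurements; Q comes from a log-linear
    tensor fit on the highest available shell (plus b0), eigenvalue-floored
    to stay PSD; f comes from that fit's MD through the mixture relation,
    clamped to [0.01, 0.99].  Voxels with non-positive mean b0 are flagged
    (dropped from the mask).
    """
    b0 = ds.scheme.b0_mask
    if not np.any(b0):
        raise ValueError("dataset has no b=0 measurements")
    s0 = ds.data[..., b0].mean(axis=-1)
    valid = ds.mask & (s0 > 0)
    n_flagged = int(np.count_nonzero(ds.mask & ~valid))
    if n_flagged:
        logger.warning("%d voxels flagged: non-positive mean b0", n_flagged)

    shells = ds.scheme.shells()
    top = max(b for b in shells if b > 0)
    keep = np.sort(np.concatenate([shells[0.0], shells[top]]))
    sub = ds.scheme.subset(keep)
    q6, _ = fit_tensor_lls(ds.data[..., keep], sub)
    q6 = _psd_project(q6)
    md = np.trace(tensor_to_matrix(q6), axis1=-2, axis2=-1) / 3.0
    f = np.clip(_mixture_f_estimate(md, top, d_iso), 0.01, 0.99)
    s0_safe = np.where(valid, s0, 1.0)
    return FreeWaterTensorField(
        q=q6, f=f, s0=s0_safe, d_iso=d_iso, mask=valid
    )


# ---------------------------------------------------------------------------
# Cholesky-factor parameterization helpers (scaled units, µm²/ms)
# ---------------------------------------------------------------------------

def _chol_from_q(q6_scaled: np.ndarray) -> np.ndarray:
    """Lower-triangular factors (6 elements) of scaled tensors."""
    m = tensor_to_matrix(q6_scaled)
    m = m + 1e-8 * np.eye(3)
    l = np.linalg.cholesky(m)
    return matrix_to_tensor(l)  # picks exactly the lower-triangular entries


def _q_from_chol(l6: np.ndarray) -> np.ndarray:
    """q6 = unique elements of L Lᵀ, vectorized over leading axes."""
    l11, l21, l22, l31, l32, l33 = np.moveaxis(l6, -1, 0)
    return np.stack(
        [
            l11**2,
            l21 * l11,
            l21**2 + l22**2,
            l31 * l11,
            l31 * l21 + l32 * l22,
            l31**2 + l32**2 + l33**2,
        ],
        axis=-1,
    )


def _dq_dl(l6: np.ndarray) -> np.ndarray:
    """Jacobian of q6 w.r.t. the 6 factor elements, shape (..., 6, 6)."""
    l11, l21, l22, l31, l32, l33 = np.moveaxis(l6, -1, 0)
    z = np.zeros_like(l11)
    rows = [
        [2 * l11, z, z, z, z, z],
        [l21, l11, z, z, z, z],
        [z, 2 * l21, 2 * l22, z, z, z],
        [l31, z, z, l11, z, z],
        [z, l31, l32, l21, l22, z],
        [z, z, z, 2 * l31, 2 * l32, 2 * l33],
    ]
    return np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)


# ---------------------------------------------------------------------------
# Multi-shell voxel-wise non-linear least squares
# ---------------------------------------------------------------------------

class MultiShellFreeWaterModel(TransformerMixin, BaseEstimator):
    """Voxel-wise NLS fit of the bi-tensor model on multi-shell data.

    Parameters
    ----------
    d_iso : float
        Free-water diffusivity (mm²/s).
    max_nfev : int or None
        Cap on function evaluations per voxel (None = scipy default).
    xtol, ftol, gtol : float
        scipy ``least_squares`` termination tolerances.

    Attributes
    ----------
    field_ : FreeWaterTensorField
        Fitted per-voxel parameters.
    converged_ : bool ndarray
        Per-voxel convergence status (True if the solver reported success).
    n_voxels_ : int
        Number of voxels fit.
    """

    def __init__(
        self,
        d_iso: float = D_ISO,
        max_nfev: int | None = None,
        xtol: float = 1e-12,
        ftol: float = 1e-12,
        gtol: float = 1e-10,
    ):
        self.d_iso = d_iso
        self.max_nfev = max_nfev
        self.xtol = xtol
        self.ftol = ftol
        self.gtol = gtol

    def fit(self, ds: DWIDataset, y=None) -> "MultiShellFreeWaterModel":
        scheme = ds.scheme
        shells = scheme.nonzero_shells()
        if len(shells) < 2:
            raise ValueError(
                "multi-shell fit requires >= 2 non-zero shells; got "
                f"{shells} — use SingleShellFreeWaterModel / fit_singleshell"
            )
        if int(np.count_nonzero(~scheme.b0_mask)) < 7:
            raise ValueError("need at least 7 diffusion-weighted measurements")

        init = initialize_fit(ds, d_iso=self.d_iso)
        mask = init.mask
        vox = np.flatnonzero(mask.ravel())
        data = ds.data.reshape(-1, len(scheme))
        design = design_quadratic(scheme)  # dimensionless once q is scaled
        e_water = np.exp(-scheme.bvals * self.d_iso)

        q0 = init.q.reshape(-1, 6)[vox] * _SCALE
        l0 = _chol_from_q(q0)
        f0 = init.f.ravel()[vox]
        s0 = init.s0.ravel()[vox]

        q_out = np.zeros((data.shape[0], 6))
        f_out = np.zeros(data.shape[0])
        s0_out = np.ones(data.shape[0])
        conv = np.zeros(data.shape[0], dtype=bool)

        lo = np.array([1e-6, 0.0, -np.inf, -np.inf, -np.inf, -np.inf, -np.inf, -np.inf])
        hi = np.array([np.inf, 1.0, np.inf, np.inf, np.inf, np.inf, np.inf, np.inf])
        design_s = design / _SCALE  # so design_s @ (q*_SCALE) = b thetaQtheta

        for j, v in enumerate(vox):
            y_v = data[v]
            scale = max(s0[j], 1e-12)
            yn = y_v / scale
            x0 = np.concatenate(([1.0, np.clip(f0[j], 1e-3, 1 - 1e-3)], l0[j]))
            res = least_squares(
                _ms_residuals,
                x0,
                jac=_ms_jacobian,
                bounds=(lo, hi),
                method="trf",
                xtol=self.xtol,
                ftol=self.ftol,
                gtol=self.gtol,
                max_nfev=self.max_nfev,
                args=(yn, design_s, e_water),
            )
            p = res.x
            q_out[v] = _q_from_chol(p[2:]) / _SCALE
            f_out[v] = p[1]
            s0_out[v] = p[0] * scale
            conv[v] = res.status > 0

        shape = ds.spatial_shape
        self.field_ = FreeWaterTensorField(
            q=q_out.reshape(shape + (6,)),
            f=f_out.reshape(shape),
            s0=s0_out.reshape(shape),
            d_iso=self.d_iso,
            mask=mask,
        )
        self.converged_ = conv.reshape(shape)
        self.n_voxels_ = int(len(vox))
        return self

    def transform(self, ds: DWIDataset) -> DWIDataset:
        """Free-water-eliminate ``ds`` using the fitted field."""
        if not hasattr(self, "field_"):
            raise RuntimeError("call fit() before transform()")
        return eliminate_free_water(ds, self.field_)


def _ms_model(p, design_s, e_water):
    s0r, f = p[0], p[1]
    q6 = _q_from_chol(p[2:])
    e_t = np.exp(-design_s @ q6)
    return s0r * ((1 - f) * e_t + f * e_water), e_t


def _ms_residuals(p, yn, design_s, e_water):
    m, _ = _ms_model(p, design_s, e_water)
    return m - yn


def _ms_jacobian(p, yn, design_s, e_water):
    s0r, f = p[0], p[1]
    m, e_t = _ms_model(p, design_s, e_water)
    jac = np.empty((len(yn), 8))
    jac[:, 0] = m / s0r
    jac[:, 1] = s0r * (e_water - e_t)
    dm_dq = (-s0r * (1 - f)) * e_t[:, None] * design_s  # (M, 6)
    jac[:, 2:] = dm_dq @ _dq_dl(p[2:])
    return jac


# ---------------------------------------------------------------------------
# Single-shell spatially regularized gradient descent
# ---------------------------------------------------------------------------

@dataclass
class _GDState:
    """Flattened optimization state for the single-shell field fit."""

    u: np.ndarray  # logit of normalized f, (V,)
    l6: np.ndarray  # Cholesky factors of scaled tensors, (V, 6)


class SingleShellFreeWaterModel(TransformerMixin, BaseEstimator):
    """Spatially regularized field fit of the bi-tensor model, one shell.

    The cost is

        sum_v sum_i (ahat_vi - a_vi)^2
        + reg_weight * sum_{v~n} || Q'_v - Q'_n ||_F^2

    over in-mask voxels v, shell measurements i and 6-neighbor pairs v~n,
    with attenuations a = S/S0 and tensors Q' in µm²/ms.  S0 is fixed at
    the per-voxel b0 mean.  f is optimized through a logistic transform
    confined to a per-voxel feasibility interval computed from the mean
    observed attenuation under tissue diffusivities in ``tissue_d_bounds``.

    The raw gradient is useless here: the cost surface has a nearly flat
    curved valley along the per-voxel f/mean-diffusivity trade-off, and
    fixed-step descent stalls in it.  Each descent direction is therefore
    the damped Gauss-Newton direction of the full coupled cost — per-voxel
    data blocks plus the sparse neighbor-coupling blocks of the penalty —
    solved with block-Jacobi-preconditioned conjugate gradients.  The
    damping parameter plays the role of an adaptive step size: a trial step
    that increases the cost is rejected and retried with ten-fold damping
    (shorter, more gradient-like step), so the recorded cost sequence is
    non-increasing by construction.

    Parameters
    ----------
    reg_weight : float
        Spatial regularization weight (on scaled tensors, µm²/ms).
    step_size : float
        Multiplier on the damped Newton step; halved together with the
        damping escalation when a trial step increases the cost.
    max_iter : int
        Maximum accepted descent steps.
    tol : float
        Stop when the relative cost decrease falls below this.
    tissue_d_bounds : (float, float)
        Assumed tissue diffusivity range (mm²/s) for the f feasibility
        interval.

    Attributes
    ----------
    field_ : FreeWaterTensorField
    cost_history_ : list of accepted costs (non-increasing)
    n_iter_ : int
    f_bounds_ : (lo, hi) arrays of the per-voxel feasibility interval
    """

    def __init__(
        self,
        reg_weight: float = 0.03,
        step_size: float = 1.0,
        max_iter: int = 150,
        tol: float = 1e-8,
        d_iso: float = D_ISO,
        tissue_d_bounds: tuple[float, float] = (0.1e-3, 2.5e-3),
    ):
        self.reg_weight = reg_weight
        self.step_size = step_size
        self.max_iter = max_iter
        self.tol = tol
        self.d_iso = d_iso
        self.tissue_d_bounds = tissue_d_bounds

    # -- feasibility interval ------------------------------------------------
    def _f_interval(self, abar: np.ndarray, b: float):
        d_lo, d_hi = self.tissue_d_bounds
        a_max = np.exp(-b * d_lo)  # least-attenuating tissue
        a_min = np.exp(-b * d_hi)  # most-attenuating tissue
        a_w = np.exp(-b * self.d_iso)
        f_hi = np.clip((abar - a_max) / (a_w - a_max), 0.0, 1.0)
        f_lo = np.clip((abar - a_min) / (a_w - a_min), 0.0, 1.0)
        swap = f_lo > f_hi
        f_lo2 = np.where(swap, f_hi, f_lo)
        f_hi2 = np.where(swap, f_lo, f_hi)
        # keep a sliver of interior so the logistic transform is usable
        pad = 1e-3
        f_lo2 = np.clip(f_lo2, pad, 1 - 2 * pad)
        f_hi2 = np.maximum(np.clip(f_hi2, pad, 1 - pad), f_lo2 + pad)
        return f_lo2, f_hi2

    def fit(self, ds: DWIDataset, y=None) -> "SingleShellFreeWaterModel":
        shells = ds.scheme.nonzero_shells()
        if len(shells) != 1:
            raise ValueError(
                f"single-shell fit requires exactly one non-zero shell; got {shells}"
                " — use MultiShellFreeWaterModel / fit_multishell"
            )
        b = shells[0]
        if not _mask_is_contiguous(ds.mask):
            logger.warning(
                "mask is not spatially contiguous; the spatial regularization "
                "degenerates across disconnected components"
            )

        init = initialize_fit(ds, d_iso=self.d_iso)
        mask = init.mask
        shape = ds.spatial_shape
        vox_idx = np.flatnonzero(mask.ravel())
        n_v = len(vox_idx)

        shell_cols = ds.scheme.shells()[b]
        sub = ds.scheme.subset(shell_cols)
        design_s = design_quadratic(sub) / _SCALE  # (M, 6)
        s0 = init.s0.ravel()[vox_idx]
        a = ds.data.reshape(-1, len(ds.scheme))[vox_idx][:, shell_cols] / s0[:, None]
        a_w = float(np.exp(-b * self.d_iso))

        f_lo, f_hi = self._f_interval(a.mean(axis=1), b)

        # initial point: mixture-relation f (interval-clamped) and a tensor
        # fit on the free-water-corrected attenuations
        f0 = np.clip(init.f.ravel()[vox_idx], f_lo + 1e-4, f_hi - 1e-4)
        a_t0 = np.clip((a - f0[:, None] * a_w) / (1 - f0[:, None]), 1e-4, 1.0)
        q0 = -np.linalg.lstsq(design_s, np.log(a_t0).T, rcond=None)[0].T
        q0 = _psd_project(q0 / _SCALE) * _SCALE
        state = _GDState(u=_logit((f0 - f_lo) / (f_hi - f_lo)), l6=_chol_from_q(q0))

        pairs = _neighbor_pairs(mask)  # (P, 2) indices into vox_idx ordering
        w6 = np.array([1.0, 2.0, 1.0, 2.0, 2.0, 1.0])  # Frobenius weights

        def unpack(st: _GDState):
            f = f_lo + (f_hi - f_lo) * _sigmoid(st.u)
            q6 = _q_from_chol(st.l6)  # scaled
            return f, q6

        def data_terms(st: _GDState):
            """Per-voxel data cost, gradient, and Gauss-Newton block."""
            sg = _sigmoid(st.u)
            f = f_lo + (f_hi - f_lo) * sg
            q6 = _q_from_chol(st.l6)
            e_t = np.exp(-(design_s @ q6.T).T)  # (V, M)
            r = (1 - f)[:, None] * e_t + f[:, None] * a_w - a
            cost_v = np.sum(r * r, axis=1)
            df_du = (f_hi - f_lo) * sg * (1 - sg)
            dr_du = (a_w - e_t) * df_du[:, None]  # (V, M)
            j_q = -(1 - f)[:, None, None] * e_t[:, :, None] * design_s[None]
            dqdl = _dq_dl(st.l6)  # (V, 6, 6)
            j_l = np.einsum("vmk,vkj->vmj", j_q, dqdl)
            jac = np.concatenate([dr_du[:, :, None], j_l], axis=2)  # (V, M, 7)
            grad = 2.0 * np.einsum("vm,vmj->vj", r, jac)
            hess = 2.0 * np.einsum("vmi,vmj->vij", jac, jac)
            return cost_v, grad, hess, q6, dqdl

        degree = np.zeros(n_v)
        if len(pairs):
            np.add.at(degree, pairs[:, 0], 1.0)
            np.add.at(degree, pairs[:, 1], 1.0)

        def reg_terms(q6: np.ndarray, dqdl: np.ndarray):
            """Reg cost, gradient in (u, l6), diagonal and pair H blocks."""
            if self.reg_weight <= 0 or not len(pairs):
                return (
                    0.0,
                    np.zeros((n_v, 7)),
                    np.zeros((n_v, 6, 6)),
                    np.zeros((0, 6, 6)),
                )
            dq = q6[pairs[:, 0]] - q6[pairs[:, 1]]
            cost = float(self.reg_weight * np.sum(w6 * dq * dq))
            g_q = np.zeros_like(q6)
            gr = 2.0 * self.reg_weight * (w6 * dq)
            np.add.at(g_q, pairs[:, 0], gr)
            np.add.at(g_q, pairs[:, 1], -gr)
            grad = np.zeros((n_v, 7))
            grad[:, 1:] = np.einsum("vk,vkj->vj", g_q, dqdl)
            # Gauss-Newton curvature of the penalty, chained q6 -> l6:
            # diagonal blocks 2w deg_v J_v' W J_v and neighbor-coupling
            # blocks -2w J_i' W J_j for every pair
            hq = 2.0 * self.reg_weight * w6[None, :] * degree[:, None]
            h_diag = np.einsum("vkj,vk,vki->vji", dqdl, hq, dqdl)
            j_i = dqdl[pairs[:, 0]]
            j_j = dqdl[pairs[:, 1]]
            h_pair = -2.0 * self.reg_weight * np.einsum(
                "pkj,k,pki->pji", j_i, w6, j_j
            )
            return cost, grad, h_diag, h_pair

        def solve_newton(grad_tot, h_blocks, h_pair, lam):
            """PCG solve of (H + lam diag(H)) d = g on the coupled system.

            H has per-voxel 7x7 blocks plus 6x6 neighbor-coupling blocks on
            the tensor coordinates; the block-diagonal inverse is the
            preconditioner.
            """
            diag = np.einsum("vii->vi", h_blocks)
            damped = h_blocks + (lam * diag + 1e-12)[:, :, None] * np.eye(7)
            damped_inv = np.linalg.inv(damped)
            if not len(h_pair):
                return np.einsum("vij,vj->vi", damped_inv, grad_tot)

            pi, pj = pairs[:, 0], pairs[:, 1]

            def matvec(x):
                x = x.reshape(n_v, 7)
                y = np.einsum("vij,vj->vi", damped, x)
                y1 = np.einsum("pij,pj->pi", h_pair, x[pj, 1:])
                y2 = np.einsum("pji,pj->pi", h_pair, x[pi, 1:])
                np.add.at(y[:, 1:], pi, y1)
                np.add.at(y[:, 1:], pj, y2)
                return y.ravel()

            def precond(x):
                return np.einsum(
                    "vij,vj->vi", damped_inv, x.reshape(n_v, 7)
                ).ravel()

            op = splinalg.LinearOperator((7 * n_v, 7 * n_v), matvec=matvec)
            m_op = splinalg.LinearOperator((7 * n_v, 7 * n_v), matvec=precond)
            d, info = splinalg.cg(
                op, grad_tot.ravel(), M=m_op, rtol=1e-8, maxiter=500
            )
            if info != 0:
                logger.debug("inner CG stopped early (info=%d)", info)
            return d.reshape(n_v, 7)

        def apply_step(st: _GDState, d: np.ndarray, scale=1.0):
            # |u| capped where the logistic saturates: beyond the cap the
            # fraction is within 3e-4 of its bound but the gradient stays
            # finite enough for the voxel to re-enter the interior
            return _GDState(
                u=np.clip(st.u - scale * d[:, 0], -8.0, 8.0),
                l6=st.l6 - scale * d[:, 1:],
            )

        cost_v, grad, hess, q6, dqdl = data_terms(state)
        c_reg, g_reg, h_diag, h_pair = reg_terms(q6, dqdl)
        cost = float(cost_v.sum()) + c_reg
        history = [cost]
        lam = 1e-3
        step = float(self.step_size)
        n_stale = 0
        for _ in range(self.max_iter):
            h_blocks = hess.copy()
            h_blocks[:, 1:, 1:] += h_diag
            accepted = False
            for _shrink in range(25):
                d = solve_newton(grad + g_reg, h_blocks, h_pair, lam)
                trial = apply_step(state, d, scale=step)
                cv_t, gr_t, h_t, q6_t, dqdl_t = data_terms(trial)
                creg_t, greg_t, hdiag_t, hpair_t = reg_terms(q6_t, dqdl_t)
                c_new = float(cv_t.sum()) + creg_t
                if c_new <= cost:
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                break
            state, cost = trial, c_new
            cost_v, grad, hess, q6, dqdl = cv_t, gr_t, h_t, q6_t, dqdl_t
            g_reg, h_diag, h_pair = greg_t, hdiag_t, hpair_t
            history.append(cost)
            lam = max(lam / 3.0, 1e-10)
            # a single heavily-damped micro-step must not read as
            # convergence: require sustained stagnation
            if history[-2] > 0 and (history[-2] - history[-1]) / history[-2] < self.tol:
                n_stale += 1
                if n_stale >= 3:
                    break
            else:
                n_stale = 0

        f_fit, q6_fit = unpack(state)
        q_out = np.zeros((mask.size, 6))
        f_out = np.zeros(mask.size)
        s0_out = np.ones(mask.size)
        q_out[vox_idx] = q6_fit / _SCALE
        f_out[vox_idx] = f_fit
        s0_out[vox_idx] = s0

        self.field_ = FreeWaterTensorField(
            q=q_out.reshape(shape + (6,)),
            f=f_out.reshape(shape),
            s0=s0_out.reshape(shape),
            d_iso=self.d_iso,
            mask=mask,
        )
        self.cost_history_ = history
        self.n_iter_ = len(history) - 1
        self.f_bounds_ = (f_lo, f_hi)
        return self

    def transform(self, ds: DWIDataset) -> DWIDataset:
        if not hasattr(self, "field_"):
            raise RuntimeError("call fit() before transform()")
        return eliminate_free_water(ds, self.field_)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _neighbor_pairs(mask: np.ndarray) -> np.ndarray:
    """Unique in-mask 6-neighbor pairs as indices into the masked ordering."""
    order = -np.ones(mask.shape, dtype=int)
    order[mask] = np.arange(int(mask.sum()))
    pairs = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = order[tuple(sl_a)]
        bb = order[tuple(sl_b)]
        ok = (a >= 0) & (bb >= 0)
        pairs.append(np.column_stack([a[ok], bb[ok]]))
    pairs = np.vstack(pairs) if pairs else np.empty((0, 2), dtype=int)
    return pairs


def _mask_is_contiguous(mask: np.ndarray) -> bool:
    from scipy.ndimage import label

    _, n = label(mask)
    return n <= 1


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def fit_multishell(ds: DWIDataset, **params) -> FreeWaterTensorField:
    """NLS bi-tensor fit on multi-shell data; returns the fitted field."""
    return MultiShellFreeWaterModel(**params).fit(ds).field_


def fit_singleshell(
    ds: DWIDataset,
    reg_weight: float = 0.1,
    step_size: float = 0.02,
    max_iter: int = 400,
    **params,
) -> FreeWaterTensorField:
    """Spatially regularized bi-tensor fit on single-shell data."""
    est = SingleShellFreeWaterModel(
        reg_weight=reg_weight, step_size=step_size, max_iter=max_iter, **params
    )
    return est.fit(ds).field_
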