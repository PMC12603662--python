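"""Diffusion acquisitions: gradient tables, 4-D datasets, derived datasets.

Reads NIfTI volumes with FSL-style ``.bval``/``.bvec`` gradient tables,
assigns measurements to shells with a configurable b-value tolerance, and
constructs the two derived datasets the reliability analyses need: a
single-shell subsample (b=0 plus one shell) and a seeded random split of
every shell into two disjoint halves.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

__all__ = [
    "GradientScheme",
    "DWIDataset",
    "load_dwi",
    "save_dwi",
    "subsample_single_shell",
    "split_half",
]

DEFAULT_SHELL_TOLERANCE = 50.0  # s/mm²; scanners jitter nominal b-values


class GradientFormatError(ValueError):
    """Gradient table does not match the image or the FSL convention."""


@dataclass(frozen=True)
class GradientScheme:
    """Per-measurement b-values and unit gradient directions.

    Parameters
    ----------
    bvals : (M,) array
        Diffusion weighting per measurement in s/mm².
    bvecs : (M, 3) array
        Unit direction per measurement.  Directions of b=0 measurements are
        treated as undefined and are not validated.
    shell_tolerance : float
        Maximum |b - nominal| for a measurement to join a shell; b-values at
        or below the tolerance count as b=0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientFormatError("bvecs must be an (M, 3) array")
        if len(bvals) != len(bvecs):
            raise GradientFormatError(
                f"bval count {len(bvals)} != bvec count {len(bvecs)}"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        dw = bvals > self.shell_tolerance
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(norms - 1.0) > 1e-6))
            raise ValueError(
                "non-b0 gradient directions must be unit vectors "
                f"(first offender: index {np.flatnonzero(dw)[bad]})"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.shell_tolerance

    def shells(self) -> dict[float, np.ndarray]:
        """Nominal shell -> measurement-index array (b0 under key 0.0).

        Nominal shells are formed greedily: b-values within
        ``shell_tolerance`` of an existing shell's nominal value join it,
        otherwise they found a new shell named by the first b-value seen.
        """
        out: dict[float, list[int]] = {}
        for i, b in enumerate(self.bvals):
            if b <= self.shell_tolerance:
                out.setdefault(0.0, []).append(i)
                continue
            for nominal in out:
                if nominal > 0 and abs(b - nominal) <= self.shell_tolerance:
                    out[nominal].append(i)
                    break
            else:
                out.setdefault(float(b), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def nonzero_shells(self) -> list[float]:
        return sorted(b for b in self.shells() if b > 0)

    def subset(self, indices: np.ndarray) -> "GradientScheme":
        indices = np.asarray(indices, dtype=int)
        return GradientScheme(
            bvals=self.bvals[indices],
            bvecs=self.bvecs[indices],
            shell_tolerance=self.shell_tolerance,
        )


@dataclass(frozen=True)
class DWIDataset:
    """A 4-D diffusion-weighted volume bound to its scheme and mask."""

    data: np.ndarray
    scheme: GradientScheme
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        mask = np.asarray(self.mask).astype(bool)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, measurement)")
        if data.shape[-1] != len(self.scheme):
            raise GradientFormatError(
                f"data has {data.shape[-1]} measurements but the gradient "
                f"scheme has {len(self.scheme)}"
            )
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape must equal the data's spatial shape")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(data < 0):
            raise ValueError("input signal values must be non-negative")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", affine)

    def __len__(self) -> int:
        return len(self.scheme)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def subset(self, indices: np.ndarray) -> "DWIDataset":
        indices = np.asarray(indices, dtype=int)
        return DWIDataset(
            data=self.data[..., indices],
            scheme=self.scheme.subset(indices),
            mask=self.mask,
            affine=self.affine,
        )


def _read_fsl_table(path: str | os.PathLike) -> np.ndarray:
    try:
        return np.loadtxt(path, ndmin=2)
    except ValueError as exc:  # pragma: no cover - numpy error text varies
        raise GradientFormatError(f"could not parse {path}: {exc}") from exc


def load_dwi(
    image_path: str | os.PathLike,
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
    mask_path: str | os.PathLike | None = None,
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
) -> DWIDataset:
    """Load a NIfTI DWI plus FSL ``.bval``/``.bvec`` (and optional mask).

    ``bvec`` files may be 3 rows x M columns (FSL) or M rows x 3 columns;
    both are accepted.  When no mask is given, every voxel is in-mask.
    """
    img = nib.load(os.fspath(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    bvals = _read_fsl_table(bval_path).ravel()
    bvecs = _read_fsl_table(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    scheme = GradientScheme(bvals=bvals, bvecs=bvecs, shell_tolerance=shell_tolerance)
    if mask_path is not None:
        mask = np.asarray(nib.load(os.fspath(mask_path)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return DWIDataset(data=data, scheme=scheme, mask=mask, affine=img.affine)


def save_dwi(ds: DWIDataset, prefix: str | os.PathLike) -> dict[str, str]:
    """Write ``<prefix>.nii.gz`` + ``.bval``/``.bvec`` + ``_mask.nii.gz``."""
    prefix = os.fspath(prefix)
    paths = {
        "image": prefix + ".nii.gz",
        "bval": prefix + ".bval",
        "bvec": prefix + ".bvec",
        "mask": prefix + "_mask.nii.gz",
    }
    nib.save(nib.Nifti1Image(ds.data.astype(np.float32), ds.affine), paths["image"])
    np.savetxt(paths["bval"], ds.scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(paths["bvec"], ds.scheme.bvecs.T, fmt="%.8f")
    nib.save(nib.Nifti1Image(ds.mask.astype(np.uint8), ds.affine), paths["mask"])
    return paths


def subsample_single_shell(ds: DWIDataset, shell: float) -> DWIDataset:
    """Keep only b=0 measurements plus one shell, preserving ordering."""
    shells = ds.scheme.shells()
    nominal = None
    for b in shells:
        if b > 0 and abs(b - shell) <= ds.scheme.shell_tolerance:
            nominal = b
            break
    if nominal is None:
        available = sorted(b for b in shells if b > 0)
        raise ValueError(
            f"shell {shell} not present; available shells: {available}"
        )
    keep = np.sort(np.concatenate([shells.get(0.0, np.empty(0, int)), shells[nominal]]))
    return ds.subset(keep)


def split_half(ds: DWIDataset, seed: int) -> tuple[DWIDataset, DWIDataset]:
    """Randomly and evenly split every shell (including b=0) into two.

    Each shell's measurements are permuted with a generator seeded by
    ``seed`` and dealt alternately; for odd counts the first half receives
    the extra measurement.  Original measurement ordering is preserved
    within each half, so the two halves partition the dataset exactly.
    """
    rng = np.random.default_rng(seed)
    shells = ds.scheme.shells()
    idx_a: list[np.ndarray] = []
    idx_b: list[np.ndarray] = []
    for b in sorted(shells):
        members = shells[b]
        if len(members) < 2:
            raise ValueError(
                f"shell b={b:g} has {len(members)} measurement(s); "
                "need at least 2 to split"
            )
        perm = rng.permutation(len(members))
        half = (len(members) + 1) // 2  # odd count: extra goes to first half
        idx_a.append(members[perm[:half]])
        idx_b.append(members[perm[half:]])
    order_a = np.sort(np.concatenate(idx_a))
    order_b = np.sort(np.concatenate(idx_b))
    return ds.subset(order_a), ds.subset(order_b)
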