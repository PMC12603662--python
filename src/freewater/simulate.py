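"""Synthetic diffusion acquisitions, voxels, and phantoms.

Everything downstream — fitting, free-water elimination, split-half
reliability — is testable without scanner data by simulating the reference
acquisition (b = 500/1000/2500 s/mm² with 32/64/128 directions plus 26
interleaved b=0 volumes) over phantoms that mix an anisotropic tissue
tensor with an isotropic free-water compartment at controlled fraction f.
The default phantom has three regions mimicking the tissue classes the
reliability analyses contrast: normal-appearing white matter (moderate f),
a hyperintensity-like block (high f), and a ventricle (pure free water).

Noise is Rician: the magnitude of the noiseless signal plus complex
Gaussian noise with sigma = S0 / SNR, matching magnitude MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import DWIDataset, GradientScheme
from .model import D_ISO, FreeWaterTensorField, matrix_to_tensor

__all__ = [
    "PAPER_SHELLS",
    "PAPER_N_B0",
    "make_scheme",
    "paper_scheme",
    "simulate_voxel",
    "PhantomRegion",
    "default_regions",
    "simulate_phantom",
]

#: The reference acquisition: (b-value s/mm², direction count) per shell.
PAPER_SHELLS: tuple[tuple[float, int], ...] = ((500.0, 32), (1000.0, 64), (2500.0, 128))
PAPER_N_B0 = 26

#: Prolate tissue tensor used by the default phantom (mm²/s):
#: FA = 0.70, MD = 0.85e-3 — typical coherent white matter.
DEFAULT_TISSUE_EVALS = (1.7e-3, 0.43e-3, 0.43e-3)


def _dispersed_directions(n: int, seed: int) -> np.ndarray:
    """n well-spread unit directions: golden-spiral start + electrostatic
    repulsion with antipodal symmetry, under a seeded random rotation so
    different shells (different seeds) get distinct point sets."""
    k = np.arange(n)
    z = 1.0 - (k + 0.5) / n * 2.0
    r = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # a few projected-gradient repulsion sweeps on the antipodal energy
    for _ in range(20):
        diff = pts[:, None, :] - pts[None, :, :]
        diff_anti = pts[:, None, :] + pts[None, :, :]
        d1 = np.linalg.norm(diff, axis=-1) + np.eye(n)
        d2 = np.linalg.norm(diff_anti, axis=-1) + 1e-12
        force = (diff / d1[..., None] ** 3).sum(axis=1) + (
            diff_anti / d2[..., None] ** 3
        ).sum(axis=1)
        force -= pts * (force * pts).sum(axis=1, keepdims=True)  # tangential
        pts = pts + 0.05 * force / n
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    rot = np.linalg.qr(rng.standard_normal((3, 3)))[0]
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    return pts @ rot.T


def make_scheme(
    shells: list[tuple[float, int]] | tuple[tuple[float, int], ...] = PAPER_SHELLS,
    n_b0: int = PAPER_N_B0,
    seed: int = 0,
    shell_tolerance: float = 50.0,
) -> GradientScheme:
    """Build an acquisition with dispersed directions and interleaved b0s.

    Direction sets are deterministic given ``seed``; b=0 measurements are
    spread evenly through the measurement list, as on the scanner.
    """
    dw_bvals: list[float] = []
    dw_bvecs: list[np.ndarray] = []
    for i, (b, n_dir) in enumerate(shells):
        if n_dir < 6:
            raise ValueError("need >= 6 directions per shell for tensor fitting")
        dirs = _dispersed_directions(n_dir, seed=seed * 131 + i)
        dw_bvals.extend([b] * n_dir)
        dw_bvecs.extend(dirs)
    n_dw = len(dw_bvals)
    n_total = n_dw + n_b0
    b0_slots = np.unique(
        np.round(np.linspace(0, n_total - 1, n_b0)).astype(int)
    ) if n_b0 else np.empty(0, int)
    bvals = np.empty(n_total)
    bvecs = np.zeros((n_total, 3))
    dw_iter = iter(range(n_dw))
    b0_set = set(b0_slots.tolist())
    for m in range(n_total):
        if m in b0_set:
            bvals[m] = 0.0
        else:
            j = next(dw_iter)
            bvals[m] = dw_bvals[j]
            bvecs[m] = dw_bvecs[j]
    return GradientScheme(bvals=bvals, bvecs=bvecs, shell_tolerance=shell_tolerance)


def paper_scheme(seed: int = 0) -> GradientScheme:
    """The reference multi-shell acquisition (250 measurements)."""
    return make_scheme(PAPER_SHELLS, PAPER_N_B0, seed=seed)


def _add_rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator):
    n1 = rng.normal(0.0, sigma, noiseless.shape)
    n2 = rng.normal(0.0, sigma, noiseless.shape)
    return np.sqrt((noiseless + n1) ** 2 + n2**2)


def simulate_voxel(
    compartments: list[tuple[float, np.ndarray]],
    f_free: float,
    s0: float,
    scheme: GradientScheme,
    snr: float = np.inf,
    seed: int | None = None,
    d_iso: float = D_ISO,
    noise_model: str = "rician",
) -> np.ndarray:
    """Simulate one voxel's signal from tissue compartments plus free water.

    Parameters
    ----------
    compartments : list of (fraction, q6)
        Tissue compartments; ``q6`` are the 6 unique tensor elements
        (mm²/s).  Fractions plus ``f_free`` must sum to 1.
    f_free : float
        Free-water volume fraction.
    snr : float
        b0 signal-to-noise ratio; ``inf`` means noiseless.
    noise_model : {"rician", "gaussian"}
        Gaussian is a debugging aid; Rician matches magnitude MRI.
    """
    fracs = np.array([fr for fr, _ in compartments], dtype=float)
    total = fracs.sum() + f_free
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"fractions must sum to 1, got {total}")
    from .model import design_quadratic

    design = design_quadratic(scheme)
    signal = s0 * f_free * np.exp(-scheme.bvals * d_iso)
    for frac, q6 in compartments:
        signal = signal + s0 * frac * np.exp(-design @ np.asarray(q6, dtype=float))
    if np.isinf(snr):
        return signal
    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    if noise_model == "gaussian":
        return np.maximum(signal + rng.normal(0.0, sigma, signal.shape), 0.0)
    if noise_model != "rician":
        raise ValueError(f"unknown noise model {noise_model!r}")
    return _add_rician(signal, sigma, rng)


def _prolate_tensor(
    evals: tuple[float, float, float] = DEFAULT_TISSUE_EVALS,
    axis: np.ndarray | None = None,
) -> np.ndarray:
    """q6 of a cylindrically symmetric tensor with principal ``axis``."""
    if axis is None:
        axis = np.array([1.0, 0.0, 0.0])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal completion
    other = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(axis, other)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(axis, e2)
    basis = np.column_stack([axis, e2, e3])
    m = basis @ np.diag(evals) @ basis.T
    return matrix_to_tensor(m)


@dataclass(frozen=True)
class PhantomRegion:
    """A labeled block of the phantom with its own mixture parameters."""

    name: str
    slices: tuple[slice, slice, slice]
    f_free: float
    compartments: tuple[tuple[float, tuple[float, ...]], ...]
    # compartments: ((fraction, q6), ...); fractions sum to 1 - f_free


def default_regions(
    shape: tuple[int, int, int] = (20, 20, 5),
    include_crossing: bool = False,
) -> list[PhantomRegion]:
    """NAWM background (f=0.15), WMH block (f=0.6), ventricle (f=1.0).

    The tissue tensor is the same prolate tensor everywhere (FA ~= 0.70),
    reflecting that hyperintensities mostly add free water rather than
    reorient fibers; the ventricle is pure free water.
    """
    nx, ny, nz = shape
    q_main = tuple(_prolate_tensor())
    regions = [
        PhantomRegion(
            "nawm",
            (slice(0, nx), slice(0, ny), slice(0, nz)),
            f_free=0.15,
            compartments=((0.85, q_main),),
        ),
        PhantomRegion(
            "wmh",
            (slice(nx // 4, nx // 4 + max(nx // 4, 2)),
             slice(ny // 4, ny // 4 + max(ny // 4, 2)),
             slice(0, nz)),
            f_free=0.6,
            compartments=((0.4, q_main),),
        ),
        PhantomRegion(
            "ventricle",
            (slice(nx - max(nx // 6, 2), nx), slice(0, max(ny // 6, 2)), slice(0, nz)),
            f_free=1.0,
            compartments=(),
        ),
    ]
    if include_crossing:
        q_cross = tuple(_prolate_tensor(axis=np.array([0.0, 1.0, 0.0])))
        regions.append(
            PhantomRegion(
                "crossing",
                (slice(nx - max(nx // 5, 2), nx),
                 slice(ny - max(ny // 5, 2), ny),
                 slice(0, nz)),
                f_free=0.15,
                compartments=((0.425, q_main), (0.425, q_cross)),
            )
        )
    return regions


REGION_LABELS = {"nawm": 1, "wmh": 2, "ventricle": 3, "crossing": 4}


def simulate_phantom(
    shape: tuple[int, int, int] = (20, 20, 5),
    regions: list[PhantomRegion] | None = None,
    scheme: GradientScheme | None = None,
    snr: float = 40.0,
    seed: int = 0,
    s0: float = 100.0,
    d_iso: float = D_ISO,
) -> tuple[DWIDataset, FreeWaterTensorField, np.ndarray]:
    """Simulate a labeled phantom volume on the given acquisition.

    Later regions overwrite earlier ones where they overlap (the default
    background region spans the whole volume by design); two non-background
    regions occupying the same voxel is an error.

    Returns
    -------
    ds : DWIDataset (with Rician noise unless snr=inf)
    truth : FreeWaterTensorField (single-tensor ground truth; in crossing
        regions ``q`` holds the fraction-weighted mean tensor)
    labels : int ndarray coded by ``REGION_LABELS`` (0 = unassigned)
    """
    if scheme is None:
        scheme = paper_scheme(seed=0)
    if regions is None:
        regions = default_regions(shape)

    labels = np.zeros(shape, dtype=int)
    f_map = np.zeros(shape)
    q_map = np.zeros(shape + (6,))
    comp_map: dict[str, list] = {}

    background = {r.name for r in regions if r.slices == (slice(0, shape[0]), slice(0, shape[1]), slice(0, shape[2]))}
    claimed = np.zeros(shape, dtype=bool)
    label_codes = dict(REGION_LABELS)
    for r in regions:
        if r.name not in label_codes:
            label_codes[r.name] = max(label_codes.values()) + 1
        label = label_codes[r.name]
        block = np.zeros(shape, dtype=bool)
        block[r.slices] = True
        if r.name not in background and np.any(claimed & block):
            raise ValueError(f"region {r.name!r} overlaps another region")
        if r.name not in background:
            claimed |= block
        labels[block] = label
        f_map[block] = r.f_free
        if r.compartments:
            q_mean = sum(
                fr * np.asarray(q6) for fr, q6 in r.compartments
            ) / max(sum(fr for fr, _ in r.compartments), 1e-12)
            q_map[block] = q_mean
        else:
            q_map[block] = matrix_to_tensor(d_iso * np.eye(3))
        comp_map[r.name] = [(fr, np.asarray(q6)) for fr, q6 in r.compartments]

    # build noiseless signal region by region (regions are homogeneous)
    from .model import design_quadratic

    design = design_quadratic(scheme)
    signal = np.zeros(shape + (len(scheme),))
    for r in regions:
        block = labels == label_codes[r.name]
        voxel_sig = s0 * r.f_free * np.exp(-scheme.bvals * d_iso)
        for fr, q6 in comp_map[r.name]:
            voxel_sig = voxel_sig + s0 * fr * np.exp(-design @ q6)
        signal[block] = voxel_sig

    if not np.isinf(snr):
        rng = np.random.default_rng(seed)
        signal = _add_rician(signal, s0 / snr, rng)

    mask = np.ones(shape, dtype=bool)
    ds = DWIDataset(data=signal, scheme=scheme, mask=mask, affine=np.eye(4))
    truth = FreeWaterTensorField(
        q=q_map, f=f_map, s0=np.full(shape, float(s0)), d_iso=d_iso, mask=mask
    )
    return ds, truth, labels
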