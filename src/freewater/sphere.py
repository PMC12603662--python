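"""Fixed discretization of the unit sphere.

Spherical functions (tensor ODFs, fODF stand-ins) are compared voxel-wise
across split halves by correlating their values on a common, versioned set
of sphere vertices.  The default grid has 362 antipodally symmetric
vertices: 181 near-uniform points on the upper hemisphere generated by a
golden-angle spiral, plus their antipodes.  The construction is pure
arithmetic, so the grid is bit-reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: Identifier written to sidecar metadata so that serialized spherical
#: fields can be checked against the grid they were sampled on.
DEFAULT_SPHERE_VERSION = "golden-spiral-362-v1"


@dataclass(frozen=True)
class SphereGrid:
    """A fixed set of unit vectors on which spherical functions are sampled.

    Attributes
    ----------
    vertices : (N, 3) ndarray
        Unit-norm sample directions.
    version : str
        Identifier of the construction; grids only compare equal when both
        the vertices and the version match.
    """

    vertices: np.ndarray
    version: str = DEFAULT_SPHERE_VERSION

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("all sphere vertices must be unit-norm")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SphereGrid):
            return NotImplemented
        return (
            self.version == other.version
            and self.vertices.shape == other.vertices.shape
            and np.array_equal(self.vertices, other.vertices)
        )

    def __hash__(self) -> int:  # frozen dataclass with ndarray field
        return hash((self.version, self.vertices.shape))

    @property
    def is_antipodal(self) -> bool:
        """True if the vertex set is exactly closed under negation."""
        n = len(self.vertices)
        if n % 2:
            return False
        return np.array_equal(self.vertices[n // 2 :], -self.vertices[: n // 2])


def hemisphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform points on the open upper hemisphere (z > 0)."""
    k = np.arange(n)
    # z strictly inside (0, 1] so no point sits on the equator where its
    # antipode would coincide with another hemisphere point.
    z = (k + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    phi = k * GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_sphere(n_vertices: int = 362) -> SphereGrid:
    """The package's versioned antipodally symmetric sphere grid.

    Parameters
    ----------
    n_vertices : int
        Total vertex count; must be even (antipodal pairs).
    """
    if n_vertices % 2:
        raise ValueError("n_vertices must be even for an antipodal grid")
    half = hemisphere_points(n_vertices // 2)
    vertices = np.vstack([half, -half])
    version = f"golden-spiral-{n_vertices}-v1"
    return SphereGrid(vertices=vertices, version=version)
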