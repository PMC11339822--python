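"""Rigid-body machinery: superposition, tile normals, flattening, density maps.

Assembly flattening mirrors how a curved shell facet is converted into a
planar sheet: each multimeric tile is moved rigidly — no internal distortion —
so that its pore normal aligns with a common axis and its centroid lies in the
z = 0 plane. The flattened model can then serve as the rigid target for a
synthetic density map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import Selection, Structure, select

__all__ = [
    "RigidTransform",
    "DensityGrid",
    "superpose",
    "tile_normal",
    "plane_normal",
    "flatten_assembly",
    "synthetic_density",
    "write_dx",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflection is not a rigid transform (det must be +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix representation."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition (Kabsch) of ``mobile`` onto ``reference``.

    Returns the transform minimising the (weighted) RMSD and that minimum RMSD
    in Angstrom. Reflections are excluded by construction.

    Raises
    ------
    ValueError
        For fewer than 3 points, mismatched shapes, or a degenerate
        (all-collinear) configuration.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_r = w @ reference
    A = mobile - mu_m
    B = reference - mu_r
    # Degeneracy: all points collinear leaves a free rotation axis.
    if np.linalg.matrix_rank(A - A[0], tol=1e-9) < 2 and np.linalg.matrix_rank(
        B - B[0], tol=1e-9
    ) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    H = (A * w[:, None]).T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    transform = RigidTransform(R, t)
    diff = transform.apply(mobile) - reference
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return transform, rmsd


def tile_normal(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Unit normal of the plane through three monomer reference points.

    Returns normalize((p2 - p1) x (p3 - p1)); the sign follows the right-hand
    rule on input order, so swapping two points flips the normal.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1.0)
    if norm <= 1e-12 * scale**2:
        raise ValueError("collinear points do not define a plane normal")
    return n / norm


def plane_normal(coords: np.ndarray, orient: np.ndarray | None = None) -> np.ndarray:
    """Least-squares plane normal of a point cloud (smallest principal axis).

    ``orient`` resolves the sign ambiguity: the returned normal has a
    non-negative dot product with it.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate point cloud: no unique plane")
    n = Vt[2]
    if orient is not None and float(np.dot(n, orient)) < 0:
        n = -n
    return n / np.linalg.norm(n)


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # 180 degree flip about any axis perpendicular to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis = axis / np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def flatten_assembly(
    assembly: Structure,
    tile_definitions: Sequence[Selection | str],
    target_axis: np.ndarray = np.array([0.0, 0.0, 1.0]),
    flip: bool = False,
) -> tuple[Structure, list[RigidTransform]]:
    """Rigidly rotate each tile so its pore normal aligns with ``target_axis``
    and translate its centroid into the z = 0 plane.

    Each tile's normal is taken as the least-squares plane normal of its atom
    coordinates (tiles are thin, roughly planar multimers), oriented toward
    ``target_axis`` (or away, with ``flip=True``). Intra-tile geometry is
    untouched; the operation is idempotent.

    Returns the flattened structure and the per-tile transforms applied.
    """
    target_axis = np.asarray(target_axis, dtype=float)
    target_axis = target_axis / np.linalg.norm(target_axis)
    idx_sets = [select(assembly, sel) for sel in tile_definitions]
    for i, idx in enumerate(idx_sets):
        if idx.size == 0:
            raise ValueError(f"tile selection {i} matches no atoms")
    all_idx = np.concatenate(idx_sets)
    if len(np.unique(all_idx)) != len(all_idx):
        raise ValueError("tile selections overlap")

    new_coords = assembly.coords.copy()
    transforms: list[RigidTransform] = []
    orient = -target_axis if flip else target_axis
    for idx in idx_sets:
        tile = assembly.coords[idx]
        centroid = tile.mean(axis=0)
        normal = plane_normal(tile, orient=orient)
        R = _rotation_aligning(normal, target_axis)
        # Rotate about the tile centroid, then drop the centroid onto z = 0.
        t = centroid - R @ centroid
        t = t - target_axis * float(np.dot(centroid, target_axis))
        tr = RigidTransform(R, t)
        new_coords[idx] = tr.apply(tile)
        transforms.append(tr)
    return assembly.with_coords(new_coords), transforms


@dataclass
class DensityGrid:
    """A non-negative scalar field on a regular cubic grid (Angstrom units)."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    def integral(self) -> float:
        """Numerical integral of the field (value sum x voxel volume)."""
        return float(self.values.sum() * self.spacing**3)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing * np.arange(self.values.shape[k])
            for k in range(3)
        )


def synthetic_density(
    structure: Structure,
    resolution: float = 4.0,
    spacing: float = 1.0,
    weights: np.ndarray | None = None,
) -> DensityGrid:
    """Gaussian-smoothed synthetic density map of a structure.

    Each atom contributes an isotropic, unit-integral Gaussian of width
    sigma = resolution / (2 sqrt(2 ln 2)) — i.e. FWHM equals the nominal map
    resolution. The grid extends at least 3.5 sigma beyond the atom extent.
    """
    if structure.n_atoms == 0:
        raise ValueError("cannot build a density map from an empty structure")
    if resolution < 2 * spacing:
        raise ValueError("resolution must be at least twice the grid spacing")
    sigma = resolution / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    pad = 3.5 * sigma
    coords = structure.coords
    w = np.ones(structure.n_atoms) if weights is None else np.asarray(weights, float)
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    ax = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    values = np.zeros(shape)
    norm = (2 * np.pi * sigma**2) ** -1.5
    cutoff = 4.5 * sigma  # per-atom support; tails beyond are negligible
    for pos, wt in zip(coords, w):
        sl = []
        gx = []
        for k in range(3):
            i0 = int(np.searchsorted(ax[k], pos[k] - cutoff))
            i1 = int(np.searchsorted(ax[k], pos[k] + cutoff))
            sl.append(slice(i0, i1))
            gx.append(np.exp(-((ax[k][i0:i1] - pos[k]) ** 2) / (2 * sigma**2)))
        values[sl[0], sl[1], sl[2]] += (
            wt * norm * gx[0][:, None, None] * gx[1][None, :, None] * gx[2][None, None, :]
        )
    return DensityGrid(origin=lo, spacing=spacing, values=values, resolution=resolution)


def write_dx(grid: DensityGrid, path: str | Path) -> None:
    """Write a density grid in OpenDX scalar format (plain text)."""
    nx, ny, nz = grid.values.shape
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}",
        f"delta {grid.spacing:.6f} 0 0",
        f"delta 0 {grid.spacing:.6f} 0",
        f"delta 0 0 {grid.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.values.ravel(order="C")
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    Path(path).write_text("\n".join(lines) + "\n")
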