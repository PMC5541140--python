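"""Volume/mesh data model, coordinate handling, distance fields and segment geometry.

All geometry is computed in world millimetres. Voxel indices are 0-based and a
voxel is centred on its integer index, so a world point belongs to the voxel
whose index coordinates round to it under half-open boundaries
``[i - 0.5, i + 0.5)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage


class GeometryError(ValueError):
    """Raised for invalid or inconsistent geometric inputs."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class ScalarField:
    """A 3-D voxel grid of real values with a voxel-index -> world-mm affine.

    Parameters
    ----------
    values : ndarray, shape (ni, nj, nk)
        Finite real values, one per voxel.
    affine : ndarray, shape (4, 4)
        Maps homogeneous voxel indices to world millimetres. Must be
        invertible with strictly positive voxel spacing on every axis.
    name : str
        Human-readable identifier used in error messages and NIfTI export.
    """

    values: np.ndarray
    affine: np.ndarray
    name: str = "field"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError(f"{self.name}: values must be 3-D")
        if self.affine.shape != (4, 4):
            raise GeometryError(f"{self.name}: affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError(f"{self.name}: affine is singular")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError(f"{self.name}: non-finite values")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"{self.name}: non-positive voxel spacing")
        self._inv_affine = np.linalg.inv(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm along each index axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    # -- coordinate transforms ------------------------------------------------

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Continuous voxel-index coordinates of world points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self._inv_affine[:3, :3].T + self._inv_affine[:3, 3]

    def containing_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Integer voxel indices under half-open voxel boundaries."""
        return np.floor(self.world_to_voxel(pts) + 0.5).astype(int)

    # -- sampling -------------------------------------------------------------

    def sample_world(self, pts: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at world points; edge values extend outside."""
        idx = self.world_to_voxel(pts)
        return ndimage.map_coordinates(self.values, idx.T, order=1, mode="nearest")

    def same_geometry(self, other: "ScalarField | LabelVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=1e-6)

    # -- IO -------------------------------------------------------------------

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), path)

    @classmethod
    def from_nifti(cls, path: str, name: str | None = None) -> "ScalarField":
        img = nib.load(path)
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, name or str(path))


@dataclass
class LabelVolume:
    """Integer label volume (parcellation or binary mask) with a legend."""

    labels: np.ndarray
    affine: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)
    name: str = "labels"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise GeometryError(f"{self.name}: labels must be integers")
            self.labels = np.round(self.labels).astype(np.int32)
        if np.any(self.labels < 0):
            raise GeometryError(f"{self.name}: negative labels")
        self.affine = np.asarray(self.affine, dtype=float)
        self._geom = ScalarField(np.zeros(self.labels.shape), self.affine, self.name)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return self._geom.spacing

    def mask(self, label: int | None = None) -> np.ndarray:
        """Boolean mask of one label, or of all non-zero voxels."""
        return self.labels > 0 if label is None else self.labels == label

    def geometry(self) -> ScalarField:
        """An empty ScalarField sharing this volume's grid and affine."""
        return ScalarField(np.zeros(self.shape), self.affine, self.name + "_geom")

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine), path)

    @classmethod
    def from_nifti(cls, path: str, legend: dict[int, str] | None = None,
                   name: str | None = None) -> "LabelVolume":
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        return cls(np.round(data).astype(np.int32), img.affine, legend or {}, name or str(path))


class SurfaceMesh:
    """Triangulated surface in world mm with outward unit vertex normals.

    Thin wrapper over :class:`trimesh.Trimesh`; the skull surface must be
    watertight for reliable inside/outside reasoning — a warning is emitted at
    load time if it is not.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, name: str = "mesh",
                 check_watertight: bool = True):
        self.name = name
        self._mesh = trimesh.Trimesh(vertices=np.asarray(vertices, dtype=float),
                                     faces=np.asarray(faces, dtype=int), process=False)
        if len(self._mesh.faces) and self._mesh.faces.max() >= len(self._mesh.vertices):
            raise GeometryError(f"{name}: face index out of range")
        if check_watertight and not self._mesh.is_watertight:
            warnings.warn(f"mesh '{name}' is not watertight; inside/outside tests unreliable",
                          stacklevel=2)

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self._mesh.vertices)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self._mesh.faces)

    @property
    def vertex_normals(self) -> np.ndarray:
        n = np.asarray(self._mesh.vertex_normals, dtype=float)
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(norms == 0, 1.0, norms)

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self._mesh.centroid)

    @property
    def is_watertight(self) -> bool:
        return bool(self._mesh.is_watertight)

    def trimesh(self) -> trimesh.Trimesh:
        return self._mesh

    def save(self, path: str) -> None:
        self._mesh.export(path)

    @classmethod
    def load(cls, path: str, name: str | None = None) -> "SurfaceMesh":
        m = trimesh.load(path, force="mesh")
        return cls(m.vertices, m.faces, name or str(path))


@dataclass(frozen=True)
class Segment:
    """Directed trajectory segment from a deep target to a skull entry (mm)."""

    target: np.ndarray
    entry: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float).reshape(3))
        object.__setattr__(self, "entry", np.asarray(self.entry, dtype=float).reshape(3))
        if self.length <= 0:
            raise GeometryError("segment has zero length")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.entry - self.target))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from target to entry."""
        return (self.entry - self.target) / self.length


# ---------------------------------------------------------------------------
# distance fields
# ---------------------------------------------------------------------------


def _rasterize_mesh(mesh: SurfaceMesh, grid: ScalarField) -> np.ndarray:
    # subdivide until edges are shorter than half a voxel, then bin vertices:
    # every voxel the surface passes through gets marked, to voxel accuracy
    max_edge = 0.5 * float(grid.spacing.min())
    tm = mesh.trimesh()
    v, f, *_ = trimesh.remesh.subdivide_to_size(tm.vertices, tm.faces, max_edge=max_edge)
    idx = grid.containing_voxel(v)
    ok = np.all((idx >= 0) & (idx < np.array(grid.shape)), axis=1)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[tuple(idx[ok].T)] = True
    return mask


def distance_field(structure: LabelVolume | SurfaceMesh | np.ndarray,
                   grid: ScalarField, label: int | None = None,
                   name: str = "distance") -> ScalarField:
    """Unsigned Euclidean distance (mm) from every voxel to a structure.

    ``structure`` is a binary/label volume, a boolean array on the grid, or a
    surface mesh (rasterised to the grid first). The field is exactly zero on
    voxels inside the structure.
    """
    if isinstance(structure, SurfaceMesh):
        mask = _rasterize_mesh(structure, grid)
    elif isinstance(structure, LabelVolume):
        if not np.allclose(structure.affine, grid.affine, atol=1e-6) \
                or structure.shape != grid.shape:
            raise GeometryError(f"{name}: structure and grid geometry mismatch")
        mask = structure.mask(label)
    else:
        mask = np.asarray(structure, dtype=bool)
        if mask.shape != grid.shape:
            raise GeometryError(f"{name}: mask shape mismatch")
    if not mask.any():
        raise GeometryError(f"{name}: empty structure")
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
    return ScalarField(dist, grid.affine, name)


def normalize_field(d: ScalarField) -> ScalarField:
    """Scale a non-negative field by its grid-wide maximum, onto [0, 1]."""
    m = float(d.values.max())
    if m <= 0:
        raise GeometryError(f"{d.name}: degenerate field (max <= 0)")
    return ScalarField(d.values / m, d.affine, d.name + "_norm")


def signed_gm_distance(gm_mask: LabelVolume, label: int | None = None) -> ScalarField:
    """Signed distance to the grey-matter surface: positive inside, negative outside.

    The Heaviside step of this field (with H(0) = 1) is 1 on GM voxels and 0
    elsewhere; trilinear sampling puts the zero crossing halfway between a GM
    voxel and its non-GM neighbour.
    """
    mask = gm_mask.mask(label)
    if not mask.any() or mask.all():
        raise GeometryError("GM mask empty or covers the whole grid")
    sp = gm_mask.spacing
    inside = ndimage.distance_transform_edt(mask, sampling=sp)
    outside = ndimage.distance_transform_edt(~mask, sampling=sp)
    return ScalarField(np.where(mask, inside, -outside), gm_mask.affine, "gm_signed")


# ---------------------------------------------------------------------------
# segment geometry
# ---------------------------------------------------------------------------


def sample_segment(seg: Segment, step: float = 1.0) -> np.ndarray:
    """Uniformly spaced world points from target to entry, both inclusive.

    Spacing never exceeds ``step``; the point count is chosen so the spacing
    is constant along the segment.
    """
    if step <= 0:
        raise GeometryError("step must be positive")
    n = int(np.ceil(seg.length / step)) + 1
    t = np.linspace(0.0, 1.0, n)
    return seg.target[None, :] + t[:, None] * (seg.entry - seg.target)[None, :]


def segment_segment_distance(a: Segment, b: Segment) -> float:
    """Minimum Euclidean distance between two closed 3-D segments (mm)."""
    return _seg_seg_dist(a.target, a.entry, b.target, b.entry)


def _seg_seg_dist(p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray) -> float:
    # closest points of two segments, clamped quadratic minimisation
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    eps = 1e-12
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= eps:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    c1 = p1 + s * d1
    c2 = p2 + t * d2
    return float(np.linalg.norm(c1 - c2))
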