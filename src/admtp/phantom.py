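"""Synthetic head phantoms with known-safe implantation corridors.

The generator emulates the inputs the planner consumes in a clinical
pipeline: a brain parcellation restricted to the requested ROIs, binary
masks for arteries, veins, sulci and grey matter, a watertight skull
surface mesh, and a strategy file listing the electrodes. Anatomy is
idealised — a spherical (optionally ellipsoidal) skull shell, a cortical
GM ribbon plus deep GM blobs coinciding with the ROIs, vascular trees as
tubes around polylines, and sulci as thin radial sheets. Each phantom
declares guaranteed vessel- and sulcus-free cones ("corridors") from every
ROI out to the skull; corridor emptiness is verified after rasterisation so
every generated phantom is a certified planning instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
import yaml

from .geometry import GeometryError, LabelVolume, ScalarField, SurfaceMesh


@dataclass(frozen=True)
class VesselTube:
    """A tube of constant radius around a polyline of control points (mm)."""

    points: tuple[tuple[float, float, float], ...]
    radius: float = 1.5
    kind: str = "vein"  # "vein" or "artery"


@dataclass(frozen=True)
class SulcusSheet:
    """A thin oriented sheet: |(p-origin)·normal| <= thickness/2 within a
    radial band and lateral extent, mimicking a CSF-filled groove."""

    origin: tuple[float, float, float]
    normal: tuple[float, float, float]
    thickness: float = 1.0
    r_inner: float = 50.0
    r_outer: float = 80.0
    extent: float = 25.0


@dataclass(frozen=True)
class RoiBlob:
    label: int
    centre: tuple[float, float, float]
    semi_axes: tuple[float, float, float] = (8.0, 8.0, 8.0)
    name: str = ""


@dataclass(frozen=True)
class Corridor:
    """A cone certified free of vessels and sulci: apex inside an ROI,
    outward axis, half-angle in degrees, reaching out to ``length`` mm."""

    apex: tuple[float, float, float]
    axis: tuple[float, float, float]
    half_angle: float = 10.0
    length: float = 45.0


# eight ROI directions: normalised cube corners, >70 degrees apart
_CUBE_DIRS = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                       for sz in (-1, 1)], dtype=float) / np.sqrt(3.0)


def _default_rois(roi_radius: float) -> tuple[RoiBlob, ...]:
    names = ["amygdala-like", "hippocampus-like", "insula-like", "cingulate-like",
             "orbitofrontal-like", "parietal-like", "occipital-like", "temporal-like"]
    return tuple(RoiBlob(i + 1, tuple(roi_radius * _CUBE_DIRS[i]), (8.0, 8.0, 8.0),
                         names[i]) for i in range(8))


def _default_vessels() -> tuple[VesselTube, ...]:
    # midline arc emulating the superior sagittal sinus, plus two lateral
    # branches threaded between corridors; one vein runs parallel to the
    # first corridor axis at 10 mm offset to exercise non-zero risk scores
    theta = np.linspace(-1.1 * np.pi / 2, 1.1 * np.pi / 2, 25)
    arc = tuple((0.0, 75.0 * np.sin(t), 75.0 * np.cos(t)) for t in theta)
    d1 = _CUBE_DIRS[7]  # (+1,+1,+1)/sqrt(3)
    perp = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
    near = tuple(tuple(t * d1 + 10.0 * perp) for t in np.linspace(35.0, 80.0, 10))
    lateral = tuple((55.0, 20.0 * np.cos(t), 35.0 * np.sin(t))
                    for t in np.linspace(-np.pi / 2, np.pi / 2, 12))
    return (VesselTube(arc, 2.0, "vein"),
            VesselTube(near, 1.5, "vein"),
            VesselTube(lateral, 1.2, "artery"))


def _default_sulci() -> tuple[SulcusSheet, ...]:
    return (SulcusSheet((0.0, -60.0, 0.0), (0.0, 1.0, 0.0), 1.0, 55.0, 78.0, 18.0),
            SulcusSheet((-60.0, 0.0, 0.0), (1.0, 0.0, 0.0), 1.0, 55.0, 78.0, 18.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameterised synthetic head. Defaults mimic the clinical imaging
    scale: 1 mm isotropic voxels, ~180 mm head diameter, eight deep ROIs."""

    grid_shape: tuple[int, int, int] = (176, 176, 176)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    skull_outer_radius: tuple[float, float, float] = (85.0, 85.0, 85.0)
    brain_radius: float = 80.0
    gm_ribbon: tuple[float, float] = (74.0, 80.0)   # radial band of cortical GM
    rois: tuple[RoiBlob, ...] = field(default_factory=lambda: _default_rois(45.0))
    vessels: tuple[VesselTube, ...] = field(default_factory=_default_vessels)
    sulci: tuple[SulcusSheet, ...] = field(default_factory=_default_sulci)
    corridors: tuple[Corridor, ...] = ()
    mesh_subdivisions: int = 3
    seed: int = 0

    def with_default_corridors(self) -> "PhantomSpec":
        """One radial corridor per ROI, apex at the ROI centre, out to the skull."""
        cors = []
        for roi in self.rois:
            c = np.asarray(roi.centre)
            axis = c / np.linalg.norm(c)
            length = float(min(self.skull_outer_radius) - np.linalg.norm(c))
            cors.append(Corridor(tuple(c), tuple(axis), 10.0, length))
        return replace(self, corridors=tuple(cors))


@dataclass
class Phantom:
    """Generated phantom: everything the planner consumes, plus ground truth."""

    spec: PhantomSpec
    grid: ScalarField               # empty field carrying grid geometry
    parcellation: LabelVolume       # ROI labels with legend
    arteries: np.ndarray            # boolean masks on the grid
    veins: np.ndarray
    sulci: np.ndarray
    gm: np.ndarray
    skull: SurfaceMesh
    strategy: list[dict]

    @property
    def critical_vessels(self) -> np.ndarray:
        """Union of arteries and veins: the vascular set used for risk."""
        return self.arteries | self.veins

    @property
    def critical_all(self) -> np.ndarray:
        """Arteries, veins and sulci: the trajectory no-intersection set."""
        return self.arteries | self.veins | self.sulci

    def save(self, outdir: str) -> None:
        import os
        os.makedirs(outdir, exist_ok=True)
        aff = self.grid.affine
        self.parcellation.to_nifti(os.path.join(outdir, "parcellation.nii.gz"))
        for nm, mask in [("arteries", self.arteries), ("veins", self.veins),
                         ("sulci", self.sulci), ("gm", self.gm)]:
            LabelVolume(mask.astype(np.int16), aff, {1: nm}).to_nifti(
                os.path.join(outdir, f"{nm}.nii.gz"))
        self.skull.save(os.path.join(outdir, "skull.ply"))
        with open(os.path.join(outdir, "strategy.yaml"), "w") as fh:
            yaml.safe_dump({"electrodes": self.strategy}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# rasterisation helpers (all exact within one voxel)
# ---------------------------------------------------------------------------


def _grid_field(spec: PhantomSpec) -> ScalarField:
    shape = np.asarray(spec.grid_shape)
    sp = np.asarray(spec.spacing)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(sp)
    affine[:3, 3] = -sp * (shape - 1) / 2.0  # world origin at grid centre
    return ScalarField(np.zeros(spec.grid_shape), affine, "phantom_grid")


def _axis_coords(grid: ScalarField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    aff = grid.affine
    return tuple(aff[d, d] * np.arange(grid.shape[d]) + aff[d, 3] for d in range(3))


def _radius_sq(grid: ScalarField, scale: np.ndarray) -> np.ndarray:
    x, y, z = _axis_coords(grid)
    return ((x / scale[0]) ** 2)[:, None, None] + \
           ((y / scale[1]) ** 2)[None, :, None] + \
           ((z / scale[2]) ** 2)[None, None, :]


def _mark_tube(mask: np.ndarray, grid: ScalarField, tube: VesselTube) -> None:
    pts = np.asarray(tube.points, dtype=float)
    sp = grid.spacing
    for a, b in zip(pts[:-1], pts[1:]):
        lo = np.minimum(a, b) - tube.radius - sp
        hi = np.maximum(a, b) + tube.radius + sp
        i0 = np.maximum(grid.containing_voxel(lo)[0], 0)
        i1 = np.minimum(grid.containing_voxel(hi)[0] + 1, np.array(grid.shape))
        if np.any(i0 >= i1):
            continue
        ii, jj, kk = np.meshgrid(*[np.arange(i0[d], i1[d]) for d in range(3)],
                                 indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        p = grid.voxel_to_world(idx)
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((p - a) @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(p))
        d = np.linalg.norm(p - a - t[:, None] * ab, axis=1)
        hit = idx[d <= tube.radius]
        mask[tuple(hit.T)] = True


def _mark_ellipsoid(mask: np.ndarray, grid: ScalarField, roi: RoiBlob) -> None:
    c = np.asarray(roi.centre)
    ax = np.asarray(roi.semi_axes)
    sp = grid.spacing
    i0 = np.maximum(grid.containing_voxel(c - ax - sp)[0], 0)
    i1 = np.minimum(grid.containing_voxel(c + ax + sp)[0] + 1, np.array(grid.shape))
    ii, jj, kk = np.meshgrid(*[np.arange(i0[d], i1[d]) for d in range(3)], indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    p = grid.voxel_to_world(idx)
    rho = np.sum(((p - c) / ax) ** 2, axis=1)
    mask[tuple(idx[rho <= 1.0].T)] = True


def _mark_sheet(mask: np.ndarray, grid: ScalarField, sheet: SulcusSheet,
                r2: np.ndarray) -> None:
    x, y, z = _axis_coords(grid)
    n = np.asarray(sheet.normal, dtype=float)
    n = n / np.linalg.norm(n)
    o = np.asarray(sheet.origin, dtype=float)
    plane = (n[0] * (x - o[0]))[:, None, None] + (n[1] * (y - o[1]))[None, :, None] \
        + (n[2] * (z - o[2]))[None, None, :]
    lat2 = ((x - o[0]) ** 2)[:, None, None] + ((y - o[1]) ** 2)[None, :, None] \
        + ((z - o[2]) ** 2)[None, None, :] - plane ** 2
    band = (r2 >= sheet.r_inner ** 2) & (r2 <= sheet.r_outer ** 2)
    mask |= (np.abs(plane) <= sheet.thickness / 2) & band \
        & (lat2 <= sheet.extent ** 2)


def _corridor_hits(mask: np.ndarray, grid: ScalarField, cor: Corridor) -> int:
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return 0
    p = grid.voxel_to_world(idx)
    apex = np.asarray(cor.apex)
    axis = np.asarray(cor.axis) / np.linalg.norm(cor.axis)
    v = p - apex
    proj = v @ axis
    inside_len = (proj >= 0) & (proj <= cor.length)
    radial = np.linalg.norm(v - proj[:, None] * axis[None, :], axis=1)
    cone = radial <= proj * np.tan(np.radians(cor.half_angle))
    return int(np.count_nonzero(inside_len & cone))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Rasterise a phantom head; deterministic for a fixed spec/seed.

    Raises if any declared corridor contains a vessel or sulcus voxel —
    a phantom spec that fails its own ground-truth certificate is invalid.
    """
    if spec is None:
        spec = PhantomSpec().with_default_corridors()
    grid = _grid_field(spec)
    r2 = _radius_sq(grid, np.ones(3))

    brain = _radius_sq(grid, np.asarray(spec.skull_outer_radius)
                       / min(spec.skull_outer_radius)) \
        <= spec.brain_radius ** 2

    gm = brain & (r2 >= spec.gm_ribbon[0] ** 2) & (r2 <= spec.gm_ribbon[1] ** 2)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    legend: dict[int, str] = {}
    for roi in spec.rois:
        blob = np.zeros(spec.grid_shape, dtype=bool)
        _mark_ellipsoid(blob, grid, roi)
        labels[blob] = roi.label
        gm |= blob  # deep nuclei are grey matter
        legend[roi.label] = roi.name or f"roi_{roi.label}"

    arteries = np.zeros(spec.grid_shape, dtype=bool)
    veins = np.zeros(spec.grid_shape, dtype=bool)
    for tube in spec.vessels:
        _mark_tube(arteries if tube.kind == "artery" else veins, grid, tube)

    sulci = np.zeros(spec.grid_shape, dtype=bool)
    for sheet in spec.sulci:
        _mark_sheet(sulci, grid, sheet, r2)

    for i, cor in enumerate(spec.corridors):
        bad = _corridor_hits(arteries | veins | sulci, grid, cor)
        if bad:
            raise GeometryError(
                f"phantom spec inconsistent: corridor {i} contains {bad} "
                "vessel/sulcus voxels")

    skull_tm = trimesh.creation.icosphere(subdivisions=spec.mesh_subdivisions, radius=1.0)
    skull_tm.apply_scale(np.asarray(spec.skull_outer_radius))
    skull = SurfaceMesh(skull_tm.vertices, skull_tm.faces, "skull")

    priors = ["roi_centreline", "medial_surface"]
    strategy = [{"id": f"E{roi.label}", "deep_roi_label": int(roi.label),
                 "superficial_roi_label": None,
                 "prior": priors[i % 2]}
                for i, roi in enumerate(spec.rois)]

    parc = LabelVolume(labels, grid.affine, legend, "parcellation")
    return Phantom(spec, grid, parc, arteries, veins, sulci, gm, skull, strategy)


def perturb_vessels(phantom: Phantom, offset) -> Phantom:
    """Rigidly translate every vessel tube by ``offset`` mm and re-rasterise;
    all other structures are unchanged. Corridor certificates are not
    re-checked (a perturbed phantom is a probe, not a planning instance)."""
    off = np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(off)):
        raise GeometryError("offset must be finite")
    moved = tuple(replace(t, points=tuple(tuple(np.asarray(p) + off) for p in t.points))
                  for t in phantom.spec.vessels)
    spec = replace(phantom.spec, vessels=moved, corridors=())
    grid = phantom.grid
    arteries = np.zeros(spec.grid_shape, dtype=bool)
    veins = np.zeros(spec.grid_shape, dtype=bool)
    for tube in spec.vessels:
        _mark_tube(arteries if tube.kind == "artery" else veins, grid, tube)
    return Phantom(spec, grid, phantom.parcellation, arteries, veins,
                   phantom.sulci, phantom.gm, phantom.skull, phantom.strategy)
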