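"""Candidate target point selection.

Builds the per-ROI target risk map

    f(c) = 1                                    if c is outside the ROI
    f(c) = 1                                    if c is inside a vessel
    f(c) = w_sp * f_sp(c) + w_cri * (1 - f_cri(c))   otherwise

where ``f_cri`` is the normalized distance to the union of arteries and veins
and ``f_sp`` a normalized spatial prior (distance to the skull for deep /
medial targets, or one minus the normalized depth inside the ROI so the ROI
centreline is preferred). Local minima of f are extracted by regional-minima
flooding, clustered with K-means (one cluster per electrode sharing the ROI),
and the M lowest-f points of each cluster become that electrode's candidate
targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.morphology import local_minima
from sklearn.cluster import KMeans

from .geometry import (GeometryError, LabelVolume, ScalarField, SurfaceMesh,
                       distance_field, normalize_field)


class SpatialPrior(str, Enum):
    """User-selected spatial preference for target placement within the ROI."""

    ROI_CENTRELINE = "roi_centreline"
    MEDIAL_SURFACE = "medial_surface"


@dataclass
class TargetRiskMap:
    f: ScalarField
    roi_label: int
    weights: tuple[float, float]  # (w_sp, w_cri)
    roi_mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass
class CandidateTargetSet:
    """Ranked candidate target points for one electrode, ascending in f."""

    electrode_id: str
    targets: np.ndarray          # (n, 3) world mm, sorted ascending by f
    f_values: np.ndarray         # (n,)
    cluster_id: int = 0

    def __len__(self) -> int:
        return len(self.targets)


def compute_critical_field(critical: LabelVolume | np.ndarray,
                           grid: ScalarField) -> ScalarField:
    """Normalized distance to the union of vascular structures; 0 on vessels."""
    d = distance_field(critical, grid, name="critical")
    return normalize_field(d)


def compute_spatial_prior(choice: SpatialPrior | str, roi_mask: np.ndarray,
                          grid: ScalarField,
                          skull: SurfaceMesh | None = None) -> ScalarField:
    """Normalized spatial prior f_sp on the grid; low values are preferred.

    medial_surface: normalized distance to the skull surface, so ROI voxels
    close to the skull (the medial surface of deep ROIs abuts the inner skull
    near the midline) score low.

    roi_centreline: one minus the normalized distance to the ROI's exterior,
    so the deepest (thickest) part of the ROI scores low. Raw distance *to*
    the ROI is zero everywhere inside it and cannot rank interior points,
    hence the interior depth is used instead.
    """
    choice = SpatialPrior(choice)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise GeometryError("empty ROI")
    if choice is SpatialPrior.MEDIAL_SURFACE:
        if skull is None:
            raise GeometryError("medial_surface prior requires the skull mesh")
        return normalize_field(distance_field(skull, grid, name="skull_dist"))
    depth = distance_field(~roi_mask, grid, name="roi_depth")
    norm = normalize_field(depth)
    return ScalarField(1.0 - norm.values, grid.affine, "roi_centreline_prior")


def compute_target_risk_map(roi_mask: np.ndarray, roi_label: int,
                            critical_mask: np.ndarray,
                            f_cri: ScalarField, f_sp: ScalarField,
                            w_sp: float = 0.25, w_cri: float = 0.75) -> TargetRiskMap:
    """Assemble the piecewise target risk map on the shared grid."""
    if f_cri.shape != f_sp.shape or not np.allclose(f_cri.affine, f_sp.affine, atol=1e-6):
        raise GeometryError("f_cri and f_sp geometry mismatch")
    if w_sp < 0 or w_cri < 0:
        raise GeometryError("weights must be non-negative")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    critical_mask = np.asarray(critical_mask, dtype=bool)
    f = w_sp * f_sp.values + w_cri * (1.0 - f_cri.values)
    f = np.where(roi_mask & ~critical_mask, f, 1.0)
    return TargetRiskMap(ScalarField(f, f_cri.affine, f"target_risk_{roi_label}"),
                         roi_label, (w_sp, w_cri), roi_mask)


def find_local_minima(risk_map: TargetRiskMap) -> np.ndarray:
    """Voxel indices (n, 3) of the regional minima of f with f < 1.

    26-connected regional minima (morphological flooding); each connected
    plateau of equal f contributes its lexicographically smallest voxel.
    """
    f = risk_map.f.values
    minima = local_minima(f, connectivity=3)
    minima &= f < 1.0
    if not minima.any():
        return np.empty((0, 3), dtype=int)
    lab, n = ndimage.label(minima, structure=np.ones((3, 3, 3), dtype=bool))
    out = np.empty((n, 3), dtype=int)
    coords = np.argwhere(lab > 0)
    comp = lab[tuple(coords.T)]
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    seen: set[int] = set()
    k = 0
    for i in order:
        c = int(comp[i])
        if c not in seen:
            seen.add(c)
            out[k] = coords[i]
            k += 1
    return out[np.lexsort((out[:k, 2], out[:k, 1], out[:k, 0]))][:k] if k else out[:0]


def _farthest_point_init(pts: np.ndarray, k: int) -> np.ndarray:
    # deterministic: start at the point nearest the centroid, then repeatedly
    # take the point farthest from the chosen set (ties -> lowest index)
    d0 = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    chosen = [int(np.argmin(d0))]
    mind = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(pts - pts[nxt], axis=1))
    return pts[chosen]


def cluster_targets(minima_world: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Assign each local minimum to one of ``k`` clusters; returns labels (n,).

    Deterministic K-means with farthest-point initialisation. If there are
    fewer minima than clusters, points are assigned round-robin by index and a
    warning is emitted (a degraded but usable grouping).
    """
    pts = np.asarray(minima_world, dtype=float)
    n = len(pts)
    if k < 1:
        raise GeometryError("electrode count must be >= 1")
    if k == 1:
        return np.zeros(n, dtype=int)
    if n < k:
        warnings.warn(f"only {n} local minima for {k} electrodes; "
                      "assigning round-robin", stacklevel=2)
        return np.arange(n, dtype=int) % k
    km = KMeans(n_clusters=k, init=_farthest_point_init(pts, k), n_init=1,
                random_state=seed)
    return km.fit_predict(pts)


def select_candidates(electrode_id: str, cluster_world: np.ndarray,
                      cluster_f: np.ndarray, m: int = 10,
                      cluster_id: int = 0) -> CandidateTargetSet:
    """The up-to-M lowest-f points of one cluster, sorted ascending in f."""
    if len(cluster_world) == 0:
        raise GeometryError(f"electrode {electrode_id}: empty target cluster")
    order = np.argsort(cluster_f, kind="stable")[:m]
    return CandidateTargetSet(electrode_id, np.asarray(cluster_world)[order],
                              np.asarray(cluster_f)[order], cluster_id)


def candidate_targets_for_roi(electrode_ids: list[str], risk_map: TargetRiskMap,
                              m: int = 10, seed: int = 0) -> list[CandidateTargetSet]:
    """Full per-ROI selection: minima -> K clusters -> M candidates each.

    Clusters are matched to electrodes in order of ascending best (lowest) f
    within the cluster, so the first-listed electrode gets the best cluster.
    """
    k = len(electrode_ids)
    idx = find_local_minima(risk_map)
    if len(idx) == 0:
        raise GeometryError(
            f"ROI {risk_map.roi_label}: no local minima below 1 (ROI may be "
            "fully covered by critical structures)")
    world = risk_map.f.voxel_to_world(idx)
    fvals = risk_map.f.values[tuple(idx.T)]
    labels = cluster_targets(world, k, seed=seed)
    present = [c for c in range(k) if np.any(labels == c)]
    best_f = {c: fvals[labels == c].min() for c in present}
    ranked = sorted(present, key=lambda c: (best_f[c], c))
    out = []
    for eid, c in zip(electrode_ids, ranked):
        sel = labels == c
        out.append(select_candidates(eid, world[sel], fvals[sel], m, cluster_id=c))
    if len(ranked) < k:
        raise GeometryError(
            f"ROI {risk_map.roi_label}: only {len(ranked)} non-empty clusters "
            f"for {k} electrodes")
    return out
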