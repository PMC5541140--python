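"""Trajectory risk scoring.

Every (candidate target, skull-vertex entry) pair is screened against four
hard constraints — maximum length, maximum entry angle to the skull normal,
mandatory traversal of a superficial ROI when one is requested, and
non-intersection with critical structures (arteries, veins, sulci). If no
pair survives, the length and angle limits are relaxed in 10 mm / 10 degree
lockstep up to 110 mm and 45 degrees. Survivors receive

    R = mean over sampled points of clamp((d_risk - d(x)) / (d_risk - d_safe), 0, 1)
    G = sum over contacts of per-contact GM capture in {0, 1/3, 2/3, 1}
    S = 10 * R + G

where d(x) is the raw distance (mm) to the nearest blood vessel and contacts
sit every 10 mm from the target along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import GeometryError, LabelVolume, ScalarField, Segment, SurfaceMesh, sample_segment
from .targets import CandidateTargetSet


@dataclass(frozen=True)
class HardConstraintConfig:
    """Hard-constraint thresholds and their relaxation schedule.

    Defaults are the clinical consensus values: 80 mm maximum electrode
    length, 15 degrees maximum angle to the skull normal, 3 mm minimum safe
    vessel distance, 10 mm no-risk vessel distance.
    """

    d_len: float = 80.0        # mm
    d_ang: float = 15.0        # degrees
    d_safe: float = 3.0        # mm
    d_risk: float = 10.0       # mm
    relax_len_step: float = 10.0
    relax_len_cap: float = 110.0
    relax_ang_step: float = 10.0
    relax_ang_cap: float = 45.0

    def __post_init__(self) -> None:
        if not self.d_safe < self.d_risk:
            raise GeometryError("d_safe must be < d_risk")
        if self.relax_len_cap < self.d_len or self.relax_ang_cap < self.d_ang:
            raise GeometryError("relaxation caps must be >= defaults")

    @property
    def max_relax_level(self) -> int:
        lv_len = int(np.ceil((self.relax_len_cap - self.d_len) / self.relax_len_step))
        lv_ang = int(np.ceil((self.relax_ang_cap - self.d_ang) / self.relax_ang_step))
        return max(lv_len, lv_ang)


@dataclass(frozen=True)
class ElectrodeModel:
    """Contact geometry of the implanted depth electrode."""

    q_contacts: int = 10
    contact_spacing: float = 10.0  # mm
    contact_radius: float = 1.2    # mm, p_r


@dataclass
class TrajectoryCandidate:
    segment: Segment
    risk: float                 # R in [0, 1]
    gm_ratio: float             # G in [0, 1]
    entry_angle: float          # degrees to the skull normal
    relax_level: int = 0
    target_rank: int = 0
    entry_index: int = 0

    @property
    def score(self) -> float:
        """Weighted score S = 10 R + G; risk dominates GM capture."""
        return 10.0 * self.risk + self.gm_ratio


def enumerate_entry_points(skull: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """All skull-mesh vertices with their outward unit normals."""
    v = skull.vertices
    if len(v) == 0:
        raise GeometryError("empty skull mesh")
    return v, skull.vertex_normals


def entry_angle_deg(direction: np.ndarray, normal: np.ndarray) -> float:
    """Angle (degrees) between a trajectory direction and the skull normal."""
    c = abs(float(np.dot(direction, normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def relax_constraints(cfg: HardConstraintConfig, level: int) -> HardConstraintConfig:
    """Thresholds after ``level`` lockstep relaxations, saturating at the caps."""
    if level < 0:
        raise GeometryError("relaxation level must be >= 0")
    return replace(cfg,
                   d_len=min(cfg.d_len + cfg.relax_len_step * level, cfg.relax_len_cap),
                   d_ang=min(cfg.d_ang + cfg.relax_ang_step * level, cfg.relax_ang_cap))


def _points_in_mask(points: np.ndarray, volume: LabelVolume, mask: np.ndarray) -> np.ndarray:
    idx = volume._geom.containing_voxel(points)
    inside = np.all((idx >= 0) & (idx < np.array(volume.shape)), axis=1)
    hit = np.zeros(len(points), dtype=bool)
    if inside.any():
        hit[inside] = mask[tuple(idx[inside].T)]
    return hit


def check_hard_constraints(seg: Segment, entry_normal: np.ndarray,
                           cfg: HardConstraintConfig,
                           critical_mask: np.ndarray,
                           critical_volume: LabelVolume,
                           superficial_mask: np.ndarray | None = None,
                           step: float = 1.0) -> tuple[bool, str]:
    """Screen one trajectory; returns (passed, reason-of-first-violation).

    Checks, in order: length, entry angle, superficial-ROI traversal (when a
    superficial ROI is specified), and intersection with critical structures
    (arteries, veins or sulci) at ``step``-mm sample points.
    """
    if seg.length > cfg.d_len:
        return False, "length"
    if entry_angle_deg(seg.direction, entry_normal) > cfg.d_ang:
        return False, "angle"
    pts = sample_segment(seg, step)
    if superficial_mask is not None:
        if not _points_in_mask(pts, critical_volume, superficial_mask).any():
            return False, "superficial"
    if _points_in_mask(pts, critical_volume, critical_mask).any():
        return False, "critical"
    return True, ""


def risk_score(seg: Segment, raw_vessel_distance: ScalarField,
               cfg: HardConstraintConfig, step: float = 1.0,
               printed_form: bool = False) -> float:
    """Cumulative vessel-proximity risk R in [0, 1] along the trajectory.

    Each sample point contributes a linear ramp between the safe distance
    (risk 1 at d <= d_safe) and the no-risk distance (risk 0 at d >= d_risk);
    R is the mean contribution. ``printed_form=True`` evaluates the unclamped
    variant mean((d_risk - (d - d_safe)) / (d_risk - d_safe)) instead, which
    does not honour the R=1 / R=0 boundary values and exists only for
    comparison.
    """
    pts = sample_segment(seg, step)
    d = raw_vessel_distance.sample_world(pts)
    denom = cfg.d_risk - cfg.d_safe
    if printed_form:
        return float(np.mean((cfg.d_risk - (d - cfg.d_safe)) / denom))
    return float(np.mean(np.clip((cfg.d_risk - d) / denom, 0.0, 1.0)))


def gm_ratio(seg: Segment, f_gm: ScalarField,
             model: ElectrodeModel = ElectrodeModel()) -> float:
    """Fraction of electrode-contact sample points lying in grey matter.

    Contacts sit at 0, 10, ..., (Q-1)*10 mm from the target along the
    trajectory line; each is probed at its centre and both ends (centre
    +/- 1.2 mm along the trajectory). Contacts beyond the entry point are
    still evaluated at their nominal offsets and simply capture nothing
    outside the head. H(0) = 1: the GM surface counts as inside.
    """
    u = seg.direction
    offsets = np.arange(model.q_contacts) * model.contact_spacing
    probes = np.concatenate([offsets - model.contact_radius, offsets,
                             offsets + model.contact_radius])
    pts = seg.target[None, :] + probes[:, None] * u[None, :]
    inside = f_gm.sample_world(pts) >= 0.0
    return float(inside.sum()) / (3.0 * model.q_contacts)


def score_all(candidates: CandidateTargetSet,
              entries: np.ndarray, normals: np.ndarray,
              raw_vessel_distance: ScalarField,
              f_gm: ScalarField,
              critical_mask: np.ndarray,
              critical_volume: LabelVolume,
              cfg: HardConstraintConfig = HardConstraintConfig(),
              model: ElectrodeModel = ElectrodeModel(),
              superficial_mask: np.ndarray | None = None,
              step: float = 1.0,
              log: list | None = None) -> list[TrajectoryCandidate]:
    """Score the full target x entry product for one electrode.

    Returns survivors sorted ascending by S (ties: lower R, then target rank,
    then entry index). The relaxation schedule is applied only when a level
    leaves no survivor; the first level with survivors wins.
    """
    if len(candidates) == 0:
        raise GeometryError(f"electrode {candidates.electrode_id}: no candidate targets")
    targets = candidates.targets
    n_t, n_e = len(targets), len(entries)

    # vectorised length / angle screening, shared across relaxation levels
    diff = entries[None, :, :] - targets[:, None, :]           # (T, E, 3)
    lengths = np.linalg.norm(diff, axis=2)
    ok_len0 = lengths > 0
    dirs = np.where(ok_len0[..., None], diff / np.where(lengths[..., None] == 0, 1, lengths[..., None]), 0)
    cosang = np.abs(np.einsum("tej,ej->te", dirs, normals))
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    for level in range(cfg.max_relax_level + 1):
        rcfg = relax_constraints(cfg, level)
        geom_ok = ok_len0 & (lengths <= rcfg.d_len) & (angles <= rcfg.d_ang)
        survivors: list[TrajectoryCandidate] = []
        for t_rank, e_idx in np.argwhere(geom_ok):
            seg = Segment(targets[t_rank], entries[e_idx])
            pts = sample_segment(seg, step)
            if superficial_mask is not None and \
                    not _points_in_mask(pts, critical_volume, superficial_mask).any():
                continue
            if _points_in_mask(pts, critical_volume, critical_mask).any():
                continue
            r = risk_score(seg, raw_vessel_distance, rcfg, step)
            g = gm_ratio(seg, f_gm, model)
            survivors.append(TrajectoryCandidate(
                seg, r, g, angles[t_rank, e_idx], level, int(t_rank), int(e_idx)))
        if survivors:
            if log is not None and level > 0:
                log.append({"electrode": candidates.electrode_id, "relax_level": level,
                            "d_len": rcfg.d_len, "d_ang": rcfg.d_ang})
            survivors.sort(key=lambda c: (c.score, c.risk, c.target_rank, c.entry_index))
            return survivors
    raise GeometryError(
        f"electrode {candidates.electrode_id}: no feasible trajectory after "
        f"maximal relaxation (d_len={cfg.relax_len_cap} mm, d_ang={cfg.relax_ang_cap} deg)")
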