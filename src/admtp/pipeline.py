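"""End-to-end planning pipeline: target selection -> trajectory scoring ->
implantation plan, with per-stage timing mirroring the method's three steps.

The pipeline operates on in-memory objects (:func:`plan_inputs`); file-based
entry points (:func:`run_plan`) load NIfTI volumes, a skull mesh, and a YAML
strategy file, then delegate. Per-electrode failures (no feasible trajectory
after maximal relaxation, empty target clusters) do not abort the run: the
remaining electrodes are planned and the failures reported alongside.
"""

from __future__ import annotations

import csv
import json
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .geometry import (GeometryError, LabelVolume, ScalarField, SurfaceMesh,
                       distance_field, signed_gm_distance)
from .planning import ImplantationPlan, solve_plan
from .scoring import TrajectoryCandidate, enumerate_entry_points, score_all
from .targets import (CandidateTargetSet, SpatialPrior, candidate_targets_for_roi,
                      compute_critical_field, compute_spatial_prior,
                      compute_target_risk_map)


class UnknownLabelError(GeometryError):
    """A strategy file references a label absent from the parcellation."""


class MissingInputError(FileNotFoundError):
    """A configured input file does not exist."""


@dataclass
class Electrode:
    """One strategy-file entry."""

    id: str
    deep_roi_label: int
    superficial_roi_label: int | None = None
    prior: str = "roi_centreline"


@dataclass
class PlanningInputs:
    parcellation: LabelVolume
    arteries: np.ndarray
    veins: np.ndarray
    sulci: np.ndarray
    gm: np.ndarray
    skull: SurfaceMesh
    electrodes: list[Electrode]


@dataclass
class PipelineResult:
    plan: ImplantationPlan | None
    electrodes: list[Electrode]
    candidates: dict[str, CandidateTargetSet]
    scored: dict[str, list[TrajectoryCandidate]]
    failures: dict[str, str]
    timings: dict[str, float]
    relax_log: list = field(default_factory=list)
    risk_maps: dict[int, ScalarField] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.plan is not None and not self.failures


def load_inputs(cfg: RunConfig) -> PlanningInputs:
    import yaml
    paths = {"parcellation": cfg.parcellation, "arteries": cfg.arteries,
             "veins": cfg.veins, "sulci": cfg.sulci, "gm": cfg.gm,
             "skull": cfg.skull, "strategy": cfg.strategy}
    for nm, p in paths.items():
        if not p or not os.path.exists(p):
            raise MissingInputError(f"missing input '{nm}': {p!r}")
    parc = LabelVolume.from_nifti(cfg.parcellation, name="parcellation")
    parc.legend = {int(v): f"label_{int(v)}" for v in np.unique(parc.labels) if v != 0}
    masks = {nm: LabelVolume.from_nifti(paths[nm]).mask()
             for nm in ("arteries", "veins", "sulci", "gm")}
    skull = SurfaceMesh.load(cfg.skull, "skull")
    with open(cfg.strategy) as fh:
        raw = yaml.safe_load(fh)
    entries = raw["electrodes"] if isinstance(raw, dict) else raw
    electrodes = [Electrode(str(e["id"]), int(e["deep_roi_label"]),
                            e.get("superficial_roi_label"),
                            e.get("prior", "roi_centreline")) for e in entries]
    return PlanningInputs(parc, masks["arteries"], masks["veins"], masks["sulci"],
                          masks["gm"], skull, electrodes)


def plan_inputs(inputs: PlanningInputs, cfg: RunConfig | None = None,
                keep_risk_maps: bool = False) -> PipelineResult:
    """Run the three planning stages over in-memory inputs."""
    cfg = cfg or RunConfig()
    parc = inputs.parcellation
    grid = parc.geometry()
    known = set(np.unique(parc.labels)) - {0}
    for e in inputs.electrodes:
        if e.deep_roi_label not in known:
            raise UnknownLabelError(f"electrode {e.id}: unknown label {e.deep_roi_label}")
        if e.superficial_roi_label is not None and e.superficial_roi_label not in known:
            raise UnknownLabelError(
                f"electrode {e.id}: unknown superficial label {e.superficial_roi_label}")

    timings: dict[str, float] = {}
    failures: dict[str, str] = {}
    relax_log: list = []

    # ---- stage 1: candidate target selection -------------------------------
    t0 = time.perf_counter()
    vessels = inputs.arteries | inputs.veins
    raw_vessel_distance = distance_field(vessels, grid, name="vessel_raw")
    f_cri = ScalarField(raw_vessel_distance.values / raw_vessel_distance.values.max(),
                        grid.affine, "f_cri")
    candidates: dict[str, CandidateTargetSet] = {}
    risk_maps: dict[int, ScalarField] = {}
    groups: dict[tuple[int, str], list[Electrode]] = {}
    for e in inputs.electrodes:
        groups.setdefault((e.deep_roi_label, e.prior), []).append(e)
    for (label, prior), members in groups.items():
        roi_mask = parc.mask(label)
        try:
            f_sp = compute_spatial_prior(SpatialPrior(prior), roi_mask, grid,
                                         skull=inputs.skull)
            rmap = compute_target_risk_map(roi_mask, label, vessels, f_cri, f_sp,
                                           cfg.w_roi, cfg.w_cri)
            if keep_risk_maps:
                risk_maps[label] = rmap.f
            sets = candidate_targets_for_roi([e.id for e in members], rmap,
                                             m=cfg.m_targets, seed=cfg.seed)
            for s in sets:
                candidates[s.electrode_id] = s
        except GeometryError as err:
            for e in members:
                failures[e.id] = f"target selection: {err}"
    timings["target_selection_s"] = time.perf_counter() - t0

    # ---- stage 2: trajectory risk scoring ----------------------------------
    t0 = time.perf_counter()
    entries, normals = enumerate_entry_points(inputs.skull)
    f_gm = signed_gm_distance(LabelVolume(inputs.gm.astype(np.int16), grid.affine))
    critical_all = vessels | inputs.sulci
    crit_volume = LabelVolume(np.zeros(grid.shape, dtype=np.int16), grid.affine)
    scored: dict[str, list[TrajectoryCandidate]] = {}
    hc = cfg.hard_constraints()
    for e in inputs.electrodes:
        if e.id in failures:
            continue
        sup = parc.mask(e.superficial_roi_label) \
            if e.superficial_roi_label is not None else None
        try:
            scored[e.id] = score_all(candidates[e.id], entries, normals,
                                     raw_vessel_distance, f_gm, critical_all,
                                     crit_volume, hc, cfg.electrode_model(),
                                     superficial_mask=sup, step=cfg.sampling_step,
                                     log=relax_log)
        except GeometryError as err:
            failures[e.id] = f"scoring: {err}"
    timings["trajectory_scoring_s"] = time.perf_counter() - t0

    # ---- stage 3: implantation plan ----------------------------------------
    t0 = time.perf_counter()
    planned = [e for e in inputs.electrodes if e.id in scored]
    plan = None
    if planned:
        plan = solve_plan([scored[e.id] for e in planned], cfg.search(),
                          electrode_ids=[e.id for e in planned])
    timings["plan_computation_s"] = time.perf_counter() - t0
    timings["total_s"] = sum(timings.values())

    return PipelineResult(plan, planned, candidates, scored, failures, timings,
                          relax_log, risk_maps)


def _plan_json(result: PipelineResult, cfg: RunConfig) -> dict:
    plan = result.plan
    # timings deliberately excluded: plan.json is byte-reproducible for a
    # fixed seed and inputs; wall-clock numbers live in timings.json
    out: dict = {"seed": cfg.seed, "feasible": None, "electrodes": [],
                 "failures": result.failures,
                 "relaxations": result.relax_log}
    if plan is None:
        return out
    out["feasible"] = plan.feasible
    out["nodes_expanded"] = plan.nodes_expanded
    out["diversity_pruned"] = plan.pruned_duplicates
    out["s_total"] = round(plan.s_total, 6)
    out["min_pairwise_distance_mm"] = (round(plan.min_pairwise_distance, 3)
                                       if np.isfinite(plan.min_pairwise_distance) else None)
    for e, tc in zip(result.electrodes, plan.trajectories):
        out["electrodes"].append({
            "id": e.id, "deep_roi_label": e.deep_roi_label, "prior": e.prior,
            "target_mm": [round(float(v), 3) for v in tc.segment.target],
            "entry_mm": [round(float(v), 3) for v in tc.segment.entry],
            "length_mm": round(tc.segment.length, 3),
            "angle_deg": round(tc.entry_angle, 3),
            "R": round(tc.risk, 6), "G": round(tc.gm_ratio, 6),
            "S": round(tc.score, 6), "relax_level": tc.relax_level,
        })
    if plan.pairwise_distances is not None:
        out["pairwise_distance_mm"] = [
            [round(float(v), 3) for v in row] for row in plan.pairwise_distances]
    return out


def write_outputs(result: PipelineResult, cfg: RunConfig) -> str:
    """Write plan JSON/CSV, per-electrode candidate CSVs, timing report and
    (optionally) QC risk maps into ``cfg.outdir``; returns the plan path."""
    os.makedirs(cfg.outdir, exist_ok=True)
    plan_path = os.path.join(cfg.outdir, "plan.json")
    with open(plan_path, "w") as fh:
        json.dump(_plan_json(result, cfg), fh, indent=2, sort_keys=True)
    with open(os.path.join(cfg.outdir, "plan.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["electrode_id", "target_x", "target_y", "target_z",
                    "entry_x", "entry_y", "entry_z", "length_mm", "angle_deg",
                    "R", "G", "S", "relax_level"])
        if result.plan:
            for e, tc in zip(result.electrodes, result.plan.trajectories):
                w.writerow([e.id, *[f"{v:.3f}" for v in tc.segment.target],
                            *[f"{v:.3f}" for v in tc.segment.entry],
                            f"{tc.segment.length:.3f}", f"{tc.entry_angle:.3f}",
                            f"{tc.risk:.6f}", f"{tc.gm_ratio:.6f}",
                            f"{tc.score:.6f}", tc.relax_level])
    for eid, cands in result.scored.items():
        with open(os.path.join(cfg.outdir, f"candidates_{eid}.csv"), "w",
                  newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["electrode_id", "target_x", "target_y", "target_z",
                        "entry_x", "entry_y", "entry_z", "length_mm",
                        "angle_deg", "R", "G", "S", "relax_level"])
            for tc in cands:
                w.writerow([eid, *[f"{v:.3f}" for v in tc.segment.target],
                            *[f"{v:.3f}" for v in tc.segment.entry],
                            f"{tc.segment.length:.3f}", f"{tc.entry_angle:.3f}",
                            f"{tc.risk:.6f}", f"{tc.gm_ratio:.6f}",
                            f"{tc.score:.6f}", tc.relax_level])
    with open(os.path.join(cfg.outdir, "timings.json"), "w") as fh:
        json.dump(result.timings, fh, indent=2)
    for label, fmap in result.risk_maps.items():
        fmap.to_nifti(os.path.join(cfg.outdir, f"target_risk_map_{label}.nii.gz"))
    cfg.to_yaml(os.path.join(cfg.outdir, "resolved_config.yaml"))
    return plan_path


def run_plan(cfg: RunConfig) -> PipelineResult:
    """File-based end-to-end run: load inputs, plan, write outputs."""
    inputs = load_inputs(cfg)
    result = plan_inputs(inputs, cfg, keep_risk_maps=cfg.write_qc_maps)
    write_outputs(result, cfg)
    if result.failures:
        warnings.warn(f"{len(result.failures)} electrode(s) failed: "
                      f"{sorted(result.failures)}", stacklevel=2)
    return result
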