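"""Implantation plan computation.

Chooses one trajectory per electrode minimising the mean weighted score S
subject to every pair of chosen trajectories being separated by more than
d_traj millimetres. The solver is a depth-first search over electrodes in
input order, trying each electrode's candidates in ascending S; after a
conflict, near-duplicates of the conflicting trajectory (within a 0.5 mm
diversity threshold) are skipped at that node. When no combination is
feasible, a fallback returns the plan with the largest achievable minimum
pairwise separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, segment_segment_distance
from .scoring import TrajectoryCandidate


@dataclass(frozen=True)
class SearchConfig:
    d_traj: float = 10.0            # mm, minimum inter-electrode separation
    diversity_epsilon: float = 0.5  # mm, near-duplicate skip threshold
    max_nodes: int = 1_000_000      # node-expansion budget before fallback

    def __post_init__(self) -> None:
        if self.d_traj <= 0 or self.diversity_epsilon < 0:
            raise GeometryError("d_traj must be > 0 and diversity_epsilon >= 0")


@dataclass
class ImplantationPlan:
    trajectories: list[TrajectoryCandidate]
    s_total: float                    # mean S over members
    min_pairwise_distance: float      # mm
    feasible: bool
    nodes_expanded: int = 0
    pruned_duplicates: int = 0
    pairwise_distances: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _pairwise_matrix(trajs: list[TrajectoryCandidate]) -> np.ndarray:
    n = len(trajs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = segment_segment_distance(trajs[i].segment, trajs[j].segment)
    return d


def _min_pairwise(trajs: list[TrajectoryCandidate]) -> float:
    n = len(trajs)
    if n < 2:
        return float("inf")
    d = _pairwise_matrix(trajs)
    return float(d[np.triu_indices(n, 1)].min())


def next_diverse_candidate(candidates: list[TrajectoryCandidate],
                           conflicting: TrajectoryCandidate,
                           from_rank: int, eps: float) -> int | None:
    """Rank of the first candidate after ``from_rank`` that is more than
    ``eps`` mm from the conflicting trajectory, or None when exhausted."""
    for r in range(from_rank + 1, len(candidates)):
        if segment_segment_distance(candidates[r].segment, conflicting.segment) > eps:
            return r
    return None


def solve_plan(per_electrode: list[list[TrajectoryCandidate]],
               cfg: SearchConfig = SearchConfig(),
               electrode_ids: list[str] | None = None) -> ImplantationPlan:
    """Depth-first search for the minimum-mean-S feasible combination.

    Electrodes are processed in input order; within an electrode candidates
    are tried in ascending S. Branch-and-bound on the partial score sum plus
    the best-possible remaining scores keeps the search exact; with
    diversity_epsilon = 0 only exact spatial duplicates of a conflicting
    trajectory are skipped, so the result equals exhaustive enumeration.
    Falls back to the max-separation plan when no feasible combination exists
    (or the node budget is exhausted).
    """
    ids = electrode_ids or [f"e{i}" for i in range(len(per_electrode))]
    for i, cands in enumerate(per_electrode):
        if not cands:
            raise GeometryError(f"electrode {ids[i]}: empty candidate list")
    n = len(per_electrode)
    best_rest = [sum(min(c.score for c in cands) for cands in per_electrode[k + 1:])
                 for k in range(n)]

    best_sum = float("inf")
    best_combo: list[TrajectoryCandidate] | None = None
    nodes = 0
    pruned = 0
    budget_hit = False

    def dfs(depth: int, chosen: list[TrajectoryCandidate], part_sum: float) -> None:
        nonlocal best_sum, best_combo, nodes, pruned, budget_hit
        if budget_hit:
            return
        if depth == n:
            if part_sum < best_sum:
                best_sum = part_sum
                best_combo = chosen.copy()
            return
        cands = per_electrode[depth]
        rank = 0
        while rank is not None and rank < len(cands):
            nodes += 1
            if nodes > cfg.max_nodes:
                budget_hit = True
                return
            cand = cands[rank]
            if part_sum + cand.score + best_rest[depth] >= best_sum:
                return  # candidates are S-sorted: no later rank can improve
            conflict = None
            for prev in chosen:
                if segment_segment_distance(cand.segment, prev.segment) <= cfg.d_traj:
                    conflict = cand
                    break
            if conflict is None:
                chosen.append(cand)
                dfs(depth + 1, chosen, part_sum + cand.score)
                chosen.pop()
                rank += 1
            else:
                nxt = next_diverse_candidate(cands, conflict, rank, cfg.diversity_epsilon)
                if nxt is not None:
                    pruned += nxt - rank - 1
                rank = nxt

    dfs(0, [], 0.0)

    if best_combo is None:
        if budget_hit:
            warnings.warn("plan search node budget exhausted; using max-separation "
                          "fallback", stacklevel=2)
        plan = fallback_max_separation(per_electrode, cfg)
        plan.nodes_expanded = nodes
        plan.pruned_duplicates = pruned
        return plan

    d = _pairwise_matrix(best_combo)
    mind = float(d[np.triu_indices(n, 1)].min()) if n > 1 else float("inf")
    return ImplantationPlan(best_combo, best_sum / n, mind, True,
                            nodes_expanded=nodes, pruned_duplicates=pruned,
                            pairwise_distances=d)


def fallback_max_separation(per_electrode: list[list[TrajectoryCandidate]],
                            cfg: SearchConfig = SearchConfig(),
                            pool_size: int = 50) -> ImplantationPlan:
    """Best-effort plan maximising the minimum pairwise separation.

    Greedy construction over each electrode's ``pool_size`` lowest-S
    candidates, refined by single-electrode swaps until no swap improves the
    minimum separation (ties broken toward lower mean S). Marked infeasible.
    """
    pools = [cands[:pool_size] for cands in per_electrode]
    chosen = [pool[0] for pool in pools]

    def objective(combo: list[TrajectoryCandidate]) -> tuple[float, float]:
        return (_min_pairwise(combo), -sum(c.score for c in combo))

    improved = True
    while improved:
        improved = False
        for i, pool in enumerate(pools):
            cur = objective(chosen)
            best_alt = None
            for cand in pool:
                if cand is chosen[i]:
                    continue
                trial = chosen.copy()
                trial[i] = cand
                val = objective(trial)
                if val > cur:
                    cur = val
                    best_alt = cand
            if best_alt is not None:
                chosen[i] = best_alt
                improved = True

    d = _pairwise_matrix(chosen)
    n = len(chosen)
    mind = float(d[np.triu_indices(n, 1)].min()) if n > 1 else float("inf")
    return ImplantationPlan(chosen, sum(c.score for c in chosen) / n, mind, False,
                            pairwise_distances=d)
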