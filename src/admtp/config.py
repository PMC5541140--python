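"""Run configuration: all planning thresholds in one place.

Defaults are the published clinical-consensus values: M = 10 candidate
targets, spatial-prior weight w_roi = 0.25 and vessel-avoidance weight
w_cri = 0.75, maximum length 80 mm, maximum entry angle 15 degrees, safe
vessel distance 3 mm, no-risk distance 10 mm, inter-electrode separation
10 mm.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .planning import SearchConfig
from .scoring import ElectrodeModel, HardConstraintConfig


@dataclass
class RunConfig:
    # target selection
    m_targets: int = 10
    w_roi: float = 0.25      # spatial-prior weight (w_sp in the risk-map formula)
    w_cri: float = 0.75
    # hard constraints / risk
    d_len: float = 80.0
    d_ang: float = 15.0
    d_safe: float = 3.0
    d_risk: float = 10.0
    # plan search
    d_traj: float = 10.0
    diversity_epsilon: float = 0.5
    max_nodes: int = 1_000_000
    # numerics
    sampling_step: float = 1.0   # mm, along-trajectory sample spacing
    seed: int = 0
    # inputs / outputs (paths; unused when planning in-memory objects)
    parcellation: str = ""
    arteries: str = ""
    veins: str = ""
    sulci: str = ""
    gm: str = ""
    skull: str = ""
    strategy: str = ""
    outdir: str = "admtp_out"
    write_qc_maps: bool = False
    extra: dict = field(default_factory=dict)

    def hard_constraints(self) -> HardConstraintConfig:
        return HardConstraintConfig(d_len=self.d_len, d_ang=self.d_ang,
                                    d_safe=self.d_safe, d_risk=self.d_risk)

    def search(self) -> SearchConfig:
        return SearchConfig(d_traj=self.d_traj,
                            diversity_epsilon=self.diversity_epsilon,
                            max_nodes=self.max_nodes)

    def electrode_model(self) -> ElectrodeModel:
        return ElectrodeModel()

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = {k: v for k, v in data.items() if k not in known}
        kwargs = {k: v for k, v in data.items() if k in known}
        cfg = cls(**kwargs)
        cfg.extra.update(extra)
        return cfg
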