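"""Declarative pipeline configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import SimConfig


@dataclass
class PipelineConfig:
    """All thresholds, input paths and the random seed for one pipeline run.

    With ``simulate = True`` the inputs are generated in memory from
    ``sim`` (and written alongside the results); otherwise every path in
    ``inputs`` must point at an existing file.
    """

    seed: int = 0
    outdir: str = "results"
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    inputs: dict = field(default_factory=dict)   # name -> path, for simulate=False

    # DMC calling
    fdr_q: float = 0.05
    ms_cutoff: float = 0.0025
    multi_frac: float = 0.9
    min_donors: int = 3
    # consensus calls
    state_min_votes: int = 3
    dnase_min_votes_mono: int = 13
    dnase_min_votes_mac: int = 2
    # WGBS / DMR
    wgbs_min_diff: float = 0.05
    dmr_max_gap: int = 1000
    wgbs_min_donors: int = 3
    # motifs
    motif_window: int = 25
    motif_threshold_frac: float = 0.8
    background_n: int = 50000
    # thresholds stage
    rerun_min_size: int = 20
    stages: tuple[str, ...] = (
        "ewas", "annotate", "enrich", "dmr", "motif", "thresholds")

    def validate(self) -> None:
        for name, v in [("fdr_q", self.fdr_q), ("multi_frac", self.multi_frac),
                        ("wgbs_min_diff", self.wgbs_min_diff),
                        ("motif_threshold_frac", self.motif_threshold_frac)]:
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.ms_cutoff < 0:
            raise ValueError("ms_cutoff must be >= 0")
        for name, v in [("dmr_max_gap", self.dmr_max_gap),
                        ("motif_window", self.motif_window),
                        ("background_n", self.background_n)]:
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        self.sim.validate()
        if not self.simulate:
            needed = {"beta", "samples", "cpg_map"}
            if "dmr" in self.stages:
                needed |= {"wgbs_monocyte", "wgbs_macrophage"}
            missing = needed - set(self.inputs)
            if missing:
                raise ValueError(f"missing input paths for: {sorted(missing)}")
            for k, p in self.inputs.items():
                if not Path(p).exists():
                    raise ValueError(f"input {k!r} not found at {p}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["sim"]["cell_states"] = list(self.sim.cell_states)
        for key in ("gain_effect_range", "loss_effect_range"):
            d["sim"][key] = list(d["sim"][key])
        d["sim"]["activation_counts"] = {
            k: list(v) for k, v in d["sim"]["activation_counts"].items()}
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        sim = dict(sim)
        if "cell_states" in sim:
            sim["cell_states"] = tuple(sim["cell_states"])
        for key in ("gain_effect_range", "loss_effect_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if "activation_counts" in sim:
            sim["activation_counts"] = {
                k: tuple(v) for k, v in sim["activation_counts"].items()}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(sim=SimConfig(**sim), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
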