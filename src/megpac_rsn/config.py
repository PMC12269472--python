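"""Pipeline configuration: every analysis constant is a named, defaulted key.

Defaults are the method's canonical constants: 10 Hz megPAC rate, 7 mm
smoothing FWHM, ten SVD modes, 40 % relative binarization threshold, phase
grid 2-30 Hz, amplitude grid 80-150 Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pac import FrequencyGrid
from .simulate import EffectRegion, NetworkSpec, SimulationConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)
    fwhm_mm: float = 7.0
    n_modes: int = 10
    rel_threshold: float = 0.4
    megpac_rate: float = 10.0        # Hz
    subset_k: int | None = None      # None -> min(n_vertices, 1000)
    jackknife_correction: bool = True
    signed_extrema: bool = True
    fdr_q: float = 0.05
    alpha: float = 0.05
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def resolve_subset_k(self, n_vertices: int) -> int:
        if self.subset_k is None:
            return min(n_vertices, 1000)
        return int(self.subset_k)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"]["phase_freqs"] = list(d["grid"]["phase_freqs"])
        d["grid"]["amp_freqs"] = list(d["grid"]["amp_freqs"])
        sim = d["simulation"]
        for key in ("networks", "effect_regions"):
            if sim[key] is not None:
                sim[key] = [
                    {**item, "vertices": list(item["vertices"])}
                    for item in [dict(zip(x.keys(), x.values()))
                                 if isinstance(x, dict) else x
                                 for x in sim[key]]
                ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "grid" in d and not isinstance(d["grid"], FrequencyGrid):
            g = dict(d["grid"])
            g["phase_freqs"] = tuple(g.get("phase_freqs", ()))
            g["amp_freqs"] = tuple(g.get("amp_freqs", ()))
            d["grid"] = FrequencyGrid(**g)
        if "simulation" in d and not isinstance(d["simulation"], SimulationConfig):
            s = dict(d["simulation"])
            if s.get("networks") is not None:
                s["networks"] = tuple(
                    NetworkSpec(
                        name=n["name"], vertices=tuple(n["vertices"]),
                        phase_freq=n["phase_freq"], amp_freq=n["amp_freq"],
                    ) for n in s["networks"]
                )
            if s.get("effect_regions") is not None:
                s["effect_regions"] = tuple(
                    EffectRegion(
                        name=r["name"], vertices=tuple(r["vertices"]),
                        multipliers=dict(r["multipliers"]),
                    ) for r in s["effect_regions"]
                )
            d["simulation"] = SimulationConfig(**s)
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(d)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
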