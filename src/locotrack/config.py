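"""Pipeline configuration with YAML round-trip.

One flat config object collects every stage's parameters.  Defaults marked
``assay`` are the conventional assay constants (1 Hz frames, 2 min assays,
5-sample smoothing window, 30 s minimum track); the rest are artifact
defaults exposed for override.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import PRESETS, GenotypeParams, SimConfig

__all__ = ["PipelineConfig"]

#: which fields carry assay-convention defaults (provenance flag)
ASSAY_DEFAULTS = {"dt", "duration_s", "window", "min_track_s", "hist_bin_width"}


@dataclass
class PipelineConfig:
    # simulation
    n_animals: int = 40
    duration_s: float = 120.0
    dt: float = 1.0  # s per frame (1 Hz)
    # same animal density as the 20-animal SimConfig default
    arena_size: tuple[float, float] = (17.0, 17.0)
    dropout_prob: float = 0.135
    min_separation: float | None = None
    genotypes: list[str] = field(default_factory=lambda: ["wild_type", "cat2_like"])
    seed: int = 0
    # rendering / detection
    render: bool = False
    mm_per_px: float = 0.01
    blob_sigma_px: float = 3.0
    intensity: float = 255.0
    threshold: float = 25.0
    min_area: int = 5
    # tracking
    max_disp: float = 0.5  # mm per frame
    max_gap: int = 2  # frames
    # kinematics
    window: int = 5  # samples (5 s at 1 Hz)
    min_track_s: float = 30.0
    # statistics
    hist_bin_width: float = 0.006  # mm/s
    curve_bin_width: float = 0.03  # mm/s
    field_name: str = "speed_sd"

    def genotype_params(self) -> list[GenotypeParams]:
        out = []
        for g in self.genotypes:
            if g not in PRESETS:
                raise KeyError(
                    f"unknown genotype preset {g!r}; known: {sorted(PRESETS)}"
                )
            out.append(PRESETS[g])
        return out

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_animals=self.n_animals,
            duration_s=self.duration_s,
            dt=self.dt,
            arena_size=tuple(self.arena_size),
            dropout_prob=self.dropout_prob,
            mm_per_px=self.mm_per_px,
            min_separation=self.min_separation,
            seed=self.seed,
        )

    def provenance(self) -> dict[str, str]:
        """Per-field flag: assay-convention default vs artifact default."""
        return {
            f.name: ("assay" if f.name in ASSAY_DEFAULTS else "artifact")
            for f in dataclasses.fields(self)
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["arena_size"] = list(d["arena_size"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "arena_size" in d:
            d["arena_size"] = tuple(d["arena_size"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
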