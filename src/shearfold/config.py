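"""Experiment configuration: YAML round-trip of every pipeline block."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .labels import LabelConfig
from .model import ForestConfig
from .simulation import SimParams

__all__ = ["DatasetConfig", "ExperimentConfig"]


@dataclass(frozen=True)
class DatasetConfig:
    """Observation pool, balancing and split settings."""

    n_total: int = 20_000
    stride: int | str = "auto"
    train_frac: float = 0.7
    seed: int = 0
    burn_frames: int = 12  # sheared-steady-state transient discarded per replica


@dataclass
class ExperimentConfig:
    """All knobs of a full simulate-to-importance run.

    A single root seed drives deterministic per-stage sub-seeds; the
    requested resolutions must be a subset of {1, 5, 10}.
    """

    sim: SimParams = field(default_factory=SimParams)
    label: LabelConfig = field(default_factory=LabelConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    resolutions: tuple[int, ...] = (1, 5, 10)
    #: optional per-resolution subset of response targets to fit
    #: (e.g. {10: ("y_s5", "y_s6")}); None fits every segment.
    targets: dict[int, tuple[str, ...]] | None = None
    out_dir: str = "shearfold_run"

    def __post_init__(self) -> None:
        if not set(self.resolutions) <= {1, 5, 10}:
            raise ValueError("resolutions must be a subset of {1, 5, 10}")

    def with_seed(self, seed: int) -> "ExperimentConfig":
        """Re-seed every stage from one root seed."""
        return dataclasses.replace(
            self,
            sim=self.sim.replaced(seed=seed),
            dataset=dataclasses.replace(self.dataset, seed=seed + 1),
            forest=dataclasses.replace(self.forest, seed=seed + 2),
        )

    def to_dict(self) -> dict:
        return {
            "sim": dataclasses.asdict(self.sim),
            "label": dataclasses.asdict(self.label),
            "dataset": dataclasses.asdict(self.dataset),
            "forest": dataclasses.asdict(self.forest),
            "resolutions": list(self.resolutions),
            "targets": (
                None if self.targets is None
                else {str(k): list(v) for k, v in self.targets.items()}
            ),
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(
            sim=SimParams(**d.get("sim", {})),
            label=LabelConfig(**d.get("label", {})),
            dataset=DatasetConfig(**d.get("dataset", {})),
            forest=ForestConfig(**d.get("forest", {})),
            resolutions=tuple(d.get("resolutions", (1, 5, 10))),
            targets=(
                None if d.get("targets") is None
                else {int(k): tuple(v) for k, v in d["targets"].items()}
            ),
            out_dir=d.get("out_dir", "shearfold_run"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
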