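"""Run configuration for the pipeline CLI.

Defaults pin the analysis constants: data CV 0.25, Notch fold cap 3.5,
half-life plausibility window (1, 48) hours, 101-point bifurcation
sweeps.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    input_path: Optional[str] = None
    output_dir: str = "tcommit_out"
    seed: int = 0
    cv: float = 0.25
    fold_cap: float = 3.5
    hl_window: Tuple[float, float] = (1.0, 48.0)
    tgb_maxiter: int = 120
    pu1_maxiter: int = 80
    pu1_starts: int = 10
    sweep_points: int = 101

    def __post_init__(self) -> None:
        self.hl_window = tuple(self.hl_window)
        if not (0 < self.cv < 1):
            raise ValueError("cv must be in (0, 1)")
        if self.fold_cap < 1:
            raise ValueError("fold_cap must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def echo(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)
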