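"""Run configuration: plain-text (YAML) serializable, CLI flags override."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Every tunable of the pipeline in one serializable record.

    CLI flags take precedence over file values (see ``merged``).
    """

    # patch selection
    alpha: float = 1.0
    beta: float = 2.0
    box_radius: int = 3
    n_select: int = 100
    # pipeline
    method: str = "magnitude"          # none | magnitude | complex
    model: str = "dki"                 # dti | dki
    shrink: bool = True
    scale: str = "M"                   # shrinker scaling convention
    phase_kernel: int = 15
    phase_stride: int = 1
    # fitting / statistics
    wlls_iterations: int = 2
    quadrature_nodes: int = 10000
    cv_mean_epsilon: float = 1e-12
    # reproducibility
    seed: int = 0
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def merged(self, **overrides) -> "RunConfig":
        """New config with non-None overrides (CLI flags) applied."""
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)
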