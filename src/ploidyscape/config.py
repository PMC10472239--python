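"""Run configuration: YAML round-trip for every tunable in the pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Top-level configuration binding the pipeline stages.

    ``stages`` lists stage names to execute in order; ``params`` holds one
    sub-dict per stage with that stage's tunables (defaults applied by the
    stage itself when a key is absent). The global seed feeds every stage
    through per-stage derived seeds; no stage reads ambient entropy.
    """
    stages: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in ("stages", "params", "seed", "out_dir",
                                     "log_level") if k in raw}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = 2166136261
        for ch in stage.encode():
            h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
        return (self.seed * 1000003 + h) % (2**31 - 1)
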