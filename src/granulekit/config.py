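"""Run configuration: one serializable object driving the whole pipeline.

Defaults mirror the per-module defaults (qc_tolerance 0.02, Otsu
thresholding, 5 px/frame tracking displacement, ...) so an empty config
runs the standard analysis. Configs round-trip losslessly through YAML or
JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=lambda: ["simulate", "frap"])
    seed: int = 0
    out_dir: str = "results"
    frame_interval: float = 1.0   # s
    pixel_size: float = 0.1       # µm / pixel

    # FRAP stage
    qc_tolerance: float = 0.02
    include_offset: bool = False
    traces_path: str | None = None   # input CSV when not simulating
    stack_path: str | None = None    # TIFF input (frap-from-stack or morphometry)
    rois_path: str | None = None     # ROI CSV for frap-from-stack
    bleach_frame: int | None = None

    # simulate stage: group name -> FrapSimConfig field overrides
    groups: dict[str, dict] = field(default_factory=lambda: {"groupA": {}})

    # morphometry stage
    threshold_method: str = "otsu"
    manual_threshold: float | None = None
    min_area: float = 0.0
    circ_min: float = 0.0
    circ_max: float = 1.0
    max_displacement: float = 5.0  # px/frame, fusion tracking

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"RunConfig: unknown fields {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        """Short stable hash of the analysis parameters (output path excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha1(canonical.encode()).hexdigest()[:12]
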