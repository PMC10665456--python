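"""Run configuration: one serializable source of truth for reproducible runs.

A pipeline run is described by a single JSON document; command-line flags
override individual fields. Unknown keys are rejected on load so typos
fail loudly instead of silently falling back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .errors import FormatError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Paths and parameters tying the calibration/conversion stages together."""

    checker_csv: str | None = None
    illuminant_csv: str | None = None
    cmfs_csv: str | None = None
    n_components: int = 12
    regressor_degree: int = 3
    score_features: str = "polynomial"
    adaptation: str = "bradford"
    band_wavelengths: list = field(default_factory=lambda: [415.0, 540.0])
    hnbi_mapping: dict = field(default_factory=lambda: {"R": 540.0, "G": 415.0, "B": 415.0})
    target_size: int = 380
    seed: int = 0
    output_dir: str = "."

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def load_config(path) -> PipelineConfig:
    """Load and validate a JSON pipeline configuration (unknown keys rejected)."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from None
    if not isinstance(payload, dict):
        raise FormatError(f"{path}: configuration must be a JSON object")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(payload) - known
    if unknown:
        raise FormatError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return PipelineConfig(**payload)
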