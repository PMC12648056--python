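"""Run configuration: YAML/JSON loading with validation and defaults."""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Validated analysis-run configuration.

    Paths are optional (a run may be driven programmatically); any path
    that is set must exist at load time. Defaults follow the clinical
    protocol: a 3 mm BEV line pitch over -120..120 mm, a 3x3 smoothing
    window on the measured image, PTV-based normalization, 1 mm
    clip-region refinement pitch and a 10% peak-validity threshold.
    """

    predicted_path: str | None = None
    measured_path: str | None = None
    ct_path: str | None = None
    body_mask_path: str | None = None
    ptv_mask_path: str | None = None
    boost_mask_path: str | None = None
    clip_mask_path: str | None = None
    artifact_mask_path: str | None = None

    beam_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bev_extent_mm: tuple[float, float] = (-120.0, 120.0)
    bev_pitch_mm: float = 3.0

    smoothing_window: int = 3
    smoothing_mode: str = "slicewise2d"
    norm_target: str = "ptv"  # "ptv" | "boost"
    fine_pitch_mm: float = 1.0
    min_peak_frac: float = 0.1
    control_shift_mm: float = 10.0
    t_variant: str = "pooled"
    seed: int = 0
    out_dir: str = "protonpet_out"

    def __post_init__(self) -> None:
        if self.smoothing_window not in (3, 5):
            raise ValueError("smoothing_window must be 3 or 5")
        if self.smoothing_mode not in ("slicewise2d", "full3d"):
            raise ValueError("smoothing_mode must be 'slicewise2d' or 'full3d'")
        if self.norm_target not in ("ptv", "boost"):
            raise ValueError("norm_target must be 'ptv' or 'boost'")
        if self.bev_pitch_mm <= 0 or self.fine_pitch_mm <= 0:
            raise ValueError("pitches must be positive")
        if not (0 <= self.min_peak_frac < 1):
            raise ValueError("min_peak_frac must be in [0, 1)")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError("t_variant must be 'pooled' or 'welch'")
        if self.bev_extent_mm[1] <= self.bev_extent_mm[0]:
            raise ValueError("bev_extent_mm max must exceed min")
        for f in fields(self):
            if f.name.endswith("_path"):
                p = getattr(self, f.name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{f.name}: file not found: {p}")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Unknown keys are rejected, defaults are filled in, and the result
    can be echoed verbatim into the run's JSON summary.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    text = p.read_text()
    data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("beam_direction", "isocenter_mm", "bev_extent_mm"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)
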