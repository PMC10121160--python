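"""Analysis configuration with per-task defaults.

Defaults follow the published analysis settings for each task mode:

* track (wired, rectangular maze): 2-cm arclength bins, sigma = 5 cm
  smoothing, speed threshold 20 cm/s, 500 shuffles (trialwise and
  session-wide frame shifts), significance 0.95, no occupancy mask;
* open_field (wire-free, 80-cm circle): 2 cm x 2 cm bins, sigma = 3 cm,
  speed threshold 5 cm/s, 100-ms minimum occupancy, position time-shift
  shuffle with a 10-s margin, 500 shuffles, significance 0.95.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    mode: str  # "open_field" | "track"
    bin_size_cm: float = 2.0
    sigma_cm: float = 3.0
    speed_threshold_cm_s: float = 5.0
    min_occupancy_s: float | None = 0.1
    n_shuffles: int = 500
    shuffle_margin_s: float = 10.0
    significance: float = 0.95
    field_connectivity: int = 4
    field_min_seed_bins: int = 5
    field_peak_fraction: float = 0.05
    registration_gate_um: float = 24.0
    registration_max_distance_um: float = 6.0
    registration_min_correlation: float = 0.8
    speed_smoothing_window_s: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("open_field", "track"):
            raise ValueError("mode must be 'open_field' or 'track'")
        if self.n_shuffles < 1 or not (0 < self.significance <= 1):
            raise ValueError("invalid shuffle/significance settings")

    @classmethod
    def open_field(cls, **overrides) -> "AnalysisConfig":
        return cls(mode="open_field", **overrides)

    @classmethod
    def track(cls, **overrides) -> "AnalysisConfig":
        defaults = dict(sigma_cm=5.0, speed_threshold_cm_s=20.0, min_occupancy_s=None)
        defaults.update(overrides)
        return cls(mode="track", **defaults)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
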