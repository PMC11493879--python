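"""Pipeline configuration.

A single flat dataclass holds every tunable of the pipeline (filtering,
beat detection, notch search, xBRS, summary statistics, model training).
Defaults reproduce the published analysis choices where those are stated;
the remainder are documented package defaults.

Configs round-trip through a flat YAML key-value file and accept
``key=value`` overrides from the command line.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All pipeline tunables with reproducible defaults."""

    # --- waveform admission ---
    sample_rate: float = 200.0          # Hz
    min_duration_s: float = 180.0       # shortest admissible recording (3 min)
    max_duration_s: float = 600.0       # analysis window cap (10 min)
    truncate_from: str = "start"        # keep the first max_duration_s seconds

    # --- Savitzky-Golay smoothing ---
    sg_window: int = 15                 # samples (75 ms at 200 Hz)
    sg_order: int = 3

    # --- beat detection ---
    upstroke_threshold_frac: float = 0.4   # fraction of rolling p95 of dP/dt
    upstroke_percentile: float = 95.0
    threshold_block_s: float = 10.0        # rolling block for the adaptive threshold
    refractory_s: float = 0.3
    min_beat_s: float = 0.3
    max_beat_s: float = 2.0
    min_valid_beats: int = 60
    onset_search_s: float = 0.25           # how far before an upstroke to look for the foot
    onset_smooth_window: int = 15          # SG window used for foot localization
    onset_plateau_mmhg: float = 0.2        # tolerance defining the diastolic minimum plateau

    # --- artefact / segment selection ---
    pressure_min: float = 20.0             # mmHg
    pressure_max: float = 300.0
    max_step_mmhg: float = 60.0            # |dP| between adjacent samples

    # --- landmarks / notch ---
    notch_search_s: float = 0.35           # window after the systolic peak
    derivative_source: str = "smoothed"    # {"smoothed", "raw"}
    d2_window: int = 21                    # SG window for the 2nd derivative trace
    peak_prominence_frac: float = 0.10     # min derivative-peak prominence, rel. to max
    notch_auc_mode: str = "above_notch"    # {"above_notch", "time_fraction"}

    # --- pulse-contour surrogate ---
    sv_calibration_k: float = 3.9          # mL per mmHg*s; set so control median SV ~ 77 mL

    # --- xBRS ---
    xbrs_window_s: float = 10.0
    xbrs_step_s: float = 1.0
    xbrs_resample_hz: float = 1.0
    xbrs_max_delay_s: float = 5.0
    xbrs_alpha: float = 0.01
    xbrs_max_gap_s: float = 3.0

    # --- summary statistics ---
    deciles_of: str = "diff"               # {"diff", "level"}: deciles of the change vs the level
    min_series_entries: int = 10

    # --- detection model ---
    train_fraction: float = 0.75
    cv_folds: int = 4
    smote_k: int = 5
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_window <= self.sg_order or self.sg_order < 1:
            raise ValueError("require sg_window > sg_order >= 1")
        if self.truncate_from not in ("start", "end"):
            raise ValueError("truncate_from must be 'start' or 'end'")
        if self.deciles_of not in ("diff", "level"):
            raise ValueError("deciles_of must be 'diff' or 'level'")
        if self.notch_auc_mode not in ("above_notch", "time_fraction"):
            raise ValueError("notch_auc_mode must be 'above_notch' or 'time_fraction'")
        if self.derivative_source not in ("smoothed", "raw"):
            raise ValueError("derivative_source must be 'smoothed' or 'raw'")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def with_overrides(self, overrides: dict | None = None, **kwargs) -> "PipelineConfig":
        """Return a copy with ``key=value`` overrides applied (types coerced)."""
        merged = self.to_dict()
        items = dict(overrides or {})
        items.update(kwargs)
        for key, value in items.items():
            if key not in merged:
                raise KeyError(f"unknown config key: {key!r}")
            current = merged[key]
            if isinstance(value, str) and not isinstance(current, str):
                value = type(current)(yaml.safe_load(value))
            merged[key] = value
        return PipelineConfig(**merged)

    def hash(self) -> str:
        """Stable short hash of the resolved configuration."""
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def parse_override(text: str) -> tuple[str, str]:
    """Split a ``key=value`` CLI override."""
    if "=" not in text:
        raise ValueError(f"override {text!r} is not of the form key=value")
    key, _, value = text.partition("=")
    return key.strip(), value.strip()
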