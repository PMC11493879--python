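"""File formats and domain containers for waveform cohorts.

The canonical waveform carrier is a two-column CSV (``time_s,pressure_mmHg``,
'.' decimal separator, LF endings) holding a uniformly sampled brachial
arterial pressure trace at 200 Hz.  A cohort is a manifest CSV pointing at
waveform files plus per-patient metadata (age, sex, height, weight, label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .summary import FEATURE_NAMES, STAT_NAMES, FeatureSummary

log = logging.getLogger(__name__)

LABELS = ("AoS", "noAoS")

#: accepted spellings in manifest files -> canonical label
_LABEL_TOKENS = {"aos": "AoS", "noaos": "noAoS"}


class WaveformError(ValueError):
    """Malformed or inadmissible waveform data."""


@dataclass(frozen=True)
class WaveformRecording:
    """A uniformly sampled arterial pressure trace.

    Attributes
    ----------
    patient_id : str
        Opaque identifier.
    sample_rate : float
        Sampling frequency in Hz (200 for the supported device stream).
    pressure : np.ndarray
        Pressure in mmHg, one value per sample.
    start_offset : float
        Time of the first sample, seconds.
    """

    patient_id: str
    sample_rate: float
    pressure: np.ndarray
    start_offset: float = 0.0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise WaveformError("sample_rate must be positive")
        object.__setattr__(self, "pressure", np.asarray(self.pressure, dtype=float))

    @property
    def duration(self) -> float:
        return len(self.pressure) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_offset + np.arange(len(self.pressure)) / self.sample_rate

    def slice(self, start_idx: int, stop_idx: int) -> "WaveformRecording":
        return replace(
            self,
            pressure=self.pressure[start_idx:stop_idx],
            start_offset=self.start_offset + start_idx / self.sample_rate,
        )


def du_bois_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the Du Bois formula."""
    return 0.007184 * height_cm**0.725 * weight_kg**0.425


@dataclass(frozen=True)
class PatientMeta:
    """Demographics and the echocardiography-derived stenosis label."""

    patient_id: str
    age: float
    sex: str
    height_cm: float
    weight_kg: float
    label: str

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; allowed: {', '.join(LABELS)}"
            )

    @property
    def bsa(self) -> float:
        return du_bois_bsa(self.height_cm, self.weight_kg)


# ---------------------------------------------------------------------------
# waveform CSV
# ---------------------------------------------------------------------------

def read_waveform(
    path: str | Path,
    expected_rate: float = 200.0,
    min_duration_s: float = 180.0,
    patient_id: str | None = None,
) -> WaveformRecording:
    """Read and validate a two-column waveform CSV.

    Rejects non-numeric rows (naming the line), non-monotone or non-uniform
    timestamps, sample-rate mismatches above 0.5 %, and recordings shorter
    than ``min_duration_s`` (the 3-minute admission rule).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise WaveformError(f"{path}: cannot parse: {exc}") from exc
    if list(df.columns) != ["time_s", "pressure_mmHg"]:
        raise WaveformError(
            f"{path}: expected header 'time_s,pressure_mmHg', got {list(df.columns)}"
        )
    t = pd.to_numeric(df["time_s"], errors="coerce").to_numpy()
    p = pd.to_numeric(df["pressure_mmHg"], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(t) | ~np.isfinite(p))
    if bad.size:
        # +2: one for the header, one for 1-based line numbering
        raise WaveformError(f"{path}: malformed row at line {bad[0] + 2}")
    if len(t) < 2:
        raise WaveformError(f"{path}: fewer than two samples")

    dt = np.diff(t)
    nonmono = np.flatnonzero(dt <= 0)
    if nonmono.size:
        raise WaveformError(
            f"{path}: non-increasing timestamp at line {nonmono[0] + 3}"
        )
    step = np.median(dt)
    if np.max(np.abs(dt - step)) > 1e-6:
        raise WaveformError(f"{path}: non-uniform sampling beyond 1e-6 s tolerance")
    rate = 1.0 / step
    if abs(rate - expected_rate) / expected_rate > 0.005:
        raise WaveformError(
            f"{path}: sample rate {rate:.3f} Hz deviates > 0.5% from "
            f"expected {expected_rate:g} Hz"
        )
    duration = len(t) / rate
    if duration < min_duration_s - 1e-6:
        raise WaveformError(
            f"{path}: duration {duration:.1f} s is below the {min_duration_s:.0f} s "
            f"(3-minute) admission minimum"
        )
    return WaveformRecording(
        patient_id=patient_id or path.stem,
        sample_rate=rate,
        pressure=p,
        start_offset=float(t[0]),
    )


def write_waveform(recording: WaveformRecording, path: str | Path) -> None:
    """Write a recording in the canonical two-column dialect."""
    t = recording.times
    df = pd.DataFrame({"time_s": t, "pressure_mmHg": recording.pressure})
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.6f")


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "patient_id", "waveform_path", "age", "sex", "height_cm", "weight_kg", "label",
]


def read_cohort_manifest(path: str | Path) -> list[tuple[Path, PatientMeta]]:
    """Read a cohort manifest; returns (waveform path, metadata) per row.

    Waveform paths are resolved relative to the manifest's directory.
    Every referenced file must exist and labels are parsed strictly.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: manifest missing columns {missing_cols}")
    if df.empty:
        log.warning("%s: empty cohort manifest", path)
        return []
    out: list[tuple[Path, PatientMeta]] = []
    for row in df.itertuples(index=False):
        token = str(row.label).strip()
        label = _LABEL_TOKENS.get(token.lower())
        if label is None:
            raise ValueError(
                f"{path}: unknown label {token!r} for patient {row.patient_id}; "
                f"allowed tokens: {', '.join(LABELS)}"
            )
        wf = Path(row.waveform_path)
        if not wf.is_absolute():
            wf = path.parent / wf
        if not wf.exists():
            raise FileNotFoundError(f"{path}: waveform file not found: {wf}")
        meta = PatientMeta(
            patient_id=str(row.patient_id),
            age=float(row.age),
            sex=str(row.sex),
            height_cm=float(row.height_cm),
            weight_kg=float(row.weight_kg),
            label=label,
        )
        out.append((wf, meta))
    return out


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

META_COLUMNS = ["patient_id", "age", "label"]


def feature_columns() -> list[str]:
    """The deterministic 135-column order: 27 base features x 5 statistics."""
    return [f"{feat}_{stat}" for feat in FEATURE_NAMES for stat in STAT_NAMES]


def write_feature_table(rows: list[FeatureSummary], path: str | Path) -> None:
    """Write per-recording summaries as a CSV with a fixed column order.

    Re-reading round-trips bit-exactly (full shortest-repr floats are
    written; missing statistics stay empty cells).
    """
    cols = feature_columns()
    records = []
    for summary in rows:
        if list(summary.values.keys()) != cols:
            raise ValueError(
                f"summary for {summary.patient_id} has a different column set/order"
            )
        rec = {
            "patient_id": summary.patient_id,
            "age": summary.age,
            "label": summary.label,
        }
        rec.update(summary.values)
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=META_COLUMNS + cols)
    # 17 significant digits: decimal text round-trips IEEE doubles exactly
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_feature_table(path: str | Path, age_adjusted: bool = True) -> list[FeatureSummary]:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = feature_columns()
    expected = META_COLUMNS + cols
    if list(df.columns) != expected:
        raise ValueError(f"{path}: unexpected feature-table schema")
    out = []
    for row in df.itertuples(index=False):
        values = {k: float(v) for k, v in zip(cols, list(row)[len(META_COLUMNS):])}
        out.append(
            FeatureSummary(
                patient_id=str(row.patient_id),
                age=float(row.age),
                label=str(row.label),
                values=values,
                age_adjusted=age_adjusted,
            )
        )
    return out
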