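"""Per-recording feature summaries and the cohort design matrix.

Each of the 27 base hemodynamic features is observed as a series (one value
per beat, or per accepted xBRS window) and collapsed into five statistics:
median, interquartile range, variance (n-1 denominator), and the 1st and
9th decile of the beat-to-beat change (first differences).  Statistics are
then divided by the patient's age to remove the dominant age dependence of
arterial waveform morphology, and assembled into a patients x statistics
design matrix for classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: the 27 base features in canonical (reporting) order
FEATURE_NAMES = [
    "ibi",                  # interbeat interval, s
    "hr",                   # heart rate, min^-1
    "lvet",                 # left ventricular ejection time (onset -> notch), s
    "sap",                  # systolic arterial pressure, mmHg
    "dap",                  # diastolic arterial pressure, mmHg
    "map",                  # mean arterial pressure (time average), mmHg
    "sv",                   # stroke volume (pulse-contour surrogate), mL
    "co",                   # cardiac output, L/min
    "svr",                  # systemic vascular resistance, dyn*s*cm^-5
    "svi",                  # stroke volume index, mL/m^2
    "ci",                   # cardiac index, L/min/m^2
    "svri",                 # systemic vascular resistance index
    "dpdt",                 # max dP/dt, mmHg/s
    "pp",                   # pulse pressure, mmHg
    "sw",                   # stroke work, mL*mmHg
    "sap_time",             # onset -> systolic peak, s
    "sap_auc",              # beat AUC up to the notch, % of total
    "dap_auc",              # beat AUC after the notch, % of total
    "notch_time",           # onset -> dicrotic notch, s
    "notch_pressure",       # pressure at the notch, mmHg
    "notch_auc",            # AUC above the notch pressure, % of total
    "max_upstroke",         # pressure at the steepest upstroke, mmHg
    "max_upstroke_time",    # onset -> steepest upstroke, s
    "max_downstroke",       # pressure at the steepest systolic downstroke, mmHg
    "max_downstroke_time",  # onset -> steepest systolic downstroke, s
    "xbrs_gain",            # baroreflex sensitivity, ms/mmHg
    "xbrs_tau",             # baroreflex delay, s
]

STAT_NAMES = ["median", "iqr", "variance", "decile1", "decile9"]

#: the published best-feature subset, as printed (grouped by statistic)
BEST_FEATURE_SUBSET = (
    [f"{f}_median" for f in [
        "ibi", "hr", "sap", "dap", "map", "sv", "co", "svi", "ci", "dpdt",
        "sw", "sap_time", "notch_time", "notch_pressure", "sap_auc", "dap_auc",
        "max_upstroke_time", "max_upstroke", "max_downstroke", "xbrs_tau"]]
    + [f"{f}_iqr" for f in [
        "map", "dpdt", "sw", "notch_time", "max_upstroke_time", "max_upstroke"]]
    + [f"{f}_variance" for f in [
        "svr", "svri", "dpdt", "pp", "max_downstroke_time", "max_upstroke"]]
    + [f"{f}_decile1" for f in [
        "sap", "dpdt", "notch_pressure", "max_upstroke", "max_downstroke"]]
    + [f"{f}_decile9" for f in [
        "sap", "dpdt", "notch_pressure", "max_upstroke"]]
)


@dataclass(frozen=True)
class FeatureSummary:
    """The 27 x 5 summary-statistic vector for one recording."""

    patient_id: str
    age: float
    label: str
    values: dict[str, float]
    age_adjusted: bool = False

    def __post_init__(self):
        expected = [f"{f}_{s}" for f in FEATURE_NAMES for s in STAT_NAMES]
        if list(self.values.keys()) != expected:
            raise ValueError("summary values must enumerate all 27x5 statistics in order")


def _quantile(sorted_values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile on pre-sorted data."""
    return float(np.quantile(sorted_values, q, method="linear"))


def summarize_series(values: np.ndarray, deciles_of: str = "diff",
                     min_entries: int = 10) -> dict[str, float]:
    """Five summary statistics of one feature series.

    ``decile1``/``decile9`` are the 10th/90th percentiles of the first
    difference series (the beat-to-beat *change*) by default, or of the
    level distribution when ``deciles_of='level'``.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < min_entries:
        return {s: math.nan for s in STAT_NAMES}
    s = np.sort(v)
    out = {
        "median": _quantile(s, 0.5),
        "iqr": _quantile(s, 0.75) - _quantile(s, 0.25),
        "variance": float(np.var(v, ddof=1)),
    }
    basis = np.sort(np.diff(v)) if deciles_of == "diff" else s
    out["decile1"] = _quantile(basis, 0.1)
    out["decile9"] = _quantile(basis, 0.9)
    return out


def summarize(series: dict[str, np.ndarray], patient_id: str, age: float,
              label: str, deciles_of: str = "diff",
              min_entries: int = 10) -> FeatureSummary:
    """Collapse the per-beat/per-window series into an unadjusted summary.

    ``series`` maps base-feature names to arrays; features absent from the
    mapping (or with too few valid entries) get missing (NaN) statistics.
    """
    values: dict[str, float] = {}
    for feat in FEATURE_NAMES:
        stats = summarize_series(
            series.get(feat, np.empty(0)), deciles_of=deciles_of, min_entries=min_entries
        )
        for stat in STAT_NAMES:
            values[f"{feat}_{stat}"] = stats[stat]
    return FeatureSummary(patient_id=patient_id, age=age, label=label,
                          values=values, age_adjusted=False)


def age_adjust(summary: FeatureSummary, age: float | None = None) -> FeatureSummary:
    """Divide every statistic by the patient's age.

    Raises if the summary was already adjusted (the adjustment is not
    idempotent) or if age is non-positive.
    """
    if summary.age_adjusted:
        raise ValueError(f"summary for {summary.patient_id} is already age-adjusted")
    age = summary.age if age is None else age
    if age <= 0:
        raise ValueError("age must be positive")
    values = {k: v / age for k, v in summary.values.items()}
    return replace(summary, values=values, age_adjusted=True)


def build_design_matrix(
    summaries: list[FeatureSummary],
    feature_subset: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Assemble the cohort design matrix.

    Returns ``(X, y, patient_ids)`` where ``X`` is a patients x statistics
    DataFrame in deterministic column order and ``y`` is 1 for AoS.
    Rows containing a missing selected value are dropped (logged).
    """
    if feature_subset is not None:
        if not feature_subset:
            raise ValueError("feature_subset must not be empty")
        valid = {f"{f}_{s}" for f in FEATURE_NAMES for s in STAT_NAMES}
        unknown = [c for c in feature_subset if c not in valid]
        if unknown:
            raise ValueError(
                f"unknown feature names {unknown}; valid names are "
                f"'{{base}}_{{stat}}' with base in FEATURE_NAMES and stat in {STAT_NAMES}"
            )
        cols = list(feature_subset)
    else:
        cols = [f"{f}_{s}" for f in FEATURE_NAMES for s in STAT_NAMES]

    rows = pd.DataFrame([s.values for s in summaries])[cols]
    ids = [s.patient_id for s in summaries]
    y = np.array([1 if s.label == "AoS" else 0 for s in summaries])
    keep = rows.notna().all(axis=1).to_numpy()
    if (~keep).any():
        dropped = [ids[i] for i in np.flatnonzero(~keep)]
        log.info("dropping %d patients with missing features: %s", len(dropped), dropped)
    X = rows.loc[keep].reset_index(drop=True)
    X.index = pd.Index([ids[i] for i in np.flatnonzero(keep)], name="patient_id")
    return X, y[keep], [ids[i] for i in np.flatnonzero(keep)]
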