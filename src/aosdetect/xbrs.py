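"""Time-domain cross-correlation baroreflex sensitivity (xBRS).

Beat-to-beat systolic pressure (SAP) and interbeat interval (IBI) series
are step-interpolated to a uniform 1 Hz base.  In sliding 10-s windows the
IBI series is shifted 0-5 s later than SAP; the delay with the highest
positive Pearson correlation is kept, and if that correlation is
significant (two-sided, alpha = 0.01) the window emits a gain - the
regression slope of IBI on SAP in ms/mmHg - and the delay tau.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class XbrsEstimate:
    """One accepted window's baroreflex estimate."""

    window_start: float   # s
    gain: float           # ms/mmHg
    tau: float            # s
    correlation: float


def beat_series_resample(
    onset_s: np.ndarray,
    sap: np.ndarray,
    ibi_s: np.ndarray,
    rate: float = 1.0,
    max_gap_s: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Step-interpolate beat series to a uniform grid.

    Returns ``(t, sap_series, ibi_series, valid)`` where each grid point
    takes the value of the beat active at that time; points farther than
    ``max_gap_s`` from any beat onset (detection gaps) are flagged invalid.
    """
    onset_s = np.asarray(onset_s, float)
    if onset_s.size < 2 or onset_s[-1] - onset_s[0] < 15.0:
        raise ValueError("need at least 15 s of valid beats")
    t = np.arange(math.ceil(onset_s[0]), math.floor(onset_s[-1]) + 1) / 1.0
    if rate != 1.0:
        t = np.arange(math.ceil(onset_s[0] * rate), math.floor(onset_s[-1] * rate) + 1) / rate
    idx = np.clip(np.searchsorted(onset_s, t, side="right") - 1, 0, len(onset_s) - 1)
    sap_series = np.asarray(sap, float)[idx]
    ibi_series = np.asarray(ibi_s, float)[idx]
    # a grid point is valid when its governing beat covers it without a gap
    gap = t - onset_s[idx]
    valid = (gap <= np.maximum(np.asarray(ibi_s, float)[idx], 0.0) + max_gap_s) & \
        np.isfinite(sap_series) & np.isfinite(ibi_series)
    return t, sap_series, ibi_series, valid


def xbrs_windows(
    sap_series: np.ndarray,
    ibi_series: np.ndarray,
    t: np.ndarray | None = None,
    valid: np.ndarray | None = None,
    window_s: float = 10.0,
    step_s: float = 1.0,
    max_delay_s: float = 5.0,
    alpha: float = 0.01,
    rate: float = 1.0,
) -> list[XbrsEstimate]:
    """Scan sliding windows for significant positive SAP->IBI correlation.

    For each window start and each integer delay ``d``, SAP(t) is
    correlated with IBI(t + d); the best positive-correlation delay is
    tested against the two-sided significance threshold and, if accepted,
    the regression slope of IBI (ms) on SAP (mmHg) is emitted as the gain.
    """
    sap_series = np.asarray(sap_series, float)
    ibi_series = np.asarray(ibi_series, float)
    n = len(sap_series)
    w = int(round(window_s * rate))
    step = max(1, int(round(step_s * rate)))
    delays = np.arange(0, int(round(max_delay_s * rate)) + 1)
    if t is None:
        t = np.arange(n) / rate
    if valid is None:
        valid = np.ones(n, dtype=bool)
    if w < 3 or n < w + delays[-1]:
        return []

    # two-sided critical |r| for the window's sample size
    df = w - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    r_crit = t_crit / math.sqrt(df + t_crit**2)

    starts = np.arange(0, n - w - int(delays[-1]) + 1, step)
    if starts.size == 0:
        return []
    sw = np.lib.stride_tricks.sliding_window_view
    sap_w = sw(sap_series, w)
    ibi_w = sw(ibi_series, w)
    valid_w = sw(valid, w).all(axis=1)

    x = sap_w[starts]
    x_mean = x.mean(axis=1, keepdims=True)
    xc = x - x_mean
    sx = np.sqrt((xc**2).mean(axis=1))

    n_s, n_d = starts.size, delays.size
    r = np.full((n_s, n_d), -np.inf)
    slope = np.zeros((n_s, n_d))
    for j, d in enumerate(delays):
        y = ibi_w[starts + d]
        yc = y - y.mean(axis=1, keepdims=True)
        sy = np.sqrt((yc**2).mean(axis=1))
        cov = (xc * yc).mean(axis=1)
        ok = valid_w[starts] & valid_w[starts + d] & (sx > 0) & (sy > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r[:, j] = np.where(ok, cov / (sx * sy), -np.inf)
            slope[:, j] = np.where(ok, cov / sx**2, 0.0)

    best_j = np.argmax(r, axis=1)
    rows = np.arange(n_s)
    best_r = r[rows, best_j]
    accept = (best_r > 0.0) & (best_r >= r_crit)
    estimates = [
        XbrsEstimate(
            window_start=float(t[starts[i]]),
            gain=float(slope[i, best_j[i]]) * 1000.0,  # s/mmHg -> ms/mmHg
            tau=float(delays[best_j[i]] / rate),
            correlation=float(best_r[i]),
        )
        for i in np.flatnonzero(accept)
    ]
    return estimates


def summarize_xbrs(estimates: list[XbrsEstimate]) -> dict[str, np.ndarray]:
    """Per-window gain and tau series for the feature summary stage."""
    if not estimates:
        log.info("no accepted xBRS windows; gain/tau features will be missing")
        return {"xbrs_gain": np.empty(0), "xbrs_tau": np.empty(0)}
    return {
        "xbrs_gain": np.array([e.gain for e in estimates]),
        "xbrs_tau": np.array([e.tau for e in estimates]),
    }


def xbrs_from_beats(
    onset_s: np.ndarray,
    sap: np.ndarray,
    ibi_s: np.ndarray,
    window_s: float = 10.0,
    step_s: float = 1.0,
    resample_hz: float = 1.0,
    max_delay_s: float = 5.0,
    alpha: float = 0.01,
    max_gap_s: float = 3.0,
) -> dict[str, np.ndarray]:
    """Convenience: beats -> resample -> windows -> per-recording series."""
    try:
        t, s, i, valid = beat_series_resample(
            onset_s, sap, ibi_s, rate=resample_hz, max_gap_s=max_gap_s
        )
    except ValueError:
        return {"xbrs_gain": np.empty(0), "xbrs_tau": np.empty(0)}
    est = xbrs_windows(
        s, i, t=t, valid=valid, window_s=window_s, step_s=step_s,
        max_delay_s=max_delay_s, alpha=alpha, rate=resample_hz,
    )
    return summarize_xbrs(est)
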