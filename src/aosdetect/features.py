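"""Per-beat landmarks and hemodynamic features.

The dicrotic notch is located by averaging the times of the second local
maxima of the first and second pressure derivatives (counted from beat
onset; both must fall within a bounded window after the systolic peak).
Ejection time is the onset-to-notch interval.  Stroke volume is a
pulse-contour surrogate: a calibrated systolic pressure-time integral.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .beats import Beat
from .config import PipelineConfig
from .io import PatientMeta, WaveformRecording

log = logging.getLogger(__name__)


class NotchNotFound(ValueError):
    """The dicrotic notch could not be located on this beat."""


class LandmarkError(ValueError):
    """Beat landmarks violate their ordering invariant."""


@dataclass(frozen=True)
class BeatLandmarks:
    """Timing/pressure landmarks of one beat (times onset-referenced, s)."""

    sap: float
    t_sap: float
    dap: float
    t_notch: float
    p_notch: float
    t_max_up: float
    p_max_up: float
    max_up_slope: float
    t_max_down: float
    p_max_down: float
    max_down_slope: float

    def validate(self) -> None:
        ok = (0.0 < self.t_max_up < self.t_sap < self.t_max_down < self.t_notch
              and self.dap <= self.p_notch <= self.sap
              and self.max_up_slope > 0.0 > self.max_down_slope)
        if not ok:
            raise LandmarkError(f"landmark ordering invariant violated: {self}")


def _parabolic_refine(y: np.ndarray, i: int, dt: float) -> float:
    """Sub-sample extremum time via a 3-point parabola (clipped to +-1 step)."""
    if i <= 0 or i >= len(y) - 1:
        return i * dt
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return i * dt
    delta = float(np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -1.0, 1.0))
    return (i + delta) * dt


_QV_X = np.arange(-3, 4, dtype=float)
_QV_SX2, _QV_SX4, _QV_N = 28.0, 196.0, 7.0


def _quadratic_vertex(y: np.ndarray, i: int, dt: float, half: int = 3,
                      maximum: bool = True) -> float:
    """Sub-sample extremum time by a least-squares quadratic over +-half
    samples around i (more noise-robust than a 3-point parabola for the
    broad pressure/slope extrema)."""
    if half == 3 and i - 3 >= 0 and i + 4 <= len(y):
        # closed-form LS quadratic on the symmetric 7-point stencil
        w = y[i - 3: i + 4]
        sy = w.sum()
        sxy = float(_QV_X @ w)
        sx2y = float((_QV_X * _QV_X) @ w)
        a = (_QV_N * sx2y - _QV_SX2 * sy) / (_QV_N * _QV_SX4 - _QV_SX2**2)
        b = sxy / _QV_SX2
        if a == 0 or (maximum and a > 0) or (not maximum and a < 0):
            return i * dt
        return (i + float(np.clip(-b / (2.0 * a), -3.0, 3.0))) * dt
    lo, hi = max(0, i - half), min(len(y), i + half + 1)
    if hi - lo < 3:
        return i * dt
    x = np.arange(lo, hi, dtype=float)
    a, b, _ = np.polyfit(x, y[lo:hi], 2)
    if a == 0 or (maximum and a > 0) or (not maximum and a < 0):
        return i * dt
    v = float(np.clip(-b / (2.0 * a), lo, hi - 1))
    return v * dt


def beat_derivatives(
    pressure: np.ndarray,
    fs: float,
    window: int = 15,
    order: int = 3,
    d2_window: int = 21,
) -> tuple[np.ndarray, np.ndarray]:
    """Savitzky-Golay first and second derivative traces of a pressure signal.

    SG differentiation (least-squares polynomial slopes) keeps derivative
    noise bounded; the second derivative uses a somewhat wider window since
    double differentiation amplifies noise the most.
    """
    x = np.asarray(pressure, dtype=float)
    w1 = min(window, len(x) - 1 - (len(x) % 2 == 0))
    w1 = w1 if w1 % 2 == 1 else w1 - 1
    w2 = min(d2_window, len(x) - 1)
    w2 = w2 if w2 % 2 == 1 else w2 - 1
    if w1 <= order or w2 <= order:
        raise ValueError("beat too short to differentiate")
    d1 = savgol_filter(x, w1, order, deriv=1, delta=1.0 / fs, mode="interp")
    d2 = savgol_filter(x, w2, order, deriv=2, delta=1.0 / fs, mode="interp")
    return d1, d2


def _second_local_max(y: np.ndarray, prominence: float, i_sap: int) -> int:
    """Index of the second beat-wide local maximum of a derivative trace.

    The first maximum of either pressure derivative always falls in the
    systolic upstroke - frequently at the beat's leading edge, where it is
    not an interior extremum - so the second one is located as the first
    prominent interior maximum after the systolic peak.
    """
    peaks, _ = find_peaks(y[i_sap:], prominence=prominence)
    if len(peaks) < 1:
        raise NotchNotFound("no post-systolic local maximum in the derivative")
    return int(peaks[0]) + i_sap


def locate_dicrotic_notch(
    pressure: np.ndarray,
    fs: float,
    t_sap: float,
    search_s: float = 0.35,
    d1: np.ndarray | None = None,
    d2: np.ndarray | None = None,
    prominence_frac: float = 0.10,
) -> tuple[float, float]:
    """Locate the dicrotic notch on one beat.

    ``t_notch`` is the mean of the times of the second local maxima (counted
    from beat onset) of dP/dt and d2P/dt2, each refined by a parabolic
    vertex fit; both must lie in ``(t_sap, t_sap + search_s]`` or the notch
    is declared not found.  ``p_notch`` is the pressure at ``t_notch``.
    Local maxima below a prominence floor (a fraction of the trace's own
    maximum) are treated as noise and not counted.
    """
    dt = 1.0 / fs
    if d1 is None or d2 is None:
        d1, d2 = beat_derivatives(pressure, fs)
    t_lo, t_hi = t_sap, t_sap + search_s
    i_sap = max(1, int(round(t_sap / dt)))
    times = []
    for deriv in (d1, d2):
        prom = prominence_frac * np.max(deriv)
        idx = _second_local_max(deriv, prom, i_sap)
        t = _parabolic_refine(deriv, idx, dt)
        if not (t_lo < t <= t_hi):
            raise NotchNotFound(
                f"second derivative maximum at {t:.3f} s outside ({t_lo:.3f}, {t_hi:.3f}]"
            )
        times.append(t)
    t_notch = float(np.mean(times))
    p_notch = float(np.interp(t_notch, np.arange(len(pressure)) * dt, pressure))
    return t_notch, p_notch


def extract_landmarks(
    pressure: np.ndarray,
    fs: float,
    search_s: float = 0.35,
    prominence_frac: float = 0.10,
    d1: np.ndarray | None = None,
    d2: np.ndarray | None = None,
) -> BeatLandmarks:
    """Extract all landmarks of one (smoothed) beat.

    The systolic peak is the pressure maximum (first occurrence on ties);
    DAP is the onset pressure; the steepest up/downstrokes are the extrema
    of dP/dt restricted to the systolic part (before the notch).
    """
    dt = 1.0 / fs
    if d1 is None or d2 is None:
        d1, d2 = beat_derivatives(pressure, fs)

    i_sap = int(np.argmax(pressure))
    t_sap = _quadratic_vertex(pressure, i_sap, dt)
    sap = float(pressure[i_sap])
    dap = float(pressure[0])

    t_notch, p_notch = locate_dicrotic_notch(
        pressure, fs, t_sap, search_s=search_s, d1=d1, d2=d2,
        prominence_frac=prominence_frac,
    )

    # systolic part: (0, t_notch)
    n_sys = max(2, min(len(pressure), int(math.floor(t_notch / dt))))
    sys_d1 = d1[:n_sys]
    i_up = int(np.argmax(sys_d1))
    i_down = int(np.argmin(sys_d1))
    lm = BeatLandmarks(
        sap=sap, t_sap=t_sap, dap=dap,
        t_notch=t_notch, p_notch=p_notch,
        t_max_up=_quadratic_vertex(sys_d1, i_up, dt),
        p_max_up=float(pressure[i_up]),
        max_up_slope=float(sys_d1[i_up]),
        t_max_down=_quadratic_vertex(sys_d1, i_down, dt, maximum=False),
        p_max_down=float(pressure[i_down]),
        max_down_slope=float(sys_d1[i_down]),
    )
    lm.validate()
    return lm


def _trapezoid_to(pressure: np.ndarray, dt: float, t_end: float) -> float:
    """Trapezoidal integral of the sampled trace from 0 to a sub-sample
    endpoint (linear interpolation over the final fractional step)."""
    n = len(pressure)
    i = min(n - 1, int(math.floor(t_end / dt)))
    total = float(np.trapezoid(pressure[: i + 1], dx=dt))
    frac = t_end - i * dt
    if frac > 0 and i + 1 < n:
        p_end = pressure[i] + (pressure[i + 1] - pressure[i]) * frac / dt
        total += 0.5 * (pressure[i] + p_end) * frac
    return total


def compute_beat_features(
    landmarks: BeatLandmarks,
    pressure: np.ndarray,
    fs: float,
    meta: PatientMeta,
    calibration_k: float = 6.0,
    notch_auc_mode: str = "above_notch",
) -> dict[str, float]:
    """The per-beat subset of the 27 features (all but the xBRS pair).

    Integrals are trapezoidal on the sample grid.  ``sv`` is the calibrated
    systolic pressure-time integral surrogate ``k * int_0^lvet (P - DAP) dt``;
    downstream indices use the Du Bois body surface area.
    """
    dt = 1.0 / fs
    n = len(pressure)
    ibi = n * dt

    lvet = landmarks.t_notch

    total_auc = float(np.trapezoid(pressure, dx=dt))
    sys_auc = _trapezoid_to(pressure, dt, lvet)
    sap_auc = 100.0 * sys_auc / total_auc
    dap_auc = 100.0 - sap_auc
    if notch_auc_mode == "time_fraction":
        notch_auc = 100.0 * lvet / ibi
    else:
        above = np.maximum(pressure - landmarks.p_notch, 0.0)
        notch_auc = 100.0 * float(np.trapezoid(above, dx=dt)) / total_auc

    map_ = total_auc / ((n - 1) * dt)  # trapezoid mean over the sampled span
    hr = 60.0 / ibi
    pp = landmarks.sap - landmarks.dap
    sv = calibration_k * (sys_auc - landmarks.dap * lvet)
    co = sv * hr / 1000.0  # L/min
    sw = sv * map_
    bsa = meta.bsa
    out = {
        "ibi": ibi,
        "hr": hr,
        "lvet": lvet,
        "sap": landmarks.sap,
        "dap": landmarks.dap,
        "map": map_,
        "sv": sv,
        "co": co,
        "svr": math.nan,
        "svi": sv / bsa,
        "ci": co / bsa,
        "svri": math.nan,
        "dpdt": landmarks.max_up_slope,
        "pp": pp,
        "sw": sw,
        "sap_time": landmarks.t_sap,
        "sap_auc": sap_auc,
        "dap_auc": dap_auc,
        "notch_time": landmarks.t_notch,
        "notch_pressure": landmarks.p_notch,
        "notch_auc": notch_auc,
        "max_upstroke": landmarks.p_max_up,
        "max_upstroke_time": landmarks.t_max_up,
        "max_downstroke": landmarks.p_max_down,
        "max_downstroke_time": landmarks.t_max_down,
    }
    if co > 0:
        svr = 80.0 * map_ / co
        out["svr"] = svr
        out["svri"] = svr * bsa
    return out


def extract_recording_features(
    recording: WaveformRecording,
    beats: list[Beat],
    meta: PatientMeta,
    smoothed: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, np.ndarray]:
    """Per-beat feature series for one recording.

    Returns a mapping base-feature -> array with one entry per valid beat
    (NaN where a beat's notch could not be located), plus ``_onset_s`` and
    ``_sap``/``_ibi`` helper series consumed by the xBRS stage.
    """
    cfg = config or PipelineConfig()
    fs = recording.sample_rate
    if cfg.derivative_source == "smoothed":
        from .beats import smooth
        sig = smoothed if smoothed is not None else smooth(recording, cfg.sg_window, cfg.sg_order)
    else:
        sig = recording.pressure
    # SG-differentiate the whole recording once; beats reuse the slices
    d1_all, d2_all = beat_derivatives(
        recording.pressure, fs, window=cfg.sg_window, order=cfg.sg_order,
        d2_window=cfg.d2_window,
    )

    names = [
        "ibi", "hr", "lvet", "sap", "dap", "map", "sv", "co", "svr", "svi",
        "ci", "svri", "dpdt", "pp", "sw", "sap_time", "sap_auc", "dap_auc",
        "notch_time", "notch_pressure", "notch_auc", "max_upstroke",
        "max_upstroke_time", "max_downstroke", "max_downstroke_time",
    ]
    valid_beats = [b for b in beats if b.valid]
    series: dict[str, list] = {k: [] for k in names}
    onsets, saps, ibis = [], [], []
    n_failed = 0
    for beat in valid_beats:
        seg = sig[beat.onset_idx: beat.end_idx]
        try:
            lm = extract_landmarks(
                seg, fs, search_s=cfg.notch_search_s,
                prominence_frac=cfg.peak_prominence_frac,
                d1=d1_all[beat.onset_idx: beat.end_idx],
                d2=d2_all[beat.onset_idx: beat.end_idx],
            )
            feats = compute_beat_features(
                lm, seg, fs, meta,
                calibration_k=cfg.sv_calibration_k,
                notch_auc_mode=cfg.notch_auc_mode,
            )
        except (NotchNotFound, LandmarkError):
            n_failed += 1
            for k in names:
                series[k].append(math.nan)
            onsets.append(beat.onset_time)
            saps.append(float(np.max(seg)))
            ibis.append(beat.ibi)
            continue
        for k in names:
            series[k].append(feats[k])
        onsets.append(beat.onset_time)
        saps.append(lm.sap)
        ibis.append(beat.ibi)
    if n_failed:
        log.debug("%s: %d/%d beats without a locatable notch",
                  recording.patient_id, n_failed, len(valid_beats))
    out = {k: np.asarray(v, dtype=float) for k, v in series.items()}
    out["_onset_s"] = np.asarray(onsets, dtype=float)
    out["_sap"] = np.asarray(saps, dtype=float)
    out["_ibi"] = np.asarray(ibis, dtype=float)
    return out
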