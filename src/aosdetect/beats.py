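"""Signal conditioning and beat segmentation.

The raw pressure trace is smoothed with a Savitzky-Golay filter, artefacts
are excised by keeping the longest clean window, and beats are segmented at
the pressure foot: each steep-upstroke event (first-derivative peak above an
adaptive threshold, with a refractory period) is traced back to the local
pressure minimum that precedes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .config import PipelineConfig
from .io import WaveformError, WaveformRecording

log = logging.getLogger(__name__)


class InsufficientDataError(WaveformError):
    """Too few valid beats for feature extraction."""


@dataclass(frozen=True)
class Beat:
    """One segmented cardiac cycle, referenced into the recording."""

    onset_idx: int
    end_idx: int          # exclusive; the next beat's onset
    onset_time: float     # s, recording-referenced
    end_time: float
    valid: bool

    @property
    def ibi(self) -> float:
        return self.end_time - self.onset_time


def smooth(recording: WaveformRecording | np.ndarray, window: int = 15,
           order: int = 3) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing.

    Output length equals input length; edges are handled by polynomial fits
    on the truncated window (``mode='interp'``).
    """
    x = recording.pressure if isinstance(recording, WaveformRecording) else np.asarray(recording, float)
    if window % 2 == 0 or window <= order or order < 1:
        raise ValueError("require odd window > order >= 1")
    if window >= len(x):
        raise ValueError(f"window ({window}) must be shorter than the signal ({len(x)})")
    return savgol_filter(x, window_length=window, polyorder=order, mode="interp")


def select_segment(
    recording: WaveformRecording,
    max_len: float = 600.0,
    min_len: float = 180.0,
    pressure_min: float = 20.0,
    pressure_max: float = 300.0,
    max_step: float = 60.0,
    truncate_from: str = "start",
) -> WaveformRecording:
    """Return the longest artefact-free window, capped at ``max_len`` seconds.

    A sample is an artefact if it leaves the physiological pressure band or
    jumps more than ``max_step`` mmHg from its neighbour.  Raises when the
    best clean window is shorter than ``min_len`` (the admission minimum).
    """
    p = recording.pressure
    bad = (p < pressure_min) | (p > pressure_max) | ~np.isfinite(p)
    step_bad = np.abs(np.diff(p)) > max_step
    bad[:-1] |= step_bad
    bad[1:] |= step_bad

    # longest run of clean samples
    clean = ~bad
    if not clean.any():
        raise WaveformError("recording is all artefact")
    edges = np.diff(clean.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if clean[0]:
        starts.insert(0, 0)
    if clean[-1]:
        ends.append(len(p))
    lengths = np.array(ends) - np.array(starts)
    best = int(np.argmax(lengths))
    s, e = int(starts[best]), int(ends[best])

    fs = recording.sample_rate
    if (e - s) / fs < min_len - 1e-6:
        raise WaveformError(
            f"longest artefact-free window ({(e - s) / fs:.1f} s) is below the "
            f"{min_len:.0f} s admission minimum"
        )
    max_samples = int(round(max_len * fs))
    if e - s > max_samples:
        if truncate_from == "start":
            e = s + max_samples
        else:
            s = e - max_samples
    return recording.slice(s, e)


def _adaptive_threshold(d1: np.ndarray, fs: float, block_s: float,
                        percentile: float, frac: float) -> np.ndarray:
    """Per-sample upstroke threshold: ``frac`` of the rolling block p95 of dP/dt."""
    n = len(d1)
    block = max(1, int(round(block_s * fs)))
    n_blocks = int(np.ceil(n / block))
    centers = np.empty(n_blocks)
    values = np.empty(n_blocks)
    for i in range(n_blocks):
        seg = d1[i * block: (i + 1) * block]
        centers[i] = (i + 0.5) * block
        values[i] = np.percentile(seg, percentile)
    thr = np.interp(np.arange(n), centers, values) * frac
    return thr


def detect_beats(
    recording: WaveformRecording,
    smoothed: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> list[Beat]:
    """Segment a recording into beats at the pressure foot.

    Upstroke events are peaks of the smoothed first derivative exceeding an
    adaptive threshold (robust to slow pressure drift), separated by a
    refractory period.  Each event's onset is the preceding local pressure
    minimum, localized on a wider smoothing window and refined by a
    parabolic vertex fit.  Beats outside [min_beat_s, max_beat_s] are
    marked invalid.
    """
    cfg = config or PipelineConfig()
    fs = recording.sample_rate
    sm = smoothed if smoothed is not None else smooth(recording, cfg.sg_window, cfg.sg_order)
    d1 = savgol_filter(recording.pressure, cfg.sg_window, cfg.sg_order,
                       deriv=1, delta=1.0 / fs, mode="interp")
    thr = _adaptive_threshold(d1, fs, cfg.threshold_block_s,
                              cfg.upstroke_percentile, cfg.upstroke_threshold_frac)
    if np.all(thr <= 0) or np.percentile(d1, cfg.upstroke_percentile) < 50.0:
        raise InsufficientDataError("no systolic upstrokes found (flat or drifting signal)")
    peaks, _ = find_peaks(d1, distance=max(1, int(cfg.refractory_s * fs)))
    peaks = peaks[d1[peaks] > thr[peaks]]
    if peaks.size < 2:
        raise InsufficientDataError("fewer than two upstroke events detected")
    # late-systolic (dicrotic) upslopes can sneak past the absolute
    # refractory period; reject the weaker of two events much closer than
    # the running beat interval
    gaps = np.diff(peaks)
    big = gaps[gaps > 0.4 * fs]
    if big.size:
        med_gap = float(np.median(big))
        kept = [int(peaks[0])]
        for pk in peaks[1:]:
            if pk - kept[-1] < 0.55 * med_gap:
                if d1[pk] > d1[kept[-1]]:
                    kept[-1] = int(pk)
            else:
                kept.append(int(pk))
        peaks = np.array(kept)

    # wider smoothing only for foot localization (robust to residual noise)
    wide = savgol_filter(recording.pressure, cfg.onset_smooth_window, cfg.sg_order,
                         mode="interp")
    search = max(2, int(round(cfg.onset_search_s * fs)))
    onsets = np.empty(peaks.size, dtype=int)
    for k, pk in enumerate(peaks):
        lo = max(0, pk - search)
        seg = wide[lo: pk + 1]
        # last sample still on the diastolic minimum plateau (the pressure
        # foot is the end of the flat minimum, not its noisy argmin)
        at_min = np.flatnonzero(seg <= seg.min() + cfg.onset_plateau_mmhg)
        onsets[k] = lo + int(at_min[-1])
    onsets = np.unique(onsets)

    beats: list[Beat] = []
    t0 = recording.start_offset
    for a, b in zip(onsets[:-1], onsets[1:]):
        ibi = (b - a) / fs
        valid = cfg.min_beat_s <= ibi <= cfg.max_beat_s
        beats.append(Beat(
            onset_idx=int(a), end_idx=int(b),
            onset_time=t0 + a / fs, end_time=t0 + b / fs, valid=valid,
        ))
    n_valid = sum(b.valid for b in beats)
    if n_valid < cfg.min_valid_beats:
        raise InsufficientDataError(
            f"only {n_valid} valid beats detected (< {cfg.min_valid_beats})"
        )
    return beats
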