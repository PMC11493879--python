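"""Synthetic two-group arterial-pressure cohort generator.

Each patient is a smooth parametric beat template (quintic Hermite segments
through landmark knots, so the curve is twice continuously differentiable
and every landmark the feature extractor measures is controlled directly),
repeated with per-beat jitter, respiratory baseline modulation, a
baroreflex coupling from systolic pressure to interbeat interval, and
additive observation noise.  Group parameter distributions default to the
published contrasts between patients with and without aortic valve
stenosis: a delayed steepest upstroke, a delayed systolic peak, a longer
ejection time, and a slightly lower pulse-contour stroke volume in the
stenosis group.

Every simulated beat is logged with its ground-truth onset, systolic
pressure, landmark times and interbeat interval, so downstream detection
and feature extraction can be scored against the generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .io import PatientMeta, WaveformRecording

# --- template shape constants (fixed package choices) ----------------------
_SMAX_COEF = 2.0         # s_max ~ coef * PP / t_peak (pre-normalization)
_SHOULDER_FRAC = 0.45    # broad-shoulder velocity level relative to the peak
_W_SPIKE_S = 0.030       # half-width of the sharp ejection velocity spike, s
_T_APPROACH_S = 0.035    # flattening approach into the notch, s
_T_REBOUND_S = 0.020     # notch -> dicrotic-wave upslope duration, s
_T_DIC_FALL_S = 0.030    # dicrotic-wave downslope duration, s
_W_DIASTOLE_S = 0.08     # onset width of the diastolic decay velocity
_GRID_RATE = 2000.0      # internal dense template grid, Hz
_TEMPLATE_SPAN_S = 2.4   # template support (covers the longest valid beat)

#: conversion between the quartiles of a log-normal and its log-space sigma
_Z75 = 0.6744897501960817


class ParameterError(ValueError):
    """Infeasible beat-template parameters."""


@dataclass(frozen=True)
class BeatTemplateParams:
    """Morphology parameters of one patient's beat template.

    Timings are onset-referenced seconds; pressures in mmHg.
    """

    dap: float = 76.0                # diastolic (onset) pressure
    pp: float = 80.0                 # pulse pressure
    t_peak: float = 0.17             # onset -> systolic peak
    t_max_up: float = 0.060          # onset -> steepest upstroke
    lvet: float = 0.325              # onset -> dicrotic notch (ejection time)
    notch_depth: float = 40.0        # systolic peak -> notch pressure drop
    dicrotic_wave_amp: float = 6.0   # notch -> dicrotic-wave peak rebound
    diastolic_decay_tau: float = 0.45  # exponential diastolic decay constant, s
    true_sv: float = 77.0            # nominal stroke volume, mL (ground truth)

    def validate(self) -> None:
        if not (0.0 < self.t_max_up < self.t_peak < self.lvet):
            raise ParameterError(
                f"require 0 < t_max_up < t_peak < lvet, got "
                f"({self.t_max_up}, {self.t_peak}, {self.lvet})"
            )
        if self.notch_depth <= 0:
            raise ParameterError("notch_depth must be positive")
        if self.notch_depth >= self.pp:
            raise ParameterError("notch_depth must be below the pulse pressure")
        if self.dicrotic_wave_amp < 0 or self.dicrotic_wave_amp >= self.notch_depth:
            raise ParameterError("dicrotic_wave_amp must be in [0, notch_depth)")
        if self.pp <= 0 or self.dap <= 0 or self.diastolic_decay_tau <= 0:
            raise ParameterError("pressures and decay tau must be positive")


@dataclass(frozen=True)
class BeatTemplate:
    """Densely sampled beat template (pressure relative to DAP) plus its
    numerically located ground-truth landmarks."""

    params: BeatTemplateParams
    ibi0: float
    grid_t: np.ndarray
    grid_v: np.ndarray
    t_peak: float      # numeric argmax of the template
    t_max_up: float    # numeric argmax of the template derivative
    t_notch: float     # notch local-minimum time (== params.lvet by construction)
    v_peak: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.grid_t, self.grid_v)


def _s5(u: np.ndarray) -> np.ndarray:
    """Quintic smoothstep on [0, 1] (zero slope and curvature at both ends)."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


_S5_GRID_U = np.linspace(0.0, 1.0, 2001)
_S5_GRID_V = _s5(_S5_GRID_U)


def _s5_inv(v: float) -> float:
    return float(np.interp(v, _S5_GRID_V, _S5_GRID_U))


def _spike_bump(u: np.ndarray) -> np.ndarray:
    """C^2 unit bump on [-1, 1] built from the quintic smoothstep."""
    return _s5(1.0 - np.abs(u))


def _build_velocity(params: BeatTemplateParams, s_down: float,
                    grid_t: np.ndarray) -> tuple[np.ndarray, float]:
    """dP/dt of the systole-through-dicrotic-wave section on the grid.

    The base is a chain of quintic-smoothstep ramps: foot upstroke to the
    broad-shoulder level peaking at ``t_max_up``; descent to ``-s_down``
    crossing zero exactly at ``t_peak``; a taper and flattening approach
    into the notch (velocity reaches zero exactly at ``lvet``); the
    dicrotic-wave upslope and downslope.  A sharp, symmetric ejection
    spike is added on top of the shoulder at ``t_max_up`` - arterial dP/dt
    peaks briefly during early ejection and then rides a plateau while
    pressure keeps climbing to its (much later) maximum.  Returns the
    velocity trace (zero after the dicrotic peak) and the dicrotic-peak
    time.
    """
    p = params
    s_max = _SMAX_COEF * p.pp / p.t_peak
    s_sh = _SHOULDER_FRAC * s_max
    a_spike = s_max - s_sh
    s_b = 2.0 * p.dicrotic_wave_amp / (_T_REBOUND_S + _T_DIC_FALL_S)
    s_notch = min(1.2 * s_b, 0.8 * s_down)

    # shoulder descent ramp spans [t_max_up, t_md]; its zero crossing is
    # the systolic peak, pinned at t_peak
    u_star = _s5_inv(s_sh / (s_sh + s_down))
    t_md = p.t_max_up + (p.t_peak - p.t_max_up) / max(u_star, 1e-6)
    t_a = min(_T_APPROACH_S, 0.6 * max(p.lvet - t_md, 1e-3))
    t_b0 = p.lvet - t_a
    if t_md >= t_b0:
        t_md = max(p.t_peak + 1e-3, t_b0 - 1e-3)
    t_r = p.lvet + _T_REBOUND_S
    t_dic = t_r + _T_DIC_FALL_S

    t = grid_t
    v = np.zeros_like(t)
    seg = t < p.t_max_up
    # foot ramp 1-(1-u)^3: nonzero initial dP/dt slope, so pressure leaves
    # the diastolic minimum parabolically (the valve-opening kink real
    # waveforms show at the foot); C^2 at the junction with the descent
    u = t[seg] / p.t_max_up
    v[seg] = s_sh * (1.0 - (1.0 - u) ** 3)
    seg = (t >= p.t_max_up) & (t < t_md)
    v[seg] = s_sh - (s_sh + s_down) * _s5((t[seg] - p.t_max_up) / (t_md - p.t_max_up))
    seg = (t >= t_md) & (t < t_b0)
    v[seg] = -s_down + (s_down - s_notch) * _s5((t[seg] - t_md) / max(t_b0 - t_md, 1e-9))
    seg = (t >= t_b0) & (t < p.lvet)
    v[seg] = -s_notch * (1.0 - _s5((t[seg] - t_b0) / max(p.lvet - t_b0, 1e-9)))
    seg = (t >= p.lvet) & (t < t_r)
    v[seg] = s_b * _s5((t[seg] - p.lvet) / (t_r - p.lvet))
    seg = (t >= t_r) & (t < t_dic)
    v[seg] = s_b * (1.0 - _s5((t[seg] - t_r) / (t_dic - t_r)))

    w = min(_W_SPIKE_S, p.t_max_up)  # keep the spike inside the beat
    seg = np.abs(t - p.t_max_up) < w
    v[seg] += a_spike * _spike_bump((t[seg] - p.t_max_up) / w)
    return v, t_dic


def build_template(params: BeatTemplateParams, ibi0: float) -> BeatTemplate:
    """Construct the C^2 beat template for a nominal interbeat interval.

    The template is built in velocity space from smoothstep ramps (so the
    first and second pressure derivatives each have exactly one clean local
    maximum at the foot and one at the notch), integrated, and normalized
    so the peak sits exactly PP above the onset pressure.  Diastole is a
    smooth decay whose amplitude is solved so pressure returns exactly to
    DAP at ``ibi0``.
    """
    params.validate()
    if ibi0 <= params.lvet + 0.05:
        raise ParameterError(
            f"ibi ({ibi0}) must exceed lvet + 0.05 s ({params.lvet + 0.05:.3f})"
        )
    p = params
    grid_t = np.arange(0.0, _TEMPLATE_SPAN_S, 1.0 / _GRID_RATE)
    dt = 1.0 / _GRID_RATE

    # solve the descent magnitude so the realized peak-to-notch drop /
    # peak ratio matches notch_depth / pp (scale-invariant target)
    target = p.notch_depth / p.pp

    def drop_ratio(s_down: float) -> float:
        v, _ = _build_velocity(p, s_down, grid_t)
        pr = cumulative_trapezoid(v, dx=dt, initial=0.0)
        peak = pr.max()
        i_n = int(round(p.lvet / dt))
        return (peak - pr[i_n]) / peak

    base = p.notch_depth / (p.lvet - p.t_peak)
    lo, hi = 0.2 * base, 6.0 * base
    from scipy.optimize import brentq
    try:
        s_down = brentq(lambda s: drop_ratio(s) - target, lo, hi, xtol=1e-3)
    except ValueError:
        # target unreachable within the bracket: use the closest endpoint
        s_down = lo if abs(drop_ratio(lo) - target) < abs(drop_ratio(hi) - target) else hi

    v, t_dic = _build_velocity(p, s_down, grid_t)
    pressure = cumulative_trapezoid(v, dx=dt, initial=0.0)

    # diastole: smooth decay velocity, amplitude solved so P(ibi0) == 0
    i_dic = int(round(t_dic / dt))
    tau = p.diastolic_decay_tau
    rel = grid_t[i_dic:] - t_dic
    q = (rel / _W_DIASTOLE_S) ** 2 / (1.0 + (rel / _W_DIASTOLE_S) ** 2) * np.exp(-rel / tau)
    q_int = cumulative_trapezoid(q, dx=dt, initial=0.0)
    i_end = int(round(ibi0 / dt)) - i_dic
    i_end = max(1, min(i_end, len(q_int) - 1))
    s_d = pressure[i_dic] / q_int[i_end]
    pressure[i_dic:] = pressure[i_dic] - s_d * q_int

    # normalize: peak exactly PP above onset
    pressure *= p.pp / pressure.max()

    i_pk = int(np.argmax(pressure))
    t_peak_num = _parabolic_vertex(grid_t, pressure, i_pk)
    dv = np.gradient(pressure, grid_t)
    i_mu = int(np.argmax(dv[: i_pk + 1]))
    t_mu_num = _parabolic_vertex(grid_t, dv, i_mu)

    return BeatTemplate(
        params=params, ibi0=ibi0, grid_t=grid_t, grid_v=pressure,
        t_peak=t_peak_num, t_max_up=t_mu_num, t_notch=p.lvet,
        v_peak=float(pressure[i_pk]),
    )


def _parabolic_vertex(t: np.ndarray, v: np.ndarray, i: int) -> float:
    """Sub-sample extremum location by a 3-point parabola around index i."""
    if i <= 0 or i >= len(v) - 1:
        return float(t[i])
    denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (v[i - 1] - v[i + 1]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(t[i] + delta * (t[1] - t[0]))


def render_beat(params: BeatTemplateParams, ibi: float, rate: float = 200.0) -> np.ndarray:
    """Render a single beat of ``ceil(ibi*rate)`` samples at the given rate."""
    template = build_template(params, ibi)
    n = math.ceil(ibi * rate)
    t = np.arange(n) / rate
    return params.dap + template(t)


# ---------------------------------------------------------------------------
# recording simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HemodynamicCouplings:
    """Beat-to-beat couplings and disturbance settings for one recording."""

    ibi0: float = 0.88               # nominal interbeat interval, s
    gain_ms_per_mmhg: float = 5.0    # baroreflex gain G: IBI response per mmHg SAP
    delay_s: float = 3.0             # baroreflex delay (rounded to whole beats)
    resp_amp_mmhg: float = 6.0       # respiratory baseline modulation amplitude
    resp_freq_hz: float = 0.25       # respiratory frequency
    noise_sd_mmhg: float = 1.0       # additive white observation noise
    time_jitter_sd: float = 0.015    # per-beat multiplicative timing jitter (rel.)
    amp_jitter_sd: float = 0.02      # per-beat multiplicative amplitude jitter (rel.)
    ibi_jitter_sd_s: float = 0.008   # per-beat additive IBI jitter, s


def simulate_recording(
    params: BeatTemplateParams,
    couplings: HemodynamicCouplings | None = None,
    duration: float = 300.0,
    seed: int = 0,
    rate: float = 200.0,
    patient_id: str = "sim",
) -> tuple[WaveformRecording, pd.DataFrame]:
    """Simulate one recording and its ground-truth beat log.

    The baroreflex coupling is ``IBI_n = IBI0 + G*(SAP_{n-d} - SAP0)`` with
    the configured gain (positive: higher pressure lengthens the interval)
    and delay rounded to whole beats; respiratory modulation is a baseline
    sinusoid; per-beat jitter scales the template in time and amplitude.

    Returns the recording and a DataFrame with one row per beat:
    ``onset_s, ibi_s, sap, t_sap_s, t_max_up_s, lvet_s``.
    """
    if duration < 180.0:
        raise ParameterError("duration must be at least 180 s")
    cpl = couplings or HemodynamicCouplings()
    rng = np.random.default_rng(seed)
    template = build_template(params, cpl.ibi0)
    g_s = cpl.gain_ms_per_mmhg / 1000.0
    sap0 = params.dap + template.v_peak
    d_beats = max(0, round(cpl.delay_s / cpl.ibi0))

    two_pi_f = 2.0 * math.pi * cpl.resp_freq_hz

    n_total = int(round(duration * rate))
    chunks: list[np.ndarray] = []
    truth_rows: list[tuple] = []
    sap_hist: list[float] = []
    onset_idx = 0
    while onset_idx < n_total:
        ts_n = max(0.8, 1.0 + rng.normal(0.0, cpl.time_jitter_sd))
        amp_n = max(0.5, 1.0 + rng.normal(0.0, cpl.amp_jitter_sd))
        n = len(sap_hist)
        if d_beats == 0:
            sap_ref = None  # filled in below once this beat's SAP is known
        elif n >= d_beats:
            sap_ref = sap_hist[n - d_beats]
        else:
            sap_ref = sap0

        onset_t = onset_idx / rate
        # this beat's SAP is known analytically before rendering
        sap_n = (
            params.dap
            + amp_n * template.v_peak
            + cpl.resp_amp_mmhg * math.sin(two_pi_f * (onset_t + ts_n * template.t_peak))
        )
        if sap_ref is None:
            sap_ref = sap_n
        ibi_n = cpl.ibi0 + g_s * (sap_ref - sap0) + rng.normal(0.0, cpl.ibi_jitter_sd_s)
        ibi_n = float(np.clip(ibi_n, params.lvet * max(ts_n, 1.0) + 0.08, 2.0))
        n_samp = max(1, round(ibi_n * rate))
        ibi_n = n_samp / rate  # quantize to the sample grid

        t_local = np.arange(n_samp) / rate
        v = amp_n * template(t_local / ts_n)
        # linear ramp so the beat lands exactly on DAP at the next onset
        v_end = amp_n * float(template(np.array([ibi_n / ts_n]))[0])
        v -= v_end * (np.arange(n_samp) / n_samp)
        chunks.append(v)

        sap_hist.append(sap_n)
        truth_rows.append((
            onset_t, ibi_n, sap_n,
            ts_n * template.t_peak, ts_n * template.t_max_up, ts_n * template.t_notch,
        ))
        onset_idx += n_samp

    signal = params.dap + np.concatenate(chunks)[:n_total]
    t_global = np.arange(len(signal)) / rate
    signal = signal + cpl.resp_amp_mmhg * np.sin(two_pi_f * t_global)
    if cpl.noise_sd_mmhg > 0:
        signal = signal + rng.normal(0.0, cpl.noise_sd_mmhg, size=len(signal))

    truth = pd.DataFrame(
        truth_rows,
        columns=["onset_s", "ibi_s", "sap", "t_sap_s", "t_max_up_s", "lvet_s"],
    )
    # drop the final (truncated) beat from the log if it ran past the end
    truth = truth[truth["onset_s"] + truth["ibi_s"] <= duration + 1e-9].reset_index(drop=True)
    rec = WaveformRecording(patient_id=patient_id, sample_rate=rate, pressure=signal)
    return rec, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: (median, q1, q3) per parameter; calibrated to the published group tables
CONTROL_GROUP: dict[str, tuple[float, float, float]] = {
    "age": (73, 68, 77),
    "weight": (83, 75, 92),
    "height": (176, 172, 179),
    "ibi": (0.88, 0.84, 0.95),
    "dap": (76, 72, 87),
    "pp": (80, 65, 88),
    "t_peak": (0.17, 0.15, 0.19),
    "t_max_up": (0.060, 0.053, 0.065),
    "lvet": (0.325, 0.310, 0.345),
    "notch_depth": (40, 33, 48),
    "dicrotic_wave_amp": (6.0, 4.5, 8.0),
    "decay_tau": (0.45, 0.40, 0.50),
    "xbrs_gain": (5.1, 3.4, 8.0),
    "duration": (400, 250, 600),
}

AOS_GROUP: dict[str, tuple[float, float, float]] = {
    "age": (78, 73, 83),
    "weight": (76, 70, 87),
    "height": (170, 164, 178),
    "ibi": (0.87, 0.77, 0.97),
    "dap": (75, 68, 81),
    "pp": (84, 67, 94),
    "t_peak": (0.20, 0.18, 0.23),
    "t_max_up": (0.075, 0.065, 0.091),
    "lvet": (0.345, 0.325, 0.365),
    "notch_depth": (44, 37, 52),
    "dicrotic_wave_amp": (5.0, 3.8, 6.8),
    "decay_tau": (0.45, 0.40, 0.50),
    "xbrs_gain": (4.7, 3.0, 7.3),
    "duration": (600, 435, 600),
}

FEMALE_FRAC = {"noAoS": 0.15, "AoS": 0.46}


@dataclass(frozen=True)
class CohortParams:
    """Two-group cohort settings; distributions default to the published tables."""

    n_aos: int = 101
    n_control: int = 48
    seed: int = 0
    rate: float = 200.0
    min_duration_s: float = 180.0
    max_duration_s: float = 600.0
    baroreflex_delay_s: float = 3.0
    resp_amp_mmhg: float = 6.0
    resp_freq_hz: float = 0.25
    noise_sd_mmhg: float = 1.0
    time_jitter_sd: float = 0.015
    amp_jitter_sd: float = 0.02
    ibi_jitter_sd_s: float = 0.008
    aos_dists: dict = field(default_factory=lambda: dict(AOS_GROUP))
    control_dists: dict = field(default_factory=lambda: dict(CONTROL_GROUP))


def _lognormal(rng: np.random.Generator, median: float, q1: float, q3: float) -> float:
    """Sample from a log-normal matched to the printed median and quartiles."""
    sigma = math.log(q3 / q1) / (2.0 * _Z75)
    return float(math.exp(math.log(median) + sigma * rng.standard_normal()))


def _draw(rng, dists, name):
    return _lognormal(rng, *dists[name])


def draw_patient(
    rng: np.random.Generator, label: str, cohort: CohortParams
) -> tuple[BeatTemplateParams, HemodynamicCouplings, float, dict]:
    """Draw one patient's template, couplings, duration and demographics."""
    dists = cohort.aos_dists if label == "AoS" else cohort.control_dists
    for _ in range(200):
        t_mu = max(0.03, _draw(rng, dists, "t_max_up"))
        t_pk = _draw(rng, dists, "t_peak")
        lvet = _draw(rng, dists, "lvet")
        pp = _draw(rng, dists, "pp")
        depth = _draw(rng, dists, "notch_depth")
        dic = _draw(rng, dists, "dicrotic_wave_amp")
        if t_mu < t_pk - 0.02 and t_pk < lvet - 0.05 and dic < depth - 1.0 and depth < pp - 5.0:
            break
    else:  # pragma: no cover - essentially unreachable with the defaults
        raise ParameterError("could not draw a feasible parameter set")
    params = BeatTemplateParams(
        dap=_draw(rng, dists, "dap"),
        pp=pp,
        t_peak=t_pk,
        t_max_up=t_mu,
        lvet=lvet,
        notch_depth=depth,
        dicrotic_wave_amp=dic,
        diastolic_decay_tau=_draw(rng, dists, "decay_tau"),
    )
    ibi0 = max(_draw(rng, dists, "ibi"), lvet + 0.15)
    couplings = HemodynamicCouplings(
        ibi0=ibi0,
        gain_ms_per_mmhg=_draw(rng, dists, "xbrs_gain"),
        delay_s=cohort.baroreflex_delay_s,
        resp_amp_mmhg=cohort.resp_amp_mmhg,
        resp_freq_hz=rng.uniform(0.9, 1.1) * cohort.resp_freq_hz,
        noise_sd_mmhg=cohort.noise_sd_mmhg,
        time_jitter_sd=cohort.time_jitter_sd,
        amp_jitter_sd=cohort.amp_jitter_sd,
        ibi_jitter_sd_s=cohort.ibi_jitter_sd_s,
    )
    duration = float(np.clip(_draw(rng, dists, "duration"),
                             cohort.min_duration_s, cohort.max_duration_s))
    demo = {
        "age": max(65.0, round(_draw(rng, dists, "age"))),
        "sex": "female" if rng.random() < FEMALE_FRAC[label] else "male",
        "height_cm": round(_draw(rng, dists, "height"), 1),
        "weight_kg": round(_draw(rng, dists, "weight"), 1),
    }
    return params, couplings, duration, demo


@dataclass
class SimulatedPatient:
    recording: WaveformRecording
    meta: PatientMeta
    truth: pd.DataFrame
    params: BeatTemplateParams
    couplings: HemodynamicCouplings


def simulate_cohort(cohort: CohortParams | None = None) -> list[SimulatedPatient]:
    """Simulate the full two-group cohort in memory.

    Patient order is all stenosis patients first, then controls; per-patient
    randomness is drawn from one seeded generator so the cohort is fully
    reproducible.
    """
    cohort = cohort or CohortParams()
    if cohort.n_aos < 1 or cohort.n_control < 1:
        raise ParameterError("need at least one patient per group")
    rng = np.random.default_rng(cohort.seed)
    patients: list[SimulatedPatient] = []
    for label, n, prefix in (("AoS", cohort.n_aos, "aos"), ("noAoS", cohort.n_control, "ctl")):
        for i in range(n):
            params, couplings, duration, demo = draw_patient(rng, label, cohort)
            pid = f"{prefix}_{i + 1:03d}"
            rec, truth = simulate_recording(
                params, couplings, duration=duration,
                seed=int(rng.integers(0, 2**31 - 1)), rate=cohort.rate, patient_id=pid,
            )
            meta = PatientMeta(patient_id=pid, label=label, **demo)
            patients.append(SimulatedPatient(rec, meta, truth, params, couplings))
    return patients


def write_cohort(patients: list[SimulatedPatient], out_dir) -> None:
    """Write waveform CSVs, the cohort manifest, and the ground-truth table."""
    from pathlib import Path

    from .io import write_waveform

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_frames = []
    for pat in patients:
        fname = f"{pat.meta.patient_id}.csv"
        write_waveform(pat.recording, out / fname)
        rows.append({
            "patient_id": pat.meta.patient_id,
            "waveform_path": fname,
            "age": pat.meta.age,
            "sex": pat.meta.sex,
            "height_cm": pat.meta.height_cm,
            "weight_kg": pat.meta.weight_kg,
            "label": pat.meta.label,
        })
        tf = pat.truth.copy()
        tf.insert(0, "patient_id", pat.meta.patient_id)
        truth_frames.append(tf)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False, lineterminator="\n")
    pd.concat(truth_frames, ignore_index=True).to_csv(
        out / "ground_truth.csv", index=False, lineterminator="\n"
    )
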