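"""End-to-end study pipeline: recordings -> features -> detection model.

``extract_summary`` turns one recording into its 27 x 5 age-adjusted
summary vector; ``WaveformFeaturizer`` exposes the same step as a
scikit-learn transformer; ``run_study`` executes the full protocol
(extract, summarize, age-adjust, stratified split, SMOTE, min-max
normalization, AUROC-optimized grid search, held-out evaluation) on a
cohort and returns the evaluation report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .beats import detect_beats, select_segment, smooth
from .config import PipelineConfig
from .features import extract_recording_features
from .io import PatientMeta, WaveformRecording
from .model import AoSDetector, EvaluationReport, SplitSpec, stratified_split
from .summary import FeatureSummary, age_adjust, build_design_matrix, summarize
from .xbrs import xbrs_from_beats

log = logging.getLogger(__name__)


def extract_beat_series(
    recording: WaveformRecording,
    meta: PatientMeta,
    config: PipelineConfig | None = None,
) -> dict[str, np.ndarray]:
    """Segment one recording and compute all 27 per-beat/per-window series."""
    cfg = config or PipelineConfig()
    segment = select_segment(
        recording,
        max_len=cfg.max_duration_s, min_len=cfg.min_duration_s,
        pressure_min=cfg.pressure_min, pressure_max=cfg.pressure_max,
        max_step=cfg.max_step_mmhg, truncate_from=cfg.truncate_from,
    )
    sm = smooth(segment, cfg.sg_window, cfg.sg_order)
    beats = detect_beats(segment, smoothed=sm, config=cfg)
    series = extract_recording_features(segment, beats, meta, smoothed=sm, config=cfg)
    xbrs = xbrs_from_beats(
        series.pop("_onset_s"), series.pop("_sap"), series.pop("_ibi"),
        window_s=cfg.xbrs_window_s, step_s=cfg.xbrs_step_s,
        resample_hz=cfg.xbrs_resample_hz, max_delay_s=cfg.xbrs_max_delay_s,
        alpha=cfg.xbrs_alpha, max_gap_s=cfg.xbrs_max_gap_s,
    )
    series.update(xbrs)
    return series


def extract_summary(
    recording: WaveformRecording,
    meta: PatientMeta,
    config: PipelineConfig | None = None,
    adjusted: bool = True,
) -> FeatureSummary:
    """One recording -> 27 x 5 summary statistics, age-adjusted by default."""
    cfg = config or PipelineConfig()
    series = extract_beat_series(recording, meta, cfg)
    summary = summarize(
        series, patient_id=meta.patient_id, age=meta.age, label=meta.label,
        deciles_of=cfg.deciles_of, min_entries=cfg.min_series_entries,
    )
    return age_adjust(summary) if adjusted else summary


class WaveformFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer mapping (recording, metadata) pairs to summary vectors.

    ``transform`` takes a list of ``(WaveformRecording, PatientMeta)`` and
    returns a patients x 135 DataFrame of age-adjusted statistics.  The
    transform is stateless; ``fit`` only validates parameters.
    """

    def __init__(self, config: PipelineConfig | None = None, adjusted: bool = True):
        self.config = config
        self.adjusted = adjusted

    def fit(self, X=None, y=None):
        self.config_ = self.config or PipelineConfig()
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit()
        summaries = [
            extract_summary(rec, meta, self.config_, adjusted=self.adjusted)
            for rec, meta in X
        ]
        frame = pd.DataFrame([s.values for s in summaries],
                             index=[s.patient_id for s in summaries])
        frame.index.name = "patient_id"
        return frame


@dataclass
class StudyResult:
    """Everything the full protocol produced for one seed."""

    report: EvaluationReport
    detector: AoSDetector
    summaries: list[FeatureSummary]
    train_ids: list[str]
    test_ids: list[str]
    X: pd.DataFrame
    y: np.ndarray


def run_study(
    cohort: list[tuple[WaveformRecording, PatientMeta]],
    config: PipelineConfig | None = None,
    seed: int = 0,
    feature_subset: list[str] | None = None,
    summaries: list[FeatureSummary] | None = None,
) -> StudyResult:
    """Run the full detection protocol on a cohort.

    ``summaries`` may be supplied to skip re-extraction (e.g. from a saved
    feature table); otherwise every recording is processed from scratch.
    """
    cfg = config or PipelineConfig()
    if summaries is None:
        summaries = [extract_summary(rec, meta, cfg) for rec, meta in cohort]
    X, y, ids = build_design_matrix(summaries, feature_subset=feature_subset)
    train_idx, test_idx = stratified_split(
        X.to_numpy(), y,
        SplitSpec(train_fraction=cfg.train_fraction, stratified=True, seed=seed),
    )
    detector = AoSDetector(
        smote_k=cfg.smote_k, cv_folds=cfg.cv_folds,
        threshold=cfg.decision_threshold, random_state=seed,
    )
    detector.fit(X.to_numpy()[train_idx], y[train_idx])
    report = detector.evaluate(X.to_numpy()[test_idx], y[test_idx])
    return StudyResult(
        report=report, detector=detector, summaries=summaries,
        train_ids=[ids[i] for i in train_idx], test_ids=[ids[i] for i in test_idx],
        X=X, y=y,
    )
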