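"""End-to-end analysis of one recording and of cohort manifests.

One recording: register -> extract ROI traces -> smooth/baseline/dF/F0 ->
detect events -> classify cells -> organoid summary. A cohort manifest
(organoid_id, group, path[, truth_path]) maps each recording through the
same chain and hands the per-organoid summaries to the group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .classify import ActivityClassifier, compare_groups, summarize_organoid
from .events import EventDetector
from .processing import TraceProcessor
from .registration import MotionCorrector
from .rois import extract_traces, grow_roi
from .types import CaEvent, CellActivityRecord, Movie, OrganoidSummary, ROI


@dataclass
class PipelineResult:
    """All artefacts of one recording's analysis."""

    summary: OrganoidSummary
    records: List[CellActivityRecord]
    events: List[CaEvent]
    dff: np.ndarray
    smoothed: np.ndarray
    f0: np.ndarray
    roi_ids: List[int]
    shifts: Optional[np.ndarray] = None


def analyze_movie(
    movie: Movie,
    rois: Optional[Sequence[ROI]] = None,
    seeds: Optional[np.ndarray] = None,
    organoid_id: str = "",
    group: str = "",
    register: bool = True,
    corrector: Optional[MotionCorrector] = None,
    processor: Optional[TraceProcessor] = None,
    detector: Optional[EventDetector] = None,
    classifier: Optional[ActivityClassifier] = None,
    roi_max_radius: int = 8,
    roi_tolerance: float = 0.3,
) -> PipelineResult:
    """Run the full chain on one movie.

    ROIs may be given directly or grown from ``seeds`` (n x 2 array of
    (row, col)) on the registered mean image.
    """
    fr = movie.frame_rate
    shifts = None
    if register and movie.n_frames > 1:
        corrector = corrector or MotionCorrector()
        movie = corrector.fit_transform(movie)
        shifts = corrector.shifts_.shifts
    if rois is None:
        if seeds is None:
            raise ValueError("either rois or seeds must be provided")
        mean_img = movie.frames.mean(axis=0)
        rois = [grow_roi(mean_img, tuple(s), max_radius=roi_max_radius,
                         tolerance=roi_tolerance, roi_id=i)
                for i, s in enumerate(np.atleast_2d(seeds))]
    traces = extract_traces(movie, rois)
    raw = np.stack([t.raw for t in traces])
    roi_ids = [t.roi_id for t in traces]
    return analyze_traces(raw, fr, roi_ids=roi_ids, organoid_id=organoid_id,
                          group=group, processor=processor, detector=detector,
                          classifier=classifier, shifts=shifts)


def analyze_traces(
    raw: np.ndarray,
    frame_rate: float,
    roi_ids: Optional[Sequence[int]] = None,
    organoid_id: str = "",
    group: str = "",
    processor: Optional[TraceProcessor] = None,
    detector: Optional[EventDetector] = None,
    classifier: Optional[ActivityClassifier] = None,
    shifts: Optional[np.ndarray] = None,
) -> PipelineResult:
    """Run smoothing -> baseline -> dF/F0 -> events -> classification."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if roi_ids is None:
        roi_ids = list(range(raw.shape[0]))
    processor = processor or TraceProcessor(frame_rate=frame_rate)
    detector = detector or EventDetector(frame_rate=frame_rate)
    classifier = classifier or ActivityClassifier(frame_rate=frame_rate)
    dff = processor.transform(raw)
    events_per_roi = detector.detect_all(dff, roi_ids=roi_ids)
    records = classifier.classify_all(dff, events=events_per_roi,
                                      roi_ids=roi_ids)
    summary = summarize_organoid(records, organoid_id=organoid_id,
                                 group=group)
    return PipelineResult(
        summary=summary,
        records=records,
        events=[e for evs in events_per_roi for e in evs],
        dff=dff,
        smoothed=processor.smoothed_,
        f0=processor.f0_,
        roi_ids=list(roi_ids),
        shifts=shifts,
    )


def analyze_cohort(
    manifest: pd.DataFrame,
    control: Optional[str] = None,
    measure: str = "active_cell_rate",
    method: str = "auto",
    **analysis_kwargs,
) -> tuple:
    """Analyse every recording in a manifest and compare the groups.

    Trace-bundle CSVs are analysed from the raw traces; TIFF/HDF5 movies
    additionally need ``seeds`` per recording (grown from truth centers is
    the caller's responsibility). Returns ``(summaries, stats_table)``.
    """
    summaries = []
    for row in manifest.itertuples():
        path = Path(row.path)
        if path.suffix == ".csv":
            raw, fr, ids = _io.read_traces_csv(path)
            res = analyze_traces(raw, fr, roi_ids=ids,
                                 organoid_id=row.organoid_id,
                                 group=row.group, **analysis_kwargs)
        else:
            movie = _io.read_movie(path)
            res = analyze_movie(movie, organoid_id=row.organoid_id,
                                group=row.group, **analysis_kwargs)
        summaries.append(res.summary)
    stats_table = compare_groups(summaries, measure=measure, control=control,
                                 method=method)
    return summaries, stats_table
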