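"""Active-cell classification and cohort summaries.

A cell is called *active* when all three of the following hold on its
dF/F0 series over the whole recording (strict inequalities):

1. skewness of the dF/F0 distribution > 1.0,
2. standard deviation of dF/F0 > 0.04,
3. at least one detected Ca2+ event.

Skewness is the biased moment (Fisher-Pearson g1) estimator; the SD uses
the n-1 denominator. Both are configurable. Per-recording summaries report
the active-cell rate (percent of ROIs active) and, over active cells, the
event frequency (events/min) and mean event amplitude.

Group comparisons follow the conventional design for this kind of study:
two groups are compared with a two-tailed Student's t-test (equal
variances); more than two groups with one-way ANOVA followed by Dunnett's
test against a named control (or Tukey's HSD over all pairs). The
statistical unit is the organoid for active-cell rates and the cell for
frequency and amplitude.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .events import EventDetector, event_rate, mean_amplitude
from .types import CaEvent, CellActivityRecord, OrganoidSummary, Trace

__all__ = [
    "ActivityClassifier",
    "is_active",
    "classify_cell",
    "summarize_organoid",
    "compare_groups",
]

SKEW_THRESHOLD = 1.0
SD_THRESHOLD = 0.04
MIN_EVENTS = 1


def is_active(skewness: float, sd: float, n_events: int,
              skew_threshold: float = SKEW_THRESHOLD,
              sd_threshold: float = SD_THRESHOLD,
              min_events: int = MIN_EVENTS) -> bool:
    """The three-criterion predicate; thresholds are strict inequalities."""
    return (skewness > skew_threshold) and (sd > sd_threshold) \
        and (n_events >= min_events)


class ActivityClassifier(BaseEstimator):
    """Classify ROIs as active/inactive from their dF/F0 series.

    Parameters
    ----------
    skew_threshold : float, default 1.0
    sd_threshold : float, default 0.04
    min_events : int, default 1
    biased_skew : bool, default True
        Fisher-Pearson g1 (biased moment) estimator; set False for the
        bias-corrected form.
    frame_rate : float, default 30.0
        Used to convert event counts into events/min.
    """

    def __init__(self, skew_threshold: float = SKEW_THRESHOLD,
                 sd_threshold: float = SD_THRESHOLD,
                 min_events: int = MIN_EVENTS,
                 biased_skew: bool = True,
                 frame_rate: float = 30.0):
        self.skew_threshold = skew_threshold
        self.sd_threshold = sd_threshold
        self.min_events = min_events
        self.biased_skew = biased_skew
        self.frame_rate = frame_rate

    def classify(self, dff: np.ndarray, events: Sequence[CaEvent],
                 roi_id: int = 0) -> CellActivityRecord:
        """Per-cell statistics and verdict for one dF/F0 series."""
        dff = np.asarray(dff, dtype=float)
        if dff.ndim != 1 or dff.size < 3:
            raise ValueError(
                "dff must be 1-D with at least 3 samples (skewness is "
                "undefined otherwise)"
            )
        skewness = float(stats.skew(dff, bias=self.biased_skew))
        sd = float(np.std(dff, ddof=1))
        n_events = len(events)
        duration = dff.size / self.frame_rate
        active = is_active(skewness, sd, n_events,
                           self.skew_threshold, self.sd_threshold,
                           self.min_events)
        return CellActivityRecord(
            roi_id=roi_id,
            skewness=skewness,
            sd=sd,
            n_events=n_events,
            active=active,
            frequency=event_rate(events, duration),
            mean_amplitude=mean_amplitude(events) if n_events else None,
        )

    def predict(self, dff_matrix: np.ndarray,
                events: Optional[Sequence[Sequence[CaEvent]]] = None,
                detector: Optional[EventDetector] = None) -> np.ndarray:
        """Boolean active/inactive labels for rows of a dF/F0 matrix.

        Events are detected with ``detector`` (default parameters if None)
        unless pre-computed event lists are supplied.
        """
        recs = self.classify_all(dff_matrix, events=events, detector=detector)
        return np.array([r.active for r in recs])

    def classify_all(self, dff_matrix: np.ndarray,
                     events: Optional[Sequence[Sequence[CaEvent]]] = None,
                     detector: Optional[EventDetector] = None,
                     roi_ids: Optional[Sequence[int]] = None
                     ) -> List[CellActivityRecord]:
        dff_matrix = np.atleast_2d(np.asarray(dff_matrix, dtype=float))
        if events is None:
            if detector is None:
                detector = EventDetector(frame_rate=self.frame_rate)
            events = detector.detect_all(dff_matrix)
        if roi_ids is None:
            roi_ids = range(dff_matrix.shape[0])
        return [self.classify(row, ev, roi_id=rid)
                for row, ev, rid in zip(dff_matrix, events, roi_ids)]


def classify_cell(trace: Trace, events: Sequence[CaEvent],
                  **params) -> CellActivityRecord:
    """Classify one processed trace (dff channel required)."""
    if trace.dff is None:
        raise ValueError("trace has no dff channel; run TraceProcessor first")
    clf = ActivityClassifier(**{"frame_rate": trace.frame_rate, **params})
    return clf.classify(trace.dff, events, roi_id=trace.roi_id)


def summarize_organoid(records: Sequence[CellActivityRecord],
                       organoid_id: str = "", group: str = "",
                       active_only: bool = True) -> OrganoidSummary:
    """Roll one recording's cell records up into an organoid summary.

    ``active_only`` restricts the frequency/amplitude vectors to active
    cells (the convention for reporting per-cell transient statistics);
    set False to include every cell with at least one event.
    """
    if len(records) == 0:
        raise ValueError("cannot summarise an empty record list")
    n_rois = len(records)
    n_active = sum(r.active for r in records)
    pool = [r for r in records if (r.active if active_only else r.n_events)]
    freqs = np.array([r.frequency for r in pool], dtype=float)
    amps = np.array([r.mean_amplitude for r in pool
                     if r.mean_amplitude is not None], dtype=float)
    return OrganoidSummary(
        organoid_id=organoid_id,
        group=group,
        n_rois=n_rois,
        n_active=n_active,
        active_cell_rate=100.0 * n_active / n_rois,
        frequencies=freqs,
        amplitudes=amps,
    )


def _collect_measure(summaries: Sequence[OrganoidSummary], measure: str,
                     group: str) -> np.ndarray:
    subset = [s for s in summaries if s.group == group]
    if measure == "active_cell_rate":
        return np.array([s.active_cell_rate for s in subset], dtype=float)
    if measure == "frequency":
        return np.concatenate([s.frequencies for s in subset]) \
            if subset else np.empty(0)
    if measure == "amplitude":
        return np.concatenate([s.amplitudes for s in subset]) \
            if subset else np.empty(0)
    raise ValueError(f"unknown measure {measure!r}")


def compare_groups(summaries: Sequence[OrganoidSummary],
                   measure: str = "active_cell_rate",
                   control: Optional[str] = None,
                   method: str = "auto") -> pd.DataFrame:
    """Compare groups on a summary measure.

    measure : {"active_cell_rate", "frequency", "amplitude"}
        active_cell_rate uses organoids as units; frequency/amplitude pool
        cells across an entire group.
    method : {"auto", "ttest", "dunnett", "tukey"}
        "auto" picks Student's t for two groups and ANOVA + Dunnett
        (control required) for more.

    Returns a tidy table with group means/SDs/n and one row per comparison
    (test name, statistic, p-value). For >2 groups the one-way ANOVA row is
    included ahead of the per-comparison rows.
    """
    groups = list(dict.fromkeys(s.group for s in summaries))
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    data = {g: _collect_measure(summaries, measure, g) for g in groups}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(
                f"group {g!r} has {v.size} unit(s); at least 2 are needed "
                f"for a variance estimate"
            )
    desc = {g: (float(np.mean(v)), float(np.std(v, ddof=1)), int(v.size))
            for g, v in data.items()}

    if method == "auto":
        method = "ttest" if len(groups) == 2 else "dunnett"

    rows = []

    def _row(test, comparison, statistic, p):
        rows.append({
            "test": test, "comparison": comparison, "measure": measure,
            "statistic": float(statistic), "p_value": float(p),
            "significant": bool(p < 0.05),
        })

    if method == "ttest":
        if len(groups) != 2:
            raise ValueError("Student's t-test needs exactly two groups")
        a, b = (data[g] for g in groups)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        _row("student_t", f"{groups[0]} vs {groups[1]}", t, p)
    elif method in ("dunnett", "tukey"):
        f, p_anova = stats.f_oneway(*(data[g] for g in groups))
        _row("anova", " vs ".join(groups), f, p_anova)
        if method == "dunnett":
            if control is None:
                raise ValueError("Dunnett's test needs an explicit control "
                                 "group label")
            if control not in groups:
                raise ValueError(f"control group {control!r} not found")
            treat = [g for g in groups if g != control]
            res = stats.dunnett(*(data[g] for g in treat),
                                control=data[control])
            for g, t, p in zip(treat, res.statistic, res.pvalue):
                _row("dunnett", f"{g} vs {control}", t, p)
        else:
            res = stats.tukey_hsd(*(data[g] for g in groups))
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    _row("tukey_hsd", f"{groups[i]} vs {groups[j]}",
                         res.statistic[i, j], res.pvalue[i, j])
    else:
        raise ValueError(f"unknown method {method!r}")

    table = pd.DataFrame(rows)
    for g in groups:
        m, sd, n = desc[g]
        table[f"mean_{g}"] = m
        table[f"sd_{g}"] = sd
        table[f"n_{g}"] = n
    return table
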