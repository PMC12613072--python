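"""Active-cell criteria, organoid summaries and group statistics."""

import numpy as np
import pytest

from organoid_calcium import (
    ActivityClassifier,
    CaEvent,
    CellActivityRecord,
    OrganoidSummary,
    SynthConfig,
    analyze_traces,
    compare_groups,
    generate_traces,
    is_active,
    summarize_organoid,
)


def fake_event(frame=100, height=0.5):
    return CaEvent(roi_id=0, peak_frame=frame, peak_time=frame / 30.0,
                   height=height, width=20.0, prominence=height)


class TestCriteria:
    def test_symmetric_distribution_is_inactive(self, rng):
        """Skewness ~0 fails criterion 1 regardless of SD and events."""
        dff = rng.normal(0, 0.5, 4000)
        clf = ActivityClassifier()
        rec = clf.classify(dff, [fake_event()])
        assert abs(rec.skewness) < 0.5
        assert not rec.active

    def test_constant_series_is_inactive(self):
        rec = ActivityClassifier().classify(np.full(100, 0.1),
                                            [fake_event()])
        assert rec.sd < 1e-12
        assert not rec.active

    def test_boundary_values_are_strict(self):
        """Skewness exactly 1.0 or SD exactly 0.04 fails (strict >)."""
        assert not is_active(1.0, 0.10, 3)
        assert not is_active(2.0, 0.04, 3)
        assert not is_active(2.0, 0.10, 0)
        assert is_active(1.0 + 1e-12, 0.04 + 1e-12, 1)

    def test_event_criterion_requires_detected_event(self, rng):
        # strongly skewed, high-SD series but no events -> inactive
        dff = np.abs(rng.standard_cauchy(1000)) * 0.1
        rec = ActivityClassifier().classify(dff, [])
        assert rec.n_events == 0 and not rec.active

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            ActivityClassifier().classify(np.zeros(2), [])

    def test_active_cell_has_defined_amplitude(self):
        rng = np.random.default_rng(1)
        dff = np.zeros(2000)
        dff[500:540] = 0.5  # one strong transient
        dff += rng.normal(0, 0.01, 2000)
        rec = ActivityClassifier().classify(dff, [fake_event(520)])
        assert rec.active
        assert rec.mean_amplitude == pytest.approx(0.5)
        assert rec.frequency == pytest.approx(1 / (2000 / 30 / 60))

    def test_determinism(self, rng):
        dff = rng.normal(0, 0.1, 500) ** 2
        ev = [fake_event()]
        r1 = ActivityClassifier().classify(dff, ev)
        r2 = ActivityClassifier().classify(dff, ev)
        assert r1 == r2

    def test_classification_recovery_on_labeled_cohort(self):
        """Synthetic 50-cell organoid with known labels: accuracy >= 95%."""
        cfg = SynthConfig(n_cells=50, active_fraction=0.2, seed=13)
        raw, truth = generate_traces(cfg)
        res = analyze_traces(raw, cfg.frame_rate)
        pred = np.array([r.active for r in res.records])
        assert (pred == truth.labels).mean() >= 0.95


class TestSummaries:
    def _records(self, actives, n=10):
        recs = []
        for i in range(n):
            active = i < actives
            recs.append(CellActivityRecord(
                roi_id=i, skewness=2.0 if active else 0.0,
                sd=0.1 if active else 0.01,
                n_events=2 if active else 0, active=active,
                frequency=1.0 if active else 0.0,
                mean_amplitude=0.5 if active else None))
        return recs

    def test_rate_arithmetic(self):
        s = summarize_organoid(self._records(2), "o1", "NC")
        assert s.active_cell_rate == 20.0
        assert s.n_active == 2 and s.n_rois == 10

    def test_zero_active_gives_empty_vectors(self):
        s = summarize_organoid(self._records(0), "o1", "NC")
        assert s.active_cell_rate == 0.0
        assert s.frequencies.size == 0 and s.amplitudes.size == 0

    def test_active_only_pooling_switch(self):
        recs = self._records(3)
        s_active = summarize_organoid(recs, active_only=True)
        assert s_active.frequencies.size == 3
        # include every cell with >= 1 event when switched off
        recs.append(CellActivityRecord(roi_id=99, skewness=0.5, sd=0.1,
                                       n_events=1, active=False,
                                       frequency=0.5, mean_amplitude=0.3))
        s_all = summarize_organoid(recs, active_only=False)
        assert s_all.frequencies.size == 4

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_organoid([])


def _summary(org, group, rate):
    n = 20
    n_active = int(round(rate / 100 * n))
    return OrganoidSummary(organoid_id=org, group=group, n_rois=n,
                          n_active=n_active, active_cell_rate=rate)


class TestGroupComparison:
    def test_identical_groups_give_t0_p1(self):
        summaries = [_summary(f"a{i}", "A", r) for i, r in
                     enumerate([10, 20, 30])]
        summaries += [_summary(f"b{i}", "B", r) for i, r in
                      enumerate([10, 20, 30])]
        table = compare_groups(summaries)
        assert table.iloc[0]["statistic"] == pytest.approx(0.0)
        assert table.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        summaries = [_summary(f"a{i}", "A", r) for i, r in
                     enumerate([5, 10, 15])]
        summaries += [_summary(f"b{i}", "B", r) for i, r in
                      enumerate([65, 70, 75])]
        table = compare_groups(summaries)
        assert table.iloc[0]["p_value"] < 0.05
        assert bool(table.iloc[0]["significant"])

    def test_closed_form_t_statistic(self):
        """Equal-n pooled-variance Student's t reproduced by hand."""
        a, b = [10.0, 20.0, 30.0], [40.0, 50.0, 60.0]
        summaries = [_summary(f"a{i}", "A", r) for i, r in enumerate(a)]
        summaries += [_summary(f"b{i}", "B", r) for i, r in enumerate(b)]
        table = compare_groups(summaries)
        sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        t_manual = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * 2 / 3)
        assert table.iloc[0]["statistic"] == pytest.approx(t_manual)

    def test_dunnett_has_one_row_per_treatment(self):
        summaries = []
        rng = np.random.default_rng(0)
        for g, base in [("ctrl", 20), ("t1", 25), ("t2", 40), ("t3", 60)]:
            for i in range(4):
                summaries.append(_summary(f"{g}{i}", g,
                                          base + 5 * rng.random()))
        table = compare_groups(summaries, control="ctrl", method="dunnett")
        dunnett_rows = table[table["test"] == "dunnett"]
        assert len(dunnett_rows) == 3
        assert all("vs ctrl" in c for c in dunnett_rows["comparison"])
        assert (table["test"] == "anova").sum() == 1

    def test_tukey_covers_all_pairs(self):
        summaries = []
        for g, base in [("A", 20), ("B", 30), ("C", 40)]:
            for i in range(3):
                summaries.append(_summary(f"{g}{i}", g, base + i))
        table = compare_groups(summaries, method="tukey")
        assert (table["test"] == "tukey_hsd").sum() == 3

    def test_dunnett_requires_control(self):
        summaries = [_summary(f"{g}{i}", g, 20.0 + i)
                     for g in "ABC" for i in range(3)]
        with pytest.raises(ValueError, match="control"):
            compare_groups(summaries, method="dunnett")

    def test_single_unit_group_rejected(self):
        summaries = [_summary("a0", "A", 10), _summary("a1", "A", 20),
                     _summary("b0", "B", 30)]
        with pytest.raises(ValueError, match="unit"):
            compare_groups(summaries)

    def test_one_group_rejected(self):
        summaries = [_summary(f"a{i}", "A", 10.0 + i) for i in range(3)]
        with pytest.raises(ValueError, match="two groups"):
            compare_groups(summaries)
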