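"""Event detection semantics: findpeaks-compatible criteria."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from organoid_calcium import (
    EventDetector,
    SynthConfig,
    Trace,
    event_rate,
    find_events,
    generate_trace,
    mean_amplitude,
    process_trace,
)
from conftest import gaussian_bump, random_dff_like
from oracles import brute_force_find_events


def detect(x, **kw):
    params = dict(min_height=0.2, min_distance=30, min_width=15)
    params.update(kw)
    return EventDetector(**params).detect(np.asarray(x, dtype=float))


class TestBasicSemantics:
    def test_flat_trace_has_no_events(self):
        assert detect(np.zeros(500)) == []

    def test_single_broad_bump_one_event_height_exact(self):
        x = gaussian_bump(600, 300, 0.5, fwhm=40)
        events = detect(x)
        assert len(events) == 1
        assert events[0].height == pytest.approx(0.5, abs=1e-12)
        assert events[0].peak_frame == 300

    def test_subthreshold_bump_rejected(self):
        x = gaussian_bump(600, 300, 0.15, fwhm=40)
        assert detect(x) == []

    def test_close_pair_keeps_taller(self):
        x = gaussian_bump(600, 300, 0.5, fwhm=18) \
            + gaussian_bump(600, 320, 0.4, fwhm=18)
        events = detect(x)
        assert len(events) == 1
        assert abs(events[0].peak_frame - 300) <= 2

    def test_plateau_peak_at_center(self):
        x = np.zeros(200)
        x[90:101] = 0.5  # 11-sample plateau, center 95
        events = detect(x, min_width=1, min_distance=1)
        assert len(events) == 1
        assert events[0].peak_frame == 95

    def test_events_sorted_and_separated(self):
        x = sum(gaussian_bump(3000, c, 0.3 + 0.01 * i, fwhm=30)
                for i, c in enumerate(range(100, 2900, 200)))
        events = detect(x)
        frames = [e.peak_frame for e in events]
        assert frames == sorted(frames)
        assert np.all(np.diff(frames) >= 30)

    def test_missing_dff_channel_rejected(self):
        tr = Trace(raw=np.zeros(100), frame_rate=30.0)
        with pytest.raises(ValueError, match="dff"):
            find_events(tr)


class TestBoundaryCompatibility:
    """Hand-constructed traces around each printed criterion boundary."""

    @pytest.mark.parametrize("height,expected", [(0.19, 0), (0.21, 1)])
    def test_min_peak_height_boundary(self, height, expected):
        x = gaussian_bump(600, 300, height, fwhm=60)
        assert len(detect(x)) == expected

    @pytest.mark.parametrize("fwhm,expected", [(14, 0), (16, 1)])
    def test_min_peak_width_boundary(self, fwhm, expected):
        # bump baseline at zero: prominence = height, so FWHM is the width
        # at half prominence
        x = gaussian_bump(600, 300, 0.5, fwhm=fwhm)
        assert len(detect(x)) == expected

    @pytest.mark.parametrize("gap,expected", [(29, 1), (31, 2)])
    def test_min_peak_distance_boundary(self, gap, expected):
        # compact trapezoid pulses: wide enough at half prominence (~19
        # frames) yet non-overlapping, so only the distance rule decides
        def trapezoid(n, center, height, plateau=15, ramp=4):
            x = np.zeros(n)
            half = plateau // 2
            x[center - half: center + half + 1] = height
            for k in range(1, ramp + 1):
                x[center - half - k] = height * (1 - k / (ramp + 1))
                x[center + half + k] = height * (1 - k / (ramp + 1))
            return x

        x = trapezoid(900, 300, 0.5) + trapezoid(900, 300 + gap, 0.45)
        events = detect(x)
        assert len(events) == expected
        assert any(e.peak_frame == 300 for e in events)


class TestOracleEquivalence:
    def test_matches_bruteforce_on_random_traces(self, rng):
        """Implementation and brute-force enumeration agree event-for-event
        on random smooth traces, including plateau/tie cases."""
        for i in range(150):
            n = int(rng.integers(50, 2000))
            x = random_dff_like(rng, n, quantize=(i % 5 == 0))
            got = detect(x)
            expected = brute_force_find_events(x, 0.2, 30, 15)
            assert [(e.peak_frame, e.height) for e in got] == \
                [(p, h) for p, h, _ in expected], f"trace {i}"
            np.testing.assert_allclose(
                [e.width for e in got], [w for _, _, w in expected],
                rtol=1e-9, atol=1e-9)

    @given(st.integers(0, 500))
    def test_raising_height_threshold_never_adds_events(self, seed):
        rng = np.random.default_rng(seed)
        x = random_dff_like(rng, 600)
        counts = [len(detect(x, min_height=h))
                  for h in (0.05, 0.2, 0.4, 0.8)]
        assert counts == sorted(counts, reverse=True)


class TestRatesAndAmplitudes:
    def test_event_rate_arithmetic(self):
        events = detect(sum(gaussian_bump(3600, c, 0.5, fwhm=30)
                            for c in (400, 1300, 2200, 3100)))
        assert len(events) == 4
        assert event_rate(events, 120.0) == pytest.approx(2.0)

    def test_zero_events_rate_zero(self):
        assert event_rate([], 60.0) == 0.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            event_rate([], 0.0)

    def test_mean_amplitude_values(self):
        x = gaussian_bump(900, 200, 0.4, fwhm=30) \
            + gaussian_bump(900, 600, 0.6, fwhm=30)
        events = detect(x)
        assert mean_amplitude(events) == pytest.approx(0.5, abs=1e-6)
        assert mean_amplitude(events[:1]) == pytest.approx(
            events[0].height)

    def test_mean_amplitude_undefined_for_no_events(self):
        with pytest.raises(ValueError, match="undefined"):
            mean_amplitude([])

    def test_detection_recall_precision_on_synthetic_cells(self):
        """Well-separated synthetic events (amplitude >= 0.4) are found
        with recall and precision >= 0.9 against ground truth."""
        from organoid_calcium import GroundTruth

        rng = np.random.default_rng(99)
        cfg = SynthConfig(n_frames=3600, noise_sd=2.0, seed=0)
        tp = fp = fn = 0
        for _ in range(20):
            # events at least 2*min_distance apart
            times = np.sort(rng.uniform(5, cfg.duration - 15, 4))
            while np.any(np.diff(times) < 2 * 30 / cfg.frame_rate + 10):
                times = np.sort(rng.uniform(5, cfg.duration - 15, 4))
            amps = rng.uniform(0.4, 0.8, times.size)
            truth = GroundTruth(labels=np.array([True]),
                                event_times=[times],
                                event_amplitudes=[amps])
            trace, _ = generate_trace(cfg, truth=truth,
                                      rng=np.random.default_rng(rng.integers(2**31)))
            events = find_events(process_trace(trace))
            matched = set()
            for e in events:
                cand = [i for i, t in enumerate(times)
                        if i not in matched
                        and abs(e.peak_time - t) <= 3 * cfg.decay_tau]
                if cand:
                    matched.add(cand[0])
                    tp += 1
                else:
                    fp += 1
            fn += times.size - len(matched)
        assert tp / (tp + fn) >= 0.9  # recall
        assert tp / (tp + fp) >= 0.9  # precision
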