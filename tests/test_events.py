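import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ictalmea.errors import ConfigError
from ictalmea.events import (
    EpileptiformEvent,
    MaxIntervalParams,
    classify_events,
    classify_onset,
    detect_discharges,
    group_maxed_interval,
    summarize_epoch,
)
from ictalmea.synthetic import RecordingConfig, _render_source_trace, PlantedEvent

from _reference import reference_maxed_interval


class TestDetectDischarges:
    def test_all_zero_trace_empty(self):
        assert detect_discharges(np.zeros(1000), 1000.0).size == 0

    def test_noiseless_planted_spikes(self):
        fs = 1000.0
        trace = np.zeros(4000)
        for t in (1.0, 2.0, 3.0):
            trace[int(t * fs)] = -50.0
        times = detect_discharges(trace, fs)
        assert np.allclose(times, [1.0, 2.0, 3.0], atol=1.5 / fs)

    def test_refractory_collapses_close_spikes(self):
        fs = 1000.0
        trace = np.zeros(2000)
        trace[500] = -40.0
        trace[510] = -30.0  # 10 ms later
        assert detect_discharges(trace, fs, refractory_s=0.05).size == 1

    def test_detection_time_is_local_peak(self):
        fs = 1000.0
        trace = np.zeros(2000)
        trace[700] = -20.0
        trace[705] = -60.0  # the larger deflection wins
        times = detect_discharges(trace, fs, refractory_s=0.05)
        assert times.size == 1 and times[0] == pytest.approx(0.705)


DEFAULT = dict(max_begin=0.5, max_end=0.5, min_ibi=1.0, min_duration=0.3, min_count=3)


def _params(**kw):
    d = dict(DEFAULT, **kw)
    return MaxIntervalParams(
        max_begin_isi_s=d["max_begin"],
        max_end_isi_s=d["max_end"],
        min_ibi_s=d["min_ibi"],
        min_event_duration_s=d["min_duration"],
        min_discharges=d["min_count"],
        ile_min_duration_s=max(d["min_duration"], 0.3),
    )


class TestMaxedInterval:
    def test_empty_input(self):
        assert group_maxed_interval(np.array([]), _params()) == []

    def test_hand_traced_two_events(self):
        t = np.array([0.0, 0.2, 0.4, 5.0, 5.2, 5.4, 5.6])
        events = group_maxed_interval(t, _params())
        assert len(events) == 2
        (s0, e0, m0), (s1, e1, m1) = events
        assert (s0, e0, len(m0)) == (0.0, 0.4, 3)
        assert (s1, e1, len(m1)) == (5.0, 5.6, 4)

    def test_hand_traced_merge(self):
        t = np.array([0.0, 0.2, 0.4, 5.0, 5.2, 5.4, 5.6])
        events = group_maxed_interval(t, _params(min_ibi=5.0))
        assert len(events) == 1
        s, e, m = events[0]
        assert (s, e, len(m)) == (0.0, 5.6, 7)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ConfigError):
            group_maxed_interval(np.array([1.0, 0.5]), _params())

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 60))
        times = np.sort(rng.uniform(0, 30, size=n)).round(3)
        times = np.unique(times)
        mb, me = rng.uniform(0.05, 2.0, size=2)
        ibi = rng.uniform(0.1, 5.0)
        dur = rng.uniform(0.0, 3.0)
        cnt = int(rng.integers(2, 6))
        p = MaxIntervalParams(
            max_begin_isi_s=mb, max_end_isi_s=me, min_ibi_s=ibi,
            min_event_duration_s=max(dur, 1e-6), min_discharges=cnt,
            ile_min_duration_s=max(dur, 1e-6),
        )
        got = group_maxed_interval(times, p)
        want = reference_maxed_interval(times, mb, me, ibi, max(dur, 1e-6), cnt)
        assert len(got) == len(want)
        for (gs, ge, gm), (ws, we, wm) in zip(got, want):
            assert gs == ws and ge == we
            assert np.allclose(gm, wm)

    @given(seed=st.integers(0, 2_000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_min_discharges(self, seed):
        rng = np.random.default_rng(seed)
        times = np.unique(np.sort(rng.uniform(0, 20, size=40)))
        counts = [
            len(group_maxed_interval(times, _params(min_count=k, min_duration=0.1)))
            for k in (2, 4, 6, 8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_events_disjoint_and_sorted(self):
        rng = np.random.default_rng(5)
        times = np.unique(np.sort(rng.uniform(0, 60, size=200)))
        events = group_maxed_interval(times, _params(min_duration=0.1, min_count=2))
        for (s0, e0, _), (s1, e1, _) in zip(events, events[1:]):
            assert e0 < s1


class TestClassifyEvents:
    def test_long_event_is_single_ile(self):
        members = np.linspace(0.0, 20.0, 61)
        grouped = {0: [(0.0, 20.0, members)]}
        events = classify_events(grouped, {0: members})
        assert [e.kind for e in events] == ["ILE"]

    def test_isolated_singles_in_ile_free_source_kept_as_iilds(self):
        singles = np.array([10.0, 50.0, 90.0])
        events = classify_events({1: []}, {1: singles})
        assert [e.kind for e in events] == ["IILD"] * 3
        assert not any(e.excluded for e in events)

    def test_iild_soon_after_ile_same_source_excluded(self):
        members = np.linspace(0.0, 20.0, 61)
        d = np.concatenate([members, [50.0]])
        events = classify_events(
            {0: [(0.0, 20.0, members)]}, {0: d},
            postictal_exclusion_s=60.0, iild_requires_ile_free_source=False,
        )
        iilds = [e for e in events if e.kind == "IILD"]
        assert len(iilds) == 1 and iilds[0].excluded

    def test_any_iild_on_ile_source_excluded_by_default(self):
        members = np.linspace(0.0, 20.0, 61)
        d = np.concatenate([members, [200.0]])
        events = classify_events({0: [(0.0, 20.0, members)]}, {0: d})
        iilds = [e for e in events if e.kind == "IILD"]
        assert len(iilds) == 1 and iilds[0].excluded


def _planted_trace(onset_class: str, fs: float = 1000.0, seed: int = 0):
    """Render one ILE with a planted onset class on a clean source trace."""
    cfg = RecordingConfig(fs_hz=fs)
    rng = np.random.default_rng(seed)
    dur = 20.0
    rate = 3.0
    if onset_class == "LVF":
        rel = np.concatenate([[0.05, 1.0], np.arange(cfg.lvf_onset_s, dur, 1.0 / rate)])
    else:
        rel = np.arange(0.0, dur, 1.0 / rate)
    ev = PlantedEvent(
        source=0, kind="ILE", epoch="baseline", start_s=30.0, end_s=30.0 + dur,
        discharge_times_s=30.0 + rel, onset_class=onset_class, preictal_times_s=np.array([]),
    )
    trace = _render_source_trace(cfg, [ev], int(60.0 * fs), fs, rng)
    trace += 10.0 * rng.standard_normal(trace.size)  # channel-level noise floor
    det = EpileptiformEvent(
        source=0, kind="ILE", start_s=float(ev.discharge_times_s[0]),
        end_s=float(ev.discharge_times_s[-1]), discharge_times_s=ev.discharge_times_s,
    )
    return det, trace


class TestClassifyOnset:
    def test_planted_lvf_recovered(self):
        det, trace = _planted_trace("LVF")
        assert classify_onset(det, trace, 1000.0) == "LVF"

    def test_planted_hypersynchronous_recovered(self):
        det, trace = _planted_trace("hypersynchronous")
        assert classify_onset(det, trace, 1000.0) == "hypersynchronous"

    def test_flat_onset_unclassified(self):
        fs = 1000.0
        trace = np.zeros(40_000)
        d = 10.0 + np.arange(0.0, 20.0, 0.4)
        for t in d[5:]:
            trace[int(t * fs)] = -100.0
        ev = EpileptiformEvent(source=0, kind="ILE", start_s=10.0, end_s=30.0, discharge_times_s=d)
        assert classify_onset(ev, trace, fs) == "unclassified"

    def test_window_past_trace_end_unclassified(self):
        ev = EpileptiformEvent(source=0, kind="ILE", start_s=1.0, end_s=12.0,
                               discharge_times_s=np.linspace(1, 12, 30))
        assert classify_onset(ev, np.zeros(2000), 1000.0) == "unclassified"


class _FakeModel:
    """Minimal stand-in with the SourceModel surface summarize_epoch needs."""

    def __init__(self, n_ics=2, n_electrodes=59):
        self.weights = np.zeros((n_ics, n_electrodes))
        self.weights[:, :21] = 1.0
        self.n_ics = n_ics


class TestSummarizeEpoch:
    def test_no_events_reports_zeros_without_activity(self):
        df = summarize_epoch([], _FakeModel(), ("baseline", 0.0, 1200.0))
        assert len(df) == 1
        row = df.iloc[0]
        assert row.n_ile_per_20min == 0 and row.mean_ile_duration_s == 0
        assert not row.had_activity

    def test_arithmetic_over_three_iles(self):
        events = []
        for start, dur, n in ((10.0, 10.0, 30), (100.0, 20.0, 60), (300.0, 30.0, 90)):
            events.append(
                EpileptiformEvent(
                    source=0, kind="ILE", start_s=start, end_s=start + dur,
                    discharge_times_s=np.linspace(start, start + dur, n),
                )
            )
        df = summarize_epoch(events, _FakeModel(), ("baseline", 0.0, 1200.0))
        row = df.iloc[0]
        assert row.n_ile_per_20min == pytest.approx(3.0)
        assert row.mean_ile_duration_s == pytest.approx(20.0)
        assert row.within_ile_discharge_freq_hz == pytest.approx(3.0)
        assert row.ile_spatial_extent_electrodes == 21
        assert row.had_activity

    def test_count_normalized_to_20_minutes(self):
        ev = EpileptiformEvent(source=0, kind="ILE", start_s=10.0, end_s=30.0,
                               discharge_times_s=np.linspace(10, 30, 60))
        df = summarize_epoch([ev], _FakeModel(), ("baseline", 0.0, 600.0))
        assert df.iloc[0].n_ile_per_20min == pytest.approx(2.0)

    def test_time_shift_invariance(self):
        def metrics(offset):
            ev = EpileptiformEvent(
                source=0, kind="ILE", start_s=10.0 + offset, end_s=30.0 + offset,
                discharge_times_s=np.linspace(10 + offset, 30 + offset, 60),
            )
            return summarize_epoch([ev], _FakeModel(), ("baseline", offset, 1200.0 + offset)).iloc[0]
        a, b = metrics(0.0), metrics(500.0)
        for col in ("n_ile_per_20min", "mean_ile_duration_s", "within_ile_discharge_freq_hz"):
            assert a[col] == pytest.approx(b[col])

    def test_zero_length_epoch_rejected(self):
        with pytest.raises(ConfigError):
            summarize_epoch([], _FakeModel(), ("baseline", 5.0, 5.0))
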