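import numpy as np
import pytest

import polku as pk
from polku.corrections import EfretTrace
from tests.conftest import make_trajectory

DT = 0.2


def brute_force_coloc_spans(x, threshold, min_frames=2, merge_gap=2):
    """Independent frame-by-frame scanner for colocalization events."""
    n = len(x)
    spans = []
    i = 0
    while i < n:
        if x[i] > threshold:
            start = end = i
            gap = 0
            j = i + 1
            while j < n:
                if x[j] > threshold:
                    end = j
                    gap = 0
                else:
                    gap += 1
                    if gap > merge_gap:
                        break
                j += 1
            if end - start + 1 >= min_frames:
                spans.append((start, end))
            i = end + 1
        else:
            i += 1
    return spans


def brute_force_fret_spans(e, valid, e_min=0.3, e_max=0.8, min_frames=5,
                           max_duration_s=20.0, merge_gap=4, dt=DT):
    """Independent scanner for FRET events (band runs, merge, filters)."""
    n = len(e)
    ok = [bool(valid[i]) and e_min <= e[i] <= e_max
          if not np.isnan(e[i]) else False for i in range(n)]
    spans = []
    i = 0
    while i < n:
        if ok[i]:
            start = end = i
            j = i + 1
            gap_frames = []
            while j < n:
                if ok[j]:
                    end = j
                    gap_frames = []
                else:
                    gap_frames.append(j)
                    if (len(gap_frames) > merge_gap
                            or not valid[j]):  # cannot bridge invalid frames
                        break
                j += 1
            spans.append((start, end))
            i = end + 1
        else:
            i += 1
    kept = []
    for start, end in spans:
        nf = end - start + 1
        if nf < min_frames or nf * dt >= max_duration_s:
            continue
        t = np.arange(start, end + 1) * dt
        if np.polyfit(t, e[start:end + 1], 1)[0] >= 0:
            continue
        kept.append((start, end))
    return kept


class TestCallColocalization:
    def test_single_run_duration(self):
        x = np.zeros(40)
        x[10:21] = 100.0
        events = pk.call_colocalization(make_trajectory(x), 50.0)
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_frame, ev.end_frame) == (10, 20)
        assert ev.duration_s == pytest.approx(11 * DT)
        assert ev.mean_partner_intensity == pytest.approx(100.0)

    def test_single_frame_spike_is_not_an_event(self):
        x = np.zeros(30)
        x[12] = 200.0
        assert pk.call_colocalization(make_trajectory(x), 50.0) == []

    def test_two_frame_gap_merges_runs(self):
        x = np.zeros(20)
        x[1:6] = 120.0
        x[8:13] = 120.0
        events = pk.call_colocalization(make_trajectory(x), 50.0)
        assert len(events) == 1
        assert (events[0].start_frame, events[0].end_frame) == (1, 12)

    def test_three_frame_gap_keeps_events_separate(self):
        x = np.zeros(20)
        x[1:6] = 120.0
        x[9:14] = 120.0
        events = pk.call_colocalization(make_trajectory(x), 50.0)
        assert [(e.start_frame, e.end_frame) for e in events] == [(1, 5), (9, 13)]

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            pk.call_colocalization(make_trajectory(np.zeros(5)), 0.0)

    def test_matches_brute_force_scanner_on_random_traces(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(5, 120)
            x = rng.choice([0.0, 30.0, 60.0, 200.0], size=n,
                           p=[0.4, 0.2, 0.2, 0.2])
            events = pk.call_colocalization(make_trajectory(x), 50.0)
            got = [(e.start_frame, e.end_frame) for e in events]
            assert got == brute_force_coloc_spans(x, 50.0)

    def test_events_ordered_and_non_overlapping(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.choice([0.0, 200.0], size=200, p=[0.6, 0.4])
            events = pk.call_colocalization(make_trajectory(x), 50.0)
            for a, b in zip(events, events[1:]):
                assert a.end_frame < b.start_frame - 2  # >= 3-frame separation

    def test_idempotence_on_called_event(self):
        x = np.zeros(50)
        x[7:23] = 150.0
        (event,) = pk.call_colocalization(make_trajectory(x), 50.0)
        sub = x[event.start_frame:event.end_frame + 1]
        (again,) = pk.call_colocalization(make_trajectory(sub), 50.0)
        assert (again.start_frame, again.end_frame) == (0, len(sub) - 1)


def _trace(e, valid=None):
    e = np.asarray(e, dtype=float)
    if valid is None:
        valid = ~np.isnan(e)
    return EfretTrace(0, np.arange(e.size) * DT, e,
                      np.asarray(valid, bool), (e >= 0) & (e <= 1), DT)


class TestCallFretEvents:
    def test_linear_ramp_truncated_at_band_floor(self):
        e = np.linspace(0.6, 0.2, 10)  # crosses 0.3 before the end
        events = pk.call_fret_events(_trace(e), merge_gap=0,
                                     delta_mode="endpoint")
        assert len(events) == 1
        ev = events[0]
        assert ev.start_frame == 0
        assert e[ev.end_frame] >= 0.3 > e[ev.end_frame + 1]
        assert ev.slope < 0
        assert ev.delta_e == pytest.approx(e[0] - e[ev.end_frame])

    def test_constant_efficiency_rejected_for_zero_slope(self):
        assert pk.call_fret_events(_trace(np.full(10, 0.6))) == []

    def test_long_events_rejected(self):
        e = np.linspace(0.75, 0.35, 125)  # 25 s at 0.2 s per frame
        assert pk.call_fret_events(_trace(e)) == []
        shorter = np.linspace(0.75, 0.35, 90)  # 18 s: retained
        assert len(pk.call_fret_events(_trace(shorter))) == 1

    def test_out_of_band_frames_excluded(self):
        e = np.concatenate([np.full(4, 0.9), np.linspace(0.7, 0.4, 8)])
        (ev,) = pk.call_fret_events(_trace(e))
        assert ev.start_frame == 4

    def test_invalid_gap_frames_break_events(self):
        e = np.concatenate([np.linspace(0.7, 0.6, 6), [0.1, 0.1],
                            np.linspace(0.55, 0.35, 6)])
        valid = np.ones(e.size, bool)
        valid[6:8] = False
        events = pk.call_fret_events(_trace(e, valid))
        assert [(ev.start_frame, ev.end_frame) for ev in events] == [
            (0, 5), (8, 13)]

    def test_matches_brute_force_scanner_on_random_traces(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = rng.integers(6, 150)
            e = rng.choice([0.1, 0.35, 0.55, 0.75, 0.95], size=n)
            e += rng.normal(0, 0.02, size=n)
            valid = rng.random(n) > 0.1
            events = pk.call_fret_events(_trace(e, valid))
            got = [(ev.start_frame, ev.end_frame) for ev in events]
            assert got == brute_force_fret_spans(e, valid)

    def test_delta_modes_agree_on_clean_staircase(self):
        e = np.concatenate([np.full(8, 0.6), np.full(8, 0.5), np.full(8, 0.4)])
        for mode, expected in [("endpoint", 0.2), ("plateau", 0.2)]:
            (ev,) = pk.call_fret_events(_trace(e), delta_mode=mode)
            assert ev.delta_e == pytest.approx(expected, abs=1e-9)

    def test_plateau_delta_counts_step_below_band(self):
        """The final step that leaves the band is included in delta_e."""
        e = np.concatenate([np.full(6, 0.6), np.full(6, 0.4),
                            np.full(8, 0.2)])
        (ev,) = pk.call_fret_events(_trace(e), delta_mode="plateau")
        assert ev.delta_e == pytest.approx(0.4, abs=1e-9)
        (ev,) = pk.call_fret_events(_trace(e), delta_mode="endpoint")
        assert ev.delta_e == pytest.approx(0.2, abs=1e-9)


class TestFirstBindingTimes:
    def test_first_event_and_censoring(self):
        x = np.zeros(200)
        x[62:80] = 100.0   # first event starts at 12.4 s
        x[150:170] = 100.0
        events = {0: pk.call_colocalization(make_trajectory(x), 50.0),
                  1: []}
        firsts = pk.first_binding_times(events, observation_window=180.0)
        by_id = {fb.molecule_id: fb for fb in firsts}
        assert by_id[0].time_s == pytest.approx(12.4)
        assert not by_id[0].censored
        assert by_id[1].censored
        assert by_id[1].time_s == pytest.approx(180.0)

    def test_binder_fraction_recovered(self, alone_scenario):
        """The fraction of molecules ever binding matches the 67% plateau."""
        scen = alone_scenario.replace(n_molecules=500, seed=31)
        trajset, _ = pk.simulate_colocalization(scen)
        events = pk.call_colocalization_set(trajset, 50.0)
        firsts = pk.first_binding_times(events, scen.movie_length)
        frac = np.mean([not fb.censored for fb in firsts])
        # binders may still be unbound at the end of the 180 s window
        expected = scen.bound_fraction * -np.expm1(
            -scen.k_bind * scen.movie_length)
        se = np.sqrt(expected * (1 - expected) / scen.n_molecules)
        assert frac == pytest.approx(expected, abs=3 * se)


def test_truth_recovery_on_noiseless_colocalization(ku_scenario):
    """Called events match ground-truth binding intervals frame-for-frame."""
    scen = ku_scenario.replace(n_molecules=40, seed=17, background=0.0)
    trajset, truth = pk.simulate_colocalization(scen, noiseless=True)
    dt = scen.frame_interval
    checked = 0
    for traj in trajset:
        true_events = [ev for ev in truth
                       if ev.molecule_id == traj.molecule_id]
        gaps = [b.t_start - a.t_end
                for a, b in zip(true_events, true_events[1:])]
        if any(g < 5 * dt for g in gaps):
            continue  # nearly touching truth events pair ambiguously
        if any(ev.t_end - ev.t_start < 2 * dt for ev in true_events):
            continue  # sub-frame dwells may never cross the photon threshold
        events = pk.call_colocalization(traj, 50.0, merge_gap=0, min_frames=1)
        assert len(events) == len(true_events)
        for ev, tru in zip(events, true_events):
            assert ev.start_frame == pytest.approx(tru.t_start / dt, abs=1)
            assert ev.end_frame + 1 == pytest.approx(tru.t_end / dt, abs=1)
            checked += 1
    assert checked >= 20


def test_events_to_csv_round_trip(tmp_path):
    x = np.zeros(60)
    x[5:25] = 150.0
    events = pk.call_colocalization(make_trajectory(x), 50.0)
    path = tmp_path / "events.csv"
    pk.events_to_csv(events, path)
    import pandas as pd
    df = pd.read_csv(path)
    assert df.loc[0, "start_frame"] == 5
    assert df.loc[0, "duration_s"] == pytest.approx(4.0)
    pk.events_to_csv([], path)
    assert pd.read_csv(path).empty
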