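"""Dot-probe measures: response filtering, fixation detection, bias scores."""

import numpy as np
import pandas as pd
import pytest

from pupilbias.gazedpt import (AOILayout, FixationEvent, detect_fixations,
                               dpt_fixations, dwell_time_bias,
                               filter_responses, first_fixation_bias,
                               rt_bias, sample_velocities)

DT = 1000.0 / 600.0


def _trials(rows):
    return pd.DataFrame(rows, columns=["participant_id", "task", "trial",
                                       "target_on", "rt_ms", "correct",
                                       "practice"])


# ---------------------------------------------------------------------------
# response filtering and RT bias
# ---------------------------------------------------------------------------

def test_response_filter_boundaries():
    trials = _trials([
        ("p", "DPT", 0, "NRS", 90.0, True, False),    # anticipation
        ("p", "DPT", 1, "NRS", 100.0, True, False),   # exactly at boundary
        ("p", "DPT", -1, "NRS", 500.0, True, True),   # practice
        ("p", "DPT", 2, "control", 480.0, True, False),
    ])
    kept = filter_responses(trials)
    assert kept["trial"].tolist() == [1, 2]


@pytest.mark.parametrize("ctrl, nrs, expected", [
    ([547.0, 547.0], [538.0, 538.0], 9.0),    # smokers' descriptives
    ([540.0, 540.0], [537.0, 537.0], 3.0),    # non-smokers'
    ([500.0], [500.0], 0.0),
])
def test_rt_bias_is_control_minus_nrs(ctrl, nrs, expected):
    rows = ([("p", "DPT", i, "control", v, True, False)
             for i, v in enumerate(ctrl)]
            + [("p", "DPT", 100 + i, "NRS", v, True, False)
               for i, v in enumerate(nrs)])
    assert rt_bias(_trials(rows)) == pytest.approx(expected)


def test_rt_bias_missing_condition_gives_nan():
    only_nrs = _trials([("p", "DPT", 0, "NRS", 500.0, True, False)])
    assert np.isnan(rt_bias(only_nrs))
    # incorrect responses never enter the means
    mixed = _trials([("p", "DPT", 0, "NRS", 500.0, False, False),
                     ("p", "DPT", 1, "control", 600.0, True, False)])
    assert np.isnan(rt_bias(mixed))


# ---------------------------------------------------------------------------
# fixation detection
# ---------------------------------------------------------------------------

def _stationary(n, x, y, jitter=0.0, rng=None):
    gx = np.full(n, float(x))
    gy = np.full(n, float(y))
    if jitter and rng is not None:
        gx = gx + rng.normal(0, jitter, n)
        gy = gy + rng.normal(0, jitter, n)
    return gx, gy


def test_stationary_gaze_yields_single_full_fixation():
    n = 120  # 200 ms at 600 Hz
    t = np.arange(n) * DT
    gx, gy = _stationary(n, 1.0, -0.5)
    events = detect_fixations(t, gx, gy)
    assert len(events) == 1
    assert events[0].duration_ms == pytest.approx(200.0)
    assert events[0].centroid_x_deg == pytest.approx(1.0)
    assert events[0].centroid_y_deg == pytest.approx(-0.5)


def test_short_plateau_between_saccades_not_emitted():
    # 100 ms at A, 30 ms at B, 100 ms at C with instantaneous jumps
    seg = [(60, 0.0), (18, 5.0), (60, -5.0)]  # 18 samples = 30 ms
    gx = np.concatenate([np.full(n, x) for n, x in seg])
    t = np.arange(gx.size) * DT
    events = detect_fixations(t, gx, np.zeros_like(gx))
    assert len(events) == 2
    assert all(abs(e.centroid_x_deg) > 4 or abs(e.centroid_x_deg) < 1
               for e in events)
    assert not any(4.0 < e.centroid_x_deg < 6.0 and e.duration_ms < 40
                   for e in events)


def _oracle_fixations(t, x, y, threshold, min_dur=40.0, smooth=3):
    """Independent sample-wise velocity classifier (explicit loops)."""
    n = t.size
    speed = np.empty(n)
    for i in range(1, n):
        dt_s = (t[i] - t[i - 1]) / 1000.0
        speed[i] = np.hypot(x[i] - x[i - 1], y[i] - y[i - 1]) / dt_s
    speed[0] = speed[1]
    sm = np.empty(n)
    half = smooth // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sm[i] = speed[lo:hi].mean()
    slow = sm < threshold
    events, i = [], 0
    dt = float(np.median(np.diff(t)))
    while i < n:
        if slow[i]:
            j = i
            while j + 1 < n and slow[j + 1]:
                j += 1
            if t[j] - t[i] + dt >= min_dur:
                events.append((t[i], t[j] + dt,
                               x[i:j + 1].mean(), y[i:j + 1].mean()))
            i = j + 1
        else:
            i += 1
    return events


@pytest.mark.parametrize("threshold", [10.0, 30.0, 100.0])
def test_detector_matches_sample_wise_oracle(threshold, rng):
    """On noise-free synthetic gaze with a 500 deg/s step between two
    plateaus, the detector equals a brute-force velocity classification."""
    plateaus = [(90, -5.0, 0.0), (4, 0.0, 0.0), (150, 5.0, 1.0),
                (30, 0.0, 0.0), (200, -5.0, -1.0)]
    gx = np.concatenate([np.full(n, x) for n, x, _ in plateaus])
    gy = np.concatenate([np.full(n, y) for n, _, y in plateaus])
    t = np.arange(gx.size) * DT
    got = detect_fixations(t, gx, gy, velocity_threshold=threshold)
    expected = _oracle_fixations(t, gx, gy, threshold)
    assert len(got) == len(expected)
    for e, (on, off, cx, cy) in zip(got, expected):
        assert e.onset_ms == pytest.approx(on)
        assert e.offset_ms == pytest.approx(off)
        assert e.centroid_x_deg == pytest.approx(cx)
        assert e.centroid_y_deg == pytest.approx(cy)


def test_fully_missing_window_warns_and_returns_empty():
    t = np.arange(60) * DT
    with pytest.warns(UserWarning, match="fully missing"):
        events = detect_fixations(t, np.full(60, np.nan), np.full(60, np.nan))
    assert events == []


def test_gap_interpolation_feeds_detector():
    n = 300
    t = np.arange(n) * DT
    gx = np.full(n, 5.0)
    gx[100:140] = np.nan  # blink inside a fixation
    events = detect_fixations(t, gx, np.zeros(n))
    assert len(events) == 1
    assert events[0].duration_ms == pytest.approx(n * DT)


# ---------------------------------------------------------------------------
# AOI bias scores
# ---------------------------------------------------------------------------

LAYOUT = AOILayout()


def _fix(x, dur=300.0, onset=200.0):
    return FixationEvent(onset, onset + dur, x, 0.0)


def test_first_fixation_bias_extremes_and_table_values():
    all_nrs = [[_fix(5.0)] for _ in range(10)]
    assert first_fixation_bias(all_nrs, ["right"] * 10) == 1.0
    # 49 NRS-first vs 51 control-first trials -> -0.02
    trials = ([[_fix(5.0)] for _ in range(49)]
              + [[_fix(-5.0)] for _ in range(51)])
    bias = first_fixation_bias(trials, ["right"] * 100)
    assert bias == pytest.approx(-0.02)
    even = [[_fix(5.0)] for _ in range(5)] + [[_fix(-5.0)] for _ in range(5)]
    assert first_fixation_bias(even, ["right"] * 10) == 0.0


def test_first_fixation_skips_central_fixations():
    # central fixation first, then NRS: counts as NRS-first
    trials = [[_fix(0.0), _fix(5.0)]]
    assert first_fixation_bias(trials, ["right"]) == 1.0
    assert np.isnan(first_fixation_bias([[_fix(0.0)]], ["right"]))


def test_dwell_bias_arithmetic():
    # one trial: 513 ms on NRS, 502 ms on control -> +11 ms
    trial = [FixationEvent(0, 513, 5.0, 0.0),
             FixationEvent(600, 1102, -5.0, 0.0)]
    assert dwell_time_bias([trial], ["right"]) == pytest.approx(11.0)
    single = [FixationEvent(0, 300, 5.0, 0.0)]
    assert dwell_time_bias([single], ["right"]) == pytest.approx(300.0)
    balanced = [FixationEvent(0, 400, 5.0, 0.0),
                FixationEvent(500, 900, -5.0, 0.0)]
    assert dwell_time_bias([balanced], ["right"]) == 0.0


def test_one_sided_fixations_give_consistent_maximal_biases():
    trials = [[_fix(5.0, dur=500.0)] for _ in range(8)]
    sides = ["right"] * 8
    assert first_fixation_bias(trials, sides) == 1.0
    assert dwell_time_bias(trials, sides) == pytest.approx(500.0)


def test_aoi_layout_geometry():
    assert LAYOUT.side_of(5.0, 0.0) == "right"
    assert LAYOUT.side_of(-5.0, 2.0) == "left"
    assert LAYOUT.side_of(0.0, 0.0) is None      # central cross
    assert LAYOUT.side_of(5.0, 3.0) is None      # above the image
    with pytest.raises(Exception):
        AOILayout(center_x=1.0)                  # regions would overlap


# ---------------------------------------------------------------------------
# integration with generated streams
# ---------------------------------------------------------------------------

def test_generated_dpt_dwell_never_exceeds_cue_window(tiny_dataset,
                                                      tiny_config):
    streams, trials, _ = tiny_dataset
    dpt = next(s for s in streams if s.task == "DPT")
    mine = trials.loc[trials["participant_id"] == dpt.participant_id]
    fixes, sides = dpt_fixations(dpt, mine)
    assert len(fixes) == tiny_config.dpt_trials
    for trial_fixes in fixes:
        total = sum(f.duration_ms for f in trial_fixes)
        assert total <= tiny_config.cue_ms + 1e-6
        for a, b in zip(trial_fixes, trial_fixes[1:]):
            assert a.offset_ms <= b.onset_ms  # ordered, non-overlapping
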