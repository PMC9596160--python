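"""Touch-response scoring, freezing detection, novel-tank metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arborquant.behavior import (
    Trajectory,
    detect_freezing,
    group_session_stats,
    habituation_series,
    sessions_to_frame,
    tank_session,
    touch_response,
)
from arborquant.syndata import SynthTrajectorySpec, generate_trajectory


# ---------------------------------------------------------------------------
# touch assay

def _trace(moving_spans, n=1050):
    tr = np.zeros(n, dtype=bool)
    for a, b in moving_spans:
        tr[a:b + 1] = True
    return tr


def test_single_run_response_time():
    resp = touch_response(_trace([(10, 60)]))
    assert resp.responded
    assert resp.response_time_s == pytest.approx(1.0)
    assert resp.n_bouts == 1


def test_two_bouts_with_short_gap_span_one_response():
    # gap of 8 frames: below the >15-frame termination but above the
    # 5-frame bout separator -> 2 bouts, response spans both runs
    resp = touch_response(_trace([(10, 40), (49, 79)]))
    assert resp.n_bouts == 2
    assert resp.response_time_s == pytest.approx((79 - 10) / 50.0)


def test_gap_longer_than_termination_ends_response():
    resp = touch_response(_trace([(10, 40), (60, 80)]))
    assert resp.response_time_s == pytest.approx((40 - 10) / 50.0)
    assert resp.n_bouts == 1


def test_no_movement_is_non_responder():
    resp = touch_response(_trace([]))
    assert not resp.responded
    assert np.isnan(resp.response_time_s)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.booleans(), min_size=2, max_size=200))
def test_bout_count_matches_run_length_encoding_oracle(bits):
    trace = np.array(bits, dtype=bool)
    resp = touch_response(trace, stim_frame=0, pause_frames=10 ** 6, bout_gap_frames=5)
    # oracle: RLE over the whole trace (termination disabled)
    runs = []
    i = 0
    while i < len(trace):
        if trace[i]:
            j = i
            while j + 1 < len(trace) and trace[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if not runs:
        assert not resp.responded
    else:
        bouts = 1
        for (a1, b1), (a2, b2) in zip(runs, runs[1:]):
            if a2 - b1 - 1 > 5:
                bouts += 1
        assert resp.n_bouts == bouts


# ---------------------------------------------------------------------------
# freezing

def _traj_from_speeds(step_cm, fps=10.0, w=30.0, h=20.0):
    x = np.concatenate([[5.0], 5.0 + np.cumsum(step_cm)])
    df = pd.DataFrame(dict(t_s=np.arange(len(x)) / fps, x_cm=x, y_cm=np.full(len(x), 5.0)))
    return Trajectory(df, fps, w, h)


def test_exact_3s_immobility_is_a_bout_but_2p9_is_not():
    # displacement per frame: 0.3 cm while swimming (3 cm/s at 10 fps),
    # exactly 0 while immobile; an immobile stretch of n frames lasts
    # n/fps seconds (boundary inclusive at 3.0 s)
    fps = 10
    swim = [0.3] * 30
    for immobile_frames, expect in [(30, 1), (29, 0)]:
        steps = swim + [0.0] * (immobile_frames - 1) + swim
        traj = _traj_from_speeds(np.array(steps), fps=fps)
        bouts = detect_freezing(traj, speed_eps_cm_s=0.2, min_freeze_s=3.0)
        assert len(bouts) == expect, f"{immobile_frames} frames"
        if expect:
            assert bouts[0].duration_s == pytest.approx(3.0)


def test_programmed_bouts_recovered_with_frame_accuracy():
    hits, total_gt, total_det = 0, 0, 0
    for s in range(10):
        spec = SynthTrajectorySpec(seed=s, duration_s=300, jitter_cm_s=0.05)
        traj, gt = generate_trajectory(spec)
        T = Trajectory(traj, spec.fps, *spec.tank_size_cm)
        bouts = detect_freezing(T)
        tru = gt.freeze_bouts
        total_gt += len(tru)
        total_det += len(bouts)
        for b, r in zip(bouts, tru.itertuples()):
            if (abs(b.start_s - r.start_s) <= 1.0 / spec.fps + 1e-9
                    and abs(b.end_s - r.end_s) <= 1.0 / spec.fps + 1e-9):
                hits += 1
    assert total_gt == total_det == hits
    assert total_gt >= 10


# ---------------------------------------------------------------------------
# tank sessions

def test_fish_staying_low_never_enters_upper():
    spec = SynthTrajectorySpec(upper_zone_preference=0.0, duration_s=120, seed=1)
    traj, _ = generate_trajectory(spec)
    s = tank_session(Trajectory(traj, spec.fps, *spec.tank_size_cm))
    assert not s.entered_upper
    assert s.latency_to_upper_s is None
    assert s.pct_time_upper == 0.0


def test_constant_swimmer_total_equals_mobile():
    fps = 10.0
    n = 600
    df = pd.DataFrame(dict(t_s=np.arange(n) / fps,
                           x_cm=np.cumsum(np.full(n, 2.0 / fps)),
                           y_cm=np.full(n, 5.0)))
    s = tank_session(Trajectory(df, fps, 1e9, 20.0))
    assert s.total_velocity_cm_s == pytest.approx(2.0)
    assert s.mobile_velocity_cm_s == pytest.approx(2.0)
    assert s.n_freeze_bouts == 0


def test_half_frozen_session_velocity_arithmetic():
    fps = 10.0
    half = 900  # 90 s
    moving = np.cumsum(np.full(half, 2.0 / fps))
    frozen = np.full(half, moving[-1])
    x = np.concatenate([moving, frozen])
    df = pd.DataFrame(dict(t_s=np.arange(2 * half) / fps, x_cm=x,
                           y_cm=np.full(2 * half, 5.0)))
    s = tank_session(Trajectory(df, fps, 1e9, 20.0))
    assert s.total_velocity_cm_s == pytest.approx(1.0, rel=0.02)
    assert s.mobile_velocity_cm_s == pytest.approx(2.0, rel=0.02)
    assert s.froze and s.total_frozen_s >= 80.0


def test_zone_times_conserve_session_length_and_mobile_ge_total():
    for s in range(12):
        spec = SynthTrajectorySpec(seed=s, duration_s=180,
                                   upper_zone_preference=0.4)
        traj, _ = generate_trajectory(spec)
        summ = tank_session(Trajectory(traj, spec.fps, *spec.tank_size_cm))
        assert summ.time_in_upper_s + summ.time_in_lower_s == pytest.approx(
            summ.session_length_s, abs=1e-9)
        assert summ.mobile_velocity_cm_s >= summ.total_velocity_cm_s - 1e-9


# ---------------------------------------------------------------------------
# groups and habituation

def _fake_sessions(froze_flags, entered_flags, group, day=None):
    rows = []
    for i, (f, e) in enumerate(zip(froze_flags, entered_flags)):
        rows.append(dict(
            entered_upper=bool(e), latency_to_upper_s=50.0 if e else None,
            time_in_upper_s=14.0 if e else 0.0, time_in_lower_s=166.0,
            pct_time_upper=7.8 if e else 0.0, n_freeze_bouts=int(f),
            total_frozen_s=20.0 if f else 0.0, froze=bool(f),
            total_velocity_cm_s=2.0, mobile_velocity_cm_s=2.5,
            session_length_s=180.0, group=group,
            day=(day if day is not None else i % 3),
        ))
    return rows


def test_group_percentages():
    rows = _fake_sessions([0] * 11, [1] * 10 + [0], "wt")
    res = group_session_stats(pd.DataFrame(rows), day_col="day")
    assert res["per_group"]["wt"]["pct_entered_upper"] == pytest.approx(100 * 10 / 11)
    assert res["per_group"]["wt"]["pct_froze"] == 0.0


def test_freeze_power_at_novel_tank_design():
    # freeze probabilities 0.43 vs 0.03 at n=30 vs 39: detected at
    # alpha=0.05 in >= 90% of 200 replicates
    rng = np.random.default_rng(99)
    rejections = 0
    for _ in range(200):
        wt = _fake_sessions(rng.random(30) < 0.43, np.ones(30), "mut")
        mut = _fake_sessions(rng.random(39) < 0.03, np.ones(39), "wt")
        res = group_session_stats(pd.DataFrame(wt + mut))
        p = res["tests"].set_index("metric").loc["froze", "p"]
        rejections += p < 0.05
    assert rejections >= 180


def test_habituation_flat_when_sessions_identical():
    rows = []
    for exp in range(1, 7):
        for r in _fake_sessions([1, 0, 0], [1, 1, 0], "wt"):
            r["exposure"] = exp
            rows.append(r)
    res = habituation_series(pd.DataFrame(rows))
    assert res["curves"].pct_froze.nunique() == 1


def test_habituation_decreasing_freeze_probability_trend():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(5)
    neg = 0
    reps = 100
    for _ in range(reps):
        rows = []
        for exp, p_freeze in enumerate([0.8, 0.65, 0.5, 0.35, 0.2, 0.1], start=1):
            for r in _fake_sessions(rng.random(20) < p_freeze, np.ones(20), "wt"):
                r["exposure"] = exp
                rows.append(r)
        curves = habituation_series(pd.DataFrame(rows))["curves"]
        rho, _ = spearmanr(curves.exposure, curves.pct_froze)
        neg += rho < 0
    assert neg >= 95


def test_habituation_missing_exposure_is_null_not_zero():
    rows = []
    for exp in (1, 2, 4, 5, 6):
        for r in _fake_sessions([1, 0], [1, 1], "wt"):
            r["exposure"] = exp
            rows.append(r)
    # exposure 3 untrackable for everyone
    for r in _fake_sessions([1, 1], [1, 1], "wt"):
        r["exposure"] = 3
        r["untrackable"] = True
        rows.append(r)
    res = habituation_series(pd.DataFrame(rows))
    assert res["n_omitted"] == 2
    assert 3 not in res["curves"].exposure.values
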