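"""Larval touch-response and adult novel-tank behavioral metrics.

Larval touch assay: high-speed video at 50 fps (1050 frames, 21 s); the
response time runs from the first movement after the touch to the
cessation of movement for more than 15 frames; swim bouts are maximal
movement runs separated by more than a short inter-bout gap (~5 frames —
distinct from the 15-frame termination criterion, since inter-bout pauses
last only ~7–8 frames).  Larvae that never move are non-responders and
are excluded from summaries.

Novel tank diving test: an adult fish is introduced to an unfamiliar
tank and tracked; metrics are latency to first enter the upper half,
cumulative upper-zone time, freezing (immobility for at least 3 s),
total swim velocity, and mobile-only velocity (excluding frozen /
zero-speed periods).  Habituation: the same metrics across six repeated
exposures.

Trajectories are inputs (produced upstream by an automated tracker after
first-frame background subtraction of the video); digitized tracks are
never exactly at 0 cm/s, so immobility uses a small configurable speed
threshold (default 0.2 cm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import medfilt

from .errors import ConfigError
from .stats import choose_test

TOUCH_FPS = 50.0
TOUCH_FRAMES = 1050
FREEZE_MIN_S = 3.0
SPEED_EPS_CM_S = 0.2


# ---------------------------------------------------------------------------
# larval touch assay

@dataclass
class TouchResponse:
    responded: bool
    response_time_s: float = np.nan
    n_bouts: int = 0


def _runs(mask: np.ndarray):
    """(start, end) index pairs (inclusive) of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def touch_response(trace, stim_frame: int = 0, fps: float = TOUCH_FPS,
                   pause_frames: int = 15, bout_gap_frames: int = 5) -> TouchResponse:
    """Score one touch trial from a per-frame movement trace.

    ``trace`` is boolean (moving) or numeric (displacement, nonzero =
    moving) per frame.  The response spans from the first moving frame
    after ``stim_frame`` to the last moving frame before a gap of more
    than ``pause_frames`` still frames; movement runs separated by more
    than ``bout_gap_frames`` count as separate bouts.
    """
    moving = np.asarray(trace)
    if moving.dtype != bool:
        moving = moving != 0
    if not 0 <= stim_frame < len(moving):
        raise ConfigError("stim_frame outside the trace")
    runs = _runs(moving[stim_frame:])
    if not runs:
        return TouchResponse(responded=False)
    # terminate the response at the first inter-run gap > pause_frames
    kept = [runs[0]]
    for r in runs[1:]:
        if r[0] - kept[-1][1] - 1 > pause_frames:
            break
        kept.append(r)
    first, last = kept[0][0], kept[-1][1]
    bouts = 1
    for prev, cur in zip(kept, kept[1:]):
        if cur[0] - prev[1] - 1 > bout_gap_frames:
            bouts += 1
    return TouchResponse(True, response_time_s=(last - first) / fps, n_bouts=bouts)


# ---------------------------------------------------------------------------
# trajectories

@dataclass
class Trajectory:
    """Timestamped 2D positions with tank geometry.

    y_cm is measured upward from the tank bottom; the upper/lower zone
    boundary defaults to half the water-column height.
    """

    data: pd.DataFrame  # t_s, x_cm, y_cm
    fps: float
    tank_w_cm: float
    tank_h_cm: float
    zone_boundary_cm: float | None = None

    def __post_init__(self):
        need = {"t_s", "x_cm", "y_cm"} - set(self.data.columns)
        if need:
            raise ConfigError(f"trajectory lacks columns {sorted(need)}")
        t = self.data["t_s"].to_numpy()
        if len(t) < 2 or not np.all(np.diff(t) > 0):
            raise ConfigError("trajectory times must be strictly increasing")
        if self.zone_boundary_cm is None:
            self.zone_boundary_cm = self.tank_h_cm / 2.0

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def step_speeds(self, median_window: int = 3) -> np.ndarray:
        """Per-step speeds (cm/s), median-filtered to suppress jitter."""
        x = self.data["x_cm"].to_numpy()
        y = self.data["y_cm"].to_numpy()
        v = np.hypot(np.diff(x), np.diff(y)) * self.fps
        if median_window > 1 and len(v) >= median_window:
            # edge-pad so the filter does not zero-pad the boundary steps
            pad = median_window // 2
            vp = np.concatenate([np.full(pad, v[0]), v, np.full(pad, v[-1])])
            v = medfilt(vp, median_window)[pad:-pad]
        return v


@dataclass
class FreezeBout:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def detect_freezing(traj: Trajectory, speed_eps_cm_s: float = SPEED_EPS_CM_S,
                    min_freeze_s: float = FREEZE_MIN_S,
                    median_window: int = 3) -> list:
    """Find freezing bouts: immobility lasting at least ``min_freeze_s``.

    A bout is a maximal run of steps with speed below the threshold; a
    run of m sub-threshold steps spans m+1 frames, i.e. (m+1)/fps of
    wall time, which must be >= ``min_freeze_s`` (boundary inclusive).
    Bouts are separated by at least one supra-threshold step.
    """
    v = traj.step_speeds(median_window)
    t = traj.data["t_s"].to_numpy()
    dt = 1.0 / traj.fps
    bouts = []
    for a, b in _runs(v < speed_eps_cm_s):
        dur = (b - a + 2) * dt  # steps a..b cover frames a..b+1
        if dur >= min_freeze_s - 1e-9:
            bouts.append(FreezeBout(start_s=float(t[a]), end_s=float(t[a]) + dur))
    return bouts


@dataclass
class TankSessionSummary:
    entered_upper: bool
    latency_to_upper_s: float | None
    time_in_upper_s: float
    time_in_lower_s: float
    pct_time_upper: float
    n_freeze_bouts: int
    total_frozen_s: float
    froze: bool
    total_velocity_cm_s: float
    mobile_velocity_cm_s: float
    session_length_s: float

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def tank_session(traj: Trajectory, speed_eps_cm_s: float = SPEED_EPS_CM_S,
                 min_freeze_s: float = FREEZE_MIN_S,
                 median_window: int = 3) -> TankSessionSummary:
    """Summarize one novel-tank exposure.

    Zone times are per-frame counts times the frame period, so upper +
    lower equals the session length exactly.  Total velocity is path
    length over elapsed time; mobile velocity averages only steps at or
    above the speed threshold (never less than total velocity).
    """
    df = traj.data
    dt = 1.0 / traj.fps
    upper = (df["y_cm"].to_numpy() > traj.zone_boundary_cm)
    time_upper = float(upper.sum() * dt)
    time_lower = float((~upper).sum() * dt)
    session_len = traj.n_frames * dt
    entered = bool(upper.any())
    latency = float(df["t_s"].to_numpy()[np.argmax(upper)]) if entered else None

    bouts = detect_freezing(traj, speed_eps_cm_s, min_freeze_s, median_window)
    frozen = float(sum(b.duration_s for b in bouts))

    v = traj.step_speeds(median_window)
    steps = np.hypot(np.diff(df["x_cm"].to_numpy()), np.diff(df["y_cm"].to_numpy()))
    elapsed = float(df["t_s"].iloc[-1] - df["t_s"].iloc[0])
    total_v = float(steps.sum() / elapsed)
    mobile = v >= speed_eps_cm_s
    mobile_v = float(steps[mobile].sum() / (mobile.sum() * dt)) if mobile.any() else 0.0

    return TankSessionSummary(
        entered_upper=entered, latency_to_upper_s=latency,
        time_in_upper_s=time_upper, time_in_lower_s=time_lower,
        pct_time_upper=100.0 * time_upper / session_len,
        n_freeze_bouts=len(bouts), total_frozen_s=frozen, froze=bool(bouts),
        total_velocity_cm_s=total_v, mobile_velocity_cm_s=mobile_v,
        session_length_s=session_len,
    )


# ---------------------------------------------------------------------------
# group statistics

_CONTINUOUS_METRICS = ("time_in_upper_s", "total_frozen_s",
                       "total_velocity_cm_s", "mobile_velocity_cm_s")


def sessions_to_frame(summaries, **extra) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = s.to_row() if isinstance(s, TankSessionSummary) else dict(s)
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)


def group_session_stats(sessions: pd.DataFrame, group_col: str = "group",
                        day_col: str | None = None) -> dict:
    """Per-group novel-tank statistics with between-group tests.

    ``sessions`` is one row per fish (columns from TankSessionSummary
    plus a group label and optionally an experiment-day label).  Binary
    outcomes (entered upper zone, froze) are summarized as percentages —
    per experiment day when a day column is given, since that is the
    replicate unit for those panels — and tested with Fisher's exact
    test; continuous metrics get a normality-screened two-sample test.
    Latency to the upper zone is summarized over entrants only.
    """
    if sessions.empty:
        raise ConfigError("no sessions")
    groups = list(sessions[group_col].unique())
    per_group, tests = {}, []
    for g, df in sessions.groupby(group_col):
        rec = {
            "n_fish": len(df),
            "pct_entered_upper": 100.0 * df["entered_upper"].mean(),
            "pct_froze": 100.0 * df["froze"].mean(),
        }
        for m in _CONTINUOUS_METRICS:
            rec[f"mean_{m}"] = float(df[m].mean())
            rec[f"sem_{m}"] = float(df[m].std(ddof=1) / np.sqrt(len(df))) if len(df) > 1 else np.nan
        entr = df.loc[df["entered_upper"], "latency_to_upper_s"].dropna()
        rec["mean_latency_entrants_s"] = float(entr.mean()) if len(entr) else np.nan
        rec["n_entrants"] = int(len(entr))
        if day_col is not None:
            by_day = df.groupby(day_col).agg(
                pct_entered=("entered_upper", lambda s: 100.0 * s.mean()),
                pct_froze=("froze", lambda s: 100.0 * s.mean()),
            )
            rec["per_day"] = by_day
        per_group[g] = rec
    if len(groups) == 2:
        a = sessions[sessions[group_col] == groups[0]]
        b = sessions[sessions[group_col] == groups[1]]
        for flag, name in (("entered_upper", "entered_upper"), ("froze", "froze")):
            table = [[int(a[flag].sum()), int((~a[flag]).sum())],
                     [int(b[flag].sum()), int((~b[flag]).sum())]]
            _, p = stats.fisher_exact(table)
            tests.append(dict(metric=name, test="fisher_exact", statistic=np.nan,
                              p=float(p), n=f"{len(a)}/{len(b)}"))
        for m in _CONTINUOUS_METRICS:
            rec = choose_test([a[m].to_numpy(), b[m].to_numpy()])
            tests.append(dict(metric=m, test=rec.test_name, statistic=rec.statistic,
                              p=rec.p, n=f"{len(a)}/{len(b)}"))
    return {"per_group": per_group, "tests": pd.DataFrame(tests)}


def habituation_series(sessions: pd.DataFrame, group_col: str = "group",
                       exposure_col: str = "exposure") -> dict:
    """Per-exposure habituation curves with SEM.

    ``sessions`` rows are fish × exposure; rows flagged untrackable
    (``untrackable == True``) or with missing metrics are omitted and
    counted.  A group with no fish at an exposure yields no row (null,
    not zero).
    """
    df = sessions.copy()
    n_omitted = 0
    if "untrackable" in df.columns:
        flag = df["untrackable"].astype("boolean").fillna(False).astype(bool)
        n_omitted = int(flag.sum())
        df = df[~flag]
    df = df.dropna(subset=["total_frozen_s"])
    rows = []
    for (g, e), sub in df.groupby([group_col, exposure_col]):
        n = len(sub)
        row = dict(group=g, exposure=e, n_fish=n,
                   pct_froze=100.0 * sub["froze"].mean(),
                   pct_entered_upper=100.0 * sub["entered_upper"].mean())
        for m in ("total_frozen_s", "pct_time_upper",
                  "total_velocity_cm_s", "mobile_velocity_cm_s"):
            row[f"mean_{m}"] = float(sub[m].mean())
            row[f"sem_{m}"] = (float(sub[m].std(ddof=1) / np.sqrt(n))
                               if n > 1 else np.nan)
        entr = sub.loc[sub["entered_upper"], "latency_to_upper_s"].dropna()
        row["mean_latency_entrants_s"] = float(entr.mean()) if len(entr) else np.nan
        rows.append(row)
    curves = pd.DataFrame(rows).sort_values(["group", "exposure"]).reset_index(drop=True)
    return {"curves": curves, "n_omitted": n_omitted}
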