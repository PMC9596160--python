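"""Synthetic swim trajectories with programmed freezing and zone preference.

A fish alternates between three behavioral states — ``swim``, ``pause``
(brief immobility shorter than the freezing criterion) and ``freeze``
(immobility of at least ``freeze_min_s``) — according to a continuous-time
Markov jump process discretized at the video frame rate.  Freeze dwell
times are a shifted exponential (``freeze_min_s`` plus an exponential
tail), so every bout labeled freeze satisfies the duration criterion;
pause dwells are capped strictly below it.  Swim bouts last at least four
frames so that smoothing in the downstream detector cannot merge adjacent
immobile bouts.

During a swim bout the fish picks the upper tank zone as its target with
probability ``upper_zone_preference`` and is confined to the target zone
once reached; with preference 0 a fish started in the lower zone never
crosses the half-height boundary.

Immobile states emit exactly constant positions, or a sub-threshold
jitter step of magnitude ``jitter_cm_s``·dt when jitter is enabled, which
lets tests exercise the freezing speed threshold.

For ground-truth exactness pause and freeze states should not be adjacent
(default rates keep ``pause<->freeze`` at 0); otherwise consecutive
immobile bouts merge in any speed-threshold detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigError

STATES = ("swim", "pause", "freeze")

_DEFAULT_RATES = {
    ("swim", "pause"): 0.10,
    ("swim", "freeze"): 0.02,
    ("pause", "swim"): 0.50,
    ("freeze", "swim"): 0.20,
}


@dataclass
class SynthTrajectorySpec:
    fps: float = 10.0
    duration_s: float = 180.0
    tank_size_cm: tuple = (30.0, 20.0)  # (width, height of water column)
    state_rates: dict = field(default_factory=lambda: dict(_DEFAULT_RATES))
    swim_speed_cm_s: float = 2.0
    freeze_min_s: float = 3.0
    upper_zone_preference: float = 0.5
    jitter_cm_s: float = 0.0
    initial_state: str = "swim"
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0 or self.duration_s <= 0:
            raise ConfigError("fps and duration_s must be positive")
        if not 0.0 <= self.upper_zone_preference <= 1.0:
            raise ConfigError("upper_zone_preference must be in [0, 1]")
        if self.initial_state not in STATES:
            raise ConfigError(f"initial_state must be one of {STATES}")
        for (a, b), r in self.state_rates.items():
            if a not in STATES or b not in STATES or r < 0:
                raise ConfigError(f"bad transition rate {(a, b)}: {r}")


@dataclass
class TrajectoryGroundTruth:
    states: pd.DataFrame       # state, start_s, end_s, duration_s (end exclusive)
    freeze_bouts: pd.DataFrame  # subset of states with state == 'freeze'
    upper_zone_fraction: float  # fraction of frames with y above half height
    frame_states: np.ndarray    # per-frame state label


def _dwell_frames(state: str, spec: SynthTrajectorySpec, rng) -> int:
    q = sum(r for (a, _), r in spec.state_rates.items() if a == state)
    if q <= 0:
        return int(1e12)  # absorbing: rest of the session
    draw = rng.exponential(1.0 / q)
    fps = spec.fps
    if state == "freeze":
        return int(np.ceil((spec.freeze_min_s + draw) * fps))
    if state == "pause":
        # a pause of n frames yields n+1 equal positions (the position is
        # held from the last swim frame), i.e. (n+1)/fps of immobility;
        # cap keeps that strictly below the freezing criterion
        cap = max(1, int(np.floor(spec.freeze_min_s * fps)) - 2)
        return int(np.clip(round(draw * fps), 1, cap))
    return max(4, int(round(draw * fps)))


def _next_state(state: str, spec: SynthTrajectorySpec, rng) -> str:
    outs = [(b, r) for (a, b), r in spec.state_rates.items() if a == state and r > 0]
    if not outs:
        return state
    names, rates = zip(*outs)
    p = np.array(rates) / sum(rates)
    return str(rng.choice(names, p=p))


def expected_state_fractions(spec: SynthTrajectorySpec) -> dict:
    """Long-run expected fraction of time in each state.

    Semi-Markov stationary occupancy: stationary distribution of the
    embedded jump chain weighted by mean dwell times (continuous-dwell
    approximation of the frame-discretized generator).
    """
    # restrict to states that actually participate in the chain
    active = [s for s in STATES
              if any(s in pair for pair in spec.state_rates if spec.state_rates[pair] > 0)]
    if not active:
        active = [spec.initial_state]
    idx = {s: i for i, s in enumerate(active)}
    k = len(active)
    q_out = np.zeros(k)
    P = np.zeros((k, k))
    for (a, b), r in spec.state_rates.items():
        if r > 0 and a in idx and b in idx:
            q_out[idx[a]] += r
            P[idx[a], idx[b]] += r
    for i in range(k):
        if q_out[i] > 0:
            P[i] /= q_out[i]
        else:
            P[i, i] = 1.0
    # mean dwell per state, mirroring _dwell_frames
    m = np.zeros(k)
    for s, i in idx.items():
        if q_out[i] <= 0:
            m[i] = np.inf
            continue
        mean_exp = 1.0 / q_out[i]
        if s == "freeze":
            m[i] = spec.freeze_min_s + mean_exp
        elif s == "pause":
            cap = max(1, int(np.floor(spec.freeze_min_s * spec.fps)) - 2) / spec.fps
            m[i] = mean_exp * (1.0 - np.exp(-cap / mean_exp))  # E[min(X, cap)]
        else:
            m[i] = max(4.0 / spec.fps, mean_exp)
    # stationary distribution of the jump chain
    w, v = np.linalg.eig(P.T)
    psi = np.real(v[:, np.argmax(np.real(w))])
    psi = np.abs(psi) / np.abs(psi).sum()
    occ = np.where(psi > 0, psi * m, 0.0)
    occ = occ / occ.sum()
    return {s: float(occ[idx[s]]) if s in idx else 0.0 for s in STATES}


def generate_trajectory(spec: SynthTrajectorySpec):
    """Simulate one session; returns (trajectory DataFrame, ground truth).

    The trajectory has columns ``t_s, x_cm, y_cm`` with y measured upward
    from the tank bottom; the upper/lower zone boundary sits at half the
    water-column height.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fps))
    dt = 1.0 / spec.fps
    w, h = spec.tank_size_cm
    boundary = h / 2.0

    # build the frame-quantized state timeline
    frame_states = np.empty(n, dtype=object)
    timeline = []
    state = spec.initial_state
    f = 0
    while f < n:
        dwell = _dwell_frames(state, spec, rng)
        # never start a freeze that cannot satisfy its minimum duration
        if state == "freeze" and (n - f) * dt < spec.freeze_min_s:
            state = "swim"
            dwell = n - f
        dwell = min(dwell, n - f)
        frame_states[f:f + dwell] = state
        timeline.append((state, f, f + dwell))
        f += dwell
        state = _next_state(state, spec, rng)

    x = np.empty(n)
    y = np.empty(n)
    # start mid-width, mid-lower-zone
    pos = np.array([w / 2.0, boundary / 2.0])
    heading = rng.uniform(0, 2 * np.pi)
    target_upper = False
    prev_state = None
    for i in range(n):
        s = frame_states[i]
        if s == "swim":
            if prev_state != "swim":
                target_upper = rng.random() < spec.upper_zone_preference
            in_upper = pos[1] > boundary
            if in_upper != target_upper:
                aim = np.pi / 2 if target_upper else -np.pi / 2
                heading = aim + rng.normal(0.0, 0.2)
            else:
                heading += rng.normal(0.0, 0.35)
            step = spec.swim_speed_cm_s * dt
            prev = pos.copy()
            pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
            # mirror-reflect at the walls (and, once inside the target
            # zone, at its boundary) so the fish never sticks in place
            xr, yr = False, False
            if pos[0] < 0.0 or pos[0] > w:
                pos[0] = np.clip(2 * np.clip(pos[0], 0.0, w) - pos[0], 0.0, w)
                xr = True
            if in_upper == target_upper:
                # already inside the target zone before the step: confined
                ylo, yhi = (boundary, h) if target_upper else (0.0, boundary)
            else:
                ylo, yhi = 0.0, h  # still travelling toward the target zone
            if pos[1] < ylo or pos[1] > yhi:
                pos[1] = np.clip(2 * np.clip(pos[1], ylo, yhi) - pos[1], ylo, yhi)
                yr = True
            if xr:
                heading = np.pi - heading
            if yr:
                heading = -heading
            # a mirror reflection close to a wall can cancel the step; a
            # swimming frame must always displace the fish, so retake the
            # step along the reflected heading
            if np.linalg.norm(pos - prev) < 0.5 * step:
                pos = prev + step * np.array([np.cos(heading), np.sin(heading)])
                pos[0] = np.clip(pos[0], 0.0, w)
                pos[1] = np.clip(pos[1], ylo, yhi)
        else:
            if spec.jitter_cm_s > 0:
                ang = rng.uniform(0, 2 * np.pi)
                pos = pos + spec.jitter_cm_s * dt * np.array([np.cos(ang), np.sin(ang)])
                pos[0] = np.clip(pos[0], 0.0, w)
                pos[1] = np.clip(pos[1], 0.0, h)
        x[i], y[i] = pos
        prev_state = s

    t = np.arange(n) * dt
    traj = pd.DataFrame({"t_s": t, "x_cm": x, "y_cm": y})
    srows = [
        dict(state=s, start_s=f0 * dt, end_s=f1 * dt, duration_s=(f1 - f0) * dt)
        for s, f0, f1 in timeline
    ]
    states_df = pd.DataFrame(srows)
    freeze_df = states_df[states_df.state == "freeze"].reset_index(drop=True)
    gt = TrajectoryGroundTruth(
        states=states_df,
        freeze_bouts=freeze_df,
        upper_zone_fraction=float(np.mean(y > boundary)),
        frame_states=frame_states,
    )
    return traj, gt
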