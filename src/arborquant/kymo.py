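"""Kymograph construction and intracellular transport analytics.

A kymograph is a distance-versus-time intensity image built by sampling
a traced axon path in every frame of a time-lapse stack; a punctum
(microtubule plus-end comet, endosomal vesicle) moving at constant
velocity appears as a sloped ridge whose slope is its velocity.  The
distance axis increases away from the cell body, so positive slope is
anterograde.

Track extraction is automated: per-frame intensity peaks are linked
greedily by nearest neighbor and fitted with a constant-velocity line.
Kymographs were traditionally measured by hand; a CSV import path for
hand-traced tracks (:func:`tracks_from_frame`) bypasses detection.

Photoactivated-cargo accumulation at branch points is analyzed by
splitting the post-activation movie into equal windows (four by default,
7–8 min each for a ~30 min movie), max-projecting each window, and
normalizing the background-subtracted branch-point signal to the first
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, map_coordinates
from scipy.signal import find_peaks

from .errors import ConfigError, PathOutOfBoundsError

SEGMENT_CLASSES = ("peripheral", "central", "nascent_branch")
NASCENT_BRANCH_MAX_UM = 10.0


# ---------------------------------------------------------------------------
# paths and kymographs

@dataclass
class PathTrace:
    """Polyline along an axon segment, in µm image coordinates (x, y).

    A peripheral segment spans between two branch nodes (or from the
    first visible axon to the first node); growth cones and filopodia are
    excluded from tracing.  Nascent branches must be shorter than 10 µm.
    The cell body lies at the start vertex: distance along the path is
    distance from the soma, so anterograde motion increases it.
    """

    vertices_um: np.ndarray
    line_width_px: int = 1
    segment_class: str = "peripheral"

    def __post_init__(self):
        self.vertices_um = np.atleast_2d(np.asarray(self.vertices_um, dtype=float))
        if self.vertices_um.shape[0] < 2 or self.vertices_um.shape[1] != 2:
            raise ConfigError("a path needs >= 2 (x, y) vertices")
        if self.segment_class not in SEGMENT_CLASSES:
            raise ConfigError(f"segment_class must be one of {SEGMENT_CLASSES}")
        if self.line_width_px < 1 or self.line_width_px % 2 == 0:
            raise ConfigError("line_width_px must be a positive odd integer")
        if self.segment_class == "nascent_branch" and self.length_um >= NASCENT_BRANCH_MAX_UM:
            raise ConfigError(
                f"nascent branches must be < {NASCENT_BRANCH_MAX_UM} µm, "
                f"got {self.length_um:.1f} µm"
            )

    @property
    def length_um(self) -> float:
        return float(np.hypot(*np.diff(self.vertices_um, axis=0).T).sum())


@dataclass
class Kymograph:
    """Distance × time intensity matrix with calibration."""

    data: np.ndarray  # (n_distance, n_frames)
    px_size_um: float
    frame_interval_s: float
    path: PathTrace | None = None

    def __post_init__(self):
        if self.frame_interval_s <= 0 or self.px_size_um <= 0:
            raise ConfigError("calibration values must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def length_um(self) -> float:
        return (self.data.shape[0] - 1) * self.px_size_um

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s

    @classmethod
    def from_profile(cls, profile: np.ndarray, px_size_um: float,
                     frame_interval_s: float) -> "Kymograph":
        """Wrap a pre-computed (distance × time) profile (e.g. syndata)."""
        return cls(np.asarray(profile, dtype=float), px_size_um, frame_interval_s)


def _resample_path(vertices_px: np.ndarray):
    seglen = np.hypot(*np.diff(vertices_px, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    n = int(np.floor(cum[-1])) + 1
    s = np.arange(n, dtype=float)
    x = np.interp(s, cum, vertices_px[:, 0])
    y = np.interp(s, cum, vertices_px[:, 1])
    return x, y


def build_kymograph(stack: np.ndarray, path: PathTrace, px_size_um: float,
                    frame_interval_s: float) -> Kymograph:
    """Sample a time-lapse stack along a path, 1 px per distance step.

    ``stack`` is (t, y, x) or (t, z, y, x); z is max-projected per frame.
    Intensity at each distance step is the mean across ``line_width_px``
    samples perpendicular to the path.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 4:
        stack = stack.max(axis=1)
    if stack.ndim != 3:
        raise ConfigError("stack must be (t, y, x) or (t, z, y, x)")
    h, w = stack.shape[1:]
    verts_px = path.vertices_um / px_size_um
    for i, (vx, vy) in enumerate(verts_px):
        if not (0 <= vx <= w - 1 and 0 <= vy <= h - 1):
            raise PathOutOfBoundsError(i, (vx, vy), (h, w))
    x, y = _resample_path(verts_px)
    # unit tangent and normal at each sample
    tx, ty = np.gradient(x), np.gradient(y)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx, ny = -ty / norm, tx / norm
    half = path.line_width_px // 2
    offsets = np.arange(-half, half + 1)
    rows = np.clip(y[None, :] + offsets[:, None] * ny[None, :], 0, h - 1)
    cols = np.clip(x[None, :] + offsets[:, None] * nx[None, :], 0, w - 1)
    out = np.empty((len(x), stack.shape[0]))
    for f in range(stack.shape[0]):
        samp = map_coordinates(stack[f], [rows, cols], order=1, mode="nearest")
        out[:, f] = samp.mean(axis=0)
    return Kymograph(out, px_size_um, frame_interval_s, path=path)


# ---------------------------------------------------------------------------
# track detection

@dataclass
class ParticleTrack:
    """One comet/vesicle run extracted from a kymograph."""

    anchors: np.ndarray  # (n, 2) columns (time_s, distance_um)
    velocity_um_s: float  # signed slope of the constant-velocity fit
    run_length_um: float  # |net displacement|
    duration_s: float
    direction: str | None  # 'anterograde' / 'retrograde' / None
    motile: bool

    def to_row(self) -> dict:
        return dict(t_start_s=self.anchors[0, 0], t_end_s=self.anchors[-1, 0],
                    x_start_um=self.anchors[0, 1], x_end_um=self.anchors[-1, 1],
                    velocity_um_s=self.velocity_um_s,
                    run_length_um=self.run_length_um, duration_s=self.duration_s,
                    direction=self.direction, motile=self.motile)


def tracks_to_frame(tracks: list) -> pd.DataFrame:
    return pd.DataFrame([t.to_row() for t in tracks])


def tracks_from_frame(df: pd.DataFrame) -> list:
    """Build ParticleTrack objects from a manual-annotation table.

    Expected columns: t_start_s, t_end_s, x_start_um, x_end_um (anchor
    endpoints of each hand-traced run).
    """
    out = []
    for _, r in df.iterrows():
        anchors = np.array([[r.t_start_s, r.x_start_um], [r.t_end_s, r.x_end_um]])
        out.append(_fit_track(anchors, motility_floor_um=0.5))
    return out


def _fit_track(anchors: np.ndarray, motility_floor_um: float) -> ParticleTrack:
    t, d = anchors[:, 0], anchors[:, 1]
    dur = float(t[-1] - t[0])
    vel = float(np.polyfit(t, d, 1)[0]) if dur > 0 else 0.0
    net = float(d[-1] - d[0])
    motile = abs(net) >= motility_floor_um
    if not motile or vel == 0:
        direction = None
    else:
        direction = "anterograde" if vel > 0 else "retrograde"
    return ParticleTrack(anchors, vel, abs(net), dur, direction, motile)


def _merge_fragments(chains: list, max_step_px: float,
                     merge_gap_frames: int = 5, tol_px: float = 3.0) -> list:
    """Join track fragments split by missed detections.

    Two chains merge when the second starts shortly after the first ends
    and lies on the linear extrapolation of the first's motion.
    """
    chains = sorted(chains, key=lambda c: c["anchors"][0][0])

    def _fit_slope(anchors):
        a = np.array(anchors, dtype=float)
        if len(a) < 2:
            return 0.0
        return np.polyfit(a[:, 0], a[:, 1], 1)[0]

    merged = True
    while merged:
        merged = False
        for i, a in enumerate(chains):
            for j, b in enumerate(chains):
                if i == j:
                    continue
                fa_end, pa_end = a["anchors"][-1]
                fb_start, pb_start = b["anchors"][0]
                gap = fb_start - fa_end
                if not 1 <= gap <= merge_gap_frames:
                    continue
                if len(a["anchors"]) < 3 or len(b["anchors"]) < 3:
                    continue
                slope = _fit_slope(a["anchors"][-5:])
                slope_b = _fit_slope(b["anchors"][:5])
                if abs(slope) > max_step_px:
                    continue
                if abs(slope - slope_b) > 0.25 * max(abs(slope), abs(slope_b)) + 0.3:
                    continue
                pred = pa_end + slope * gap
                if abs(pred - pb_start) > tol_px:
                    continue
                a["anchors"] = a["anchors"] + b["anchors"]
                chains.pop(j)
                merged = True
                break
            if merged:
                break
    return chains


def detect_tracks(kymo: Kymograph, min_run_um: float = 1.0, min_frames: int = 3,
                  max_velocity_um_s: float = 2.5, max_gap_frames: int = 1,
                  peak_prominence: float | None = None,
                  motility_floor_um: float = 0.5,
                  smooth_sigma_px: float = 2.0) -> list:
    """Extract particle tracks from a kymograph.

    The kymograph is first smoothed along the distance axis (Gaussian,
    ``smooth_sigma_px``, matched to the diffraction-limited spot size) to
    suppress pixel noise.  Per frame, intensity peaks are located
    (prominence defaults to 25% of the smoothed dynamic range); peaks in
    consecutive frames are linked greedily by nearest neighbor within
    the displacement implied by ``max_velocity_um_s`` (allowing
    ``max_gap_frames`` missed frames).  Linked chains shorter than
    ``min_frames`` frames or ``min_run_um`` of net displacement are
    discarded; survivors get a constant-velocity fit.  Tracks with net
    displacement below ``motility_floor_um`` are kept but flagged
    non-motile.  An empty list is a valid result.
    """
    data = kymo.data
    if smooth_sigma_px > 0:
        data = gaussian_filter1d(data, smooth_sigma_px, axis=0, mode="nearest")
    baseline = np.median(data)
    noise = 1.4826 * np.median(np.abs(data - baseline))
    rng_int = data.max() - baseline
    if rng_int <= 0:
        return []
    # peaks must clear the noise floor and a fraction of the dynamic range
    prom = (max(0.3 * rng_int, 4.0 * noise)
            if peak_prominence is None else peak_prominence)
    max_step_px = max(1.0, max_velocity_um_s * kymo.frame_interval_s / kymo.px_size_um)

    def _predict(tr, f):
        """Expected position at frame f from the track's recent motion."""
        a = tr["anchors"]
        if len(a) == 1:
            return a[-1][1], max_step_px * (f - a[-1][0])
        tail = np.array(a[-5:], dtype=float)
        slope = np.polyfit(tail[:, 0], tail[:, 1], 1)[0]
        slope = np.clip(slope, -max_step_px, max_step_px)
        tol = max(2.0, 0.2 * max_step_px) * (f - a[-1][0])
        return a[-1][1] + slope * (f - a[-1][0]), tol

    active = []  # dicts: anchors=[(f, pos_px)], miss=count
    done = []
    for f in range(kymo.n_frames):
        peaks, _ = find_peaks(data[:, f], prominence=prom,
                              height=baseline + max(0.25 * rng_int, 3.0 * noise))
        peaks = list(peaks.astype(float))
        # greedy matching on prediction error, best pairs first
        cand = []
        for ti, tr in enumerate(active):
            pred, tol = _predict(tr, f)
            for pi, p in enumerate(peaks):
                err = abs(p - pred)
                if err <= tol:
                    cand.append((err, ti, pi))
        cand.sort()
        used_t, used_p = set(), set()
        for _, ti, pi in cand:
            if ti in used_t or pi in used_p:
                continue
            active[ti]["anchors"].append((f, peaks[pi]))
            active[ti]["miss"] = 0
            used_t.add(ti)
            used_p.add(pi)
        still = []
        for ti, tr in enumerate(active):
            if ti in used_t:
                still.append(tr)
            else:
                tr["miss"] += 1
                (still if tr["miss"] <= max_gap_frames else done).append(tr)
        active = still
        for pi, p in enumerate(peaks):
            if pi not in used_p:
                active.append({"anchors": [(f, p)], "miss": 0})
    done.extend(active)
    done = _merge_fragments(done, max_step_px)

    tracks = []
    for tr in done:
        anchors = np.array(tr["anchors"], dtype=float)
        if len(anchors) < min_frames:
            continue
        anchors[:, 0] *= kymo.frame_interval_s
        anchors[:, 1] *= kymo.px_size_um
        if abs(anchors[-1, 1] - anchors[0, 1]) < min_run_um:
            continue
        tracks.append(_fit_track(anchors, motility_floor_um))
    return tracks


# ---------------------------------------------------------------------------
# summaries

@dataclass
class TransportSummary:
    """Per-segment transport statistics.

    Frequency is normalized to tracks·min⁻¹·(10 µm)⁻¹ so segments of
    different length are comparable.
    """

    n_tracks: int
    frequency_per_min_per_10um: float
    pct_retrograde_of_all: float
    pct_anterograde_of_motile: float
    mean_run_length_um: dict
    max_run_length_um: dict
    mean_velocity_um_s: dict
    mean_duration_s: float

    def to_row(self) -> dict:
        row = dict(n_tracks=self.n_tracks,
                   frequency_per_min_per_10um=self.frequency_per_min_per_10um,
                   pct_retrograde_of_all=self.pct_retrograde_of_all,
                   pct_anterograde_of_motile=self.pct_anterograde_of_motile,
                   mean_duration_s=self.mean_duration_s)
        for d in ("anterograde", "retrograde"):
            row[f"mean_run_{d}_um"] = self.mean_run_length_um.get(d, np.nan)
            row[f"max_run_{d}_um"] = self.max_run_length_um.get(d, np.nan)
            row[f"mean_velocity_{d}_um_s"] = self.mean_velocity_um_s.get(d, np.nan)
        return row


def transport_summary(tracks: list, segment_length_um: float,
                      duration_min: float) -> TransportSummary:
    """Summarize a track list for one axon segment."""
    if segment_length_um <= 0 or duration_min <= 0:
        raise ConfigError("segment length and duration must be positive")
    n = len(tracks)
    freq = n / duration_min / (segment_length_um / 10.0)
    directional = [t for t in tracks if t.direction is not None]
    motile = [t for t in tracks if t.motile]
    pct_retro = (100.0 * sum(t.direction == "retrograde" for t in directional) / len(directional)
                 if directional else np.nan)
    motile_dir = [t for t in motile if t.direction is not None]
    pct_antero_mot = (100.0 * sum(t.direction == "anterograde" for t in motile_dir) / len(motile_dir)
                      if motile_dir else np.nan)
    mean_run, max_run, mean_vel = {}, {}, {}
    for d in ("anterograde", "retrograde"):
        runs = [t.run_length_um for t in tracks if t.direction == d]
        vels = [abs(t.velocity_um_s) for t in tracks if t.direction == d]
        mean_run[d] = float(np.mean(runs)) if runs else np.nan
        max_run[d] = float(np.max(runs)) if runs else np.nan
        mean_vel[d] = float(np.mean(vels)) if vels else np.nan
    mean_dur = float(np.mean([t.duration_s for t in tracks])) if tracks else np.nan
    return TransportSummary(n, freq, pct_retro, pct_antero_mot,
                            mean_run, max_run, mean_vel, mean_dur)


# ---------------------------------------------------------------------------
# branch-point accumulation

@dataclass
class AccumulationSeries:
    """Windowed branch-point signal after photoactivation.

    ``normalized_pct`` is 100 × (window − background) / (t1 − background);
    an invalid series (corrected t1 ≤ 0) carries NaNs and valid=False.
    """

    window_means: np.ndarray
    background: float
    normalized_pct: np.ndarray
    valid: bool


def branchpoint_accumulation(stack: np.ndarray, roi: tuple,
                             activation_frame: int,
                             n_windows: int = 4) -> AccumulationSeries:
    """Measure cargo accumulation at a branch point after activation.

    ``roi`` is (y0, y1, x0, x1) in pixels.  Frames after
    ``activation_frame`` are split into ``n_windows`` equal spans; each
    window is max-projected over time (and z, if present) and the mean
    ROI intensity taken.  The pre-activation ROI signal, measured the
    same way, is subtracted before normalizing to the first window.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 4:
        stack = stack.max(axis=1)
    if stack.ndim != 3:
        raise ConfigError("stack must be (t, y, x) or (t, z, y, x)")
    nt, h, w = stack.shape
    if not 0 < activation_frame < nt:
        raise ConfigError("activation_frame must leave pre- and post-activation frames")
    y0, y1, x0, x1 = roi
    if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
        raise ConfigError(f"ROI {roi} outside stack of shape {(h, w)}")

    def _roi_mean_maxproj(frames):
        return float(frames.max(axis=0)[y0:y1, x0:x1].mean())

    background = _roi_mean_maxproj(stack[:activation_frame])
    windows = np.array_split(np.arange(activation_frame, nt), n_windows)
    if any(len(wi) == 0 for wi in windows):
        raise ConfigError("too few post-activation frames for the window count")
    means = np.array([_roi_mean_maxproj(stack[wi]) for wi in windows])
    corrected = means - background
    if corrected[0] <= 0:
        return AccumulationSeries(means, background,
                                  np.full(n_windows, np.nan), valid=False)
    return AccumulationSeries(means, background,
                              100.0 * corrected / corrected[0], valid=True)


# ---------------------------------------------------------------------------
# benchmarking helper

def match_tracks(detected: list, truth: pd.DataFrame,
                 max_velocity_err: float = 0.25,
                 max_position_err_um: float = 2.0) -> dict:
    """Greedy one-to-one match of detected tracks to ground truth.

    A detected track matches a true track when the midpoint positions
    agree within ``max_position_err_um`` (at the overlapping mid-time)
    and relative velocity error is within ``max_velocity_err``.  Returns
    precision/recall/F1 and the matched pairs, plus direction accuracy
    among matches.
    """
    pairs = []
    for di, d in enumerate(detected):
        tm = 0.5 * (d.anchors[0, 0] + d.anchors[-1, 0])
        for ti, r in truth.iterrows():
            if not (r.t_start_s - 1e-9 <= tm <= r.t_start_s + r.duration_s + 1e-9):
                continue
            x_true = r.x_start_um + r.velocity_um_s * (tm - r.t_start_s)
            x_det = float(np.interp(tm, d.anchors[:, 0], d.anchors[:, 1]))
            if abs(x_det - x_true) > max_position_err_um:
                continue
            vref = max(abs(r.velocity_um_s), 1e-9)
            if abs(d.velocity_um_s - r.velocity_um_s) / vref > max_velocity_err:
                continue
            pairs.append((abs(x_det - x_true), di, ti))
    pairs.sort()
    used_d, used_t, matches = set(), set(), []
    for _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matches.append((di, ti))
    tp = len(matches)
    precision = tp / len(detected) if detected else np.nan
    recall = tp / len(truth) if len(truth) else np.nan
    f1 = (2 * precision * recall / (precision + recall)
          if tp and (precision + recall) > 0 else 0.0)
    dir_ok = [detected[di].direction == truth.loc[ti, "direction"]
              for di, ti in matches]
    return {"precision": precision, "recall": recall, "f1": f1,
            "direction_accuracy": float(np.mean(dir_ok)) if dir_ok else np.nan,
            "matches": matches}
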