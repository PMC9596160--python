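"""Synthetic time-lapse movies of moving puncta with known tracks.

Emulates live imaging of fluorescent puncta (microtubule plus-end comets,
endosomal vesicles) moving along an axon segment.  Acquisition defaults
follow the assay convention of 2–5 s frame intervals over 7–10 min.

Each particle moves at constant velocity, x(t) = x_start + v·(t −
t_start), until its run length is consumed or it exits the path domain /
movie; the ground-truth table records the realized (possibly truncated)
run.  Positive velocity is anterograde (increasing distance from the cell
body).

Movies can be emitted either as a (distance × time) intensity profile —
i.e. directly in kymograph geometry, which separates track-detection
errors from path-tracing errors — or as a rendered (t, y, x) image stack
with the path along a horizontal line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigError


@dataclass
class Particle:
    t_start_s: float
    x_start_um: float
    velocity_um_s: float  # signed; + = anterograde
    run_length_um: float
    intensity: float = 1.0


@dataclass
class SynthMovieSpec:
    path_length_um: float = 30.0
    frame_interval_s: float = 2.5
    n_frames: int = 150
    particles: list = field(default_factory=list)
    background: float = 0.0
    snr: float = float("inf")
    seed: int = 0
    px_size_um: float = 0.2
    spot_sigma_px: float = 1.5

    def __post_init__(self):
        if self.path_length_um <= 0 or self.frame_interval_s <= 0:
            raise ConfigError("path_length_um and frame_interval_s must be positive")
        if not self.snr > 0:
            raise ConfigError("snr must be positive")
        self.particles = [
            p if isinstance(p, Particle) else Particle(*p) for p in self.particles
        ]


def _truncated_run(p: Particle, spec: SynthMovieSpec):
    """Realized run after clipping to the path domain and the movie end."""
    total_time = (spec.n_frames - 1) * spec.frame_interval_s
    if p.velocity_um_s == 0:
        dur = max(0.0, total_time - p.t_start_s)
        return 0.0, dur, p.x_start_um
    run = p.run_length_um
    if p.velocity_um_s > 0:
        run = min(run, spec.path_length_um - p.x_start_um)
    else:
        run = min(run, p.x_start_um)
    run = max(run, 0.0)
    dur = run / abs(p.velocity_um_s)
    if p.t_start_s + dur > total_time:
        dur = max(0.0, total_time - p.t_start_s)
        run = dur * abs(p.velocity_um_s)
    x_end = p.x_start_um + np.sign(p.velocity_um_s) * run
    return run, dur, x_end


def ground_truth_tracks(spec: SynthMovieSpec) -> pd.DataFrame:
    """Ground-truth ParticleTrack table (one row per particle)."""
    rows = []
    for i, p in enumerate(spec.particles):
        run, dur, x_end = _truncated_run(p, spec)
        if p.velocity_um_s > 0:
            direction = "anterograde"
        elif p.velocity_um_s < 0:
            direction = "retrograde"
        else:
            direction = None
        rows.append(
            dict(track_id=i, t_start_s=p.t_start_s, x_start_um=p.x_start_um,
                 x_end_um=x_end, velocity_um_s=p.velocity_um_s,
                 run_length_um=run, duration_s=dur, direction=direction,
                 motile=bool(run > 0))
        )
    return pd.DataFrame(rows)


def generate_particle_movie(spec: SynthMovieSpec, as_stack: bool = False,
                            stack_height_px: int = 15):
    """Render the movie and return (data, ground_truth_tracks).

    ``data`` is a (n_distance_px, n_frames) profile by default, or a
    (n_frames, stack_height_px, n_distance_px) stack when ``as_stack`` is
    True (path along the central row).
    """
    rng = np.random.default_rng(spec.seed)
    n_px = int(round(spec.path_length_um / spec.px_size_um)) + 1
    x_grid = np.arange(n_px) * spec.px_size_um
    sigma_um = spec.spot_sigma_px * spec.px_size_um
    profile = np.full((n_px, spec.n_frames), float(spec.background))

    gt = ground_truth_tracks(spec)
    for p, (_, row) in zip(spec.particles, gt.iterrows()):
        for f in range(spec.n_frames):
            t = f * spec.frame_interval_s
            if t < p.t_start_s - 1e-9 or t > p.t_start_s + row.duration_s + 1e-9:
                continue
            x = p.x_start_um + p.velocity_um_s * (t - p.t_start_s)
            profile[:, f] += p.intensity * np.exp(-((x_grid - x) ** 2) / (2 * sigma_um ** 2))

    peak = max((p.intensity for p in spec.particles), default=1.0)
    if as_stack:
        yc = stack_height_px // 2
        y = np.arange(stack_height_px)
        lateral = np.exp(-((y - yc) ** 2) / (2 * spec.spot_sigma_px ** 2))
        data = lateral[None, :, None] * (profile.T[:, None, :] - spec.background) + spec.background
    else:
        data = profile
    if np.isfinite(spec.snr):
        data = data + rng.normal(0.0, peak / spec.snr, size=data.shape)
        data = np.clip(data, 0.0, None)
    return data, gt
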