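"""Kymograph construction, track detection, transport summaries."""

import numpy as np
import pandas as pd
import pytest

from arborquant.errors import ConfigError, PathOutOfBoundsError
from arborquant.kymo import (
    Kymograph,
    PathTrace,
    branchpoint_accumulation,
    build_kymograph,
    detect_tracks,
    match_tracks,
    tracks_from_frame,
    transport_summary,
)
from arborquant.syndata import SynthMovieSpec, generate_particle_movie


def _movie_particles(rng, n, length_um):
    parts = []
    for _ in range(n):
        v = rng.choice([-1, 1]) * rng.uniform(0.1, 2.0)
        run = max(6.0, 14.0 * abs(v))
        parts.append((rng.uniform(0, 200), rng.uniform(2, length_um - 2), v, run, 1.0))
    return parts


# ---------------------------------------------------------------------------
# construction

def test_static_stack_gives_constant_kymograph():
    stack = np.full((5, 20, 40), 2.5)
    path = PathTrace([(1.0, 2.0), (7.0, 2.0)])
    k = build_kymograph(stack, path, px_size_um=0.2, frame_interval_s=2.0)
    assert np.allclose(k.data, 2.5)
    assert k.n_frames == 5


def test_kymograph_ridge_slope_recovers_particle_velocity():
    spec = SynthMovieSpec(path_length_um=30, frame_interval_s=2.0, n_frames=60,
                          particles=[(0.0, 2.0, 0.5, 25.0, 1.0)])
    stack, _ = generate_particle_movie(spec, as_stack=True)
    path = PathTrace([(0.0, 1.4), (30.0, 1.4)])
    k = build_kymograph(stack, path, spec.px_size_um, spec.frame_interval_s)
    frames = np.arange(5, 24)  # within the particle's 50 s lifetime
    ridge_um = k.data[:, frames].argmax(axis=0) * k.px_size_um
    slope = np.polyfit(frames * spec.frame_interval_s, ridge_um, 1)[0]
    assert slope == pytest.approx(0.5, rel=0.1)


def test_line_width_does_not_shift_ridge_on_clean_data():
    spec = SynthMovieSpec(path_length_um=20, n_frames=20,
                          particles=[(0.0, 10.0, 0.2, 5.0, 1.0)])
    stack, _ = generate_particle_movie(spec, as_stack=True)
    p1 = PathTrace([(0.0, 1.4), (20.0, 1.4)], line_width_px=1)
    p3 = PathTrace([(0.0, 1.4), (20.0, 1.4)], line_width_px=3)
    k1 = build_kymograph(stack, p1, spec.px_size_um, spec.frame_interval_s)
    k3 = build_kymograph(stack, p3, spec.px_size_um, spec.frame_interval_s)
    assert np.array_equal(k1.data.argmax(axis=0), k3.data.argmax(axis=0))


def test_path_leaving_image_names_vertex():
    stack = np.zeros((3, 10, 10))
    with pytest.raises(PathOutOfBoundsError, match="vertex 1"):
        build_kymograph(stack, PathTrace([(0.5, 0.5), (50.0, 0.5)]), 0.2, 2.0)


def test_nascent_branch_length_contract():
    with pytest.raises(ConfigError):
        PathTrace([(0.0, 0.0), (12.0, 0.0)], segment_class="nascent_branch")


# ---------------------------------------------------------------------------
# detection

def test_blank_kymograph_yields_no_tracks():
    k = Kymograph.from_profile(np.zeros((100, 50)), 0.2, 2.0)
    assert detect_tracks(k) == []


def test_noise_free_detection_recovers_all_tracks():
    rng = np.random.default_rng(1)
    spec = SynthMovieSpec(path_length_um=60, frame_interval_s=2.0, n_frames=150,
                          particles=_movie_particles(rng, 10, 60), seed=2)
    prof, gt = generate_particle_movie(spec)
    k = Kymograph.from_profile(prof, spec.px_size_um, spec.frame_interval_s)
    tracks = detect_tracks(k)
    m = match_tracks(tracks, gt)
    assert len(tracks) == 10
    assert m["f1"] == 1.0
    assert m["direction_accuracy"] == 1.0
    for di, ti in m["matches"]:
        v_true = gt.loc[ti, "velocity_um_s"]
        assert tracks[di].velocity_um_s == pytest.approx(v_true, rel=0.1)


def test_direction_sign_exact_on_clean_tracks():
    # 40 tracks over several seeds: zero direction errors expected
    errors = 0
    total = 0
    for s in range(4):
        rng = np.random.default_rng(300 + s)
        spec = SynthMovieSpec(path_length_um=60, frame_interval_s=2.0,
                              n_frames=150,
                              particles=_movie_particles(rng, 10, 60), seed=s)
        prof, gt = generate_particle_movie(spec)
        k = Kymograph.from_profile(prof, spec.px_size_um, spec.frame_interval_s)
        m = match_tracks(detect_tracks(k), gt)
        tr = detect_tracks(k)
        for di, ti in m["matches"]:
            total += 1
            errors += tr[di].direction != gt.loc[ti, "direction"]
    assert total >= 30
    assert errors == 0


# ---------------------------------------------------------------------------
# summaries

def _manual_tracks():
    df = pd.DataFrame(dict(
        t_start_s=[0.0, 0.0, 10.0, 5.0, 0.0, 2.0],
        t_end_s=[10.0, 20.0, 30.0, 25.0, 40.0, 22.0],
        x_start_um=[0.0, 18.0, 5.0, 12.0, 3.0, 9.0],
        x_end_um=[5.0, 12.0, 9.0, 6.0, 3.2, 15.0],
    ))
    return tracks_from_frame(df)


def test_transport_frequency_normalization():
    tracks = _manual_tracks()
    summ = transport_summary(tracks, segment_length_um=20.0, duration_min=6.0)
    assert summ.frequency_per_min_per_10um == pytest.approx(6 / 6.0 / 2.0)


def test_transport_summary_matches_brute_force_recount():
    tracks = _manual_tracks()
    summ = transport_summary(tracks, 20.0, 6.0)
    antero = [t for t in tracks if t.direction == "anterograde"]
    retro = [t for t in tracks if t.direction == "retrograde"]
    directional = antero + retro
    motile = [t for t in tracks if t.motile]
    assert summ.n_tracks == len(tracks)
    assert summ.pct_retrograde_of_all == pytest.approx(100 * len(retro) / len(directional))
    assert summ.pct_anterograde_of_motile == pytest.approx(
        100 * sum(t.direction == "anterograde" for t in motile if t.direction)
        / sum(1 for t in motile if t.direction)
    )
    assert summ.mean_run_length_um["anterograde"] == pytest.approx(
        np.mean([t.run_length_um for t in antero]))
    assert summ.max_run_length_um["retrograde"] == pytest.approx(
        max(t.run_length_um for t in retro))
    assert summ.max_run_length_um["anterograde"] >= summ.mean_run_length_um["anterograde"]


def test_all_anterograde_has_zero_retrograde_percent():
    df = pd.DataFrame(dict(t_start_s=[0, 0], t_end_s=[10, 10],
                           x_start_um=[0, 5], x_end_um=[4, 9]))
    summ = transport_summary(tracks_from_frame(df), 20.0, 5.0)
    assert summ.pct_retrograde_of_all == 0.0
    assert summ.pct_anterograde_of_motile == 100.0


def test_sub_floor_displacement_flagged_non_motile():
    df = pd.DataFrame(dict(t_start_s=[0.0], t_end_s=[20.0],
                           x_start_um=[5.0], x_end_um=[5.2]))
    (tr,) = tracks_from_frame(df)
    assert not tr.motile
    assert tr.direction is None


# ---------------------------------------------------------------------------
# accumulation

def _ramp_stack(n_pre=10, n_post=40, alpha=None):
    # uniform frames with intensity I(t); default ramp doubles by the
    # midpoint of the fourth window
    nt = n_pre + n_post
    if alpha is None:
        mid_t4 = n_pre + 3.5 * n_post / 4.0
        alpha = 1.0 / (mid_t4 - n_pre)
    frames = np.ones((nt, 8, 8))
    for f in range(n_pre, nt):
        frames[f] *= 1.0 + alpha * (f - n_pre)
    return frames, alpha


def test_constant_signal_gives_flat_100pct_series():
    stack = np.ones((30, 6, 6))
    stack[10:] = 5.0
    series = branchpoint_accumulation(stack, (1, 5, 1, 5), activation_frame=10)
    assert series.valid
    assert np.allclose(series.normalized_pct, 100.0)


def test_linear_ramp_matches_closed_form_window_maxima():
    stack, alpha = _ramp_stack()
    series = branchpoint_accumulation(stack, (2, 6, 2, 6), activation_frame=10)
    windows = np.array_split(np.arange(10, 50), 4)
    bg = 1.0  # pre-activation intensity
    expected = []
    for wi in windows:
        last = wi[-1]
        expected.append(1.0 + alpha * (last - 10) - bg)
    expected = 100.0 * np.array(expected) / expected[0]
    assert np.allclose(series.normalized_pct, expected, rtol=1e-2)


def test_zero_corrected_t1_flags_invalid():
    stack = np.ones((20, 6, 6))  # post-activation equals background
    series = branchpoint_accumulation(stack, (1, 5, 1, 5), activation_frame=5)
    assert not series.valid
    assert np.isnan(series.normalized_pct).all()


def test_accumulation_invariant_under_affine_rescale():
    stack, _ = _ramp_stack()
    series = branchpoint_accumulation(stack, (2, 6, 2, 6), activation_frame=10)
    rescaled = branchpoint_accumulation(3.0 * stack + 7.0, (2, 6, 2, 6),
                                        activation_frame=10)
    assert np.allclose(series.normalized_pct, rescaled.normalized_pct)


def test_velocity_sweep_recovered_within_10pct():
    # constant-velocity ridges across the physiological range, frame
    # intervals spanning the acquisition convention
    for v, interval in [(0.1, 5.0), (0.25, 4.0), (0.5, 3.0), (1.0, 2.0), (2.0, 2.0)]:
        run = max(6.0, 14.0 * v)
        spec = SynthMovieSpec(path_length_um=40, frame_interval_s=interval,
                              n_frames=120,
                              particles=[(0.0, 2.0, v, run, 1.0)])
        prof, gt = generate_particle_movie(spec)
        k = Kymograph.from_profile(prof, spec.px_size_um, spec.frame_interval_s)
        tracks = detect_tracks(k)
        assert len(tracks) == 1, f"v={v}"
        assert tracks[0].velocity_um_s == pytest.approx(v, rel=0.1)
        assert tracks[0].direction == "anterograde"
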