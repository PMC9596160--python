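"""End-to-end recovery benchmarks on synthetic ground truth.

The study's headline numbers come from microscopy movies and behavioral
videos that exist only as summary statistics, so validation here is
parameter recovery: simulate data with known ground truth — using the
published values (initiation rates, loss probabilities, freezing
probabilities, angular ranges) as generator parameters — run the full
analysis path, and measure how well it recovers what was put in.

Each routine takes a master seed and derives all internal seeds from it,
so a whole benchmark run is reproducible from one integer.
"""

from __future__ import annotations

import numpy as np

from . import behavior, branchmetrics, kymo, orientation, syndata
from .behavior import Trajectory


def _sub_seeds(seed: int, n: int, stream: int) -> np.ndarray:
    return np.random.default_rng([seed, stream]).integers(2 ** 31, size=n)


def _axial_err(a, b):
    return abs((a - b + 90.0) % 180.0 - 90.0)


def _argmax_deg(profile):
    return float(profile.bin_centers_deg[np.argmax(profile.signal_per_bin)])


# ---------------------------------------------------------------------------
# orientation

def orientation_recovery(seed: int = 0, n_seeds_snr3: int = 20) -> dict:
    """Histogram-argmax error for single-orientation arbors.

    Noise-free images at theta in {-85, ..., +85} step 10 deg, and the
    same angles at SNR 3 with the profile averaged over ``n_seeds_snr3``
    seeded replicates.
    """
    angles = np.arange(-85.0, 86.0, 10.0)
    noise_free_err, snr3_err = [], []
    for i, th in enumerate(angles):
        mix = [(float(th), 1e9, 1.0)]
        spec = syndata.SynthArborSpec(orientation_mixture=mix, n_segments=15,
                                      seed=int(_sub_seeds(seed, 1, 10 + i)[0]))
        img, _ = syndata.generate_arbor_image(spec)
        prof = orientation.orientation_histogram(img)
        noise_free_err.append(_axial_err(_argmax_deg(prof), th))

        profs = []
        for s in _sub_seeds(seed, n_seeds_snr3, 100 + i):
            spec = syndata.SynthArborSpec(orientation_mixture=mix, n_segments=15,
                                          snr=3.0, seed=int(s))
            img, _ = syndata.generate_arbor_image(spec)
            profs.append(orientation.orientation_histogram(img))
        avg = orientation.average_profiles(profs)
        snr3_err.append(_axial_err(_argmax_deg(avg), th))
    return {
        "angles": angles,
        "max_err_noise_free_deg": float(max(noise_free_err)),
        "max_err_snr3_deg": float(max(snr3_err)),
        "n_angles": len(angles),
    }


BIAS_RANGE_DEG = (-50.5, -20.5)
#: baseline orientation mixture of a wild-type-like arbor (two broad
#: posterior/anterior-ventral lobes) and the same mixture with 10% of the
#: orientation mass moved into a posterior component inside BIAS_RANGE_DEG
BASE_MIXTURE = [(-60.0, 3.0, 0.5), (60.0, 3.0, 0.5)]
BIASED_MIXTURE = [(-60.0, 3.0, 0.45), (60.0, 3.0, 0.45), (-35.5, 20.0, 0.10)]


def _profile_group(mixture, seeds):
    out = []
    for s in seeds:
        spec = syndata.SynthArborSpec(
            orientation_mixture=mixture, n_segments=30, image_size_px=(256, 256),
            stratified_mixture=True, seed=int(s),
        )
        img, _ = syndata.generate_arbor_image(spec)
        out.append(orientation.normalize_profile(
            orientation.orientation_histogram(img)))
    return out


def bias_detection_rate(seed: int = 0, n_reps: int = 100,
                        n_images: int = 20) -> dict:
    """Fraction of replicates in which the injected posterior bias is
    detected (compare_auc p < 0.05 over the biased angular range)."""
    hits = 0
    for rep in range(n_reps):
        a = _profile_group(BASE_MIXTURE, _sub_seeds(seed, n_images, 1000 + 2 * rep))
        b = _profile_group(BIASED_MIXTURE, _sub_seeds(seed, n_images, 1001 + 2 * rep))
        cmp_ = orientation.compare_auc(a, b, BIAS_RANGE_DEG)
        hits += cmp_.p < 0.05
    return {"detection_rate": hits / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# branch density / events

def density_exactness(seed: int = 0, n_seeds: int = 20) -> dict:
    """Fraction of synthetic arbors whose 8-ROI counts equal ground truth."""
    exact = 0
    for s in _sub_seeds(seed, n_seeds, 2000):
        img, gt = syndata.generate_arbor_image(syndata.SynthArborSpec(seed=int(s)))
        prof = branchmetrics.count_branch_crossings(img, gt.grid)
        exact += np.array_equal(prof.counts, gt.band_crossings)
    return {"exact_fraction": exact / n_seeds, "n_seeds": n_seeds}


def event_recovery(seed: int = 0) -> dict:
    """Initiation-rate and loss-ratio recovery at published parameters.

    Simulates branch-event tables with GCB initiation 2.22/neuron/h and
    loss probabilities 0.13 (wild-type-like) and 0.58 (mutant-like), then
    recovers each with the event statistics; also verifies the statistics
    against brute-force recounts.
    """
    seeds = _sub_seeds(seed, 3, 3000)
    out = {}
    spec = syndata.SynthEventTableSpec(
        n_neurons=200, duration_h=2.0, gcb_rate_per_h=2.22, ib_rate_per_h=0.0,
        gcb_loss_prob=0.13, seed=int(seeds[0]))
    ev = syndata.generate_event_table(spec)
    rate = branchmetrics.initiation_rate(ev, 2.0, n_neurons=200)["per_type"]["GCB"]
    out["gcb_rate_est"] = float(rate)
    out["gcb_rate_true"] = 2.22
    out["gcb_rate_se"] = float(np.sqrt(2.22 / 400.0))
    # exactness vs brute force
    out["recount_exact"] = bool(
        np.isclose(rate, len(ev) / 200 / 2.0)
        and np.isclose(branchmetrics.loss_ratio(ev)["per_type"]["GCB"],
                       ev.retracted.sum() / len(ev))
    )
    for label, p_loss, s in (("wt", 0.13, seeds[1]), ("mut", 0.58, seeds[2])):
        spec = syndata.SynthEventTableSpec(
            n_neurons=200, duration_h=2.0, gcb_rate_per_h=2.22,
            ib_rate_per_h=0.0, gcb_loss_prob=p_loss, seed=int(s))
        ev = syndata.generate_event_table(spec)
        lr = branchmetrics.loss_ratio(ev)["per_type"]["GCB"]
        out[f"loss_{label}_est"] = float(lr)
        out[f"loss_{label}_true"] = p_loss
        out[f"loss_{label}_sigma"] = float(np.sqrt(p_loss * (1 - p_loss) / len(ev)))
        out[f"loss_{label}_n_events"] = int(len(ev))
    return out


# ---------------------------------------------------------------------------
# kymograph transport

VELOCITY_SWEEP_UM_S = (0.1, 0.25, 0.5, 1.0, 2.0)


def _random_particles(rng, n, length_um):
    parts = []
    for _ in range(n):
        v = rng.choice([-1, 1]) * rng.uniform(0.1, 2.0)
        run = max(6.0, 14.0 * abs(v))
        parts.append((rng.uniform(0, 200), rng.uniform(2, length_um - 2), v, run, 1.0))
    return parts


def velocity_recovery(seed: int = 0, n_seeds_snr3: int = 20) -> dict:
    """Velocity, direction and detection benchmarks for kymograph tracks.

    Noise-free: single constant-velocity particles across the
    physiological sweep (relative velocity error), plus 200 random clean
    tracks for sign-exact direction classification.  SNR 3: detection F1
    and direction accuracy over seeded 20-particle movies.
    """
    out = {}
    rel_errs = []
    for v, interval in zip(VELOCITY_SWEEP_UM_S, (5.0, 4.0, 3.0, 2.0, 2.0)):
        spec = syndata.SynthMovieSpec(
            path_length_um=40.0, frame_interval_s=interval, n_frames=120,
            particles=[(0.0, 2.0, v, max(6.0, 14.0 * v), 1.0)])
        prof, _ = syndata.generate_particle_movie(spec)
        k = kymo.Kymograph.from_profile(prof, spec.px_size_um, spec.frame_interval_s)
        tracks = kymo.detect_tracks(k)
        if len(tracks) != 1:
            rel_errs.append(np.inf)
            continue
        rel_errs.append(abs(tracks[0].velocity_um_s - v) / v)
    out["velocity_max_rel_err"] = float(max(rel_errs))

    # direction classification on clean data: 200 tracks
    n_dir, n_dir_ok = 0, 0
    for s in _sub_seeds(seed, 20, 4000):
        rng = np.random.default_rng(int(s))
        spec = syndata.SynthMovieSpec(
            path_length_um=60.0, frame_interval_s=2.0, n_frames=150,
            particles=_random_particles(rng, 10, 60.0), seed=int(s))
        prof, gt = syndata.generate_particle_movie(spec)
        k = kymo.Kymograph.from_profile(prof, spec.px_size_um, spec.frame_interval_s)
        tracks = kymo.detect_tracks(k)
        m = kymo.match_tracks(tracks, gt)
        for di, ti in m["matches"]:
            n_dir += 1
            n_dir_ok += tracks[di].direction == gt.loc[ti, "direction"]
    out["direction_accuracy_noise_free"] = n_dir_ok / n_dir if n_dir else np.nan
    out["n_direction_tracks"] = n_dir

    f1s, accs = [], []
    for s in _sub_seeds(seed, n_seeds_snr3, 5000):
        rng = np.random.default_rng(int(s))
        spec = syndata.SynthMovieSpec(
            path_length_um=60.0, frame_interval_s=2.0, n_frames=150,
            particles=_random_particles(rng, 20, 60.0), snr=3.0, seed=int(s))
        prof, gt = syndata.generate_particle_movie(spec)
        k = kymo.Kymograph.from_profile(prof, spec.px_size_um, spec.frame_interval_s)
        m = kymo.match_tracks(kymo.detect_tracks(k), gt)
        f1s.append(m["f1"])
        accs.append(m["direction_accuracy"])
    out["f1_snr3"] = float(np.mean(f1s))
    out["direction_accuracy_snr3"] = float(np.nanmean(accs))
    return out


# ---------------------------------------------------------------------------
# accumulation

def accumulation_checks() -> dict:
    """Closed-form ramp check and affine-gain invariance (deterministic)."""
    n_pre, n_post = 10, 40
    mid_t4 = n_pre + 3.5 * n_post / 4.0
    alpha = 1.0 / (mid_t4 - n_pre)  # doubles by the t4 midpoint
    stack = np.ones((n_pre + n_post, 8, 8))
    for f in range(n_pre, n_pre + n_post):
        stack[f] *= 1.0 + alpha * (f - n_pre)
    roi = (2, 6, 2, 6)
    series = kymo.branchpoint_accumulation(stack, roi, activation_frame=n_pre)
    windows = np.array_split(np.arange(n_pre, n_pre + n_post), 4)
    expected = np.array([alpha * (wi[-1] - n_pre) for wi in windows])
    expected = 100.0 * expected / expected[0]
    rel_err = float(np.max(np.abs(series.normalized_pct - expected) / expected))
    rescaled = kymo.branchpoint_accumulation(3.0 * stack + 7.0, roi,
                                             activation_frame=n_pre)
    gain_dev = float(np.max(np.abs(series.normalized_pct - rescaled.normalized_pct)))
    return {"t4_rel_err": rel_err, "t4_normalized_pct": float(series.normalized_pct[3]),
            "gain_invariance_dev_pct": gain_dev}


# ---------------------------------------------------------------------------
# behavior

def freezing_fidelity(seed: int = 0, n_seeds: int = 50) -> dict:
    """Freeze-bout detection on trajectories with programmed bouts.

    Jitter stays below the speed threshold and every programmed bout is
    at least 3 s, so precision and recall should both be 1.  Also checks
    zone-time conservation and the mobile >= total velocity bound.
    """
    tp = fp = fn = 0
    conservation_ok = True
    mobile_ok = True
    for s in _sub_seeds(seed, n_seeds, 6000):
        spec = syndata.SynthTrajectorySpec(seed=int(s), duration_s=300.0,
                                           jitter_cm_s=0.05,
                                           upper_zone_preference=0.4)
        traj, gt = syndata.generate_trajectory(spec)
        T = Trajectory(traj, spec.fps, *spec.tank_size_cm)
        bouts = behavior.detect_freezing(T)
        tol = 1.0 / spec.fps + 1e-9
        truth = list(gt.freeze_bouts.itertuples())
        used = set()
        for b in bouts:
            hit = None
            for j, r in enumerate(truth):
                if j not in used and abs(b.start_s - r.start_s) <= tol \
                        and abs(b.end_s - r.end_s) <= tol:
                    hit = j
                    break
            if hit is None:
                fp += 1
            else:
                used.add(hit)
                tp += 1
        fn += len(truth) - len(used)
        summ = behavior.tank_session(T)
        conservation_ok &= np.isclose(
            summ.time_in_upper_s + summ.time_in_lower_s, summ.session_length_s)
        mobile_ok &= summ.mobile_velocity_cm_s >= summ.total_velocity_cm_s - 1e-9
    precision = tp / (tp + fp) if (tp + fp) else np.nan
    recall = tp / (tp + fn) if (tp + fn) else np.nan
    return {"precision": precision, "recall": recall, "n_true_bouts": tp + fn,
            "conservation_ok": bool(conservation_ok),
            "mobile_ge_total_ok": bool(mobile_ok)}


NOVEL_TANK_DESIGN = dict(p_freeze_mut=0.43, p_freeze_wt=0.03, n_mut=30, n_wt=39)
MIDLINE_DESIGN = dict(rate_mut=0.04, rate_wt=0.01, n_mut_embryos=50,
                      n_wt_embryos=20, neurons_per_embryo=30)


def behavioral_power(seed: int = 0, n_reps: int = 200) -> dict:
    """Power of the group comparisons at the study sample sizes.

    Novel-tank freezing: probabilities 0.43 vs 0.03 at n = 30 vs 39 fish
    (Fisher exact on the froze flag).  Midline crossing: per-neuron rates
    0.04 vs 0.01 over 50 vs 20 embryos of ~30 neurons (Mann-Whitney on
    per-embryo percentages).
    """
    rng = np.random.default_rng([seed, 7000])
    freeze_hits = 0
    midline_hits = 0
    import pandas as pd

    for _ in range(n_reps):
        rows = []
        for grp, n, p in (("mut", NOVEL_TANK_DESIGN["n_mut"], NOVEL_TANK_DESIGN["p_freeze_mut"]),
                          ("wt", NOVEL_TANK_DESIGN["n_wt"], NOVEL_TANK_DESIGN["p_freeze_wt"])):
            froze = rng.random(n) < p
            for f in froze:
                rows.append(dict(entered_upper=True, latency_to_upper_s=50.0,
                                 time_in_upper_s=10.0, time_in_lower_s=170.0,
                                 pct_time_upper=5.6, n_freeze_bouts=int(f),
                                 total_frozen_s=15.0 * f, froze=bool(f),
                                 total_velocity_cm_s=2.0,
                                 mobile_velocity_cm_s=2.2,
                                 session_length_s=180.0, group=grp))
        res = behavior.group_session_stats(pd.DataFrame(rows))
        p_freeze = res["tests"].set_index("metric").loc["froze", "p"]
        freeze_hits += p_freeze < 0.05

        rows = []
        d = MIDLINE_DESIGN
        for e in range(d["n_mut_embryos"]):
            k = rng.binomial(d["neurons_per_embryo"], d["rate_mut"])
            for i in range(d["neurons_per_embryo"]):
                rows.append(dict(group="mut", embryo_id=f"m{e}",
                                 crosses_midline=i < k))
        for e in range(d["n_wt_embryos"]):
            k = rng.binomial(d["neurons_per_embryo"], d["rate_wt"])
            for i in range(d["neurons_per_embryo"]):
                rows.append(dict(group="wt", embryo_id=f"w{e}",
                                 crosses_midline=i < k))
        res = branchmetrics.midline_crossing_fraction(pd.DataFrame(rows),
                                                      group_col="group")
        midline_hits += res["test"]["p"] < 0.05
    return {"freeze_power": freeze_hits / n_reps,
            "midline_power": midline_hits / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# published-value recoveries (geometry and proportions)

def published_value_recoveries(seed: int = 0) -> dict:
    """Recover published point values used as generator parameters."""
    import pandas as pd

    out = {}
    # sister-branch separation programmed at the wild-type 15-min mean
    half = np.deg2rad(96.5 / 2.0)
    a = pd.DataFrame(dict(t_min=[0.0, 15.0], x_um=[0.0, 20 * np.cos(half)],
                          y_um=[0.0, -20 * np.sin(half)]))
    b = pd.DataFrame(dict(t_min=[0.0, 15.0], x_um=[0.0, 20 * np.cos(half)],
                          y_um=[0.0, 20 * np.sin(half)]))
    out["sister_angle_15min_deg"] = branchmetrics.sister_branch_angle(a, b)[15.0]

    # novel-tank upper-zone entry at the published per-group proportions
    rng = np.random.default_rng([seed, 8000])
    rows = []
    for grp, n, p_enter in (("wt", 33, 0.909), ("mut", 32, 0.188)):
        entered = rng.random(n) < p_enter
        for e in entered:
            rows.append(dict(entered_upper=bool(e),
                             latency_to_upper_s=100.0 if e else None,
                             time_in_upper_s=14.0 * e, time_in_lower_s=166.0,
                             pct_time_upper=7.8 * e, n_freeze_bouts=0,
                             total_frozen_s=0.0, froze=False,
                             total_velocity_cm_s=2.0, mobile_velocity_cm_s=2.0,
                             session_length_s=180.0, group=grp))
    res = behavior.group_session_stats(pd.DataFrame(rows))
    out["pct_entered_upper_wt"] = res["per_group"]["wt"]["pct_entered_upper"]
    out["pct_entered_upper_mut"] = res["per_group"]["mut"]["pct_entered_upper"]

    # nascent-branch acetylation at the 50% wild-type-like proportion
    branches = pd.DataFrame(dict(length_um=np.full(132, 6.0),
                                 signal_present=[True] * 66 + [False] * 66))
    out["pct_acetylated_nascent"] = branchmetrics.nascent_branch_acetylation(
        branches)["pct_with_signal"]
    return out
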