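"""Branch density and branch-dynamics statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arborquant.branchmetrics import (
    compare_density,
    count_branch_crossings,
    fasciculation_stats,
    growth_direction_histogram,
    growth_velocity,
    initiation_rate,
    loss_ratio,
    midline_crossing_fraction,
    nascent_branch_acetylation,
    retraction_direction_bias,
    sister_branch_angle,
)
from arborquant.errors import ConfigError
from arborquant.images import PixelImage
from arborquant.roi import ROIGrid
from arborquant.syndata import (
    SynthArborSpec,
    SynthEventTableSpec,
    generate_arbor_image,
    generate_event_table,
)

# ---------------------------------------------------------------------------
# density


def test_blank_image_counts_zero_everywhere():
    img = PixelImage(np.zeros((100, 100)), 0.5)
    grid = ROIGrid.standard_for_image((100, 100), 0.5)
    assert count_branch_crossings(img, grid).counts.sum() == 0


def test_counts_match_ground_truth_on_noise_free_arbors():
    for seed in range(8):
        img, gt = generate_arbor_image(SynthArborSpec(seed=seed))
        prof = count_branch_crossings(img, gt.grid)
        assert np.array_equal(prof.counts, gt.band_crossings), f"seed {seed}"


def test_counts_invariant_under_global_intensity_scaling():
    img, gt = generate_arbor_image(SynthArborSpec(seed=5))
    scaled = PixelImage(img.data * 3.0, img.px_size_um)
    a = count_branch_crossings(img, gt.grid).counts
    b = count_branch_crossings(scaled, gt.grid).counts
    assert np.array_equal(a, b)


def test_grid_outside_image_names_offending_roi():
    img = PixelImage(np.zeros((40, 40)), 0.5)
    grid = ROIGrid(n_rois=8, roi_height_um=3.0, spacing_um=2.0, top_anchor_um=0.0)
    with pytest.raises(ConfigError, match="ROI"):
        count_branch_crossings(img, grid)


def _density_frame(counts_per_embryo):
    rows = []
    for e, counts in enumerate(counts_per_embryo):
        for i, c in enumerate(counts, start=1):
            rows.append(dict(embryo_id=e, roi=i, count=c))
    return pd.DataFrame(rows)


def test_identical_density_groups_not_significant():
    g = _density_frame([[5, 6, 7, 8, 7, 6, 5, 4]] * 3)
    cmp_ = compare_density(g, g.copy())
    assert cmp_.p == pytest.approx(1.0)


def test_halved_counts_halve_the_auc():
    a = _density_frame([[8, 8, 8, 8, 8, 8, 8, 8]] * 3)
    b = _density_frame([[4, 4, 4, 4, 4, 4, 4, 4]] * 3)
    cmp_ = compare_density(a, b)
    assert cmp_.mean_a / cmp_.mean_b == pytest.approx(2.0)


def test_density_power_poisson_10_vs_7():
    # per-ROI Poisson means 10 vs 7, n=30 embryos/group: AUC t-test should
    # reject at alpha=0.05 in at least 80% of 200 replicates
    rng = np.random.default_rng(2024)
    rejections = 0
    for _ in range(200):
        a = _density_frame(rng.poisson(10.0, size=(30, 8)))
        b = _density_frame(rng.poisson(7.0, size=(30, 8)))
        rejections += compare_density(a, b).p < 0.05
    assert rejections >= 160


# ---------------------------------------------------------------------------
# event statistics


def _events(n_gcb, n_gcb_retracted, n_ib=0, n_ib_retracted=0):
    rows = []
    for i in range(n_gcb):
        rows.append(dict(neuron_id=0, type="GCB", t_init_min=float(i),
                         retracted=i < n_gcb_retracted, direction=None))
    for i in range(n_ib):
        rows.append(dict(neuron_id=0, type="IB", t_init_min=float(i),
                         retracted=i < n_ib_retracted, direction=None))
    return pd.DataFrame(rows)


def test_initiation_rate_simple_count():
    res = initiation_rate(_events(4, 0), obs_duration_h=2.0)
    assert res["per_type"]["GCB"] == pytest.approx(2.0)


def test_initiation_rate_empty_table_is_zero():
    res = initiation_rate(pd.DataFrame(columns=["neuron_id", "type", "retracted"]),
                          obs_duration_h=2.0, n_neurons=5)
    assert res["per_type"].empty


def test_loss_ratio_fraction_and_undefined_marker():
    res = loss_ratio(_events(12, 7))
    assert res["per_type"]["GCB"] == pytest.approx(7 / 12)
    res0 = loss_ratio(_events(5, 0))
    assert res0["per_type"]["GCB"] == 0.0
    # absent type: no entry rather than a silent 0
    assert "IB" not in res0["per_type"].index


def test_event_statistics_match_brute_force_recount():
    ev = generate_event_table(SynthEventTableSpec(n_neurons=40, seed=8))
    rates = initiation_rate(ev, obs_duration_h=2.0, n_neurons=40)["per_type"]
    losses = loss_ratio(ev)["per_type"]
    for btype in ("GCB", "IB"):
        sub = ev[ev.type == btype]
        assert rates[btype] == pytest.approx(len(sub) / 40 / 2.0)
        assert losses[btype] == pytest.approx(sub.retracted.sum() / len(sub))


def test_rate_and_loss_recovery_at_published_parameters():
    # GCB initiation 2.22/h and mutant-like loss probability 0.58 used as
    # simulation parameters; estimates within 3 SE / 3 sigma
    spec = SynthEventTableSpec(n_neurons=200, duration_h=2.0,
                               gcb_rate_per_h=2.22, gcb_loss_prob=0.58,
                               ib_rate_per_h=0.0, seed=17)
    ev = generate_event_table(spec)
    rate = initiation_rate(ev, 2.0, n_neurons=200)["per_type"]["GCB"]
    se_rate = np.sqrt(2.22 / (200 * 2.0))
    assert abs(rate - 2.22) <= 3 * se_rate
    n = len(ev)
    assert n >= 500
    lr = loss_ratio(ev)["per_type"]["GCB"]
    assert abs(lr - 0.58) <= 3 * np.sqrt(0.58 * 0.42 / n)


def test_retraction_bias_extremes_and_type1_error():
    all_ant = pd.DataFrame(dict(neuron_id=[0, 0], type=["GCB"] * 2,
                                retracted=[True, True],
                                direction=["anterior", "anterior"]))
    assert retraction_direction_bias(all_ant)["mean_pct_anterior"] == 100.0
    # unbiased simulation: the test against 50% should rarely reject
    rng = np.random.default_rng(5)
    false_pos = 0
    for _ in range(100):
        df = pd.DataFrame(dict(
            neuron_id=np.repeat(np.arange(100), 6), type="GCB", retracted=True,
            direction=rng.choice(["anterior", "posterior"], size=600),
        ))
        false_pos += retraction_direction_bias(df)["p"] < 0.05
    assert false_pos <= 10


# ---------------------------------------------------------------------------
# growth tracks


def _track(points, dt_min=1.0):
    return pd.DataFrame(dict(t_min=np.arange(len(points)) * dt_min,
                             x_um=[p[0] for p in points],
                             y_um=[p[1] for p in points]))


def test_growth_velocity_straight_and_stationary():
    assert growth_velocity(_track([(0, 0), (10, 0)], dt_min=5.0)) == pytest.approx(2.0)
    assert growth_velocity(_track([(3, 3)] * 4)) == 0.0


def test_growth_velocity_counts_path_length_not_displacement():
    # 20 unit steps zig-zagging over 10 min: 2 um/min regardless of turns
    pts = [(0, 0)]
    for i in range(20):
        pts.append((pts[-1][0] + (1 if i % 2 == 0 else 0),
                    pts[-1][1] + (0 if i % 2 == 0 else 1)))
    assert growth_velocity(_track(pts, dt_min=0.5)) == pytest.approx(2.0)


def test_growth_velocity_invariant_under_time_reversal():
    rng = np.random.default_rng(9)
    pts = rng.random((10, 2)) * 20
    fwd = _track(pts)
    rev = _track(pts[::-1])
    assert growth_velocity(fwd) == pytest.approx(growth_velocity(rev))


def test_rose_histogram_posterior_track_and_counts():
    tr = _track([(0, 0), (5, 0), (10, 0)])  # +x = posterior
    rose = growth_direction_histogram(tr)
    assert rose.posterior_fraction == 1.0
    assert rose.counts.sum() == rose.n_steps == 2


def test_rose_quadrant_bookkeeping():
    # one step anterior-ward (-x) and ventral-ward (+y in image coords)
    tr = _track([(0, 0), (-1, 1)])
    rose = growth_direction_histogram(tr, sector_deg=90.0)
    # angle = atan2(-1, -1) = 225 deg -> anterior-ventral quadrant
    assert rose.counts[2] == 1
    assert rose.anterior_fraction == 1.0


def test_rose_symmetric_random_walk_is_unbiased():
    rng = np.random.default_rng(11)
    steps = rng.normal(size=(10_000, 2))
    pts = np.cumsum(np.vstack([[0, 0], steps]), axis=0)
    rose = growth_direction_histogram(_track(pts))
    assert abs(rose.anterior_fraction - 0.5) <= 3 * np.sqrt(0.25 / 10_000)


def test_sister_branch_angle_geometry():
    a = _track([(0, 0), (0, -10)], dt_min=15.0)   # straight dorsal
    b = _track([(0, 0), (0, 10)], dt_min=15.0)    # straight ventral
    assert sister_branch_angle(a, b, offsets_min=(15.0,))[15.0] == pytest.approx(180.0)
    c = _track([(0, 0), (10, 0)], dt_min=15.0)
    assert sister_branch_angle(b, c, offsets_min=(15.0,))[15.0] == pytest.approx(90.0)


def test_sister_branch_angle_programmed_separation_recovered():
    # branches opened symmetrically to a 96.5 degree separation
    half = np.deg2rad(96.5 / 2)
    a = _track([(0, 0), (20 * np.cos(half), -20 * np.sin(half))], dt_min=15.0)
    b = _track([(0, 0), (20 * np.cos(half), 20 * np.sin(half))], dt_min=15.0)
    res = sister_branch_angle(a, b)
    assert res[15.0] == pytest.approx(96.5, abs=1e-9)
    assert np.isnan(res[75.0])  # branches end before 75 min -> no data
    sym = sister_branch_angle(b, a)
    assert sym[15.0] == pytest.approx(res[15.0])


# ---------------------------------------------------------------------------
# fasciculation / midline / acetylation


def test_fasciculation_frequency_and_empty():
    empty = fasciculation_stats(
        pd.DataFrame(columns=["neuron_id", "class", "length_um", "resolved"]), 10
    )
    assert empty["events_per_neuron"] == 0.0
    assert len(empty["lengths_um"]) == 0
    ev = pd.DataFrame(dict(neuron_id=range(19), **{"class": "non-self"},
                           length_um=np.linspace(7.5, 60.5, 19), resolved=True))
    res = fasciculation_stats(ev, 37)
    assert res["events_per_neuron"] == pytest.approx(19 / 37)


def test_fasciculation_lengths_stay_in_sampled_support():
    rng = np.random.default_rng(1)
    lengths = rng.uniform(7.5, 60.5, size=10_000)
    ev = pd.DataFrame(dict(neuron_id=0, **{"class": "self"},
                           length_um=lengths, resolved=False))
    res = fasciculation_stats(ev, 100)
    assert res["length_summary"]["min"] >= 7.5
    assert res["length_summary"]["max"] <= 60.5


def test_midline_fraction_per_embryo():
    df = pd.DataFrame(dict(embryo_id=[0] * 50, crosses_midline=[True] * 2 + [False] * 48))
    res = midline_crossing_fraction(df)
    assert res["per_embryo_pct"].iloc[0] == pytest.approx(4.0)


def test_midline_power_at_study_design():
    # rates 0.04 vs 0.01, 50 vs 20 embryos of ~30 neurons, Mann-Whitney:
    # rejection in >= 80% of 200 replicates
    rng = np.random.default_rng(77)
    rejections = 0
    for _ in range(200):
        rows = []
        for e in range(50):
            rows.append(dict(group="wt", embryo_id=e,
                             pct=100 * rng.binomial(30, 0.04) / 30))
        for e in range(20):
            rows.append(dict(group="mut", embryo_id=e,
                             pct=100 * rng.binomial(30, 0.01) / 30))
        df = pd.DataFrame(rows)
        from scipy.stats import mannwhitneyu

        _, p = mannwhitneyu(df[df.group == "wt"].pct, df[df.group == "mut"].pct,
                            alternative="two-sided")
        rejections += p < 0.05
    assert rejections >= 160


def test_nascent_filter_excludes_long_branches():
    df = pd.DataFrame(dict(length_um=[5.0, 8.0, 12.0, 9.0],
                           signal_present=[True, False, True, True],
                           embryo_id=[0, 0, 1, 1]))
    res = nascent_branch_acetylation(df)
    assert res["n_admitted"] == 3
    assert res["n_excluded"] == 1
    assert res["pct_with_signal"] == pytest.approx(100 * 2 / 3)


def test_acetylation_percentage_simple():
    df = pd.DataFrame(dict(length_um=np.full(132, 5.0),
                           signal_present=[True] * 66 + [False] * 66))
    assert nascent_branch_acetylation(df)["pct_with_signal"] == pytest.approx(50.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.booleans(), min_size=1, max_size=60),
       st.integers(min_value=1, max_value=20))
def test_loss_ratio_matches_recount_property(flags, n_neurons):
    df = pd.DataFrame(dict(
        neuron_id=np.arange(len(flags)) % n_neurons,
        type="GCB", t_init_min=np.arange(len(flags), dtype=float),
        retracted=flags, direction=None,
    ))
    assert loss_ratio(df)["per_type"]["GCB"] == pytest.approx(
        sum(flags) / len(flags)
    )
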