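"""Branch-density profiling and branch-dynamics statistics.

Density: the number of thresholded objects crossing each band of a
dorsoventral ROI grid (8 bands of 3 µm by default), compared between
groups by per-embryo area under the ROI-index curve.

Dynamics: initiation rates (branches/neuron/hour by branch type), loss
ratios (retracted / total branching events), retraction direction bias,
growth-cone velocity and direction rose histograms, sister-branch
separation angles, fasciculation statistics, midline-crossing fractions,
and acetylated-tubulin scoring of nascent (≤ 10 µm) branches.

Branch events and growth tracks are inputs (scored upstream); this module
computes statistics, it does not detect events in movies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import ConfigError
from .images import PixelImage
from .orientation import AUCComparison, _se
from .roi import ROIGrid

NASCENT_BRANCH_MAX_UM = 10.0


# ---------------------------------------------------------------------------
# density

@dataclass
class DensityProfile:
    """Object counts per ROI band for one image/embryo."""

    counts: np.ndarray
    grid: ROIGrid

    def to_frame(self, embryo_id=None) -> pd.DataFrame:
        df = pd.DataFrame({"roi": np.arange(1, len(self.counts) + 1),
                           "count": self.counts})
        if embryo_id is not None:
            df.insert(0, "embryo_id", embryo_id)
        return df


def count_branch_crossings(image: PixelImage, grid: ROIGrid,
                           threshold_method: str = "otsu",
                           min_object_px: int = 2,
                           rel_signal_floor: float = 0.02) -> DensityProfile:
    """Count thresholded objects inside each ROI band.

    Each band is cropped, thresholded (Otsu by default), binarized, and
    connected components of at least ``min_object_px`` pixels are
    counted.  A band whose dynamic range is below ``rel_signal_floor``
    of the whole image's dynamic range is treated as signal-free and
    counts zero (Otsu on a near-empty strip would otherwise binarize
    faint tails of structures lying outside the band).
    """
    if threshold_method != "otsu":
        raise ConfigError(f"unknown threshold_method {threshold_method!r}")
    grid.validate_for_image(image.shape, image.px_size_um)
    x0, x1 = grid.x_bounds_px(image.px_size_um, image.shape[1])
    dyn = float(image.data.max() - image.data.min())
    counts = []
    for y0, y1 in grid.band_bounds_px(image.px_size_um):
        crop = image.data[y0:y1, x0:x1]
        if crop.size == 0 or crop.max() - crop.min() <= rel_signal_floor * dyn:
            counts.append(0)
            continue
        binary = crop > threshold_otsu(crop)
        lab = label(binary, connectivity=2)
        n = sum(1 for r in regionprops(lab) if r.area >= min_object_px)
        counts.append(n)
    return DensityProfile(np.asarray(counts, dtype=int), grid)


def compare_density(group_a: pd.DataFrame, group_b: pd.DataFrame,
                    roi_subset=None) -> AUCComparison:
    """Welch t-test on per-embryo AUC of the count-vs-ROI-index curve.

    Groups are tidy frames with columns ``embryo_id, roi, count``.
    ``roi_subset`` restricts the AUC to a list of ROI indices (1-based).
    """

    def _aucs(df):
        out = []
        for _, g in df.groupby("embryo_id"):
            g = g.sort_values("roi")
            if roi_subset is not None:
                g = g[g.roi.isin(roi_subset)]
            if len(g) < 2:
                raise ConfigError("need at least two ROIs per embryo for an AUC")
            out.append(np.trapezoid(g["count"].to_numpy(), g["roi"].to_numpy()))
        return np.array(out, dtype=float)

    a, b = _aucs(group_a), _aucs(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("need at least two embryos per group")
    ma, mb = float(a.mean()), float(b.mean())
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
        t, p = (0.0, 1.0) if np.isclose(ma, mb) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    rois = sorted(roi_subset) if roi_subset is not None else sorted(group_a.roi.unique())
    direction = "A>B" if ma > mb else ("B>A" if mb > ma else "A=B")
    return AUCComparison((float(rois[0]), float(rois[-1])), a, b, ma, mb, _se(a), _se(b),
                         float(t), float(p), direction)


# ---------------------------------------------------------------------------
# branch events

def _require_events(events: pd.DataFrame):
    missing = {"neuron_id", "type", "retracted"} - set(events.columns)
    if missing:
        raise ConfigError(f"event table lacks columns {sorted(missing)}")


def initiation_rate(events: pd.DataFrame, obs_duration_h: float,
                    n_neurons: int | None = None) -> dict:
    """Branch initiations per neuron per hour, by branch type.

    Returns ``{"per_type": Series, "per_neuron": DataFrame}``; the
    per-neuron rates (neuron × type) are retained for dispersion and
    group tests.  ``n_neurons`` defaults to the distinct neurons in the
    table — pass it explicitly if some neurons produced no events.
    """
    if obs_duration_h <= 0:
        raise ConfigError("obs_duration_h must be positive")
    _require_events(events)
    if n_neurons is None:
        n_neurons = max(events.neuron_id.nunique(), 1)
    types = sorted(events["type"].unique()) if len(events) else []
    per_type = pd.Series(
        {t: len(events[events["type"] == t]) / n_neurons / obs_duration_h
         for t in types},
        dtype=float, name="rate_per_neuron_per_h",
    )
    if len(events):
        per_neuron = (
            events.groupby(["neuron_id", "type"]).size().unstack(fill_value=0)
            / obs_duration_h
        )
    else:
        per_neuron = pd.DataFrame()
    return {"per_type": per_type, "per_neuron": per_neuron}


def loss_ratio(events: pd.DataFrame) -> dict:
    """Branch loss ratio (retracted / total events) by branch type.

    A type with zero events has an undefined ratio, reported as NaN (an
    explicit undefined marker — never 0).  Per-neuron ratios are also
    emitted, since group comparisons are typically made on per-neuron
    means.
    """
    _require_events(events)
    types = sorted(events["type"].unique()) if len(events) else []
    pooled = pd.Series(
        {t: (events.loc[events["type"] == t, "retracted"].mean()
             if (events["type"] == t).any() else np.nan) for t in types},
        dtype=float, name="loss_ratio",
    )
    if len(events):
        per_neuron = (
            events.groupby(["neuron_id", "type"])["retracted"].mean().unstack()
        )
    else:
        per_neuron = pd.DataFrame()
    return {"per_type": pooled, "per_neuron": per_neuron}


def retraction_direction_bias(events: pd.DataFrame) -> dict:
    """Per-neuron percent of retracted branches directed anteriorly.

    Returns per-neuron percentages, their group mean, and a two-sided
    one-sample t-test against the unbiased 50%.
    """
    _require_events(events)
    lost = events[events.retracted & events.direction.notna()]
    if lost.empty:
        return {"per_neuron_pct_anterior": pd.Series(dtype=float),
                "mean_pct_anterior": np.nan, "t": np.nan, "p": np.nan}
    pct = lost.groupby("neuron_id")["direction"].apply(
        lambda d: 100.0 * (d == "anterior").mean()
    )
    if pct.nunique() <= 1:
        t, p = (0.0, 1.0) if np.isclose(pct.iloc[0], 50.0) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_1samp(pct, 50.0)
    return {"per_neuron_pct_anterior": pct, "mean_pct_anterior": float(pct.mean()),
            "t": float(t), "p": float(p)}


# ---------------------------------------------------------------------------
# growth tracks

def _steps(track: pd.DataFrame):
    t = track["t_min"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ConfigError("a growth track needs at least two samples")
    if not np.all(np.diff(t) > 0):
        raise ConfigError("track times must be strictly increasing")
    dx = np.diff(track["x_um"].to_numpy(dtype=float))
    dy = np.diff(track["y_um"].to_numpy(dtype=float))
    return t, dx, dy


def growth_velocity(track: pd.DataFrame) -> float:
    """Accumulated path length over elapsed time, in µm/min."""
    t, dx, dy = _steps(track)
    return float(np.hypot(dx, dy).sum() / (t[-1] - t[0]))


@dataclass
class RoseHistogram:
    """Directional histogram of per-step growth angles on [0°, 360°)."""

    sector_edges_deg: np.ndarray
    counts: np.ndarray
    resultant_length: float
    mean_angle_deg: float
    anterior_fraction: float
    posterior_fraction: float
    n_steps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sector_lo_deg": self.sector_edges_deg[:-1],
                             "sector_hi_deg": self.sector_edges_deg[1:],
                             "count": self.counts})


def growth_direction_histogram(track: pd.DataFrame,
                               sector_deg: float = 15.0) -> RoseHistogram:
    """Rose histogram of frame-to-frame growth directions.

    Angles follow the anterior-left convention with 0° pointing posterior
    (+x) and 90° dorsal (up); anterior-directed steps fall in (90°, 270°).
    Zero-length steps carry no direction and are excluded from the count.
    """
    if not 0 < sector_deg <= 360 or 360.0 % sector_deg > 1e-9:
        raise ConfigError("sector_deg must divide 360")
    _, dx, dy = _steps(track)
    keep = (dx != 0) | (dy != 0)
    dx, dy = dx[keep], dy[keep]
    ang = np.rad2deg(np.arctan2(-dy, dx)) % 360.0  # image y runs ventral-down
    edges = np.arange(0.0, 360.0 + sector_deg / 2, sector_deg)
    counts, _ = np.histogram(ang, bins=edges)
    n = len(ang)
    if n:
        c = np.exp(1j * np.deg2rad(ang)).mean()
        r, mean_ang = float(np.abs(c)), float(np.rad2deg(np.angle(c)) % 360.0)
        ant = float(np.mean((ang > 90.0) & (ang < 270.0)))
    else:
        r, mean_ang, ant = np.nan, np.nan, np.nan
    return RoseHistogram(edges, counts, r, mean_ang, ant,
                         1.0 - ant if n else np.nan, n)


def sister_branch_angle(branch_a: pd.DataFrame, branch_b: pd.DataFrame,
                        offsets_min=(15.0, 75.0)) -> dict:
    """Angle between sister branches at fixed offsets after bifurcation.

    Each branch is a track of (t_min, x_um, y_um) starting at the
    bifurcation node (t=0).  At each offset the angle between the two
    node-to-tip vectors is returned in degrees [0, 180]; an offset at
    which either branch no longer exists (it retracted before then)
    yields NaN.  Symmetric in branch order.
    """
    node = branch_a[["x_um", "y_um"]].iloc[0].to_numpy(dtype=float)
    node_b = branch_b[["x_um", "y_um"]].iloc[0].to_numpy(dtype=float)
    if not np.allclose(node, node_b, atol=1e-6):
        raise ConfigError("sister branches must share their bifurcation node")
    out = {}
    for off in offsets_min:
        vecs = []
        for br in (branch_a, branch_b):
            t = br["t_min"].to_numpy(dtype=float)
            if t[-1] < off - 1e-9:
                vecs = None
                break
            x = np.interp(off, t, br["x_um"].to_numpy(dtype=float))
            y = np.interp(off, t, br["y_um"].to_numpy(dtype=float))
            vecs.append(np.array([x, y]) - node)
        if vecs is None or any(np.linalg.norm(v) == 0 for v in vecs):
            out[off] = np.nan
            continue
        u, v = (w / np.linalg.norm(w) for w in vecs)
        out[off] = float(np.rad2deg(np.arccos(np.clip(u @ v, -1.0, 1.0))))
    return out


# ---------------------------------------------------------------------------
# fasciculation, midline, acetylation

def fasciculation_stats(events: pd.DataFrame, n_neurons: int) -> dict:
    """Per-neuron fasciculation frequency by class, lengths, resolution.

    ``events`` columns: neuron_id, class ('self'/'non-self'), length_um
    (measured at the last frame of the imaging period), resolved (bool).
    """
    if n_neurons <= 0:
        raise ConfigError("n_neurons must be positive")
    if len(events) and (events["length_um"] < 0).any():
        raise ConfigError("fasciculation lengths must be non-negative")
    by_class = {
        cls: len(events[events["class"] == cls]) / n_neurons
        for cls in ("self", "non-self")
    }
    lengths = events["length_um"].to_numpy(dtype=float) if len(events) else np.array([])
    return {
        "events_per_neuron": len(events) / n_neurons,
        "events_per_neuron_by_class": by_class,
        "lengths_um": lengths,
        "length_summary": {
            "n": len(lengths),
            "mean": float(lengths.mean()) if len(lengths) else np.nan,
            "min": float(lengths.min()) if len(lengths) else np.nan,
            "max": float(lengths.max()) if len(lengths) else np.nan,
        },
        "resolved_fraction": float(events["resolved"].mean()) if len(events) else np.nan,
    }


def midline_crossing_fraction(neurons: pd.DataFrame,
                              group_col: str | None = None) -> dict:
    """Percent of neurons per embryo with a midline-crossing protrusion.

    ``neurons`` columns: embryo_id, crosses_midline (bool) and optionally
    a group column.  With exactly two groups a Mann-Whitney test on the
    per-embryo percentages is included.
    """
    if neurons.empty:
        raise ConfigError("neuron table is empty")
    per_embryo = neurons.groupby(
        [group_col, "embryo_id"] if group_col else "embryo_id"
    )["crosses_midline"].mean().mul(100.0).rename("pct_crossing")
    out = {"per_embryo_pct": per_embryo}
    if group_col:
        groups = {g: v.to_numpy() for g, v in per_embryo.groupby(level=0)}
        summary = {g: {"mean": float(v.mean()), "sem": _se(v), "n_embryos": len(v)}
                   for g, v in groups.items()}
        out["group_summary"] = summary
        if len(groups) == 2:
            (ga, va), (gb, vb) = groups.items()
            if np.array_equal(np.sort(va), np.sort(vb)):
                u, p = np.nan, 1.0
            else:
                u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            out["test"] = {"name": "mannwhitney", "groups": (ga, gb),
                           "U": float(u), "p": float(p)}
    else:
        vals = per_embryo.to_numpy()
        out["group_summary"] = {"mean": float(vals.mean()), "sem": _se(vals),
                                "n_embryos": len(vals)}
    return out


def nascent_branch_acetylation(branches: pd.DataFrame) -> dict:
    """Percent of nascent branches (≤ 10 µm) with acetylated-tubulin signal.

    Branches longer than 10 µm are rejected by the nascent filter and
    reported in ``n_excluded``; percentages are computed among admitted
    branches only, with a per-embryo breakdown when embryo_id is present.
    """
    admitted = branches[branches["length_um"] <= NASCENT_BRANCH_MAX_UM]
    n_excluded = len(branches) - len(admitted)
    if admitted.empty:
        return {"pct_with_signal": np.nan, "n_admitted": 0,
                "n_excluded": n_excluded, "per_embryo_pct": pd.Series(dtype=float)}
    pct = 100.0 * admitted["signal_present"].mean()
    per_embryo = (
        admitted.groupby("embryo_id")["signal_present"].mean().mul(100.0)
        if "embryo_id" in admitted.columns else pd.Series(dtype=float)
    )
    return {"pct_with_signal": float(pct), "n_admitted": len(admitted),
            "n_excluded": n_excluded, "per_embryo_pct": per_embryo}
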