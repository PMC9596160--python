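"""Synthetic fluorescent arbor images with known orientation ground truth.

Renders a field of line segments ("neurites") whose orientations are drawn
from a mixture of axial von Mises components.  Line orientation is an
axial quantity (defined mod 180°), so each mixture component is a von
Mises distribution on the doubled angle; infinite concentration collapses
to the component mean exactly.

Segments are placed by rejection sampling under two geometric
constraints:

* a minimum centreline separation, so that on noise-free renders each
  segment remains a distinct connected component after thresholding;
* a clearance between segment endpoints and the edges of the standard
  8-band dorsoventral ROI grid, so that whether a segment crosses a band
  is unambiguous at the rendered tube width.

Together these make the per-band crossing counts in the ground truth
exactly recoverable by the branch-density counter on noise-free images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

from ..errors import ConfigError
from ..images import PixelImage
from ..roi import ROIGrid

#: concentration above which a mixture component is treated as a point mass
_KAPPA_POINT = 1e5


@dataclass
class SynthArborSpec:
    """Parameters of a synthetic arbor image.

    orientation_mixture is a list of (mean_angle_deg, concentration,
    weight) triples; mean angles follow the analysis convention
    (0° = anterior–posterior horizontal axis, negative = descending toward
    posterior, range (−90°, +90°]).  Weights must sum to 1.
    snr is peak signal over noise standard deviation; ``inf`` disables
    noise.
    """

    image_size_px: tuple = (192, 192)
    px_size_um: float = 0.5
    n_segments: int = 25
    orientation_mixture: list = field(
        default_factory=lambda: [(-60.0, 3.0, 0.5), (60.0, 3.0, 0.5)]
    )
    segment_length_um: tuple = (15.0, 35.0)
    tube_sigma_px: float = 1.2
    snr: float = float("inf")
    noise_model: str = "gaussian"
    seed: int = 0
    stratified_mixture: bool = False
    min_separation_px: float = 8.0
    edge_margin_px: float = 4.0

    def __post_init__(self):
        w = sum(c[2] for c in self.orientation_mixture)
        if abs(w - 1.0) > 1e-8:
            raise ConfigError(f"orientation mixture weights sum to {w}, expected 1")
        if self.px_size_um <= 0:
            raise ConfigError("px_size_um must be positive")
        if not self.snr > 0:
            raise ConfigError("snr must be positive")
        if self.noise_model not in ("gaussian", "poisson+gaussian"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        lo, hi = self.segment_length_um
        if lo <= 0 or hi < lo:
            raise ConfigError("segment_length_um must be a positive (lo, hi) range")


@dataclass
class ArborGroundTruth:
    """True geometry of a rendered arbor image."""

    segments: pd.DataFrame  # segment_id, angle_deg, x0..y1 (px), length_um
    band_crossings: np.ndarray  # distinct segments crossing each grid band
    grid: ROIGrid


def _wrap_axial(deg):
    """Wrap an angle to the axial range (−90, 90]."""
    a = (np.asarray(deg) + 90.0) % 180.0 - 90.0
    return np.where(a == -90.0, 90.0, a)


def sample_axial_mixture(mixture, n, rng, stratified: bool = False) -> np.ndarray:
    """Draw n axial angles (deg) from a von Mises mixture on doubled angles.

    With ``stratified=True`` the number of segments per component is the
    largest-remainder rounding of weight × n (exact mixture proportions
    in every image) instead of a multinomial draw.
    """
    weights = np.array([c[2] for c in mixture])
    if stratified:
        exact = weights / weights.sum() * n
        counts = np.floor(exact).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(exact - counts))
        counts[order[:rem]] += 1
        comp = rng.permutation(np.repeat(np.arange(len(mixture)), counts))
    else:
        comp = rng.choice(len(mixture), size=n, p=weights / weights.sum())
    out = np.empty(n)
    for i, (mean, kappa, _) in enumerate(mixture):
        m = comp == i
        k = m.sum()
        if k == 0:
            continue
        if kappa >= _KAPPA_POINT:
            out[m] = mean
        else:
            phi = rng.vonmises(np.deg2rad(2.0 * mean), kappa, size=k)
            out[m] = _wrap_axial(np.rad2deg(phi) / 2.0)
    return out


def _pts_to_segs(P, A, B):
    """Distance from each point P[i] to each segment A[j]-B[j]; (n, m)."""
    AB = B - A  # (m, 2)
    denom = np.einsum("ij,ij->i", AB, AB)
    denom[denom == 0] = 1.0
    AP = P[:, None, :] - A[None, :, :]  # (n, m, 2)
    t = np.clip(np.einsum("nmj,mj->nm", AP, AB) / denom[None, :], 0.0, 1.0)
    closest = A[None, :, :] + t[:, :, None] * AB[None, :, :]
    return np.linalg.norm(P[:, None, :] - closest, axis=2)


def _min_dist_to_placed(p1, p2, P1, P2) -> float:
    """Min distance between candidate segment p1-p2 and placed segments."""
    if len(P1) == 0:
        return np.inf
    P1, P2 = np.asarray(P1), np.asarray(P2)
    # endpoint-to-segment distances both ways
    d = min(
        _pts_to_segs(np.array([p1, p2]), P1, P2).min(),
        _pts_to_segs(np.vstack([P1, P2]), p1[None, :], p2[None, :]).min(),
    )
    # proper crossings → distance 0
    d1 = p2 - p1
    d2 = P2 - P1
    r = P1 - p1
    denom = d1[0] * d2[:, 1] - d1[1] * d2[:, 0]
    ok = np.abs(denom) > 1e-12
    if ok.any():
        t = (r[:, 0] * d2[:, 1] - r[:, 1] * d2[:, 0]) / np.where(ok, denom, 1.0)
        u = (r[:, 0] * d1[1] - r[:, 1] * d1[0]) / np.where(ok, denom, 1.0)
        if np.any(ok & (t >= 0) & (t <= 1) & (u >= 0) & (u <= 1)):
            return 0.0
    return float(d)


def _clear_of_edges(y, edges, clearance):
    return all(abs(y - e) >= clearance for e in edges)


def generate_arbor_image(spec: SynthArborSpec, grid: ROIGrid | None = None):
    """Render a synthetic arbor image.

    Returns
    -------
    (PixelImage, ArborGroundTruth)
        The ground truth lists the true orientation of every rendered
        segment and the true number of distinct segments crossing each
        band of the dorsoventral ROI grid (the standard 8-band grid for
        the image unless one is supplied).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    if grid is None:
        grid = ROIGrid.standard_for_image((h, w), spec.px_size_um)
    grid.validate_for_image((h, w), spec.px_size_um)
    edge_rows = [b for y0, y1 in grid.band_bounds_px(spec.px_size_um) for b in (y0, y1)]
    clearance = max(spec.edge_margin_px, 2.5 * spec.tube_sigma_px)

    angles = sample_axial_mixture(spec.orientation_mixture, spec.n_segments, rng,
                                  stratified=spec.stratified_mixture)
    placed = []  # (p_start, p_end) in px, x-y order
    placed_a, placed_b = [], []
    rows = []
    border = 2.0 + 2.5 * spec.tube_sigma_px
    max_tries = 4000 * spec.n_segments
    tries = 0
    for sid, ang in enumerate(angles):
        # direction of the centreline in array coords (y down): visual
        # angle theta has dx = cos(theta), dy_image = -sin(theta)
        th = np.deg2rad(ang)
        d = np.array([np.cos(th), -np.sin(th)])
        while True:
            tries += 1
            if tries > max_tries:
                raise ConfigError(
                    "could not place all segments; spec too crowded for the "
                    "separation/clearance constraints"
                )
            length_px = rng.uniform(*spec.segment_length_um) / spec.px_size_um
            c = np.array([rng.uniform(border, w - border), rng.uniform(border, h - border)])
            p1, p2 = c - d * length_px / 2, c + d * length_px / 2
            if not (border <= p1[0] <= w - border and border <= p2[0] <= w - border
                    and border <= p1[1] <= h - border and border <= p2[1] <= h - border):
                continue
            if not (_clear_of_edges(p1[1], edge_rows, clearance)
                    and _clear_of_edges(p2[1], edge_rows, clearance)):
                continue
            if _min_dist_to_placed(p1, p2, placed_a, placed_b) < spec.min_separation_px:
                continue
            break
        placed.append((p1, p2))
        placed_a.append(p1)
        placed_b.append(p2)
        rows.append(
            dict(segment_id=sid, angle_deg=float(ang),
                 x0_px=p1[0], y0_px=p1[1], x1_px=p2[0], y1_px=p2[1],
                 length_um=float(length_px * spec.px_size_um))
        )

    canvas = np.zeros((h, w), dtype=float)
    for p1, p2 in placed:
        rr, cc, val = line_aa(int(round(p1[1])), int(round(p1[0])),
                              int(round(p2[1])), int(round(p2[0])))
        np.maximum.at(canvas, (rr, cc), val)
    img = gaussian_filter(canvas, spec.tube_sigma_px)
    peak = img.max()
    if peak > 0:
        img /= peak

    if np.isfinite(spec.snr):
        sd = 1.0 / spec.snr
        if spec.noise_model == "poisson+gaussian":
            photons_at_peak = spec.snr ** 2
            img = rng.poisson(img * photons_at_peak) / photons_at_peak
            img = img + rng.normal(0.0, 0.5 * sd, size=img.shape)
        else:
            img = img + rng.normal(0.0, sd, size=img.shape)
        img = np.clip(img, 0.0, None)

    seg_df = pd.DataFrame(rows)
    crossings = np.zeros(grid.n_rois, dtype=int)
    for i, (y0, y1) in enumerate(grid.band_bounds_px(spec.px_size_um)):
        for p1, p2 in placed:
            ymin, ymax = sorted((p1[1], p2[1]))
            if ymin < y1 and ymax > y0:
                crossings[i] += 1
    gt = ArborGroundTruth(segments=seg_df, band_crossings=crossings, grid=grid)
    return PixelImage(data=img, px_size_um=spec.px_size_um), gt
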