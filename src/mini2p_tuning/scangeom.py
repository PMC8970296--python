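"""MEMS point-scan geometry, quasi-resonant working region, distortion model.

A two-axis MEMS mirror raster-scans the excitation beam: the slow axis tilts
the mirror normal (incidence angle alpha = 45 - theta1 degrees), the fast
axis adds theta2.  Closed forms give the laser-spot position on the scanning
plane:

    x = L / sin(alpha) * tan(theta2)
    y = L * (cot(alpha) - 1 / cos^2(theta2))
    cos(beta) = cos(alpha) * cos(theta2)

The footprint over an angle rectangle is a curved trapezoid, which motivates
the image-based distortion calibration: anchor crosses of a 50-um grid
target are detected in the distorted image and a piecewise-affine transform
maps them back onto the ideal lattice.  The fast axis runs quasi-resonantly;
its admissible working band is the amplification band minus the +/-20%
neighbourhood of the first resonance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay


@dataclass
class ScanConfig:
    """Static scan geometry: mirror-to-plane distance and axis angles (deg)."""

    L: float = 1.0
    theta1_deg: float = 0.0
    theta2_deg: float = 0.0

    @property
    def alpha_deg(self) -> float:
        return 45.0 - self.theta1_deg


def spot_position(cfg: ScanConfig) -> tuple[float, float, float]:
    """Laser-spot position (x, y) and incidence angle beta (degrees)."""
    alpha = np.radians(cfg.alpha_deg)
    if np.sin(alpha) < 1e-12 or not 0 < cfg.alpha_deg < 90:
        raise ValueError("alpha must lie strictly between 0 and 90 degrees")
    th2 = np.radians(cfg.theta2_deg)
    x = cfg.L / np.sin(alpha) * np.tan(th2)
    y = cfg.L * (1.0 / np.tan(alpha) - 1.0 / np.cos(th2) ** 2)
    beta = np.degrees(np.arccos(np.cos(alpha) * np.cos(th2)))
    return float(x), float(y), float(beta)


@dataclass
class ScanField:
    """Sampled scan footprint with shape metrics."""

    x: np.ndarray  # (n1, n2) spot positions over the angle grid
    y: np.ndarray
    waist: float          # minimum fast-axis line width
    height: float         # slow-axis extent
    waist_height_ratio: float
    max_line_curvature: float  # max deviation of a constant-theta1 line from its chord


def scan_field(
    L: float,
    theta1_range_deg: tuple,
    theta2_range_deg: tuple,
    n1: int = 41,
    n2: int = 81,
) -> ScanField:
    """Sample the scan footprint over a rectangle of axis angles.

    The footprint is symmetric about the slow axis but not the fast axis:
    line width shrinks as alpha grows, giving a trapezoid whose waist/height
    ratio approaches sqrt(2)/2 for equal half-angle ranges; constant-theta1
    lines are curved by the 1/cos^2(theta2) term.
    """
    t1 = np.linspace(*theta1_range_deg, n1)
    t2 = np.linspace(*theta2_range_deg, n2)
    X = np.empty((n1, n2))
    Y = np.empty((n1, n2))
    for i, a in enumerate(t1):
        for j, b in enumerate(t2):
            X[i, j], Y[i, j], _ = spot_position(ScanConfig(L, a, b))
    widths = X.max(axis=1) - X.min(axis=1)
    height = float(Y.max() - Y.min())
    waist = float(widths.min())
    curv = 0.0
    for i in range(n1):
        p0 = np.array([X[i, 0], Y[i, 0]])
        p1 = np.array([X[i, -1], Y[i, -1]])
        chord = p1 - p0
        norm = np.hypot(*chord)
        if norm < 1e-12:
            continue
        rel = np.column_stack([X[i] - p0[0], Y[i] - p0[1]])
        dev = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
        curv = max(curv, float(dev.max()))
    ratio = waist / height if height > 0 else float("inf")
    return ScanField(x=X, y=Y, waist=waist, height=height,
                     waist_height_ratio=ratio, max_line_curvature=curv)


def working_region(
    f_first_khz: float,
    amplification_band_khz: tuple,
) -> list:
    """Admissible working frequencies: amplification band minus the unstable
    +/-20% neighbourhood of the first resonance.

    Both the band and the returned intervals are open; the unstable zone
    [0.8 f, 1.2 f] is removed as a closed interval, matching the strict
    inequalities of the printed constraints.  Returns sorted disjoint
    (low, high) tuples in kHz; may be empty.
    """
    if f_first_khz <= 0:
        raise ValueError("first resonant frequency must be positive")
    lo, hi = amplification_band_khz
    if not lo < hi:
        raise ValueError("amplification band must be a nonempty interval")
    ulo, uhi = 0.8 * f_first_khz, 1.2 * f_first_khz
    pieces = []
    if lo < min(hi, ulo):
        pieces.append((lo, min(hi, ulo)))
    if max(lo, uhi) < hi:
        pieces.append((max(lo, uhi), hi))
    return [(float(a), float(b)) for a, b in pieces if b - a > 1e-12]


# ---------------------------------------------------------------------------
# Piecewise-affine distortion calibration


class PiecewiseAffine:
    """Triangulation-based piecewise-linear map: measured -> ideal coordinates.

    Exact at every anchor; affine within each Delaunay triangle of the
    measured anchors; outside the hull the nearest triangle's (by centroid)
    affine map extends the transform.
    """

    def __init__(self, measured: np.ndarray, ideal: np.ndarray):
        measured = np.asarray(measured, dtype=float)
        ideal = np.asarray(ideal, dtype=float)
        if measured.shape != ideal.shape or measured.ndim != 2 or measured.shape[1] != 2:
            raise ValueError("anchor sets must be matching (N, 2) arrays")
        if len(measured) < 3:
            raise ValueError("need at least three anchors")
        try:
            self.tri = Delaunay(measured)
        except Exception as exc:  # collinear anchors
            raise ValueError("anchors are degenerate (collinear?)") from exc
        if self.tri.nsimplex == 0:
            raise ValueError("anchors are degenerate (collinear?)")
        self.measured = measured
        self.ideal = ideal
        # affine coefficients per simplex: [x y 1] @ A = ideal
        self._A = np.empty((self.tri.nsimplex, 3, 2))
        for s, verts in enumerate(self.tri.simplices):
            src = np.column_stack([measured[verts], np.ones(3)])
            self._A[s] = np.linalg.solve(src, ideal[verts])
        self._centroids = measured[self.tri.simplices].mean(axis=1)

    def _simplex_of(self, pts: np.ndarray) -> np.ndarray:
        s = self.tri.find_simplex(pts)
        outside = s < 0
        if outside.any():
            d = ((pts[outside, None, :] - self._centroids[None, :, :]) ** 2).sum(-1)
            s[outside] = d.argmin(axis=1)
        return s

    def transform(self, pts: np.ndarray) -> np.ndarray:
        """Map measured-space points to ideal space."""
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        s = self._simplex_of(pts)
        hom = np.column_stack([pts, np.ones(len(pts))])
        return np.einsum("ni,nij->nj", hom, self._A[s])

    def inverse(self) -> "PiecewiseAffine":
        """The ideal -> measured map (triangulated on the ideal anchors)."""
        return PiecewiseAffine(self.ideal, self.measured)


def calibrate_distortion(measured: np.ndarray, ideal: np.ndarray) -> PiecewiseAffine:
    """Build the piecewise-linear correction taking measured anchor points
    exactly onto the ideal lattice."""
    return PiecewiseAffine(measured, ideal)


def apply_correction(
    transform: PiecewiseAffine,
    image: np.ndarray | None = None,
    coordinates: np.ndarray | None = None,
) -> np.ndarray:
    """Apply a calibrated correction to coordinates or resample an image.

    Coordinates map forward through the transform.  Images are resampled by
    inverse mapping with bilinear interpolation: each corrected pixel looks
    up its source position in the distorted image.
    """
    if (image is None) == (coordinates is None):
        raise ValueError("pass exactly one of image or coordinates")
    if coordinates is not None:
        return transform.transform(coordinates)
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    inv = transform.inverse()
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    src = inv.transform(np.column_stack([cols.ravel(), rows.ravel()]))
    sampled = map_coordinates(img, [src[:, 1], src[:, 0]], order=1, mode="nearest")
    return sampled.reshape(h, w)


# ---------------------------------------------------------------------------
# Anchor detection on grid-target images


def detect_anchors(
    image: np.ndarray,
    ideal_anchors: np.ndarray,
    search_radius_px: float = 8.0,
    arm_px: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate grid-line crossings near each expected lattice point.

    The image is correlated with a plus-shaped kernel (both line arms); for
    each ideal anchor the response maximum within ``search_radius_px`` is
    refined to sub-pixel precision by a centre of mass of the local response.
    Returns (matched_ideal, detected) with anchors dropped when no response
    peak lies in reach.
    """
    from scipy.ndimage import convolve

    img = np.asarray(image, dtype=float)
    kernel = np.zeros((2 * arm_px + 1, 2 * arm_px + 1))
    kernel[arm_px, :] = 1.0
    kernel[:, arm_px] = 1.0
    resp = convolve(img, kernel / kernel.sum(), mode="nearest")
    h, w = resp.shape
    matched, detected = [], []
    r = int(np.ceil(search_radius_px))
    for ax, ay in np.asarray(ideal_anchors, dtype=float):
        cx, cy = int(round(ax)), int(round(ay))
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        if x1 <= x0 or y1 <= y0:
            continue
        win = resp[y0:y1, x0:x1]
        py, px = np.unravel_index(np.argmax(win), win.shape)
        peak_y, peak_x = y0 + py, x0 + px
        # sub-pixel: parabolic interpolation of the response peak per axis
        sub_x, sub_y = float(peak_x), float(peak_y)
        if 0 < peak_x < w - 1:
            f0, f1, f2 = resp[peak_y, peak_x - 1:peak_x + 2]
            den = f0 - 2 * f1 + f2
            if den < 0:
                sub_x += 0.5 * (f0 - f2) / den
        if 0 < peak_y < h - 1:
            f0, f1, f2 = resp[peak_y - 1:peak_y + 2, peak_x]
            den = f0 - 2 * f1 + f2
            if den < 0:
                sub_y += 0.5 * (f0 - f2) / den
        detected.append([sub_x, sub_y])
        matched.append([ax, ay])
    return np.asarray(matched, dtype=float), np.asarray(detected, dtype=float)
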