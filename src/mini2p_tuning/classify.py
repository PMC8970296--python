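"""Shuffle-null classification of spatially tuned cells.

Statistics (spatial information, mean vector length, half-session stability,
grid score) are compared per cell against a null distribution obtained by
circularly time-shifting the cell's deconvolved activity along the animal's
path — shifts uniform between 30 s and 30 s short of the session length,
wrapped — which breaks the activity-behaviour coupling while preserving the
activity autocorrelation.  A cell is flagged when its observed statistic
exceeds the 95th percentile of its own null and any additional structural
criteria (place fields; grid geometry) hold.

All shuffle evaluators are vectorised over permutations: binning indices and
occupancy depend only on behaviour, so a whole null distribution reduces to
batched weighted histograms of the rolled event series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, label

from .maps import (TuningCurve, TuningMap, smooth_masked,
                   spatial_autocorrelogram)

DEG = np.pi / 180.0


# ---------------------------------------------------------------------------
# Closed-form statistics


def spatial_information(tm: TuningMap) -> float:
    """Skaggs-style information: sum_i p_i (l_i/l) log2(l_i/l).

    p_i is the occupancy probability of bin i, l_i the bin's mean calcium
    activity and l the occupancy-weighted overall mean; zero-rate bins
    contribute nothing; an all-zero map yields 0.
    """
    p = tm.occupancy_probability[tm.visit_mask]
    lam = np.nan_to_num(tm.rate[tm.visit_mask])
    mean = float((p * lam).sum())
    if mean <= 0:
        return 0.0
    ratio = lam / mean
    pos = ratio > 0
    return float((p[pos] * ratio[pos] * np.log2(ratio[pos])).sum())


def mean_vector_length(curve: TuningCurve | tuple) -> float:
    """Modulus of the circular mean of a directional tuning curve, in [0, 1]."""
    if isinstance(curve, TuningCurve):
        values, centers = curve.values, curve.bin_centers
    else:
        values, centers = curve
    w = np.nan_to_num(np.asarray(values, dtype=float))
    total = w.sum()
    if total <= 0:
        return 0.0
    th = np.asarray(centers, dtype=float) * DEG
    return float(np.abs((w * np.exp(1j * th)).sum()) / total)


# ---------------------------------------------------------------------------
# Circular-shift shuffling


def draw_circular_shifts(
    n_frames: int,
    frame_rate_hz: float,
    n_perm: int,
    rng: np.random.Generator,
    margin_s: float = 30.0,
) -> np.ndarray:
    """Random whole-frame circular shifts in [margin, T - margin].

    Raises when the session is too short to leave any admissible shift.
    """
    lo = int(round(margin_s * frame_rate_hz))
    hi = n_frames - lo
    if hi <= lo:
        raise ValueError("session too short for the shuffle margins")
    return rng.integers(lo, hi + 1, size=n_perm)


def rolled(events: np.ndarray, shifts: np.ndarray, take: np.ndarray) -> np.ndarray:
    """Values of each circularly shifted event series at frames ``take``.

    Row p holds roll(events, shifts[p])[take]; shift 0 reproduces the
    observed sequence.
    """
    n = len(events)
    idx = (np.asarray(take)[None, :] - np.asarray(shifts)[:, None]) % n
    return np.asarray(events, dtype=float)[idx]


def null_threshold(null_values: np.ndarray, percentile: float = 95.0) -> float:
    vals = np.asarray(null_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return float("nan")
    return float(np.percentile(vals, percentile))


# ---------------------------------------------------------------------------
# Session context: behaviour-dependent precomputation shared by all cells


@dataclass
class SessionContext:
    """Binned behaviour of one (plane-aligned) session.

    Precomputes everything that does not depend on a cell's activity: the
    speed-filtered frame set, spatial and directional bin indices, occupancy
    and visit masks for the full session and for its two exact-half splits.
    """

    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray
    direction: np.ndarray
    frame_rate_hz: float
    extent_cm: tuple
    bin_cm: float = 2.5
    smooth_sd_cm: float = 3.0
    speed_floor: float = 2.5
    min_visit_s: float = 0.1
    dir_bin_deg: float = 3.0
    dir_smooth_deg: float = 6.0

    def __post_init__(self) -> None:
        from .maps import _bin_edges

        n = len(self.x)
        self.n_frames = n
        valid = (np.isfinite(self.x) & np.isfinite(self.y)
                 & (np.asarray(self.speed) >= self.speed_floor))
        self.valid = valid
        ex = _bin_edges(self.extent_cm[0], self.bin_cm)
        ey = _bin_edges(self.extent_cm[1], self.bin_cm)
        self.shape = (len(ey) - 1, len(ex) - 1)
        xi = np.clip(np.searchsorted(ex, self.x, side="right") - 1, 0, self.shape[1] - 1)
        yi = np.clip(np.searchsorted(ey, self.y, side="right") - 1, 0, self.shape[0] - 1)
        self.flat_bin = yi * self.shape[1] + xi

        self.dir_nb = int(round(360.0 / self.dir_bin_deg))
        dv = np.mod(np.asarray(self.direction, dtype=float), 360.0)
        db = np.floor(dv / self.dir_bin_deg).astype(int) % self.dir_nb
        self.dir_valid = valid & np.isfinite(self.direction)
        self.dir_bin = db
        self.dir_centers = (np.arange(self.dir_nb) + 0.5) * self.dir_bin_deg

        half = n // 2
        self.frame_sets = {
            "full": np.flatnonzero(valid),
            "h1": np.flatnonzero(valid & (np.arange(n) < half)),
            "h2": np.flatnonzero(valid & (np.arange(n) >= half)),
        }
        self.dir_frame_sets = {
            k: v[np.isfinite(self.direction[v])] for k, v in self.frame_sets.items()
        }
        self.occupancy = {}
        self.visit = {}
        self.dir_occ = {}
        self.dir_visit = {}
        nbins = self.shape[0] * self.shape[1]
        for k, fr in self.frame_sets.items():
            occ = np.bincount(self.flat_bin[fr], minlength=nbins).reshape(self.shape) \
                / self.frame_rate_hz
            self.occupancy[k] = occ
            self.visit[k] = occ >= self.min_visit_s
        for k, fr in self.dir_frame_sets.items():
            occ = np.bincount(self.dir_bin[fr], minlength=self.dir_nb) / self.frame_rate_hz
            self.dir_occ[k] = occ
            self.dir_visit[k] = occ > 0

    # -- batched builders ---------------------------------------------------

    def rate_maps(self, events: np.ndarray, shifts: np.ndarray, part: str = "full") -> np.ndarray:
        """Smoothed rate-map stack (P, H, W) for each circular shift."""
        fr = self.frame_sets[part]
        occ = self.occupancy[part]
        vis = self.visit[part]
        ev = rolled(events, shifts, fr)
        P = len(shifts)
        nbins = self.shape[0] * self.shape[1]
        flat = (np.arange(P)[:, None] * nbins + self.flat_bin[fr][None, :]).ravel()
        wsum = np.bincount(flat, weights=ev.ravel(), minlength=P * nbins)
        wsum = wsum.reshape(P, *self.shape)
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(vis[None], wsum / occ[None], 0.0)
        sm = _smooth_stack(raw, vis, self.smooth_sd_cm / self.bin_cm)
        return sm

    def dir_curves(self, events: np.ndarray, shifts: np.ndarray, part: str = "full") -> np.ndarray:
        """Smoothed directional tuning-curve stack (P, n_dir_bins)."""
        fr = self.dir_frame_sets[part]
        occ = self.dir_occ[part]
        vis = self.dir_visit[part]
        ev = rolled(events, shifts, fr)
        P = len(shifts)
        flat = (np.arange(P)[:, None] * self.dir_nb + self.dir_bin[fr][None, :]).ravel()
        wsum = np.bincount(flat, weights=ev.ravel(), minlength=P * self.dir_nb)
        wsum = wsum.reshape(P, self.dir_nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(vis[None], wsum / occ[None], 0.0)
        sig = self.dir_smooth_deg / self.dir_bin_deg
        num = gaussian_filter1d(raw * vis[None], sig, axis=-1, mode="wrap")
        den = gaussian_filter1d(vis.astype(float), sig, mode="wrap")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den[None]
        sm[:, ~vis] = np.nan
        return sm

    def observed_map(self, events: np.ndarray, part: str = "full") -> TuningMap:
        sm = self.rate_maps(events, np.array([0]), part)[0]
        vis = self.visit[part]
        rate = np.where(vis, sm, np.nan)
        return TuningMap(rate=rate, rate_raw=rate, occupancy_s=self.occupancy[part],
                         visit_mask=vis, bin_size_cm=self.bin_cm,
                         smoothing_sd_cm=self.smooth_sd_cm)

    # -- batched statistics -------------------------------------------------

    def si_batch(self, map_stack: np.ndarray, part: str = "full") -> np.ndarray:
        vis = self.visit[part]
        occ = np.where(vis, self.occupancy[part], 0.0)
        p = (occ / occ.sum())[vis]
        lam = np.nan_to_num(map_stack[:, vis])
        mean = lam @ p
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = lam / mean[:, None]
            terms = np.where(ratio > 0, ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
        si = terms @ p
        si[mean <= 0] = 0.0
        return si

    def mvl_batch(self, curve_stack: np.ndarray) -> np.ndarray:
        w = np.nan_to_num(curve_stack)
        z = np.exp(1j * self.dir_centers * DEG)
        num = np.abs(w @ z)
        den = w.sum(axis=1)
        out = np.zeros(len(w))
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        return out

    def stability_batch(self, events: np.ndarray, shifts: np.ndarray) -> np.ndarray:
        """Pearson correlation between half-session maps for each shift."""
        m1 = self.rate_maps(events, shifts, "h1")
        m2 = self.rate_maps(events, shifts, "h2")
        common = self.visit["h1"] & self.visit["h2"]
        if common.sum() < 10:
            return np.full(len(shifts), np.nan)
        return _pearson_rows(m1[:, common], m2[:, common])

    def dir_stability_batch(self, events: np.ndarray, shifts: np.ndarray) -> np.ndarray:
        c1 = self.dir_curves(events, shifts, "h1")
        c2 = self.dir_curves(events, shifts, "h2")
        common = self.dir_visit["h1"] & self.dir_visit["h2"]
        if common.sum() < 10:
            return np.full(len(shifts), np.nan)
        return _pearson_rows(c1[:, common], c2[:, common])


def _smooth_stack(raw: np.ndarray, vis: np.ndarray, sigma: float) -> np.ndarray:
    """Missing-aware Gaussian smoothing of a (P, H, W) stack, shared mask."""
    from scipy.ndimage import gaussian_filter
    num = gaussian_filter(raw * vis[None], (0, sigma, sigma), mode="constant")
    den = gaussian_filter(vis.astype(float), sigma, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den[None]
    out[:, ~vis] = 0.0
    return out


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# Place fields


@dataclass
class PlaceField:
    """Connected set of bins above 20% of the map peak."""

    bins: np.ndarray  # (N, 2) row/col indices
    area_bins: int
    mean_rate: float
    peak_rate: float


def detect_place_fields(
    tm: TuningMap,
    rel_threshold: float = 0.2,
    min_bins: int = 9,
    max_bins: int = 625,
    min_mean_rate: float = 0.1,
) -> list:
    """Connected components of bins above ``rel_threshold`` of the map peak,
    kept when their area is within [min_bins, max_bins] and their mean rate
    exceeds ``min_mean_rate`` (0.1 dF/F per s for VC, 0.02 for CA1).
    8-neighbourhood connectivity."""
    rate = tm.rate
    finite = np.isfinite(rate)
    if not finite.any():
        return []
    peak = np.nanmax(rate)
    if not peak > 0:
        return []
    above = finite & (rate > rel_threshold * peak)
    lab, nlab = label(above, structure=np.ones((3, 3), dtype=int))
    fields = []
    for k in range(1, nlab + 1):
        sel = lab == k
        area = int(sel.sum())
        mean_rate = float(rate[sel].mean())
        if min_bins <= area <= max_bins and mean_rate > min_mean_rate:
            fields.append(PlaceField(
                bins=np.argwhere(sel), area_bins=area,
                mean_rate=mean_rate, peak_rate=float(rate[sel].max())))
    return fields


# ---------------------------------------------------------------------------
# Grid score


def _rotate_bilinear(stack: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate (..., H, W) about the centre bin by bilinear resampling.

    Output pixel p takes the value of the input at p rotated by -angle about
    the centre; samples falling outside the grid or touching a NaN bin are
    NaN.
    """
    a = np.asarray(stack, dtype=float)
    h, w = a.shape[-2:]
    cy, cx = h // 2, w // 2
    th = angle_deg * DEG
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    sx = cx + np.cos(th) * dx + np.sin(th) * dy
    sy = cy - np.sin(th) * dx + np.cos(th) * dy
    x0 = np.floor(sx).astype(int)
    y0 = np.floor(sy).astype(int)
    fx, fy = sx - x0, sy - y0
    inside = (x0 >= 0) & (x0 + 1 <= w - 1) & (y0 >= 0) & (y0 + 1 <= h - 1)
    x0c = np.clip(x0, 0, w - 2)
    y0c = np.clip(y0, 0, h - 2)
    flat = a.reshape(*a.shape[:-2], h * w)
    i00 = y0c * w + x0c
    v00 = flat[..., i00.ravel()].reshape(*a.shape[:-2], h, w)
    v01 = flat[..., (i00 + 1).ravel()].reshape(*a.shape[:-2], h, w)
    v10 = flat[..., (i00 + w).ravel()].reshape(*a.shape[:-2], h, w)
    v11 = flat[..., (i00 + w + 1).ravel()].reshape(*a.shape[:-2], h, w)
    out = (v00 * (1 - fx) * (1 - fy) + v01 * fx * (1 - fy)
           + v10 * (1 - fx) * fy + v11 * fx * fy)
    out[..., ~inside] = np.nan
    return out


GROUP1_ANGLES = (60.0, 120.0)
GROUP2_ANGLES = (30.0, 90.0, 150.0)


def grid_score_batch(ac_stack: np.ndarray, min_annulus_bins: int = 20) -> np.ndarray:
    """Grid scores of a stack of autocorrelograms sharing one NaN pattern.

    For every annulus in the sweep (inner radius at the first local minimum
    of the angularly averaged autocorrelogram — the central-peak exclusion —
    outer radius from inner+2 to the largest inscribed circle in 1-bin
    steps), the sample is correlated with itself rotated by 60 and 120
    degrees (group 1) and by 30, 90 and 150 degrees (group 2); the annulus
    score is min(group 1) - max(group 2) and the grid score the maximum over
    annuli.
    """
    ac = np.asarray(ac_stack, dtype=float)
    if ac.ndim == 2:
        ac = ac[None]
    P, h, w = ac.shape
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    rad = np.hypot(yy - cy, xx - cx)
    shell = np.rint(rad).astype(int)
    rmax = min(cy, cx)
    valid = np.isfinite(ac).all(axis=0) & (shell <= rmax)

    # angular average -> per-permutation inner radius
    ns = rmax + 1
    sel = valid
    sh = shell[sel]
    counts = np.bincount(sh, minlength=ns).astype(float)
    vals = np.nan_to_num(ac[:, sel])
    onehot_t = np.zeros((len(sh), ns))
    onehot_t[np.arange(len(sh)), sh] = 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = (vals @ onehot_t) / counts[None, :]
    inner = _first_local_min(profile)

    # per-shell sums for each rotation angle, cumulated over shells
    angles = GROUP1_ANGLES + GROUP2_ANGLES
    corr = np.full((len(angles), P, ns, ns), np.nan)
    ring = valid & (shell >= 1)
    for ai, ang in enumerate(angles):
        rot = _rotate_bilinear(ac, ang)
        ok = ring & np.isfinite(rot).all(axis=0)
        sh_ok = shell[ok]
        oh = np.zeros((len(sh_ok), ns))
        oh[np.arange(len(sh_ok)), sh_ok] = 1.0
        X = np.nan_to_num(ac[:, ok])
        Y = np.nan_to_num(rot[:, ok])
        cnt = np.cumsum(np.bincount(sh_ok, minlength=ns).astype(float))
        Sx = np.cumsum(X @ oh, axis=1)
        Sy = np.cumsum(Y @ oh, axis=1)
        Sxy = np.cumsum((X * Y) @ oh, axis=1)
        Sxx = np.cumsum((X * X) @ oh, axis=1)
        Syy = np.cumsum((Y * Y) @ oh, axis=1)
        # annulus (i, o]: cumulative difference
        n_ann = cnt[None, None, :] - cnt[None, :, None]
        dSx = Sx[:, None, :] - Sx[:, :, None]
        dSy = Sy[:, None, :] - Sy[:, :, None]
        dSxy = Sxy[:, None, :] - Sxy[:, :, None]
        dSxx = Sxx[:, None, :] - Sxx[:, :, None]
        dSyy = Syy[:, None, :] - Syy[:, :, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            num = n_ann * dSxy - dSx * dSy
            den = np.sqrt(np.maximum(n_ann * dSxx - dSx**2, 0.0)
                          * np.maximum(n_ann * dSyy - dSy**2, 0.0))
            c = num / den
        c[np.broadcast_to(n_ann < min_annulus_bins, c.shape)] = np.nan
        corr[ai] = c

    # strict combination: a NaN in any rotation invalidates the annulus
    grp1 = np.minimum(corr[0], corr[1])
    grp2 = np.maximum(np.maximum(corr[2], corr[3]), corr[4])
    diff = grp1 - grp2

    o_idx = np.arange(ns)
    scores = np.full(P, np.nan)
    for p in range(P):
        i = inner[p]
        if i is None or i + 2 > rmax:
            continue
        row = diff[p, i, :]
        cand = row[(o_idx >= i + 2) & (o_idx <= rmax)]
        cand = cand[np.isfinite(cand)]
        if len(cand):
            scores[p] = cand.max()
    return scores


def _first_local_min(profile: np.ndarray) -> list:
    """Index of the first local minimum (end of the central-peak decrease)."""
    out = []
    for prof in profile:
        idx = None
        for s in range(1, len(prof) - 1):
            if not (np.isfinite(prof[s]) and np.isfinite(prof[s + 1])):
                continue
            if prof[s + 1] >= prof[s]:
                idx = s
                break
        out.append(idx)
    return out


def grid_score(acorr, min_annulus_bins: int = 20) -> float:
    """Grid score of a single autocorrelogram (see grid_score_batch)."""
    values = acorr.values if hasattr(acorr, "values") else np.asarray(acorr)
    return float(grid_score_batch(values[None], min_annulus_bins)[0])


# ---------------------------------------------------------------------------
# Grid geometry


@dataclass
class GridGeometry:
    """Spacing, axes and orientation extracted from an autocorrelogram."""

    valid: bool
    reason: str = ""
    spacing_cm: float = float("nan")
    field_distances_cm: np.ndarray = field(default_factory=lambda: np.array([]))
    axis_angles_deg: tuple = ()
    orientation_deg: float = float("nan")
    orientation_offset_deg: float = float("nan")
    interaxis_ok: bool = False
    distance_ratio_ok: bool = False
    field_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))


def _axis_dist(a: float, b: float, period: float = 180.0) -> float:
    """Distance between undirected axis angles (period 180 degrees)."""
    d = (a - b) % period
    return min(d, period - d)


def grid_geometry(
    acorr,
    bin_cm: float,
    field_threshold: float = 0.3,
    horizontal_ref_deg: float = 0.0,
    wall_ref_deg: float = 90.0,
) -> GridGeometry:
    """Extract grid spacing, axes, orientation and validity flags.

    Fields are 8-connected components of autocorrelogram bins above
    ``field_threshold``; the component containing the centre is the central
    peak.  Spacing is the mean distance of the six field centres (of mass,
    weighted by correlation above threshold) closest to the centre.  Axis 1
    is the axis closest to the horizontal reference; orientation is the
    circular arithmetic mean of the three axes (each mapped within 30
    degrees of Axis 1); the orientation offset is the smallest axis angle to
    the ``wall_ref_deg`` wall.  Validity needs interaxis angles in (30, 90)
    degrees and all field-distance ratios within [0.5, 2].
    """
    values = acorr.values if hasattr(acorr, "values") else np.asarray(acorr)
    h, w = values.shape
    cy, cx = h // 2, w // 2
    above = np.isfinite(values) & (values > field_threshold)
    lab, nlab = label(above, structure=np.ones((3, 3), dtype=int))
    central = lab[cy, cx]
    centers = []
    for k in range(1, nlab + 1):
        if k == central:
            continue
        sel = lab == k
        wts = values[sel] - field_threshold
        pos = np.argwhere(sel).astype(float)
        com = (pos * wts[:, None]).sum(axis=0) / wts.sum()
        centers.append(com)
    if central == 0 or len(centers) < 6:
        return GridGeometry(valid=False, reason="fewer than six fields")
    centers = np.array(centers)
    d = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
    order = np.argsort(d)[:6]
    six = centers[order]
    dist = d[order]
    spacing = float(dist.mean() * bin_cm)
    ratios_ok = bool(dist.max() / dist.min() <= 2.0) if dist.min() > 0 else False

    ang = np.degrees(np.arctan2(six[:, 0] - cy, six[:, 1] - cx))  # row lag = y
    axes6 = ((ang + 90.0) % 180.0) - 90.0  # axis angles in (-90, 90]
    axis_angles = _cluster_axes(axes6)
    if len(axis_angles) != 3:
        return GridGeometry(valid=False, reason="axes unresolved",
                            spacing_cm=spacing, field_centers=six,
                            field_distances_cm=dist * bin_cm)

    a1 = min(axis_angles, key=lambda a: _axis_dist(a, horizontal_ref_deg))
    rest = [a for a in axis_angles if a != a1]
    rel = [((a - a1 + 90.0) % 180.0) - 90.0 for a in rest]
    a2 = rest[int(np.argmax(rel))]
    a3 = rest[int(np.argmin(rel))]

    def wrap60(x):
        return ((x + 30.0) % 60.0) - 30.0

    orientation = a1 + float(np.mean([0.0, wrap60(a2 - a1), wrap60(a3 - a1)]))
    offset = float(min(_axis_dist(a, wall_ref_deg) for a in (a1, a2, a3)))

    inter = [_axis_dist(a1, a2), _axis_dist(a1, a3), _axis_dist(a2, a3)]
    interaxis_ok = bool(min(inter) > 30.0 and max(inter) < 90.0)

    return GridGeometry(
        valid=interaxis_ok and ratios_ok,
        reason="" if (interaxis_ok and ratios_ok) else "geometry filters failed",
        spacing_cm=spacing, field_distances_cm=dist * bin_cm,
        axis_angles_deg=(a1, a2, a3), orientation_deg=orientation,
        orientation_offset_deg=offset, interaxis_ok=interaxis_ok,
        distance_ratio_ok=ratios_ok, field_centers=six)


def _cluster_axes(axes6: np.ndarray, tol_deg: float = 15.0) -> list:
    """Collapse six field axis angles into axes (period-180 clustering).

    Antipodal field pairs share an axis, so the six angles should form three
    tight clusters; angles within ``tol_deg`` (axis distance) merge.  Returns
    the per-cluster circular means — the caller treats anything other than
    exactly three clusters as unresolved geometry.
    """
    a = np.sort(np.asarray(axes6, dtype=float))
    n = len(a)
    gaps = np.array([(a[(i + 1) % n] - a[i]) % 180.0 for i in range(n)])
    clusters = []
    current = [a[0]]
    for i in range(n - 1):
        if gaps[i] <= tol_deg:
            current.append(a[i + 1])
        else:
            clusters.append(current)
            current = [a[i + 1]]
    clusters.append(current)
    if len(clusters) > 1 and gaps[n - 1] <= tol_deg:  # circular wrap merge
        first = clusters.pop(0)
        ref = clusters[-1][0]
        clusters[-1].extend(ref + (((c - ref) + 90.0) % 180.0) - 90.0
                            for c in first)
    means = []
    for cl in clusters:
        ref = cl[0]
        vals = [ref + (((c - ref) + 90.0) % 180.0) - 90.0 for c in cl]
        m = float(np.mean(vals))
        means.append(((m + 90.0) % 180.0) - 90.0)
    return means


# ---------------------------------------------------------------------------
# Cell-level verdicts


@dataclass
class CriterionResult:
    statistic: float
    threshold: float
    passed: bool


@dataclass
class CellVerdict:
    """Classification outcome for one cell with its component statistics."""

    cell_id: int
    eligible: bool
    snr: float = float("nan")
    n_events: int = 0
    flags: dict = field(default_factory=dict)
    criteria: dict = field(default_factory=dict)
    geometry: GridGeometry | None = None
    n_fields: int = 0


def classify_place_cell(
    events: np.ndarray,
    ctx: SessionContext,
    rng: np.random.Generator,
    n_perm: int = 200,
    min_field_rate: float = 0.1,
    percentile: float = 95.0,
    margin_s: float = 30.0,
    cell_id: int = 0,
    eligible: bool = True,
    snr: float = float("nan"),
) -> CellVerdict:
    """Place-cell verdict: information and stability above their nulls plus
    at least one valid place field."""
    v = CellVerdict(cell_id=cell_id, eligible=eligible, snr=snr)
    if not eligible:
        return v
    shifts = np.concatenate([[0], draw_circular_shifts(
        ctx.n_frames, ctx.frame_rate_hz, n_perm, rng, margin_s)])
    stack = ctx.rate_maps(events, shifts)
    si = ctx.si_batch(stack)
    stab = ctx.stability_batch(events, shifts)
    si_thr = null_threshold(si[1:], percentile)
    st_thr = null_threshold(stab[1:], percentile)
    fields = detect_place_fields(ctx.observed_map(events),
                                 min_mean_rate=min_field_rate)
    v.criteria["spatial_information"] = CriterionResult(float(si[0]), si_thr,
                                                        bool(si[0] > si_thr))
    v.criteria["stability"] = CriterionResult(
        float(stab[0]), st_thr,
        bool(np.isfinite(stab[0]) and stab[0] > st_thr))
    v.n_fields = len(fields)
    v.flags["place"] = (v.criteria["spatial_information"].passed
                        and v.criteria["stability"].passed
                        and len(fields) >= 1)
    return v


def classify_hd_cell(
    events: np.ndarray,
    ctx: SessionContext,
    rng: np.random.Generator,
    n_perm: int = 200,
    percentile: float = 95.0,
    margin_s: float = 30.0,
    cell_id: int = 0,
    eligible: bool = True,
    snr: float = float("nan"),
) -> CellVerdict:
    """Head-direction verdict: MVL and directional stability above nulls."""
    v = CellVerdict(cell_id=cell_id, eligible=eligible, snr=snr)
    if not eligible:
        return v
    shifts = np.concatenate([[0], draw_circular_shifts(
        ctx.n_frames, ctx.frame_rate_hz, n_perm, rng, margin_s)])
    curves = ctx.dir_curves(events, shifts)
    mvl = ctx.mvl_batch(curves)
    stab = ctx.dir_stability_batch(events, shifts)
    mvl_thr = null_threshold(mvl[1:], percentile)
    st_thr = null_threshold(stab[1:], percentile)
    v.criteria["mvl"] = CriterionResult(float(mvl[0]), mvl_thr,
                                        bool(mvl[0] > mvl_thr))
    v.criteria["dir_stability"] = CriterionResult(
        float(stab[0]), st_thr,
        bool(np.isfinite(stab[0]) and stab[0] > st_thr))
    v.flags["head_direction"] = (v.criteria["mvl"].passed
                                 and v.criteria["dir_stability"].passed)
    curve = curves[0]
    w = np.nan_to_num(curve)
    if w.sum() > 0:
        # circular mean of the tuning curve: less bin noise than the argmax
        mean_dir = np.degrees(np.angle((w * np.exp(1j * ctx.dir_centers * DEG)).sum()))
        v.criteria["preferred_direction_deg"] = CriterionResult(
            float(mean_dir % 360.0), float("nan"), True)
    return v


def classify_grid_cell(
    events: np.ndarray,
    ctx: SessionContext,
    rng: np.random.Generator,
    n_perm: int = 1000,
    percentile: float = 95.0,
    margin_s: float = 30.0,
    field_threshold: float = 0.3,
    cell_id: int = 0,
    eligible: bool = True,
    snr: float = float("nan"),
) -> CellVerdict:
    """Grid verdict: grid score above its null plus geometry filters."""
    v = CellVerdict(cell_id=cell_id, eligible=eligible, snr=snr)
    if not eligible:
        return v
    shifts = np.concatenate([[0], draw_circular_shifts(
        ctx.n_frames, ctx.frame_rate_hz, n_perm, rng, margin_s)])
    stack = ctx.rate_maps(events, shifts)
    rate = np.where(ctx.visit["full"][None], stack, np.nan)
    ac = spatial_autocorrelogram(rate).values
    scores = grid_score_batch(ac)
    thr = null_threshold(scores[1:], percentile)
    geom = grid_geometry(ac[0], ctx.bin_cm, field_threshold)
    v.criteria["grid_score"] = CriterionResult(
        float(scores[0]), thr,
        bool(np.isfinite(scores[0]) and scores[0] > thr))
    v.geometry = geom
    v.flags["grid"] = v.criteria["grid_score"].passed and geom.valid
    return v


def conjunctive_flag(grid_verdict: CellVerdict, hd_verdict: CellVerdict) -> bool:
    """Conjunctive grid x head-direction cell: both criteria sets passed."""
    return bool(grid_verdict.flags.get("grid") and hd_verdict.flags.get("head_direction"))


# ---------------------------------------------------------------------------
# Escape-active cells and population-ratio nulls


def escape_active(
    dff: np.ndarray,
    escape_mask: np.ndarray,
    frame_rate_hz: float,
    rng: np.random.Generator,
    n_perm: int = 1000,
    percentile: float = 95.0,
    margin_s: float = 30.0,
) -> tuple[float, float, bool]:
    """Escape-active distinction score with its shuffle threshold.

    score = (F_escape - F_other) / (F_escape + F_other) from mean dF/F inside
    versus outside the escape frames; the null circularly shifts the trace.
    Returns (score, threshold, flagged); the score is NaN when the sum of
    means is not positive.
    """
    dff = np.asarray(dff, dtype=float)
    mask = np.asarray(escape_mask, dtype=bool)
    n = len(dff)
    if mask.sum() == 0 or mask.all():
        raise ValueError("escape mask must be nonempty and not cover the session")
    shifts = np.concatenate([[0], draw_circular_shifts(
        n, frame_rate_hz, n_perm, rng, margin_s)])
    in_idx = np.flatnonzero(mask)
    total = dff.sum()
    s_in = rolled(dff, shifts, in_idx).sum(axis=1)
    f_esc = s_in / len(in_idx)
    f_oth = (total - s_in) / (n - len(in_idx))
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (f_esc - f_oth) / (f_esc + f_oth)
    scores[(f_esc + f_oth) <= 0] = np.nan
    thr = null_threshold(scores[1:], percentile)
    flagged = bool(np.isfinite(scores[0]) and scores[0] > thr)
    return float(scores[0]), thr, flagged


def population_ratio_null(
    flagged_events: list,
    total_n: int,
    n_rounds: int,
    criterion,
    frame_rate_hz: float,
    rng: np.random.Generator,
    margin_s: float = 30.0,
) -> np.ndarray:
    """Chance-level distribution of the population fraction of flagged cells.

    Each round builds ``total_n`` pseudo-cells by cycling circularly shifted
    copies of the flagged cells' event series and counts how many pass the
    supplied ``criterion(events) -> bool``; repeated ``n_rounds`` times the
    passing fractions form the chance distribution.
    """
    if not flagged_events:
        raise ValueError("flagged set must be nonempty")
    fractions = np.empty(n_rounds)
    for r in range(n_rounds):
        passed = 0
        for i in range(total_n):
            ev = flagged_events[i % len(flagged_events)]
            shift = draw_circular_shifts(len(ev), frame_rate_hz, 1, rng, margin_s)[0]
            passed += bool(criterion(np.roll(ev, shift)))
        fractions[r] = passed / total_n
    return fractions
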