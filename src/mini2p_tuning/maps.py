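"""Occupancy-normalised tuning maps, curves, autocorrelograms, field sign.

The central object is the occupancy-normalised tuning map: in every spatial
bin, the summed amplitude of deconvolved calcium activity divided by the time
spent there, computed after discarding frames slower than a speed floor, then
smoothed with a missing-aware Gaussian kernel.  1D analogues cover head
direction (circular) and running speed.  The spatial autocorrelogram —
Pearson correlation of the map with itself at every 2D lag — feeds the grid
analysis, and the visual-field-sign formula serves retinotopic parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy.ndimage import gaussian_filter, gaussian_filter1d


@dataclass
class TuningMap:
    """Binned occupancy-normalised rate map (dF/F per second units).

    ``rate`` is smoothed and NaN on unvisited bins; ``rate_raw`` is the
    pre-smoothing ratio.  ``occupancy_probability`` sums to 1 over visited
    bins.
    """

    rate: np.ndarray
    rate_raw: np.ndarray
    occupancy_s: np.ndarray
    visit_mask: np.ndarray
    bin_size_cm: float
    smoothing_sd_cm: float

    @property
    def occupancy_probability(self) -> np.ndarray:
        p = np.where(self.visit_mask, self.occupancy_s, 0.0)
        total = p.sum()
        return p / total if total > 0 else p

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted overall mean of the smoothed map."""
        p = self.occupancy_probability
        r = np.where(self.visit_mask, np.nan_to_num(self.rate), 0.0)
        return float((p * r).sum())


@dataclass
class TuningCurve:
    """1D tuning curve over angular (circular) or speed bins."""

    values: np.ndarray
    values_raw: np.ndarray
    occupancy_s: np.ndarray
    bin_centers: np.ndarray
    bin_width: float
    smoothing_sd: float
    circular: bool


@dataclass
class Autocorrelogram:
    """Spatial autocorrelation on a (2H-1, 2W-1) lag grid; NaN where undefined."""

    values: np.ndarray

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


def _bin_edges(extent_cm: float, bin_cm: float) -> np.ndarray:
    """Bin grid anchored to the arena walls; a partial edge bin is kept."""
    n_full = int(np.floor(extent_cm / bin_cm + 1e-9))
    edges = np.arange(n_full + 1) * bin_cm
    if edges[-1] < extent_cm - 1e-9:
        edges = np.append(edges, extent_cm)
    return edges


def occupancy_and_weights(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    extent_cm: tuple[float, float],
    frame_rate_hz: float,
    bin_cm: float = 2.5,
    speed: np.ndarray | None = None,
    speed_floor: float = 2.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin occupancy (seconds) and summed weights on the arena grid.

    Frames with speed below ``speed_floor`` (and NaN positions) are dismissed
    before binning.  Returns (occupancy_s, weight_sum, valid_frame_mask).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    valid = np.isfinite(x) & np.isfinite(y)
    if speed is not None:
        valid &= np.asarray(speed, dtype=float) >= speed_floor
    ex = _bin_edges(extent_cm[0], bin_cm)
    ey = _bin_edges(extent_cm[1], bin_cm)
    xi = np.clip(np.searchsorted(ex, x[valid], side="right") - 1, 0, len(ex) - 2)
    yi = np.clip(np.searchsorted(ey, y[valid], side="right") - 1, 0, len(ey) - 2)
    shape = (len(ey) - 1, len(ex) - 1)
    flat = yi * shape[1] + xi
    occ = np.bincount(flat, minlength=shape[0] * shape[1]).reshape(shape) / frame_rate_hz
    wsum = np.bincount(flat, weights=weights[valid],
                       minlength=shape[0] * shape[1]).reshape(shape)
    return occ, wsum, valid


def smooth_masked(values: np.ndarray, mask: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Missing-aware Gaussian smoothing: unvisited bins neither receive nor
    donate mass; result is NaN outside the mask."""
    v = np.where(mask, np.nan_to_num(values), 0.0)
    m = mask.astype(float)
    num = gaussian_filter(v, sigma_bins, mode="constant")
    den = gaussian_filter(m, sigma_bins, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~mask] = np.nan
    return out


def tuning_map_2d(
    events_clear: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    extent_cm: tuple[float, float],
    frame_rate_hz: float,
    bin_cm: float = 2.5,
    smooth_sd_cm: float = 3.0,
    speed: np.ndarray | None = None,
    speed_floor: float = 2.5,
    min_visit_s: float = 0.1,
) -> TuningMap:
    """Occupancy-normalised 2D tuning map.

    Per visited bin (occupancy >= ``min_visit_s``): summed event amplitude
    over time spent, then missing-aware Gaussian smoothing of the ratio.
    """
    occ, wsum, valid = occupancy_and_weights(
        x, y, events_clear, extent_cm, frame_rate_hz, bin_cm, speed, speed_floor)
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy after the speed filter")
    visit = occ >= min_visit_s
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(visit, wsum / occ, np.nan)
    sm = smooth_masked(raw, visit, smooth_sd_cm / bin_cm)
    return TuningMap(rate=sm, rate_raw=raw, occupancy_s=occ, visit_mask=visit,
                     bin_size_cm=bin_cm, smoothing_sd_cm=smooth_sd_cm)


def coverage(occupancy_s: np.ndarray, min_visit_s: float = 0.1) -> float:
    """Fraction of arena bins the animal visited for at least min_visit_s."""
    occ = np.asarray(occupancy_s, dtype=float)
    return float((occ >= min_visit_s).sum() / occ.size)


def tuning_curve(
    events_clear: np.ndarray,
    variable: np.ndarray,
    kind: str,
    frame_rate_hz: float,
    bin_width: float | None = None,
    smooth_sd: float | None = None,
    speed: np.ndarray | None = None,
    speed_floor: float = 2.5,
    min_visit_s: float = 0.0,
    speed_range: tuple[float, float] | None = None,
) -> TuningCurve:
    """1D occupancy-normalised tuning curve over direction or speed.

    Directional curves use 3-degree bins and circular (wrapped) 6-degree
    Gaussian smoothing; speed curves 1.5 cm/s bins and 3 cm/s smoothing.
    Bins without occupancy are NaN and excluded downstream.
    """
    if kind not in {"direction", "speed"}:
        raise ValueError("kind must be 'direction' or 'speed'")
    circular = kind == "direction"
    if bin_width is None:
        bin_width = 3.0 if circular else 1.5
    if smooth_sd is None:
        smooth_sd = 6.0 if circular else 3.0
    v = np.asarray(variable, dtype=float)
    e = np.asarray(events_clear, dtype=float)
    valid = np.isfinite(v)
    if speed is not None:
        valid &= np.asarray(speed, dtype=float) >= speed_floor
    if circular:
        edges = np.arange(0.0, 360.0 + bin_width / 2, bin_width)
        vv = np.mod(v[valid], 360.0)
    else:
        top = speed_range[1] if speed_range else (np.nanmax(v[valid]) if valid.any() else bin_width)
        top = max(float(top), bin_width)
        edges = np.arange(0.0, top + bin_width, bin_width)
        vv = np.clip(v[valid], 0.0, edges[-1] - 1e-9)
    bi = np.clip(np.searchsorted(edges, vv, side="right") - 1, 0, len(edges) - 2)
    nb = len(edges) - 1
    occ = np.bincount(bi, minlength=nb) / frame_rate_hz
    wsum = np.bincount(bi, weights=e[valid], minlength=nb)
    visited = occ > max(min_visit_s, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(visited, wsum / occ, np.nan)
    sigma_bins = smooth_sd / bin_width
    if circular:
        filled = np.nan_to_num(raw)
        mask = visited.astype(float)
        num = gaussian_filter1d(filled, sigma_bins, mode="wrap")
        den = gaussian_filter1d(mask, sigma_bins, mode="wrap")
    else:
        filled = np.nan_to_num(raw)
        mask = visited.astype(float)
        num = gaussian_filter1d(filled, sigma_bins, mode="constant")
        den = gaussian_filter1d(mask, sigma_bins, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    sm[~visited] = np.nan
    centers = (edges[:-1] + edges[1:]) / 2
    return TuningCurve(values=sm, values_raw=raw, occupancy_s=occ,
                       bin_centers=centers, bin_width=bin_width,
                       smoothing_sd=smooth_sd, circular=circular)


def _xcorr2(a: np.ndarray, b: np.ndarray, shape, fshape) -> np.ndarray:
    """Full 2D cross-correlation sum_t a[t] * b[t + lag] via FFT."""
    fa = sfft.rfft2(a, fshape)
    fb = sfft.rfft2(b, fshape)
    out = sfft.irfft2(np.conj(fa) * fb, fshape)
    h, w = shape
    return np.roll(out, (h - 1, w - 1), axis=(-2, -1))[..., :2 * h - 1, :2 * w - 1]


def spatial_autocorrelogram(
    rate: np.ndarray | TuningMap,
    min_overlap: int = 20,
) -> Autocorrelogram:
    """Pearson autocorrelation of a tuning map at every 2D lag.

    Only bins valid in both the original and the shifted copy enter each
    lag's correlation; lags with fewer than ``min_overlap`` common bins, or
    zero variance on either side, are NaN.  Accepts a single map or a stack
    (..., H, W) sharing one validity mask (NaN marks missing bins).
    """
    if isinstance(rate, TuningMap):
        rate = rate.rate
    r = np.asarray(rate, dtype=float)
    mask = np.isfinite(r)
    if r.ndim > 2:
        mask = mask.all(axis=tuple(range(r.ndim - 2)))
    f = np.where(np.isfinite(r), r, 0.0) * mask
    m = mask.astype(float)
    h, w = r.shape[-2:]
    fshape = [sfft.next_fast_len(2 * h - 1), sfft.next_fast_len(2 * w - 1)]

    mb = m if f.ndim == 2 else np.broadcast_to(m, f.shape)
    n = _xcorr2(m, m, (h, w), fshape)
    sx = _xcorr2(f, mb, (h, w), fshape)
    sy = _xcorr2(mb, f, (h, w), fshape)
    sxy = _xcorr2(f, f, (h, w), fshape)
    sxx = _xcorr2(f * f, mb, (h, w), fshape)
    syy = _xcorr2(mb, f * f, (h, w), fshape)

    n = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        # guard numerically-zero variances (constant overlap) against FFT noise
        vx = np.where(vx <= 1e-10 * np.abs(n * sxx) + 1e-30, 0.0, vx)
        vy = np.where(vy <= 1e-10 * np.abs(n * syy) + 1e-30, 0.0, vy)
        ac = (n * sxy - sx * sy) / np.sqrt(np.maximum(vx, 0.0) * np.maximum(vy, 0.0))
    ac[..., n < max(min_overlap, 2)] = np.nan
    ac[~np.isfinite(ac)] = np.nan
    return Autocorrelogram(values=ac)


def map_correlation(a: TuningMap | np.ndarray, b: TuningMap | np.ndarray,
                    min_common: int = 10) -> float:
    """Pearson correlation between two maps over bins valid in both."""
    ra = a.rate if isinstance(a, TuningMap) else np.asarray(a, dtype=float)
    rb = b.rate if isinstance(b, TuningMap) else np.asarray(b, dtype=float)
    common = np.isfinite(ra) & np.isfinite(rb)
    if common.sum() < min_common:
        return float("nan")
    va, vb = ra[common], rb[common]
    if va.std() == 0 or vb.std() == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def visual_field_sign(azimuth: np.ndarray, altitude: np.ndarray) -> np.ndarray:
    """Sine of the angle between local azimuth and altitude gradients.

    +1 where the retinotopic gradients form a right-handed (non-mirror)
    frame, -1 where mirrored; NaN where either gradient vanishes.
    """
    az = np.asarray(azimuth, dtype=float)
    al = np.asarray(altitude, dtype=float)
    if az.shape != al.shape:
        raise ValueError("maps must share a grid")
    gay, gax = np.gradient(az)
    gly, glx = np.gradient(al)
    cross = gax * gly - gay * glx
    na = np.hypot(gax, gay)
    nl = np.hypot(glx, gly)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = cross / (na * nl)
    s[(na == 0) | (nl == 0)] = np.nan
    return s
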