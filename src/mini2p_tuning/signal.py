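"""Calcium-trace conditioning: dF/F, significant transients, events, SNR.

The chain mirrors a standard two-photon pipeline: neuropil subtraction with a
fixed coefficient, a running 8th-percentile baseline over a +/-15 s window
with a constant offset fitted on quiescent ("baseline") points, dF/F,
significant-transient detection (2 sigma for more than 0.75 s), non-negative
deconvolution against an exponential kernel (1.5 s decay for GCaMP6s), and a
transient-gated, rescaled event series used by all tuning analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BaselineModel:
    """Running-percentile baseline: F0(t) = F_s(t) + m.

    ``baseline_mask`` marks quiescent frames (local std below the cutoff
    std_min + frac*(std_max - std_min)); ``m`` centres the residual
    F_corr - F0 at zero over those frames.
    """

    F_s: np.ndarray
    m: float
    baseline_mask: np.ndarray
    local_std: np.ndarray

    @property
    def F_0(self) -> np.ndarray:
        return self.F_s + self.m


@dataclass
class ActivitySeries:
    """Conditioned per-cell activity bundle."""

    F_corr: np.ndarray
    dff: np.ndarray
    transient_mask: np.ndarray
    dff_clear: np.ndarray
    events: np.ndarray
    events_clear: np.ndarray
    snr: float
    snr_flag: str  # "ok", "no_transients", "zero_noise"
    n_events: int


def neuropil_correct(F_cell: np.ndarray, F_np: np.ndarray, coefficient: float = 0.7) -> np.ndarray:
    """F_corr = F_cell - coefficient * F_np (fixed-coefficient subtraction)."""
    F_cell = np.asarray(F_cell, dtype=float)
    F_np = np.asarray(F_np, dtype=float)
    if F_cell.shape != F_np.shape:
        raise ValueError("cell and neuropil traces must have equal length")
    return F_cell - coefficient * F_np


def _windowed(x: np.ndarray, half_w: int) -> np.ndarray:
    """Sliding view of x with +/- half_w frames, NaN-padded at the edges."""
    pad = np.full(half_w, np.nan)
    xp = np.concatenate([pad, x, pad])
    return np.lib.stride_tricks.sliding_window_view(xp, 2 * half_w + 1)


def running_baseline(
    F_corr: np.ndarray,
    frame_rate_hz: float,
    window_s: float = 15.0,
    percentile: float = 8.0,
    std_window_s: float = 15.0,
    std_frac: float = 0.1,
) -> BaselineModel:
    """Estimate the slow baseline of a corrected fluorescence trace.

    F_s is the running ``percentile`` (8th) of F_corr in a +/- ``window_s``
    window, truncated at the session edges.  Quiescent frames are those whose
    local standard deviation (same +/- window) stays below
    std_min + std_frac*(std_max - std_min); the constant offset m is the
    median of F_corr - F_s over those frames, so that the residual is centred
    at zero in the absence of calcium activity.  An all-constant trace makes
    every frame quiescent (degenerate rule).
    """
    F_corr = np.asarray(F_corr, dtype=float)
    if not np.all(np.isfinite(F_corr)):
        raise ValueError("non-finite values in trace")
    n = len(F_corr)
    half_w = max(1, int(round(window_s * frame_rate_hz)))
    if n <= half_w:
        raise ValueError("trace shorter than one baseline window")

    F_s = np.empty(n)
    chunk = max(1, int(2e6) // (2 * half_w + 1))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        F_s[lo:hi] = np.nanpercentile(
            _windowed(F_corr, half_w)[lo:hi], percentile, axis=1)

    half_s = max(1, int(round(std_window_s * frame_rate_hz)))
    local_std = _running_std(F_corr, half_s)

    std_min, std_max = local_std.min(), local_std.max()
    if std_max - std_min < 1e-15:
        mask = np.ones(n, dtype=bool)
    else:
        mask = local_std <= std_min + std_frac * (std_max - std_min)
    m = float(np.median(F_corr[mask] - F_s[mask]))
    return BaselineModel(F_s=F_s, m=m, baseline_mask=mask, local_std=local_std)


def _running_std(x: np.ndarray, half_w: int) -> np.ndarray:
    """Truncated-window running standard deviation via cumulative sums."""
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(0, idx - half_w)
    hi = np.minimum(n, idx + half_w + 1)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cnt = (hi - lo).astype(float)
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    var = np.maximum(s2 / cnt - (s1 / cnt) ** 2, 0.0)
    return np.sqrt(var)


def compute_dff(F_corr: np.ndarray, baseline: BaselineModel, f0_tol: float = 1e-9) -> np.ndarray:
    """dF/F(t) = (F_corr(t) - F0(t)) / F0(t)."""
    F0 = baseline.F_0
    bad = np.abs(F0) < f0_tol
    if bad.any():
        raise ValueError(
            f"baseline magnitude below tolerance at frame {int(np.flatnonzero(bad)[0])}")
    return (np.asarray(F_corr, dtype=float) - F0) / F0


def detect_significant_transients(
    dff: np.ndarray,
    baseline: BaselineModel,
    frame_rate_hz: float,
    k_sigma: float = 2.0,
    min_duration_s: float = 0.75,
) -> np.ndarray:
    """Mask of significant transients: dF/F above k_sigma local baseline noise
    for strictly more than ``min_duration_s``.

    The local noise is the running std of F_corr expressed in dF/F units
    (divided by F0).
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    sigma_dff = baseline.local_std / baseline.F_0
    above = np.asarray(dff, dtype=float) > k_sigma * sigma_dff
    mask = np.zeros(len(above), dtype=bool)
    for start, stop in _runs(above):
        if (stop - start) / frame_rate_hz > min_duration_s:
            mask[start:stop] = True
    return mask


def _runs(mask: np.ndarray) -> list:
    """Maximal runs of True as (start, stop) half-open intervals."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(len(m))
    return list(zip(starts, stops))


def deconvolve(trace: np.ndarray, frame_rate_hz: float, decay_s: float = 1.5) -> np.ndarray:
    """Non-negative deconvolution with a constant exponential kernel.

    Solves min ||c - trace||^2 subject to c following an AR(1) decay
    (gamma = exp(-1/(decay_s * frame_rate))) with non-negative innovations,
    by pool adjacent violators; returns the innovation (event) series E >= 0.
    The kernel value at the event frame equals the event amplitude.
    """
    if decay_s <= 0:
        raise ValueError("decay_s must be positive")
    y = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in trace")
    n = len(y)
    if n == 0:
        return np.zeros(0)
    g = np.exp(-1.0 / (decay_s * frame_rate_hz))

    # pools of (value, weight, start, length)
    v = np.empty(n)
    w = np.empty(n)
    t0 = np.empty(n, dtype=int)
    ln = np.empty(n, dtype=int)
    k = -1
    for t in range(n):
        k += 1
        v[k], w[k], t0[k], ln[k] = y[t], 1.0, t, 1
        while k > 0 and v[k] / w[k] < g ** ln[k - 1] * (v[k - 1] / w[k - 1]):
            gl = g ** ln[k - 1]
            v[k - 1] += gl * v[k]
            w[k - 1] += gl * gl * w[k]
            ln[k - 1] += ln[k]
            k -= 1
    c = np.empty(n)
    for i in range(k + 1):
        start, length = t0[i], ln[i]
        c0 = max(v[i] / w[i], 0.0)
        c[start:start + length] = c0 * g ** np.arange(length)
    E = np.empty(n)
    E[0] = c[0]
    E[1:] = c[1:] - g * c[:-1]
    np.clip(E, 0.0, None, out=E)
    return E


def finalize_events(E: np.ndarray, transient_mask: np.ndarray, dff_clear: np.ndarray) -> np.ndarray:
    """Gate events by the transient mask and rescale to the dF/F ceiling.

    E is zeroed outside significant transients, then scaled so that its
    maximum equals the maximum of dF/F_clear; an all-zero input stays zero.
    """
    E = np.asarray(E, dtype=float)
    if E.shape != np.shape(transient_mask) or E.shape != np.shape(dff_clear):
        raise ValueError("inputs must be aligned")
    out = np.where(transient_mask, E, 0.0)
    peak = out.max() if out.size else 0.0
    if peak > 0:
        out = out * (np.max(dff_clear) / peak)
    return out


def count_events(events_clear: np.ndarray) -> int:
    """Number of calcium events: maximal runs of consecutive nonzero samples."""
    return len(_runs(np.asarray(events_clear) > 0))


def compute_snr(dff: np.ndarray, transient_mask: np.ndarray) -> tuple[float, str]:
    """Signal-to-noise ratio of a dF/F trace.

    Signal: mean over significant transients of the within-transient 90th
    percentile of dF/F.  Noise: mean absolute successive difference of dF/F
    outside transients.  Returns (snr, flag); flag is 'no_transients' (snr 0)
    or 'zero_noise' (snr +inf) in the degenerate cases.
    """
    dff = np.asarray(dff, dtype=float)
    mask = np.asarray(transient_mask, dtype=bool)
    runs = _runs(mask)
    if not runs:
        return 0.0, "no_transients"
    signal = float(np.mean([np.percentile(dff[a:b], 90) for a, b in runs]))
    outside = ~mask
    both_out = outside[1:] & outside[:-1]
    diffs = np.abs(np.diff(dff))[both_out]
    noise = float(np.mean(diffs)) if len(diffs) else 0.0
    if noise == 0.0:
        return float("inf"), "zero_noise"
    return signal / noise, "ok"


def process_trace(
    F_cell: np.ndarray,
    F_np: np.ndarray,
    frame_rate_hz: float,
    neuropil_coefficient: float = 0.7,
    decay_s: float = 1.5,
    window_s: float = 15.0,
    percentile: float = 8.0,
    k_sigma: float = 2.0,
    min_duration_s: float = 0.75,
) -> ActivitySeries:
    """Full conditioning chain from raw traces to an ActivitySeries.

    Deconvolution runs on the baseline-subtracted corrected trace so the
    slow component does not leak into events.
    """
    F_corr = neuropil_correct(F_cell, F_np, neuropil_coefficient)
    baseline = running_baseline(F_corr, frame_rate_hz, window_s=window_s,
                                percentile=percentile)
    dff = compute_dff(F_corr, baseline)
    mask = detect_significant_transients(dff, baseline, frame_rate_hz,
                                         k_sigma=k_sigma,
                                         min_duration_s=min_duration_s)
    dff_clear = np.where(mask, dff, 0.0)
    E = deconvolve(F_corr - baseline.F_0, frame_rate_hz, decay_s)
    events_clear = finalize_events(E, mask, dff_clear)
    snr, flag = compute_snr(dff, mask)
    return ActivitySeries(
        F_corr=F_corr, dff=dff, transient_mask=mask, dff_clear=dff_clear,
        events=E, events_clear=events_clear, snr=snr, snr_flag=flag,
        n_events=count_events(events_clear),
    )
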