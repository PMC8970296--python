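"""Brute-force grid-score oracle: explicit loops, independent of the package.

Same mathematical definition as the library scorer — bilinear rotation about
the centre bin, Pearson correlation over annuli between the first local
minimum of the radial profile and the largest inscribed circle — but written
as direct per-pixel loops and np.corrcoef, with no shared code.
"""

import numpy as np


def rotate_brute(a, angle_deg):
    h, w = a.shape
    cy, cx = h // 2, w // 2
    th = np.radians(angle_deg)
    out = np.full_like(a, np.nan, dtype=float)
    for r in range(h):
        for c in range(w):
            dy, dx = r - cy, c - cx
            sx = cx + np.cos(th) * dx + np.sin(th) * dy
            sy = cy - np.sin(th) * dx + np.cos(th) * dy
            x0, y0 = int(np.floor(sx)), int(np.floor(sy))
            if x0 < 0 or y0 < 0 or x0 + 1 > w - 1 or y0 + 1 > h - 1:
                continue
            fx, fy = sx - x0, sy - y0
            v00, v01 = a[y0, x0], a[y0, x0 + 1]
            v10, v11 = a[y0 + 1, x0], a[y0 + 1, x0 + 1]
            out[r, c] = (v00 * (1 - fx) * (1 - fy) + v01 * fx * (1 - fy)
                         + v10 * (1 - fx) * fy + v11 * fx * fy)
    return out


def grid_score_brute(ac, min_annulus_bins=20):
    ac = np.asarray(ac, dtype=float)
    h, w = ac.shape
    cy, cx = h // 2, w // 2
    rmax = min(cy, cx)
    shell = np.empty((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            shell[r, c] = int(round(np.hypot(r - cy, c - cx)))
    valid = np.isfinite(ac) & (shell <= rmax)

    # radial profile and first local minimum
    profile = np.full(rmax + 1, np.nan)
    for s in range(rmax + 1):
        sel = valid & (shell == s)
        if sel.any():
            profile[s] = ac[sel].mean()
    inner = None
    for s in range(1, rmax):
        if np.isfinite(profile[s]) and np.isfinite(profile[s + 1]) \
                and profile[s + 1] >= profile[s]:
            inner = s
            break
    if inner is None or inner + 2 > rmax:
        return float("nan")

    rotations = {ang: rotate_brute(ac, ang) for ang in (30, 60, 90, 120, 150)}
    best = float("nan")
    for outer in range(inner + 2, rmax + 1):
        corrs = {}
        ok_all = True
        for ang, rot in rotations.items():
            sel = (valid & np.isfinite(rot) & (shell >= 1)
                   & (shell > inner) & (shell <= outer))
            xs, ys = ac[sel], rot[sel]
            if sel.sum() < min_annulus_bins or xs.std() == 0 or ys.std() == 0:
                ok_all = False
                break
            corrs[ang] = np.corrcoef(xs, ys)[0, 1]
        if not ok_all:
            continue
        diff = min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150])
        if not np.isfinite(best) or diff > best:
            best = diff
    return best
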