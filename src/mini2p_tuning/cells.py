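"""ROI bookkeeping: repeated-cell removal across planes and stitched FOVs.

Multi-plane imaging and multi-FOV stitching can both extract the same neuron
as two ROIs.  Plane duplicates are found by a disjunction of three criteria
(centre distance, pixel-overlap ratio, signal correlation); cross-FOV
duplicates by a stricter overlap-only rule.  Within each duplicate group only
the member with the highest mean dF/F is kept.  Also provides the bounded
cross-correlation refinement for FOV placement and the per-frame non-rigid
motion summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RoiFootprint:
    """Pixel footprint of one ROI with plane/FOV identity.

    ``pixels`` is an (N, 2) integer array of (row, col) coordinates in a
    common global frame; ``mean_dff`` drives the keep rule in deduplication.
    """

    cell_id: int
    pixels: np.ndarray
    plane: int = 0
    fov: int = 0
    pixel_size_um: float = 1.0
    mean_dff: float = 0.0
    trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)
        if len(self.pixels) == 0:
            raise ValueError("footprint pixel set must be nonempty")

    @property
    def center(self) -> np.ndarray:
        """Mean pixel position (row, col)."""
        return self.pixels.mean(axis=0)

    def center_um(self) -> np.ndarray:
        return self.center * self.pixel_size_um


def _pixel_keys(pixels: np.ndarray) -> np.ndarray:
    p = pixels.astype(np.int64) + 2**20  # keep keys positive
    return p[:, 0] * (2**42) + p[:, 1]


def overlap_ratio(a: RoiFootprint, b: RoiFootprint) -> float:
    """min(shared/|a|, shared/|b|): containment fraction of the smaller side."""
    shared = len(np.intersect1d(_pixel_keys(a.pixels), _pixel_keys(b.pixels),
                                assume_unique=False))
    return min(shared / len(a.pixels), shared / len(b.pixels))


def pair_repeated_planes(
    rois: list,
    d_max_um: float = 15.0,
    overlap_min: float = 0.5,
    corr_min: float = 0.5,
    rule: str = "any",
) -> list:
    """Flag duplicate ROI pairs across adjacent planes.

    A pair is flagged when its centre distance is below ``d_max_um``, its
    overlap ratio exceeds ``overlap_min``, or the Pearson correlation of the
    two dF/F traces exceeds ``corr_min``.  ``rule='all'`` switches to the
    conjunctive reading (all three criteria required).
    """
    if rule not in {"any", "all"}:
        raise ValueError("rule must be 'any' or 'all'")
    pairs = []
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            a, b = rois[i], rois[j]
            if abs(a.plane - b.plane) != 1:
                continue
            close = float(np.linalg.norm(a.center_um() - b.center_um())) < d_max_um
            over = overlap_ratio(a, b) > overlap_min
            corr = False
            if a.trace is not None and b.trace is not None:
                if len(a.trace) != len(b.trace):
                    raise ValueError("traces of unequal length")
                corr = _pearson(a.trace, b.trace) > corr_min
            hit = (close or over or corr) if rule == "any" else (close and over and corr)
            if hit:
                pairs.append((a.cell_id, b.cell_id))
    return pairs


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def dedup(pairs: list, rois: list) -> list:
    """Reduce connected duplicate groups to their highest-mean-dF/F member.

    Pairs are merged transitively (union-find); ties break to the lower cell
    id.  Returns the kept ROI list in input order.
    """
    parent = {r.cell_id: r.cell_id for r in rois}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for r in rois:
        groups.setdefault(find(r.cell_id), []).append(r)
    kept_ids = set()
    for members in groups.values():
        best = max(members, key=lambda r: (r.mean_dff, -r.cell_id))
        kept_ids.add(best.cell_id)
    return [r for r in rois if r.cell_id in kept_ids]


def dedup_across_fovs(rois: list, overlap_min: float = 0.75) -> list:
    """Remove repeated cells across stitched FOVs (overlap-only rule).

    The 0.75 threshold is deliberately stricter than the 0.5 used across
    planes: the same cell seen in two FOVs of the same plane should look
    nearly identical.
    """
    pairs = []
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            a, b = rois[i], rois[j]
            if a.fov == b.fov:
                continue
            if overlap_ratio(a, b) > overlap_min:
                pairs.append((a.cell_id, b.cell_id))
    return dedup(pairs, rois)


def refine_stitch(
    ref: np.ndarray,
    moving: np.ndarray,
    max_shift: int = 5,
) -> tuple[tuple[int, int], bool]:
    """Bounded integer alignment of two overlap images.

    Searches shifts of ``moving`` within +/- ``max_shift`` pixels and returns
    the (drow, dcol) translation to apply to ``moving`` so it aligns with
    ``ref`` — the shift maximising the normalised cross-correlation over the
    intersection — plus a flag that is True when the refinement is unreliable:
    either the overlap is flat (zero variance; placement kept at (0, 0)) or
    the optimum sits on the search boundary (the true shift may be larger).
    """
    ref = np.asarray(ref, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if ref.shape != moving.shape:
        raise ValueError("overlap images must share a shape")
    if ref.std() == 0 or moving.std() == 0:
        return (0, 0), True
    best, best_val = (0, 0), -np.inf
    h, w = ref.shape
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            r0, r1 = max(0, dr), min(h, h + dr)
            c0, c1 = max(0, dc), min(w, w + dc)
            a = ref[r0:r1, c0:c1]
            b = moving[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            if a.size < 16 or a.std() == 0 or b.std() == 0:
                continue
            val = _pearson(a.ravel(), b.ravel())
            if val > best_val:
                best_val, best = val, (dr, dc)
    at_bound = abs(best[0]) == max_shift or abs(best[1]) == max_shift
    return best, at_bound


def nonrigid_summary(mx: np.ndarray, my: np.ndarray) -> np.ndarray:
    """Per-frame non-rigid motion: max block-pair shift-vector difference.

    ``mx``/``my`` have shape (n_frames, B, B) holding per-block shifts; the
    summary is max over block pairs of the root-sum-square difference.
    """
    mx = np.asarray(mx, dtype=float)
    my = np.asarray(my, dtype=float)
    if mx.shape != my.shape:
        raise ValueError("mx and my must share a shape")
    single = mx.ndim == 2
    if single:
        mx, my = mx[None], my[None]
    f = mx.shape[0]
    fx = mx.reshape(f, -1)
    fy = my.reshape(f, -1)
    dx = fx[:, :, None] - fx[:, None, :]
    dy = fy[:, :, None] - fy[:, None, :]
    v = np.sqrt(dx**2 + dy**2).max(axis=(1, 2))
    return v[0] if single else v
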