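"""Synthetic sessions with known ground truth.

Everything downstream — signal conditioning, tuning maps, shuffle-null
classification, ROI dedup, distortion calibration — is exercised on data
generated here: random-foraging trajectories in a square arena, Poisson
calcium events driven by place/grid/head-direction rate models, fluorescence
traces built from an exponential indicator kernel with noise and neuropil
contamination, overlapping ROI footprints across planes and fields of view,
and warped grid-target calibration images.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import TrackingSeries, head_kinematics

EAR_SEPARATION_CM = 2.0


@dataclass
class ArenaSpec:
    """Square (or rectangular) open-field arena and recording cadence.

    Defaults match an 80x80 cm open field tracked at 15 Hz.
    """

    width_cm: float = 80.0
    height_cm: float = 80.0
    frame_rate_hz: float = 15.0
    duration_s: float = 1800.0

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


@dataclass
class Mobility:
    """Foraging-style locomotion parameters.

    ``mean_speed_cm_s`` sets the expected path length per unit time;
    ``turn_persistence`` in [0, 1) controls heading smoothness (1 = straight
    runs, 0 = uncorrelated headings); ``speed_sd_frac`` the relative spread of
    the slowly varying speed process.
    """

    mean_speed_cm_s: float = 10.0
    turn_persistence: float = 0.95
    speed_sd_frac: float = 0.35


@dataclass
class TuningModel:
    """Ground-truth firing-rate model for one synthetic cell.

    kinds: place (Gaussian bump), grid (thresholded three-cosine interference
    pattern), head_direction (von Mises), conjunctive (grid x head
    direction), untuned (constant), escape (gain during flagged frames).
    """

    kind: str
    params: dict = field(default_factory=dict)
    baseline_rate_hz: float = 0.1

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline_rate_hz must be nonnegative")
        if self.kind not in {"place", "grid", "head_direction", "conjunctive",
                             "untuned", "escape"}:
            raise ValueError(f"unknown tuning kind: {self.kind!r}")


@dataclass
class CalciumModel:
    """Fluorescence-generation parameters for the exponential indicator kernel.

    The 1.5 s decay is the GCaMP6s time constant used throughout.
    """

    decay_s: float = 1.5
    amplitude_scale: float = 1.0
    noise_sd: float = 0.0
    neuropil_fraction: float = 0.0
    baseline_f: float = 100.0
    neuropil_baseline_f: float = 50.0

    def __post_init__(self) -> None:
        if self.decay_s <= 0:
            raise ValueError("decay_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.neuropil_fraction < 1:
            raise ValueError("neuropil_fraction must be in [0, 1)")


def simulate_trajectory(
    arena: ArenaSpec,
    mobility: Mobility | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a smooth random-foraging path and emit a body-part table.

    The head follows a smoothed random walk: heading is an AR(1)-persistent
    angular random walk, speed an Ornstein-Uhlenbeck process clipped at zero,
    and walls reflect.  Rows are emitted for left ear, right ear, body centre
    and tail base (likelihood 1.0); ear separation is constant so head
    direction is always well defined and equals the heading of motion.
    """
    mobility = mobility or Mobility()
    rng = np.random.default_rng(seed)
    n = arena.n_frames
    dt = 1.0 / arena.frame_rate_hz
    margin = EAR_SEPARATION_CM

    # heading: persistent angular random walk
    turn_sd = np.sqrt(max(1e-12, 1.0 - mobility.turn_persistence))  # rad/step scale
    heading = np.cumsum(rng.normal(0.0, turn_sd, size=n))
    heading += rng.uniform(0, 2 * np.pi)

    # speed: OU around the mean, clipped at zero
    mu, sd = mobility.mean_speed_cm_s, mobility.speed_sd_frac * mobility.mean_speed_cm_s
    theta = 0.2  # mean-reversion per frame
    speed = np.empty(n)
    speed[0] = mu
    noise = rng.normal(0.0, sd * np.sqrt(2 * theta), size=n)
    for i in range(1, n):
        speed[i] = speed[i - 1] + theta * (mu - speed[i - 1]) + noise[i]
    np.clip(speed, 0.0, None, out=speed)

    x = np.empty(n)
    y = np.empty(n)
    x[0] = rng.uniform(margin, arena.width_cm - margin)
    y[0] = rng.uniform(margin, arena.height_cm - margin)
    cos_h, sin_h = np.cos(heading), np.sin(heading)
    for i in range(1, n):
        step = speed[i] * dt
        nx = x[i - 1] + step * cos_h[i]
        ny = y[i - 1] + step * sin_h[i]
        nx, rx = _reflect(nx, margin, arena.width_cm - margin)
        ny, ry = _reflect(ny, margin, arena.height_cm - margin)
        if rx:
            cos_h[i:] = -cos_h[i:]
        if ry:
            sin_h[i:] = -sin_h[i:]
        x[i], y[i] = nx, ny

    heading = np.arctan2(sin_h, cos_h)
    return _body_part_table(x, y, heading)


def _reflect(v: float, lo: float, hi: float) -> tuple[float, bool]:
    reflected = False
    # walls are reflecting; a step never exceeds the arena so one pass suffices
    if v < lo:
        v = 2 * lo - v
        reflected = True
    elif v > hi:
        v = 2 * hi - v
        reflected = True
    return v, reflected


def _body_part_table(x: np.ndarray, y: np.ndarray, heading: np.ndarray) -> pd.DataFrame:
    """Assemble the four body-part rows from head path and facing direction."""
    n = len(x)
    half = EAR_SEPARATION_CM / 2.0
    # facing direction phi: left->right ear vector points at phi - 90 deg
    ear_dx, ear_dy = np.cos(heading - np.pi / 2), np.sin(heading - np.pi / 2)
    back_dx, back_dy = -np.cos(heading), -np.sin(heading)
    parts = {
        "left_ear": (x - half * ear_dx, y - half * ear_dy),
        "right_ear": (x + half * ear_dx, y + half * ear_dy),
        "body_center": (x + 2.0 * back_dx, y + 2.0 * back_dy),
        "tail_base": (x + 4.5 * back_dx, y + 4.5 * back_dy),
    }
    frames = np.arange(n)
    rows = []
    for part, (px, py) in parts.items():
        rows.append(pd.DataFrame({
            "frame": frames, "part": part, "x": px, "y": py,
            "likelihood": np.ones(n),
        }))
    return (pd.concat(rows, ignore_index=True)
            .sort_values(["frame", "part"]).reset_index(drop=True))


def rate_from_tuning(model: TuningModel, tracking: TrackingSeries) -> np.ndarray:
    """Evaluate a tuning model along a trajectory, returning rate in Hz."""
    x, y = tracking.x, tracking.y
    base = model.baseline_rate_hz
    p = model.params
    if model.kind == "untuned":
        return np.full(len(x), base)
    if model.kind == "place":
        cx, cy = p["center_cm"]
        w = p["width_cm"]
        g = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * w * w))
        return base + p["peak_rate_hz"] * g
    if model.kind == "grid":
        return base + p["peak_rate_hz"] * grid_pattern(
            x, y, p["spacing_cm"], p.get("orientation_deg", 0.0),
            p.get("phase_cm", (0.0, 0.0)))
    if model.kind == "head_direction":
        g = _von_mises(tracking.direction, p["preferred_deg"], p["concentration"])
        return base + p["peak_rate_hz"] * g
    if model.kind == "conjunctive":
        gg = grid_pattern(x, y, p["spacing_cm"], p.get("orientation_deg", 0.0),
                          p.get("phase_cm", (0.0, 0.0)))
        gh = _von_mises(tracking.direction, p["preferred_deg"], p["concentration"])
        return base + p["peak_rate_hz"] * gg * gh
    if model.kind == "escape":
        mask = np.asarray(p["escape_mask"], dtype=bool)
        return base + p.get("gain_hz", 0.0) * mask
    raise ValueError(f"unknown tuning kind: {model.kind!r}")


def grid_pattern(
    x: np.ndarray,
    y: np.ndarray,
    spacing_cm: float,
    orientation_deg: float = 0.0,
    phase_cm: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Hexagonal firing pattern in [0, 1]: thresholded three-cosine interference.

    Three plane waves at 60-degree separations with wavevector magnitude
    4*pi/(sqrt(3)*spacing) sum to a hexagonal lattice of bumps with the given
    spacing; the sum is rectified and normalised to peak 1.
    """
    if spacing_cm <= 0:
        raise ValueError("spacing_cm must be positive")
    k = 4 * np.pi / (np.sqrt(3) * spacing_cm)
    xr = np.asarray(x, dtype=float) - phase_cm[0]
    yr = np.asarray(y, dtype=float) - phase_cm[1]
    total = np.zeros_like(xr)
    # wave vectors sit 30 degrees off the lattice axes, so offset them to make
    # orientation_deg the orientation of the nearest-neighbour field axis
    for ang_deg in (orientation_deg + 30.0, orientation_deg + 90.0,
                    orientation_deg + 150.0):
        a = np.radians(ang_deg)
        total += np.cos(k * (xr * np.cos(a) + yr * np.sin(a)))
    return np.clip(total, 0.0, None) / 3.0


def _von_mises(direction_deg: np.ndarray, preferred_deg: float, kappa: float) -> np.ndarray:
    """Von Mises directional gain normalised to peak 1; NaN direction -> 0."""
    if kappa < 0:
        raise ValueError("concentration must be nonnegative")
    d = np.radians(np.asarray(direction_deg, dtype=float) - preferred_deg)
    g = np.exp(kappa * (np.cos(d) - 1.0))
    return np.where(np.isfinite(g), np.nan_to_num(g), 0.0)


def draw_events(
    rate_hz: np.ndarray,
    frame_rate_hz: float,
    seed: int,
    amplitude_sigma: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-frame calcium events by Poisson thinning of a rate series.

    Event counts per frame are Poisson with mean rate*dt; amplitudes are
    log-normal with unit median.  Returns (event_frames, amplitudes), one
    entry per event, frames nondecreasing.
    """
    rng = np.random.default_rng(seed)
    counts = rng.poisson(np.asarray(rate_hz, dtype=float) / frame_rate_hz)
    frames = np.repeat(np.arange(len(counts)), counts)
    amps = rng.lognormal(mean=0.0, sigma=amplitude_sigma, size=len(frames))
    return frames, amps


def events_to_traces(
    event_frames: np.ndarray,
    amplitudes: np.ndarray,
    calcium: CalciumModel,
    n_frames: int,
    frame_rate_hz: float,
    seed: int = 0,
    neuropil_process: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render raw and neuropil fluorescence traces from events.

    raw = baseline + sum_k amp_k * exp(-(t - t_k)/decay) * 1[t >= t_k]
          + Gaussian noise + neuropil_fraction * shared neuropil fluctuation.

    The kernel value at the event frame equals the amplitude.  The neuropil
    trace (slow shared fluctuation plus its own noise) is returned alongside
    so correction can be tested.
    """
    event_frames = np.asarray(event_frames, dtype=int)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(amplitudes < 0):
        raise ValueError("event amplitudes must be nonnegative")
    if len(event_frames) and (event_frames.min() < 0 or event_frames.max() >= n_frames):
        raise ValueError("event frames outside the session")
    rng = np.random.default_rng(seed)

    impulses = np.zeros(n_frames)
    np.add.at(impulses, event_frames, amplitudes * calcium.amplitude_scale)
    gamma = np.exp(-1.0 / (calcium.decay_s * frame_rate_hz))
    signal = _ar1_filter(impulses, gamma)

    if neuropil_process is None:
        slow = _smooth_noise(rng, n_frames, frame_rate_hz, tau_s=5.0)
        neuropil_process = calcium.neuropil_baseline_f * (1.0 + 0.05 * slow)
    np_fluct = neuropil_process - np.mean(neuropil_process)

    raw = (calcium.baseline_f + signal
           + calcium.neuropil_fraction * np_fluct
           + rng.normal(0.0, calcium.noise_sd, size=n_frames))
    neuropil = neuropil_process + rng.normal(0.0, calcium.noise_sd, size=n_frames)
    return raw, neuropil


def _ar1_filter(impulses: np.ndarray, gamma: float) -> np.ndarray:
    from scipy.signal import lfilter
    return lfilter([1.0], [1.0, -gamma], impulses)


def _smooth_noise(rng: np.random.Generator, n: int, frame_rate_hz: float, tau_s: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d
    raw = rng.normal(size=n)
    sm = gaussian_filter1d(raw, sigma=max(1.0, tau_s * frame_rate_hz / 4))
    sd = sm.std()
    return sm / sd if sd > 0 else sm


@dataclass
class SyntheticCell:
    """One simulated cell: its truth record and rendered traces."""

    cell_id: int
    model: TuningModel
    event_frames: np.ndarray
    event_amplitudes: np.ndarray
    raw: np.ndarray
    neuropil: np.ndarray
    plane: int = 0


@dataclass
class SyntheticSession:
    """A complete simulated recording with ground truth for every cell."""

    arena: ArenaSpec
    table: pd.DataFrame
    tracking: TrackingSeries
    cells: list
    calcium: CalciumModel
    seed: int
    n_planes: int = 1


def simulate_session(
    arena: ArenaSpec,
    models: list,
    calcium: CalciumModel | None = None,
    mobility: Mobility | None = None,
    seed: int = 0,
    n_planes: int = 1,
) -> SyntheticSession:
    """Simulate a full session: trajectory plus one cell per tuning model.

    With ``n_planes`` > 1 cells are assigned round-robin to planes and each
    cell's rate is evaluated on its plane's tracking subsequence (frame k of
    plane p maps to tracking frame k*n_planes + p), mirroring interleaved
    multi-plane acquisition.
    """
    calcium = calcium or CalciumModel()
    ss = np.random.SeedSequence([int(seed), 2026])
    traj_seed, *cell_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                              ss.spawn(1 + 2 * len(models))]
    table = simulate_trajectory(arena, mobility, seed=traj_seed)
    tracking = head_kinematics(table, arena.frame_rate_hz)

    cells = []
    for i, model in enumerate(models):
        plane = i % n_planes
        sub = plane_tracking(tracking, plane, n_planes)
        rate = rate_from_tuning(model, sub)
        frames, amps = draw_events(rate, arena.frame_rate_hz / n_planes,
                                   seed=cell_seeds[2 * i])
        raw, npil = events_to_traces(frames, amps, calcium, sub.n_frames,
                                     arena.frame_rate_hz / n_planes,
                                     seed=cell_seeds[2 * i + 1])
        cells.append(SyntheticCell(cell_id=i, model=model, event_frames=frames,
                                   event_amplitudes=amps, raw=raw, neuropil=npil,
                                   plane=plane))
    return SyntheticSession(arena=arena, table=table, tracking=tracking,
                            cells=cells, calcium=calcium, seed=seed,
                            n_planes=n_planes)


def plane_tracking(tracking: TrackingSeries, plane: int, n_planes: int) -> TrackingSeries:
    """Tracking subsequence seen by cells of one plane (every n-th frame)."""
    if n_planes == 1:
        return tracking
    n_usable = tracking.n_frames - tracking.n_frames % n_planes
    idx = np.arange(plane, n_usable, n_planes)
    return TrackingSeries(
        x=tracking.x[idx], y=tracking.y[idx],
        speed=tracking.speed[idx], direction=tracking.direction[idx],
        frame_rate_hz=tracking.frame_rate_hz / n_planes,
    )


# ---------------------------------------------------------------------------
# ROI footprint fixtures and calibration targets


def _disk_pixels(center_rc: tuple[int, int], radius_px: int) -> np.ndarray:
    r0, c0 = center_rc
    rr, cc = np.mgrid[-radius_px:radius_px + 1, -radius_px:radius_px + 1]
    inside = rr**2 + cc**2 <= radius_px**2
    return np.column_stack([rr[inside] + r0, cc[inside] + c0])


def _offset_for_overlap(radius_px: int, target: float) -> int:
    """Integer x-offset of two equal disks giving overlap closest to target."""
    base = _disk_pixels((0, 0), radius_px)
    from .cells import RoiFootprint
    a = RoiFootprint(cell_id=0, pixels=base)
    best_d, best_err = 0, np.inf
    for d in range(0, 4 * radius_px + 1):
        b = RoiFootprint(cell_id=1, pixels=base + np.array([0, d]))
        from .cells import overlap_ratio
        err = abs(overlap_ratio(a, b) - target)
        if err < best_err:
            best_err, best_d = err, d
    return best_d


def make_footprint_fixture(
    n_cells: int = 20,
    duplicate_pairs: int = 5,
    mode: str = "plane",
    duplicate_overlap: float = 0.7,
    radius_px: int = 5,
    pixel_size_um: float = 2.0,
    n_trace_frames: int = 1000,
    seed: int = 0,
) -> tuple[list, list]:
    """Build ROI footprints with planted duplicates and a truth table.

    Base cells sit on a jittered grid with pairwise separation far above the
    duplicate criteria, each with an independent white-noise dF/F trace.  For
    each planted duplicate, a partner ROI is placed in the adjacent plane
    (``mode='plane'``) or neighbouring FOV (``mode='fov'``) at an offset tuned
    to the requested pixel-overlap ratio, sharing the original's trace.

    Returns ``(rois, truth)`` where truth lists (original_id, duplicate_id).
    """
    from .cells import RoiFootprint

    if duplicate_pairs > n_cells:
        raise ValueError("cannot plant more duplicate pairs than cells")
    if mode not in {"plane", "fov"}:
        raise ValueError("mode must be 'plane' or 'fov'")
    rng = np.random.default_rng(seed)
    # grid spacing in px large enough that non-duplicates never trip any rule
    spacing = max(6 * radius_px, int(np.ceil(40.0 / pixel_size_um)) + 4 * radius_px)
    side = int(np.ceil(np.sqrt(n_cells)))
    rois = []
    for i in range(n_cells):
        r = (i // side) * spacing + spacing
        c = (i % side) * spacing + spacing
        jitter = rng.integers(-radius_px // 2, radius_px // 2 + 1, size=2)
        trace = rng.normal(size=n_trace_frames)
        rois.append(RoiFootprint(
            cell_id=i, pixels=_disk_pixels((r + jitter[0], c + jitter[1]), radius_px),
            plane=0, fov=0, pixel_size_um=pixel_size_um,
            mean_dff=float(rng.uniform(0.1, 1.0)), trace=trace))

    truth = []
    offset = _offset_for_overlap(radius_px, duplicate_overlap)
    chosen = rng.choice(n_cells, size=duplicate_pairs, replace=False)
    for k, orig_idx in enumerate(chosen):
        orig = rois[orig_idx]
        dup_id = n_cells + k
        dup = RoiFootprint(
            cell_id=dup_id,
            pixels=orig.pixels + np.array([0, offset]),
            plane=1 if mode == "plane" else 0,
            fov=0 if mode == "plane" else 1,
            pixel_size_um=pixel_size_um,
            mean_dff=float(rng.uniform(0.1, 1.0)),
            trace=orig.trace + rng.normal(0.0, 0.05, size=n_trace_frames),
        )
        rois.append(dup)
        truth.append((orig.cell_id, dup_id))
    return rois, truth


def make_grid_target_image(
    grid_pitch_um: float = 50.0,
    pixel_size_um: float = 2.0,
    size_px: int = 256,
    warp=None,
    line_sigma_px: float = 1.2,
    margin_px: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a (possibly warped) grid calibration target.

    The ideal pattern is a square lattice of bright lines (Gaussian profile)
    with the given pitch; ``warp`` is a displacement field ``warp(x, y) ->
    (dx, dy)`` mapping ideal to measured coordinates (identity when None).
    The warped image is rendered by inverting the warp per pixel (fixed-point
    iteration); a folding (non-injective) warp raises.

    Returns ``(image, ideal_anchors, warped_anchors)`` with anchors as
    (x, y) pixel coordinates of the line crossings.
    """
    pitch_px = grid_pitch_um / pixel_size_um
    if pitch_px < 4:
        raise ValueError("grid pitch below 4 px cannot be resolved")

    def disp(x, y):
        if warp is None:
            return np.zeros_like(x, dtype=float), np.zeros_like(y, dtype=float)
        dx, dy = warp(x, y)
        return np.asarray(dx, dtype=float), np.asarray(dy, dtype=float)

    # injectivity: Jacobian determinant of q -> q + disp(q) on a coarse grid
    gs = np.linspace(0, size_px - 1, 24)
    gx, gy = np.meshgrid(gs, gs)
    eps = 0.5
    dxp, dyp = disp(gx + eps, gy)
    dxm, dym = disp(gx - eps, gy)
    j11 = 1 + (dxp - dxm) / (2 * eps)
    j21 = (dyp - dym) / (2 * eps)
    dxp, dyp = disp(gx, gy + eps)
    dxm, dym = disp(gx, gy - eps)
    j12 = (dxp - dxm) / (2 * eps)
    j22 = 1 + (dyp - dym) / (2 * eps)
    if np.any(j11 * j22 - j12 * j21 <= 0):
        raise ValueError("warp folds (non-injective) on the image domain")

    cols, rows = np.meshgrid(np.arange(size_px, dtype=float),
                             np.arange(size_px, dtype=float))
    qx, qy = cols.copy(), rows.copy()
    for _ in range(12):
        dx, dy = disp(qx, qy)
        qx = cols - dx
        qy = rows - dy

    def pattern(x, y):
        fx = np.abs(((x - margin_px) / pitch_px + 0.5) % 1.0 - 0.5) * pitch_px
        fy = np.abs(((y - margin_px) / pitch_px + 0.5) % 1.0 - 0.5) * pitch_px
        return (np.exp(-fx**2 / (2 * line_sigma_px**2))
                + np.exp(-fy**2 / (2 * line_sigma_px**2)))

    image = pattern(qx, qy)

    k = np.arange(0, int((size_px - 2 * margin_px) // pitch_px) + 1)
    ax, ay = np.meshgrid(margin_px + k * pitch_px, margin_px + k * pitch_px)
    ideal = np.column_stack([ax.ravel(), ay.ravel()])
    dx, dy = disp(ideal[:, 0], ideal[:, 1])
    warped = ideal + np.column_stack([dx, dy])
    keep = ((warped[:, 0] > 2) & (warped[:, 0] < size_px - 3)
            & (warped[:, 1] > 2) & (warped[:, 1] < size_px - 3))
    return image, ideal[keep], warped[keep]
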