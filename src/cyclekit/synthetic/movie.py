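"""Two-channel time-lapse movie renderer with recorded ground truth.

Channel 0 is the nuclear marker (constant nuclear intensity); channel 1 is the
translocation sensor, partitioned between the nucleus and a perinuclear
cytoplasm so that

    (cytoplasmic median - background) / (nuclear median - background)

equals the prescribed CDK2 activity.  Nuclei are ellipses with Gaussian-
smoothed edges (sigma = 1 px).  A smooth multiplicative bias field and
additive Gaussian noise are applied last:

    raw = bias * (scene + background) + N(0, noise_sd)

Cell motion is a bounded random walk around a per-cell home position, which
keeps neighbours separated so scheduled divisions stay resolvable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .trajectory import FATE_LABELS, TrajectoryParams, generate_cdk2_trajectory


@dataclass
class SimMovieConfig:
    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.65
    frame_interval_min: float = 12.0
    n_frames: int = 40
    n_cells_initial: int = 20
    division_schedule: list[tuple[int, int, tuple[float, float]]] = field(default_factory=list)
    death_schedule: list[tuple[int, int]] = field(default_factory=list)
    fate_assignment: dict[int, str] = field(default_factory=dict)
    bias_amplitude: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    # Rendering conventions (not part of the public schedule contract).
    nucleus_area_um2: float = 120.0
    cytoplasm_width_um: float = 8.0
    marker_intensity: float = 1000.0
    sensor_nuclear_intensity: float = 400.0
    background: float = 50.0
    motion_step_px: float = 2.0
    home_radius_px: float = 5.0
    default_activity: float = 0.3
    trajectory_params: TrajectoryParams = field(default_factory=TrajectoryParams)
    positions: list[tuple[float, float]] | None = None

    def validate(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.bias_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("bias_amplitude and noise_sd must be >= 0")
        if self.n_cells_initial < 0 or self.n_frames < 1:
            raise ValueError("n_cells_initial >= 0 and n_frames >= 1 required")
        for cid, frame, fracs in self.division_schedule:
            if not 1 <= frame < self.n_frames:
                raise ValueError(f"division frame {frame} outside movie for cell {cid}")
            for f in fracs:
                if not 0.0 < f < 1.0:
                    raise ValueError(f"daughter area fraction {f} not in (0, 1)")
        for cid, frame in self.death_schedule:
            if not 0 <= frame < self.n_frames:
                raise ValueError(f"death frame {frame} outside movie for cell {cid}")
        for cid, fate in self.fate_assignment.items():
            if fate not in FATE_LABELS:
                raise ValueError(f"unknown fate {fate!r} for cell {cid}")


@dataclass
class MovieStack:
    """(n_frames, 2, H, W) float32 stack plus acquisition metadata."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    channel_names: tuple[str, str] = ("nuclear_marker", "sensor")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class GroundTruth:
    label_masks: np.ndarray  # (n_frames, H, W) uint16, 0 = background
    trajectories: dict[int, dict]  # cell id -> frames/x/y/area_px/activity arrays
    divisions: list[dict]  # mother, frame, daughters, fractions
    deaths: list[dict]  # cell, frame
    fates: dict[int, str]
    bias_field: np.ndarray
    background: float

    def cells_alive(self, frame: int) -> list[int]:
        return [
            cid
            for cid, tr in self.trajectories.items()
            if tr["frames"][0] <= frame <= tr["frames"][-1]
        ]


def _place_homes(cfg: SimMovieConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid home positions with room for cytoplasm and motion."""
    if cfg.positions is not None:
        homes = np.asarray(cfg.positions, dtype=float)
        if len(homes) < cfg.n_cells_initial:
            raise ValueError("fewer positions than n_cells_initial")
        return homes[: cfg.n_cells_initial]
    h, w = cfg.field_size_px
    r_nuc = np.sqrt(cfg.nucleus_area_um2 / np.pi) / cfg.pixel_size_um
    margin = r_nuc + cfg.cytoplasm_width_um / cfg.pixel_size_um + cfg.home_radius_px + 2
    # Spacing keeps a divided pair's nuclei clear of the neighbouring pair.
    spacing = max(2 * margin * 0.85, 4.5 * r_nuc)
    ys = np.arange(margin, h - margin + 1e-9, spacing)
    xs = np.arange(margin, w - margin + 1e-9, spacing)
    grid = [(y, x) for y in ys for x in xs]
    if len(grid) < cfg.n_cells_initial:
        raise ValueError(
            f"field {cfg.field_size_px} holds at most {len(grid)} cells; "
            f"{cfg.n_cells_initial} scheduled outside the field"
        )
    idx = rng.permutation(len(grid))[: cfg.n_cells_initial]
    homes = np.array([grid[i] for i in idx], dtype=float)
    homes += rng.uniform(-0.15 * spacing, 0.15 * spacing, size=homes.shape)
    return homes


def _bounded_walk(
    rng: np.random.Generator, home: np.ndarray, n: int, step: float, radius: float
) -> np.ndarray:
    pos = np.empty((n, 2))
    cur = home.copy()
    for i in range(n):
        cur = cur + rng.normal(0.0, step, size=2)
        off = cur - home
        d = np.hypot(*off)
        if d > radius:
            cur = home + off * (radius / d)
        pos[i] = cur
    return pos


def _smooth_bias(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape, dtype=np.float32)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy / max(h - 1, 1) - 0.5
    x = xx / max(w - 1, 1) - 0.5
    c = rng.uniform(-1, 1, size=5)
    g = c[0] * x + c[1] * y + c[2] * x * y + c[3] * (x**2 - 1 / 12) + c[4] * (y**2 - 1 / 12)
    g -= g.mean()
    peak = np.abs(g).max()
    if peak == 0:
        return np.ones(shape, dtype=np.float32)
    return (1.0 + amplitude * g / peak).astype(np.float32)


def _fill_ellipse(
    mask: np.ndarray,
    cy: float,
    cx: float,
    a: float,
    b: float,
    theta: float,
    value: int,
    target_px: float | None = None,
) -> int:
    """Rasterize an ellipse (semi-axes a, b, rotation theta) into ``mask``.

    When ``target_px`` is given the axes are rescaled (bisection on a common
    scale factor) until the pixel count matches the target to within 1 px, so
    scheduled daughter/mother area fractions survive rasterization.  Returns
    the number of pixels written.
    """
    h, w = mask.shape
    r = int(np.ceil(max(a, b) * 1.2)) + 2
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    # Normalized squared radius; pixels sorted by it give a nested family of
    # rasterizations, from which the count closest to target is selected.
    q = (u / a) ** 2 + (v / b) ** 2
    if target_px is None:
        inside = q <= 1.0
    else:
        flat = np.sort(q.ravel())
        n = int(round(target_px))
        n = max(min(n, flat.size), 1)
        cut = flat[n - 1]
        inside = q <= cut
    mask[y0:y1, x0:x1][inside] = value
    return int(inside.sum())


class _SimCell:
    __slots__ = (
        "cid", "start", "end", "area_px", "ecc", "theta",
        "positions", "activity", "fate", "death_frame",
    )

    def __init__(self, cid, start, end, area_px, ecc, theta, positions, activity, fate, death_frame=None):
        self.cid = cid
        self.start = start
        self.end = end  # inclusive last frame rendered
        self.area_px = area_px
        self.ecc = ecc
        self.theta = theta
        self.positions = positions  # (end-start+1, 2)
        self.activity = activity  # same length
        self.fate = fate
        self.death_frame = death_frame


def render_movie(config: SimMovieConfig) -> tuple[MovieStack, GroundTruth]:
    """Render the configured movie; identical seeds give identical stacks."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.field_size_px
    n_frames = config.n_frames
    px = config.pixel_size_um
    area_px = config.nucleus_area_um2 / px**2
    horizon_min = n_frames * config.frame_interval_min

    homes = _place_homes(config, rng)
    div_by_cell = {cid: (fr, fracs) for cid, fr, fracs in config.division_schedule}
    death_by_cell = dict(config.death_schedule)

    fates: dict[int, str] = dict(config.fate_assignment)

    def fate_of(cid: int) -> str | None:
        return fates.get(cid)

    def activity_series(cid: int, start: int, end: int, anaphase_frame: int | None) -> np.ndarray:
        """Prescribed activity for frames start..end (inclusive)."""
        fate = fate_of(cid)
        n = end - start + 1
        if fate is None:
            return np.full(n, config.default_activity)
        if anaphase_frame is None:
            # Mother awaiting (or never reaching) its scheduled division: use
            # the pre-anaphase ramp anchored at the scheduled division frame,
            # else a flat default.
            if cid in div_by_cell:
                ana_min = div_by_cell[cid][0] * config.frame_interval_min
                t, v = generate_cdk2_trajectory(
                    fate, max(ana_min, config.frame_interval_min), horizon_min,
                    config.trajectory_params, config.frame_interval_min,
                )
                return v[start : end + 1]
            return np.full(n, config.default_activity)
        # Daughter: trajectory relative to its own anaphase.
        ana_min = anaphase_frame * config.frame_interval_min
        t, v = generate_cdk2_trajectory(
            fate, max(ana_min, 1e-9), horizon_min, config.trajectory_params,
            config.frame_interval_min,
        )
        return v[start : end + 1]

    cells: list[_SimCell] = []
    divisions: list[dict] = []
    deaths: list[dict] = []
    next_id = config.n_cells_initial

    def spawn(cid: int, start: int, home: np.ndarray, cell_area: float,
              anaphase_frame: int | None, inherit_fate: str | None) -> None:
        nonlocal next_id
        end = n_frames - 1
        div = div_by_cell.get(cid)
        death = death_by_cell.get(cid)
        if div is not None and div[0] > start:
            end = min(end, div[0] - 1)
        elif div is not None and div[0] <= start:
            div = None  # schedule already consumed or invalid for this track
        if death is not None and start <= death <= end:
            end = death
        else:
            death = None
        ecc = rng.uniform(1.0, 1.25)
        theta = rng.uniform(0, np.pi)
        positions = _bounded_walk(
            rng, home, end - start + 1, config.motion_step_px, config.home_radius_px
        )
        if inherit_fate is not None and cid not in fates:
            fates[cid] = inherit_fate
        act = activity_series(cid, start, end, anaphase_frame)
        cells.append(
            _SimCell(cid, start, end, cell_area, ecc, theta, positions, act,
                     fates.get(cid), death)
        )
        if death is not None:
            deaths.append({"cell": cid, "frame": death})
        if div is not None:
            fr, (f1, f2) = div
            d1, d2 = next_id, next_id + 1
            next_id += 2
            mother_last_pos = positions[-1]
            r_m = np.sqrt(cell_area / np.pi)
            axis = rng.uniform(0, np.pi)
            # 1.2 r keeps sibling nuclei separated by a clear background gap
            # so threshold segmentation resolves them at the anaphase frame
            off = np.array([np.sin(axis), np.cos(axis)]) * 1.2 * r_m
            divisions.append(
                {"mother": cid, "frame": fr, "daughters": (d1, d2), "fractions": (f1, f2)}
            )
            mf = fates.get(cid)
            daughter_fate = mf if mf in FATE_LABELS else None
            spawn(d1, fr, mother_last_pos + off, cell_area * f1, fr, daughter_fate)
            spawn(d2, fr, mother_last_pos - off, cell_area * f2, fr, daughter_fate)

    for cid in range(config.n_cells_initial):
        spawn(cid, 0, homes[cid], area_px, None, None)

    # --- rasterize ---------------------------------------------------------
    label_masks = np.zeros((n_frames, h, w), dtype=np.uint16)
    data = np.empty((n_frames, 2, h, w), dtype=np.float32)
    bias = _smooth_bias((h, w), config.bias_amplitude, rng)
    cyto_w_px = config.cytoplasm_width_um / px
    trajectories: dict[int, dict] = {}

    for cell in cells:
        trajectories[cell.cid] = {
            "frames": np.arange(cell.start, cell.end + 1),
            "y": cell.positions[:, 0].copy(),
            "x": cell.positions[:, 1].copy(),
            "area_px": np.full(cell.end - cell.start + 1, cell.area_px),
            "activity": cell.activity.copy(),
        }
        if cell.death_frame is not None:
            trajectories[cell.cid]["area_px"][-1] = 0.3 * cell.area_px

    noise_rng = np.random.default_rng(rng.integers(0, 2**63))
    for f in range(n_frames):
        marker = np.zeros((h, w), dtype=np.float32)
        sensor = np.zeros((h, w), dtype=np.float32)
        labels = label_masks[f]
        frame_cells = [c for c in cells if c.start <= f <= c.end]
        for c in frame_cells:
            i = f - c.start
            area = trajectories[c.cid]["area_px"][i]
            b_ax = np.sqrt(area / (np.pi * c.ecc))
            a_ax = c.ecc * b_ax
            cy, cx = c.positions[i]
            _fill_ellipse(labels, cy, cx, a_ax, b_ax, c.theta, c.cid + 1, target_px=area)
        nuc = labels > 0
        marker[nuc] = config.marker_intensity
        sensor[nuc] = config.sensor_nuclear_intensity
        # Perinuclear cytoplasm: per-cell local distance band, intensity
        # activity * nuclear sensor level; overlaps resolved by max.
        for c in frame_cells:
            i = f - c.start
            act = c.activity[i]
            cy, cx = c.positions[i]
            r = int(np.ceil(np.sqrt(c.area_px / np.pi) * 1.4 + cyto_w_px)) + 3
            y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
            x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
            sub = labels[y0:y1, x0:x1]
            own = sub == c.cid + 1
            if not own.any():
                continue
            dist = ndimage.distance_transform_edt(~own)
            ring = (dist > 0) & (dist <= cyto_w_px) & (sub == 0)
            val = act * config.sensor_nuclear_intensity
            region = sensor[y0:y1, x0:x1]
            region[ring] = np.maximum(region[ring], val)
        marker = ndimage.gaussian_filter(marker, 1.0)
        sensor = ndimage.gaussian_filter(sensor, 1.0)
        for ch, scene in enumerate((marker, sensor)):
            raw = bias * (scene + config.background)
            if config.noise_sd > 0:
                raw = raw + noise_rng.normal(0.0, config.noise_sd, size=raw.shape)
            data[f, ch] = raw

    stack = MovieStack(data, px, config.frame_interval_min)
    truth = GroundTruth(
        label_masks=label_masks,
        trajectories=trajectories,
        divisions=divisions,
        deaths=deaths,
        fates=fates,
        bias_field=bias,
        background=config.background,
    )
    return stack, truth


# --- persistence -----------------------------------------------------------

def save_movie(path: str | Path, stack: MovieStack, truth: GroundTruth | None = None) -> None:
    """Write a frame-major, channel-interleaved multi-page TIFF + JSON sidecar."""
    import tifffile

    path = Path(path)
    n, c, h, w = stack.data.shape
    pages = stack.data.reshape(n * c, h, w)
    tifffile.imwrite(path, pages)
    sidecar = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_min": stack.frame_interval_min,
        "n_frames": n,
        "n_channels": c,
        "channel_names": list(stack.channel_names),
    }
    if truth is not None:
        sidecar["ground_truth"] = {
            "divisions": [
                {**d, "daughters": list(d["daughters"]), "fractions": list(d["fractions"])}
                for d in truth.divisions
            ],
            "deaths": truth.deaths,
            "fates": {str(k): v for k, v in truth.fates.items()},
            "background": truth.background,
        }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_movie(path: str | Path) -> tuple[MovieStack, dict]:
    """Read a TIFF written by :func:`save_movie`; returns (stack, sidecar)."""
    import tifffile

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    pages = tifffile.imread(path)
    n, c = sidecar["n_frames"], sidecar["n_channels"]
    data = pages.reshape(n, c, pages.shape[-2], pages.shape[-1])
    stack = MovieStack(
        data,
        sidecar["pixel_size_um"],
        sidecar["frame_interval_min"],
        tuple(sidecar["channel_names"]),
    )
    return stack, sidecar
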