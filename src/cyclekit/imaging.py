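"""Illumination correction, nuclear segmentation and cytoplasmic-ring sensor
measurement.

The measurement chain per frame is: flatten with an empirically derived
multiplicative bias surface and subtract a global background; segment nuclei
on the marker channel (threshold + marker-controlled watershed on the
distance transform); build, per nucleus, a cytoplasmic ring of pixels whose
distance to the nuclear boundary lies in (2 um, 10 um], excluding pixels
within 10 um of any other nucleus; read the sensor channel as median
intensities over nucleus and ring (ring pixels indistinguishable from
background are dropped); CDK2 activity = cytoplasmic median / nuclear median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_isodata
from skimage.measure import regionprops
from skimage.segmentation import watershed

RING_INNER_UM = 2.0
RING_OUTER_UM = 10.0
NEIGHBOR_EXCLUSION_UM = 10.0


@dataclass
class BiasField:
    """Multiplicative illumination surface (mean 1) plus a global background."""

    surface: np.ndarray
    background: float

    def __post_init__(self) -> None:
        if np.any(self.surface <= 0):
            raise ValueError("bias surface must be strictly positive")

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "BiasField":
        return cls(np.ones(shape, dtype=float), 0.0)


@dataclass
class NucleusDetection:
    frame: int
    label: int
    centroid: tuple[float, float]  # (y, x) px
    area_px: float
    area_um2: float
    mask_slice: tuple[slice, slice]
    mask: np.ndarray  # boolean, within mask_slice
    nuc_median_sensor: float = np.nan
    nuc_median_marker: float = np.nan


@dataclass
class RingMeasurement:
    frame: int
    label: int
    mask_slice: tuple[slice, slice] | None
    mask: np.ndarray | None
    cyto_median: float = np.nan
    n_pixels_used: int = 0
    n_pixels_excluded: int = 0
    missing: bool = False
    reason: str = ""


def _sigma_clipped_background(img: np.ndarray, n_iter: int = 5, k: float = 3.0) -> np.ndarray:
    """Boolean mask of background pixels by iterative upper sigma clipping."""
    mask = np.ones(img.shape, dtype=bool)
    for _ in range(n_iter):
        vals = img[mask]
        mu, sd = float(vals.mean()), float(vals.std())
        new = img <= mu + k * sd
        if new.sum() == mask.sum():
            break
        mask = new
    return mask


def estimate_illumination_bias(
    frames: list[np.ndarray] | np.ndarray,
    block_size: int = 32,
    poly_order: int = 2,
    min_background_fraction: float = 0.02,
    foreground_masks: list[np.ndarray] | None = None,
) -> BiasField:
    """Fit a smooth multiplicative surface from cell-free pixels.

    Background pixels (auto-detected by sigma clipping, or the complement of
    ``foreground_masks``) are summarized per block by their median across all
    sampled frames; a 2-D polynomial of order ``poly_order`` is fitted to the
    block medians, normalized to mean 1.  The global background is the mean of
    the flattened background samples.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) == 0:
        raise ValueError("at least one frame required")
    shape = frames[0].shape
    bg_masks = []
    for i, f in enumerate(frames):
        if foreground_masks is not None:
            bg_masks.append(~foreground_masks[i].astype(bool))
        else:
            bg_masks.append(_sigma_clipped_background(f))
    frac = sum(m.sum() for m in bg_masks) / (len(frames) * np.prod(shape))
    if frac < min_background_fraction:
        raise ValueError(
            f"background fraction {frac:.3f} below {min_background_fraction}; "
            "frames appear fully covered by cells - surface fit refused"
        )

    h, w = shape
    ys, xs, vals = [], [], []
    for by in range(0, h, block_size):
        for bx in range(0, w, block_size):
            block_vals = []
            for f, m in zip(frames, bg_masks):
                sub = f[by : by + block_size, bx : bx + block_size]
                subm = m[by : by + block_size, bx : bx + block_size]
                if subm.any():
                    block_vals.append(sub[subm])
            if block_vals:
                ys.append(min(by + block_size / 2, h - 1))
                xs.append(min(bx + block_size / 2, w - 1))
                vals.append(float(np.median(np.concatenate(block_vals))))
    if len(vals) < (poly_order + 1) ** 2:
        raise ValueError("too few background blocks for the polynomial fit")

    ys, xs, vals = np.asarray(ys), np.asarray(xs), np.asarray(vals)
    yn, xn = ys / h - 0.5, xs / w - 0.5

    def design(yn: np.ndarray, xn: np.ndarray) -> np.ndarray:
        cols = []
        for i in range(poly_order + 1):
            for j in range(poly_order + 1 - i):
                cols.append((yn**i) * (xn**j))
        return np.stack(cols, axis=-1)

    coef, *_ = np.linalg.lstsq(design(yn, xn), vals, rcond=None)
    yy, xx = np.mgrid[0:h, 0:w]
    surf = design(yy.ravel() / h - 0.5, xx.ravel() / w - 0.5) @ coef
    surf = surf.reshape(h, w)
    if np.any(surf <= 0):
        raise ValueError("fitted surface not strictly positive; fit refused")
    scale = surf.mean()
    surface = surf / scale
    # Background level on the flattened scale.
    bg_samples = np.concatenate(
        [(f / surface)[m] for f, m in zip(frames, bg_masks)]
    )
    return BiasField(surface=surface, background=float(np.mean(bg_samples)))


def flatten_and_subtract(image: np.ndarray, bias: BiasField) -> np.ndarray:
    """``image / surface - background``, clipped at 0."""
    image = np.asarray(image, dtype=float)
    if image.shape != bias.surface.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs surface {bias.surface.shape}")
    return np.clip(image / bias.surface - bias.background, 0.0, None)


@dataclass
class SegmentationParams:
    pixel_size_um: float = 0.65
    min_area_um2: float = 30.0
    max_area_um2: float = 500.0
    smooth_sigma: float = 1.0
    threshold: float | None = None  # absolute; None -> Otsu
    split_min_distance_px: int = 5


def segment_nuclei(
    marker: np.ndarray, params: SegmentationParams, frame: int = 0
) -> list[NucleusDetection]:
    """Threshold + watershed-split nuclear segmentation on a corrected frame."""
    img = ndimage.gaussian_filter(np.asarray(marker, dtype=float), params.smooth_sigma)
    if params.threshold is not None:
        thr = params.threshold
    else:
        finite = img[np.isfinite(img)]
        if finite.size == 0 or finite.max() <= finite.min():
            return []
        # Isodata converges to the midpoint of the class means, which for a
        # smoothed binary nucleus sits at the half-height contour and so
        # keeps measured areas unbiased.
        thr = threshold_isodata(finite)
        # Thresholding a frame without foreground splits the noise; require
        # real contrast before accepting any object.
        fg, bg = img > thr, img <= thr
        if fg.any() and bg.any():
            if img[fg].mean() - img[bg].mean() < 4 * max(img[bg].std(), 1e-12):
                return []
    binary = img > thr
    if not binary.any():
        return []
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(
        dist,
        min_distance=params.split_min_distance_px,
        labels=binary,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        labeled, _ = ndimage.label(binary)
    else:
        labeled = watershed(-dist, markers, mask=binary)

    detections: list[NucleusDetection] = []
    px2 = params.pixel_size_um**2
    for rp in regionprops(labeled, intensity_image=np.asarray(marker, dtype=float)):
        area_um2 = rp.area * px2
        if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
            continue
        sl = rp.slice
        detections.append(
            NucleusDetection(
                frame=frame,
                label=rp.label,
                centroid=tuple(rp.centroid),
                area_px=float(rp.area),
                area_um2=float(area_um2),
                mask_slice=(sl[0], sl[1]),
                mask=rp.image.copy(),
                nuc_median_marker=float(np.median(rp.image_intensity[rp.image])),
            )
        )
    return detections


def _paint_labels(shape: tuple[int, int], detections: list[NucleusDetection]) -> np.ndarray:
    lab = np.zeros(shape, dtype=np.int32)
    for d in detections:
        lab[d.mask_slice][d.mask] = d.label
    return lab


def make_cytoplasmic_ring(
    detection: NucleusDetection,
    all_detections: list[NucleusDetection],
    pixel_size_um: float,
    image_shape: tuple[int, int],
) -> RingMeasurement:
    """Ring = pixels with distance to the parent nucleus in (2, 10] um, minus
    pixels within 10 um of any other nucleus.  Empty rings are flagged
    missing, never zero."""
    # Ring pixels reach 10 um from the parent; neighbours up to another 10 um
    # beyond a ring pixel can still veto it, so the window pads by the sum.
    pad = int(np.ceil((RING_OUTER_UM + NEIGHBOR_EXCLUSION_UM) / pixel_size_um)) + 2
    sy, sx = detection.mask_slice
    y0, y1 = max(sy.start - pad, 0), min(sy.stop + pad, image_shape[0])
    x0, x1 = max(sx.start - pad, 0), min(sx.stop + pad, image_shape[1])
    win = (slice(y0, y1), slice(x0, x1))

    own = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    own[sy.start - y0 : sy.stop - y0, sx.start - x0 : sx.stop - x0] = detection.mask
    others = np.zeros_like(own)
    any_nuc = own.copy()
    for d in all_detections:
        if d is detection or d.label == detection.label and d.frame == detection.frame:
            continue
        oy, ox = d.mask_slice
        iy0, iy1 = max(oy.start, y0), min(oy.stop, y1)
        ix0, ix1 = max(ox.start, x0), min(ox.stop, x1)
        if iy0 >= iy1 or ix0 >= ix1:
            continue
        sub = d.mask[iy0 - oy.start : iy1 - oy.start, ix0 - ox.start : ix1 - ox.start]
        others[iy0 - y0 : iy1 - y0, ix0 - x0 : ix1 - x0] |= sub
    any_nuc |= others

    dist_parent = ndimage.distance_transform_edt(~own) * pixel_size_um
    ring = (dist_parent > RING_INNER_UM) & (dist_parent <= RING_OUTER_UM) & ~any_nuc
    if others.any():
        dist_other = ndimage.distance_transform_edt(~others) * pixel_size_um
        ring &= dist_other > NEIGHBOR_EXCLUSION_UM
    if not ring.any():
        return RingMeasurement(
            frame=detection.frame, label=detection.label, mask_slice=None, mask=None,
            missing=True, reason="ring empty (crowding)",
        )
    return RingMeasurement(
        frame=detection.frame, label=detection.label, mask_slice=win, mask=ring
    )


def measure_sensor(
    sensor: np.ndarray,
    detection: NucleusDetection,
    ring: RingMeasurement,
    background_sd: float,
    k_background: float = 2.0,
    min_ring_pixels: int = 10,
) -> tuple[float, float]:
    """(nuclear median, cytoplasmic median) on the bias-corrected sensor image.

    Ring pixels with intensity <= k * background_sd are excluded as
    background-indistinguishable; if fewer than ``min_ring_pixels`` survive the
    cytoplasmic value is missing (NaN).
    """
    sensor = np.asarray(sensor, dtype=float)
    nuc_vals = sensor[detection.mask_slice][detection.mask]
    nuc_median = float(np.median(nuc_vals))
    detection.nuc_median_sensor = nuc_median
    if ring.missing or ring.mask is None:
        return nuc_median, np.nan
    vals = sensor[ring.mask_slice][ring.mask]
    keep = vals > k_background * background_sd
    ring.n_pixels_excluded = int((~keep).sum())
    vals = vals[keep]
    ring.n_pixels_used = int(vals.size)
    if vals.size < min_ring_pixels:
        ring.missing = True
        ring.reason = "too few ring pixels above background"
        return nuc_median, np.nan
    ring.cyto_median = float(np.median(vals))
    return nuc_median, ring.cyto_median


def compute_cdk2_activity(cyto_median: float, nuc_median: float) -> float:
    """Cytoplasmic/nuclear sensor ratio; missing or non-positive nuclear
    signal propagates to NaN."""
    if not np.isfinite(cyto_median) or not np.isfinite(nuc_median):
        return np.nan
    if nuc_median <= 0:
        return np.nan
    return float(cyto_median) / float(nuc_median)


@dataclass
class MeasureConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    k_background: float = 2.0
    min_ring_pixels: int = 10
    # Radius around a nucleus treated as potentially cell-covered when
    # estimating the sensor-channel background (cytoplasm reach + margin).
    cell_exclusion_um: float = 12.0


def _cell_vicinity_mask(corrected_marker: np.ndarray, radius_px: float) -> np.ndarray:
    """Pixels within ``radius_px`` of any marker-bright nucleus."""
    img = ndimage.gaussian_filter(np.asarray(corrected_marker, dtype=float), 1.0)
    finite = img[np.isfinite(img)]
    if finite.size == 0 or finite.max() <= finite.min():
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_isodata(finite)
    fg, bg = img > thr, img <= thr
    if not fg.any() or not bg.any():
        return np.zeros(img.shape, dtype=bool)
    if img[fg].mean() - img[bg].mean() < 4 * max(img[bg].std(), 1e-12):
        return np.zeros(img.shape, dtype=bool)  # no real nuclei in frame
    dist = ndimage.distance_transform_edt(~fg)
    return dist <= radius_px


def measure_movie(
    data: np.ndarray,
    pixel_size_um: float,
    config: MeasureConfig | None = None,
    bias: tuple[BiasField, BiasField] | None = None,
) -> pd.DataFrame:
    """Run the full per-frame measurement chain on an (n, 2, H, W) stack.

    Returns the detection table (frame, label, x, y, areas, medians,
    activity, flags).  ``bias`` holds (marker, sensor) bias fields; if None
    they are estimated from up to 8 frames sampled across the movie.
    """
    config = config or MeasureConfig()
    config.segmentation.pixel_size_um = pixel_size_um
    n_frames = data.shape[0]
    if bias is None:
        idx = np.unique(np.linspace(0, n_frames - 1, min(8, n_frames)).astype(int))
        marker_bias = estimate_illumination_bias([data[i, 0] for i in idx])
        # The sensor channel has dim, extended cytoplasm that auto-detection
        # mistakes for background; exclude everything near a marker-bright
        # nucleus instead.
        fg = [
            _cell_vicinity_mask(
                flatten_and_subtract(data[i, 0], marker_bias),
                config.cell_exclusion_um / pixel_size_um,
            )
            for i in idx
        ]
        sensor_bias = estimate_illumination_bias([data[i, 1] for i in idx], foreground_masks=fg)
        bias = (marker_bias, sensor_bias)
    rows = []
    for f in range(n_frames):
        marker = flatten_and_subtract(data[f, 0], bias[0])
        sensor = flatten_and_subtract(data[f, 1], bias[1])
        # Background sd from unclipped residuals in cell-free territory.
        far = ~_cell_vicinity_mask(marker, config.cell_exclusion_um / pixel_size_um)
        resid = (np.asarray(data[f, 1], dtype=float) / bias[1].surface - bias[1].background)[far]
        if resid.size:
            mad = np.median(np.abs(resid - np.median(resid)))
            bg_sd = float(1.4826 * mad)
        else:
            bg_sd = _robust_background_sd(sensor)
        dets = segment_nuclei(marker, config.segmentation, frame=f)
        for d in dets:
            ring = make_cytoplasmic_ring(d, dets, pixel_size_um, marker.shape)
            nuc_med, cyto_med = measure_sensor(
                sensor, d, ring, bg_sd, config.k_background, config.min_ring_pixels
            )
            act = compute_cdk2_activity(cyto_med, nuc_med)
            rows.append(
                {
                    "frame": f,
                    "label": d.label,
                    "x": d.centroid[1],
                    "y": d.centroid[0],
                    "area_px": d.area_px,
                    "area_um2": d.area_um2,
                    "nuc_median": nuc_med,
                    "cyto_median": cyto_med,
                    "activity": act,
                    "flag": ring.reason if ring.missing else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "label", "x", "y", "area_px", "area_um2",
            "nuc_median", "cyto_median", "activity", "flag",
        ],
    )


def _robust_background_sd(corrected: np.ndarray) -> float:
    """Robust sd of the (zero-clipped) background after correction."""
    bg = corrected[_sigma_clipped_background(corrected)]
    mad = np.median(np.abs(bg - np.median(bg)))
    return float(1.4826 * mad)
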