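"""Single-session plaque measurement.

The measurement scheme, applied independently to every plaque in every
session:

1. *Center frame* — the z-slice whose mean intensity over a region of
   interest around the plaque is highest.
2. *Background* — per frame, the mean of the lowest-decile pixel
   intensities of the entire frame; the dispersion of that same pixel set
   gives the background standard deviation.
3. *Border* — pixels strictly brighter than ``mu_bg + 3 * sigma_bg``
   connected (8-connectivity) to the plaque seed, interior holes filled.
4. *Size* — the plaque border mask is computed on the center frame and the
   two frames above and below it (five frames combined); the size is the
   mean of the per-frame areas in um^2.

A plaque whose five-frame window is truncated by the stack ends, or whose
mask touches a lateral frame edge, is flagged ``clipped`` and excluded from
group size statistics downstream.

Automated seeding (:func:`detect_plaques`) is provided so full stacks can
be processed without manual clicking: candidate plaques are local maxima of
a smoothed maximum-intensity projection, refined to the brightest voxel of
a smoothed local 3D window.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import feature, measure

from .stack_io import ImageStack

__all__ = [
    "BackgroundStats",
    "PlaqueObservation",
    "EmptyMaskError",
    "estimate_background",
    "border_threshold",
    "segment_plaque",
    "select_center_frame",
    "measure_plaque",
    "detect_plaques",
]


class EmptyMaskError(ValueError):
    """No above-threshold component reachable from the seed in the center frame."""


@dataclasses.dataclass(frozen=True)
class BackgroundStats:
    """Background fluorescence of one frame.

    ``mu_bg`` is the mean of the lowest 10% of pixel intensities of the
    frame; ``sigma_bg`` is the standard deviation (population form) of that
    same pixel set unless the whole-frame alternative was requested.
    """

    mu_bg: float
    sigma_bg: float
    frame_index: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_bg < 0:
            raise ValueError("sigma_bg must be non-negative")


def estimate_background(
    frame: np.ndarray,
    frame_index: int | None = None,
    *,
    sd_population: str = "decile",
) -> BackgroundStats:
    """Estimate background fluorescence from the darkest decile of a frame.

    Parameters
    ----------
    frame
        2D intensity array with at least 10 pixels.
    sd_population
        ``"decile"`` (default) computes ``sigma_bg`` over the same
        lowest-decile pixel set as ``mu_bg``; ``"frame"`` computes it over
        the whole frame.  Only the decile population is unambiguously the
        background, hence the default; the whole-frame variant is useful on
        projections where bright structure should widen the threshold.
    """
    flat = np.asarray(frame, dtype=np.float64).ravel()
    if flat.size < 10:
        raise ValueError("background estimation needs at least 10 pixels")
    k = flat.size // 10
    lowest = np.partition(flat, k - 1)[:k]
    mu = float(lowest.mean())
    if sd_population == "decile":
        sigma = float(lowest.std())
    elif sd_population == "frame":
        sigma = float(flat.std())
    else:
        raise ValueError(f"unknown sd_population {sd_population!r}")
    return BackgroundStats(mu_bg=mu, sigma_bg=sigma, frame_index=frame_index)


def border_threshold(bg: BackgroundStats) -> float:
    """Plaque-border intensity threshold: background mean plus 3 SD."""
    return bg.mu_bg + 3.0 * bg.sigma_bg


def segment_plaque(
    frame: np.ndarray,
    threshold: float,
    seed_point: tuple[float, float],
    *,
    seed_reach_px: float = 3.0,
) -> np.ndarray:
    """Segment the plaque containing (or nearest to) a seed pixel.

    The mask is the 8-connected component of pixels with intensity
    *strictly* above ``threshold`` that contains the seed — or, if the seed
    pixel itself is below threshold, the component nearest to it within
    ``seed_reach_px`` pixels — with interior holes filled.  An empty mask is
    a valid outcome (no component within reach).
    """
    frame = np.asarray(frame)
    binary = frame > threshold
    sy = int(np.clip(round(seed_point[0]), 0, frame.shape[0] - 1))
    sx = int(np.clip(round(seed_point[1]), 0, frame.shape[1] - 1))
    labels = measure.label(binary, connectivity=2)
    lab = labels[sy, sx]
    if lab == 0:
        r = int(math.ceil(seed_reach_px))
        y0, y1 = max(0, sy - r), min(frame.shape[0], sy + r + 1)
        x0, x1 = max(0, sx - r), min(frame.shape[1], sx + r + 1)
        window = labels[y0:y1, x0:x1]
        ys, xs = np.nonzero(window)
        if ys.size:
            d2 = (ys + y0 - sy) ** 2 + (xs + x0 - sx) ** 2
            best = int(np.argmin(d2))
            if d2[best] <= seed_reach_px**2:
                lab = window[ys[best], xs[best]]
    if lab == 0:
        return np.zeros(frame.shape, dtype=bool)
    mask = labels == lab
    return ndimage.binary_fill_holes(mask)


def select_center_frame(
    voxels: np.ndarray, roi_box: tuple[int, int, int, int]
) -> int:
    """Index of the frame with highest mean intensity over an ROI crop.

    ``roi_box`` is ``(y0, y1, x0, x1)`` in pixels.  Ties go to the lowest z.
    """
    y0, y1, x0, x1 = roi_box
    if not (0 <= y0 < y1 <= voxels.shape[1] and 0 <= x0 < x1 <= voxels.shape[2]):
        raise ValueError(f"roi_box {roi_box} outside stack bounds")
    means = voxels[:, y0:y1, x0:x1].mean(axis=(1, 2))
    return int(np.argmax(means))


@dataclasses.dataclass
class PlaqueObservation:
    """One plaque measured in one imaging session.

    ``size_um2`` is the arithmetic mean of the per-frame border areas over
    the (up to five) analyzed frames.  ``centroid_um`` is the center-frame
    mask centroid in um, used for between-session matching.
    """

    plaque_seed_um: tuple[float, float, float]  # (y, x, z)
    session_day: int
    region_id: str
    center_frame: int
    frame_indices: list[int]
    frame_masks: list[np.ndarray]
    frame_areas_um2: list[float]
    size_um2: float
    clipped: bool
    centroid_um: tuple[float, float]  # (y, x)
    #: border mask swallowed a second detected plaque (fused component);
    #: such observations are excluded from size statistics like clipped ones
    merged: bool = False
    #: frame areas are mutually inconsistent for a compact plaque (the
    #: center frame does not carry the maximal area, or one frame's area
    #: jumps far above the rest — transient fusion with a neighbor);
    #: excluded from size statistics like clipped observations
    irregular: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.frame_masks) <= 5:
            raise ValueError("an observation covers between 1 and 5 frames")
        if len(self.frame_masks) != len(self.frame_areas_um2):
            raise ValueError("one area per analyzed frame is required")
        if not math.isclose(
            self.size_um2, float(np.mean(self.frame_areas_um2)), rel_tol=1e-9
        ):
            raise ValueError("size_um2 must equal the mean of frame areas")

    @property
    def z_um(self) -> float:
        return self.plaque_seed_um[2]

    @property
    def centroid3_um(self) -> tuple[float, float, float]:
        return (self.centroid_um[0], self.centroid_um[1], self.plaque_seed_um[2])

    @property
    def center_mask(self) -> np.ndarray:
        return self.frame_masks[self.frame_indices.index(self.center_frame)]

    @property
    def equivalent_radius_um(self) -> float:
        """Radius of the circle with the observation's mean area."""
        return math.sqrt(max(self.size_um2, 0.0) / math.pi)


def measure_plaque(
    stack: ImageStack,
    seed_um: tuple[float, float, float],
    *,
    expected_diameter_um: float = 20.0,
    n_extra_frames: int = 2,
    sd_population: str = "decile",
    z_search_halfwidth_um: float | None = None,
) -> PlaqueObservation:
    """Measure one plaque: center frame, per-frame border masks, mean area.

    ``seed_um`` is ``(y, x, z)`` in um from the stack origin.  The ROI used
    for center-frame selection is a square of side four expected diameters
    around the seed, searched over the entire stack by default; pass
    ``z_search_halfwidth_um`` to restrict the search to frames near the
    seed's depth, which keeps a brighter plaque overlapping the same ROI at
    a different depth from hijacking the center frame in crowded fields.
    Raises :class:`EmptyMaskError` when the center frame holds no
    above-threshold component near the seed.
    """
    ps, zs = stack.pixel_size_um, stack.z_step_um
    vox = stack.voxels
    sy = int(np.clip(round(seed_um[0] / ps), 0, vox.shape[1] - 1))
    sx = int(np.clip(round(seed_um[1] / ps), 0, vox.shape[2] - 1))
    sz = int(np.clip(round(seed_um[2] / zs), 0, vox.shape[0] - 1))
    if not (0 <= seed_um[0] and 0 <= seed_um[1] and 0 <= seed_um[2]):
        raise ValueError(f"seed {seed_um} outside the stack")

    half_px = max(1, int(round(2.0 * expected_diameter_um / ps)))
    roi = (
        max(0, sy - half_px),
        min(vox.shape[1], sy + half_px + 1),
        max(0, sx - half_px),
        min(vox.shape[2], sx + half_px + 1),
    )
    if z_search_halfwidth_um is None:
        center = select_center_frame(vox, roi)
    else:
        hw = max(1, int(round(z_search_halfwidth_um / zs)))
        z0 = max(0, sz - hw)
        z1 = min(vox.shape[0], sz + hw + 1)
        center = z0 + select_center_frame(vox[z0:z1], roi)
    frames = [
        f
        for f in range(center - n_extra_frames, center + n_extra_frames + 1)
        if 0 <= f < vox.shape[0]
    ]

    masks: list[np.ndarray] = []
    areas: list[float] = []
    touches_edge = False
    for f in frames:
        bg = estimate_background(vox[f], f, sd_population=sd_population)
        mask = segment_plaque(vox[f], border_threshold(bg), (sy, sx))
        if f == center and not mask.any():
            raise EmptyMaskError(
                f"no plaque found at seed {seed_um} um in center frame {center} "
                f"of day-{stack.session_day} stack"
            )
        if mask.any() and (
            mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
        ):
            touches_edge = True
        masks.append(mask)
        areas.append(float(mask.sum()) * ps * ps)

    center_mask = masks[frames.index(center)]
    cy, cx = ndimage.center_of_mass(center_mask)
    clipped = touches_edge or len(frames) < 2 * n_extra_frames + 1

    # quality control on the five areas: a compact plaque has its maximal
    # border area in the center frame, and no single frame far above the
    # rest; violations indicate a mis-centred window or a transient fusion
    # with a neighbouring plaque, measurements a human analyst would reject
    areas_arr = np.asarray(areas)
    median_area = float(np.median(areas_arr))
    irregular = bool(
        areas_arr[frames.index(center)] < 0.9 * areas_arr.max()
        or (median_area > 0 and areas_arr.max() > 1.4 * median_area)
    )
    return PlaqueObservation(
        plaque_seed_um=(float(seed_um[0]), float(seed_um[1]), float(seed_um[2])),
        session_day=stack.session_day,
        region_id=stack.region_id,
        center_frame=center,
        frame_indices=frames,
        frame_masks=masks,
        frame_areas_um2=areas,
        size_um2=float(np.mean(areas)),
        clipped=clipped,
        centroid_um=(float(cy) * ps, float(cx) * ps),
        irregular=irregular,
    )


def detect_plaques(
    stack: ImageStack,
    *,
    min_distance_um: float = 10.0,
    smooth_sigma_um: float = 2.0,
    refine_sigma_um: float = 5.0,
    refine_halfwidth_um: float = 25.0,
) -> list[tuple[float, float, float]]:
    """Automatically seed plaques in a stack.

    Seeds are local maxima of a Gaussian-smoothed maximum-intensity
    projection that exceed the projection-level border threshold (lowest
    decile mean + 3 whole-projection SD — the bright structure itself widens
    the threshold, making it self-calibrating across plaque loads),
    separated by at least ``min_distance_um``.  Each 2D peak is refined to
    the brightest voxel of a heavily smoothed local 3D window, which sits at
    the plaque center rather than on a noise spike of the bright plateau.

    Returns seed points as ``(y, x, z)`` in um; an empty list is valid.
    """
    ps, zstep = stack.pixel_size_um, stack.z_step_um
    mip = stack.max_projection().astype(np.float64)
    thr = border_threshold(estimate_background(mip, sd_population="frame"))
    smoothed = ndimage.gaussian_filter(mip, smooth_sigma_um / ps)
    peaks = feature.peak_local_max(
        smoothed,
        min_distance=max(1, int(round(min_distance_um / ps))),
        threshold_abs=thr,
        exclude_border=False,
    )

    seeds: list[tuple[float, float, float]] = []
    vox = stack.voxels
    rp = max(1, int(round(refine_halfwidth_um / ps)))
    rz = max(1, int(round(refine_halfwidth_um / zstep)))
    for py, px in peaks:
        y0, y1 = max(0, py - rp), min(vox.shape[1], py + rp + 1)
        x0, x1 = max(0, px - rp), min(vox.shape[2], px + rp + 1)
        column = vox[:, y0:y1, x0:x1].mean(axis=(1, 2))
        z_peak = int(np.argmax(ndimage.gaussian_filter1d(column, 2.0 / zstep)))
        z0, z1 = max(0, z_peak - rz), min(vox.shape[0], z_peak + rz + 1)
        sub = ndimage.gaussian_filter(
            vox[z0:z1, y0:y1, x0:x1].astype(np.float64),
            (refine_sigma_um / zstep, refine_sigma_um / ps, refine_sigma_um / ps),
        )
        dz, dy, dx = np.unravel_index(int(np.argmax(sub)), sub.shape)
        seeds.append(
            (float((y0 + dy) * ps), float((x0 + dx) * ps), float((z0 + dz) * zstep))
        )

    return _suppress_duplicates(seeds, min_separation_um=2.0)


def _suppress_duplicates(
    seeds: Sequence[tuple[float, float, float]], *, min_separation_um: float
) -> list[tuple[float, float, float]]:
    """Drop seeds that refined into (nearly) the same voxel, keeping the first."""
    kept: list[tuple[float, float, float]] = []
    for s in seeds:
        if all(
            math.dist(s, k) >= min_separation_um for k in kept
        ):
            kept.append(s)
    return kept
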