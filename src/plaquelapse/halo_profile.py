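"""Radial fluorescence profiles and the 5 um peri-plaque band statistic.

Fluorescence just outside a plaque border reports diffuse amyloid
accumulating around the dense core.  For each plaque a single radial line
is cast from the plaque centroid outward in a *randomized but persisted*
direction: the angle is a pure function of the plaque identifier and a
master seed, so all sessions — and all reruns — of the same plaque use the
same line.  Intensities are sampled along the line by bilinear
interpolation, split at the plaque border (the last sample inside the
border mask), and normalized to a 0-100% scale with the highest value
across the whole line as 100%.  The peri-plaque statistic is the mean
normalized intensity over the half-open band ``(border, border + 5 um]``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math

import numpy as np
from scipy import ndimage

from .plaque_quant import PlaqueObservation
from .stack_io import ImageStack

__all__ = [
    "RadialProfile",
    "pick_direction",
    "sample_profile",
    "split_and_normalize",
    "halo_change",
    "profile_observation",
]

DEFAULT_STEP_UM = 0.25
BAND_WIDTH_UM = 5.0
OUTSIDE_LENGTH_UM = 15.0


@dataclasses.dataclass
class RadialProfile:
    """Intensity along one plaque's radial line.

    ``positions_um`` are distances from the plaque centroid (step 0.25 um
    by default); ``normalized`` is ``100 * raw / max(raw)`` so its maximum
    is exactly 100.  ``band_mean_pct`` is the mean normalized intensity
    over ``(border_radius_um, border_radius_um + 5]``.
    """

    plaque_id: str
    session_day: int
    direction_angle: float
    centroid_um: tuple[float, float]
    positions_um: np.ndarray
    raw: np.ndarray
    truncated: bool = False
    normalized: np.ndarray | None = None
    border_radius_um: float | None = None
    band_mean_pct: float | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.positions_um.shape != self.raw.shape:
            raise ValueError("one intensity per sample position is required")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("sample positions must strictly increase")


def pick_direction(plaque_id: str | int, master_seed: int) -> float:
    """Persisted random direction for a plaque's radial line.

    Uniform on [0, 2*pi) and a pure function of ``(plaque_id,
    master_seed)``: the same pair always yields the same angle, so the line
    direction survives across sessions and reruns without any stored state.
    """
    digest = hashlib.sha256(str(plaque_id).encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
    return float(np.random.default_rng(ss).uniform(0.0, 2.0 * math.pi))


def sample_profile(
    frame: np.ndarray,
    centroid_um: tuple[float, float],
    angle: float,
    length_um: float,
    *,
    step_um: float = DEFAULT_STEP_UM,
    pixel_size_um: float = 1.0,
    plaque_id: str = "",
    session_day: int = 0,
) -> RadialProfile:
    """Sample raw intensities along a radial line by bilinear interpolation.

    The line starts at the centroid and runs outward at ``angle`` (radians,
    measured from the +x axis toward +y).  If it exits the frame the
    profile is truncated at the last in-frame sample and flagged.
    """
    frame = np.asarray(frame, dtype=np.float64)
    positions = np.arange(0, int(math.floor(length_um / step_um)) + 1) * step_um
    dy, dx = math.sin(angle), math.cos(angle)
    ys = (centroid_um[0] + positions * dy) / pixel_size_um
    xs = (centroid_um[1] + positions * dx) / pixel_size_um
    inside = (
        (ys >= 0) & (ys <= frame.shape[0] - 1) & (xs >= 0) & (xs <= frame.shape[1] - 1)
    )
    truncated = not bool(inside.all())
    if truncated:
        first_out = int(np.argmin(inside))
        positions, ys, xs = positions[:first_out], ys[:first_out], xs[:first_out]
        if positions.size == 0:
            raise ValueError("radial line starts outside the frame")
    raw = ndimage.map_coordinates(frame, [ys, xs], order=1)
    return RadialProfile(
        plaque_id=str(plaque_id),
        session_day=session_day,
        direction_angle=float(angle),
        centroid_um=(float(centroid_um[0]), float(centroid_um[1])),
        positions_um=positions,
        raw=raw,
        truncated=truncated,
    )


def split_and_normalize(
    profile: RadialProfile,
    mask: np.ndarray,
    *,
    pixel_size_um: float = 1.0,
    band_width_um: float = BAND_WIDTH_UM,
) -> RadialProfile:
    """Split a raw profile at the plaque border and normalize to 0-100%.

    The border radius is the distance from the centroid to the last sample
    whose nearest pixel lies inside the plaque mask.  Normalization uses
    the highest raw value across the whole line (inside + outside) as
    100%.  The band statistic averages normalized samples over the
    half-open interval ``(border, border + band_width_um]``.
    """
    mask = np.asarray(mask, dtype=bool)
    dy, dx = math.sin(profile.direction_angle), math.cos(profile.direction_angle)
    ys = np.rint((profile.centroid_um[0] + profile.positions_um * dy) / pixel_size_um)
    xs = np.rint((profile.centroid_um[1] + profile.positions_um * dx) / pixel_size_um)
    in_frame = (
        (ys >= 0) & (ys < mask.shape[0]) & (xs >= 0) & (xs < mask.shape[1])
    )
    in_mask = np.zeros_like(in_frame)
    in_mask[in_frame] = mask[ys[in_frame].astype(int), xs[in_frame].astype(int)]
    if not in_mask.any():
        raise ValueError("plaque border not found along the radial line (empty mask)")
    border = float(profile.positions_um[np.nonzero(in_mask)[0][-1]])

    peak = float(profile.raw.max())
    if peak <= 0:
        raise ValueError("cannot normalize an all-non-positive profile")
    normalized = 100.0 * profile.raw / peak

    band_sel = (profile.positions_um > border) & (
        profile.positions_um <= border + band_width_um
    )
    if not band_sel.any():
        raise ValueError(
            "no samples in the peri-plaque band; the line is too short or truncated"
        )
    return dataclasses.replace(
        profile,
        normalized=normalized,
        border_radius_um=border,
        band_mean_pct=float(normalized[band_sel].mean()),
    )


def halo_change(profile_a: RadialProfile, profile_b: RadialProfile) -> float:
    """Percent change of the peri-plaque band mean between two sessions."""
    if profile_a.plaque_id != profile_b.plaque_id:
        raise ValueError("profiles belong to different plaques")
    if not math.isclose(profile_a.direction_angle, profile_b.direction_angle):
        raise ValueError("profiles were sampled along different directions")
    a, b = profile_a.band_mean_pct, profile_b.band_mean_pct
    if a is None or b is None:
        raise ValueError("profiles must be split and normalized first")
    if a == 0:
        raise ValueError("band change undefined for a zero baseline band")
    return 100.0 * (b - a) / a


def profile_observation(
    stack: ImageStack,
    observation: PlaqueObservation,
    master_seed: int,
    *,
    plaque_id: str | None = None,
    outside_length_um: float = OUTSIDE_LENGTH_UM,
    step_um: float = DEFAULT_STEP_UM,
) -> RadialProfile:
    """Full radial profile of a measured plaque on its center frame.

    Casts the persisted-direction line, finds the border from the
    observation's center-frame mask, then resamples out to ``border +
    outside_length_um`` and normalizes over that whole line.
    """
    pid = plaque_id if plaque_id is not None else f"{observation.region_id}"
    angle = pick_direction(pid, master_seed)
    frame = stack.voxels[observation.center_frame]
    probe_len = 2.0 * observation.equivalent_radius_um + 4.0 * outside_length_um
    probe = sample_profile(
        frame,
        observation.centroid_um,
        angle,
        probe_len,
        step_um=step_um,
        pixel_size_um=stack.pixel_size_um,
        plaque_id=pid,
        session_day=stack.session_day,
    )
    probe = split_and_normalize(probe, observation.center_mask,
                                pixel_size_um=stack.pixel_size_um)
    line = sample_profile(
        frame,
        observation.centroid_um,
        angle,
        probe.border_radius_um + outside_length_um,
        step_um=step_um,
        pixel_size_um=stack.pixel_size_um,
        plaque_id=pid,
        session_day=stack.session_day,
    )
    return split_and_normalize(line, observation.center_mask,
                               pixel_size_um=stack.pixel_size_um)
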