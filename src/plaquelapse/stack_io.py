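"""Image-stack containers, TIFF I/O and between-session registration.

An in vivo imaging session yields one 3D fluorescence stack per cortical
region: a ``z x y x x`` voxel grid of Congo Red intensity with a physical
calibration (lateral pixel size and axial step, both in micrometres).  The
default calibration matches a 508 x 508 um field imaged at 512 x 512 px with
1 um axial steps.

Sessions of the same region taken days apart are brought into a common
lateral coordinate frame by translation-only registration of their
maximum-intensity projections.  Rotation and scale changes over one to two
weeks of chronic-window imaging are negligible, so a 2D translation is all
that is estimated; voxels are never resampled — offsets are applied at the
coordinate level when plaques are matched.

Coordinate conventions used throughout the package:

* axis order ``(z, y, x)``, 0-based indices;
* physical positions in um measured from the stack origin (the corner of
  the first frame), so pixel ``j`` along an axis sits at ``j * pixel_size``;
* areas are reported in um^2 using ``pixel_size_um ** 2``.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Sequence

import numpy as np
import tifffile
from skimage.registration import phase_cross_correlation

#: Lateral calibration of a 508 um field sampled at 512 px.
DEFAULT_PIXEL_SIZE_UM = 508.0 / 512.0
DEFAULT_Z_STEP_UM = 1.0

_ACCEPTED_DTYPES = ("uint8", "uint16", "float32", "float64")


@dataclasses.dataclass
class ImageStack:
    """One session's 3D voxel grid with physical calibration.

    Parameters
    ----------
    voxels
        Intensity grid of shape ``(z, y, x)``; converted to ``float32``.
        Intensities must be finite and non-negative (fluorescence counts).
    pixel_size_um
        Lateral sampling, um per pixel.
    z_step_um
        Axial sampling, um per frame.
    session_day
        Integer day label of the imaging session (e.g. 13, 20, 27).
    region_id
        Free-text identifier of the imaged cortical region.
    """

    voxels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM
    session_day: int = 0
    region_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(
                f"voxels must be a (z, y, x) grid, got shape {self.voxels.shape}"
            )
        if self.voxels.dtype != np.float32:
            self.voxels = self.voxels.astype(np.float32)
        if not np.isfinite(self.voxels).all():
            raise ValueError("voxel intensities must be finite")
        if float(self.voxels.min()) < 0:
            raise ValueError("voxel intensities must be non-negative")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("calibration values must be strictly positive")

    # -- geometry ---------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]

    @property
    def field_size_um(self) -> tuple[float, float]:
        """Lateral extent ``(y, x)`` of the imaged field, um."""
        return (
            self.voxels.shape[1] * self.pixel_size_um,
            self.voxels.shape[2] * self.pixel_size_um,
        )

    @property
    def depth_um(self) -> float:
        return self.n_frames * self.z_step_um

    @property
    def volume_mm3(self) -> float:
        """Imaged volume in mm^3 (lateral area x depth)."""
        fy, fx = self.field_size_um
        return fy * fx * self.depth_um * 1e-9

    def max_projection(self) -> np.ndarray:
        return self.voxels.max(axis=0)


def read_stack(
    path: str | pathlib.Path,
    *,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    z_step_um: float = DEFAULT_Z_STEP_UM,
    session_day: int = 0,
    region_id: str = "",
) -> ImageStack:
    """Load a single-channel multi-page TIFF as an :class:`ImageStack`.

    Unsigned 8/16-bit (and float) pages are converted to floating point.
    Multi-channel/RGB files and files with non-uniform page sizes are
    rejected explicitly; the loader is otherwise agnostic to bit depth.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    with tifffile.TiffFile(path) as tif:
        first = tif.pages[0]
        if first.samplesperpixel != 1:
            raise ValueError(
                f"{path}: multi-channel/RGB TIFF ({first.samplesperpixel} "
                "samples per pixel); a single fluorescence channel is required"
            )
        shapes = {page.shape for page in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"{path}: non-uniform page sizes {sorted(shapes)}")
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {arr.shape}")
    if arr.dtype.name not in _ACCEPTED_DTYPES:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    return ImageStack(
        arr,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        session_day=session_day,
        region_id=region_id,
    )


def write_stack(stack: ImageStack, path: str | pathlib.Path, dtype=None) -> None:
    """Write a stack as a multi-page TIFF.

    By default voxels are written as ``float32`` so that
    ``read_stack(write_stack(s))`` round-trips exactly; pass ``dtype`` (e.g.
    ``np.uint16``) to emit detector-like integer data.
    """
    data = stack.voxels
    if dtype is not None:
        info = np.iinfo(dtype) if np.issubdtype(dtype, np.integer) else None
        if info is not None:
            data = np.clip(np.rint(data), info.min, info.max)
        data = data.astype(dtype)
    tifffile.imwrite(pathlib.Path(path), data, photometric="minisblack")


@dataclasses.dataclass
class SessionSet:
    """Ordered stacks of one region across imaging days, registered.

    ``offsets_um[k]`` is the lateral translation ``(dy, dx)`` to *add* to a
    coordinate in session ``k`` to express it in the session-1 frame.  The
    first entry is always ``(0, 0)``.
    """

    stacks: list[ImageStack]
    offsets_um: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.stacks) != len(self.offsets_um):
            raise ValueError("one offset per session is required")
        days = [s.session_day for s in self.stacks]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"session days must strictly increase, got {days}")

    @property
    def days(self) -> list[int]:
        return [s.session_day for s in self.stacks]

    def offset_for_day(self, day: int) -> tuple[float, float]:
        for stack, off in zip(self.stacks, self.offsets_um):
            if stack.session_day == day:
                return off
        raise KeyError(f"no session on day {day}")


def register_sessions(
    stacks: Sequence[ImageStack],
    *,
    upsample_factor: int = 10,
    max_shift_fraction: float = 0.25,
) -> SessionSet:
    """Estimate per-session lateral offsets against the first session.

    The translation maximizing the cross-correlation of maximum-intensity
    projections is found by phase correlation (sub-pixel via Fourier
    upsampling).  An estimated offset exceeding ``max_shift_fraction`` of
    the field is treated as non-overlapping fields and raised as an error.
    Voxels are left untouched.
    """
    stacks = list(stacks)
    if len(stacks) < 2:
        raise ValueError("registration needs at least two sessions")
    ref = stacks[0]
    for s in stacks[1:]:
        if (
            s.pixel_size_um != ref.pixel_size_um
            or s.z_step_um != ref.z_step_um
            or s.frame_shape != ref.frame_shape
        ):
            raise ValueError("all sessions must share calibration and frame size")

    ref_mip = ref.max_projection()
    offsets: list[tuple[float, float]] = [(0.0, 0.0)]
    for s in stacks[1:]:
        shift, _, _ = phase_cross_correlation(
            ref_mip,
            s.max_projection(),
            upsample_factor=upsample_factor,
            normalization=None,
        )
        limits = np.array(ref.frame_shape) * max_shift_fraction
        if np.any(np.abs(shift) > limits):
            raise ValueError(
                f"estimated offset {tuple(shift)} px exceeds "
                f"{max_shift_fraction:.0%} of the field; sessions do not overlap"
            )
        offsets.append(
            (float(shift[0]) * ref.pixel_size_um, float(shift[1]) * ref.pixel_size_um)
        )
    return SessionSet(stacks=stacks, offsets_um=offsets)
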