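"""Synthetic longitudinal plaque scenes and dendrite images with ground truth.

No raw microscopy data accompany the study design this package implements,
so every downstream stage is validated against simulated scenes whose true
plaque positions, sizes and dendrite geometry are known exactly.

Plaque model
------------
A plaque is a solid sphere of uniform core intensity surrounded by an
isotropic halo decaying exponentially with distance from the sphere
surface.  Between sessions a plaque grows *self-similarly*: a growth factor
``g`` scales both the core radius and the halo length scale, so the whole
radial intensity profile dilates by ``g`` and the above-threshold
cross-section area scales by ``g**2`` for any fixed threshold.

Sensor model
------------
Rendered intensities sit on a constant detector background.  Noise is
additive Gaussian with a signal-proportional variance term (a proxy for
two-photon shot plus detector noise), after which intensities are rounded
to integer counts and clipped at zero, as a photon-counting detector would
report them.  The sub-count read noise combined with quantization gives the
darkest-decile background statistic a well-behaved, narrow distribution, as
in real detector data; purely continuous Gaussian backgrounds do not have
this property.

All randomness flows from a single seed through named substreams
(placement, radii, noise, jitter) so each stage is independently
reproducible: a fixed seed yields byte-identical scenes.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dendrite_morph import DendriteTrace
from .stack_io import ImageStack, write_stack

__all__ = [
    "SceneConfig",
    "SceneGroundTruth",
    "DendriteSceneConfig",
    "expected_plaque_count",
    "make_scene",
    "render_noise_free",
    "make_dendrite_scene",
    "write_scene",
    "write_dendrite_annotations",
]

#: Names and order of the per-scene random substreams spawned from the seed.
_SUBSTREAMS = ("placement", "radii", "noise", "jitter")


@dataclasses.dataclass
class SceneConfig:
    """Acquisition geometry and plaque/noise parameters of a synthetic scene.

    Defaults emulate the study conditions: a 508 x 508 um field at
    512 x 512 px, 1 um axial steps to 300 um depth, a plaque density of
    515 per mm^3 and log-normal plaque radii with a 10 um median
    (a 10 um radius gives a ~314 um^2 cross-section, matching the
    published 309-343 um^2 mean plaque sizes).  Core and halo intensities
    are free parameters — no plaque intensity statistics are published —
    chosen so that plaques are far brighter than background while halo
    tails fade into it.
    """

    field_size_um: tuple[float, float] = (508.0, 508.0)
    pixels_per_axis: int = 512
    z_depth_um: float = 300.0
    z_step_um: float = 1.0
    plaque_density_per_mm3: float = 515.0
    plaque_radius_median_um: float = 10.0
    plaque_radius_sigma: float = 0.25
    min_plaque_radius_um: float = 2.0
    core_intensity: float = 200.0
    halo_amplitude: float = 30.0
    halo_decay_um: float = 2.0
    background_level: float = 3.0
    noise_gaussian_sd: float = 0.2
    noise_signal_scale: float = 0.01
    quantize: bool = True
    lateral_margin_diameters: float = 1.0
    overlap_tolerance_um: float = 2.0
    jitter_px: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fy, fx = self.field_size_um
        if fy <= 0 or fx <= 0 or self.z_depth_um <= 0 or self.z_step_um <= 0:
            raise ValueError("all extents must be strictly positive")
        if not math.isclose(fy, fx):
            raise ValueError("only square fields (isotropic pixels) are supported")
        if self.pixels_per_axis < 64:
            raise ValueError("pixels_per_axis must be at least 64")
        if min(self.core_intensity, self.background_level) <= 0:
            raise ValueError("intensities must be strictly positive")
        if self.min_plaque_radius_um < 2.0:
            raise ValueError("plaque radii below 2 um are not simulated")

    @property
    def pixel_size_um(self) -> float:
        return self.field_size_um[0] / self.pixels_per_axis

    @property
    def n_frames(self) -> int:
        return int(round(self.z_depth_um / self.z_step_um))

    @property
    def volume_mm3(self) -> float:
        return self.field_size_um[0] * self.field_size_um[1] * self.z_depth_um * 1e-9


@dataclasses.dataclass
class SceneGroundTruth:
    """True plaque geometry of a simulated longitudinal scene.

    ``centers_um`` has one ``(y, x, z)`` row per plaque (fixed across
    sessions); ``radii_by_session_um`` and ``halo_decay_by_session_um`` have
    shape ``(n_sessions, n_plaques)``.  ``jitter_px`` holds the integer
    lateral translation applied to each session's rendering.
    """

    centers_um: np.ndarray
    radii_by_session_um: np.ndarray
    halo_amplitude: float
    halo_decay_by_session_um: np.ndarray
    session_days: list[int]
    jitter_px: np.ndarray
    rng_seed: int

    def __post_init__(self) -> None:
        self.centers_um = np.asarray(self.centers_um, dtype=float).reshape(-1, 3)
        self.radii_by_session_um = np.atleast_2d(
            np.asarray(self.radii_by_session_um, dtype=float)
        )
        self.halo_decay_by_session_um = np.atleast_2d(
            np.asarray(self.halo_decay_by_session_um, dtype=float)
        )
        self.jitter_px = np.atleast_2d(np.asarray(self.jitter_px, dtype=int))
        if self.radii_by_session_um.shape[1] != self.n_plaques and self.n_plaques:
            raise ValueError("one radius per plaque per session is required")
        if self.n_plaques and (self.radii_by_session_um <= 0).any():
            raise ValueError("radii must be positive")

    @property
    def n_plaques(self) -> int:
        return self.centers_um.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.radii_by_session_um.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "rng_seed": self.rng_seed,
                "session_days": list(self.session_days),
                "halo_amplitude": self.halo_amplitude,
                "centers_um": self.centers_um.tolist(),
                "radii_by_session_um": self.radii_by_session_um.tolist(),
                "halo_decay_by_session_um": self.halo_decay_by_session_um.tolist(),
                "jitter_px": self.jitter_px.tolist(),
            },
            indent=2,
        )


def expected_plaque_count(config: SceneConfig) -> int:
    """Number of plaques placed: density times field volume, rounded."""
    return int(round(config.plaque_density_per_mm3 * config.volume_mm3))


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _sample_radii(rng: np.random.Generator, n: int, config: SceneConfig) -> np.ndarray:
    radii = np.empty(n)
    mu = math.log(config.plaque_radius_median_um)
    for i in range(n):
        r = rng.lognormal(mu, config.plaque_radius_sigma)
        while r <= config.min_plaque_radius_um:
            r = rng.lognormal(mu, config.plaque_radius_sigma)
        radii[i] = r
    return radii


def _place_plaques(
    rng: np.random.Generator,
    radii_max_um: np.ndarray,
    config: SceneConfig,
    *,
    max_attempts: int = 2000,
) -> np.ndarray:
    """Uniform placement with lateral/axial margins and overlap rejection.

    Each plaque keeps one diameter (of its largest session radius) clear of
    the lateral field edges and enough axial clearance for its five-frame
    measurement window.  Sphere overlaps deeper than
    ``overlap_tolerance_um`` are rejected and resampled.
    """
    fy, fx = config.field_size_um
    depth = config.z_depth_um
    centers = np.empty((len(radii_max_um), 3))
    for i, r in enumerate(radii_max_um):
        margin_lat = config.lateral_margin_diameters * 2.0 * r
        margin_z = r + 2.0 * config.z_step_um
        if fy - 2 * margin_lat <= 0 or fx - 2 * margin_lat <= 0 or depth - 2 * margin_z <= 0:
            raise ValueError(
                f"field too small to place a plaque of radius {r:.1f} um "
                "clear of the boundary margin"
            )
        for _ in range(max_attempts):
            y = rng.uniform(margin_lat, fy - margin_lat)
            x = rng.uniform(margin_lat, fx - margin_lat)
            z = rng.uniform(margin_z, depth - margin_z)
            cand = np.array([y, x, z])
            if i == 0:
                centers[i] = cand
                break
            d = np.linalg.norm(centers[:i] - cand, axis=1)
            if np.all(d >= radii_max_um[:i] + r - config.overlap_tolerance_um):
                centers[i] = cand
                break
        else:
            raise RuntimeError(
                f"could not place plaque {i} without excess overlap after "
                f"{max_attempts} attempts; lower the density or enlarge the field"
            )
    return centers


def render_noise_free(
    gt: SceneGroundTruth, session: int, config: SceneConfig
) -> ImageStack:
    """Deterministically render one session's stack without noise.

    Each plaque contributes a solid sphere of ``core_intensity`` plus an
    exponential halo of amplitude ``halo_amplitude`` and per-session length
    scale, added onto the constant detector background.  Halos are truncated
    where their contribution falls below 1% of a count.
    """
    if not 0 <= session < gt.n_sessions:
        raise IndexError(f"session {session} out of range")
    ps, zstep = config.pixel_size_um, config.z_step_um
    nz, nxy = config.n_frames, config.pixels_per_axis
    canvas = np.full((nz, nxy, nxy), config.background_level, dtype=np.float64)

    jy, jx = gt.jitter_px[session] if gt.n_plaques else (0, 0)
    amp = gt.halo_amplitude
    cutoff = 0.01
    for p in range(gt.n_plaques):
        cy, cx, cz = gt.centers_um[p]
        cy, cx = cy + jy * ps, cx + jx * ps
        r = gt.radii_by_session_um[session, p]
        lam = gt.halo_decay_by_session_um[session, p]
        ext = r + (lam * math.log(amp / cutoff) if amp > cutoff else 0.0)
        z0 = max(0, int(math.floor((cz - ext) / zstep)))
        z1 = min(nz, int(math.ceil((cz + ext) / zstep)) + 1)
        y0 = max(0, int(math.floor((cy - ext) / ps)))
        y1 = min(nxy, int(math.ceil((cy + ext) / ps)) + 1)
        x0 = max(0, int(math.floor((cx - ext) / ps)))
        x1 = min(nxy, int(math.ceil((cx + ext) / ps)) + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        dz = np.arange(z0, z1) * zstep - cz
        dy = np.arange(y0, y1) * ps - cy
        dx = np.arange(x0, x1) * ps - cx
        rho = np.sqrt(
            dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
        )
        contrib = np.where(
            rho <= r,
            config.core_intensity,
            amp * np.exp(-(np.maximum(rho - r, 0.0)) / lam) if amp > 0 else 0.0,
        )
        contrib[rho > ext] = 0.0
        canvas[z0:z1, y0:y1, x0:x1] += contrib

    return ImageStack(
        canvas.astype(np.float32),
        pixel_size_um=ps,
        z_step_um=zstep,
        session_day=gt.session_days[session],
        region_id=f"synthetic-seed{gt.rng_seed}",
    )


def _apply_noise(
    voxels: np.ndarray, rng: np.random.Generator, config: SceneConfig
) -> np.ndarray:
    sd = np.sqrt(
        config.noise_gaussian_sd**2 + config.noise_signal_scale * voxels
    )
    noisy = voxels + rng.standard_normal(voxels.shape) * sd
    if config.quantize:
        noisy = np.rint(noisy)
    return np.clip(noisy, 0.0, None).astype(np.float32)


def make_scene(
    config: SceneConfig,
    n_sessions: int = 2,
    growth_factors: Sequence[float] | None = None,
    session_days: Sequence[int] | None = None,
) -> tuple[list[ImageStack], SceneGroundTruth]:
    """Generate a longitudinal scene: one noisy stack per session plus truth.

    ``growth_factors`` holds ``n_sessions - 1`` per-interval radial scale
    factors (> 0); session ``k+1`` radii are session ``k`` radii times the
    factor, and the halo length scale dilates with them (self-similar
    growth).  Session days default to 13, 20, 27, ... (one-week spacing).
    """
    if n_sessions < 1:
        raise ValueError("at least one session is required")
    growth = tuple(growth_factors) if growth_factors is not None else (1.0,) * (
        n_sessions - 1
    )
    if len(growth) != n_sessions - 1:
        raise ValueError(
            f"expected {n_sessions - 1} growth factors, got {len(growth)}"
        )
    if any(g <= 0 for g in growth):
        raise ValueError("growth factors must be strictly positive")
    days = list(session_days) if session_days is not None else [
        13 + 7 * k for k in range(n_sessions)
    ]
    if len(days) != n_sessions:
        raise ValueError("one session day per session is required")

    rngs = _substreams(config.rng_seed)
    n = expected_plaque_count(config)
    radii0 = _sample_radii(rngs["radii"], n, config)
    cum = np.concatenate([[1.0], np.cumprod(growth)])
    radii_by_session = radii0[None, :] * cum[:, None] if n else np.empty((n_sessions, 0))
    halo_decay = config.halo_decay_um * cum
    halo_decay_by_session = (
        np.broadcast_to(halo_decay[:, None], (n_sessions, n)).copy()
        if n
        else np.empty((n_sessions, 0))
    )

    radii_max = radii_by_session.max(axis=0) if n else np.empty(0)
    centers = _place_plaques(rngs["placement"], radii_max, config) if n else np.empty((0, 3))

    jitter = np.zeros((n_sessions, 2), dtype=int)
    if config.jitter_px > 0:
        jitter[1:] = rngs["jitter"].integers(
            -config.jitter_px, config.jitter_px + 1, size=(n_sessions - 1, 2)
        )

    gt = SceneGroundTruth(
        centers_um=centers,
        radii_by_session_um=radii_by_session,
        halo_amplitude=config.halo_amplitude,
        halo_decay_by_session_um=halo_decay_by_session,
        session_days=days,
        jitter_px=jitter,
        rng_seed=config.rng_seed,
    )

    stacks = []
    for s in range(n_sessions):
        clean = render_noise_free(gt, s, config)
        stacks.append(
            ImageStack(
                _apply_noise(clean.voxels.astype(np.float64), rngs["noise"], config),
                pixel_size_um=clean.pixel_size_um,
                z_step_um=clean.z_step_um,
                session_day=clean.session_day,
                region_id=clean.region_id,
            )
        )
    return stacks, gt


# ---------------------------------------------------------------------------
# Dendrite scenes
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DendriteSceneConfig:
    """Geometry of a synthetic dendrite rendered into a 2D image.

    The shaft is rendered with a Gaussian cross-sectional profile whose
    full width at half maximum equals the configured diameter at each
    arclength (``diameter_breakpoints`` is a piecewise-constant profile:
    ``(arclength_um, diameter_um)`` pairs, each diameter applying from its
    arclength onward).  Spines are short perpendicular protrusions at the
    configured arclengths, alternating sides.
    """

    vertices_um: np.ndarray  # (N, 2) polyline, (y, x) um, ordered
    soma_end: str = "start"
    spine_arclengths_um: tuple[float, ...] = ()
    diameter_breakpoints: tuple[tuple[float, float], ...] = ((0.0, 0.9),)
    plaque_interval_um: tuple[float, float] | None = None
    min_distance_to_border_um: float | None = None
    shaft_intensity: float = 100.0
    spine_intensity: float = 60.0
    spine_length_um: float = 1.2
    spine_width_um: float = 0.4
    background_level: float = 0.0
    margin_um: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.vertices_um = np.asarray(self.vertices_um, dtype=float).reshape(-1, 2)
        if self.vertices_um.shape[0] < 2:
            raise ValueError("a trace needs at least two vertices")
        L = self.total_length_um
        if any(not 0 <= s <= L for s in self.spine_arclengths_um):
            raise ValueError("spine positions must lie within the trace")
        if any(d <= 0 for _, d in self.diameter_breakpoints):
            raise ValueError("shaft diameters must be positive")
        if self.plaque_interval_um is not None:
            a, b = self.plaque_interval_um
            if not a < b:
                raise ValueError("plaque entry must precede exit")

    @property
    def total_length_um(self) -> float:
        seg = np.diff(self.vertices_um, axis=0)
        return float(np.sqrt((seg**2).sum(axis=1)).sum())

    def diameter_at(self, s: float | np.ndarray) -> np.ndarray:
        """Piecewise-constant shaft diameter at arclength ``s``."""
        bps = sorted(self.diameter_breakpoints)
        starts = np.array([b[0] for b in bps])
        values = np.array([b[1] for b in bps])
        idx = np.clip(np.searchsorted(starts, np.asarray(s, float), side="right") - 1, 0, None)
        return values[idx]


def make_dendrite_scene(
    config: DendriteSceneConfig, pixel_size_um: float = 0.2
) -> tuple[DendriteTrace, np.ndarray]:
    """Render a dendrite scene and return the annotated trace plus image.

    The returned trace is expressed in image coordinates (um from the image
    origin).  Raises if any configured diameter spans fewer than two pixels
    at the given calibration — such a shaft is unmeasurable.
    """
    min_d = float(np.min([d for _, d in config.diameter_breakpoints]))
    if min_d < 2.0 * pixel_size_um:
        raise ValueError(
            f"shaft diameter {min_d} um is below two pixels at "
            f"{pixel_size_um} um/px and cannot be measured"
        )

    verts = config.vertices_um
    lo = verts.min(axis=0) - config.margin_um
    hi = verts.max(axis=0) + config.margin_um
    shape = tuple(int(math.ceil((hi[i] - lo[i]) / pixel_size_um)) + 1 for i in range(2))
    verts_img = verts - lo

    yy = np.arange(shape[0])[:, None] * pixel_size_um
    xx = np.arange(shape[1])[None, :] * pixel_size_um

    # nearest point on the polyline for every pixel: perpendicular distance
    # and the arclength of the foot of the perpendicular
    best_rho = np.full(shape, np.inf)
    best_s = np.zeros(shape)
    seg_start_s = 0.0
    for a, b in zip(verts_img[:-1], verts_img[1:]):
        ab = b - a
        seg_len = float(np.hypot(*ab))
        if seg_len == 0:
            continue
        t = ((yy - a[0]) * ab[0] + (xx - a[1]) * ab[1]) / (seg_len**2)
        t = np.clip(t, 0.0, 1.0)
        py = a[0] + t * ab[0]
        px = a[1] + t * ab[1]
        rho = np.hypot(yy - py, xx - px)
        closer = rho < best_rho
        best_rho = np.where(closer, rho, best_rho)
        best_s = np.where(closer, seg_start_s + t * seg_len, best_s)
        seg_start_s += seg_len

    d = config.diameter_at(best_s)
    ln2 = math.log(2.0)
    shaft = config.shaft_intensity * np.exp(-4.0 * ln2 * best_rho**2 / d**2)
    image = np.maximum(config.background_level, shaft)

    trace = DendriteTrace(
        vertices_um=verts_img,
        soma_end=config.soma_end,
        spine_arclengths_um=config.spine_arclengths_um,
        plaque_interval_um=config.plaque_interval_um,
        min_distance_to_border_um=config.min_distance_to_border_um,
    )

    for k, s in enumerate(sorted(config.spine_arclengths_um)):
        base = trace.point_at(s)
        tangent = trace.tangent_at(s)
        normal = np.array([-tangent[1], tangent[0]]) * (1 if k % 2 == 0 else -1)
        d_here = float(config.diameter_at(s))
        tip = base + normal * (d_here / 2.0 + config.spine_length_um)
        image = np.maximum(
            image,
            _render_segment_gaussian(
                shape, pixel_size_um, base, tip,
                config.spine_intensity, config.spine_width_um,
            ),
        )

    return trace, image.astype(np.float32)


def _render_segment_gaussian(
    shape: tuple[int, int],
    pixel_size_um: float,
    a: np.ndarray,
    b: np.ndarray,
    intensity: float,
    width_um: float,
) -> np.ndarray:
    """Gaussian-profile line segment (FWHM ``width_um``) on a zero canvas."""
    out = np.zeros(shape)
    pad = 3.0 * width_um
    lo = np.minimum(a, b) - pad
    hi = np.maximum(a, b) + pad
    y0 = max(0, int(lo[0] / pixel_size_um))
    y1 = min(shape[0], int(math.ceil(hi[0] / pixel_size_um)) + 1)
    x0 = max(0, int(lo[1] / pixel_size_um))
    x1 = min(shape[1], int(math.ceil(hi[1] / pixel_size_um)) + 1)
    if y0 >= y1 or x0 >= x1:
        return out
    yy = np.arange(y0, y1)[:, None] * pixel_size_um
    xx = np.arange(x0, x1)[None, :] * pixel_size_um
    ab = b - a
    seg_len2 = float(ab[0] ** 2 + ab[1] ** 2)
    t = np.clip(((yy - a[0]) * ab[0] + (xx - a[1]) * ab[1]) / seg_len2, 0.0, 1.0)
    rho = np.hypot(yy - (a[0] + t * ab[0]), xx - (a[1] + t * ab[1]))
    out[y0:y1, x0:x1] = intensity * np.exp(-4.0 * math.log(2.0) * rho**2 / width_um**2)
    return out


# ---------------------------------------------------------------------------
# On-disk artefacts
# ---------------------------------------------------------------------------


def write_scene(
    stacks: Sequence[ImageStack],
    gt: SceneGroundTruth,
    outdir: str | pathlib.Path,
) -> list[pathlib.Path]:
    """Write one uint16 multi-page TIFF per session plus a truth manifest."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for stack in stacks:
        p = outdir / f"day{stack.session_day:03d}.tif"
        write_stack(stack, p, dtype=np.uint16)
        paths.append(p)
    (outdir / "ground_truth.json").write_text(gt.to_json())
    return paths


def write_dendrite_annotations(
    config: DendriteSceneConfig, path: str | pathlib.Path
) -> None:
    """Annotation CSV: arclength_um, is_spine, diameter_um (1 um sampling)."""
    L = config.total_length_um
    grid = np.arange(0.0, L + 1e-9, 1.0)
    rows = [
        {"arclength_um": float(s), "is_spine": False,
         "diameter_um": float(config.diameter_at(s))}
        for s in grid
    ]
    rows += [
        {"arclength_um": float(s), "is_spine": True,
         "diameter_um": float(config.diameter_at(s))}
        for s in config.spine_arclengths_um
    ]
    pd.DataFrame(rows).sort_values("arclength_um").to_csv(path, index=False)
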