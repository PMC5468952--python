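"""End-to-end convenience drivers over the module-level operations.

These functions wire the stages together the way the command-line interface
and the validation experiments use them: automatic seeding, per-plaque
measurement, between-session registration and matching, and pooled size
statistics over one or many imaged regions.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import plaque_quant, plaque_track, stack_io, synthetic_scene

logger = logging.getLogger(__name__)

__all__ = [
    "quantify_session",
    "observations_frame",
    "ObservationRecord",
    "records_from_frame",
    "longitudinal_size_change",
]


def quantify_session(
    stack: stack_io.ImageStack,
    seeds_um: Sequence[tuple[float, float, float]] | None = None,
    **measure_kwargs,
) -> list[plaque_quant.PlaqueObservation]:
    """Detect (or accept) seeds and measure every plaque in one stack.

    Because automatically detected seeds carry their own depth estimate,
    the center-frame search is restricted to a window around the seed's z
    (default two expected diameters) so that an unrelated brighter plaque
    overlapping the same lateral ROI at a different depth cannot hijack the
    center frame.  Seeds whose center frame holds no plaque are logged and
    skipped, as are observations whose centroids collapse onto an
    already-measured plaque (two seeds landing in one merged
    above-threshold component).
    """
    if seeds_um is None:
        seeds_um = plaque_quant.detect_plaques(stack)
    measure_kwargs.setdefault("z_search_halfwidth_um", 40.0)
    observations: list[plaque_quant.PlaqueObservation] = []
    for seed in seeds_um:
        try:
            obs = plaque_quant.measure_plaque(stack, seed, **measure_kwargs)
        except plaque_quant.EmptyMaskError as exc:
            logger.info("seed rejected: %s", exc)
            continue
        if any(
            np.linalg.norm(
                np.subtract(obs.centroid3_um, prev.centroid3_um)
            ) < plaque_track.DUPLICATE_SEED_DISTANCE_UM
            for prev in observations
        ):
            logger.info(
                "seed %s measured an already-covered plaque; skipped", seed
            )
            continue
        observations.append(obs)
    _flag_merged(stack, observations, seeds_um)
    return observations


def _flag_merged(
    stack: stack_io.ImageStack,
    observations: Sequence[plaque_quant.PlaqueObservation],
    seeds_um: Sequence[tuple[float, float, float]],
    *,
    z_window_um: float = 20.0,
) -> None:
    """Mark observations whose border mask swallowed another detected plaque.

    When two plaques fuse into one above-threshold component, the mask (and
    so the area) covers both and its apparent size change is an artifact of
    the fusion, not growth; such observations keep their track (the plaque
    is real) but are excluded from size statistics.
    """
    ps, zs = stack.pixel_size_um, stack.z_step_um
    for obs in observations:
        mask = obs.center_mask
        inside = 0
        for seed in seeds_um:
            if abs(seed[2] - obs.center_frame * zs) > z_window_um:
                continue
            iy, ix = int(round(seed[0] / ps)), int(round(seed[1] / ps))
            if 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and mask[iy, ix]:
                inside += 1
        obs.merged = inside >= 2


def flag_cross_session_merges(
    stacks: Sequence[stack_io.ImageStack],
    observations_by_day: dict[int, Sequence[plaque_quant.PlaqueObservation]],
    session_set: stack_io.SessionSet | None = None,
    *,
    z_window_um: float = 20.0,
) -> None:
    """Mark observations whose mask covers several plaques of another session.

    Detection cannot see a fusion from inside one session (the fused pair
    yields a single peak), but the other session still resolves the two
    plaques: when two or more of its centroids fall inside one border mask,
    that mask measures a fused component and is flagged ``merged``.
    """
    days = sorted(observations_by_day)
    stacks_by_day = {s.session_day: s for s in stacks}

    def offset_for(day: int) -> tuple[float, float]:
        if session_set is None:
            return (0.0, 0.0)
        return session_set.offset_for_day(day)

    for day in days:
        stack = stacks_by_day[day]
        ps, zs = stack.pixel_size_um, stack.z_step_um
        oy, ox = offset_for(day)
        for obs in observations_by_day[day]:
            mask = obs.center_mask
            for other_day in days:
                if other_day == day:
                    continue
                ooy, oox = offset_for(other_day)
                inside = 0
                for other in observations_by_day[other_day]:
                    cy, cx, cz = other.centroid3_um
                    if abs(cz - obs.center_frame * zs) > z_window_um:
                        continue
                    # express the other session's centroid in this session's frame
                    iy = int(round((cy + ooy - oy) / ps))
                    ix = int(round((cx + oox - ox) / ps))
                    if (
                        0 <= iy < mask.shape[0]
                        and 0 <= ix < mask.shape[1]
                        and mask[iy, ix]
                    ):
                        inside += 1
                if inside >= 2:
                    obs.merged = True


def observations_frame(
    observations: Sequence[plaque_quant.PlaqueObservation],
) -> pd.DataFrame:
    """Tabulate observations, one row per plaque per session."""
    return pd.DataFrame(
        [
            {
                "plaque_id": i,
                "session_day": o.session_day,
                "region_id": o.region_id,
                "center_frame": o.center_frame,
                "centroid_y_um": o.centroid_um[0],
                "centroid_x_um": o.centroid_um[1],
                "z_um": o.z_um,
                "size_um2": o.size_um2,
                "clipped": o.clipped,
                "merged": o.merged,
                "irregular": o.irregular,
            }
            for i, o in enumerate(observations)
        ]
    )


@dataclasses.dataclass(frozen=True)
class ObservationRecord:
    """A plaque observation reconstructed from a results table.

    Carries exactly what matching and size statistics require, so tracking
    can run from CSV output without re-reading image stacks.
    """

    session_day: int
    size_um2: float
    clipped: bool
    merged: bool
    irregular: bool
    centroid_y_um: float
    centroid_x_um: float
    z_um: float

    @property
    def centroid3_um(self) -> tuple[float, float, float]:
        return (self.centroid_y_um, self.centroid_x_um, self.z_um)


def records_from_frame(frame: pd.DataFrame) -> list[ObservationRecord]:
    return [
        ObservationRecord(
            session_day=int(r.session_day),
            size_um2=float(r.size_um2),
            clipped=bool(r.clipped),
            merged=bool(getattr(r, "merged", False)),
            irregular=bool(getattr(r, "irregular", False)),
            centroid_y_um=float(r.centroid_y_um),
            centroid_x_um=float(r.centroid_x_um),
            z_um=float(r.z_um),
        )
        for r in frame.itertuples()
    ]


def longitudinal_size_change(
    field_configs: Sequence[synthetic_scene.SceneConfig],
    growth_factor: float,
    *,
    day_a: int = 13,
    day_b: int = 20,
) -> tuple[list[float], int]:
    """Simulate fields, run the full measurement pipeline, pool size changes.

    For each field configuration a two-session scene is generated with the
    given radial growth factor, both sessions are quantified independently
    (automatic seeding), sessions are registered and matched, and the
    percent size changes of all usable (complete, unclipped) tracks are
    pooled.  Returns the pooled changes and the total ground-truth plaque
    count.
    """
    changes: list[float] = []
    n_true = 0
    for config in field_configs:
        stacks, gt = synthetic_scene.make_scene(
            config, n_sessions=2, growth_factors=(growth_factor,),
            session_days=(day_a, day_b),
        )
        n_true += gt.n_plaques
        session_set = stack_io.register_sessions(stacks)
        obs_by_day = {
            stack.session_day: quantify_session(stack) for stack in stacks
        }
        flag_cross_session_merges(stacks, obs_by_day, session_set)
        result = plaque_track.match_plaques(obs_by_day, session_set)
        for track in result.tracks:
            try:
                changes.append(plaque_track.percent_size_change(track, day_a, day_b))
            except ValueError:
                continue
    return changes, n_true
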