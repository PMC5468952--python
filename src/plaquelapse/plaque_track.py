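"""Linking plaques across imaging sessions; density and size-change statistics.

Observations from consecutive sessions are matched greedily by
offset-corrected centroid distance, closest pairs first, one-to-one, with
pairs farther apart than 10 um (well below the nearest-neighbor spacing at
~500 plaques per mm^3) left unmatched.  Unmatched observations on a later
day open new tracks ("appeared"); tracks that fail to extend record a
disappearance.  Greedy matching rather than a global assignment is
deliberate: at these densities and displacements conflicts are negligible,
and the closest-first order is deterministic and auditable.

Size change between two days of a track is ``100 * (size_b - size_a) /
size_a``; clipped observations take part in matching (so the count
bookkeeping stays exact) but never in size statistics.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Protocol, Sequence

import numpy as np

from . import stats_report
from .stack_io import SessionSet

__all__ = [
    "PlaqueTrack",
    "MatchResult",
    "DensityReport",
    "GroupSizeChange",
    "match_plaques",
    "percent_size_change",
    "plaque_density",
    "group_size_change",
]

DEFAULT_MAX_MATCH_DISTANCE_UM = 10.0
DUPLICATE_SEED_DISTANCE_UM = 2.0


class Observation(Protocol):
    """What matching and size statistics need from a plaque observation."""

    session_day: int
    size_um2: float
    clipped: bool

    @property
    def centroid3_um(self) -> tuple[float, float, float]: ...


@dataclasses.dataclass
class PlaqueTrack:
    """One plaque followed across sessions (at most one observation per day)."""

    track_id: int
    observations: dict[int, Observation] = dataclasses.field(default_factory=dict)

    def add(self, obs: Observation) -> None:
        if obs.session_day in self.observations:
            raise ValueError(
                f"track {self.track_id} already has day {obs.session_day}"
            )
        self.observations[obs.session_day] = obs

    @property
    def days(self) -> list[int]:
        return sorted(self.observations)

    def has(self, day: int) -> bool:
        return day in self.observations


@dataclasses.dataclass
class MatchResult:
    """Tracks plus appearance/disappearance bookkeeping.

    Every observation belongs to exactly one track.  ``appeared`` lists
    track ids whose first observation is after the first session;
    ``disappeared`` lists ``(track_id, last_day)`` for tracks that end
    before the last session.
    """

    tracks: list[PlaqueTrack]
    appeared: list[int]
    disappeared: list[tuple[int, int]]
    session_days: list[int]

    @property
    def n_observations(self) -> int:
        return sum(len(t.observations) for t in self.tracks)


def _corrected(obs: Observation, offset: tuple[float, float]) -> np.ndarray:
    y, x, z = obs.centroid3_um
    return np.array([y + offset[0], x + offset[1], z])


def match_plaques(
    observations_by_day: Mapping[int, Sequence[Observation]],
    offsets_um: Mapping[int, tuple[float, float]] | SessionSet | None = None,
    *,
    max_distance_um: float = DEFAULT_MAX_MATCH_DISTANCE_UM,
) -> MatchResult:
    """Link per-session observations into tracks.

    ``offsets_um`` maps each session day to the lateral translation into
    the first session's frame (a registered :class:`SessionSet` works
    directly); omitted days default to zero offset.  Two observations of
    the same session closer than 2 um are rejected as duplicate seeds.
    """
    days = sorted(observations_by_day)
    if not days:
        raise ValueError("no sessions to match")

    def offset_for(day: int) -> tuple[float, float]:
        if offsets_um is None:
            return (0.0, 0.0)
        if isinstance(offsets_um, SessionSet):
            return offsets_um.offset_for_day(day)
        return offsets_um.get(day, (0.0, 0.0))

    for day in days:
        obs = list(observations_by_day[day])
        for i in range(len(obs)):
            for j in range(i + 1, len(obs)):
                d = math.dist(obs[i].centroid3_um, obs[j].centroid3_um)
                if d < DUPLICATE_SEED_DISTANCE_UM:
                    raise ValueError(
                        f"duplicate seeds on day {day}: observations at "
                        f"{obs[i].centroid3_um} and {obs[j].centroid3_um} are "
                        f"{d:.2f} um apart"
                    )

    next_id = 0
    tracks: list[PlaqueTrack] = []
    active: dict[int, Observation] = {}  # track_id -> latest observation

    def new_track(obs: Observation) -> int:
        nonlocal next_id
        t = PlaqueTrack(track_id=next_id)
        t.add(obs)
        tracks.append(t)
        active[t.track_id] = obs
        next_id += 1
        return t.track_id

    for obs in observations_by_day[days[0]]:
        new_track(obs)
    appeared: list[int] = []
    disappeared: list[tuple[int, int]] = []

    for prev_day, day in zip(days, days[1:]):
        prev_ids = list(active)
        prev_pos = {
            tid: _corrected(active[tid], offset_for(active[tid].session_day))
            for tid in prev_ids
        }
        new_obs = list(observations_by_day[day])
        new_pos = [_corrected(o, offset_for(day)) for o in new_obs]

        pairs = sorted(
            (float(np.linalg.norm(prev_pos[tid] - p)), tid, j)
            for tid in prev_ids
            for j, p in enumerate(new_pos)
        )
        used_tracks: set[int] = set()
        used_obs: set[int] = set()
        for d, tid, j in pairs:
            if d > max_distance_um:
                break
            if tid in used_tracks or j in used_obs:
                continue
            track = next(t for t in tracks if t.track_id == tid)
            track.add(new_obs[j])
            active[tid] = new_obs[j]
            used_tracks.add(tid)
            used_obs.add(j)

        for tid in prev_ids:
            if tid not in used_tracks:
                disappeared.append((tid, prev_day))
                del active[tid]
        for j, obs in enumerate(new_obs):
            if j not in used_obs:
                appeared.append(new_track(obs))

    return MatchResult(
        tracks=tracks, appeared=appeared, disappeared=disappeared, session_days=days
    )


def percent_size_change(track: PlaqueTrack, day_a: int, day_b: int) -> float:
    """Percent change in plaque size between two observed days of a track."""
    for day in (day_a, day_b):
        if not track.has(day):
            raise ValueError(f"track {track.track_id} has no observation on day {day}")
    a, b = track.observations[day_a], track.observations[day_b]
    if a.clipped or b.clipped:
        raise ValueError(
            f"track {track.track_id} is clipped on one of the endpoint days; "
            "size change is excluded"
        )
    if getattr(a, "merged", False) or getattr(b, "merged", False):
        raise ValueError(
            f"track {track.track_id} has a fused (merged-mask) measurement on "
            "one of the endpoint days; size change is excluded"
        )
    if getattr(a, "irregular", False) or getattr(b, "irregular", False):
        raise ValueError(
            f"track {track.track_id} failed measurement quality control on "
            "one of the endpoint days; size change is excluded"
        )
    if a.size_um2 <= 0:
        raise ValueError(
            f"track {track.track_id} has zero size on day {day_a}; "
            "percent change undefined"
        )
    return 100.0 * (b.size_um2 - a.size_um2) / a.size_um2


@dataclasses.dataclass(frozen=True)
class DensityReport:
    """Plaque count per imaged volume for one session."""

    session_day: int
    count: int
    volume_mm3: float
    density_per_mm3: float
    appeared: int = 0
    disappeared: int = 0

    def __post_init__(self) -> None:
        if self.count < 0 or self.appeared < 0 or self.disappeared < 0:
            raise ValueError("counts must be non-negative")
        if not math.isclose(
            self.density_per_mm3, self.count / self.volume_mm3, rel_tol=1e-9
        ):
            raise ValueError("density must equal count / volume")


def plaque_density(
    count: int, volume_mm3: float, *, session_day: int = 0,
    appeared: int = 0, disappeared: int = 0,
) -> DensityReport:
    """Density report for one session; volume is lateral area x depth."""
    if volume_mm3 <= 0:
        raise ValueError("imaged volume must be strictly positive")
    return DensityReport(
        session_day=session_day,
        count=count,
        volume_mm3=volume_mm3,
        density_per_mm3=count / volume_mm3,
        appeared=appeared,
        disappeared=disappeared,
    )


def density_reports(result: MatchResult, volume_mm3: float) -> list[DensityReport]:
    """Per-day density with appearance/disappearance counts from a match."""
    reports = []
    for i, day in enumerate(result.session_days):
        count = sum(1 for t in result.tracks if t.has(day))
        appeared = sum(
            1 for tid in result.appeared
            if min(t.days for t in result.tracks if t.track_id == tid)[0] == day
        )
        disappeared = sum(1 for _, d in result.disappeared if d == result.session_days[i - 1]) if i else 0
        reports.append(
            plaque_density(
                count, volume_mm3, session_day=day,
                appeared=appeared, disappeared=disappeared,
            )
        )
    return reports


@dataclasses.dataclass(frozen=True)
class GroupSizeChange:
    """Group summary of per-track percent size changes between two days."""

    day_a: int
    day_b: int
    n: int
    mean_pct: float
    sem_pct: float
    changes_pct: tuple[float, ...]
    comparison: stats_report.GroupComparison


def group_size_change(
    tracks: Sequence[PlaqueTrack], day_a: int, day_b: int, *, min_tracks: int = 3
) -> GroupSizeChange:
    """Mean +/- SEM percent size change with a paired significance test.

    Only tracks observed and unclipped on both days with a positive
    baseline size are usable; fewer than ``min_tracks`` of them is an
    error.  The paired comparison of the raw sizes is delegated to the
    gated test-selection procedure.
    """
    changes: list[float] = []
    sizes_a: list[float] = []
    sizes_b: list[float] = []
    for t in tracks:
        try:
            changes.append(percent_size_change(t, day_a, day_b))
        except ValueError:
            continue
        sizes_a.append(t.observations[day_a].size_um2)
        sizes_b.append(t.observations[day_b].size_um2)
    if len(changes) < min_tracks:
        raise ValueError(
            f"only {len(changes)} usable tracks between days {day_a} and {day_b}; "
            f"at least {min_tracks} are required"
        )
    summary = stats_report.summarize(changes)
    comparison = stats_report.compare(sizes_a, sizes_b, paired=True)
    return GroupSizeChange(
        day_a=day_a,
        day_b=day_b,
        n=len(changes),
        mean_pct=summary.mean,
        sem_pct=summary.sem if summary.sem is not None else 0.0,
        changes_pct=tuple(changes),
        comparison=comparison,
    )
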