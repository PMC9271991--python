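"""Trajectory cleaning, junction, interpolation, rediscretization and geometry.

A trajectory is the time series of locations of one individual, at integer
seconds, possibly with missing seconds (the tag was concealed or lost). The
operations here rebuild comparable movement variables from such fragments:

* conflict handling — simultaneous tracks in one recording are either noise
  or a second animal; small overlaps are resolved automatically, large ones
  are written to a review file for an explicit exclusion list;
* junction — fragments separated by at most a time gap ``t_g`` and a
  distance gap ``d_g`` are merged chronologically;
* near-edge removal — points within the edge buffer (default 35 px ~ 5.1 cm)
  of the arena border are dropped *after* junction, splitting trajectories;
* interpolation — missing seconds are filled linearly between observed
  neighbors, flagged, and never extrapolated;
* rediscretization — segments of one fixed duration tau are cut from the
  trajectory. Without interpolation a re-anchoring walk is used: from the
  current anchor, a segment is emitted only if a point exists exactly tau
  seconds later, otherwise the anchor advances to the next observed point.
  With interpolation the (now gap-free) trajectory is tiled at
  t0, t0+tau, t0+2*tau, ...

Distances are segment lengths in px; speeds divide by tau and the px/cm
calibration. Turning angles are signed heading changes between time-adjacent
segments, computed in a y-up frame so that positive angles are left turns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ArenaGeometry, ConfigurationError, DEFAULT_PX_PER_CM

__all__ = [
    "Trajectory",
    "ProcedureConfig",
    "Segment",
    "TurningAngle",
    "Conflict",
    "UnresolvedConflictError",
    "detect_conflicts",
    "auto_clean",
    "join_trajectories",
    "remove_edge_points",
    "interpolate",
    "rediscretize",
    "compute_distances",
    "compute_speeds",
    "compute_turning_angles",
    "pixel_to_cm",
]


@dataclass
class Trajectory:
    """Time-ordered points of one individual (strictly increasing seconds)."""

    trajectory_id: str
    individual_id: str
    ground_type: str
    t_s: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    interpolated: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=int)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if len(self.t_s) and np.any(np.diff(self.t_s) <= 0):
            raise ValueError(f"trajectory {self.trajectory_id}: times not strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    @classmethod
    def from_points(cls, trajectory_id, t, x, y, individual_id="", ground_type="", interpolated=None):
        t = np.asarray(t, dtype=int)
        if interpolated is None:
            interpolated = np.zeros(len(t), dtype=bool)
        return cls(str(trajectory_id), str(individual_id), str(ground_type), t,
                   np.asarray(x, float), np.asarray(y, float), np.asarray(interpolated, bool))

    @classmethod
    def from_raw_track(cls, track, individual_id="", ground_type=""):
        dets = track.detections
        return cls.from_points(
            trajectory_id=str(track.track_id),
            t=[d.t_s for d in dets],
            x=[d.x_px for d in dets],
            y=[d.y_px for d in dets],
            individual_id=individual_id,
            ground_type=ground_type,
        )

    def select(self, mask: np.ndarray, trajectory_id: str | None = None) -> "Trajectory":
        return Trajectory(
            trajectory_id if trajectory_id is not None else self.trajectory_id,
            self.individual_id,
            self.ground_type,
            self.t_s[mask],
            self.x_px[mask],
            self.y_px[mask],
            self.interpolated[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "ground_type": self.ground_type,
                "trajectory_id": self.trajectory_id,
                "t_s": self.t_s,
                "x_px": self.x_px,
                "y_px": self.y_px,
                "interpolated": self.interpolated,
            }
        )


@dataclass(frozen=True)
class ProcedureConfig:
    """One analysis procedure: junction time gap, rediscretization, interpolation."""

    t_g_s: int = 10
    d_g_px: float = 50.0
    redisc_s: int = 1
    interpolate: bool = False

    def __post_init__(self) -> None:
        if self.t_g_s < 1 or self.redisc_s < 1:
            raise ValueError("t_g_s and redisc_s must be >= 1")

    def label(self) -> str:
        return f"tg{self.t_g_s}_tau{self.redisc_s}_{'interp' if self.interpolate else 'obs'}"


@dataclass(frozen=True)
class Segment:
    """Displacement between two trajectory points exactly tau seconds apart."""

    t_start: int
    t_end: int
    x_start: float
    y_start: float
    x_end: float
    y_end: float
    contains_interpolated: bool = False

    @property
    def distance_px(self) -> float:
        return math.hypot(self.x_end - self.x_start, self.y_end - self.y_start)

    @property
    def duration_s(self) -> int:
        return self.t_end - self.t_start

    def heading_rad(self) -> float:
        """Heading in a y-up frame (image y axis points down)."""
        return math.atan2(-(self.y_end - self.y_start), self.x_end - self.x_start)


@dataclass(frozen=True)
class TurningAngle:
    """Signed heading change in (-pi, pi]; positive = left turn."""

    value_rad: float
    t_vertex: int


# ---------------------------------------------------------------------------
# conflict detection and semi-automated cleaning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Conflict:
    id_a: str
    id_b: str
    overlap_s: int
    min_separation_px: float


class UnresolvedConflictError(RuntimeError):
    """Conflicts too large for automatic rules; resolve via the exclusion list."""

    def __init__(self, conflicts, review_path=None):
        self.conflicts = conflicts
        self.review_path = review_path
        where = f"; review file: {review_path}" if review_path else ""
        super().__init__(
            f"{len(conflicts)} unresolved trajectory conflict(s) need manual review{where}"
        )


def _as_trajectory(obj, individual_id="", ground_type="") -> Trajectory:
    if isinstance(obj, Trajectory):
        return obj
    return Trajectory.from_raw_track(obj, individual_id, ground_type)


def detect_conflicts(tracks) -> list:
    """All pairs of tracks with overlapping time support.

    Reports the number of common seconds and the minimum simultaneous
    separation (px) for each pair.
    """
    trajs = [_as_trajectory(t) for t in tracks]
    out = []
    for i in range(len(trajs)):
        for j in range(i + 1, len(trajs)):
            a, b = trajs[i], trajs[j]
            common, ia, ib = np.intersect1d(a.t_s, b.t_s, return_indices=True)
            if len(common) == 0:
                continue
            sep = np.hypot(a.x_px[ia] - b.x_px[ib], a.y_px[ia] - b.y_px[ib])
            out.append(
                Conflict(a.trajectory_id, b.trajectory_id, len(common), float(sep.min()))
            )
    return out


def auto_clean(
    tracks,
    conflicts=None,
    max_auto_points: int = 10,
    exclusion_list=None,
    px_per_cm: float = DEFAULT_PX_PER_CM,
    review_path=None,
    mutual_delete_cm: float = 5.0,
) -> list:
    """Resolve conflicting tracks automatically where rules allow.

    Rules, per conflicting pair:

    * simultaneous tracks closer than ``mutual_delete_cm`` (converted via
      ``px_per_cm``) at some common second lose the overlapping portion on
      *both* sides (the individuals cannot be told apart);
    * overlaps of at most ``max_auto_points`` seconds: the track with fewer
      total points (presumed noise) loses its overlapping points;
    * anything larger is written to ``review_path`` and raises
      :class:`UnresolvedConflictError` unless covered by ``exclusion_list``
      (an iterable of trajectory ids to drop entirely).
    """
    excl = {str(e) for e in (exclusion_list or ())}
    trajs = [_as_trajectory(t) for t in tracks]
    trajs = [t for t in trajs if t.trajectory_id not in excl and len(t) > 0]

    if conflicts is None:
        conflicts = detect_conflicts(trajs)
    by_id = {t.trajectory_id: t for t in trajs}
    drop_times: dict[str, set] = {tid: set() for tid in by_id}
    unresolved = []
    threshold_px = mutual_delete_cm * px_per_cm

    for c in conflicts:
        if c.id_a not in by_id or c.id_b not in by_id:
            continue  # one side already excluded
        a, b = by_id[c.id_a], by_id[c.id_b]
        common = np.intersect1d(a.t_s, b.t_s)
        if len(common) == 0:
            continue
        if c.min_separation_px < threshold_px:
            drop_times[c.id_a].update(common.tolist())
            drop_times[c.id_b].update(common.tolist())
        elif len(common) <= max_auto_points:
            loser = c.id_a if len(a) <= len(b) else c.id_b
            drop_times[loser].update(common.tolist())
        else:
            unresolved.append(c)

    if unresolved:
        if review_path is not None:
            pd.DataFrame(
                [(c.id_a, c.id_b, c.overlap_s, c.min_separation_px) for c in unresolved],
                columns=["id_a", "id_b", "overlap_s", "min_separation_px"],
            ).to_csv(review_path, index=False)
        raise UnresolvedConflictError(unresolved, review_path)

    cleaned = []
    for t in trajs:
        if drop_times[t.trajectory_id]:
            mask = ~np.isin(t.t_s, sorted(drop_times[t.trajectory_id]))
            t = t.select(mask)
        if len(t) > 0:
            cleaned.append(t)
    return cleaned


# ---------------------------------------------------------------------------
# junction, edge removal, interpolation
# ---------------------------------------------------------------------------

def join_trajectories(trajs: list, t_g_s: int, d_g_px: float = 50.0) -> list:
    """Merge fragments chronologically under the junction criteria.

    A trajectory ending at (t1, p1) is merged with a later one starting at
    (t2, p2) when ``t2 - t1 <= t_g_s`` and ``|p2 - p1| <= d_g_px``. Competing
    candidates are resolved by smallest time gap, then smallest distance;
    merged trajectories keep the earlier id.
    """
    alive = [
        Trajectory(t.trajectory_id, t.individual_id, t.ground_type,
                   t.t_s.copy(), t.x_px.copy(), t.y_px.copy(), t.interpolated.copy())
        for t in sorted(trajs, key=lambda t: (t.t_s[0] if len(t) else 0))
        if len(t) > 0
    ]
    while True:
        best = None
        for i, a in enumerate(alive):
            for j, b in enumerate(alive):
                if i == j:
                    continue
                dt = int(b.t_s[0]) - int(a.t_s[-1])
                if dt < 1 or dt > t_g_s:
                    continue
                dist = math.hypot(b.x_px[0] - a.x_px[-1], b.y_px[0] - a.y_px[-1])
                if dist > d_g_px:
                    continue
                key = (int(a.t_s[-1]), dt, dist, i, j)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        _, _, _, i, j = best
        a, b = alive[i], alive[j]
        alive[i] = Trajectory(
            a.trajectory_id,
            a.individual_id or b.individual_id,
            a.ground_type or b.ground_type,
            np.concatenate([a.t_s, b.t_s]),
            np.concatenate([a.x_px, b.x_px]),
            np.concatenate([a.y_px, b.y_px]),
            np.concatenate([a.interpolated, b.interpolated]),
        )
        del alive[j]
    return alive


def remove_edge_points(trajs: list, geom: ArenaGeometry) -> list:
    """Drop points within the edge buffer of the border; split survivors.

    Performed after junction (the order matters and is asserted by the
    pipeline, not here). Each maximal run of consecutive surviving points
    becomes its own trajectory with a ``#k`` id suffix.
    """
    buf = geom.edge_buffer_px
    out = []
    for t in trajs:
        keep = (
            (t.x_px >= buf)
            & (t.x_px < geom.width_px - buf)
            & (t.y_px >= buf)
            & (t.y_px < geom.height_px - buf)
        )
        if keep.all():
            out.append(t)
            continue
        idx = np.nonzero(keep)[0]
        if len(idx) == 0:
            continue
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        runs = np.split(idx, breaks + 1)
        for k, run in enumerate(runs):
            mask = np.zeros(len(t), dtype=bool)
            mask[run] = True
            out.append(t.select(mask, trajectory_id=f"{t.trajectory_id}#{k}"))
    return out


def interpolate(traj: Trajectory) -> Trajectory:
    """Fill every missing second between the endpoints by linear interpolation.

    Filled points are flagged ``interpolated``; no extrapolation occurs.
    """
    if len(traj) < 2:
        return traj
    full_t = np.arange(traj.t_s[0], traj.t_s[-1] + 1)
    if len(full_t) == len(traj):
        return traj
    x = np.interp(full_t, traj.t_s, traj.x_px)
    y = np.interp(full_t, traj.t_s, traj.y_px)
    observed = np.isin(full_t, traj.t_s)
    flags = np.ones(len(full_t), dtype=bool)
    flags[observed] = traj.interpolated  # observed points keep their flag
    return Trajectory(
        traj.trajectory_id, traj.individual_id, traj.ground_type, full_t, x, y, flags
    )


# ---------------------------------------------------------------------------
# rediscretization
# ---------------------------------------------------------------------------

def _segment(traj: Trajectory, i: int, j: int) -> Segment:
    return Segment(
        t_start=int(traj.t_s[i]),
        t_end=int(traj.t_s[j]),
        x_start=float(traj.x_px[i]),
        y_start=float(traj.y_px[i]),
        x_end=float(traj.x_px[j]),
        y_end=float(traj.y_px[j]),
        contains_interpolated=bool(traj.interpolated[i : j + 1].any()),
    )


def rediscretize(
    traj: Trajectory,
    redisc_s: int,
    interpolate_flag: bool = False,
    grid_mode: str = "anchor",
) -> list:
    """Cut segments of exactly ``redisc_s`` seconds from one trajectory.

    Without interpolation, ``grid_mode="anchor"`` (default) walks the
    observed points: a segment is emitted when a point exists exactly tau
    seconds after the current anchor, which then moves to that point; on a
    miss the anchor advances to the next observed point. The alternative
    ``grid_mode="fixed"`` keeps an absolute grid t0 + k*tau and emits only
    segments whose both endpoints were observed.

    With interpolation, missing seconds are filled first (linear), and the
    gap-free trajectory is tiled at t0, t0+tau, ...; a segment is flagged
    ``contains_interpolated`` when any covered point (endpoints included)
    is interpolated.
    """
    if redisc_s < 1:
        raise ValueError("redisc_s must be >= 1")
    tau = int(redisc_s)

    if interpolate_flag:
        traj = interpolate(traj)
        n_seg = (int(traj.t_s[-1]) - int(traj.t_s[0])) // tau if len(traj) > 1 else 0
        return [_segment(traj, k * tau, (k + 1) * tau) for k in range(n_seg)]

    # observed points only
    obs_idx = np.nonzero(~traj.interpolated)[0]
    t = traj.t_s[obs_idx]
    index_of = {int(ti): int(i) for i, ti in zip(obs_idx, t)}
    segments = []
    if grid_mode == "anchor":
        k = 0
        while k < len(t) and int(t[k]) + tau <= int(t[-1]):
            target = int(t[k]) + tau
            j = index_of.get(target)
            if j is not None:
                segments.append(_segment(traj, index_of[int(t[k])], j))
                k = int(np.searchsorted(t, target))
            else:
                k += 1
    elif grid_mode == "fixed":
        if len(t) > 0:
            t0 = int(t[0])
            for start in range(t0, int(t[-1]) - tau + 1, tau):
                i, j = index_of.get(start), index_of.get(start + tau)
                if i is not None and j is not None:
                    segments.append(_segment(traj, i, j))
    else:
        raise ValueError("grid_mode must be 'anchor' or 'fixed'")
    return segments


def compute_distances(segments: list) -> np.ndarray:
    """Segment lengths in px."""
    return np.array([s.distance_px for s in segments], dtype=float)


def compute_speeds(segments: list, redisc_s: int, px_per_cm: float = DEFAULT_PX_PER_CM) -> np.ndarray:
    """Speeds in cm/s: distance / (tau * px_per_cm)."""
    if px_per_cm <= 0:
        raise ConfigurationError("px_per_cm must be positive")
    return compute_distances(segments) / (redisc_s * px_per_cm)


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]; exact pi maps to +pi."""
    a = -((-a + math.pi) % (2.0 * math.pi) - math.pi)
    return a


def compute_turning_angles(segments: list, return_skipped: bool = False):
    """Signed heading changes between time-adjacent segment pairs.

    Consecutive segments must share their vertex (``s1.t_end == s2.t_start``);
    pairs separated by skipped seconds produce no angle. Zero-length segments
    have no heading: the pairs they participate in are skipped and counted.
    """
    angles = []
    skipped = 0
    for s1, s2 in zip(segments, segments[1:]):
        if s1.t_end != s2.t_start:
            continue
        if s1.distance_px == 0.0 or s2.distance_px == 0.0:
            skipped += 1
            continue
        angles.append(
            TurningAngle(_wrap_angle(s2.heading_rad() - s1.heading_rad()), int(s2.t_start))
        )
    if return_skipped:
        return angles, skipped
    return angles


def pixel_to_cm(value_px: float, px_per_cm: float = DEFAULT_PX_PER_CM) -> float:
    """Convert a pixel measure to cm through the calibration."""
    if px_per_cm <= 0:
        raise ConfigurationError("px_per_cm must be positive")
    return value_px / px_per_cm


def trajectories_to_frame(trajs: list) -> pd.DataFrame:
    """Concatenate trajectories to the CSV schema."""
    if not trajs:
        return pd.DataFrame(
            columns=["individual_id", "ground_type", "trajectory_id", "t_s", "x_px", "y_px", "interpolated"]
        )
    return pd.concat([t.to_frame() for t in trajs], ignore_index=True)


def trajectories_from_frame(df: pd.DataFrame) -> list:
    """Read trajectories from the CSV schema (validates required columns)."""
    required = ["individual_id", "ground_type", "trajectory_id", "t_s", "x_px", "y_px"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table is missing column(s): {', '.join(missing)}")
    out = []
    for (ind, gt, tid), g in df.groupby(["individual_id", "ground_type", "trajectory_id"], sort=True):
        g = g.sort_values("t_s")
        interp = g["interpolated"].to_numpy(bool) if "interpolated" in g else None
        out.append(
            Trajectory.from_points(
                tid, g["t_s"].to_numpy(), g["x_px"].to_numpy(), g["y_px"].to_numpy(),
                individual_id=str(ind), ground_type=str(gt), interpolated=interp,
            )
        )
    return out
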