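"""Tag detection (difference of Gaussians) and gap-closing track linking.

The reflective tag appears in treated frames as a bright blob of roughly
3 px diameter. Detection follows the standard two-scale blob recipe: the
frame is smoothed at sigma1 = d / (2*sqrt(2)) and sigma2 = sqrt(2)*sigma1,
the difference image is taken, and local maxima whose response (the
"quality", on the 0-255 intensity scale) reaches the quality threshold are
emitted with sub-pixel positions from quadratic peak interpolation.

Linking is a two-pass linear-assignment procedure: consecutive frames are
matched by the Hungarian algorithm on squared displacement, gated at the
distance gap d_g; then track ends are joined to later track starts (gap
closing) when the silent interval is at most the time gap t_g and the jump
at most d_g, resolving competing candidates by smallest time difference,
then smallest distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment

__all__ = [
    "DetectorConfig",
    "Detection",
    "LinkConfig",
    "RawTrack",
    "dog_detect",
    "detect_stack",
    "link_frames",
    "tracks_to_frame",
]

_GATED = 1e12  # assignment cost marking a forbidden link


@dataclass(frozen=True)
class DetectorConfig:
    """Blob size (px) and minimum DoG response for a detection."""

    blob_diameter_px: float = 3.0
    quality_threshold: float = 15.0

    def __post_init__(self) -> None:
        if self.blob_diameter_px <= 0:
            raise ValueError("blob_diameter_px must be positive")

    @property
    def sigma1(self) -> float:
        return self.blob_diameter_px / (2.0 * math.sqrt(2.0))

    @property
    def sigma2(self) -> float:
        return math.sqrt(2.0) * self.sigma1


@dataclass(frozen=True)
class Detection:
    """One candidate tag location at integer second ``t_s`` (sub-pixel x, y)."""

    t_s: int
    x_px: float
    y_px: float
    quality: float


@dataclass(frozen=True)
class LinkConfig:
    """Gap-closing gates: max distance (px) and max silent time (s)."""

    d_g_px: float = 30.0
    t_g_s: int = 5

    def __post_init__(self) -> None:
        if self.d_g_px <= 0 or self.t_g_s <= 0:
            raise ValueError("d_g_px and t_g_s must be positive")


@dataclass
class RawTrack:
    """Time-ordered detections of one putative individual."""

    track_id: int
    detections: list

    @property
    def t_start(self) -> int:
        return self.detections[0].t_s

    @property
    def t_end(self) -> int:
        return self.detections[-1].t_s

    def __len__(self) -> int:
        return len(self.detections)

    def check_invariants(self, cfg: LinkConfig) -> None:
        for a, b in zip(self.detections, self.detections[1:]):
            dt = b.t_s - a.t_s
            dist = math.hypot(b.x_px - a.x_px, b.y_px - a.y_px)
            if dt < 1 or dt > cfg.t_g_s or dist > cfg.d_g_px + 1e-9:
                raise AssertionError(
                    f"track {self.track_id}: link dt={dt}, dist={dist:.2f} violates gates"
                )


def _subpixel_offset(fm1: float, f0: float, fp1: float) -> float:
    """1-D quadratic peak interpolation around a discrete maximum."""
    denom = fm1 - 2.0 * f0 + fp1
    if denom >= 0:  # flat or non-concave: keep the integer position
        return 0.0
    return float(np.clip(0.5 * (fm1 - fp1) / denom, -0.5, 0.5))


def dog_detect(frame: np.ndarray, cfg: DetectorConfig, t_s: int = 0) -> list:
    """Detect bright blobs in one treated frame.

    Returns detections at strict local maxima of the DoG response that reach
    ``cfg.quality_threshold``, with sub-pixel positions.
    """
    f = np.asarray(frame, dtype=np.float32)
    dog = gaussian_filter(f, cfg.sigma1) - gaussian_filter(f, cfg.sigma2)
    # threshold first, then verify the (few) candidates are 3x3 local maxima;
    # avoids a full-frame maximum filter on frames that are mostly black
    ys, xs = np.nonzero(dog >= cfg.quality_threshold)
    out = []
    h, w = dog.shape
    for yi, xi in zip(ys.tolist(), xs.tolist()):
        if yi == 0 or xi == 0 or yi == h - 1 or xi == w - 1:
            continue
        patch = dog[yi - 1 : yi + 2, xi - 1 : xi + 2]
        if dog[yi, xi] < patch.max():
            continue
        # flat-plateau tie-break: only the first (row-major) tied pixel emits
        first_tie = np.argwhere(patch == dog[yi, xi])[0]
        if (first_tie[0], first_tie[1]) != (1, 1):
            continue
        dx = _subpixel_offset(dog[yi, xi - 1], dog[yi, xi], dog[yi, xi + 1])
        dy = _subpixel_offset(dog[yi - 1, xi], dog[yi, xi], dog[yi + 1, xi])
        out.append(Detection(t_s=t_s, x_px=xi + dx, y_px=yi + dy, quality=float(dog[yi, xi])))
    return out


def detect_stack(stack, cfg: DetectorConfig) -> list:
    """Run ``dog_detect`` on every frame; returns one detection list per frame."""
    times = stack.times()
    return [dog_detect(stack.frames[i], cfg, t_s=int(times[i])) for i in range(len(stack))]


def _group_by_time(detections) -> dict:
    """Accept per-frame lists or a flat list; return {t_s: [Detection, ...]}."""
    grouped: dict[int, list] = {}
    seq = detections
    if seq and isinstance(seq[0], Detection):
        flat = seq
    else:
        flat = [d for frame in seq for d in frame]
    for d in flat:
        grouped.setdefault(int(d.t_s), []).append(d)
    return grouped


def link_frames(detections, cfg: LinkConfig = LinkConfig()) -> list:
    """Link detections into tracks: frame-to-frame assignment, then gap closing.

    ``detections`` is either a flat list of :class:`Detection` or a list of
    per-frame lists. Returns :class:`RawTrack` objects sorted by start time.
    """
    by_time = _group_by_time(detections)
    times = sorted(by_time)
    tracks: list[list[Detection]] = []
    open_by_t: dict[int, list[int]] = {}  # last t_s -> indices of tracks ending there

    for t in times:
        cur = by_time[t]
        prev_ids = open_by_t.pop(t - 1, [])
        assigned = [False] * len(cur)
        if prev_ids:
            ends = [tracks[i][-1] for i in prev_ids]
            cost = np.full((len(ends), len(cur)), _GATED)
            for i, e in enumerate(ends):
                for j, d in enumerate(cur):
                    sq = (e.x_px - d.x_px) ** 2 + (e.y_px - d.y_px) ** 2
                    if sq <= cfg.d_g_px**2:
                        cost[i, j] = sq
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < _GATED:
                    tracks[prev_ids[i]].append(cur[j])
                    open_by_t.setdefault(t, []).append(prev_ids[i])
                    assigned[j] = True
                # unmatched previous tracks simply end here; gap closing may
                # re-join them to a later start
        for j, d in enumerate(cur):
            if not assigned[j]:
                tracks.append([d])
                open_by_t.setdefault(t, []).append(len(tracks) - 1)

    merged = _close_gaps(tracks, cfg)
    merged.sort(key=lambda dets: dets[0].t_s)
    return [RawTrack(track_id=i, detections=dets) for i, dets in enumerate(merged)]


def _close_gaps(tracks: list, cfg: LinkConfig) -> list:
    """Greedy gap closing by (smallest dt, smallest distance, lowest ids)."""
    alive = [list(t) for t in tracks]
    active = set(range(len(alive)))
    while True:
        best = None
        for i in active:
            for j in active:
                if i == j:
                    continue
                a, b = alive[i][-1], alive[j][0]
                dt = b.t_s - a.t_s
                if dt < 1 or dt > cfg.t_g_s:
                    continue
                dist = math.hypot(b.x_px - a.x_px, b.y_px - a.y_px)
                if dist > cfg.d_g_px:
                    continue
                key = (dt, dist, i, j)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        _, _, i, j = best
        alive[i].extend(alive[j])
        active.discard(j)
    return [alive[i] for i in sorted(active)]


def tracks_to_frame(tracks: list) -> pd.DataFrame:
    """Flatten tracks to a table (track_id, t_s, x_px, y_px, quality)."""
    rows = [
        (tr.track_id, d.t_s, d.x_px, d.y_px, d.quality)
        for tr in tracks
        for d in tr.detections
    ]
    return pd.DataFrame(rows, columns=["track_id", "t_s", "x_px", "y_px", "quality"])
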