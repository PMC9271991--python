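"""Stage glue shared by the CLI and the reproduction script.

Each stage is independently invocable with CSV hand-offs, so the analysis
core can be exercised on truth tables without the imaging front end, and the
imaging front end can be validated against the truth tables it was rendered
from.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import detect as dt
from . import frames as fr
from . import stats as st
from . import trajectories as tj
from .config import PipelineConfig

__all__ = [
    "track_stack",
    "clean_tracks",
    "trajectories_from_truth",
    "analyze_trajectories",
    "activity_report",
]


def track_stack(stack: fr.FrameStack, config: PipelineConfig) -> list:
    """Preprocess, detect and link one recording; returns raw tracks.

    Streams window by window and frame by frame (two passes per window: one
    to accumulate the residual-noise image, one to treat and detect), so a
    full-night stack never needs a floating-point copy in memory. Numerically
    identical to ``frames.preprocess`` followed by ``detect.detect_stack``.
    """
    det_cfg = config.detector.detector()
    times = stack.times()
    detections: list = []
    for w in fr.iter_windows(len(stack), config.preprocess.window_s):
        win = stack.frames[w]
        bg = fr._temporal_median(win).astype(np.float32)
        n = len(win)
        noise = np.zeros(bg.shape, dtype=np.float32)
        scratch = np.empty(bg.shape, dtype=np.float32)
        for i in range(n):
            np.subtract(win[i], bg, out=scratch)
            np.clip(scratch, 0.0, None, out=scratch)
            noise += scratch
        noise /= n
        for i in range(n):
            np.subtract(win[i], bg, out=scratch)
            np.clip(scratch, 0.0, None, out=scratch)
            scratch -= noise
            np.clip(scratch, 0.0, None, out=scratch)
            detections.append(dt.dog_detect(scratch, det_cfg, t_s=int(times[w.start + i])))
    return dt.link_frames(detections, config.linker.linker())


def clean_tracks(
    tracks: list,
    config: PipelineConfig,
    individual_id: str = "",
    ground_type: str = "",
    review_path=None,
) -> list:
    """Semi-automated cleaning of one recording's raw tracks."""
    trajs = [tj.Trajectory.from_raw_track(t, individual_id, ground_type) for t in tracks]
    return tj.auto_clean(
        trajs,
        max_auto_points=config.cleaning.max_auto_points,
        exclusion_list=config.cleaning.exclusion_list,
        px_per_cm=config.arena.px_per_cm,
        review_path=review_path,
        mutual_delete_cm=config.cleaning.mutual_delete_cm,
    )


def trajectories_from_truth(truths: list, drop_concealed: bool = True) -> dict:
    """Turn truth tables into per-individual trajectory fragments.

    With ``drop_concealed`` the concealed seconds are removed, emulating what
    a perfect detector would see; the junction stage is then responsible for
    re-joining the visible fragments.
    """
    out: dict[str, list] = {}
    labels: dict[str, str] = {}
    for tr in truths:
        mask = ~tr.concealed if drop_concealed else np.ones(len(tr), dtype=bool)
        traj = tj.Trajectory(
            trajectory_id=f"{tr.individual_id}/truth",
            individual_id=tr.individual_id,
            ground_type=tr.ground_type,
            t_s=tr.t_s[mask],
            x_px=tr.x_px[mask],
            y_px=tr.y_px[mask],
            interpolated=np.zeros(int(mask.sum()), dtype=bool),
        )
        out.setdefault(tr.individual_id, []).append(traj)
        labels[tr.individual_id] = tr.ground_type
    return {"trajectories": out, "labels": labels}


def analyze_trajectories(
    trajs_by_individual: dict,
    labels: dict,
    config: PipelineConfig,
    distance_grid=None,
    angle_grid=None,
) -> pd.DataFrame:
    """Run the procedure grid under the configured statistical settings."""
    return st.run_procedure_grid(
        trajs_by_individual,
        labels,
        config.arena.geometry(),
        distance_grid=distance_grid,
        angle_grid=angle_grid,
        min_individuals=config.stats.min_individuals,
        min_records=config.stats.min_records,
        n_permutations=config.stats.n_permutations,
        seed=config.stats.seed,
    )


def activity_report(trajs_by_individual: dict, labels: dict) -> pd.DataFrame:
    """Activity metrics per individual from cleaned (pre-edge-removal) points."""
    rows = []
    for ind, trajs in sorted(trajs_by_individual.items()):
        times = np.concatenate([t.t_s for t in trajs]) if trajs else np.array([], dtype=int)
        m = st.activity_metrics(times, individual_id=ind)
        rows.append(
            {
                "individual_id": ind,
                "ground_type": labels.get(ind, ""),
                "apparent_intensity_s": m.apparent_intensity_s,
                "estimated_intensity_min": m.estimated_intensity_min,
                "total_activity_period_s": m.total_activity_period_s,
            }
        )
    return pd.DataFrame(rows)
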