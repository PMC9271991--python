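"""Synthetic mesocosm: ground-truth walks and rendered frame stacks.

The generator emulates the experimental setup the pipeline is built for: a
1 x 1 m arena filmed from above at 1 frame per second under infrared light,
with a single individual carrying a small retro-reflective tag (a bright
~3 px blob) walking on a noisy, textured ground. Two ground types are
modelled: bare soil (faster, straighter movement, always visible) and soil
partly covered with plant-residue units (slower, more sinuous movement,
periodically concealed while under a residue unit).

Movement is a correlated random walk at one step per second: step lengths
are exponential with a configurable mean (in cm/s, converted through the
px/cm calibration) and turning angles are wrapped normal, parameterized
directly by the target mean resultant length rho via sigma = sqrt(-2 ln rho).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ArenaGeometry",
    "GroundTypeParams",
    "ResidueLayout",
    "TruthTrajectory",
    "bare_soil_params",
    "residue_params",
    "wrapped_normal_angles",
    "simulate_crw_trajectory",
    "render_background",
    "render_frames",
    "generate_dataset",
]

#: Calibration of the study arena: 1 cm on the ground == 6.82 px in the image.
DEFAULT_PX_PER_CM = 6.82


class ConfigurationError(ValueError):
    """Raised when a geometry or ground-type parameter is out of range."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena dimensions and camera calibration.

    Defaults correspond to a 1 x 1 m arena at 6.82 px/cm with the 35 px
    (~5.1 cm) near-edge exclusion buffer.
    """

    width_px: int = 682
    height_px: int = 682
    px_per_cm: float = DEFAULT_PX_PER_CM
    edge_buffer_px: int = 35

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ConfigurationError("px_per_cm must be positive")
        if self.width_px <= 2 * self.edge_buffer_px or self.height_px <= 2 * self.edge_buffer_px:
            raise ConfigurationError("arena must be wider than twice the edge buffer")


@dataclass(frozen=True)
class GroundTypeParams:
    """Movement and concealment parameters of one ground type.

    mean_step_cm_per_s : mean per-second step length (cm/s); step lengths
        are exponential with this mean.
    angle_concentration : target mean resultant length of per-second turning
        angles in [0, 1]; 1 = straight line, 0 = uniform (Brownian-like).
    conceal_prob_enter : probability per second spent inside a residue unit
        of starting a concealment bout.
    conceal_duration_mean_s : mean of the geometric concealment duration.
    """

    name: str
    mean_step_cm_per_s: float
    angle_concentration: float
    conceal_prob_enter: float = 0.0
    conceal_duration_mean_s: float = 60.0

    def __post_init__(self) -> None:
        if self.mean_step_cm_per_s <= 0:
            raise ConfigurationError("mean_step_cm_per_s must be positive")
        if not 0.0 <= self.angle_concentration <= 1.0:
            raise ConfigurationError("angle_concentration must be in [0, 1]")
        if not 0.0 <= self.conceal_prob_enter <= 1.0:
            raise ConfigurationError("conceal_prob_enter must be in [0, 1]")
        if self.conceal_duration_mean_s < 1.0:
            raise ConfigurationError("conceal_duration_mean_s must be >= 1")


def bare_soil_params() -> GroundTypeParams:
    """Bare-soil study conditions: 0.85 cm/s, concentration 0.77, no concealment."""
    return GroundTypeParams("bare_soil", mean_step_cm_per_s=0.85, angle_concentration=0.77)


def residue_params() -> GroundTypeParams:
    """Residue-covered study conditions: 0.36 cm/s, concentration 0.40, concealment on."""
    return GroundTypeParams(
        "residues",
        mean_step_cm_per_s=0.36,
        angle_concentration=0.40,
        conceal_prob_enter=0.3,
        conceal_duration_mean_s=60.0,
    )


@dataclass(frozen=True)
class ResidueLayout:
    """Positions of square residue units on the arena floor.

    ``unit_positions`` holds (x0, y0, x1, y1) pixel rectangles (half-open).
    """

    unit_size_cm: float = 3.0
    spacing_cm: float = 6.0
    unit_positions: tuple = ()

    @classmethod
    def regular_grid(
        cls,
        geom: ArenaGeometry,
        unit_size_cm: float = 3.0,
        spacing_cm: float = 6.0,
    ) -> "ResidueLayout":
        """Place units evenly on a grid with center-to-center ``spacing_cm``."""
        size_px = unit_size_cm * geom.px_per_cm
        pitch_px = spacing_cm * geom.px_per_cm
        if pitch_px < size_px:
            raise ConfigurationError("spacing_cm smaller than unit_size_cm: units overlap")
        rects = []
        cx = pitch_px / 2.0
        while cx + size_px / 2.0 <= geom.width_px:
            cy = pitch_px / 2.0
            while cy + size_px / 2.0 <= geom.height_px:
                rects.append(
                    (cx - size_px / 2.0, cy - size_px / 2.0, cx + size_px / 2.0, cy + size_px / 2.0)
                )
                cy += pitch_px
            cx += pitch_px
        return cls(unit_size_cm=unit_size_cm, spacing_cm=spacing_cm, unit_positions=tuple(rects))

    def contains(self, x: float, y: float) -> bool:
        for (x0, y0, x1, y1) in self.unit_positions:
            if x0 <= x < x1 and y0 <= y < y1:
                return True
        return False


@dataclass
class TruthTrajectory:
    """Ground-truth positions of one individual, one point per second."""

    individual_id: str
    ground_type: str
    t_s: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    concealed: np.ndarray

    def __len__(self) -> int:
        return len(self.t_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "ground_type": self.ground_type,
                "t_s": self.t_s,
                "x_px": self.x_px,
                "y_px": self.y_px,
                "concealed": self.concealed,
            }
        )


def wrapped_normal_angles(rho: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` turning angles with mean direction 0 and mean resultant length rho.

    Wrapped normal with sigma = sqrt(-2 ln rho); rho = 0 degenerates to the
    uniform distribution on (-pi, pi] and rho = 1 to the point mass at 0.
    """
    if not 0.0 <= rho <= 1.0:
        raise ConfigurationError("rho must be in [0, 1]")
    if rho == 0.0:
        return rng.uniform(-math.pi, math.pi, size=n)
    if rho == 1.0:
        return np.zeros(n)
    sigma = math.sqrt(-2.0 * math.log(rho))
    raw = rng.normal(0.0, sigma, size=n)
    return np.mod(raw + math.pi, 2.0 * math.pi) - math.pi


def _fold(v: np.ndarray | float, lo: float, hi: float):
    """Specular (billiard) reflection of coordinates into [lo, hi]."""
    span = hi - lo
    v = np.mod(np.asarray(v, dtype=float) - lo, 2.0 * span)
    v = np.where(v > span, 2.0 * span - v, v)
    return v + lo


def simulate_crw_trajectory(
    geom: ArenaGeometry,
    params: GroundTypeParams,
    layout: ResidueLayout | None,
    duration_s: int,
    seed: int | np.random.SeedSequence,
) -> TruthTrajectory:
    """Simulate a correlated random walk at 1 step/s with reflecting walls.

    Step lengths (px) are exponential with mean
    ``params.mean_step_cm_per_s * geom.px_per_cm``; turning angles are wrapped
    normal with mean resultant length ``params.angle_concentration``. When a
    ``layout`` is given, each second spent inside a residue unit may start a
    concealment bout (Bernoulli ``conceal_prob_enter``) lasting a geometric
    number of seconds (mean ``conceal_duration_mean_s``), truncated when the
    walker leaves the unit; concealed seconds are flagged but the walk itself
    is unchanged (concealment is observational).
    """
    if duration_s < 2:
        raise ConfigurationError("duration_s must be >= 2")
    rng = np.random.default_rng(seed)
    n = int(duration_s)
    mean_step_px = params.mean_step_cm_per_s * geom.px_per_cm

    steps = rng.exponential(mean_step_px, size=n - 1)
    turns = wrapped_normal_angles(params.angle_concentration, n - 1, rng)
    headings = rng.uniform(-math.pi, math.pi) + np.concatenate([[0.0], np.cumsum(turns[1:])])

    # Unbounded walk folded into the arena: reflections preserve the arena
    # constraint without absorbing the walk at the walls.
    x_free = np.empty(n)
    y_free = np.empty(n)
    x_free[0] = rng.uniform(geom.edge_buffer_px, geom.width_px - geom.edge_buffer_px)
    y_free[0] = rng.uniform(geom.edge_buffer_px, geom.height_px - geom.edge_buffer_px)
    x_free[1:] = x_free[0] + np.cumsum(steps * np.cos(headings))
    y_free[1:] = y_free[0] + np.cumsum(steps * np.sin(headings))
    eps = 1e-9
    x = _fold(x_free, 0.0, geom.width_px - eps)
    y = _fold(y_free, 0.0, geom.height_px - eps)

    concealed = np.zeros(n, dtype=bool)
    if layout is not None and layout.unit_positions and params.conceal_prob_enter > 0:
        p_continue = 1.0 - 1.0 / params.conceal_duration_mean_s
        remaining = 0
        for i in range(n):
            inside = layout.contains(x[i], y[i])
            if not inside:
                remaining = 0
                continue
            if remaining > 0:
                concealed[i] = True
                remaining -= 1
            elif rng.random() < params.conceal_prob_enter:
                concealed[i] = True
                # geometric duration with mean conceal_duration_mean_s
                remaining = rng.geometric(1.0 - p_continue) - 1

    return TruthTrajectory(
        individual_id="sim",
        ground_type=params.name,
        t_s=np.arange(n, dtype=int),
        x_px=x,
        y_px=y,
        concealed=concealed,
    )


def render_background(
    geom: ArenaGeometry, texture_seed: int, mean_level: float = 40.0, texture_sd: float = 10.0
) -> np.ndarray:
    """Static textured ground: a smoothed Gaussian random field (float64)."""
    rng = np.random.default_rng(texture_seed)
    field_ = rng.normal(0.0, 1.0, size=(geom.height_px, geom.width_px))
    field_ = gaussian_filter(field_, sigma=8.0)
    sd = field_.std()
    if sd > 0:
        field_ = (field_ - field_.mean()) / sd * texture_sd
    return np.clip(mean_level + field_, 0.0, 255.0)


def _add_blob(img: np.ndarray, x: float, y: float, sigma: float, peak: float) -> None:
    """Add a Gaussian intensity blob at sub-pixel position (x, y), in place."""
    h, w = img.shape
    r = int(math.ceil(4 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
    img[y0:y1, x0:x1] += peak * np.outer(gy, gx)


def render_frames(
    traj: TruthTrajectory,
    geom: ArenaGeometry,
    noise_sd: float = 5.0,
    blob_sigma_px: float = 1.5,
    blob_peak: float = 150.0,
    background_texture_seed: int = 0,
):
    """Render one 8-bit frame per second: static texture + tag blob + noise.

    The tag blob is drawn only for non-concealed seconds. The background
    texture is identical across frames; per-frame zero-mean Gaussian pixel
    noise (sd ``noise_sd``) is added independently; intensities are clipped
    to [0, 255] and quantized to 8 bits, as an 8-bit camera would.
    """
    from .frames import FrameStack

    if blob_peak <= noise_sd:
        raise ConfigurationError("blob_peak must exceed noise_sd")
    background = render_background(geom, background_texture_seed)
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(background_texture_seed), 1]))
    n = len(traj)
    frames = np.empty((n, geom.height_px, geom.width_px), dtype=np.uint8)
    for i in range(n):
        img = background.copy()
        if not traj.concealed[i]:
            _add_blob(img, traj.x_px[i], traj.y_px[i], blob_sigma_px, blob_peak)
        if noise_sd > 0:
            img += noise_rng.normal(0.0, noise_sd, size=img.shape)
        np.clip(img, 0.0, 255.0, out=img)
        frames[i] = (img + 0.5).astype(np.uint8)  # round-half-up quantization
    return FrameStack(frames=frames, t0_s=int(traj.t_s[0]))


def generate_dataset(
    n_individuals_per_type: int,
    geom: ArenaGeometry,
    params_bare: GroundTypeParams,
    params_residues: GroundTypeParams,
    layout: ResidueLayout | None,
    duration_s: int,
    seed: int,
    render: bool = True,
    noise_sd: float = 5.0,
    blob_sigma_px: float = 1.5,
    blob_peak: float = 150.0,
):
    """Generate independent truth trajectories (and optionally frame stacks).

    Returns ``(trajectories, stacks)``; ``stacks`` is empty when
    ``render=False``. Fully reproducible given ``seed``.
    """
    if n_individuals_per_type < 1:
        raise ConfigurationError("n_individuals_per_type must be >= 1")
    if layout is None:
        layout = ResidueLayout.regular_grid(geom)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_individuals_per_type)
    trajs: list[TruthTrajectory] = []
    stacks = []
    k = 0
    for params, traj_layout, prefix in (
        (params_bare, None, "bare"),
        (params_residues, layout, "res"),
    ):
        for j in range(n_individuals_per_type):
            traj = simulate_crw_trajectory(geom, params, traj_layout, duration_s, children[k])
            traj.individual_id = f"{prefix}{j:02d}"
            trajs.append(traj)
            if render:
                stacks.append(
                    render_frames(
                        traj,
                        geom,
                        noise_sd=noise_sd,
                        blob_sigma_px=blob_sigma_px,
                        blob_peak=blob_peak,
                        background_texture_seed=int(children[k].generate_state(1)[0] % 2**31),
                    )
                )
            k += 1
    return trajs, stacks


def write_truth_csv(trajs: list[TruthTrajectory], path) -> None:
    """Write truth tables (individual_id, ground_type, t_s, x_px, y_px, concealed)."""
    pd.concat([t.to_frame() for t in trajs], ignore_index=True).to_csv(path, index=False)


def read_truth_csv(path) -> list[TruthTrajectory]:
    df = pd.read_csv(path)
    out = []
    for (ind, gt), g in df.groupby(["individual_id", "ground_type"], sort=True):
        g = g.sort_values("t_s")
        out.append(
            TruthTrajectory(
                individual_id=str(ind),
                ground_type=str(gt),
                t_s=g["t_s"].to_numpy(dtype=int),
                x_px=g["x_px"].to_numpy(dtype=float),
                y_px=g["y_px"].to_numpy(dtype=float),
                concealed=g["concealed"].to_numpy(dtype=bool),
            )
        )
    return out
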