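"""Frame-stack IO and the two video treatments.

Nocturnal infrared footage of a soil arena has a bright, heterogeneous,
essentially static background against which a small reflective tag moves.
Two per-window treatments turn this into near black-and-white frames:

1. stationary-background subtraction — the per-pixel temporal *median* over
   each window (default 30 min at 1 fps) is subtracted from every frame of
   that window, leaving the moving tag in light gray-white on black;
2. residual-noise subtraction — a per-window noise image, the per-pixel
   temporal mean of the background-subtracted frames, is subtracted in turn.
   Pixels that flicker persistently (dark-gray static noise) accumulate a
   large mean and are suppressed to zero, while a transient that is bright
   in only one frame of an n-frame window loses at most 1/n of its
   amplitude.

All arithmetic is clamped at zero; integer frames are promoted to floats
internally and re-quantized to 8 bits only on write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameStack",
    "FormatError",
    "read_stack",
    "write_stack",
    "iter_windows",
    "compute_median_background",
    "subtract_background",
    "compute_noise_image",
    "subtract_noise",
    "preprocess",
]

DEFAULT_WINDOW_S = 1800  # 30 min at 1 fps


class FormatError(ValueError):
    """Unreadable stack path or inconsistent frame shapes."""


@dataclass
class FrameStack:
    """Ordered grayscale frames (n, height, width) at a fixed 1 fps."""

    frames: np.ndarray
    t0_s: int = 0
    fps: int = field(default=1)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise FormatError("frames must be a non-empty (n, h, w) array")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self):
        return self.frames.shape[1:]

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self), dtype=int)


_FRAME_EXTS = (".png", ".tif", ".tiff")


def read_stack(path) -> FrameStack:
    """Read a multi-page TIFF file or a directory of ordered PNG/TIFF frames."""
    import tifffile

    path = os.fspath(path)
    if os.path.isdir(path):
        import imageio.v3 as iio

        names = sorted(f for f in os.listdir(path) if f.lower().endswith(_FRAME_EXTS))
        if not names:
            raise FormatError(f"no frames found in directory {path!r}")
        frames = []
        for name in names:
            try:
                frames.append(np.asarray(iio.imread(os.path.join(path, name))))
            except Exception as exc:  # noqa: BLE001 - surface as format error
                raise FormatError(f"unreadable frame {name!r}: {exc}") from exc
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent frame shapes in {path!r}: {sorted(shapes)}")
        return FrameStack(frames=np.stack(frames))
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable stack {path!r}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"expected grayscale stack, got shape {arr.shape}")
    return FrameStack(frames=arr)


def write_stack(stack: FrameStack, path) -> None:
    """Write as multi-page TIFF (``.tif`` path) or a PNG sequence (directory)."""
    import tifffile

    path = os.fspath(path)
    frames = stack.frames
    if frames.dtype != np.uint8:
        frames = np.clip(frames, 0, 255).astype(np.uint8)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, frames, photometric="minisblack")
    else:
        import imageio.v3 as iio

        os.makedirs(path, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(os.path.join(path, f"frame_{i:06d}.png"), frame)


def iter_windows(n_frames: int, window_s: int = DEFAULT_WINDOW_S):
    """Slices covering [0, n) in chunks of window_s; the last may be shorter."""
    if window_s < 2:
        raise ValueError("window_s must be >= 2")
    return [slice(i, min(i + window_s, n_frames)) for i in range(0, n_frames, window_s)]


def _temporal_median(window: np.ndarray) -> np.ndarray:
    """Per-pixel median over axis 0; partition-based fast path for uint8."""
    if window.dtype != np.uint8:
        return np.median(window, axis=0)
    n = len(window)
    mid = n // 2
    if n % 2:
        return np.partition(window, mid, axis=0)[mid].astype(np.float32)
    part = np.partition(window, [mid - 1, mid], axis=0)
    return (part[mid - 1].astype(np.float32) + part[mid]) * 0.5


def compute_median_background(stack: FrameStack, window_s: int = DEFAULT_WINDOW_S):
    """Per-window, per-pixel temporal median images of the raw stack."""
    return [
        _temporal_median(stack.frames[w]) for w in iter_windows(len(stack), window_s)
    ]


def _check_alignment(stack: FrameStack, images, window_s: int) -> list:
    windows = iter_windows(len(stack), window_s)
    if len(images) != len(windows):
        raise ValueError(
            f"{len(images)} window images do not align with {len(windows)} windows"
        )
    return windows


def subtract_background(stack: FrameStack, backgrounds, window_s: int = DEFAULT_WINDOW_S) -> FrameStack:
    """Clamped subtraction of each window's background from its frames."""
    windows = _check_alignment(stack, backgrounds, window_s)
    out = np.empty(stack.frames.shape, dtype=np.float32)
    for w, bg in zip(windows, backgrounds):
        np.clip(stack.frames[w].astype(np.float32) - bg.astype(np.float32), 0.0, None, out=out[w])
    return FrameStack(frames=out, t0_s=stack.t0_s)


def compute_noise_image(subtracted: FrameStack, window_s: int = DEFAULT_WINDOW_S, divisor: str = "window"):
    """Per-window residual-noise images of a background-subtracted stack.

    The per-pixel sum of intensities over the window, rescaled to intensity
    units by dividing by the number of frames in the window (the temporal
    mean). ``divisor="none"`` keeps the raw sum.
    """
    out = []
    for w in iter_windows(len(subtracted), window_s):
        total = subtracted.frames[w].astype(np.float64).sum(axis=0)
        if divisor == "window":
            total /= w.stop - w.start
        elif divisor != "none":
            raise ValueError("divisor must be 'window' or 'none'")
        out.append(total)
    return out


def subtract_noise(subtracted: FrameStack, noise_images, window_s: int = DEFAULT_WINDOW_S) -> FrameStack:
    """Clamped subtraction of each window's noise image from its frames."""
    windows = _check_alignment(subtracted, noise_images, window_s)
    out = np.empty(subtracted.frames.shape, dtype=np.float32)
    for w, noise in zip(windows, noise_images):
        np.clip(subtracted.frames[w].astype(np.float32) - noise.astype(np.float32), 0.0, None, out=out[w])
    return FrameStack(frames=out, t0_s=subtracted.t0_s)


def preprocess(stack: FrameStack, window_s: int = DEFAULT_WINDOW_S) -> FrameStack:
    """Both treatments in order: median background, then residual noise."""
    backgrounds = compute_median_background(stack, window_s)
    sub = subtract_background(stack, backgrounds, window_s)
    noise = compute_noise_image(sub, window_s)
    return subtract_noise(sub, noise, window_s)
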