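# mesotrack

Video tracking of small nocturnal ground-dwelling arthropods in mesocosm
arenas, from raw 1 fps grayscale frame stacks to movement statistics.

Studying how ground cover shapes the fine (centimeter-scale) foraging
movement of soil-dwelling insects — earwigs and other predators relevant to
conservation biological control — requires tracking a ~1 cm animal at night
on a dark, heterogeneous substrate that periodically *conceals* it.
`mesotrack` implements the full chain for a fixed infrared camera over a
1 × 1 m arena, for two contrasted ground types (bare soil vs soil partly
covered by plant-residue units):

1. **Video treatments** — per 30-min window, subtract the per-pixel temporal
   *median* (stationary background), then the per-pixel temporal *mean* of
   the result (residual noise): the moving reflective tag survives, the
   static scene and persistent flicker go to zero.
2. **Detection & linking** — difference-of-Gaussians blob detection
   (σ₁ = d/(2√2), σ₂ = √2σ₁ for a tag of diameter d = 3 px, quality
   threshold 15) with sub-pixel localization; Hungarian frame-to-frame
   assignment gated at d_g = 30 px plus gap closing up to t_g = 5 s.
3. **Semi-automated cleaning** — simultaneous (conflicting) tracks resolved
   by explicit rules; large conflicts go to a review file and an exclusion
   list rather than silent heuristics.
4. **Trajectory rebuilding** — junction of fragments (d_g = 50 px, t_g per
   procedure), removal of points within 35 px (≈5.1 cm) of the arena edge,
   optional linear interpolation of missing seconds, and *rediscretization*
   into segments of one fixed duration τ via a re-anchoring walk over the
   observed points.
5. **Movement statistics** — per procedure (t_g × τ × interpolation grid):
   speeds v = d/(τ·c) with calibration c = 6.82 px/cm, compared with a
   linear mixed model √d ~ ground type + (1 | individual); sinuosity via the
   turning-angle concentration R̄ = |mean e^{iθ}| (1 − circular variance),
   compared with a Wallraff rank test on angular dispersions calibrated by a
   randomization test permuting individuals between ground types; plus
   per-night activity metrics.

A fully seeded **synthetic mesocosm** (correlated random walk with
exponential steps, wrapped-normal turning angles, residue-unit concealment,
and 8-bit frame rendering of a bright tag blob on a noisy textured
background) makes every stage testable end to end without the original
recordings.

## Worked example

```python
import numpy as np
from mesotrack import (
    ArenaGeometry, bare_soil_params, residue_params, ResidueLayout,
    simulate_crw_trajectory, render_frames,
)
from mesotrack.config import PipelineConfig
from mesotrack import pipeline as pl
from mesotrack.trajectories import join_trajectories, remove_edge_points, rediscretize, compute_speeds

cfg = PipelineConfig()
geom = cfg.arena.geometry()                      # 682 x 682 px, 6.82 px/cm

truth = simulate_crw_trajectory(geom, bare_soil_params(), None, 300, seed=1)
stack = render_frames(truth, geom, background_texture_seed=3)

tracks = pl.track_stack(stack, cfg)              # preprocess + detect + link
frags  = pl.clean_tracks(tracks, cfg, "ind0", "bare_soil")
joined = join_trajectories(frags, cfg.junction.t_g_s, cfg.junction.d_g_px)
inner  = remove_edge_points(joined, geom)
segs   = [s for t in inner for s in rediscretize(t, 1)]
speeds = compute_speeds(segs, 1, geom.px_per_cm)
print(f"{len(segs)} one-second segments, mean speed {speeds.mean():.2f} cm/s")
```

prints (seeds as above):

```
284 one-second segments, mean speed 0.82 cm/s
```

— 284 of the 299 possible one-second displacements survive edge removal and
detection, and the mean recovered speed of 0.82 cm/s estimates the
generator's bare-soil step mean of 0.85 cm/s (this single short walk carries
sampling error; the acceptance experiment below pools 20 individuals).

The same pipeline is scriptable from the shell:

```bash
mesotrack simulate --out sim/                 # truth CSV + TIFF stacks
mesotrack track sim/bare00.tif --out trk/     # detections.csv, tracks.csv
mesotrack analyze trajectories.csv --out an/  # grid_report.csv, activity.csv
mesotrack full --out run/                     # all of the above, end to end
```

Every run writes a `manifest.json` (config, seeds, versions) sufficient to
reproduce its outputs bit-identically.

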