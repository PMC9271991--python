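"""Activity metrics, circular statistics and the ground-type comparisons.

Three per-individual activity measures summarize a night of cleaned
trajectories: the apparent intensity of activity (seconds with an observed
moving detection), the estimated intensity (clock minutes containing at
least one such second) and the total activity period (seconds between the
first and last detection).

Sinuosity is summarized by the concentration of turning angles — the mean
resultant length R = |mean exp(i*theta)|, i.e. one minus the circular
variance; low concentration = sinuous path. Ground types are compared with
the Wallraff non-parametric procedure: each angle's angular dispersion
distance to its ground type's pooled mean direction is ranked, and the
Kruskal-Wallis rank statistic between ground types is the test statistic.
Significance comes from a randomization test permuting *individuals* (each
individual's full angle set moves as a block) between ground types, which
respects the unequal numbers of angles per individual.

Distances (at a fixed rediscretization tau, so speeds up to a constant) are
compared with a linear mixed model on sqrt(distance_px) with a random
intercept per individual; the slowdown ratio is the ratio of back-squared
predicted distances per ground type.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthetic import ArenaGeometry
from .trajectories import (
    ProcedureConfig,
    compute_distances,
    compute_turning_angles,
    interpolate,
    join_trajectories,
    rediscretize,
    remove_edge_points,
)

__all__ = [
    "ActivityMetrics",
    "MovementSample",
    "ConcentrationResult",
    "SlowdownResult",
    "activity_metrics",
    "concentration",
    "mean_direction",
    "angular_dispersion",
    "wallraff_statistic",
    "randomization_test",
    "fit_distance_model",
    "eligibility_filter",
    "default_distance_grid",
    "default_angle_grid",
    "run_procedure_grid",
]


@dataclass(frozen=True)
class ActivityMetrics:
    """Per-individual activity summary over one night."""

    individual_id: str
    apparent_intensity_s: int
    estimated_intensity_min: int
    total_activity_period_s: int


@dataclass
class MovementSample:
    """Per-individual movement variables produced by one procedure."""

    procedure: ProcedureConfig
    distances_px: dict  # individual_id -> np.ndarray
    turning_angles_rad: dict  # individual_id -> np.ndarray (empty if interpolated)
    labels: dict  # individual_id -> ground_type


@dataclass
class ConcentrationResult:
    """Turning-angle concentration comparison between ground types."""

    per_individual: dict
    group_means: dict
    statistic: float
    p_value: float
    n_permutations: int


@dataclass
class SlowdownResult:
    """Mixed-model comparison of sqrt-distances between ground types."""

    fixed_effects: dict
    predicted_distance_px: dict
    ratio: float
    p_value: float
    n_obs: int
    n_individuals: dict


def activity_metrics(detection_times, individual_id: str = "") -> ActivityMetrics:
    """Compute the three activity measures from detection seconds.

    Minutes are clock-aligned bins of 60 s from the recording origin (t = 0).
    """
    t = np.unique(np.asarray(list(detection_times), dtype=int))
    if len(t) == 0:
        return ActivityMetrics(individual_id, 0, 0, 0)
    return ActivityMetrics(
        individual_id=individual_id,
        apparent_intensity_s=int(len(t)),
        estimated_intensity_min=int(len(np.unique(t // 60))),
        total_activity_period_s=int(t[-1] - t[0]),
    )


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def concentration(angles) -> float:
    """Mean resultant length of the angles (1 - circular variance), in [0, 1]."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("concentration requires at least one angle")
    return float(np.hypot(np.cos(a).mean(), np.sin(a).mean()))


def mean_direction(angles) -> float:
    """Direction of the resultant vector of the angles."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("mean_direction requires at least one angle")
    return float(math.atan2(np.sin(a).sum(), np.cos(a).sum()))


def angular_dispersion(angles, mu: float) -> np.ndarray:
    """Circular distances pi - |pi - |theta - mu|| of angles to a direction."""
    d = np.abs(np.asarray(angles, dtype=float) - mu) % (2.0 * math.pi)
    return math.pi - np.abs(math.pi - d)


def _kruskal_h(values: np.ndarray, group_sizes) -> float:
    """Tie-corrected Kruskal-Wallis H for groups laid out contiguously."""
    n = len(values)
    ranks = rankdata(values)
    h = 0.0
    start = 0
    for size in group_sizes:
        h += ranks[start : start + size].sum() ** 2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def _check_two_groups(labels: dict):
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError(f"exactly two ground types required, got {groups}")
    return groups


def wallraff_statistic(angles_by_individual: dict, labels: dict, pool: str = "ground_type") -> float:
    """Wallraff rank test statistic for angular dispersion between two groups.

    Each ground type's mean direction is computed over its pooled angles
    (``pool="ground_type"``, default) or per individual (``pool="individual"``);
    every angle's circular distance to the relevant mean direction is ranked
    across both groups and the Kruskal-Wallis H between the ground types is
    returned.
    """
    groups = _check_two_groups(labels)
    dispersions = []
    sizes = []
    for g in groups:
        ids = [i for i in angles_by_individual if labels[i] == g]
        pooled = np.concatenate([np.asarray(angles_by_individual[i], float) for i in ids]) if ids else np.array([])
        if pooled.size == 0:
            raise ValueError(f"ground type {g!r} has no angles")
        if pool == "ground_type":
            mu = mean_direction(pooled)
            d = angular_dispersion(pooled, mu)
        elif pool == "individual":
            d = np.concatenate(
                [
                    angular_dispersion(angles_by_individual[i], mean_direction(angles_by_individual[i]))
                    for i in ids
                ]
            )
        else:
            raise ValueError("pool must be 'ground_type' or 'individual'")
        dispersions.append(d)
        sizes.append(len(d))
    return float(_kruskal_h(np.concatenate(dispersions), sizes))


def randomization_test(
    angles_by_individual: dict,
    labels: dict,
    n_perm: int = 1000,
    seed=None,
    pool: str = "ground_type",
) -> ConcentrationResult:
    """Permute individuals between ground types to calibrate the Wallraff statistic.

    Each individual's full angle set moves as a block; group sizes are
    preserved. The p-value uses the add-one Monte-Carlo correction
    ``(1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    groups = _check_two_groups(labels)
    ids = sorted(angles_by_individual)
    label_arr = np.array([labels[i] == groups[1] for i in ids])  # True = group 2
    n2 = int(label_arr.sum())
    if n2 == 0 or n2 == len(ids):
        raise ValueError("each ground type needs at least one individual")

    observed = wallraff_statistic(angles_by_individual, labels, pool=pool)

    n_distinct = math.comb(len(ids), n2)
    if n_distinct < n_perm:
        warnings.warn(
            f"only {n_distinct} distinct label permutations exist; sampling with replacement",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    # flat layout for fast permutation evaluation
    angle_arrays = [np.asarray(angles_by_individual[i], float) for i in ids]
    flat = np.concatenate(angle_arrays)
    owner = np.repeat(np.arange(len(ids)), [len(a) for a in angle_arrays])
    cos_by_ind = np.array([np.cos(a).sum() for a in angle_arrays])
    sin_by_ind = np.array([np.sin(a).sum() for a in angle_arrays])

    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(ids))
        in_g2 = np.zeros(len(ids), dtype=bool)
        in_g2[perm[:n2]] = True
        if pool == "ground_type":
            mus = np.empty(len(ids))
            for flag in (False, True):
                sel = in_g2 == flag
                mus[sel] = math.atan2(sin_by_ind[sel].sum(), cos_by_ind[sel].sum())
            d = math.pi - np.abs(math.pi - (np.abs(flat - mus[owner]) % (2.0 * math.pi)))
        else:
            per_ind_mu = np.array([mean_direction(a) for a in angle_arrays])
            d = math.pi - np.abs(math.pi - (np.abs(flat - per_ind_mu[owner]) % (2.0 * math.pi)))
        mask2 = in_g2[owner]
        stat = _kruskal_h(
            np.concatenate([d[~mask2], d[mask2]]), [int((~mask2).sum()), int(mask2.sum())]
        )
        if stat >= observed:
            count_ge += 1
    p = (1.0 + count_ge) / (1.0 + n_perm)

    per_ind = {i: concentration(angles_by_individual[i]) for i in ids if len(np.atleast_1d(angles_by_individual[i]))}
    group_means = {
        g: float(np.mean([per_ind[i] for i in per_ind if labels[i] == g])) for g in groups
    }
    return ConcentrationResult(
        per_individual=per_ind,
        group_means=group_means,
        statistic=observed,
        p_value=float(p),
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# distance (speed) comparison
# ---------------------------------------------------------------------------

def fit_distance_model(
    distances_by_individual: dict,
    labels: dict,
    numerator: str = "bare_soil",
    denominator: str = "residues",
) -> SlowdownResult:
    """Mixed model sqrt(distance_px) ~ ground_type + (1 | individual), REML.

    Predicted per-ground-type distances are the squared predicted means of
    sqrt(distance); the slowdown ratio divides the ``numerator`` ground
    type's prediction by the ``denominator``'s (at fixed tau this is the
    speed ratio). Falls back to the two sorted group labels when the named
    ones are absent.
    """
    import statsmodels.formula.api as smf

    groups = _check_two_groups(labels)
    counts = {g: sum(1 for i in distances_by_individual if labels[i] == g) for g in groups}
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 individuals per ground type for a mixed model, got {counts}")

    rows = []
    for ind, dists in distances_by_individual.items():
        for d in np.asarray(dists, float):
            rows.append((ind, labels[ind], math.sqrt(d)))
    df = pd.DataFrame(rows, columns=["individual", "ground_type", "sqrt_dist"])

    ref = numerator if numerator in groups else groups[0]
    other = [g for g in groups if g != ref][0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            f"sqrt_dist ~ C(ground_type, Treatment('{ref}'))", df, groups=df["individual"]
        )
        # Powell copes with the zero-variance boundary of the random intercept,
        # where the default gradient optimizers can stall far from the optimum.
        fit = model.fit(reml=True, method="powell")
        if not fit.converged or not np.isfinite(fit.params.iloc[:2]).all():
            fit = model.fit(reml=True, method="lbfgs")
    coef_name = f"C(ground_type, Treatment('{ref}'))[T.{other}]"
    intercept = float(fit.params["Intercept"])
    effect = float(fit.params[coef_name])
    pred_sqrt = {ref: intercept, other: intercept + effect}
    pred_dist = {g: v**2 for g, v in pred_sqrt.items()}
    num = numerator if numerator in pred_dist else groups[0]
    den = denominator if denominator in pred_dist else groups[1]
    return SlowdownResult(
        fixed_effects={"Intercept": intercept, coef_name: effect},
        predicted_distance_px=pred_dist,
        ratio=pred_dist[num] / pred_dist[den],
        p_value=float(fit.pvalues[coef_name]),
        n_obs=len(df),
        n_individuals=counts,
    )


def eligibility_filter(
    values_by_individual: dict,
    labels: dict,
    min_individuals: int = 10,
    min_records: int = 10,
):
    """Drop data-poor individuals; decide whether a procedure is analyzable.

    Individuals with fewer than ``min_records`` values are dropped first;
    the procedure is eligible iff both ground types retain at least
    ``min_individuals`` individuals.
    """
    filtered = {
        i: np.asarray(v, float)
        for i, v in values_by_individual.items()
        if len(np.atleast_1d(v)) >= min_records
    }
    counts: dict = {}
    for i in filtered:
        counts[labels[i]] = counts.get(labels[i], 0) + 1
    groups = sorted(set(labels.values()))
    eligible = len(groups) == 2 and all(counts.get(g, 0) >= min_individuals for g in groups)
    return eligible, filtered


# ---------------------------------------------------------------------------
# the procedure grid
# ---------------------------------------------------------------------------

JUNCTION_GAPS_S = (10, 30, 60, 300)
REDISC_STEPS_S = (1, 5, 10, 20, 30, 40, 50, 60)


def default_distance_grid(d_g_px: float = 50.0) -> list:
    """4 junction gaps x 8 rediscretizations x 2 interpolation settings."""
    return [
        ProcedureConfig(t_g_s=tg, d_g_px=d_g_px, redisc_s=tau, interpolate=interp)
        for tg, tau, interp in itertools.product(JUNCTION_GAPS_S, REDISC_STEPS_S, (False, True))
    ]


def default_angle_grid(d_g_px: float = 50.0) -> list:
    """Angles: single junction gap (10 s), no interpolation, 8 rediscretizations."""
    return [
        ProcedureConfig(t_g_s=10, d_g_px=d_g_px, redisc_s=tau, interpolate=False)
        for tau in REDISC_STEPS_S
    ]


def _sample_for_procedure(trajs_by_individual, labels, geom, proc, cache) -> MovementSample:
    """Junction -> edge removal -> (interpolation) -> rediscretization, per individual."""
    dists: dict = {}
    angles: dict = {}
    for ind, trajs in trajs_by_individual.items():
        key = (ind, proc.t_g_s)
        if key not in cache:
            joined = join_trajectories(trajs, proc.t_g_s, proc.d_g_px)
            cache[key] = remove_edge_points(joined, geom)
        ind_dists = []
        ind_angles = []
        # segments and angles are computed per trajectory so that neither
        # straddles a trajectory boundary
        for t in cache[key]:
            segs_t = rediscretize(t, proc.redisc_s, interpolate_flag=proc.interpolate)
            ind_dists.append(compute_distances(segs_t))
            if not proc.interpolate:
                ind_angles.extend(a.value_rad for a in compute_turning_angles(segs_t))
        dists[ind] = np.concatenate(ind_dists) if ind_dists else np.array([])
        angles[ind] = np.asarray(ind_angles, float)
    return MovementSample(procedure=proc, distances_px=dists, turning_angles_rad=angles, labels=dict(labels))


def run_procedure_grid(
    trajs_by_individual: dict,
    labels: dict,
    geom: ArenaGeometry,
    distance_grid: list | None = None,
    angle_grid: list | None = None,
    min_individuals: int = 10,
    min_records: int = 10,
    n_permutations: int = 1000,
    seed=0,
    numerator: str = "bare_soil",
    denominator: str = "residues",
) -> pd.DataFrame:
    """Run every procedure; one row per procedure, eligible or not.

    Distance procedures fit the mixed model on sqrt(distance); angle
    procedures (no interpolation, junction fixed at 10 s) run the
    concentration comparison with the Wallraff randomization test. Errors in
    one procedure are recorded in its row and never abort the grid.
    """
    if distance_grid is None:
        distance_grid = default_distance_grid()
    if angle_grid is None:
        angle_grid = default_angle_grid()
    groups = sorted(set(labels.values()))
    cache: dict = {}
    ss = np.random.SeedSequence(seed)
    angle_seeds = ss.spawn(len(angle_grid))
    rows = []

    def base_row(kind, proc):
        return {
            "kind": kind,
            "t_g_s": proc.t_g_s,
            "redisc_s": proc.redisc_s,
            "interpolate": proc.interpolate,
            "eligible": False,
            "statistic": np.nan,
            "ratio": np.nan,
            "p_value": np.nan,
            "error": "",
        }

    for proc in distance_grid:
        row = base_row("distance", proc)
        try:
            sample = _sample_for_procedure(trajs_by_individual, labels, geom, proc, cache)
            eligible, filtered = eligibility_filter(
                sample.distances_px, labels, min_individuals, min_records
            )
            for g in groups:
                ids = [i for i in filtered if labels[i] == g]
                row[f"n_individuals_{g}"] = len(ids)
                row[f"n_records_{g}"] = int(sum(len(filtered[i]) for i in ids))
                if ids:
                    px_s = np.concatenate([filtered[i] for i in ids])
                    row[f"mean_speed_cm_s_{g}"] = float(
                        px_s.mean() / (proc.redisc_s * geom.px_per_cm)
                    )
            row["eligible"] = bool(eligible)
            if eligible:
                res = fit_distance_model(filtered, labels, numerator, denominator)
                row["ratio"] = res.ratio
                row["p_value"] = res.p_value
        except Exception as exc:  # noqa: BLE001 - per-procedure isolation
            row["error"] = str(exc)
        rows.append(row)

    for proc, aseed in zip(angle_grid, angle_seeds):
        row = base_row("angle", proc)
        try:
            sample = _sample_for_procedure(trajs_by_individual, labels, geom, proc, cache)
            eligible, filtered = eligibility_filter(
                sample.turning_angles_rad, labels, min_individuals, min_records
            )
            for g in groups:
                ids = [i for i in filtered if labels[i] == g]
                row[f"n_individuals_{g}"] = len(ids)
                row[f"n_records_{g}"] = int(sum(len(filtered[i]) for i in ids))
            row["eligible"] = bool(eligible)
            if eligible:
                res = randomization_test(filtered, labels, n_perm=n_permutations, seed=aseed)
                row["statistic"] = res.statistic
                row["p_value"] = res.p_value
                for g, m in res.group_means.items():
                    row[f"concentration_{g}"] = m
        except Exception as exc:  # noqa: BLE001
            row["error"] = str(exc)
        rows.append(row)

    return pd.DataFrame(rows)
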