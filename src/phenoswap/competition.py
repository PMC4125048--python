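"""Serial-transfer competition: simulation and selection-coefficient inference.

Two strains are mixed 1:1 in logarithmic phase, grown to stationary phase,
and repeatedly diluted (e.g. 1:1000) into fresh medium; one strain carries a
GFP label so its fraction can be counted by flow cytometry at each
stationary phase. Under a constant per-generation selection coefficient s
(the natural-log fitness advantage of the focal strain), the log-odds of the
focal fraction is linear in cumulative generations:

    logit(p_T) = logit(p_0) + s · T

with T advancing by log2(dilution) ≈ 10 generations per 1:1000 cycle. The
estimator is the least-squares slope of logit(observed fraction) versus
cumulative generations, with a Student-t confidence interval from the
regression standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "CompetitionParams",
    "FractionTrajectory",
    "SelectionEstimate",
    "generations_per_cycle",
    "simulate_serial_transfer",
    "estimate_selection_coefficient",
    "estimate_from_table",
    "generations_to_threshold",
    "pooled_selection_from_orientations",
]


def generations_per_cycle(dilution: float) -> float:
    """Doublings needed to regrow a ``dilution``-fold dilution to the same
    stationary density: log2(dilution). A 1:1000 cycle is ≈ 9.97 ≈ 10
    generations."""
    if dilution <= 1:
        raise ValueError("dilution must exceed 1")
    return math.log2(dilution)


@dataclass(frozen=True)
class CompetitionParams:
    """Design of a serial-transfer competition experiment.

    ``s`` is the per-generation natural-log fitness advantage of the focal
    strain; ``pre_cycle_generations`` is the initial outgrowth from the
    logarithmic 1:1 mix to the first stationary sample (8 doublings by
    default, so that 8 + 7·log2(1000) ≈ 78 generations span the default
    seven-cycle experiment). ``events_per_sample`` is the number of
    flow-cytometry events counted per sample; None disables counting noise
    (the observed fraction then equals the model fraction).
    """

    s: float
    p0: float = 0.5
    dilution: float = 1000.0
    cycles: int = 7
    pre_cycle_generations: float = 8.0
    events_per_sample: int | None = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be strictly between 0 and 1")
        if self.dilution <= 1:
            raise ValueError("dilution must exceed 1")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if self.events_per_sample is not None and self.events_per_sample < 1:
            raise ValueError("events_per_sample must be >= 1")

    def sampling_generations(self) -> np.ndarray:
        """Cumulative generations at each sampling point: the initial mix,
        then every stationary phase (outgrowth + one per dilution cycle)."""
        g = generations_per_cycle(self.dilution)
        return np.concatenate(
            [[0.0], self.pre_cycle_generations + g * np.arange(self.cycles + 1)]
        )


@dataclass
class FractionTrajectory:
    """Focal-strain fraction versus cumulative generations.

    ``p_true`` is the model fraction, ``p_obs`` the event-count estimate;
    ``counts`` holds the focal event counts (None when counting noise is
    disabled, in which case ``p_obs == p_true``).
    """

    generations: np.ndarray
    p_true: np.ndarray
    p_obs: np.ndarray
    counts: np.ndarray | None = None
    total_events: int | None = None

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.p_true = np.asarray(self.p_true, dtype=float)
        self.p_obs = np.asarray(self.p_obs, dtype=float)
        if np.any(np.diff(self.generations) < 0):
            raise ValueError("generations must be non-decreasing")
        for p in (self.p_true, self.p_obs):
            if np.any((p < 0) | (p > 1)):
                raise ValueError("fractions must lie in [0, 1]")


def simulate_serial_transfer(params: CompetitionParams) -> FractionTrajectory:
    """Simulate a serial-transfer competition under logit-linear dynamics.

    The focal fraction follows logit(p_T) = logit(p0) + s·T at each sampling
    point; the observed fraction is a binomial draw of
    ``events_per_sample`` events (reproducible under ``seed``).
    """
    gens = params.sampling_generations()
    p_true = expit(logit(params.p0) + params.s * gens)
    if params.events_per_sample is None:
        return FractionTrajectory(gens, p_true, p_true.copy())
    rng = np.random.default_rng(params.seed)
    counts = rng.binomial(params.events_per_sample, p_true)
    p_obs = counts / params.events_per_sample
    return FractionTrajectory(gens, p_true, p_obs, counts, params.events_per_sample)


@dataclass(frozen=True)
class SelectionEstimate:
    """Least-squares selection-coefficient estimate with its 95% CI."""

    s_hat: float
    ci: tuple[float, float]
    stderr: float
    intercept: float
    n_points: int
    corrected_points: tuple[int, ...] = field(default=())  # continuity-corrected


def estimate_selection_coefficient(
    traj: FractionTrajectory, level: float = 0.95
) -> SelectionEstimate:
    """Estimate s as the OLS slope of logit(observed fraction) vs generations.

    Samples at an observed fraction of exactly 0 or 1 cannot enter the logit
    directly; when event counts are available they are continuity-corrected
    (half an event added to each class) and flagged, otherwise they are
    dropped. The confidence interval uses the Student-t quantile on the
    regression standard error.
    """
    p = np.array(traj.p_obs, dtype=float)
    corrected: list[int] = []
    boundary = (p <= 0.0) | (p >= 1.0)
    if traj.counts is not None and traj.total_events:
        n = traj.total_events
        for i in np.nonzero(boundary)[0]:
            p[i] = (traj.counts[i] + 0.5) / (n + 1.0)
            corrected.append(int(i))
        usable = np.ones_like(p, dtype=bool)
    else:
        usable = ~boundary
    x = traj.generations[usable]
    y = logit(p[usable])
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("need at least two sampling points with 0 < p < 1")
    res = stats.linregress(x, y)
    df = len(x) - 2
    if df > 0:
        half = stats.t.ppf(0.5 + level / 2.0, df) * res.stderr
    else:
        half = float("inf")  # two points fix the line; no error estimate
    return SelectionEstimate(
        s_hat=float(res.slope),
        ci=(float(res.slope - half), float(res.slope + half)),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
        n_points=int(len(x)),
        corrected_points=tuple(corrected),
    )


def estimate_from_table(
    table: pd.DataFrame,
    dilution: float = 1000.0,
    pre_cycle_generations: float = 8.0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Fit s per experiment from a long table of flow-count samples.

    Expected columns: ``experiment``, ``cycle`` (0 = initial mix, 1 = after
    the first outgrowth, then one per dilution cycle), ``focal_events``,
    ``total_events``, and optionally ``generations`` (derived from the cycle
    bookkeeping when absent). Returns one row per experiment with s_hat, CI
    bounds, standard error, and the number of continuity-corrected points.
    """
    required = {"experiment", "cycle", "focal_events", "total_events"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"fractions table missing columns: {sorted(missing)}")
    rows = []
    for exp, grp in table.groupby("experiment", sort=False):
        grp = grp.sort_values("cycle")
        if "generations" in grp.columns:
            gens = grp["generations"].to_numpy(dtype=float)
        else:
            cyc = grp["cycle"].to_numpy(dtype=float)
            gens = np.where(
                cyc <= 0,
                0.0,
                pre_cycle_generations + (cyc - 1) * generations_per_cycle(dilution),
            )
        total = grp["total_events"].to_numpy(dtype=float)
        counts = grp["focal_events"].to_numpy(dtype=float)
        n_events = int(total[0])
        if np.any(total != total[0]):
            # heterogeneous event counts: fall back to per-row correction
            n_events = None
        traj = FractionTrajectory(
            generations=gens,
            p_true=counts / total,
            p_obs=counts / total,
            counts=counts if n_events else None,
            total_events=n_events,
        )
        est = estimate_selection_coefficient(traj, level=level)
        rows.append(
            {
                "experiment": exp,
                "s_hat": est.s_hat,
                "ci_low": est.ci[0],
                "ci_high": est.ci[1],
                "stderr": est.stderr,
                "n_points": est.n_points,
                "n_corrected": len(est.corrected_points),
            }
        )
    return pd.DataFrame(rows)


def generations_to_threshold(s: float, p0: float, threshold: float) -> float:
    """Generations for the focal fraction to move from p0 to ``threshold``
    under selection s: (logit(threshold) − logit(p0)) / s.

    Returns inf for s = 0 (the threshold is unreachable under neutrality);
    raises when the threshold lies on the wrong side of p0 for the sign
    of s.
    """
    if not 0.0 < p0 < 1.0 or not 0.0 < threshold < 1.0:
        raise ValueError("p0 and threshold must be strictly inside (0, 1)")
    if threshold == p0:
        return 0.0
    if s == 0.0:
        return math.inf
    t = (logit(threshold) - logit(p0)) / s
    if t < 0:
        raise ValueError(
            f"threshold {threshold} is on the wrong side of p0={p0} for s={s}"
        )
    return float(t)


def pooled_selection_from_orientations(
    s_gfp_focal_labeled: float, s_gfp_rival_labeled: float
) -> float:
    """Combine the two mutual-labeling orientations into one estimate of s.

    Both orientations are fitted on the GFP-positive fraction. With the
    label on the focal strain the GFP log-odds slope is s minus any label
    cost; with the label on the rival it is −s minus the cost. The
    half-difference cancels an additive label-cost term exactly.
    """
    return 0.5 * (s_gfp_focal_labeled - s_gfp_rival_labeled)
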