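"""Ground-truth-known synthetic inputs for every analysis module.

Growth curves are generated from a smooth specific-growth-rate schedule:
the rate rises sigmoidally from 0 to µ1 at the end of the lag phase,
holds an exactly log-linear exponential phase, and falls sigmoidally to 0
when the culture has expanded to its capacity (optionally followed by a
shoulder and a second, slower phase — the diauxic pattern of yeast on
fermentable carbon). Integrating the schedule gives a closed softplus form
for ln OD, so the true µmax, lag (tangent intercept), and rate-threshold
crossing times are all exactly defined — which is what makes parameter-
recovery tests meaningful.

The measured signal emulates a plate reader: a cubic saturation of the true
OD, an additive blank level, and additive Gaussian noise, sampled every
10 minutes. Competition tables and Ct/band-intensity fixtures likewise
carry known ground truth. Every generator is deterministic under its seed,
and plate wells draw from per-well substreams so adding wells never
perturbs existing ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .competition import CompetitionParams, simulate_serial_transfer
from .plate_io import WellSeries, write_plate_timeseries

__all__ = [
    "GrowthModelParams",
    "NoiseModel",
    "PlateSim",
    "log_od_true",
    "growth_rate_true",
    "generate_growth_curve",
    "generate_blank_well",
    "generate_plate",
    "generate_random_plate",
    "generate_competition_experiment",
    "generate_quant_fixture",
    "well_index",
]

# Default study conditions for the emulated micro-cultivation format:
# 150 µl cultures inoculated with ~10^6 cells (≈ OD600 0.45 for diploid
# cells at ~1.5e7 cells/ml per OD unit), saturating
# around 6 corrected-OD units, read every 10 min.
DEFAULT_OD0 = 0.45
DEFAULT_CAPACITY = 6.0
DEFAULT_NONLIN = 0.005
DEFAULT_BLANK = 0.08
DEFAULT_SIGMA = 0.005


@dataclass(frozen=True)
class GrowthModelParams:
    """True growth-law parameters of one well.

    ``od0`` is the initial (corrected-scale) OD, ``lag`` the hours before
    exponential growth, ``mu1`` the exponential-phase rate (h⁻¹, natural
    log), ``capacity1`` the OD plateau of phase one. A second phase
    (``mu2`` toward ``capacity2`` after a ``shoulder``-hour pause) models a
    diauxic shift. ``ramp`` is the width (hours) of the sigmoidal phase
    transitions.
    """

    od0: float
    lag: float
    mu1: float
    capacity1: float
    mu2: float | None = None
    capacity2: float | None = None
    shoulder: float = 0.0
    ramp: float = 0.1

    def __post_init__(self) -> None:
        if self.od0 <= 0 or self.mu1 <= 0:
            raise ValueError("od0 and mu1 must be positive")
        if self.capacity1 <= self.od0:
            raise ValueError("capacity1 must exceed od0")
        if self.lag < 0 or self.shoulder < 0 or self.ramp <= 0:
            raise ValueError("lag, shoulder must be >= 0 and ramp > 0")
        if (self.mu2 is None) != (self.capacity2 is None):
            raise ValueError("mu2 and capacity2 must be given together")
        if self.mu2 is not None:
            if self.mu2 <= 0 or self.capacity2 <= self.capacity1:
                raise ValueError("phase two requires mu2 > 0, capacity2 > capacity1")

    def phase_times(self) -> tuple[float, float, float | None, float | None]:
        """Rate-schedule breakpoints (phase-1 on/off, phase-2 on/off)."""
        a = self.lag
        b = a + np.log(self.capacity1 / self.od0) / self.mu1
        if self.mu2 is None:
            return a, b, None, None
        c = b + self.shoulder
        d = c + np.log(self.capacity2 / self.capacity1) / self.mu2
        return a, b, c, d


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(x / 2.0))


def log_od_true(model: GrowthModelParams, t: np.ndarray) -> np.ndarray:
    """Noise-free ln OD at times ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    a, b, c, d = model.phase_times()
    w = model.ramp
    y = np.log(model.od0) + model.mu1 * w * (
        _softplus((t - a) / w) - _softplus((t - b) / w)
    )
    if c is not None:
        y = y + model.mu2 * w * (_softplus((t - c) / w) - _softplus((t - d) / w))
    return y


def growth_rate_true(model: GrowthModelParams, t: np.ndarray) -> np.ndarray:
    """Noise-free instantaneous d(ln OD)/dt at times ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    a, b, c, d = model.phase_times()
    w = model.ramp
    r = model.mu1 * (_sigmoid((t - a) / w) - _sigmoid((t - b) / w))
    if c is not None:
        r = r + model.mu2 * (_sigmoid((t - c) / w) - _sigmoid((t - d) / w))
    return r


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model of the emulated plate reader.

    measured = blank_level + distort(true OD) + N(0, sigma_od), with the
    detector saturation distort(od) = od − nonlin_coeff·od³ (monotone over
    the generated range, enforced).
    """

    sigma_od: float = DEFAULT_SIGMA
    nonlin_coeff: float = DEFAULT_NONLIN
    blank_level: float = DEFAULT_BLANK
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_od < 0 or self.nonlin_coeff < 0:
            raise ValueError("sigma_od and nonlin_coeff must be >= 0")

    def distort(self, od: np.ndarray) -> np.ndarray:
        od = np.asarray(od, dtype=float)
        if self.nonlin_coeff > 0:
            od_max = float(np.max(od, initial=0.0))
            if od_max >= np.sqrt(1.0 / (3.0 * self.nonlin_coeff)):
                raise ValueError(
                    "detector distortion not monotone over generated OD range "
                    f"(max OD {od_max:.3g}, nonlin_coeff {self.nonlin_coeff})"
                )
        return od - self.nonlin_coeff * od**3


def generate_growth_curve(
    model: GrowthModelParams,
    noise: NoiseModel,
    duration_h: float,
    interval_min: float = 10.0,
    well_id: str = "A1",
    strain: str = "",
    condition: str = "",
    replicate: int = 1,
    rng: np.random.Generator | None = None,
) -> WellSeries:
    """One synthetic well sampled every ``interval_min`` minutes."""
    if duration_h < 8.0:
        raise ValueError("duration must cover at least two 4-h analysis windows")
    dt = interval_min / 60.0
    times = np.arange(0.0, duration_h + dt / 2, dt)
    od_true = np.exp(log_od_true(model, times))
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    measured = (
        noise.blank_level
        + noise.distort(od_true)
        + rng.normal(0.0, noise.sigma_od, size=times.shape)
    )
    return WellSeries(
        well_id=well_id,
        times=times,
        od_raw=measured,
        strain=strain,
        condition=condition,
        replicate=replicate,
        is_blank=False,
    )


def generate_blank_well(
    noise: NoiseModel,
    duration_h: float,
    interval_min: float = 10.0,
    well_id: str = "H12",
    rng: np.random.Generator | None = None,
) -> WellSeries:
    """A medium-only well: blank level plus measurement noise."""
    dt = interval_min / 60.0
    times = np.arange(0.0, duration_h + dt / 2, dt)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    measured = noise.blank_level + rng.normal(0.0, noise.sigma_od, size=times.shape)
    return WellSeries(
        well_id=well_id,
        times=times,
        od_raw=measured,
        strain="",
        condition="blank",
        replicate=1,
        is_blank=True,
    )


def well_index(well_id: str) -> int:
    """0-based plate position of a coordinate like ``C7`` (row-major, 12 columns)."""
    m = re.fullmatch(r"([A-Ha-h])(\d{1,2})", well_id.strip())
    if not m:
        raise ValueError(f"not a 96-well coordinate: {well_id!r}")
    row = ord(m.group(1).upper()) - ord("A")
    col = int(m.group(2)) - 1
    if not 0 <= col < 12:
        raise ValueError(f"column out of range in {well_id!r}")
    return row * 12 + col


@dataclass
class PlateSim:
    """A generated plate: raw wells, the plate map, and the ground truth."""

    wells: list[WellSeries]
    plate_map: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write plate.tsv / plate_map.tsv / truth.tsv under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "plate": out / "plate.tsv",
            "map": out / "plate_map.tsv",
            "truth": out / "truth.tsv",
        }
        write_plate_timeseries(self.wells, paths["plate"], paths["map"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_plate(
    layout: pd.DataFrame,
    params_by_well: Mapping[str, GrowthModelParams],
    noise: NoiseModel,
    duration_h: float,
    interval_min: float = 10.0,
    seed: int = 0,
) -> PlateSim:
    """Generate a full plate from a layout and per-well true parameters.

    ``layout`` needs columns well, strain, condition, replicate, is_blank;
    every non-blank well must appear in ``params_by_well`` and there must be
    at least one blank. Each well uses the substream ``(seed, plate
    position)``, so extending the layout leaves existing wells bit-identical.
    """
    required = {"well", "strain", "condition", "replicate", "is_blank"}
    missing = required - set(layout.columns)
    if missing:
        raise ValueError(f"layout missing columns: {sorted(missing)}")
    if len(layout) > 96:
        raise ValueError("layout exceeds 96 wells")
    if layout["well"].duplicated().any():
        raise ValueError("duplicate wells in layout")
    if not layout["is_blank"].astype(bool).any():
        raise ValueError("layout needs at least one blank well")

    wells: list[WellSeries] = []
    truth_rows = []
    for row in layout.itertuples(index=False):
        rng = np.random.default_rng([int(seed), well_index(row.well)])
        if bool(row.is_blank):
            w = generate_blank_well(
                noise, duration_h, interval_min, well_id=row.well, rng=rng
            )
            w.strain = str(row.strain)
            w.condition = str(row.condition)
            w.replicate = int(row.replicate)
            wells.append(w)
            continue
        try:
            model = params_by_well[row.well]
        except KeyError:
            raise ValueError(f"no growth parameters for non-blank well {row.well!r}")
        wells.append(
            generate_growth_curve(
                model,
                noise,
                duration_h,
                interval_min,
                well_id=row.well,
                strain=str(row.strain),
                condition=str(row.condition),
                replicate=int(row.replicate),
                rng=rng,
            )
        )
        truth_rows.append(
            {
                "well": row.well,
                "strain": row.strain,
                "condition": row.condition,
                "replicate": int(row.replicate),
                "od0": model.od0,
                "lag": model.lag,
                "mu1": model.mu1,
                "capacity1": model.capacity1,
                "mu2": model.mu2,
                "capacity2": model.capacity2,
                "shoulder": model.shoulder,
            }
        )
    return PlateSim(wells=wells, plate_map=layout.copy(), truth=pd.DataFrame(truth_rows))


def generate_random_plate(
    seed: int,
    n_strains: int = 2,
    n_replicates: int = 3,
    n_conditions: int = 15,
    n_blanks: int = 6,
    mu_range: tuple[float, float] = (0.1, 0.5),
    lag_range: tuple[float, float] = (0.0, 5.0),
    od0: float = DEFAULT_OD0,
    capacity: float = DEFAULT_CAPACITY,
    noise: NoiseModel | None = None,
    duration_h: float = 48.0,
    interval_min: float = 10.0,
) -> PlateSim:
    """A full random phenotyping plate (default: 2 strains × 3 replicates ×
    15 conditions plus 6 blanks = 96 wells) with per-group true µ and lag
    drawn uniformly from the given ranges."""
    n_samples = n_strains * n_replicates * n_conditions
    if n_samples + n_blanks > 96:
        raise ValueError("layout exceeds 96 wells")
    if noise is None:
        noise = NoiseModel(seed=seed)
    draw = np.random.default_rng([int(seed), 10_007])
    coords = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    rows, params = [], {}
    i = 0
    for strain in (f"strain{s+1}" for s in range(n_strains)):
        for cond in (f"cond{c+1:02d}" for c in range(n_conditions)):
            model = GrowthModelParams(
                od0=od0,
                lag=float(draw.uniform(*lag_range)),
                mu1=float(draw.uniform(*mu_range)),
                capacity1=capacity,
            )
            for rep in range(1, n_replicates + 1):
                well = coords[i]
                i += 1
                rows.append(
                    {
                        "well": well,
                        "strain": strain,
                        "condition": cond,
                        "replicate": rep,
                        "is_blank": False,
                    }
                )
                params[well] = model
    for b in range(n_blanks):
        rows.append(
            {
                "well": coords[i],
                "strain": "",
                "condition": "blank",
                "replicate": b + 1,
                "is_blank": True,
            }
        )
        i += 1
    layout = pd.DataFrame(rows)
    return generate_plate(layout, params, noise, duration_h, interval_min, seed=seed)


def generate_competition_experiment(
    params: CompetitionParams,
    label_on: str = "focal",
    label_cost: float = 0.0,
    experiment: str = "exp1",
) -> pd.DataFrame:
    """A serial-transfer fractions table in the compete-fit input format.

    The table reports GFP-positive event counts. ``label_on`` selects which
    strain carries the GFP cassette; ``label_cost`` is an additive
    per-generation fitness cost of the label, borne by whichever strain is
    labeled (the bias the mutual-labeling design is meant to cancel).
    Orientation swap at zero cost complements the counts exactly under a
    matched seed.
    """
    if label_on not in ("focal", "rival"):
        raise ValueError("label_on must be 'focal' or 'rival'")
    if params.events_per_sample is None:
        raise ValueError("a fractions table requires counted events per sample")
    s_eff = params.s - label_cost if label_on == "focal" else params.s + label_cost
    traj = simulate_serial_transfer(replace(params, s=s_eff))
    n = params.events_per_sample
    gfp = traj.counts if label_on == "focal" else n - traj.counts
    return pd.DataFrame(
        {
            "experiment": experiment,
            "cycle": np.arange(len(traj.generations)),
            "generations": traj.generations,
            "focal_events": gfp,
            "total_events": n,
        }
    )


def generate_quant_fixture(
    design: Mapping[str, int],
    fold_changes: Mapping[str, Mapping[str, float]],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    intensity_noise_cv: float = 0.0,
    efficiency: float = 2.0,
) -> dict[str, pd.DataFrame]:
    """Ct and band-intensity tables with known true fold changes.

    ``design`` maps group label -> replicate count; ``fold_changes`` maps
    target -> {group: true fold change} (groups absent default to 1).
    Both tables share the sample/group structure: the qPCR table carries
    three reference genes (ACT1, CYC1, U6) per sample plus one Ct row per
    target, the Northern table one loading-control row (5S) plus one band
    row per target. Per-sample RNA-input offsets shift every Ct of a sample
    together (and scale every band of a sample together), so normalization
    must remove them — which is exactly what the analysis is tested on.
    """
    ref_base = {"ACT1": 17.5, "CYC1": 22.0, "U6": 20.5}
    target_base_ct = 24.0
    loading_base, band_base = 50.0, 100.0
    for target, per_group in fold_changes.items():
        for group, fold in per_group.items():
            if fold <= 0:
                raise ValueError(f"fold change for {target}/{group} must be positive")
    rng = np.random.default_rng(seed)
    qpcr_rows, northern_rows = [], []
    for group, n_rep in design.items():
        for rep in range(1, n_rep + 1):
            sample = f"{group}_{rep}"
            delta = float(rng.normal(0.0, 0.5))  # RNA input offset, cancels in ΔCt
            load_factor = float(np.exp(rng.normal(0.0, 0.3)))
            for ref, base in ref_base.items():
                qpcr_rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "assay": ref,
                        "role": "reference",
                        "value": base + delta + float(rng.normal(0.0, ct_noise_sd)),
                    }
                )
            northern_rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "assay": "5S",
                    "role": "loading",
                    "value": loading_base
                    * load_factor
                    * float(np.exp(rng.normal(0.0, intensity_noise_cv))),
                }
            )
            for target, per_group in fold_changes.items():
                fold = float(per_group.get(group, 1.0))
                qpcr_rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "assay": target,
                        "role": "target",
                        "value": target_base_ct
                        - np.log(fold) / np.log(efficiency)
                        + delta
                        + float(rng.normal(0.0, ct_noise_sd)),
                    }
                )
                northern_rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "assay": target,
                        "role": "target",
                        "value": band_base
                        * fold
                        * load_factor
                        * float(np.exp(rng.normal(0.0, intensity_noise_cv))),
                    }
                )
    return {"qpcr": pd.DataFrame(qpcr_rows), "northern": pd.DataFrame(northern_rows)}
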