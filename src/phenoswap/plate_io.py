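"""Plate-reader ingestion and optical-density conditioning.

Turbidity readings from a micro-cultivation run arrive as a wide delimited
table (one time column plus one column per well) together with a plate map
assigning each well a strain, condition, replicate number, or a blank role.
This module turns those files into per-well series and applies the standard
conditioning chain: blank subtraction, detector-nonlinearity and path-length
correction to 1-cm-equivalent OD, and natural-log transformation.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WellSeries",
    "CorrectedSeries",
    "CalibrationModel",
    "read_plate_timeseries",
    "write_plate_timeseries",
    "apply_blank",
    "calibrate_od",
]


@dataclass
class WellSeries:
    """One well's raw OD600 time course plus identity metadata.

    ``times`` are hours and must be strictly increasing; ``od_raw`` is the
    measured absorbance at 600 nm. A nominal sampling interval that varies by
    more than 1% across the series triggers a warning (readers occasionally
    drop or delay a cycle; downstream window arithmetic assumes a uniform
    grid).
    """

    well_id: str
    times: np.ndarray
    od_raw: np.ndarray
    strain: str = ""
    condition: str = ""
    replicate: int = 1
    is_blank: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od_raw = np.asarray(self.od_raw, dtype=float)
        if self.times.ndim != 1 or self.od_raw.ndim != 1:
            raise ValueError(f"well {self.well_id}: times and od_raw must be 1-D")
        if len(self.times) != len(self.od_raw) or len(self.times) < 2:
            raise ValueError(
                f"well {self.well_id}: times and od_raw must have equal length >= 2"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"well {self.well_id}: times are not strictly increasing")
        if not np.all(np.isfinite(self.od_raw)):
            raise ValueError(f"well {self.well_id}: od_raw contains non-finite values")
        dt = np.diff(self.times)
        if (dt.max() - dt.min()) > 0.01 * np.median(dt):
            warnings.warn(
                f"well {self.well_id}: sampling interval varies by more than 1%",
                stacklevel=2,
            )

    @property
    def interval(self) -> float:
        """Median sampling interval in hours."""
        return float(np.median(np.diff(self.times)))


@dataclass
class CorrectedSeries(WellSeries):
    """A :class:`WellSeries` plus corrected OD and its natural log.

    ``od_corr`` is blank-subtracted, nonlinearity- and path-length-corrected
    1-cm-equivalent OD; ``log_od`` is ``ln(od_corr)`` where ``od_corr > 0``
    and NaN elsewhere.
    """

    od_corr: np.ndarray = field(default=None)  # type: ignore[assignment]
    log_od: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        self.od_corr = np.asarray(self.od_corr, dtype=float)
        self.log_od = np.asarray(self.log_od, dtype=float)
        if len(self.od_corr) != len(self.times) or len(self.log_od) != len(self.times):
            raise ValueError(f"well {self.well_id}: corrected arrays mismatch times")


@dataclass(frozen=True)
class CalibrationModel:
    """Odd-power polynomial OD calibration plus path-length scaling.

    The detector response of a plate reader saturates at high cell density;
    over the working range this is well captured by an odd polynomial with a
    linear and a cubic term. Two modes are supported:

    ``"correct"``
        ``poly(od) = linear*od + cubic*od**3`` is applied directly to the
        blanked measurement (the conventional calibration-curve form).
    ``"invert"``
        ``poly`` describes the detector response (true OD -> measured OD) and
        the calibration numerically inverts it, which is exact rather than
        first-order when the distortion itself is ``od - c*od**3``.

    ``path_factor`` converts the well geometry to 1-cm-equivalent OD. The
    identity model (linear=1, cubic=0, path_factor=1) maps any OD to itself
    in both modes.
    """

    linear: float = 1.0
    cubic: float = 0.0
    path_factor: float = 1.0
    mode: str = "correct"

    def __post_init__(self) -> None:
        if self.mode not in ("correct", "invert"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        if self.path_factor <= 0:
            raise ValueError("path_factor must be positive")

    def polynomial(self, od: np.ndarray) -> np.ndarray:
        od = np.asarray(od, dtype=float)
        return self.linear * od + self.cubic * od**3

    def _poly_deriv(self, od: np.ndarray) -> np.ndarray:
        return self.linear + 3.0 * self.cubic * np.asarray(od, dtype=float) ** 2

    def is_monotone(self, lo: float, hi: float) -> bool:
        """True when the polynomial is strictly increasing on [lo, hi]."""
        # derivative linear + 3*cubic*x^2 is monotone in x^2, so the
        # extremes of |x| bound it
        edges = np.array([lo, hi, 0.0 if lo < 0 < hi else lo])
        return bool(np.all(self._poly_deriv(edges) > 0))

    def correct(self, od: np.ndarray) -> np.ndarray:
        """Map blanked measured OD to corrected 1-cm-equivalent OD."""
        od = np.asarray(od, dtype=float)
        if self.mode == "correct":
            return self.path_factor * self.polynomial(od)
        return self.path_factor * self._invert_polynomial(od)

    def _invert_polynomial(self, measured: np.ndarray) -> np.ndarray:
        # Newton iteration; the monotonicity precondition keeps the
        # derivative bounded away from zero over the calibrated range.
        x = np.array(measured, dtype=float) / max(self.linear, 1e-12)
        for _ in range(60):
            f = self.polynomial(x) - measured
            step = f / self._poly_deriv(x)
            x = x - step
            if np.all(np.abs(step) < 1e-13 * np.maximum(1.0, np.abs(x))):
                break
        return x


# ---------------------------------------------------------------------------
# file IO


_TIME_COL = re.compile(r"^\s*time\b|^\s*time[_\s(\[]", re.IGNORECASE)


def _time_unit_from_header(name: str) -> float:
    """Hours-per-unit factor declared in a time-column header."""
    tokens = re.split(r"[^a-z]+", name.lower())
    if any(t in ("min", "mins", "minute", "minutes") for t in tokens):
        return 1.0 / 60.0
    if any(t in ("h", "hr", "hrs", "hour", "hours") for t in tokens):
        return 1.0
    raise ValueError(
        f"time column {name!r} does not declare its unit "
        "(expected e.g. 'time_min' or 'time_h')"
    )


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y", "t"):
        return True
    if s in ("0", "false", "no", "n", "f", ""):
        return False
    raise ValueError(f"cannot interpret {value!r} as a blank flag")


def read_plate_map(path: str | Path) -> pd.DataFrame:
    """Read a plate map (columns well, strain, condition, replicate, is_blank)."""
    pm = pd.read_csv(path, sep=None, engine="python", dtype=str)
    pm.columns = [c.strip().lower() for c in pm.columns]
    required = {"well", "strain", "condition", "replicate", "is_blank"}
    missing = required - set(pm.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    if pm["well"].duplicated().any():
        dups = pm.loc[pm["well"].duplicated(), "well"].tolist()
        raise ValueError(f"duplicate well ids in plate map: {dups}")
    return pm


def read_plate_timeseries(
    path: str | Path, plate_map: str | Path | pd.DataFrame
) -> list[WellSeries]:
    """Read a wide plate-reader export into one :class:`WellSeries` per mapped well.

    The first column must be the time column with its unit declared in the
    header (minutes or hours); times are converted to hours. Data columns not
    assigned by the plate map are reported and skipped.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    # round_trip float parsing keeps written values bit-exact
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a time column plus at least one well")
    time_col = df.columns[0]
    if not _TIME_COL.search(str(time_col)):
        raise ValueError(f"{path}: first column {time_col!r} is not a time column")
    times = df[time_col].to_numpy(dtype=float) * _time_unit_from_header(str(time_col))
    if not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: time column {time_col!r} is not strictly increasing")

    data_cols = [str(c).strip() for c in df.columns[1:]]
    if len(set(data_cols)) != len(data_cols):
        raise ValueError(f"{path}: duplicate well columns in plate file")

    pm = plate_map if isinstance(plate_map, pd.DataFrame) else read_plate_map(plate_map)
    mapped = {str(r.well).strip(): r for r in pm.itertuples(index=False)}

    wells: list[WellSeries] = []
    for col, name in zip(df.columns[1:], data_cols):
        row = mapped.pop(name, None)
        if row is None:
            warnings.warn(f"data column {name!r} has no plate-map entry; skipped",
                          stacklevel=2)
            continue
        wells.append(
            WellSeries(
                well_id=name,
                times=times,
                od_raw=df[col].to_numpy(dtype=float),
                strain=str(row.strain),
                condition=str(row.condition),
                replicate=int(row.replicate),
                is_blank=_parse_bool(row.is_blank),
            )
        )
    for leftover in mapped:
        warnings.warn(f"plate-map well {leftover!r} not found in data columns",
                      stacklevel=2)
    return wells


def write_plate_timeseries(
    wells: Sequence[WellSeries],
    plate_path: str | Path,
    map_path: str | Path | None = None,
    time_unit: str = "min",
) -> None:
    """Write wells back to the wide plate format (and optionally a plate map)."""
    if not wells:
        raise ValueError("no wells to write")
    times = wells[0].times
    for w in wells[1:]:
        if len(w.times) != len(times) or not np.allclose(w.times, times):
            raise ValueError("all wells must share one time grid")
    if time_unit == "min":
        col, vals = "time_min", times * 60.0
    elif time_unit in ("h", "hour", "hours"):
        col, vals = "time_h", times
    else:
        raise ValueError(f"unknown time unit {time_unit!r}")
    out = pd.DataFrame({col: vals})
    for w in wells:
        out[w.well_id] = w.od_raw
    # 17 significant digits guarantee an exact binary round-trip
    out.to_csv(plate_path, sep="\t", index=False, float_format="%.17g")
    if map_path is not None:
        pd.DataFrame(
            {
                "well": [w.well_id for w in wells],
                "strain": [w.strain for w in wells],
                "condition": [w.condition for w in wells],
                "replicate": [w.replicate for w in wells],
                "is_blank": [w.is_blank for w in wells],
            }
        ).to_csv(map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# conditioning


def apply_blank(
    series: WellSeries,
    blanks: Iterable[WellSeries],
    policy: str = "per-timepoint-mean",
    floor: float = 1e-4,
) -> WellSeries:
    """Subtract the blank estimate from a well's raw OD.

    ``per-timepoint-mean`` averages the blank wells at each time point (robust
    to drift of the medium signal); ``scalar-mean`` subtracts the grand mean
    of all blank readings. Results below ``floor`` are clipped to it rather
    than dropped, so the time grid stays aligned; the number of clipped points
    is logged.
    """
    blanks = list(blanks)
    if not blanks:
        raise ValueError("blank subtraction requires at least one blank well")
    if policy == "per-timepoint-mean":
        for b in blanks:
            if len(b.od_raw) != len(series.od_raw):
                raise ValueError(
                    f"blank {b.well_id} length does not match well {series.well_id}"
                )
        estimate = np.mean([b.od_raw for b in blanks], axis=0)
    elif policy == "scalar-mean":
        estimate = float(np.mean(np.concatenate([b.od_raw for b in blanks])))
    else:
        raise ValueError(f"unknown blank policy {policy!r}")
    blanked = series.od_raw - estimate
    n_clipped = int(np.sum(blanked < floor))
    if n_clipped:
        logger.warning(
            "well %s: %d point(s) at or below the blank clipped to %.2g",
            series.well_id,
            n_clipped,
            floor,
        )
    return replace(series, od_raw=np.maximum(blanked, floor))


def calibrate_od(series: WellSeries, model: CalibrationModel) -> CorrectedSeries:
    """Apply nonlinearity and path-length correction, then ln-transform.

    Raises if the calibration polynomial is not monotone increasing over the
    observed OD range (a non-invertible calibration cannot be trusted).
    """
    lo = float(min(0.0, series.od_raw.min()))
    hi = float(series.od_raw.max())
    if not model.is_monotone(lo, hi):
        raise ValueError(
            f"calibration is not monotone over observed OD range [{lo:.3g}, {hi:.3g}]"
        )
    od_corr = model.correct(series.od_raw)
    with np.errstate(invalid="ignore", divide="ignore"):
        log_od = np.where(od_corr > 0, np.log(np.where(od_corr > 0, od_corr, 1.0)), np.nan)
    return CorrectedSeries(
        well_id=series.well_id,
        times=series.times,
        od_raw=series.od_raw,
        strain=series.strain,
        condition=series.condition,
        replicate=series.replicate,
        is_blank=series.is_blank,
        od_corr=od_corr,
        log_od=log_od,
    )
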