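"""Relative RNA quantification: Northern band ratios and multi-reference ΔΔCt.

Northern blots are quantified as band intensity over a loading control
(e.g. 5S rRNA); quantitative RT-PCR as efficiency^(−ΔΔCt) with ΔCt taken
against the arithmetic mean of several reference-gene Cts (equivalent to the
geometric mean of reference abundances). In both cases quantities are
expressed relative to the calibrator group (typically the parental wild-type
strain), whose mean relative quantity is 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RelativeQuantity",
    "northern_relative_quantity",
    "qpcr_relative_quantity",
    "northern_table",
    "qpcr_table",
    "group_summary",
]


@dataclass(frozen=True)
class RelativeQuantity:
    """A normalized abundance relative to the calibrator group mean."""

    sample: str
    target: str
    rq: float
    method: str  # "northern" or "qpcr"
    references: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rq <= 0:
            raise ValueError("relative quantity must be positive")


def northern_relative_quantity(
    band: float,
    loading: float,
    calibrator_ratios: Sequence[float],
    sample: str = "",
    target: str = "",
    loading_label: str = "loading",
) -> RelativeQuantity:
    """Band/loading ratio scaled to the calibrator group's mean ratio."""
    if band <= 0 or loading <= 0:
        raise ValueError("band and loading intensities must be positive")
    ratios = np.asarray(calibrator_ratios, dtype=float)
    if ratios.size == 0 or np.any(ratios <= 0):
        raise ValueError("calibrator ratios must be non-empty and positive")
    rq = (band / loading) / float(ratios.mean())
    return RelativeQuantity(sample, target, rq, "northern", (loading_label,))


def qpcr_relative_quantity(
    ct_target: float,
    ct_refs: Sequence[float],
    calibrator: tuple[float, Sequence[float]],
    efficiency: float = 2.0,
    sample: str = "",
    target: str = "",
    reference_labels: tuple[str, ...] = (),
) -> RelativeQuantity:
    """ΔΔCt relative quantity against a single calibrator sample.

    ΔCt = Ct(target) − mean(Ct of references); rq = efficiency^(−ΔΔCt).
    ``efficiency`` is the per-cycle amplification factor, 2 for perfect
    doubling.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    refs = np.asarray(ct_refs, dtype=float)
    cal_t, cal_refs = calibrator
    cal_refs = np.asarray(cal_refs, dtype=float)
    if refs.size == 0 or cal_refs.size == 0:
        raise ValueError("reference Cts are required for sample and calibrator")
    if not (np.all(np.isfinite(refs)) and np.all(np.isfinite(cal_refs))):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target - refs.mean()) - (cal_t - cal_refs.mean())
    return RelativeQuantity(
        sample, target, float(efficiency**-ddct), "qpcr", tuple(reference_labels)
    )


def _check_long_table(df: pd.DataFrame, roles: set[str]) -> None:
    required = {"sample", "group", "assay", "role", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"quantification table missing columns: {sorted(missing)}")
    bad = set(df["role"].unique()) - roles
    if bad:
        raise ValueError(f"unexpected roles {sorted(bad)}; expected {sorted(roles)}")


def northern_table(df: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Per-sample relative quantities from a long band-intensity table.

    Expected columns: sample, group, assay, role ("target" band or
    "loading" control), value. Each sample needs exactly one loading row;
    every target band is divided by it and scaled so the ``calibrator``
    group's mean is 1 per target. Returns sample, group, target, rq.
    """
    _check_long_table(df, {"target", "loading"})
    loading = df[df["role"] == "loading"]
    counts = loading.groupby("sample").size()
    samples = df["sample"].unique()
    if not all(counts.get(s, 0) == 1 for s in samples):
        raise ValueError("each sample requires exactly one loading-control row")
    if np.any(df["value"].to_numpy(dtype=float) <= 0):
        raise ValueError("all band intensities must be positive")
    load_by_sample = loading.set_index("sample")["value"].astype(float)
    targets = df[df["role"] == "target"].copy()
    targets["ratio"] = targets["value"].astype(float) / targets["sample"].map(
        load_by_sample
    )
    if not (targets["group"] == calibrator).any():
        raise ValueError(f"calibrator group {calibrator!r} absent from table")
    cal_mean = (
        targets[targets["group"] == calibrator].groupby("assay")["ratio"].mean()
    )
    targets["rq"] = targets["ratio"] / targets["assay"].map(cal_mean)
    out = targets[["sample", "group", "assay", "rq"]].rename(columns={"assay": "target"})
    return out.reset_index(drop=True)


def qpcr_table(df: pd.DataFrame, calibrator: str, efficiency: float = 2.0) -> pd.DataFrame:
    """Per-sample ΔΔCt relative quantities from a long Ct table.

    Expected columns: sample, group, assay, role ("target" or "reference"),
    value (Ct). Reference Cts are combined per sample by arithmetic mean;
    linear quantities efficiency^(−ΔCt) are scaled so the ``calibrator``
    group's mean is exactly 1 per target. Returns sample, group, target, rq.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    _check_long_table(df, {"target", "reference"})
    refs = df[df["role"] == "reference"]
    if refs.empty:
        raise ValueError("no reference-gene rows in table")
    ref_mean = refs.groupby("sample")["value"].mean()
    targets = df[df["role"] == "target"].copy()
    if targets["sample"].map(ref_mean).isna().any():
        raise ValueError("some samples have no reference Cts")
    dct = targets["value"].astype(float) - targets["sample"].map(ref_mean)
    targets["quantity"] = efficiency ** (-dct)
    if not (targets["group"] == calibrator).any():
        raise ValueError(f"calibrator group {calibrator!r} absent from table")
    cal_mean = (
        targets[targets["group"] == calibrator].groupby("assay")["quantity"].mean()
    )
    targets["rq"] = targets["quantity"] / targets["assay"].map(cal_mean)
    out = targets[["sample", "group", "assay", "rq"]].rename(columns={"assay": "target"})
    return out.reset_index(drop=True)


def group_summary(rq_table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of per-replicate relative quantities per group × target."""
    return (
        rq_table.groupby(["group", "target"])["rq"]
        .agg(rq_mean="mean", rq_sd=lambda v: v.std(ddof=1), n="size")
        .reset_index()
    )
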