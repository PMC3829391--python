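"""Quantifications for targeted validation assays.

Four small, self-contained calculations that back the follow-up
experiments of a screen:

* reporter fold-activation with group means, SEMs and an unpaired
  two-tailed t-test on per-replicate firefly/Renilla ratios;
* ddCt relative quantification of qPCR data against a reference gene and a
  calibrator condition (RQ = efficiency ** -ddCt);
* TUNEL percent-positive cells, counts summed across microscope fields
  before dividing (robust to unequal field cellularity);
* densitometry normalized to a loading control and expressed as percent of
  the maximum condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import two_sample_p

log = logging.getLogger(__name__)

REPORTER_COLUMNS = ["cell_line", "sirna", "treatment", "firefly", "renilla", "replicate"]
QPCR_COLUMNS = ["sample", "condition", "target_ct", "reference_ct"]
TUNEL_COLUMNS = ["condition", "field_index", "dapi_count", "tunel_count"]
DENSITOMETRY_COLUMNS = ["condition", "cc3_density", "loading_density"]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary of per-replicate normalized reporter ratios."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    p_value: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "group_a", "group_b", "n_a", "n_b",
            "mean_a", "mean_b", "sem_a", "sem_b", "p_value")}


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")


def reporter_stats(
    records: pd.DataFrame,
    group_col: str,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> GroupComparison:
    """Compare normalized reporter activity between two groups.

    Each replicate contributes one firefly/Renilla ratio; groups are the
    rows where ``records[group_col]`` equals ``group_a`` / ``group_b``.
    The default test is the unpaired two-tailed Student t-test;
    ``equal_var=False`` switches to Welch.  Requires >= 2 replicates per
    group and strictly positive Renilla readings.
    """
    ratios = {}
    for label in (group_a, group_b):
        grp = records[records[group_col] == label]
        if len(grp) < 2:
            raise ValueError(
                f"group {label!r} has {len(grp)} replicate(s); need at least 2"
            )
        if (grp["renilla"] <= 0).any():
            raise ValueError(f"group {label!r} contains non-positive Renilla readings")
        ratios[label] = (grp["firefly"] / grp["renilla"]).to_numpy(dtype=float)
    a, b = ratios[group_a], ratios[group_b]
    p = two_sample_p(a, b, method="student" if equal_var else "welch")
    return GroupComparison(
        group_a, group_b, len(a), len(b),
        float(a.mean()), float(b.mean()), _sem(a), _sem(b), p,
    )


def relative_expression(
    records: pd.DataFrame, calibrator: str, efficiency: float = 2.0
) -> pd.DataFrame:
    """ddCt relative quantification, one row per sample.

    dCt = target_ct - reference_ct per sample; ddCt subtracts the mean dCt
    of the calibrator condition; RQ = efficiency ** -ddCt (amplification
    efficiency 2 assumes perfect doubling per cycle, the convention when no
    standard-curve calibration is available).  Rows with a missing
    reference Ct are excluded with a warning.  The mean RQ over calibrator
    samples is ``efficiency ** -(dCt - mean dCt)`` averaged, hence exactly
    1.0 for a single calibrator sample and centred on 1.0 in general.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must be > 1")
    df = records[QPCR_COLUMNS].copy()
    missing_ref = df["reference_ct"].isna()
    if missing_ref.any():
        log.warning(
            "%d qPCR row(s) lack a reference Ct; excluded", int(missing_ref.sum())
        )
        df = df[~missing_ref]
    for col in ("target_ct", "reference_ct"):
        bad = (df[col] <= 0) | (df[col] >= 45)
        if bad.any():
            raise ValueError(f"{col} outside the plausible (0, 45) cycle range")
    if calibrator not in set(df["condition"]):
        raise ValueError(f"calibrator condition {calibrator!r} not present")
    df["delta_ct"] = df["target_ct"] - df["reference_ct"]
    cal_mean = df.loc[df["condition"] == calibrator, "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - cal_mean
    df["rq"] = efficiency ** (-df["delta_delta_ct"])
    return df.reset_index(drop=True)


def relative_expression_summary(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and SEM of RQ from :func:`relative_expression`."""
    rows = []
    for cond, grp in per_sample.groupby("condition", sort=True):
        rq = grp["rq"].to_numpy(dtype=float)
        rows.append({
            "condition": cond,
            "n": len(rq),
            "mean_rq": float(rq.mean()),
            "sem_rq": _sem(rq),
        })
    return pd.DataFrame(rows, columns=["condition", "n", "mean_rq", "sem_rq"])


def tunel_percent(fields: pd.DataFrame) -> float:
    """Percent TUNEL-positive nuclei for one condition.

    Counts are summed across fields before dividing: the estimate weights
    each nucleus, not each field, so sparse fields do not dominate.
    """
    if len(fields) == 0:
        raise ValueError("no fields supplied")
    if (fields["tunel_count"] > fields["dapi_count"]).any():
        raise ValueError("tunel_count exceeds dapi_count in at least one field")
    total_dapi = int(fields["dapi_count"].sum())
    if total_dapi == 0:
        raise ValueError("total DAPI count is zero")
    return 100.0 * float(fields["tunel_count"].sum()) / total_dapi


def tunel_percent_by_condition(fields: pd.DataFrame) -> pd.Series:
    out = {
        cond: tunel_percent(grp)
        for cond, grp in fields.groupby("condition", sort=True)
    }
    return pd.Series(out, name="percent_tunel_positive")


def caspase_relative(records: pd.DataFrame) -> pd.Series:
    """Loading-normalized densitometry as percent of the maximum condition.

    Each condition's signal density is divided by its loading-control
    density, then scaled so the largest ratio is 100.  At least one
    condition sits at exactly 100 (ties allowed); invariant to rescaling
    all loading densities by a common factor.
    """
    if len(records) == 0:
        raise ValueError("no densitometry records")
    if (records["loading_density"] <= 0).any():
        raise ValueError("loading_density must be > 0")
    r = records["cc3_density"] / records["loading_density"]
    rmax = float(r.max())
    if rmax <= 0:
        raise ValueError("all signal densities are zero; nothing to normalize")
    out = 100.0 * r / rmax
    out.index = records["condition"]
    return out.rename("percent_of_max")
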