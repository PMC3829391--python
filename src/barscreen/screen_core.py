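"""Well-level dual-luciferase screen data: I/O, normalization, per-pool statistics.

The screen readout is firefly luciferase driven by a pathway-responsive
promoter (here a β-catenin activated reporter), divided by constitutively
expressed Renilla luciferase measured in the same well.  The ratio cancels
multiplicative factors shared by both channels — cell number, transfection
efficiency, reagent volume — which is the entire point of the dual-luciferase
design.  Each siRNA pool's effect is then expressed as the median ratio of
its replicate wells as a percentage of the same-plate negative-control
median ("percent of control"), and a two-sample test on log2 ratios against
the same-plate negative controls supplies the p-value plotted on the
volcano.

All bulk data live in :class:`pandas.DataFrame` objects with the column
schemas defined by :data:`WELL_COLUMNS` and :data:`VOLCANO_COLUMNS`;
the dataclasses mirror single records for callers that prefer objects.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import two_sample_p

log = logging.getLogger(__name__)

#: Required columns of a well-level screen table, in canonical order.
WELL_COLUMNS = [
    "plate_id",
    "well_id",
    "sample_kind",
    "pool_id",
    "firefly",
    "renilla",
    "replicate",
]

SAMPLE_KINDS = {"pool", "negative_control", "positive_control", "empty"}

#: Columns of the volcano table written by :func:`build_volcano_table`.
VOLCANO_COLUMNS = [
    "pool_id",
    "gene_symbol",
    "percent_of_control",
    "p_value",
    "log2_effect",
    "n_replicates",
]

SUMMARY_COLUMNS = VOLCANO_COLUMNS + ["median_ratio", "direction", "flagged"]


@dataclass(frozen=True)
class WellMeasurement:
    """One well's raw readings with plate, pool and control annotations."""

    plate_id: str
    well_id: str
    sample_kind: str
    pool_id: str | None
    firefly: float
    renilla: float
    replicate: int


@dataclass(frozen=True)
class PoolSummary:
    """Per-pool normalized effect and significance, one volcano row."""

    pool_id: str
    gene_symbol: str | None
    n_replicates: int
    median_ratio: float
    percent_of_control: float
    log2_effect: float
    p_value: float
    direction: str  # "up" | "down" | "none"


@dataclass(frozen=True)
class PlateControlSummary:
    plate_id: str
    n_neg_controls: int
    control_median_ratio: float
    control_log2_sd: float


def read_well_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a well-level screen table (TSV by default, CSV by extension).

    Column order in the file is irrelevant; the result carries the canonical
    :data:`WELL_COLUMNS` plus a boolean ``excluded`` column marking wells
    that must not enter any ratio (Renilla = 0).  The number of excluded
    wells is logged.

    Raises
    ------
    ValueError
        If a required column is missing (named in the message), a
        luminescence value is non-numeric or negative (reported with its
        1-based file line number), ``sample_kind`` is not a known kind, or a
        pool well lacks a ``pool_id``.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table {path} is missing required column(s): {missing}")
    df = df[WELL_COLUMNS].copy()
    for col in ("firefly", "renilla"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"non-numeric {col} value {df.loc[df.index[bad][0], col]!r} "
                f"at line {line} of {path}"
            )
        if (vals < 0).any():
            line = int(df.index[vals < 0][0]) + 2
            raise ValueError(f"negative {col} reading at line {line} of {path}")
        df[col] = vals
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    if df["replicate"].isna().any():
        line = int(df.index[df["replicate"].isna()][0]) + 2
        raise ValueError(f"non-integer replicate at line {line} of {path}")
    df["replicate"] = df["replicate"].astype(int)
    bad_kind = ~df["sample_kind"].isin(SAMPLE_KINDS)
    if bad_kind.any():
        kinds = sorted(df.loc[bad_kind, "sample_kind"].unique())
        raise ValueError(f"unknown sample_kind value(s) {kinds} in {path}")
    df["pool_id"] = df["pool_id"].replace("", None)
    orphans = (df["sample_kind"] == "pool") & df["pool_id"].isna()
    if orphans.any():
        line = int(df.index[orphans][0]) + 2
        raise ValueError(f"pool well without pool_id at line {line} of {path}")
    df["excluded"] = df["renilla"] <= 0
    n_excluded = int(df["excluded"].sum())
    if n_excluded:
        log.info("excluded %d zero-Renilla well(s) from %s", n_excluded, path)
    return df


def read_pool_annotations(path, sep: str | None = None) -> pd.DataFrame:
    """Read a pool -> gene annotation table (pool_id, gene_symbol, gene_id)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    ann = pd.read_csv(path, sep=sep, dtype={"pool_id": str, "gene_symbol": str})
    for col in ("pool_id", "gene_symbol"):
        if col not in ann.columns:
            raise ValueError(f"annotation table {path} is missing column {col!r}")
    if ann["pool_id"].duplicated().any():
        dup = ann.loc[ann["pool_id"].duplicated(), "pool_id"].iloc[0]
        raise ValueError(f"duplicate pool_id {dup!r} in annotation table {path}")
    return ann


def normalize_ratio(firefly, renilla):
    """Firefly / Renilla ratio; raises if any Renilla reading is <= 0.

    Works element-wise on arrays.  Callers must exclude zero-Renilla wells
    before normalizing; dividing by them is never silently permitted.
    """
    firefly = np.asarray(firefly, dtype=float)
    renilla = np.asarray(renilla, dtype=float)
    if np.any(renilla <= 0):
        raise ValueError("renilla must be > 0; exclude flagged wells before normalizing")
    out = firefly / renilla
    return float(out) if out.ndim == 0 else out


def _ensure_excluded(wells: pd.DataFrame) -> pd.DataFrame:
    if "excluded" not in wells.columns:
        wells = wells.copy()
        wells["excluded"] = wells["renilla"] <= 0
    return wells


def plate_control_summaries(
    wells: pd.DataFrame, min_neg_controls: int = 2
) -> pd.DataFrame:
    """Per-plate negative-control statistics used for normalization and testing.

    Returns a frame indexed by ``plate_id`` with columns ``n_neg_controls``,
    ``control_median_ratio`` and ``control_log2_sd``.  Plates with fewer than
    ``min_neg_controls`` usable negative-control wells raise, because their
    percent-of-control and p-values would be meaningless.
    """
    wells = _ensure_excluded(wells)
    neg = wells[(wells["sample_kind"] == "negative_control") & ~wells["excluded"]]
    rows = {}
    for plate, grp in neg.groupby("plate_id", sort=True):
        ratios = (grp["firefly"] / grp["renilla"]).to_numpy()
        log2r = np.log2(ratios)
        rows[plate] = {
            "n_neg_controls": len(ratios),
            "control_median_ratio": float(np.median(ratios)),
            "control_log2_sd": float(np.std(log2r, ddof=1)) if len(ratios) > 1 else 0.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "plate_id"
    short = out[out["n_neg_controls"] < min_neg_controls]
    if len(short):
        raise ValueError(
            f"plate(s) {sorted(short.index)} have fewer than "
            f"{min_neg_controls} usable negative-control wells"
        )
    return out


def _control_ratio_map(
    wells: pd.DataFrame, cross_plate: bool
) -> dict[str, np.ndarray]:
    neg = wells[(wells["sample_kind"] == "negative_control") & ~wells["excluded"]]
    per_plate = {
        plate: (grp["firefly"] / grp["renilla"]).to_numpy()
        for plate, grp in neg.groupby("plate_id", sort=True)
    }
    if cross_plate:
        pooled = np.concatenate(list(per_plate.values())) if per_plate else np.array([])
        return {plate: pooled for plate in wells["plate_id"].unique()}
    return per_plate


def _pool_seed(seed: int, pool_id: str) -> list[int]:
    # keyed on pool identity, not row position, so Monte Carlo p-values are
    # invariant to input row order
    return [seed & 0x7FFFFFFF, zlib.crc32(pool_id.encode())]


def summarize_pool(
    pool_wells: pd.DataFrame,
    control_ratios: Mapping[str, np.ndarray],
    test: str = "student",
    gene_symbol: str | None = None,
    seed: int = 0,
    n_resamples: int = 10_000,
) -> PoolSummary:
    """Summarize one pool's wells against plate-matched negative controls.

    ``percent_of_control`` is 100 x the median of the pool's per-well ratios,
    each divided by its own plate's control median; with all wells on one
    plate this is the plain median-ratio / control-median ratio.  The p-value
    compares the pool's log2 ratios with the same plates' negative-control
    log2 ratios (both plate-centred) using the configured test.

    A pool with no usable well yields a flagged summary with NaN statistics
    and direction ``"none"``.
    """
    pool_wells = _ensure_excluded(pool_wells)
    pool_id = str(pool_wells["pool_id"].iloc[0])
    usable = pool_wells[~pool_wells["excluded"]]
    if len(usable) == 0:
        log.warning("pool %s has no usable wells; summary flagged", pool_id)
        return PoolSummary(
            pool_id, gene_symbol, 0, float("nan"), float("nan"), float("nan"),
            float("nan"), "none",
        )
    ratios = (usable["firefly"] / usable["renilla"]).to_numpy()
    plates = usable["plate_id"].to_numpy()
    for plate in np.unique(plates):
        if plate not in control_ratios or len(control_ratios[plate]) < 2:
            raise ValueError(
                f"pool {pool_id}: no usable negative controls for plate {plate!r}"
            )
    plate_medians = {p: float(np.median(control_ratios[p])) for p in np.unique(plates)}
    norm = ratios / np.array([plate_medians[p] for p in plates])
    percent = 100.0 * float(np.median(norm))
    ctrl_norm = np.concatenate(
        [control_ratios[p] / plate_medians[p] for p in np.unique(plates)]
    )
    p_value = two_sample_p(
        np.log2(norm),
        np.log2(ctrl_norm),
        method=test,
        rng=_pool_seed(seed, pool_id),
        n_resamples=n_resamples,
    )
    direction = "up" if percent > 100 else ("down" if percent < 100 else "none")
    return PoolSummary(
        pool_id=pool_id,
        gene_symbol=gene_symbol,
        n_replicates=len(usable),
        median_ratio=float(np.median(ratios)),
        percent_of_control=percent,
        log2_effect=float(np.log2(percent / 100.0)),
        p_value=p_value,
        direction=direction,
    )


def summarize_pools(
    wells: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    test: str = "student",
    cross_plate_controls: bool = False,
    min_neg_controls: int = 2,
    seed: int = 0,
    n_resamples: int = 10_000,
) -> pd.DataFrame:
    """Summarize every pool in a well table; one row per pool.

    Same-plate negative controls are the normalization and testing baseline;
    ``cross_plate_controls=True`` pools controls across plates instead (only
    defensible when plate effects are known to be negligible).
    """
    wells = _ensure_excluded(wells)
    plate_control_summaries(wells, min_neg_controls=min_neg_controls)  # validates
    controls = _control_ratio_map(wells, cross_plate=cross_plate_controls)
    symbol_of: Mapping[str, str] = {}
    if annotations is not None:
        symbol_of = dict(zip(annotations["pool_id"], annotations["gene_symbol"]))
    rows = []
    pool_wells = wells[wells["sample_kind"] == "pool"]
    for pool_id, grp in pool_wells.groupby("pool_id", sort=True):
        s = summarize_pool(
            grp,
            controls,
            test=test,
            gene_symbol=symbol_of.get(pool_id),
            seed=seed,
            n_resamples=n_resamples,
        )
        rows.append(
            {
                "pool_id": s.pool_id,
                "gene_symbol": s.gene_symbol,
                "percent_of_control": s.percent_of_control,
                "p_value": s.p_value,
                "log2_effect": s.log2_effect,
                "n_replicates": s.n_replicates,
                "median_ratio": s.median_ratio,
                "direction": s.direction,
                "flagged": s.n_replicates == 0,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def build_volcano_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Volcano table: one row per pool, ascending p, ties broken by pool_id."""
    if len(summaries) == 0:
        raise ValueError("no pool summaries to tabulate")
    out = summaries[VOLCANO_COLUMNS].copy()
    out = out.sort_values(
        ["p_value", "pool_id"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    return out


def write_volcano(volcano: pd.DataFrame, path) -> None:
    volcano.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_volcano(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pool_id": str, "gene_symbol": str})
    missing = [c for c in VOLCANO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"volcano table {path} is missing column(s): {missing}")
    return df
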