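"""Pool-level and gene-level consensus hit classification.

A pool is a hit when its median effect changes reporter activity by at least
``fold_threshold`` in either direction (percent of control at or beyond
100 x fold, or at or below 100 / fold) AND its p-value beats ``alpha``.
A gene is a consensus hit only when *every* pool targeting it is a pool hit
— the stringent "all siRNAs agree" rule that trades sensitivity for
specificity against off-target effects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

HIT_UP = "hit_up"
HIT_DOWN = "hit_down"
NON_HIT = "non_hit"

DIRECTION_MIX = ("all_up", "all_down", "mixed", "na")


@dataclass(frozen=True)
class HitThresholds:
    """Fold-change and significance cutoffs for pool and gene calls.

    Defaults are the classic screen criterion: at least 2.0-fold change in
    normalized reporter activity with p < 0.01.
    """

    fold_threshold: float = 2.0
    alpha: float = 0.01
    require_direction_consensus: bool = False

    def __post_init__(self):
        if not self.fold_threshold >= 1:
            raise ValueError("fold_threshold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class GeneCall:
    gene_symbol: str
    n_pools: int
    n_pool_hits: int
    is_hit: bool
    direction_mix: str


def classify_pool(
    percent_of_control: float, p_value: float, thresholds: HitThresholds
) -> str:
    """Classify one pool as ``hit_up``, ``hit_down`` or ``non_hit``.

    The fold boundary is inclusive ("at least 2.0 fold"); the p boundary is
    strict (p < alpha).  A missing p-value yields ``non_hit`` with a warning.
    """
    if p_value is None or (isinstance(p_value, float) and math.isnan(p_value)):
        log.warning("pool with null p-value classified non_hit")
        return NON_HIT
    fold_ok = (
        percent_of_control >= 100.0 * thresholds.fold_threshold
        or percent_of_control <= 100.0 / thresholds.fold_threshold
    )
    if fold_ok and p_value < thresholds.alpha:
        return HIT_UP if percent_of_control > 100.0 else HIT_DOWN
    return NON_HIT


def call_pools(
    volcano: pd.DataFrame, thresholds: HitThresholds, bh: bool = False
) -> pd.DataFrame:
    """Classify every volcano row; adds ``pool_call`` (and ``p_adjusted``).

    ``bh=True`` applies Benjamini-Hochberg across all non-null p-values and
    thresholds the adjusted values instead — not the historical behaviour
    (raw p < alpha) but available for reuse beyond reproduction.
    """
    out = volcano.copy()
    p = out["p_value"].to_numpy(dtype=float)
    if bh:
        adj = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            adj[ok] = stats.false_discovery_control(p[ok], method="bh")
        out["p_adjusted"] = adj
        p_eff = adj
    else:
        p_eff = p
    out["pool_call"] = [
        classify_pool(poc, pv, thresholds)
        for poc, pv in zip(out["percent_of_control"], p_eff)
    ]
    return out


def _direction_mix(percents: Sequence[float]) -> str:
    signs = set()
    for poc in percents:
        if poc is None or (isinstance(poc, float) and math.isnan(poc)):
            continue
        if poc > 100:
            signs.add("up")
        elif poc < 100:
            signs.add("down")
    if not signs:
        return "na"
    if signs == {"up"}:
        return "all_up"
    if signs == {"down"}:
        return "all_down"
    return "mixed"


def classify_gene(
    gene_symbol: str,
    pool_calls: Sequence[str],
    thresholds: HitThresholds,
    percents: Sequence[float] | None = None,
) -> GeneCall:
    """Consensus call for one gene from the calls of all pools targeting it.

    ``is_hit`` requires every pool to be a hit; with
    ``require_direction_consensus`` all hits must additionally share a
    direction.  ``percents`` (percent-of-control per pool) refine
    ``direction_mix``; without them the mix is derived from hit calls alone.
    """
    if len(pool_calls) == 0:
        raise ValueError(f"gene {gene_symbol!r}: no pool calls supplied")
    n_hits = sum(c in (HIT_UP, HIT_DOWN) for c in pool_calls)
    all_hit = n_hits == len(pool_calls)
    if percents is not None:
        mix = _direction_mix(percents)
    else:
        mix = _direction_mix(
            [200.0 if c == HIT_UP else 50.0 if c == HIT_DOWN else float("nan")
             for c in pool_calls]
        )
    is_hit = all_hit
    if thresholds.require_direction_consensus and is_hit:
        hit_dirs = {c for c in pool_calls}
        is_hit = hit_dirs == {HIT_UP} or hit_dirs == {HIT_DOWN}
    return GeneCall(gene_symbol, len(pool_calls), n_hits, is_hit, mix)


def call_genes(pool_calls: pd.DataFrame, thresholds: HitThresholds) -> pd.DataFrame:
    """Gene-level consensus calls from a classified volcano table.

    Expects columns ``gene_symbol``, ``pool_call`` and ``percent_of_control``
    (as produced by :func:`call_pools`); rows without a gene symbol are
    dropped with a warning.  Output is sorted by gene symbol.
    """
    df = pool_calls
    unannotated = df["gene_symbol"].isna()
    if unannotated.any():
        log.warning("%d pool(s) lack a gene symbol; skipped", int(unannotated.sum()))
        df = df[~unannotated]
    rows = []
    for symbol, grp in df.groupby("gene_symbol", sort=True):
        gc = classify_gene(
            symbol,
            list(grp["pool_call"]),
            thresholds,
            percents=list(grp["percent_of_control"]),
        )
        rows.append(
            {
                "gene_symbol": gc.gene_symbol,
                "n_pools": gc.n_pools,
                "n_pool_hits": gc.n_pool_hits,
                "is_hit": gc.is_hit,
                "direction_mix": gc.direction_mix,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_symbol", "n_pools", "n_pool_hits", "is_hit", "direction_mix"]
    )


def write_gene_calls(gene_calls: pd.DataFrame, path) -> None:
    gene_calls.to_csv(path, sep="\t", index=False)
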