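"""AP-MS spectral-count handling: background subtraction and network export.

Affinity purification / mass spectrometry runs recover, besides genuine
bait interactors, sticky proteins that copurify with any affinity resin and
with control baits.  Following standard practice the filter here is purely
label-based: a prey is removed if it also appears in a control purification
or on a common-contaminant list, regardless of spectral counts.  An optional
minimum spectral-count cutoff exists (default 1, i.e. off).

The bait appearing as its own prey is a positive control for the
purification and is always retained, tagged with ``bait_self``.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

RUN_COLUMNS = ["bait", "prey", "spectral_counts"]
EDGE_COLUMNS = RUN_COLUMNS + ["retained", "removal_reason", "bait_self"]

REMOVAL_REASONS = ("none", "in_control", "contaminant", "low_count")


def read_spectral_counts(path, sep: str | None = None) -> pd.DataFrame:
    """Read a bait/prey/spectral_counts table; validates counts and uniqueness."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"bait": str, "prey": str})
    missing = [c for c in RUN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectral-count table {path} is missing column(s): {missing}")
    df = df[RUN_COLUMNS].copy()
    counts = pd.to_numeric(df["spectral_counts"], errors="coerce")
    if counts.isna().any() or (counts < 1).any() or (counts % 1 != 0).any():
        raise ValueError(f"spectral_counts must be integers >= 1 in {path}")
    df["spectral_counts"] = counts.astype(int)
    if df.duplicated(["bait", "prey"]).any():
        dup = df.loc[df.duplicated(["bait", "prey"]), ["bait", "prey"]].iloc[0]
        raise ValueError(f"duplicate (bait, prey) pair {tuple(dup)} in {path}")
    return df


def read_label_list(path) -> set[str]:
    """One protein label per line; '#' comment lines skipped."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def subtract_background(
    bait_run: pd.DataFrame,
    control_preys: Iterable[str] = (),
    contaminants: Iterable[str] = (),
    min_count: int = 1,
) -> pd.DataFrame:
    """Flag each prey of a bait run as retained or removed.

    Every input row appears in the output — nothing is silently dropped —
    with ``retained`` and ``removal_reason`` set.  A prey is removed if it
    is in ``control_preys`` (reason ``in_control``, checked first), in
    ``contaminants`` (``contaminant``) or below ``min_count`` spectral
    counts (``low_count``).  Bait self-rows are always retained.
    Idempotent: re-filtering the retained rows changes nothing.
    """
    if len(bait_run) == 0:
        raise ValueError("bait run is empty")
    control_preys = set(control_preys)
    contaminants = set(contaminants)
    out = bait_run[RUN_COLUMNS].copy()
    reasons = []
    for bait, prey, count in zip(out["bait"], out["prey"], out["spectral_counts"]):
        if prey == bait:
            reasons.append("none")
        elif prey in control_preys:
            reasons.append("in_control")
        elif prey in contaminants:
            reasons.append("contaminant")
        elif count < min_count:
            reasons.append("low_count")
        else:
            reasons.append("none")
    out["removal_reason"] = reasons
    out["retained"] = out["removal_reason"] == "none"
    out["bait_self"] = out["prey"] == out["bait"]
    return out[EDGE_COLUMNS]


def retained_preys(edges: pd.DataFrame, include_bait_self: bool = False) -> set[str]:
    """The retained prey set; by default the bait self-row does not count as
    an interactor."""
    keep = edges["retained"]
    if not include_bait_self:
        keep = keep & ~edges["bait_self"]
    return set(edges.loc[keep, "prey"])


def export_network(edges: pd.DataFrame, path, format: str = "sif") -> None:
    """Write retained edges in deterministic (bait, prey) lexicographic order.

    ``sif``: one ``bait interacts prey`` line per edge.
    ``tsv``: bait/prey/spectral_counts columns, round-trippable through
    :func:`read_spectral_counts`.
    """
    kept = edges[edges["retained"]].sort_values(["bait", "prey"], kind="stable")
    if format == "sif":
        with open(path, "w") as fh:
            for bait, prey in zip(kept["bait"], kept["prey"]):
                fh.write(f"{bait}\tinteracts\t{prey}\n")
    elif format == "tsv":
        kept[RUN_COLUMNS].to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}; expected 'sif' or 'tsv'")
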