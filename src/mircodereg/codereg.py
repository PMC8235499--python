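"""The co-deregulation frequency scan.

For each miRNA symbol the statistic counts, over tumor samples, how often
the log2 tumor/control-mean ratio E falls on one side of zero: f (a
count) and f% = 100*f/denominator.  Symbols are then stratified into
frequency bands — deregulated in all samples (100%), in 90-99%, 80-89%,
or 75-80% of samples — and reported per k-means cluster, mirroring the
layout of a published common-pattern table (symbol, direction, f, f%,
cluster, mean expression).

The denominator is a policy choice: platform coverage differs across
series, so the default denominator is the number of non-missing tumor
samples for that symbol; a fixed cohort-wide denominator (e.g. 195) is
available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "BANDS",
    "DeregFrequency",
    "round_half_up",
    "deregulation_frequency",
    "band_assign",
    "scan_codereg",
    "chrom_summaries",
]

# band labels, highest first; boundaries half-open as stated in band_assign
BANDS = ("100", "90-99", "80-89", "75-80", "below")

_BAND_FLOOR = {"100": 100.0, "90-99": 90.0, "80-89": 80.0, "75-80": 75.0,
               "below": 0.0}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), not banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DeregFrequency:
    """Up/down tallies for one symbol across tumor samples."""

    f_up: int
    f_down: int
    f_pct_up: float
    f_pct_down: float
    denominator: int
    direction: str  # "up" | "down" | "ambiguous"
    n_zero: int
    n_missing: int


def deregulation_frequency(e_row, denominator: int | None = None
                           ) -> DeregFrequency:
    """Count up-/down-deregulated tumor samples for one symbol.

    E > 0 counts as up, E < 0 as down; E == 0 counts toward neither.
    ``denominator`` defaults to the number of non-missing samples in the
    row (the per-symbol policy); pass a fixed cohort size for the
    alternative policy.  The direction is whichever tally is larger;
    a tie is "ambiguous".
    """
    e = np.asarray(e_row, dtype=float)
    finite = np.isfinite(e)
    if not finite.any():
        raise ValueError("all-NaN ratio row: no finite E values")
    f_up = int((e[finite] > 0).sum())
    f_down = int((e[finite] < 0).sum())
    n_zero = int((e[finite] == 0).sum())
    n_missing = int((~finite).sum())
    denom = int(finite.sum()) if denominator is None else int(denominator)
    if denom <= 0:
        raise ValueError(f"denominator must be positive, got {denom}")
    if f_up > f_down:
        direction = "up"
    elif f_down > f_up:
        direction = "down"
    else:
        direction = "ambiguous"
    return DeregFrequency(
        f_up=f_up,
        f_down=f_down,
        f_pct_up=round_half_up(100.0 * f_up / denom),
        f_pct_down=round_half_up(100.0 * f_down / denom),
        denominator=denom,
        direction=direction,
        n_zero=n_zero,
        n_missing=n_missing,
    )


def band_assign(f_pct: float) -> str:
    """Map a percentage to its frequency band.

    100 -> "100"; [90, 100) -> "90-99"; [80, 90) -> "80-89";
    [75, 80) -> "75-80"; anything lower -> "below".
    """
    if not np.isfinite(f_pct) or f_pct < 0 or f_pct > 100:
        raise ValueError(f"f_pct out of range [0, 100]: {f_pct}")
    if f_pct == 100.0:
        return "100"
    if f_pct >= 90.0:
        return "90-99"
    if f_pct >= 80.0:
        return "80-89"
    if f_pct >= 75.0:
        return "75-80"
    return "below"


def scan_codereg(ratios, clusters=None, min_band: str = "75-80",
                 denominator: int | None = None,
                 min_abs_e: float = 0.0) -> pd.DataFrame:
    """Scan every symbol for a common deregulation pattern.

    Parameters
    ----------
    ratios
        A RatioMatrix (or plain DataFrame) of E values, tumor columns.
    clusters
        Optional ClusterModel (or Series) supplying a k-means cluster id
        per symbol; symbols without an id get cluster 0.
    min_band
        Records in a band below this floor are excluded ("below" keeps
        everything).
    denominator
        None for the per-symbol non-missing policy, or a fixed cohort
        total.
    min_abs_e
        Optional magnitude floor: |E| <= min_abs_e counts as neither
        direction (default 0, i.e. pure sign rule).

    Returns a DataFrame sorted by cluster then ascending f with columns
    symbol, direction, f, f_pct, denominator, band, cluster,
    mean_expression.
    """
    values = ratios.values if hasattr(ratios, "values") and not isinstance(
        ratios, pd.DataFrame) else ratios
    if min_band not in BANDS:
        raise ValueError(f"unknown band {min_band!r}; valid: {list(BANDS)}")
    floor = _BAND_FLOOR[min_band]
    if clusters is None:
        cluster_of = {}
    elif hasattr(clusters, "assignments"):
        cluster_of = clusters.assignments.to_dict()
    else:
        cluster_of = pd.Series(clusters).to_dict()

    records = []
    for sym in values.index:
        row = values.loc[sym].to_numpy(float)
        if not np.isfinite(row).any():
            continue
        work = row.copy()
        if min_abs_e > 0:
            work = np.where(np.abs(work) <= min_abs_e, 0.0, work)
        freq = deregulation_frequency(work, denominator=denominator)
        if freq.direction == "up":
            f, f_pct = freq.f_up, freq.f_pct_up
        elif freq.direction == "down":
            f, f_pct = freq.f_down, freq.f_pct_down
        else:
            f = freq.f_up
            f_pct = freq.f_pct_up
        if f_pct < floor:
            continue
        records.append(dict(
            symbol=sym,
            direction=freq.direction,
            f=f,
            f_pct=f_pct,
            denominator=freq.denominator,
            band=band_assign(f_pct),
            cluster=int(cluster_of.get(sym, 0)),
            mean_expression=float(np.nanmean(row)),
        ))
    out = pd.DataFrame.from_records(
        records,
        columns=["symbol", "direction", "f", "f_pct", "denominator",
                 "band", "cluster", "mean_expression"],
    )
    return out.sort_values(
        ["cluster", "f", "symbol"], ascending=[True, True, True]
    ).reset_index(drop=True)


def codereg_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Census of records per (cluster, direction, band)."""
    if records.empty:
        return pd.DataFrame(columns=["cluster", "direction", "band", "n"])
    return (records.groupby(["cluster", "direction", "band"])
            .size().rename("n").reset_index())


def chrom_summaries(ratios, annotation: pd.DataFrame,
                    level: str = "chromosome") -> dict:
    """Mean E per chromosome or cytoband over annotated symbols.

    Returns a dict with a ``summary`` table (location, mean E over all
    annotated symbols and tumor samples, symbol count), a
    ``heatmap`` matrix (location x sample mean E), the top up- and
    down-regulated locations, and the list of unannotated symbols.
    """
    if level not in ("chromosome", "cytoband"):
        raise ValueError(
            f"unknown level {level!r}; valid: ['chromosome', 'cytoband']"
        )
    values = ratios.values if hasattr(ratios, "values") and not isinstance(
        ratios, pd.DataFrame) else ratios
    annotated = [s for s in values.index if s in annotation.index]
    unannotated = [s for s in values.index if s not in annotation.index]
    if not annotated:
        raise ValueError("no annotated symbols")
    sub = values.loc[annotated]
    loc = annotation.loc[annotated, level]
    groups = loc.groupby(loc).groups

    rows = []
    heat = {}
    for location, syms in groups.items():
        block = sub.loc[list(syms)]
        rows.append((location, float(np.nanmean(block.to_numpy())),
                     len(syms)))
        heat[location] = block.mean(axis=0)
    summary = pd.DataFrame(
        rows, columns=[level, "mean_e", "n_symbols"]
    ).set_index(level).sort_values("mean_e", ascending=False)
    heatmap = pd.DataFrame(heat).T.loc[summary.index]
    return {
        "summary": summary,
        "heatmap": heatmap,
        "top_up": list(summary.index[:3]),
        "top_down": list(summary.index[::-1][:3]),
        "unannotated": unannotated,
    }
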