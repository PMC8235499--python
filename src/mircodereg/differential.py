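"""Per-miRNA tumor-vs-control testing and the ratio representation.

Two parallel views of the processed hyper-matrix feed downstream stages:

* "naturals" — the averaged, rescaled intensities themselves, tested
  per symbol with a two-sample t-test plus Benjamini-Hochberg FDR;
* "ratios" — per tumor sample, log2 of its value over the mean of all
  control samples for the same symbol (E = log2(F_tumor / mean F_control)),
  the representation on which clustering and the co-deregulation scan run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEResult",
    "RatioMatrix",
    "t_test_per_symbol",
    "fdr_adjust",
    "select_de",
    "tumor_to_control_ratio",
    "split_labels",
]

TUMOR, CONTROL = "tumor", "control"


def split_labels(labels) -> tuple[list, list]:
    """Partition sample ids into (tumor_ids, control_ids)."""
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    tumors = [s for s, v in labels.items() if str(v).lower() == TUMOR]
    controls = [s for s, v in labels.items() if str(v).lower() == CONTROL]
    return tumors, controls


@dataclass
class DEResult:
    """Per-symbol differential-expression statistics.

    ``table`` columns: t, p, q, n_tumor_used, n_control_used, mean_tumor,
    mean_control.  ``untested`` lists symbols with fewer than two finite
    values in either group; ``degenerate`` lists symbols where both groups
    had zero variance and equal means (p set to 1 by convention).
    """

    table: pd.DataFrame
    untested: list = field(default_factory=list)
    degenerate: list = field(default_factory=list)


def t_test_per_symbol(naturals: pd.DataFrame, labels,
                      variant: str = "pooled") -> DEResult:
    """Two-sample t-test per symbol (row), NaN-aware.

    ``variant`` selects classic pooled-variance ("pooled", default) or
    Welch ("welch") degrees of freedom.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    tumors, controls = split_labels(labels)
    tum = naturals[[c for c in naturals.columns if c in set(tumors)]]
    ctl = naturals[[c for c in naturals.columns if c in set(controls)]]

    rows = []
    untested, degenerate = [], []
    for sym in naturals.index:
        a = tum.loc[sym].to_numpy(float)
        b = ctl.loc[sym].to_numpy(float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            untested.append(sym)
            rows.append((sym, np.nan, np.nan, len(a), len(b),
                         a.mean() if len(a) else np.nan,
                         b.mean() if len(b) else np.nan))
            continue
        # numerically constant row with equal group means: p = 1 by
        # convention (tolerance absorbs float-path differences between
        # columns, which would otherwise yield junk t statistics)
        combined = np.concatenate([a, b])
        spread = combined.max() - combined.min()
        if spread <= 1e-9 * max(1.0, np.abs(combined).max()):
            degenerate.append(sym)
            rows.append((sym, 0.0, 1.0, len(a), len(b), a.mean(), b.mean()))
            continue
        res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
        rows.append((sym, float(res.statistic), float(res.pvalue),
                     len(a), len(b), float(a.mean()), float(b.mean())))
    table = pd.DataFrame(
        rows,
        columns=["symbol", "t", "p", "n_tumor_used", "n_control_used",
                 "mean_tumor", "mean_control"],
    ).set_index("symbol")
    tested = table["p"].notna()
    q = np.full(len(table), np.nan)
    if tested.any():
        q[tested.to_numpy()] = fdr_adjust(table.loc[tested, "p"].to_numpy())
    table["q"] = q
    return DEResult(table=table, untested=untested, degenerate=degenerate)


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de(res: DEResult, p_max: float = 0.05,
              q_max: float = 0.05) -> list:
    """Symbols with p < p_max and q < q_max, sorted by ascending p."""
    t = res.table
    hit = t[(t["p"] < p_max) & (t["q"] < q_max)]
    return list(hit.sort_values("p").index)


@dataclass
class RatioMatrix:
    """Log2 tumor-over-control-mean values (tumor columns only).

    A cell is NaN where the tumor value or the per-symbol control mean is
    missing or non-positive; ``n_nonpositive`` counts cells lost to
    non-positivity and ``no_control`` lists symbols without any finite
    control value (their rows are all NaN).
    """

    values: pd.DataFrame
    control_mean: pd.Series = None
    n_nonpositive: int = 0
    no_control: list = field(default_factory=list)

    @property
    def symbols(self):
        return list(self.values.index)


def tumor_to_control_ratio(naturals: pd.DataFrame, labels) -> RatioMatrix:
    """E = log2(tumor value / mean of control samples), per symbol.

    The control mean is the NaN-ignoring mean over control columns for
    that symbol.
    """
    tumors, controls = split_labels(labels)
    tum = naturals[[c for c in naturals.columns if c in set(tumors)]]
    ctl = naturals[[c for c in naturals.columns if c in set(controls)]]
    if ctl.shape[1] == 0:
        raise ValueError("no control samples among labels")
    ctl_mean = ctl.mean(axis=1)  # NaN-ignoring; NaN if no finite control
    no_control = list(ctl_mean.index[ctl_mean.isna()])

    tarr = tum.to_numpy(float)
    cm = ctl_mean.to_numpy(float)[:, None]
    ok = np.isfinite(tarr) & np.isfinite(cm) & (tarr > 0) & (cm > 0)
    n_nonpos = int(
        (np.isfinite(tarr) & np.isfinite(cm) & ((tarr <= 0) | (cm <= 0))).sum()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(ok, np.log2(np.where(ok, tarr, 1.0) /
                                 np.where(ok, cm, 1.0)), np.nan)
    values = pd.DataFrame(e, index=naturals.index, columns=tum.columns)
    return RatioMatrix(values=values, control_mean=ctl_mean,
                       n_nonpositive=n_nonpos, no_control=no_control)
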