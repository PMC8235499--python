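"""Background correction, masking, normalization and rescaling.

The stage order is fixed: multiplicative background correction (MBC) ->
negative-value masking -> between-array normalization (quantile, loess or
rank-invariant) -> global-mean rescaling -> replicate averaging.  All
operations are NaN-aware: a NaN cell means the symbol was not measured in
that sample's series and must stay NaN through every stage.

Zeros survive masking: only strictly negative values are removed, because
very low intensities can still be biologically informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "STAGE_ORDER",
    "ExpressionMatrix",
    "background_correct_mbc",
    "mask_negative",
    "normalize",
    "quantile_normalize",
    "loess_normalize",
    "rank_invariant_normalize",
    "compare_normalizations",
    "global_mean_rescale",
    "average_replicates",
    "validate_stage_sequence",
]

STAGE_ORDER = ("raw", "mbc", "masked", "normalized", "rescaled", "averaged")

NORMALIZATION_METHODS = ("quantile", "loess", "rank_invariant")


@dataclass
class ExpressionMatrix:
    """A values DataFrame plus its provenance trail through the pipeline."""

    values: pd.DataFrame
    stage: str = "raw"
    history: list = field(default_factory=list)

    def advance(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values, stage=stage, history=self.history + [self.stage]
        )

    def stages_seen(self) -> list:
        return self.history + [self.stage]


def validate_stage_sequence(stages) -> None:
    """Check that observed stage tags appear in the canonical order."""
    order = {s: i for i, s in enumerate(STAGE_ORDER)}
    idx = [order[s] for s in stages if s in order]
    if idx != sorted(idx):
        raise ValueError(f"stages out of order: {list(stages)}")


def background_correct_mbc(fg, bg=None):
    """Multiplicative background correction: log2(fg) - log2(bg) cellwise.

    Cells where either channel is non-positive become NaN.  When no
    background channel exists the foreground is log2-transformed and
    passed through flagged as "assumed background corrected".

    Returns ``(corrected, assumed_corrected_flag)``.
    """
    fg_arr = np.asarray(fg, dtype=float)
    if bg is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(fg_arr > 0, np.log2(np.where(fg_arr > 0, fg_arr, 1.0)),
                           np.nan)
        return _like(fg, out), True
    bg_arr = np.asarray(bg, dtype=float)
    if bg_arr.shape != fg_arr.shape:
        raise ValueError(
            f"foreground shape {fg_arr.shape} != background shape {bg_arr.shape}"
        )
    ok = (fg_arr > 0) & (bg_arr > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            ok,
            np.log2(np.where(ok, fg_arr, 1.0)) - np.log2(np.where(ok, bg_arr, 1.0)),
            np.nan,
        )
    return _like(fg, out), False


def _like(template, arr):
    if isinstance(template, pd.DataFrame):
        return pd.DataFrame(arr, index=template.index, columns=template.columns)
    return arr


def mask_negative(m):
    """Replace strictly negative entries with NaN; zeros are kept.

    Returns ``(masked, n_masked)``.
    """
    arr = np.asarray(m, dtype=float)
    neg = arr < 0
    out = np.where(neg, np.nan, arr)
    return _like(m, out), int(neg.sum())


# ---------------------------------------------------------------------------
# normalization


def quantile_normalize(m) -> pd.DataFrame:
    """NaN-aware quantile normalization onto the mean quantile profile.

    Ranks are computed over each column's non-NaN entries; the target
    profile is the across-column mean of sorted values on a common
    quantile grid, linearly interpolated to each column's own non-NaN
    count.  Tied values receive the average of their target slots, so the
    map is rank-preserving and permutation-equivariant.
    """
    df = m if isinstance(m, pd.DataFrame) else pd.DataFrame(np.asarray(m, float))
    arr = df.to_numpy(float)
    _check_normalizable(arr)
    counts = np.isfinite(arr).sum(axis=0)
    n_ref = int(counts.max())
    grid = np.linspace(0.0, 1.0, n_ref)
    profiles = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        vals = np.sort(col[np.isfinite(col)])
        if len(vals) < 2:
            continue
        q = np.linspace(0.0, 1.0, len(vals))
        profiles.append(np.interp(grid, q, vals))
    ref = np.mean(profiles, axis=0)

    out = arr.copy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        finite = np.isfinite(col)
        n = int(finite.sum())
        if n < 2:
            warnings.warn(f"column {j} has < 2 finite values; left unchanged")
            continue
        target = np.interp(np.linspace(0.0, 1.0, n), grid, ref)
        ranks = stats.rankdata(col[finite], method="average")  # 1..n, ties avg
        # average target slots for ties: interpolate target at rank-1 positions
        mapped = np.interp(ranks - 1.0, np.arange(n), target)
        out[finite, j] = mapped
    return _like(df, out)


def _row_median_reference(arr: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(arr, axis=1)


def loess_normalize(m, span: float = 0.4) -> pd.DataFrame:
    """MA-style loess normalization against the row-median pseudo-reference.

    For each column, M = column - reference is smoothed over
    A = (column + reference)/2 by local regression and the fitted trend is
    subtracted.  NaN cells are untouched.
    """
    df = m if isinstance(m, pd.DataFrame) else pd.DataFrame(np.asarray(m, float))
    arr = df.to_numpy(float)
    _check_normalizable(arr)
    ref = _row_median_reference(arr)
    out = arr.copy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        ok = np.isfinite(col) & np.isfinite(ref)
        if ok.sum() < 2:
            warnings.warn(f"column {j} has < 2 finite values; left unchanged")
            continue
        a = (col[ok] + ref[ok]) / 2.0
        mm = col[ok] - ref[ok]
        if np.ptp(a) == 0:  # constant abscissa: fall back to median offset
            fitted = np.full_like(mm, np.median(mm))
        else:
            fitted = lowess(mm, a, frac=span, return_sorted=False)
        out[ok, j] = col[ok] - fitted
    return _like(df, out)


def rank_invariant_normalize(m, threshold: float = 0.05,
                             span: float = 0.4) -> pd.DataFrame:
    """Rank-invariant normalization against the row-median pseudo-reference.

    Per column, features whose rank differs from their reference rank by
    at most ``threshold`` of the (finite) feature count form the invariant
    set; a smooth curve fitted through that set maps column values onto
    the reference scale.
    """
    df = m if isinstance(m, pd.DataFrame) else pd.DataFrame(np.asarray(m, float))
    arr = df.to_numpy(float)
    _check_normalizable(arr)
    ref = _row_median_reference(arr)
    out = arr.copy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        ok = np.isfinite(col) & np.isfinite(ref)
        n = int(ok.sum())
        if n < 2:
            warnings.warn(f"column {j} has < 2 finite values; left unchanged")
            continue
        rc = stats.rankdata(col[ok])
        rr = stats.rankdata(ref[ok])
        inv = np.abs(rc - rr) <= threshold * n
        if inv.sum() < max(3, int(0.01 * n)):
            inv = np.ones(n, dtype=bool)  # degenerate: use all points
        x = col[ok][inv]
        y = ref[ok][inv]
        order = np.argsort(x)
        x_s, y_s = x[order], y[order]
        if np.ptp(x_s) == 0:
            out[ok, j] = col[ok] + (np.median(y_s) - x_s[0])
            continue
        fit = lowess(y_s, x_s, frac=span, return_sorted=True)
        out[ok, j] = np.interp(col[ok], fit[:, 0], fit[:, 1])
    return _like(df, out)


def _check_normalizable(arr: np.ndarray) -> None:
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("normalization needs a 2-D matrix with >= 2 columns")


def normalize(m, method: str = "quantile", **kwargs) -> pd.DataFrame:
    """Dispatch to one of the three between-array normalizers."""
    if method == "quantile":
        return quantile_normalize(m)
    if method == "loess":
        return loess_normalize(m, **kwargs)
    if method == "rank_invariant":
        return rank_invariant_normalize(m, **kwargs)
    raise ValueError(
        f"unknown normalization method {method!r}; "
        f"valid methods: {list(NORMALIZATION_METHODS)}"
    )


def compare_normalizations(m, methods=NORMALIZATION_METHODS,
                           include_none: bool = True) -> pd.DataFrame:
    """Score normalizers by between-column distribution agreement.

    Two criteria, lower = better: the mean pairwise two-sample
    Kolmogorov-Smirnov distance between column distributions, and the
    variance of column medians.  The report ranks methods by mean KS
    distance; the choice of criteria is this package's own (explicit
    rather than implicit).
    """
    df = m if isinstance(m, pd.DataFrame) else pd.DataFrame(np.asarray(m, float))
    candidates = {}
    if include_none:
        candidates["none"] = df
    for meth in methods:
        candidates[meth] = normalize(df, meth)
    rows = []
    for name, normed in candidates.items():
        arr = normed.to_numpy(float)
        cols = [c[np.isfinite(c)] for c in arr.T]
        cols = [c for c in cols if len(c) >= 2]
        ks = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                ks.append(stats.ks_2samp(cols[i], cols[j]).statistic)
        med_var = float(np.var([np.median(c) for c in cols]))
        rows.append((name, float(np.mean(ks)) if ks else np.nan, med_var))
    report = pd.DataFrame(
        rows, columns=["method", "mean_ks_distance", "median_variance"]
    ).set_index("method")
    report["rank"] = report["mean_ks_distance"].rank(method="min").astype(int)
    return report.sort_values("mean_ks_distance")


# ---------------------------------------------------------------------------
# rescaling and replicate averaging


def unlog2(m):
    """Return the matrix to intensity scale (2**x), NaN preserved.

    Background correction works in log2 space; the "naturals"
    representation downstream is explicitly non-log-transformed, so the
    normalized log-scale matrix is exponentiated before global-mean
    rescaling.  On intensity scale a planted log2 shift survives into the
    tumor/control ratio at full size instead of being double-logged away.
    """
    arr = np.asarray(m, dtype=float)
    return _like(m, np.power(2.0, arr))


def global_mean_rescale(m):
    """Divide every cell by the global mean of the non-NaN cells.

    Equivalent to the log2-then-exponentiate form
    R_ij = log2(x_ij / xbar), X_ij = 2^R_ij.  After rescaling the mean of
    the non-NaN entries is 1 to numerical tolerance.
    """
    arr = np.asarray(m, dtype=float)
    gm = np.nanmean(arr)
    if not np.isfinite(gm) or gm <= 0:
        raise ValueError(f"global mean must be positive, got {gm}")
    return _like(m, arr / gm)


def average_replicates(m: pd.DataFrame, symbol_of_row=None) -> pd.DataFrame:
    """Collapse replicate rows of one symbol to their NaN-ignoring mean.

    ``m`` may carry a (symbol, rep) MultiIndex — the hyper-matrix layout —
    or a plain index with an explicit ``symbol_of_row`` mapping.  A cell
    of the output is NaN iff every contributing replicate cell is NaN.
    """
    if symbol_of_row is not None:
        keys = pd.Index([symbol_of_row[r] for r in m.index], name="symbol")
    elif isinstance(m.index, pd.MultiIndex):
        keys = m.index.get_level_values(0)
    else:
        keys = m.index
    grouped = m.groupby(keys, sort=True).mean()
    grouped.index.name = "symbol"
    return grouped
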