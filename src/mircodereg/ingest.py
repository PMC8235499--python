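"""Reading per-series expression tables and assembling the hyper-matrix.

Heterogeneous miRNA microarray series measure partially overlapping feature
universes on different platforms.  The only identifier shared across
platforms is the miRNA symbol, so symbols are canonicalized
(``hsa-miR-149`` -> ``MIR149``) and used as the row key of a single
features x samples "hyper-matrix" in which each series occupies its own
block of sample columns and every cell a series did not measure is NaN.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SymbolError",
    "CanonicalSymbol",
    "SeriesTable",
    "HyperMatrix",
    "SampleMetadata",
    "canonicalize_symbol",
    "assemble_hypermatrix",
    "exclude_by_age",
    "read_series_table",
    "write_series_table",
]

VALID_GRADES = frozenset({"I", "II", "III", "IV", "CONTROL", "NA"})


class SymbolError(ValueError):
    """Raised for a miRNA symbol that cannot be mapped to canonical form."""


@dataclass(frozen=True)
class CanonicalSymbol:
    """A canonical miRNA symbol plus the mature-arm tag it carried, if any."""

    symbol: str
    arm: str | None = None


_ARM_RE = re.compile(r"[-._](5p|3p)$", re.IGNORECASE)
_PREFIX_RE = re.compile(r"^(hsa|mmu|rno)[-_]", re.IGNORECASE)
_CANON_RE = re.compile(r"^MIR(LET)?[0-9]+[A-Z0-9]*$")


def canonicalize_symbol(raw: str, collapse_arm: bool = True) -> CanonicalSymbol:
    """Map a raw platform miRNA identifier to its canonical gene symbol.

    The rule is deterministic: strip the species prefix (``hsa-``),
    uppercase, map ``miR-``/``let-`` stems to ``MIR``/``MIRLET``, drop
    hyphens.  With ``collapse_arm`` (default) a trailing ``-5p``/``-3p``
    mature-arm tag is removed and recorded separately, so both arms of one
    hairpin share a row; with ``collapse_arm=False`` the arm stays part of
    the symbol.

    Raises
    ------
    SymbolError
        If ``raw`` is empty or does not resemble a miRNA identifier.
    """
    if raw is None or not str(raw).strip():
        raise SymbolError("empty miRNA symbol")
    s = str(raw).strip()
    s = _PREFIX_RE.sub("", s)

    arm: str | None = None
    m = _ARM_RE.search(s)
    if m:
        if collapse_arm:
            arm = m.group(1).lower()
            s = s[: m.start()]
        else:
            s = s[: m.start()] + s[m.start():].replace("-", "").replace(".", "")

    s = s.upper()
    if s.startswith("LET"):
        s = "MIR" + s
    s = s.replace("-", "").replace("_", "").replace("*", "")
    if not s.startswith("MIR"):
        # bare numeric stems like "miR149" already handled; anything else
        # (spike-ins, control probes) is unmappable
        raise SymbolError(f"unmappable miRNA symbol: {raw!r}")
    if not _CANON_RE.match(s):
        raise SymbolError(f"unmappable miRNA symbol: {raw!r}")
    return CanonicalSymbol(s, arm)


@dataclass
class SeriesTable:
    """One microarray series: raw symbols, sample columns, intensity channels.

    ``foreground`` is features x samples; ``background``, when the platform
    provides one, has the same shape and feeds multiplicative background
    correction downstream.
    """

    series_id: str
    platform_id: str
    feature_symbols: list[str]
    sample_ids: list[str]
    foreground: np.ndarray
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.foreground = np.asarray(self.foreground, dtype=float)
        expected = (len(self.feature_symbols), len(self.sample_ids))
        if self.foreground.shape != expected:
            raise ValueError(
                f"series {self.series_id}: foreground shape "
                f"{self.foreground.shape} != {expected}"
            )
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != expected:
                raise ValueError(
                    f"series {self.series_id}: background shape "
                    f"{self.background.shape} != {expected}"
                )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise ValueError(
                f"series {self.series_id}: duplicate sample ids {dupes}"
            )


@dataclass
class HyperMatrix:
    """Sparse multi-series expression matrix with per-sample provenance.

    Rows are (canonical symbol, within-series replicate index) pairs until
    replicate averaging collapses them; a cell is NaN iff the sample's
    series did not measure that symbol occurrence (or it was masked later).
    """

    values: pd.DataFrame  # MultiIndex rows (symbol, rep) or plain symbol index
    series_of_sample: dict[str, str]
    arm_of_symbol: dict[str, set] = field(default_factory=dict)
    unmapped: list[tuple[str, str]] = field(default_factory=list)  # (series, raw)

    @property
    def symbols(self) -> list[str]:
        idx = self.values.index
        if isinstance(idx, pd.MultiIndex):
            return list(dict.fromkeys(idx.get_level_values(0)))
        return list(idx)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def n_observed(self) -> int:
        """Count of non-NaN cells."""
        return int(np.isfinite(self.values.to_numpy()).sum())


@dataclass
class SampleMetadata:
    """Per-sample categorical and demographic variables.

    The table is indexed by sample id and carries gender, age_years,
    gestational_age_years, sampling, diagnosis at three granularities
    (neoplasm/control; malignant/benign/control; entity), grade, and
    developmental status.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        if "grade" in t.columns:
            bad = set(t["grade"].dropna().astype(str)) - VALID_GRADES
            if bad:
                raise ValueError(f"invalid grade values: {sorted(bad)}")
        if {"diagnosis1", "diagnosis2"} <= set(t.columns):
            neoplastic = t["diagnosis2"].isin(["malignant", "benign"])
            bad_rows = t.index[neoplastic & (t["diagnosis1"] != "neoplasm")]
            if len(bad_rows):
                raise ValueError(
                    "diagnosis1 inconsistent with diagnosis2 for samples: "
                    f"{list(bad_rows[:5])}"
                )

    @classmethod
    def from_csv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def assemble_hypermatrix(
    series: Sequence[SeriesTable],
    collapse_arm: bool = True,
    values: str = "foreground",
) -> HyperMatrix:
    """Stack series into the block-diagonal hyper-matrix.

    The row universe is the union of canonical symbols across all series;
    each series' samples form a column block; a symbol measured more than
    once within a series occupies distinct replicate rows until the
    explicit replicate-averaging stage.  Unmappable raw symbols are
    collected into ``HyperMatrix.unmapped``, never silently dropped.

    Parameters
    ----------
    values
        Which channel to place into the matrix (``"foreground"`` by
        default; pass a pre-corrected SeriesTable to assemble corrected
        values).
    """
    if not series:
        raise ValueError("need at least one series")
    seen_samples: dict[str, str] = {}
    for st in series:
        for sid in st.sample_ids:
            if sid in seen_samples:
                raise ValueError(
                    f"sample id {sid!r} appears in both series "
                    f"{seen_samples[sid]!r} and {st.series_id!r}"
                )
            seen_samples[sid] = st.series_id

    arm_of_symbol: dict[str, set] = {}
    unmapped: list[tuple[str, str]] = []
    # per series: row key (symbol, replicate index) -> row of values
    blocks: list[pd.DataFrame] = []
    for st in series:
        mat = getattr(st, values)
        if mat is None:
            raise ValueError(f"series {st.series_id} lacks channel {values!r}")
        counts: dict[str, int] = {}
        keys: list[tuple[str, int]] = []
        keep_rows: list[int] = []
        for i, raw in enumerate(st.feature_symbols):
            try:
                canon = canonicalize_symbol(raw, collapse_arm=collapse_arm)
            except SymbolError:
                unmapped.append((st.series_id, raw))
                continue
            rep = counts.get(canon.symbol, 0)
            counts[canon.symbol] = rep + 1
            keys.append((canon.symbol, rep))
            keep_rows.append(i)
            if canon.arm:
                arm_of_symbol.setdefault(canon.symbol, set()).add(canon.arm)
        block = pd.DataFrame(
            np.asarray(mat, dtype=float)[keep_rows, :],
            index=pd.MultiIndex.from_tuples(keys, names=["symbol", "rep"]),
            columns=st.sample_ids,
        )
        # replicate keys are unique within a series by construction
        blocks.append(block)

    all_keys = sorted(set().union(*(b.index for b in blocks)))
    row_index = pd.MultiIndex.from_tuples(all_keys, names=["symbol", "rep"])
    cols = [sid for st in series for sid in st.sample_ids]
    out = pd.DataFrame(np.nan, index=row_index, columns=cols)
    for b in blocks:
        out.loc[b.index, b.columns] = b.to_numpy()
    return HyperMatrix(
        values=out,
        series_of_sample=seen_samples,
        arm_of_symbol=arm_of_symbol,
        unmapped=unmapped,
    )


def exclude_by_age(
    hm: HyperMatrix, meta: SampleMetadata, max_age: float = 60.0
) -> tuple[HyperMatrix, dict]:
    """Drop samples older than ``max_age`` years from the hyper-matrix.

    Samples with missing age are retained but flagged in the report, in
    line with the permissive handling of incomplete metadata elsewhere in
    the pipeline.
    """
    missing_meta = [s for s in hm.sample_ids if s not in meta.table.index]
    if missing_meta:
        raise ValueError(f"metadata missing for samples: {missing_meta[:10]}")
    ages = meta.table.loc[hm.sample_ids, "age_years"]
    removed = [s for s, a in ages.items() if pd.notna(a) and a > max_age]
    no_age = [s for s, a in ages.items() if pd.isna(a)]
    kept = [s for s in hm.sample_ids if s not in set(removed)]
    report = {
        "max_age": max_age,
        "removed": removed,
        "n_removed": len(removed),
        "retained_missing_age": no_age,
    }
    out = HyperMatrix(
        values=hm.values[kept],
        series_of_sample={s: hm.series_of_sample[s] for s in kept},
        arm_of_symbol=hm.arm_of_symbol,
        unmapped=hm.unmapped,
    )
    return out, report


# ---------------------------------------------------------------------------
# tab-delimited I/O

_BKG_SUFFIX = "_BKG"


def read_series_table(path, series_id: str, platform_id: str = "") -> SeriesTable:
    """Read one series from tab-delimited text.

    First column holds feature symbols; every other column is a sample.
    A column named ``<sample>_BKG`` is treated as the background channel
    paired with column ``<sample>``.
    """
    df = pd.read_table(path, index_col=0)
    bkg_cols = [c for c in df.columns if c.endswith(_BKG_SUFFIX)]
    fg_cols = [c for c in df.columns if not c.endswith(_BKG_SUFFIX)]
    background = None
    if bkg_cols:
        expected = [c + _BKG_SUFFIX for c in fg_cols]
        if sorted(bkg_cols) != sorted(expected):
            raise ValueError(
                f"{path}: background columns {bkg_cols} do not pair with "
                f"sample columns {fg_cols}"
            )
        background = df[[c + _BKG_SUFFIX for c in fg_cols]].to_numpy(float)
    return SeriesTable(
        series_id=series_id,
        platform_id=platform_id,
        feature_symbols=[str(s) for s in df.index],
        sample_ids=[str(c) for c in fg_cols],
        foreground=df[fg_cols].to_numpy(float),
        background=background,
    )


def write_series_table(st: SeriesTable, path) -> None:
    df = pd.DataFrame(
        st.foreground, index=st.feature_symbols, columns=st.sample_ids
    )
    if st.background is not None:
        for j, sid in enumerate(st.sample_ids):
            df[sid + _BKG_SUFFIX] = st.background[:, j]
    df.index.name = "miRNA"
    df.to_csv(path, sep="\t", na_rep="NaN")


def write_hypermatrix(hm: HyperMatrix, path) -> None:
    """Serialize as TSV with literal ``NaN`` tokens for missing cells."""
    df = hm.values.copy()
    if isinstance(df.index, pd.MultiIndex):
        df.index = [f"{sym}|rep{rep}" for sym, rep in df.index]
    df.index.name = "miRNA"
    df.to_csv(path, sep="\t", na_rep="NaN")
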