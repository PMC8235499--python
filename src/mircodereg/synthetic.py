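"""Synthetic multi-series miRNA microarray generator.

Emulates the statistical structure the meta-analysis assumes: several
series with partially overlapping miRNA universes (block-diagonal
missingness once stacked), per-series multiplicative batch effects,
optional background channels, planted globally down-regulated miRNAs,
partially penetrant up-regulated miRNAs, and grade-ordered expression
signatures — together with a cohort metadata sheet (age, diagnosis at
three granularities, grade, developmental status) and a GroundTruth record
of every planted effect.

It does not attempt probe-level thermodynamics, dye bias, or realistic
GEO SOFT files; see docs/methods.md for what passing tests on these data
do and do not show about real arrays.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import SeriesTable, SampleMetadata, canonicalize_symbol

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_multiseries",
    "generate_annotation",
    "write_bundle",
]

# canonical five-marker set used as the default planted global signature
DEFAULT_DOWN_MARKERS = ("MIR149", "MIR214", "MIR574", "MIR595", "MIR765")
DEFAULT_UP_PARTIAL = (("MIR376B", 0.85), ("MIR372", 0.76))

# ascending grade signature: controls lowest, then IV, then I < II < III
GRADE_ORDER = ("CONTROL", "IV", "I", "II", "III")

_ENTITIES = (
    # (diagnosis3, diagnosis2, grade)
    ("medulloblastoma", "malignant", "IV"),
    ("glioblastoma", "malignant", "IV"),
    ("ATRT", "malignant", "IV"),
    ("ependymoma", "malignant", "II"),
    ("astrocytoma", "malignant", "III"),
    ("astrocytoma", "benign", "I"),
    ("cortical dysplasia", "benign", "I"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition knobs for the generator.

    Defaults describe the reference conditions used throughout the test
    suite: 3 series of 100 features each sharing 50 (union of 200
    symbols), 40 tumors vs 20 controls, five fully penetrant
    down-regulated markers shifted by 2.0 log2 units, cell noise SD 0.5
    log2 units and series batch SD 0.5 log2 units.
    """

    n_series: int = 3
    features_per_series: int = 100
    shared_features: int = 50
    n_tumor: int = 40
    n_control: int = 20
    planted_down_100: tuple = DEFAULT_DOWN_MARKERS
    planted_up_partial: tuple = DEFAULT_UP_PARTIAL
    planted_shift: float = 2.0  # log2 units
    batch_scale_sd: float = 0.5  # log2-scale SD of the series factor
    noise_sd: float = 0.5  # log2-scale per-cell noise
    background_fraction: float = 0.01  # mean background / foreground ratio
    grade_ordered_features: tuple = ()
    grade_step: float = 0.75  # log2 increment per grade rank
    missing_block: bool = True
    n_old_decoys: int = 3  # extra >60 y samples exercising the age rule
    baseline_mean: float = 8.0  # log2-scale baseline intensity mean
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.shared_features > self.features_per_series:
            raise ValueError(
                "invalid config: shared_features "
                f"({self.shared_features}) exceeds features_per_series "
                f"({self.features_per_series})"
            )
        for name in ("n_series", "features_per_series", "shared_features",
                     "n_tumor", "n_control"):
            if getattr(self, name) < 1:
                raise ValueError(f"invalid config: {name} must be >= 1")
        if not (0 <= self.background_fraction < 1):
            raise ValueError(
                "invalid config: background_fraction must be in [0, 1)"
            )
        for name in ("batch_scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config: {name} must be >= 0")
        shared = set(self._shared_symbols())
        planted = set(self.planted_down_100) | {
            s for s, _ in self.planted_up_partial
        } | set(self.grade_ordered_features)
        stray = planted - shared
        if stray:
            raise ValueError(
                "invalid config: planted features must be among the shared "
                f"features (observable in every series); not shared: "
                f"{sorted(stray)}"
            )
        for sym, pen in self.planted_up_partial:
            if not (0 < pen <= 1):
                raise ValueError(
                    f"invalid config: penetrance for {sym} must be in (0, 1], "
                    f"got {pen}"
                )

    # ---- feature universe -------------------------------------------------
    def _shared_symbols(self) -> list[str]:
        named = list(self.planted_down_100) + [
            s for s, _ in self.planted_up_partial
        ] + [s for s in self.grade_ordered_features]
        named = list(dict.fromkeys(named))
        fillers = [f"MIR{9000 + i}" for i in range(self.shared_features)]
        return (named + fillers)[: self.shared_features]

    def _private_symbols(self, series_idx: int) -> list[str]:
        n_private = self.features_per_series - self.shared_features
        base = 9500 + 500 * series_idx
        return [f"MIR{base + i}" for i in range(n_private)]

    def universe(self) -> list[str]:
        syms = self._shared_symbols()
        for s in range(self.n_series):
            syms += self._private_symbols(s)
        return syms


def _raw_name(symbol: str) -> str:
    """Platform-style raw identifier for a canonical symbol (hsa-miR-149)."""
    stem = symbol[3:]
    m = ""
    for ch in stem:
        m += ch.lower() if ch.isalpha() else ch
    return f"hsa-miR-{m}"


@dataclass
class GroundTruth:
    """Record of every planted effect, for downstream recovery checks."""

    planted: list = field(default_factory=list)
    tumor_ids: list = field(default_factory=list)
    control_ids: list = field(default_factory=list)
    decoy_ids: list = field(default_factory=list)
    batch_log2_factor: dict = field(default_factory=dict)
    measured_symbols: dict = field(default_factory=dict)  # series -> [symbol]
    baseline_log2: dict = field(default_factory=dict)
    grade_order: tuple = GRADE_ORDER

    def down_100_symbols(self) -> list[str]:
        return sorted(
            p["symbol"]
            for p in self.planted
            if p["direction"] == "down" and p["penetrance"] == 1.0
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def generate_multiseries(
    config: SyntheticConfig,
) -> tuple[list[SeriesTable], SampleMetadata, GroundTruth]:
    """Draw a full multi-series bundle under ``config``.

    Identical configs (including seed) give bit-identical output: a single
    seeded generator drives every draw in a fixed order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    shared = config._shared_symbols()
    universe = config.universe()
    n_feat = len(universe)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_feat)
    # planted markers are modeled as robustly expressed but inside the
    # array's dynamic range: a miRNA assayable in every sample of every
    # platform sits above the detection floor, yet a marker at the very top
    # of the intensity scale would lose its shift to rank saturation under
    # quantile normalization.  Their baselines are therefore remapped into
    # [mean, mean + sd] via the probability transform of the same draw.
    planted_syms = set(config.planted_down_100) | {
        s for s, _ in config.planted_up_partial
    } | set(config.grade_ordered_features)
    for i, sym in enumerate(universe):
        if sym in planted_syms:
            z = (baseline[i] - config.baseline_mean) / config.baseline_sd
            baseline[i] = (
                config.baseline_mean + config.baseline_sd * stats.norm.cdf(z)
            )
    baseline_of = dict(zip(universe, baseline))

    tumor_ids = [f"T{i + 1:03d}" for i in range(config.n_tumor)]
    control_ids = [f"C{i + 1:03d}" for i in range(config.n_control)]
    decoy_ids = [f"D{i + 1:03d}" for i in range(config.n_old_decoys)]
    all_ids = tumor_ids + control_ids + decoy_ids

    gt = GroundTruth(
        tumor_ids=tumor_ids,
        control_ids=control_ids,
        decoy_ids=decoy_ids,
        baseline_log2={s: float(v) for s, v in baseline_of.items()},
    )

    # ---- metadata ---------------------------------------------------------
    meta_rows = {}
    entity_draw = rng.integers(0, len(_ENTITIES), size=config.n_tumor)
    tumor_ages = rng.uniform(0.03, 19.0, size=config.n_tumor)
    control_ages = rng.uniform(0.0, 27.0, size=config.n_control)
    decoy_ages = rng.uniform(61.0, 75.0, size=config.n_old_decoys)
    genders = rng.choice(["male", "female"], size=len(all_ids))
    gender_missing = rng.random(len(all_ids)) < 0.1

    def dev_status(age: float) -> str:
        if age < 0.077:
            return "neonate"
        if age < 1:
            return "infant"
        if age < 12:
            return "child"
        if age < 18:
            return "adolescent"
        return "adult"

    for i, sid in enumerate(tumor_ids):
        d3, d2, grade = _ENTITIES[entity_draw[i]]
        meta_rows[sid] = dict(
            gender=np.nan if gender_missing[i] else genders[i],
            age_years=round(float(tumor_ages[i]), 2),
            gestational_age_years=round(float(tumor_ages[i]) + 0.74, 2),
            sampling="vivus",
            diagnosis1="neoplasm",
            diagnosis2=d2,
            diagnosis3=d3,
            grade=grade,
            developmental_status=dev_status(tumor_ages[i]),
            outcome="alive",
        )
    for i, sid in enumerate(control_ids):
        j = config.n_tumor + i
        meta_rows[sid] = dict(
            gender=np.nan if gender_missing[j] else genders[j],
            age_years=round(float(control_ages[i]), 2),
            gestational_age_years=round(float(control_ages[i]) + 0.74, 2),
            sampling="post-mortem",
            diagnosis1="control",
            diagnosis2="control",
            diagnosis3="control",
            grade="CONTROL",
            developmental_status=dev_status(control_ages[i]),
            outcome="NA",
        )
    for i, sid in enumerate(decoy_ids):
        j = config.n_tumor + config.n_control + i
        meta_rows[sid] = dict(
            gender=np.nan if gender_missing[j] else genders[j],
            age_years=round(float(decoy_ages[i]), 2),
            gestational_age_years=round(float(decoy_ages[i]) + 0.74, 2),
            sampling="vivus",
            diagnosis1="control",
            diagnosis2="control",
            diagnosis3="control",
            grade="CONTROL",
            developmental_status="adult",
            outcome="NA",
        )
    meta = SampleMetadata(pd.DataFrame.from_dict(meta_rows, orient="index"))

    # ---- planted effects (log2-scale shifts per feature x sample) ---------
    shift = np.zeros((n_feat, len(all_ids)))
    row_of = {s: i for i, s in enumerate(universe)}
    col_of = {s: j for j, s in enumerate(all_ids)}
    tumor_cols = [col_of[s] for s in tumor_ids]

    for sym in config.planted_down_100:
        shift[row_of[sym], tumor_cols] -= config.planted_shift
        gt.planted.append(dict(
            symbol=sym, direction="down", penetrance=1.0,
            shift_log2=config.planted_shift, affected_samples=list(tumor_ids),
        ))
    for sym, pen in config.planted_up_partial:
        n_hit = math.ceil(pen * config.n_tumor)
        hit = rng.choice(config.n_tumor, size=n_hit, replace=False)
        hit_ids = sorted(tumor_ids[h] for h in hit)
        shift[row_of[sym], [col_of[s] for s in hit_ids]] += config.planted_shift
        gt.planted.append(dict(
            symbol=sym, direction="up", penetrance=float(pen),
            shift_log2=config.planted_shift, affected_samples=hit_ids,
        ))
    grade_rank = {g: r for r, g in enumerate(GRADE_ORDER)}
    for sym in config.grade_ordered_features:
        for sid in all_ids:
            r = grade_rank.get(str(meta.table.loc[sid, "grade"]), 0)
            shift[row_of[sym], col_of[sid]] += r * config.grade_step
        gt.planted.append(dict(
            symbol=sym, direction="grade-ordered",
            penetrance=1.0, shift_log2=config.grade_step,
            affected_samples=list(all_ids),
        ))

    # ---- series assembly --------------------------------------------------
    # samples dealt round-robin so each series holds tumors and controls
    series_of: dict[str, int] = {
        sid: i % config.n_series for i, sid in enumerate(all_ids)
    }
    batch = rng.normal(0.0, config.batch_scale_sd, size=config.n_series)
    noise = rng.normal(0.0, config.noise_sd, size=(n_feat, len(all_ids)))

    log2_full = baseline[:, None] + shift + batch[None, :][
        :, [series_of[s] for s in all_ids]
    ].reshape(1, -1) + noise

    series_tables: list[SeriesTable] = []
    for s in range(config.n_series):
        if config.missing_block:
            feats = shared + config._private_symbols(s)
        else:
            feats = list(universe)
        frows = [row_of[f] for f in feats]
        cols = [sid for sid in all_ids if series_of[sid] == s]
        fcols = [col_of[c] for c in cols]
        fg = np.power(2.0, log2_full[np.ix_(frows, fcols)])
        background = None
        has_bkg = config.background_fraction > 0 and s % 2 == 0
        if has_bkg:
            # background independent of the per-cell signal so MBC keeps it;
            # its variability scales with the configured noise level
            bg_noise = rng.normal(0.0, 0.5 * config.noise_sd, size=fg.shape)
            background = (
                config.background_fraction * fg.mean() * np.power(2.0, bg_noise)
            )
        series_tables.append(SeriesTable(
            series_id=f"SYN{s + 1}",
            platform_id=f"PLAT{s + 1}",
            feature_symbols=[_raw_name(f) for f in feats],
            sample_ids=cols,
            foreground=fg,
            background=background,
        ))
        gt.batch_log2_factor[f"SYN{s + 1}"] = float(batch[s])
        gt.measured_symbols[f"SYN{s + 1}"] = list(feats)

    return series_tables, meta, gt


def generate_annotation(feature_ids, seed: int = 0) -> pd.DataFrame:
    """Deterministically assign each feature a chromosome and cytoband.

    Returns a DataFrame indexed by feature id with ``chromosome`` and
    ``cytoband`` columns.  Purely synthetic positions: they exercise the
    per-chromosome / per-cytoband summaries, not real miRNA loci.
    """
    ids = list(feature_ids)
    dupes = sorted({f for f in ids if ids.count(f) > 1})
    if dupes:
        raise ValueError(f"duplicate feature ids: {dupes}")
    rng = np.random.default_rng(seed)
    chroms = [str(c) for c in range(1, 23)] + ["X", "Y"]
    rows = []
    for fid in ids:
        c = chroms[int(rng.integers(0, len(chroms)))]
        arm = "p" if rng.random() < 0.4 else "q"
        band = f"{c}{arm}{int(rng.integers(1, 4))}{int(rng.integers(1, 10))}" \
               f".{int(rng.integers(1, 4))}"
        rows.append((fid, c, band))
    return pd.DataFrame(
        rows, columns=["feature", "chromosome", "cytoband"]
    ).set_index("feature")


def write_bundle(
    series: list[SeriesTable],
    meta: SampleMetadata,
    gt: GroundTruth,
    outdir,
) -> None:
    """Write series TSVs, metadata CSV and ground-truth JSON under outdir."""
    from .ingest import write_series_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for st in series:
        write_series_table(st, outdir / f"{st.series_id}.tsv")
    meta.to_csv(outdir / "metadata.csv")
    gt.to_json(outdir / "ground_truth.json")
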