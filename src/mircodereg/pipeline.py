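"""End-to-end orchestration of the meta-analysis stages.

ingest -> background correction -> masking -> normalization -> global-mean
rescaling -> replicate averaging -> differential testing -> ratio matrix
-> k-means/CH clustering -> co-deregulation scan -> ROC / naive Bayes.

A single seed in the config fans out deterministically to per-stage seeds
by stable hashing, so each stage is individually reproducible and an
identical config yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, codereg, diagnostics, differential, preprocess
from .ingest import (HyperMatrix, SampleMetadata, assemble_hypermatrix,
                     exclude_by_age, read_series_table, write_hypermatrix)
from .synthetic import SyntheticConfig, generate_annotation, generate_multiseries

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from the run seed."""
    return (int(base_seed) * 100003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with study defaults.

    With ``simulate=True`` the synthetic generator provides the input
    bundle; otherwise ``series_dir`` + ``metadata`` are read from disk.
    """

    simulate: bool = True
    series_dir: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    outdir: str | None = None
    seed: int = 0
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides

    max_age: float = 60.0
    collapse_arm: bool = True
    normalization_method: str = "quantile"
    loess_span: float = 0.4
    rank_invariant_threshold: float = 0.05
    t_variant: str = "pooled"
    p_max: float = 0.05
    q_max: float = 0.05
    denominator: int | None = None  # None = per-symbol non-missing policy
    min_band: str = "75-80"
    min_coverage: float = 0.8
    k_min: int = 2
    k_max: int = 8
    n_restarts: int = 10
    linkage: str = "average"
    nb_folds: int = 5
    n_markers: int = 5

    _KNOWN = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # output location is not an analytic parameter
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything a run produced, stage by stage."""

    config: PipelineConfig
    meta: SampleMetadata
    ground_truth: object | None
    hypermatrix: HyperMatrix
    age_report: dict
    naturals: pd.DataFrame
    labels: pd.Series
    de_result: differential.DEResult
    de_selected: list
    ratios: differential.RatioMatrix | None
    scores_all: pd.DataFrame | None  # log2(x / control mean), all samples
    k_star: int | None
    cluster_model: clustering.ClusterModel | None
    codereg_table: pd.DataFrame
    roc_results: list
    nb_report: diagnostics.NBayesReport | None
    chrom: dict | None
    manifest: dict


def _labels_from_meta(meta: SampleMetadata, samples) -> pd.Series:
    d1 = meta.table.loc[samples, "diagnosis1"].astype(str)
    return d1.map(lambda v: "tumor" if v == "neoplasm" else "control")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; write the output bundle if ``outdir`` is set."""
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)

    # ---- stage 1: inputs --------------------------------------------------
    ground_truth = None
    if config.simulate:
        syn = SyntheticConfig(
            **{"seed": stage_seed(config.seed, "simulate"),
               **config.synthetic}
        )
        series, meta, ground_truth = generate_multiseries(syn)
        say(f"simulated {len(series)} series, "
            f"{len(meta.table)} samples (seed {syn.seed})")
    else:
        if not config.series_dir or not config.metadata:
            raise ValueError("series_dir and metadata required when "
                             "simulate is False")
        sdir = Path(config.series_dir)
        paths = sorted(sdir.glob("*.tsv"))
        if not paths:
            raise ValueError(f"no .tsv series tables under {sdir}")
        series = [read_series_table(p, series_id=p.stem) for p in paths]
        meta = SampleMetadata.from_csv(config.metadata)
        say(f"read {len(series)} series from {sdir}")

    # ---- stage 2: MBC + hyper-matrix assembly -----------------------------
    corrected = []
    for st in series:
        corr, assumed = preprocess.background_correct_mbc(
            st.foreground, st.background
        )
        if assumed:
            say(f"series {st.series_id}: no background channel, "
                "considered background corrected")
        st2 = type(st)(
            series_id=st.series_id, platform_id=st.platform_id,
            feature_symbols=st.feature_symbols, sample_ids=st.sample_ids,
            foreground=np.asarray(corr),
        )
        corrected.append(st2)
    hm = assemble_hypermatrix(corrected, collapse_arm=config.collapse_arm)
    say(f"hyper-matrix {hm.values.shape[0]} rows x "
        f"{hm.values.shape[1]} samples, {hm.n_observed()} observed cells, "
        f"{len(hm.unmapped)} unmapped symbols")

    # ---- stage 3: cohort exclusion ----------------------------------------
    hm, age_report = exclude_by_age(hm, meta, max_age=config.max_age)
    say(f"age rule (> {config.max_age} y): removed "
        f"{age_report['n_removed']} samples")

    # ---- stages 4-7: mask, normalize, rescale, average --------------------
    masked, n_masked = preprocess.mask_negative(hm.values)
    say(f"masked {n_masked} negative cells")
    kwargs = {}
    if config.normalization_method == "loess":
        kwargs["span"] = config.loess_span
    elif config.normalization_method == "rank_invariant":
        kwargs["threshold"] = config.rank_invariant_threshold
    normed = preprocess.normalize(masked, config.normalization_method,
                                  **kwargs)
    # back to intensity scale: "naturals" are non-log-transformed values
    rescaled = preprocess.global_mean_rescale(preprocess.unlog2(normed))
    naturals = preprocess.average_replicates(rescaled)
    stages = ["raw", "mbc", "masked", "normalized", "rescaled", "averaged"]
    preprocess.validate_stage_sequence(stages)
    say(f"naturals: {naturals.shape[0]} symbols x "
        f"{naturals.shape[1]} samples "
        f"(global mean {np.nanmean(rescaled.to_numpy()):.9f})")

    # ---- stage 8: differential expression ---------------------------------
    labels = _labels_from_meta(meta, list(naturals.columns))
    de_result = differential.t_test_per_symbol(
        naturals, labels, variant=config.t_variant
    )
    de_selected = differential.select_de(
        de_result, p_max=config.p_max, q_max=config.q_max
    )
    say(f"DE: {len(de_selected)} symbols at p < {config.p_max}, "
        f"q < {config.q_max} ({len(de_result.untested)} untested)")

    # ---- stage 9: ratios ---------------------------------------------------
    ratios = None
    scores_all = None
    if de_selected:
        ratios = differential.tumor_to_control_ratio(
            naturals.loc[de_selected], labels
        )
        cm = ratios.control_mean
        ok = naturals.loc[de_selected].gt(0).to_numpy() & \
            np.isfinite(naturals.loc[de_selected].to_numpy()) & \
            (cm.to_numpy() > 0)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            sa = np.where(ok, np.log2(
                naturals.loc[de_selected].to_numpy() / cm.to_numpy()[:, None]
            ), np.nan)
        scores_all = pd.DataFrame(sa, index=de_selected,
                                  columns=naturals.columns)

    # ---- stage 10: clustering ---------------------------------------------
    k_star, model = None, None
    if ratios is not None and len(de_selected) >= 4:
        try:
            complete = clustering.complete_for_clustering(
                ratios.values, min_coverage=config.min_coverage
            )
            k_hi = min(config.k_max, max(config.k_min, len(complete) - 1))
            k_star, model = clustering.select_k(
                complete, k_range=range(config.k_min, k_hi + 1),
                seed=stage_seed(config.seed, "cluster"),
                n_restarts=config.n_restarts,
            )
            say(f"k-means: k* = {k_star} by Calinski-Harabasz over "
                f"k = {config.k_min}..{k_hi}")
        except ValueError as exc:
            say(f"clustering skipped: {exc}")

    # ---- stage 11: co-deregulation scan -----------------------------------
    if ratios is not None:
        codereg_table = codereg.scan_codereg(
            ratios, clusters=model, min_band=config.min_band,
            denominator=config.denominator,
        )
    else:
        codereg_table = codereg.scan_codereg(
            pd.DataFrame(dtype=float), clusters=None,
            min_band=config.min_band,
        )
    n100_down = int(((codereg_table["band"] == "100") &
                     (codereg_table["direction"] == "down")).sum())
    say(f"codereg: {len(codereg_table)} records at band >= "
        f"{config.min_band}; {n100_down} down-regulated in 100% of samples")

    # ---- stage 12: chromosomal context ------------------------------------
    chrom = None
    if ratios is not None and len(ratios.values):
        if config.annotation:
            ann = pd.read_table(config.annotation, index_col=0)
        elif config.simulate:
            ann = generate_annotation(
                list(naturals.index), seed=stage_seed(config.seed, "annot")
            )
        else:
            ann = None
        if ann is not None:
            chrom = codereg.chrom_summaries(ratios, ann, level="chromosome")

    # ---- stage 13: diagnostics --------------------------------------------
    roc_results: list = []
    nb_report = None
    if scores_all is not None and not codereg_table.empty:
        top = codereg_table.sort_values(
            ["f_pct", "f"], ascending=False
        ).drop_duplicates("symbol")
        markers = list(top["symbol"].head(config.n_markers))
        for sym in markers:
            roc_results.append(diagnostics.roc_auc(
                scores_all.loc[sym], labels, symbol=sym
            ))
        counts = labels.value_counts()
        if (counts >= config.nb_folds).all() and markers:
            nb_report = diagnostics.naive_bayes_cv(
                scores_all.loc[markers], labels, folds=config.nb_folds,
                seed=stage_seed(config.seed, "nb"),
            )
        if roc_results:
            say("ROC AUC: " + ", ".join(
                f"{r.symbol}={r.auc:.3f}" for r in roc_results))
        if nb_report:
            say(f"naive Bayes ({config.nb_folds}-fold): "
                f"mean accuracy {nb_report.mean_accuracy:.3f}")

    # ---- manifest ----------------------------------------------------------
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {
            "hypermatrix": {"rows": int(hm.values.shape[0]),
                            "cols": int(hm.values.shape[1])},
            "naturals": {"rows": int(naturals.shape[0]),
                         "cols": int(naturals.shape[1])},
            "de_tested": int(de_result.table["p"].notna().sum()),
            "de_selected": len(de_selected),
            "codereg_records": int(len(codereg_table)),
            "codereg_100_down": n100_down,
            "k_star": k_star,
            "n_removed_by_age": age_report["n_removed"],
            "n_masked_negative": n_masked,
        },
        "log": log,
    }

    result = PipelineResult(
        config=config, meta=meta, ground_truth=ground_truth, hypermatrix=hm,
        age_report=age_report, naturals=naturals, labels=labels,
        de_result=de_result, de_selected=de_selected, ratios=ratios,
        scores_all=scores_all, k_star=k_star, cluster_model=model,
        codereg_table=codereg_table, roc_results=roc_results,
        nb_report=nb_report, chrom=chrom, manifest=manifest,
    )
    if config.outdir:
        _write_bundle(result, Path(config.outdir))
    return result


def _write_bundle(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_hypermatrix(res.hypermatrix, outdir / "hypermatrix.tsv")
    res.naturals.to_csv(outdir / "naturals.tsv", sep="\t", na_rep="NaN")
    res.de_result.table.to_csv(outdir / "de_table.tsv", sep="\t",
                               na_rep="NaN")
    if res.ratios is not None:
        res.ratios.values.to_csv(outdir / "ratios.tsv", sep="\t",
                                 na_rep="NaN")
    if res.scores_all is not None:
        res.scores_all.to_csv(outdir / "scores_all.tsv", sep="\t",
                              na_rep="NaN")
    res.codereg_table.to_csv(outdir / "codereg_table.tsv", sep="\t",
                             index=False)
    if res.cluster_model is not None:
        res.cluster_model.assignments.to_csv(outdir / "clusters.tsv",
                                             sep="\t")
        pd.Series(res.cluster_model.ch_scores, name="ch_score").to_csv(
            outdir / "ch_scores.tsv", sep="\t"
        )
    if res.roc_results:
        pd.DataFrame([
            {"symbol": r.symbol, "auc": r.auc, "p": r.p_value,
             "low_predicts_tumor": r.low_predicts_tumor}
            for r in res.roc_results
        ]).to_csv(outdir / "roc.tsv", sep="\t", index=False)
    if res.nb_report is not None:
        (outdir / "naive_bayes.json").write_text(json.dumps({
            "folds": res.nb_report.folds,
            "fold_accuracy": res.nb_report.fold_accuracy,
            "mean_accuracy": res.nb_report.mean_accuracy,
            "confusion": res.nb_report.confusion.to_dict(),
        }, indent=1))
    (outdir / "manifest.json").write_text(
        json.dumps(res.manifest, indent=1, sort_keys=True)
    )
    (outdir / "log.txt").write_text("\n".join(res.manifest["log"]) + "\n")
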