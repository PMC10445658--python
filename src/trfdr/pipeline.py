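"""End-to-end pipeline: simulate -> build LUT -> extract -> classify -> evaluate.

Every stage is seeded and the configuration is serialisable, so re-running
with the same config reproduces all outputs bit-for-bit.  The evaluation
report mirrors the standard result layout: three confusion matrices with
per-class metrics (TRF-only, DR-only, combined) and two tumor-pixel
transition tables with paired symmetry tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as dx
from . import tables
from .classify import TreeConfig
from .core import (CLASSES, FEATURES_CSV_COLUMNS, Dataset, filter_pure)
from .dr import ReflectanceLUT, default_lut, extract_dr_features
from .model import TissueClassificationModel
from .simulate import (DEFAULT_COUNTS, DEFAULT_N_PATIENTS, Cohort, IRFSpec,
                       simulate_cohort)
from .trf import InvalidRecordError, extract_trf_features

log = logging.getLogger("trfdr")

__all__ = ["PipelineConfig", "extract_features", "run_pipeline",
           "reproduce_reference_tables"]


@dataclass
class PipelineConfig:
    """Fully serialisable pipeline configuration."""

    seed: int = 0
    n_patients: int = DEFAULT_N_PATIENTS
    spectra_per_class: tuple[int, int, int] = DEFAULT_COUNTS
    irf_fwhm_ns: float = 0.5
    irf_t0_ns: float = 1.0
    lut_n_mua: int = 128
    lut_n_mus: int = 128
    lut_mua_range: tuple[float, float] = (0.001, 1.0)
    lut_mus_range: tuple[float, float] = (0.08, 6.0)
    pca_threshold: float = 0.98
    min_instances_in_leaves: int = 3
    min_subset_to_split: int = 5
    majority_stop: float = 0.95
    pca_scope: str = "fold"
    feature_sets: tuple[str, ...] = ("trf", "dr", "combined")
    outdir: str | None = None

    @property
    def irf(self) -> IRFSpec:
        return IRFSpec(fwhm=self.irf_fwhm_ns, t0=self.irf_t0_ns)

    @property
    def tree_config(self) -> TreeConfig:
        return TreeConfig(min_instances_in_leaves=self.min_instances_in_leaves,
                          min_subset_to_split=self.min_subset_to_split,
                          majority_stop=self.majority_stop)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        for key in ("spectra_per_class", "lut_mua_range", "lut_mus_range",
                    "feature_sets"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output directory does
        not affect results and is excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def extract_features(cohort: Cohort, lut: ReflectanceLUT | None = None,
                     irf: IRFSpec | None = None
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run TRF and DR extraction over every spot of a cohort.

    Returns the feature table (features-CSV column layout) and a tally of
    invalid records (flagged and excluded, never silently zeroed)."""
    lut = lut if lut is not None else default_lut()
    irf = irf if irf is not None else cohort.irf
    rows = []
    tally = {"n_spots": len(cohort), "invalid_trf": 0, "invalid_dr": 0}
    for meta, spot in zip(cohort.index.itertuples(), cohort.iter_spots()):
        try:
            trf_feats = extract_trf_features(spot, irf)
        except InvalidRecordError:
            tally["invalid_trf"] += 1
            continue
        try:
            dr_feats = extract_dr_features(spot, cohort.blank,
                                           cohort.standard, lut)
        except InvalidRecordError:
            tally["invalid_dr"] += 1
            continue
        rows.append({
            "patient_id": spot.patient_id, "sample_id": spot.sample_id,
            "x": spot.grid_x, "y": spot.grid_y, "label": meta.label,
            **asdict(trf_feats), **asdict(dr_feats)})
    return pd.DataFrame(rows, columns=list(FEATURES_CSV_COLUMNS)), tally


def extract_features_from_scan(scan, labels: pd.DataFrame,
                               lut: ReflectanceLUT | None = None,
                               irf: IRFSpec | None = None
                               ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Extraction over a scan file's spots, labeled via the histology table.

    Only pixels with a pure (100%) composition receive a class label and
    enter the feature table; mixed pixels are skipped and counted."""
    lut = lut if lut is not None else default_lut()
    irf = irf if irf is not None else IRFSpec()
    pure = filter_pure(labels)
    key_cols = ["patient_id", "sample_id", "x", "y"]
    label_of = {tuple(row[k] for k in key_cols): row["label"]
                for _, row in pure.iterrows()}
    rows = []
    tally = {"n_spots": len(scan.spots), "invalid_trf": 0, "invalid_dr": 0,
             "mixed_skipped": 0}
    for spot in scan.spots:
        key = (spot.patient_id, spot.sample_id, spot.grid_x, spot.grid_y)
        if key not in label_of:
            tally["mixed_skipped"] += 1
            continue
        try:
            trf_feats = extract_trf_features(spot, irf)
            dr_feats = extract_dr_features(spot, scan.blank, scan.standard,
                                           lut)
        except InvalidRecordError:
            tally["invalid_trf"] += 1
            continue
        rows.append({
            "patient_id": spot.patient_id, "sample_id": spot.sample_id,
            "x": spot.grid_x, "y": spot.grid_y, "label": label_of[key],
            **asdict(trf_feats), **asdict(dr_feats)})
    return pd.DataFrame(rows, columns=list(FEATURES_CSV_COLUMNS)), tally


def _metrics_dict(metrics) -> dict:
    return {cls: {"sensitivity_pct": dx.percent_round(m.sensitivity),
                  "specificity_pct": dx.percent_round(m.specificity),
                  "auc": None if m.auc is None else round(m.auc, 3)}
            for cls, m in metrics.items()}


def _comparison_dict(comp) -> dict:
    return {
        "models": list(comp.names),
        "transition_counts": comp.transition.counts.tolist(),
        "net_gain": comp.gain,
        "bowker": {"chi2": comp.bowker.statistic, "df": comp.bowker.df,
                   "p": comp.bowker.p_value},
        "mcnemar_binary_cc": {"chi2": comp.mcnemar.statistic,
                              "df": comp.mcnemar.df,
                              "p": comp.mcnemar.p_value},
    }


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute all stages in order and return (and optionally write) the
    evaluation report."""
    cfg = config or PipelineConfig()
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(cfg.to_json())
    report: dict = {"config_hash": cfg.config_hash, "seed": cfg.seed,
                    "stages": {}}
    t_all = time.perf_counter()

    t0 = time.perf_counter()
    cohort = simulate_cohort(cfg.n_patients, cfg.spectra_per_class,
                             seed=cfg.seed, irf=cfg.irf)
    log.info("simulated cohort: %d spots, %d patients", len(cohort),
             cfg.n_patients)
    report["stages"]["simulate"] = {"seconds": time.perf_counter() - t0,
                                    "n_spots": len(cohort)}

    t0 = time.perf_counter()
    lut = default_lut(cfg.lut_n_mua, cfg.lut_n_mus, cfg.lut_mua_range,
                      cfg.lut_mus_range)
    report["stages"]["build_lut"] = {"seconds": time.perf_counter() - t0}

    t0 = time.perf_counter()
    features, tally = extract_features(cohort, lut)
    report["stages"]["extract"] = {"seconds": time.perf_counter() - t0,
                                   **tally}
    log.info("extracted %d/%d records (%d TRF-invalid, %d DR-invalid)",
             len(features), tally["n_spots"], tally["invalid_trf"],
             tally["invalid_dr"])
    if outdir:
        features.to_csv(outdir / "features.csv", index=False)
        cohort.truth.to_csv(outdir / "ground_truth.csv", index=False)

    pure_labels = filter_pure(cohort.labels)
    dataset = Dataset(features)
    report["class_counts"] = dataset.class_counts
    report["n_pure_labeled"] = int(len(pure_labels))

    results = {}
    for fs in cfg.feature_sets:
        t0 = time.perf_counter()
        res = TissueClassificationModel(
            dataset, feature_set=fs, pca_threshold=cfg.pca_threshold,
            tree_config=cfg.tree_config, pca_scope=cfg.pca_scope).fit()
        results[fs] = res
        report["stages"][f"classify_{fs}"] = {
            "seconds": time.perf_counter() - t0}
        report[f"evaluation_{fs}"] = {
            "confusion_counts": res.confusion.counts.tolist(),
            "metrics": _metrics_dict(res.metrics),
            "accuracy": res.accuracy,
            "pca_components": res.pca_summary.n_components,
            "pca_cumulative_variance":
                res.pca_summary.cumulative_variance,
        }
        if outdir:
            res.predictions.to_csv(outdir / f"predictions_{fs}.csv",
                                   index=False)
        log.info("%s: accuracy %.3f", fs, res.accuracy)

    report["comparisons"] = {}
    for a in ("trf", "dr"):
        if a in results and "combined" in results:
            comp = results[a].compare(results["combined"])
            report["comparisons"][f"{a}_vs_combined"] = _comparison_dict(comp)

    report["seconds_total"] = time.perf_counter() - t_all
    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def reproduce_reference_tables() -> dict:
    """Recompute all metrics from the vendored reference matrices and check
    them against the reported values.

    Any mismatch raises ``AssertionError`` naming the offending cell.
    Returns the recomputed report."""
    report: dict = {"models": {}, "comparisons": {}}
    for model in ("trf", "dr", "combined"):
        cm = tables.reference_confusion(model)
        expected_rows = dict(zip(CLASSES, (761, 77, 347)))
        for cls, want in expected_rows.items():
            got = cm.row_total(cls)
            assert got == want, (
                f"{model} confusion row {cls}: total {got} != {want}")
        entry = {}
        for cls in CLASSES:
            sens = dx.percent_round(dx.sensitivity(cm, cls))
            spec = dx.percent_round(dx.specificity(cm, cls))
            want = tables.REPORTED_METRICS_PCT[model][cls]
            assert sens == want["sensitivity"], (
                f"{model}/{cls} sensitivity: computed {sens}, "
                f"reported {want['sensitivity']}")
            assert spec == want["specificity"], (
                f"{model}/{cls} specificity: computed {spec}, "
                f"reported {want['specificity']}")
            entry[cls] = {"sensitivity_pct": sens, "specificity_pct": spec}
        report["models"][model] = entry
    for comp in ("trf_vs_combined", "dr_vs_combined"):
        tt = tables.reference_transitions(comp)
        assert tt.total == 347, f"{comp}: transition total {tt.total} != 347"
        gain = dx.net_gain(tt)
        want = tables.REPORTED_NET_GAIN[comp]
        assert gain["net"] == want["net"], (
            f"{comp} net gain: computed {gain['net']}, "
            f"reported {want['net']}")
        assert abs(gain["pct"] - want["pct"]) < 0.05 + 1e-9, (
            f"{comp} net gain pct: computed {gain['pct']}, "
            f"reported {want['pct']}")
        bow = dx.bowker_test(tt)
        mcn = dx.mcnemar_binary_cc(tt)
        report["comparisons"][comp] = {
            "net_gain": gain,
            "bowker": {"chi2": bow.statistic, "df": bow.df,
                       "p": bow.p_value},
            "mcnemar_binary_cc": {"chi2": mcn.statistic, "df": mcn.df,
                                  "p": mcn.p_value},
        }
    assert report["comparisons"]["trf_vs_combined"]["bowker"]["p"] < 0.01, \
        "trf_vs_combined Bowker p should be < 0.01"
    return report
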