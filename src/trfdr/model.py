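"""Model/Results interface over the classification and diagnostics stages.

``TissueClassificationModel`` is built from a feature table (one row per
spectrum: patient id, tissue label and the 13 optical parameters) and
``fit()`` runs the full leave-one-patient-out evaluation, returning a
``TissueClassificationResults`` that carries the pooled out-of-fold
predictions, the confusion matrix, per-class sensitivity/specificity/AUC
and a printable summary.  Two fitted results over the same records can be
compared with :meth:`TissueClassificationResults.compare`, which produces
the tumor-pixel transition table, net-gain summary and paired symmetry
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import (FEATURE_SETS, FeatureSetSpec, TreeConfig, fit_pca,
                       lopo_cv)
from .core import CLASSES, Dataset
from .diagnostics import (ClassMetrics, ConfusionMatrix3, SymmetryTestResult,
                          TransitionTable, bowker_test, confusion_matrix,
                          mcnemar_binary_cc, metrics_table, net_gain,
                          percent_round, roc_auc, transition_table)

__all__ = ["TissueClassificationModel", "TissueClassificationResults",
           "ModelComparison"]


class TissueClassificationModel:
    """PCA + decision-tree tissue classifier evaluated patient-wise.

    Parameters
    ----------
    data:
        ``Dataset`` or DataFrame with ``patient_id``, ``label`` and the
        optical-parameter columns.
    feature_set:
        'trf' (5 parameters), 'dr' (8) or 'combined' (13), or a custom
        :class:`FeatureSetSpec`.
    pca_threshold:
        Minimum cumulative explained variance retained (default 0.98).
    tree_config:
        Stopping rules; defaults to min 3 per leaf, min 5 to split,
        95% majority stop.
    pca_scope:
        'fold' (default) refits standardization+PCA inside each training
        fold; 'global' fits them once on all records.
    """

    def __init__(self, data: Dataset | pd.DataFrame,
                 feature_set: str | FeatureSetSpec = "combined",
                 pca_threshold: float = 0.98,
                 tree_config: TreeConfig | None = None,
                 pca_scope: str = "fold"):
        self.data = data if isinstance(data, Dataset) else Dataset(data)
        self.feature_set = (feature_set if isinstance(feature_set,
                                                      FeatureSetSpec)
                            else FEATURE_SETS[feature_set])
        self.pca_threshold = pca_threshold
        self.tree_config = tree_config or TreeConfig()
        self.pca_scope = pca_scope

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs
                       ) -> "TissueClassificationModel":
        return cls(df, **kwargs)

    @classmethod
    def from_features_csv(cls, path, **kwargs) -> "TissueClassificationModel":
        return cls(Dataset.from_csv(path), **kwargs)

    def fit(self) -> "TissueClassificationResults":
        preds = lopo_cv(self.data, self.feature_set, self.pca_threshold,
                        self.tree_config, self.pca_scope)
        full_pca = fit_pca(
            self.data.records[list(self.feature_set.columns)].to_numpy(float),
            self.pca_threshold, self.feature_set.columns)
        return TissueClassificationResults(model=self, predictions=preds,
                                           pca_summary=full_pca)


class TissueClassificationResults:
    """Pooled LOPO evaluation of one feature set."""

    def __init__(self, model: TissueClassificationModel,
                 predictions: pd.DataFrame, pca_summary=None):
        self.model = model
        self.predictions = predictions
        self.pca_summary = pca_summary
        self.confusion: ConfusionMatrix3 = confusion_matrix(predictions)
        self.metrics: dict[str, ClassMetrics] = metrics_table(predictions)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion.counts) / self.confusion.total)

    def roc(self, cls: str = "tumor"):
        return roc_auc(self.predictions, cls)

    def summary(self) -> str:
        fs = self.model.feature_set
        lines = [
            "Tissue classification (leave-one-patient-out CV)",
            "=" * 56,
            f"Feature set:        {fs.name} ({len(fs.columns)} parameters)",
            f"Records:            {self.confusion.total}   "
            f"Patients: {len(self.model.data.patients)}",
        ]
        if self.pca_summary is not None:
            lines.append(
                f"PCA (all records):  {self.pca_summary.n_components} PCs, "
                f"{100 * self.pca_summary.cumulative_variance:.1f}% variance")
        lines += ["", "Confusion matrix (rows: actual, cols: predicted)",
                  self.confusion.df.to_string(), "",
                  f"{'class':<16}{'sens %':>8}{'spec %':>8}{'AUC':>8}"]
        for cls in CLASSES:
            m = self.metrics[cls]
            lines.append(f"{cls:<16}{percent_round(m.sensitivity):>8.1f}"
                         f"{percent_round(m.specificity):>8.1f}"
                         f"{m.auc:>8.3f}")
        return "\n".join(lines)

    def compare(self, other: "TissueClassificationResults",
                target: str = "tumor") -> "ModelComparison":
        tt = transition_table(self.predictions, other.predictions,
                              actual_class=target)
        return ModelComparison(
            transition=tt, gain=net_gain(tt, target),
            bowker=bowker_test(tt),
            mcnemar=mcnemar_binary_cc(tt, target),
            names=(self.model.feature_set.name,
                   other.model.feature_set.name))

    def plot_roc(self, cls: str = "tumor", ax=None):
        import matplotlib.pyplot as plt
        fpr, tpr, auc = self.roc(cls)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"{cls} (AUC {auc:.3f})")
        ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


@dataclass
class ModelComparison:
    """Cross-model change of classification over the target-actual pixels."""

    transition: TransitionTable
    gain: dict[str, float]
    bowker: SymmetryTestResult
    mcnemar: SymmetryTestResult
    names: tuple[str, str]

    def summary(self) -> str:
        a, b = self.names
        g = self.gain
        lines = [
            f"Classification change: {a} -> {b} ({self.transition.subset})",
            "=" * 56,
            self.transition.df.to_string(),
            "",
            f"gained {g['gained']}, lost {g['lost']}, net {g['net']:+d} "
            f"({g['pct']:.1f}% of {self.transition.total})",
            f"Bowker symmetry:     chi2 = {self.bowker.statistic:.2f}, "
            f"df = {self.bowker.df}, p = {self.bowker.p_value:.3g}",
            f"McNemar (binary, cc): chi2 = {self.mcnemar.statistic:.2f}, "
            f"df = 1, p = {self.mcnemar.p_value:.3g}",
        ]
        return "\n".join(lines)
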