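"""Three-class tissue classification with leave-one-patient-out CV.

The modeling recipe: standardize the chosen parameter set (the 13 optical
parameters mix ns, mm^-1 and dimensionless ratios), reduce with PCA keeping
the smallest number of components whose cumulative explained variance
reaches the threshold (default 98%), and grow a greedy binary decision tree
on the component scores.  The tree follows three stopping constraints:
at least 3 instances in every leaf, no splitting of subsets smaller than 5,
and stop once the node majority reaches 95%.

Evaluation is leave-one-patient-out: one fold per patient, with the scaler,
PCA and tree all fitted on the training fold only, and the held-out
patient's records scored.  Out-of-fold predictions from all folds are
pooled; pooled scores feed the ROC analysis downstream.

The tree is grown by exhaustive scanning of midpoint thresholds with Gini
impurity; ties are broken toward the lowest feature index, then the lowest
threshold, and majority ties in leaves follow the fixed class order, so
training is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .core import CLASSES, DR_COLUMNS, FEATURE_COLUMNS, TRF_COLUMNS, Dataset

__all__ = ["FeatureSetSpec", "FEATURE_SETS", "PCAModel", "TreeConfig",
           "DecisionTree", "fit_pca", "train_tree", "lopo_cv",
           "PREDICTION_COLUMNS"]

PREDICTION_COLUMNS = ("patient_id", "true_label", "pred_label",
                      "score_adipose", "score_fibroglandular", "score_tumor",
                      "fold")


@dataclass(frozen=True)
class FeatureSetSpec:
    """Named subset of the 13 optical parameters."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.columns) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown feature columns: {sorted(unknown)}")


FEATURE_SETS = {
    "trf": FeatureSetSpec("trf", TRF_COLUMNS),
    "dr": FeatureSetSpec("dr", DR_COLUMNS),
    "combined": FeatureSetSpec("combined", TRF_COLUMNS + DR_COLUMNS),
}


@dataclass
class PCAModel:
    """Standardization + PCA retained to a cumulative-variance threshold."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray            # (n_components, n_features)
    explained_variance_ratio: np.ndarray   # all components, non-increasing
    n_components: int
    threshold: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.mean) / self.scale
        return Z @ self.components.T

    @property
    def cumulative_variance(self) -> float:
        return float(self.explained_variance_ratio[:self.n_components].sum())


def fit_pca(features: np.ndarray, threshold: float = 0.98,
            column_names: tuple[str, ...] | None = None) -> PCAModel:
    """Standardize then PCA; keep the fewest PCs reaching the threshold."""
    X = np.asarray(features, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 records")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    std = X.std(axis=0)
    if np.any(std == 0):
        j = int(np.flatnonzero(std == 0)[0])
        name = column_names[j] if column_names else f"column {j}"
        raise ValueError(f"zero-variance feature: {name}")
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    pca = PCA(svd_solver="full").fit(Z)
    evr = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), threshold - 1e-12) + 1)
    k = min(k, len(evr))
    return PCAModel(mean=scaler.mean_, scale=scaler.scale_,
                    components=pca.components_[:k],
                    explained_variance_ratio=evr,
                    n_components=k, threshold=threshold)


@dataclass(frozen=True)
class TreeConfig:
    """Decision-tree stopping rules (values follow the modeling recipe)."""

    min_instances_in_leaves: int = 3
    min_subset_to_split: int = 5
    majority_stop: float = 0.95
    criterion: str = "gini"

    def __post_init__(self) -> None:
        if self.criterion != "gini":
            raise ValueError("only the gini criterion is implemented")


@dataclass
class _Node:
    counts: np.ndarray                 # per-class counts at this node
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def scores(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


class DecisionTree:
    """Greedy binary CART-style tree over continuous features.

    Leaf scores are training class frequencies; prediction is the majority
    class, with ties resolved by the fixed class order.
    """

    def __init__(self, config: TreeConfig | None = None,
                 classes: tuple[str, ...] = CLASSES):
        self.config = config or TreeConfig()
        self.classes = classes
        self.root: _Node | None = None

    # -- fitting ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "DecisionTree":
        X = np.asarray(X, float)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        y_idx = np.searchsorted(np.array(self.classes),
                                y.astype(str))
        if np.any(np.array(self.classes)[y_idx] != y.astype(str)):
            raise ValueError("labels outside the known classes")
        self.root = self._grow(X, y_idx)
        return self

    def _class_counts(self, y_idx: np.ndarray) -> np.ndarray:
        return np.bincount(y_idx, minlength=len(self.classes)).astype(float)

    def _grow(self, X: np.ndarray, y_idx: np.ndarray) -> _Node:
        counts = self._class_counts(y_idx)
        node = _Node(counts=counts)
        n = len(y_idx)
        cfg = self.config
        if n < cfg.min_subset_to_split:
            return node
        if counts.max() / n >= cfg.majority_stop:
            return node
        split = self.best_split(X, y_idx)
        if split is None:
            return node
        j, thr = split
        mask = X[:, j] <= thr
        node.feature, node.threshold = j, thr
        node.left = self._grow(X[mask], y_idx[mask])
        node.right = self._grow(X[~mask], y_idx[~mask])
        return node

    def best_split(self, X: np.ndarray, y_idx: np.ndarray
                   ) -> tuple[int, float] | None:
        """Best (feature, threshold) by Gini impurity decrease.

        Candidate thresholds are midpoints of consecutive distinct sorted
        values.  Splits leaving a child below the leaf minimum are skipped.
        Strictly-better comparisons with features scanned in index order
        and thresholds ascending give the documented tie-breaking.
        """
        n, d = X.shape
        k = len(self.classes)
        min_leaf = self.config.min_instances_in_leaves
        parent_gini = _gini(self._class_counts(y_idx))
        best: tuple[float, int, float] | None = None
        onehot = np.zeros((n, k))
        onehot[np.arange(n), y_idx] = 1.0
        for j in range(d):
            order = np.argsort(X[:, j], kind="stable")
            xs = X[order, j]
            cum = np.cumsum(onehot[order], axis=0)        # (n, k)
            total = cum[-1]
            cand = np.flatnonzero(np.diff(xs) > 0)         # split after i
            if cand.size == 0:
                continue
            n_l = cand + 1.0
            n_r = n - n_l
            left = cum[cand]                               # (m, k)
            right = total - left
            gini_l = 1.0 - np.sum((left / n_l[:, None]) ** 2, axis=1)
            gini_r = 1.0 - np.sum((right / n_r[:, None]) ** 2, axis=1)
            gain = parent_gini - (n_l * gini_l + n_r * gini_r) / n
            valid = (n_l >= min_leaf) & (n_r >= min_leaf) & (gain > 1e-12)
            if not valid.any():
                continue
            gv = np.where(valid, gain, -np.inf)
            i = int(np.argmax(gv))           # first max -> lowest threshold
            thr = 0.5 * (xs[cand[i]] + xs[cand[i] + 1])
            if best is None or gv[i] > best[0] + 1e-12:
                best = (float(gv[i]), j, thr)
        if best is None:
            return None
        return best[1], best[2]

    # -- prediction -------------------------------------------------------
    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        if self.root is None:
            raise RuntimeError("tree is not fitted")
        X = np.asarray(X, float)
        out = np.empty((len(X), len(self.classes)))
        for i, x in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if x[node.feature] <= node.threshold \
                    else node.right
            out[i] = node.scores
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.predict_scores(X)
        # argmax returns the first maximum -> ties follow class order
        return np.asarray(self.classes)[np.argmax(scores, axis=1)]

    # -- structural checks ------------------------------------------------
    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.extend([node.left, node.right])


def train_tree(pcs: np.ndarray, labels: np.ndarray,
               config: TreeConfig | None = None) -> DecisionTree:
    """Grow a decision tree on PC scores under the stated stopping rules."""
    return DecisionTree(config).fit(pcs, labels)


def lopo_cv(dataset: Dataset | pd.DataFrame,
            feature_set: FeatureSetSpec | str = "combined",
            threshold: float = 0.98,
            config: TreeConfig | None = None,
            pca_scope: str = "fold") -> pd.DataFrame:
    """Leave-one-patient-out cross-validation with pooled predictions.

    One fold per patient; the scaler, PCA and tree are fitted on the
    training fold only (``pca_scope='global'`` instead fits the
    standardization+PCA once on the full dataset, the recipe's ambiguous
    alternative).  Every record is predicted exactly once; patients whose
    classes are absent from a training fold are still scored.

    Returns a DataFrame with columns
    ``patient_id, true_label, pred_label, score_<class>..., fold``
    in the dataset's record order.
    """
    df = dataset.records if isinstance(dataset, Dataset) else dataset
    spec = (feature_set if isinstance(feature_set, FeatureSetSpec)
            else FEATURE_SETS[feature_set])
    if pca_scope not in ("fold", "global"):
        raise ValueError("pca_scope must be 'fold' or 'global'")
    patients = df["patient_id"].astype(str).to_numpy()
    unique_patients = sorted(set(patients))
    if len(unique_patients) < 2:
        raise ValueError("leave-one-patient-out needs >= 2 patients")
    X = df[list(spec.columns)].to_numpy(float)
    y = df["label"].astype(str).to_numpy()

    global_pca = fit_pca(X, threshold, spec.columns) \
        if pca_scope == "global" else None

    n = len(df)
    pred = np.empty(n, dtype=object)
    scores = np.empty((n, len(CLASSES)))
    fold_ids = np.empty(n, dtype=object)
    for pid in unique_patients:
        test = patients == pid
        train = ~test
        pca = global_pca if global_pca is not None else \
            fit_pca(X[train], threshold, spec.columns)
        tree = train_tree(pca.transform(X[train]), y[train], config)
        Z = pca.transform(X[test])
        scores[test] = tree.predict_scores(Z)
        pred[test] = tree.predict(Z)
        fold_ids[test] = pid

    out = pd.DataFrame({
        "patient_id": patients,
        "true_label": y,
        "pred_label": pred.astype(str),
        "score_adipose": scores[:, 0],
        "score_fibroglandular": scores[:, 1],
        "score_tumor": scores[:, 2],
        "fold": fold_ids,
    })
    return out
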