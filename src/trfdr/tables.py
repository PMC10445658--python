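"""Reference classification results for the original 80-patient cohort.

The clinical dataset behind the published confusion and transition matrices
is not deposited, so the matrices themselves are vendored here (transcribed
as CSV package data) together with the reported percentage metrics.  The
diagnostics module recomputes every sensitivity/specificity and the
transition statistics from these matrices; the reported AUCs and the
real-data PCA variance fractions cannot be recomputed without the
per-record scores and are kept as documentation-only context.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .diagnostics import ConfusionMatrix3, TransitionTable

__all__ = ["reference_confusion", "reference_transitions",
           "REPORTED_METRICS_PCT", "REPORTED_NET_GAIN",
           "REPORTED_AUC_CONTEXT", "REPORTED_PCA_VARIANCE_CONTEXT"]

_MODELS = ("trf", "dr", "combined")
_COMPARISONS = ("trf_vs_combined", "dr_vs_combined")


def _load(name: str, index_col: str) -> np.ndarray:
    with resources.files("trfdr.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, index_col=index_col)
    return df.to_numpy(dtype=int)


def reference_confusion(model: str) -> ConfusionMatrix3:
    """Vendored confusion matrix for 'trf', 'dr' or 'combined'."""
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    return ConfusionMatrix3(counts=_load(f"confusion_{model}.csv", "actual"))


def reference_transitions(comparison: str) -> TransitionTable:
    """Vendored tumor-pixel transition table:
    'trf_vs_combined' or 'dr_vs_combined'."""
    if comparison not in _COMPARISONS:
        raise ValueError(f"comparison must be one of {_COMPARISONS}")
    return TransitionTable(
        counts=_load(f"transitions_{comparison}.csv", "model_a"),
        subset="actual == tumor")


#: Reported per-class sensitivity/specificity (percent, one decimal).
REPORTED_METRICS_PCT = {
    "trf": {
        "adipose": {"sensitivity": 90.8, "specificity": 77.6},
        "fibroglandular": {"sensitivity": 14.3, "specificity": 96.5},
        "tumor": {"sensitivity": 72.3, "specificity": 88.3},
    },
    "dr": {
        "adipose": {"sensitivity": 95.8, "specificity": 84.0},
        "fibroglandular": {"sensitivity": 63.6, "specificity": 99.1},
        "tumor": {"sensitivity": 80.4, "specificity": 94.0},
    },
    "combined": {
        "adipose": {"sensitivity": 96.7, "specificity": 87.0},
        "fibroglandular": {"sensitivity": 63.6, "specificity": 99.2},
        "tumor": {"sensitivity": 85.6, "specificity": 95.3},
    },
}

#: Reported tumor-classification net gains over the 347 tumor pixels.
REPORTED_NET_GAIN = {
    "trf_vs_combined": {"net": 46, "pct": 13.3},
    "dr_vs_combined": {"net": 18, "pct": 5.2},
}

#: Reported tumor AUCs (context only: per-record scores were never
#: deposited, so these cannot be recomputed here).
REPORTED_AUC_CONTEXT = {"trf": 0.842, "dr": 0.887, "combined": 0.911}

#: Reported real-data PCA outcomes (context only, same reason):
#: (components retained, cumulative variance percent).
REPORTED_PCA_VARIANCE_CONTEXT = {"trf": (4, 99.2), "dr": (4, 98.5),
                                 "combined": (8, 98.9)}
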