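"""Training-free cancer-related factor (CF) classifier.

The CF of a sample is the ratio of the mean log2 expression of the
upregulated biomarkers to the mean log2 expression of the downregulated
ones. In a tumour sample the numerator rises and the denominator falls,
pushing CF above the value seen in normal tissue, so a single scalar
threshold separates the classes without any model fitting.

The threshold is calibrated from n paired case/control samples: the two
profiles are merged into one synthetic "boundary" profile lying between
the classes — each control sample is rescaled to its case partner's
overall biomarker mass and the pair is averaged — and the threshold is
the geometric mean of the CF values of the n synthetic samples. A
sample is called positive when its CF strictly exceeds the threshold.
See :func:`synthetic_boundary_profile` for the two rescaling
conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .core_io import ExpressionMatrix, subset_features

__all__ = [
    "CFModel",
    "ConfusionCounts",
    "cancer_factor",
    "cf_per_sample",
    "synthetic_boundary_profile",
    "calibrate_threshold",
    "classify",
    "binary_metrics",
    "roc_auc",
]


@dataclass
class CFModel:
    """Up/down biomarker sets plus the calibrated CF threshold."""

    up_ids: list[str]
    down_ids: list[str]
    cf_threshold: float
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not self.up_ids or not self.down_ids:
            raise ValueError("both up and down biomarker sets must be nonempty")
        if set(self.up_ids) & set(self.down_ids):
            raise ValueError("up and down sets must be disjoint")
        if self.cf_threshold <= 0:
            raise ValueError("cf_threshold must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "up_ids": list(self.up_ids),
                    "down_ids": list(self.down_ids),
                    "cf_threshold": self.cf_threshold,
                    "pseudocount": self.pseudocount,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CFModel":
        d = json.loads(Path(path).read_text())
        return cls(d["up_ids"], d["down_ids"], d["cf_threshold"], d["pseudocount"])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _mean_log2(values: np.ndarray, pseudocount: float) -> float:
    shifted = values + pseudocount
    if (shifted <= 0).any():
        raise ValueError("expression + pseudocount must be positive for log2")
    return float(np.log2(shifted).mean())


def cancer_factor(sample_expr: pd.Series, model: CFModel) -> float:
    """CF of one sample: mean log2(up) / mean log2(down).

    ``sample_expr`` maps feature ids to expression values and must cover
    every id in the model.
    """
    missing = [f for f in (*model.up_ids, *model.down_ids) if f not in sample_expr.index]
    if missing:
        raise KeyError(f"sample lacks model features: {missing}")
    up = _mean_log2(sample_expr[model.up_ids].to_numpy(dtype=float), model.pseudocount)
    down = _mean_log2(sample_expr[model.down_ids].to_numpy(dtype=float), model.pseudocount)
    if down == 0:
        raise ZeroDivisionError("mean log2 of downregulated biomarkers is 0")
    return up / down


def cf_per_sample(expr: ExpressionMatrix, model: CFModel) -> pd.Series:
    """CF for every sample column of an expression matrix."""
    frame = expr.to_frame()
    return pd.Series(
        {s: cancer_factor(frame[s], model) for s in expr.sample_ids}, name="cf"
    )


def synthetic_boundary_profile(
    case_expr: ExpressionMatrix,
    control_expr: ExpressionMatrix,
    scale: str = "per_sample",
) -> ExpressionMatrix:
    """Merge paired case/control profiles into one boundary profile.

    The combined profile averages each case sample with its rescaled
    control partner: per biomarker m and sample i,
    S_m(i) = (S_tm(i) + S_nm(i) * scale) / 2. Two scale conventions are
    offered:

    * ``per_sample`` (default): scale_i = sum_m S_tm(i) / sum_m S_nm(i),
      a library-size-style factor per combined sample. The control
      partner is brought to the case sample's overall magnitude while
      keeping its own up/down contrast, so the combined sample sits
      between the classes and the geometric-mean threshold discriminates
      them.
    * ``per_biomarker``: scale_m = sum_i S_tm(i) / sum_i S_nm(i), the
      per-biomarker fold change. Rescaling each control row by its own
      fold change reconstructs a case-level row (exactly so for
      proportional rows), which yields a case-like profile — retained
      for completeness, not recommended for threshold calibration.

    Both conventions are invariant to a common rescaling of the control
    profile and coincide for a single-biomarker profile.
    """
    if case_expr.feature_ids != control_expr.feature_ids:
        raise ValueError("case and control profiles must share biomarker rows")
    if case_expr.shape[1] != control_expr.shape[1]:
        raise ValueError("case and control profiles must have equal sample counts")
    t = case_expr.values
    c = control_expr.values
    if scale == "per_sample":
        denom = c.sum(axis=0)
        if (denom == 0).any():
            raise ZeroDivisionError("a control sample sums to 0 over the biomarkers")
        combined = (t + c * (t.sum(axis=0) / denom)[None, :]) / 2.0
    elif scale == "per_biomarker":
        denom = c.sum(axis=1)
        if (denom == 0).any():
            bad = case_expr.feature_ids[int(np.nonzero(denom == 0)[0][0])]
            raise ZeroDivisionError(f"control row of biomarker {bad!r} sums to 0")
        combined = (t + c * (t.sum(axis=1) / denom)[:, None]) / 2.0
    else:
        raise ValueError("scale must be 'per_sample' or 'per_biomarker'")
    n = case_expr.shape[1]
    return ExpressionMatrix(
        list(case_expr.feature_ids), [f"boundary_{i + 1}" for i in range(n)], combined
    )


def calibrate_threshold(
    case_expr: ExpressionMatrix,
    control_expr: ExpressionMatrix,
    model_ids: tuple[list[str], list[str]],
    pseudocount: float = 1.0,
    scale: str = "per_sample",
) -> float:
    """Geometric mean of the boundary-profile CF values.

    ``model_ids`` is the (up_ids, down_ids) pair. The returned threshold
    always lies between the minimum and maximum boundary CF.
    """
    up_ids, down_ids = model_ids
    keep = [*up_ids, *down_ids]
    combined = synthetic_boundary_profile(
        subset_features(case_expr, keep), subset_features(control_expr, keep), scale=scale
    )
    probe = CFModel(up_ids, down_ids, cf_threshold=1.0, pseudocount=pseudocount)
    cfs = cf_per_sample(combined, probe).to_numpy()
    if (cfs <= 0).any():
        raise ValueError("boundary CF values must be positive for a geometric mean")
    return float(np.exp(np.mean(np.log(cfs))))


def classify(expr: ExpressionMatrix, model: CFModel) -> pd.DataFrame:
    """Label every sample positive iff its CF strictly exceeds the threshold."""
    cfs = cf_per_sample(expr, model)
    labels = np.where(cfs > model.cf_threshold, "positive", "negative")
    return pd.DataFrame({"sample_id": cfs.index, "cf": cfs.to_numpy(), "label": labels})


def binary_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from confusion counts."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ZeroDivisionError("both classes must be present")
    accuracy = (c.tp + c.tn) / c.total
    sensitivity = c.tp / (c.tp + c.fn)
    specificity = c.tn / (c.tn + c.fp)
    return accuracy, sensitivity, specificity


def roc_auc(
    scores: np.ndarray | pd.Series, labels: np.ndarray | pd.Series
) -> tuple[np.ndarray, float]:
    """ROC curve points and AUC (rank formulation, ties counted half).

    ``labels`` are binary with 1 = positive. Returns an array of
    (fpr, tpr) pairs and the AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc
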