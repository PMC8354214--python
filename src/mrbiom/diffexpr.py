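"""Differential-expression screening for the discovery cohort.

Features are screened between case and control samples on two axes:
log2 fold change of group means on the log2(value + pseudocount) scale,
and a Welch two-sample t-test on the same scale with Benjamini-Hochberg
correction. A feature passes at thresholds ``(padj_max, lfc_min)`` when
``padj < padj_max`` (strict) and ``|log2fc| >= lfc_min``.

The default per-class thresholds are mRNA (0.01, 1), miRNA (0.01, 1)
and lncRNA (0.05, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, FeatureAnnotation, SampleTable, align

__all__ = [
    "DEResult",
    "DEFAULT_THRESHOLDS",
    "log2_fold_change",
    "de_test",
    "bh_adjust",
    "screen_de",
    "screen_all_classes",
]

#: (padj_max, lfc_min) per RNA class.
DEFAULT_THRESHOLDS: dict[str, tuple[float, float]] = {
    "mRNA": (0.01, 1.0),
    "miRNA": (0.01, 1.0),
    "lncRNA": (0.05, 1.0),
}


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    log2fc: float
    pvalue: float
    padj: float
    direction: str  # "up" iff log2fc > 0

    def __post_init__(self) -> None:
        expected = "up" if self.log2fc > 0 else "down"
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with log2fc {self.log2fc}"
            )


def _split(expr: ExpressionMatrix, samples: SampleTable) -> tuple[np.ndarray, np.ndarray]:
    case, control = align(expr, samples)
    return case.values, control.values


def log2_fold_change(
    expr: ExpressionMatrix, samples: SampleTable, pseudocount: float = 1.0
) -> pd.Series:
    """Per-feature difference of group means of log2(value + pseudocount).

    Positive values mean higher expression in cases. With a pseudocount
    of 0 every value must be strictly positive.
    """
    case, control = _split(expr, samples)
    if case.shape[1] == 0 or control.shape[1] == 0:
        raise ValueError("both case and control groups must be nonempty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if pseudocount == 0 and ((case == 0).any() or (control == 0).any()):
        raise ValueError("zero expression value requires a positive pseudocount")
    lfc = np.log2(case + pseudocount).mean(axis=1) - np.log2(control + pseudocount).mean(axis=1)
    return pd.Series(lfc, index=expr.feature_ids, name="log2fc")


def de_test(
    expr: ExpressionMatrix, samples: SampleTable, pseudocount: float = 1.0
) -> pd.Series:
    """Two-sided Welch t-test per feature on the log2(value + pseudocount) scale.

    Features constant within both groups get p = 1 by convention (no
    evidence either way from a degenerate test).
    """
    case, control = _split(expr, samples)
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need at least 2 samples per group for a two-sample test")
    a = np.log2(case + pseudocount)
    b = np.log2(control + pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p[degenerate & np.isnan(p)] = 1.0
    p[np.isnan(p)] = 1.0
    return pd.Series(p, index=expr.feature_ids, name="pvalue")


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return pvalues
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, padj, _, _ = multipletests(arr, method="fdr_bh")
    if isinstance(pvalues, pd.Series):
        return pd.Series(padj, index=pvalues.index, name="padj")
    return padj


def screen_de(
    expr: ExpressionMatrix,
    samples: SampleTable,
    padj_max: float,
    lfc_min: float,
    pseudocount: float = 1.0,
) -> list[DEResult]:
    """Return features with padj < padj_max and |log2fc| >= lfc_min.

    The boundary semantics are strict on the adjusted p-value and
    inclusive on the fold change. An empty result triggers a warning,
    not an error.
    """
    if padj_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    lfc = log2_fold_change(expr, samples, pseudocount)
    pvals = de_test(expr, samples, pseudocount)
    padj = bh_adjust(pvals)
    keep = (padj < padj_max) & (lfc.abs() >= lfc_min)
    results = [
        DEResult(
            feature_id=f,
            log2fc=float(lfc[f]),
            pvalue=float(pvals[f]),
            padj=float(padj[f]),
            direction="up" if lfc[f] > 0 else "down",
        )
        for f in expr.feature_ids
        if keep[f]
    ]
    if not results:
        warnings.warn("no features passed the DE screen", stacklevel=2)
    return results


def screen_all_classes(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    lncrna: ExpressionMatrix,
    samples: SampleTable,
    thresholds: dict[str, tuple[float, float]] | None = None,
    pseudocount: float = 1.0,
) -> dict[str, list[DEResult]]:
    """Screen all three RNA classes at their per-class thresholds."""
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    out: dict[str, list[DEResult]] = {}
    for rna_class, expr in (("mRNA", mrna), ("miRNA", mirna), ("lncRNA", lncrna)):
        padj_max, lfc_min = thresholds[rna_class]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[rna_class] = screen_de(expr, samples, padj_max, lfc_min, pseudocount)
    return out


def de_results_frame(
    results: dict[str, list[DEResult]] | list[DEResult],
    annotation: FeatureAnnotation | None = None,
) -> pd.DataFrame:
    """Flatten screen output into a tidy frame (feature_id, rna_class, ...)."""
    if isinstance(results, list):
        results = {"": results}
    rows = []
    for rna_class, rlist in results.items():
        for r in rlist:
            rows.append(
                {
                    "feature_id": r.feature_id,
                    "rna_class": rna_class,
                    "log2fc": r.log2fc,
                    "pvalue": r.pvalue,
                    "padj": r.padj,
                    "direction": r.direction,
                }
            )
    frame = pd.DataFrame(
        rows, columns=["feature_id", "rna_class", "log2fc", "pvalue", "padj", "direction"]
    )
    if annotation is not None and not frame.empty:
        frame["symbol"] = frame["feature_id"].map(annotation.symbol_map())
    return frame
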