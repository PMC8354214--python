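"""Evaluation stages downstream of biomarker selection.

Two independent tracks:

* classification — balanced downsampling of the case group followed by
  stratified k-fold cross-validation of plug-in classifiers (random
  forest, SVM, naive Bayes) on biomarker expression;
* survival — cohort filtering (drop patients with missing follow-up or
  very short survival), a univariate Cox screen of each biomarker, a
  multivariate Cox fit producing a linear risk score, a median split of
  patients into high-/low-risk groups, Kaplan-Meier curves with a
  log-rank test, and a time-dependent ROC at a chosen horizon.

Cox fits use lifelines with Breslow tie handling. The time-dependent
ROC uses the Kaplan-Meier estimator of case/control status probability
at the horizon (the Heagerty-Lumley-Pepe construction, as in the R
survivalROC package): with marker X, horizon t and overall survival
S(t),

    sens(c) = P(X > c) * (1 - S_{X>c}(t)) / (1 - S(t))
    spec(c) = P(X <= c) * S_{X<=c}(t) / S(t)

swept over all observed cutoffs c, and the AUC is the trapezoidal area
of the resulting curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cf_classifier import ConfusionCounts, binary_metrics
from .core_io import ExpressionMatrix, SampleTable

__all__ = [
    "CVReport",
    "RiskModel",
    "downsample_balance",
    "make_classifier",
    "kfold_cv",
    "filter_cohort",
    "cox_univariate_screen",
    "cox_multivariate_fit",
    "risk_scores",
    "median_split",
    "km_logrank",
    "survival_roc",
]

FitPredict = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


@dataclass
class CVReport:
    """Per-fold accuracy/sensitivity/specificity and their means."""

    accuracy: list[float]
    sensitivity: list[float]
    specificity: list[float]
    mean_accuracy: float = field(init=False)
    mean_sensitivity: float = field(init=False)
    mean_specificity: float = field(init=False)

    def __post_init__(self) -> None:
        if not (len(self.accuracy) == len(self.sensitivity) == len(self.specificity)):
            raise ValueError("fold metric lists must have equal length")
        self.mean_accuracy = float(np.mean(self.accuracy))
        self.mean_sensitivity = float(np.mean(self.sensitivity))
        self.mean_specificity = float(np.mean(self.specificity))


@dataclass
class RiskModel:
    """Survival-related biomarkers, their Cox coefficients and the median cutoff."""

    pmb_ids: list[str]
    coefficients: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pmb_ids) != self.coefficients.size:
            raise ValueError("one coefficient per biomarker required")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "pmb_ids": list(self.pmb_ids),
                    "coefficients": self.coefficients.tolist(),
                    "cutoff": self.cutoff,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(d["pmb_ids"], np.asarray(d["coefficients"]), d["cutoff"])


# ---------------------------------------------------------------------------
# Classification track


def downsample_balance(
    samples: SampleTable, n_case: int, n_control: int, seed: int
) -> SampleTable:
    """Random case subset of size n_case plus a control subset of size n_control.

    Sampling is uniform without replacement and deterministic under the
    seed. Typical use: shrink a large case group to roughly the control
    group's size before cross-validation.
    """
    rng = np.random.default_rng(seed)
    case_ids = samples.ids_of("case")
    control_ids = samples.ids_of("control")
    if n_case > len(case_ids) or n_control > len(control_ids):
        raise ValueError(
            f"requested {n_case}+{n_control} samples but only "
            f"{len(case_ids)}+{len(control_ids)} available"
        )
    keep_case = list(rng.choice(case_ids, size=n_case, replace=False))
    keep_control = list(rng.choice(control_ids, size=n_control, replace=False))
    return samples.subset(keep_case + keep_control)


def make_classifier(kind: str, seed: int = 0) -> FitPredict:
    """Plug-in binary classifier: 'rf', 'svm' or 'nb'.

    Returns a callable (X_train, y_train, X_test) -> predicted labels.
    SVM and NB see standardized features; defaults are untouched — the
    point of the evaluation is the biomarkers, not classifier tuning.
    """
    if kind == "rf":
        est = RandomForestClassifier(n_estimators=200, random_state=seed)
    elif kind == "svm":
        est = make_pipeline(StandardScaler(), SVC(random_state=seed))
    elif kind == "nb":
        est = make_pipeline(StandardScaler(), GaussianNB())
    else:
        raise ValueError("kind must be 'rf', 'svm' or 'nb'")

    def fit_predict(x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray) -> np.ndarray:
        from sklearn.base import clone

        model = clone(est)
        model.fit(x_train, y_train)
        return model.predict(x_test)

    return fit_predict


def kfold_cv(
    expr: ExpressionMatrix,
    labels: Sequence[int],
    k: int,
    fit_predict: FitPredict,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation with per-fold binary metrics.

    ``labels`` are 1 = case / 0 = control per sample column. The
    classifier sees only the k-1 training folds each round; folds are
    disjoint, exhaustive and label-stratified.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    x = expr.values.T  # samples x features
    if x.shape[0] != y.size:
        raise ValueError("one label per sample column required")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    acc, sens, spec = [], [], []
    for train_idx, test_idx in skf.split(x, y):
        y_test = y[test_idx]
        if len(set(y_test)) < 2:
            raise ValueError("a fold contains a single class; reduce k")
        y_pred = np.asarray(fit_predict(x[train_idx], y[train_idx], x[test_idx]), dtype=int)
        counts = ConfusionCounts(
            tp=int(((y_pred == 1) & (y_test == 1)).sum()),
            fp=int(((y_pred == 1) & (y_test == 0)).sum()),
            fn=int(((y_pred == 0) & (y_test == 1)).sum()),
            tn=int(((y_pred == 0) & (y_test == 0)).sum()),
        )
        a, se, sp = binary_metrics(counts)
        acc.append(a)
        sens.append(se)
        spec.append(sp)
    return CVReport(acc, sens, spec)


# ---------------------------------------------------------------------------
# Survival track


def filter_cohort(samples: SampleTable, min_days: int = 30) -> SampleTable:
    """Drop patients with missing survival time or follow-up below min_days.

    Very short survivors are excluded because their deaths are likely
    unrelated to the disease under study.
    """
    t = samples.table
    if "os_days" not in t.columns:
        raise ValueError("sample table carries no survival fields")
    keep = t["os_days"].notna() & (t["os_days"] >= min_days)
    return SampleTable(t[keep].copy())


def _survival_frame(expr: ExpressionMatrix, samples: SampleTable) -> pd.DataFrame:
    t = samples.table.set_index("sample_id")
    missing = [s for s in expr.sample_ids if s not in t.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    frame = expr.to_frame().T  # samples x features
    frame["os_days"] = t.loc[frame.index, "os_days"].astype(float)
    frame["os_event"] = t.loc[frame.index, "os_event"].astype(int)
    return frame


def cox_univariate_screen(
    expr: ExpressionMatrix, samples: SampleTable, alpha: float = 0.05
) -> list[str]:
    """Single-covariate Cox fit per biomarker; keep Wald p < alpha.

    Constant covariates and non-convergent fits are skipped with a
    warning rather than failing the screen.
    """
    frame = _survival_frame(expr, samples)
    if frame["os_event"].sum() == 0:
        raise ValueError("no events in the cohort")
    kept = []
    for feature in expr.feature_ids:
        sub = frame[[feature, "os_days", "os_event"]]
        if sub[feature].std() == 0:
            warnings.warn(f"constant covariate {feature!r} skipped", stacklevel=2)
            continue
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(sub, duration_col="os_days", event_col="os_event")
        except Exception as exc:  # noqa: BLE001 - lifelines raises several types
            warnings.warn(f"Cox fit failed for {feature!r}: {exc}", stacklevel=2)
            continue
        if float(cph.summary.loc[feature, "p"]) < alpha:
            kept.append(feature)
    return kept


def cox_multivariate_fit(
    expr: ExpressionMatrix, samples: SampleTable, alpha: float = 0.05
) -> RiskModel:
    """Joint Cox fit over screened biomarkers, reduced to Wald p < alpha.

    Covariates significant in the joint fit are refit together to give
    the final risk-model coefficients; the cutoff is the median training
    risk score. With a single covariate this reduces to the univariate
    fit.
    """
    if not expr.feature_ids:
        raise ValueError("screened biomarker set is empty")
    frame = _survival_frame(expr, samples)

    def _fit(features: list[str]) -> CoxPHFitter:
        cph = CoxPHFitter()
        sub = frame[[*features, "os_days", "os_event"]]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(sub, duration_col="os_days", event_col="os_event")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"multivariate Cox fit failed over {features}: {exc}") from exc
        return cph

    joint = _fit(list(expr.feature_ids))
    retained = [f for f in expr.feature_ids if float(joint.summary.loc[f, "p"]) < alpha]
    if not retained:
        raise ValueError("no covariate significant in the multivariate fit")
    final = joint if len(retained) == len(expr.feature_ids) else _fit(retained)
    coefs = final.params_[retained].to_numpy(dtype=float)
    model = RiskModel(retained, coefs, cutoff=0.0)
    scores = risk_scores(expr, model)
    model.cutoff = float(np.median(scores))
    return model


def risk_scores(expr: ExpressionMatrix, model: RiskModel) -> pd.Series:
    """Linear risk score per patient: sum of expression x coefficient."""
    missing = [f for f in model.pmb_ids if f not in expr.feature_ids]
    if missing:
        raise KeyError(f"expression lacks risk-model biomarkers: {missing}")
    frame = expr.to_frame()
    x = frame.loc[model.pmb_ids].to_numpy(dtype=float)  # biomarkers x patients
    return pd.Series(model.coefficients @ x, index=expr.sample_ids, name="risk_score")


def median_split(scores: pd.Series | np.ndarray) -> pd.Series:
    """Label each patient high iff score strictly exceeds the median.

    For odd n the median patient falls in the low group. All-equal
    scores put everyone in low with a warning.
    """
    values = np.asarray(scores, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 patients to split")
    cutoff = float(np.median(values))
    labels = np.where(values > cutoff, "high", "low")
    if (labels == "low").all():
        warnings.warn("all risk scores equal: everyone in the low group", stacklevel=2)
    index = scores.index if isinstance(scores, pd.Series) else pd.RangeIndex(values.size)
    return pd.Series(labels, index=index, name="risk_group")


def km_logrank(
    groups: pd.Series, samples: SampleTable
) -> tuple[dict[str, pd.DataFrame], float]:
    """Kaplan-Meier curves per risk group and the two-group log-rank p.

    ``groups`` maps sample id to 'high'/'low'. Returns the product-limit
    survival table per group and the log-rank chi-square p-value.
    """
    t = samples.table.set_index("sample_id")
    names = sorted(set(groups))
    if len(names) != 2:
        raise ValueError(f"exactly two nonempty groups required, got {names}")
    curves: dict[str, pd.DataFrame] = {}
    data = {}
    for name in names:
        ids = list(groups[groups == name].index)
        durations = t.loc[ids, "os_days"].astype(float)
        events = t.loc[ids, "os_event"].astype(int)
        kmf = KaplanMeierFitter()
        kmf.fit(durations, events, label=name)
        curves[name] = kmf.survival_function_
        data[name] = (durations, events)
    (d1, e1), (d2, e2) = data[names[0]], data[names[1]]
    res = logrank_test(d1, d2, event_observed_A=e1, event_observed_B=e2)
    return curves, float(res.p_value)


def _km_survival_at(times: np.ndarray, events: np.ndarray, horizon: float) -> float:
    """Product-limit survival probability at the horizon."""
    order = np.argsort(times)
    times, events = times[order], events[order]
    at_risk = times.size
    surv = 1.0
    for t_i, grp in pd.Series(events).groupby(pd.Series(times)):
        if t_i > horizon:
            break
        d = int(grp.sum())
        if d > 0:
            surv *= 1.0 - d / at_risk
        at_risk -= len(grp)
    return surv


def survival_roc(
    scores: pd.Series,
    samples: SampleTable,
    horizon: float,
) -> float:
    """Time-dependent ROC AUC at the horizon (Kaplan-Meier construction).

    Cases are patients who die by the horizon, controls those surviving
    past it; status probabilities are estimated by Kaplan-Meier within
    the marker strata (see module docstring). Higher scores are assumed
    to indicate higher risk.
    """
    t = samples.table.set_index("sample_id")
    ids = list(scores.index)
    times = t.loc[ids, "os_days"].to_numpy(dtype=float)
    events = t.loc[ids, "os_event"].to_numpy(dtype=int)
    x = scores.to_numpy(dtype=float)
    if horizon > times.max():
        raise ValueError("horizon exceeds observed follow-up")
    s_t = _km_survival_at(times, events, horizon)
    if s_t >= 1.0:
        raise ValueError("no events before the horizon; ROC undefined")
    n = x.size
    cutpoints = np.unique(x)
    tpr = [1.0]
    fpr = [1.0]
    for c in cutpoints:
        above = x > c
        p_above = above.mean()
        s_above = _km_survival_at(times[above], events[above], horizon) if above.any() else 1.0
        s_below = _km_survival_at(times[~above], events[~above], horizon) if (~above).any() else 1.0
        sens = p_above * (1.0 - s_above) / (1.0 - s_t)
        spec = (1.0 - p_above) * s_below / s_t if s_t > 0 else 0.0
        tpr.append(float(np.clip(sens, 0.0, 1.0)))
        fpr.append(float(np.clip(1.0 - spec, 0.0, 1.0)))
    tpr.append(0.0)
    fpr.append(0.0)
    order = np.argsort(fpr)
    return float(np.trapezoid(np.asarray(tpr)[order], np.asarray(fpr)[order]))
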