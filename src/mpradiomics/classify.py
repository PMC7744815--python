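"""Classifier evaluation of selected feature subsets, ROC, and SUVR correlation.

Evaluation mirrors the resampling of the selection stage: for every
(repetition, fold) run, an SVM (sigmoid / linear / radial-basis kernel) or a
random forest is trained on the 80% training split using that run's selected
subset, then evaluated on the 20% validation fold and optionally on a fixed
external test cohort.  Accuracy, sensitivity (recall on the case class) and
specificity are aggregated as mean +/- SD over the folds x repetitions runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .core import FeatureKey, FeatureMatrix
from .selection import BRANCHES, StabilityResult, _standardize

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    family: str                      # "svm" | "rf"
    kernel: str | None = None        # svm only: "sigmoid" | "linear" | "rbf"
    C: float = 1.0                   # svm regularization
    n_estimators: int = 500          # rf trees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("svm", "rf"):
            raise ValueError(f"unknown model family {self.family!r}")
        if (self.family == "svm") != (self.kernel is not None):
            raise ValueError("kernel must be given iff family == 'svm'")
        if self.kernel is not None and self.kernel not in ("sigmoid", "linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    def label(self) -> str:
        return f"svm_{self.kernel}" if self.family == "svm" else "rf"


def _make_model(spec: ModelSpec):
    if spec.family == "svm":
        # gamma="scale" = 1 / (n_features * X.var()), the rbf bandwidth default
        return SVC(kernel=spec.kernel, C=spec.C, gamma="scale", random_state=spec.seed)
    return RandomForestClassifier(
        n_estimators=spec.n_estimators, max_features="sqrt", random_state=spec.seed
    )


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float | None]:
    """Accuracy / sensitivity / specificity in percent (case class = 1).

    A metric whose denominator is empty (evaluation set missing a class) is
    reported as None, never as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    n = len(y_true)
    return {
        "accuracy": 100.0 * (tp + tn) / n if n else None,
        "sensitivity": 100.0 * tp / (tp + fn) if (tp + fn) else None,
        "specificity": 100.0 * tn / (tn + fp) if (tn + fp) else None,
    }


def train_eval(
    train_values: np.ndarray, train_labels: np.ndarray,
    eval_values: np.ndarray, eval_labels: np.ndarray,
    spec: ModelSpec,
) -> dict[str, float | None]:
    """Fit on the training slice, score one evaluation slice.

    Features are standardized with training statistics; the evaluation slice
    is transformed with the same statistics.
    """
    if train_values.shape[1] == 0:
        raise ValueError("empty feature subset")
    mu = train_values.mean(axis=0)
    sd = train_values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    model = _make_model(spec)
    model.fit((train_values - mu) / sd, train_labels)
    pred = model.predict((eval_values - mu) / sd)
    return confusion_metrics(eval_labels, pred)


@dataclass
class MetricsTable:
    """mean +/- SD of each metric per (dataset, branch, model) cell."""

    cells: dict[tuple[str, str, str], dict[str, float]]
    run_count: int
    skipped: dict[tuple[str, str, str], int]

    def summary(self) -> str:
        lines = []
        for (dataset, branch, model), m in sorted(self.cells.items()):
            parts = ", ".join(
                f"{name} {m[name + '_mean']:.1f}+/-{m[name + '_sd']:.1f}%"
                for name in ("accuracy", "sensitivity", "specificity")
                if m.get(name + "_mean") is not None
            )
            lines.append(f"{dataset:10s} {branch:7s} {model:11s} {parts}")
        return "\n".join(lines)


def evaluate_all(
    fm: FeatureMatrix,
    labels,
    stability: StabilityResult,
    specs: list[ModelSpec],
    test_fm: FeatureMatrix | None = None,
    test_labels=None,
    max_runs: int | None = None,
) -> MetricsTable:
    """Repeat train/evaluate over the stability stage's resamples.

    Each run reuses that resample's fold split and per-branch selected
    subset.  Runs with an empty selection are skipped for that branch and
    counted.  ``max_runs`` caps the number of (repetition, fold) runs used,
    taking them in order.
    """
    values = fm.values
    labels = np.asarray(labels)
    runs = list(zip(stability.run_folds, stability.run_selections))
    if max_runs is not None:
        runs = runs[:max_runs]
    per_cell: dict[tuple[str, str, str], dict[str, list[float]]] = {}
    skipped: dict[tuple[str, str, str], int] = {}
    for (rep, fold), sel in runs:
        val_mask = stability.fold_assignments[rep] == fold
        train_idx = np.where(~val_mask)[0]
        val_idx = np.where(val_mask)[0]
        for branch in BRANCHES:
            cols = sel[branch]
            for spec in specs:
                if len(cols) == 0:
                    for ds in ("validation",) + (("test",) if test_fm is not None else ()):
                        skipped[(ds, branch, spec.label())] = (
                            skipped.get((ds, branch, spec.label()), 0) + 1
                        )
                    continue
                tr_v = values[np.ix_(train_idx, cols)]
                evals = [("validation", values[np.ix_(val_idx, cols)], labels[val_idx])]
                if test_fm is not None:
                    evals.append(("test", test_fm.values[:, cols], np.asarray(test_labels)))
                mu = tr_v.mean(axis=0)
                sd = np.where(tr_v.std(axis=0) > 0, tr_v.std(axis=0), 1.0)
                model = _make_model(spec)
                model.fit((tr_v - mu) / sd, labels[train_idx])
                for ds, ev, ey in evals:
                    m = confusion_metrics(ey, model.predict((ev - mu) / sd))
                    cell = per_cell.setdefault(
                        (ds, branch, spec.label()),
                        {"accuracy": [], "sensitivity": [], "specificity": []},
                    )
                    for name, v in m.items():
                        if v is None:
                            skipped[(ds, branch, spec.label())] = (
                                skipped.get((ds, branch, spec.label()), 0) + 1
                            )
                        else:
                            cell[name].append(v)
    cells: dict[tuple[str, str, str], dict[str, float]] = {}
    for key, metric_lists in per_cell.items():
        out: dict[str, float] = {}
        for name, vals in metric_lists.items():
            if vals:
                out[name + "_mean"] = float(np.mean(vals))
                out[name + "_sd"] = float(np.std(vals))
                out[name + "_n"] = len(vals)
        cells[key] = out
    if skipped:
        log.info("evaluate_all: skipped/missing cells: %s", skipped)
    return MetricsTable(cells=cells, run_count=len(runs), skipped=skipped)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, outcomes) -> dict:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2).

    The raw AUC is reported together with an orientation flag: when raw
    AUC < 0.5 the oriented value is 1 - AUC and ``direction`` is -1 (high
    score predicts the negative class), never silently inverted.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes)
    n1 = int((outcomes == 1).sum())
    n0 = int((outcomes == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[outcomes == 1].sum() - n1 * (n1 + 1) / 2
    auc = float(u / (n0 * n1))
    direction = -1 if auc < 0.5 else 1
    # empirical ROC curve points
    thresholds = np.unique(scores)[::-1]
    curve = [(0.0, 0.0)]
    for t in thresholds:
        pred = scores >= t
        tpr = float((pred & (outcomes == 1)).sum() / n1)
        fpr = float((pred & (outcomes == 0)).sum() / n0)
        curve.append((fpr, tpr))
    if curve[-1] != (1.0, 1.0):
        curve.append((1.0, 1.0))
    return {
        "auc": auc,
        "auc_oriented": auc if direction == 1 else 1.0 - auc,
        "direction": direction,
        "curve": curve,
    }


def combined_score(feature_values: np.ndarray, outcomes) -> dict:
    """Per-subject score combining k >= 2 features by unpenalized logistic fit.

    The linear predictor of the fit (on the same subjects) is returned as
    the combined score.  Complete separation triggers a ridge-stabilized
    refit, flagged in the result.
    """
    X = np.asarray(feature_values, dtype=float)
    y = np.asarray(outcomes)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("combined_score requires k >= 2 feature columns")
    Z = _standardize(X)
    ridged = False
    model = LogisticRegression(penalty=None, max_iter=2000)
    model.fit(Z, y)
    coef = model.coef_.ravel()
    if not np.isfinite(coef).all() or np.abs(coef).max() > 1e4:
        ridged = True
        model = LogisticRegression(penalty="l2", C=1.0, max_iter=2000)
        model.fit(Z, y)
        coef = model.coef_.ravel()
        log.warning("combined_score: separation detected; ridge-stabilized fit used")
    score = Z @ coef + float(model.intercept_[0])
    return {"score": score, "coef": coef, "ridged": ridged}


# ---------------------------------------------------------------------------
# SUVR correlation
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def suvr_correlation(feature, suvr, covariates: np.ndarray | None = None) -> dict:
    """Plain and covariate-adjusted Pearson correlation with amyloid burden.

    The adjusted value is the partial correlation via double residualization
    on the covariate matrix (columns e.g. age, sex, education, MoCA), with
    the degrees of freedom reduced by the covariate count.
    """
    x = np.asarray(feature, dtype=float)
    s = np.asarray(suvr, dtype=float)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        mask = np.isfinite(x) & np.isfinite(s) & np.isfinite(covariates).all(axis=1)
    else:
        mask = np.isfinite(x) & np.isfinite(s)
    x, s = x[mask], s[mask]
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 complete observations")
    if x.std() == 0 or s.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = stats.pearsonr(x, s)
    out = {"r": float(r), "p": float(p), "n": n}
    if covariates is not None:
        C = covariates[mask]
        rx = _residualize(x, C)
        rs = _residualize(s, C)
        k = C.shape[1]
        r_adj = float(np.corrcoef(rx, rs)[0, 1])
        df = n - 2 - k
        if df <= 0:
            raise ValueError("too few observations for adjusted correlation")
        t = r_adj * np.sqrt(df / (1 - r_adj**2))
        p_adj = float(2 * stats.t.sf(abs(t), df))
        out.update({"r_adjusted": r_adj, "p_adjusted": p_adj, "df_adjusted": df})
    return out
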