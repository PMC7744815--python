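"""Resampling stability selection with per-feature occurrence tallies.

The selection chain, applied to the training 80% of every resample:

1. two-sided two-sample t-test, keep p < alpha (default 0.05);
2. decorrelation: greedy scan in ascending-p order, keeping a feature only
   if its absolute Pearson correlation with every already-kept feature is
   at most the threshold (default 0.8);
3. three independent selectors on the surviving set — Fisher-score ranking
   (top 50), L1-penalized logistic regression with an inner-CV penalty, and
   greedy mRMR (top 50).

The chain runs on every training fold of a stratified 5-fold split, and the
split is redrawn 100 times, so each selector branch tallies how often every
feature was retained, from 0 to folds x repetitions = 500.  The top 10
counts per branch are the "high-frequency" features; features high-frequency
in all three branches are "stable"; a looser variant collects features whose
raw count exceeds 300 in every branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .core import FeatureKey, FeatureMatrix, SubjectRecord

log = logging.getLogger(__name__)

BRANCHES = ("fisher", "lasso", "mrmr")


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.05
    corr_threshold: float = 0.8
    top_k_fisher: int = 50
    top_k_mrmr: int = 50
    lasso_Cs: tuple[float, ...] = tuple(np.logspace(-2.0, 1.0, 5))
    lasso_inner_folds: int = 5
    folds: int = 5
    repetitions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.corr_threshold < 1:
            raise ValueError("corr_threshold must be in (0, 1)")
        if self.folds < 2 or self.repetitions < 1:
            raise ValueError("folds >= 2 and repetitions >= 1 required")

    @property
    def max_possible(self) -> int:
        return self.folds * self.repetitions


@dataclass
class SelectionTally:
    branch: str
    counts: dict[FeatureKey, int]
    max_possible: int

    def __post_init__(self) -> None:
        bad = {k: c for k, c in self.counts.items() if not 0 <= c <= self.max_possible}
        if bad:
            raise ValueError(f"tally counts outside [0, {self.max_possible}]: {bad}")


@dataclass
class StableReport:
    high_frequency: dict[str, list[tuple[FeatureKey, int]]]
    stable: list[FeatureKey]
    stable_300: list[FeatureKey]
    mean_counts: dict[FeatureKey, float]


@dataclass
class StabilityResult:
    tallies: dict[str, SelectionTally]
    fold_assignments: np.ndarray          # (repetitions, n_subjects) fold ids
    run_selections: list[dict[str, np.ndarray]]  # per run: branch -> column idx
    run_folds: list[tuple[int, int]]      # per run: (repetition, fold)
    keys: list[FeatureKey]


# ---------------------------------------------------------------------------
# Covariate adjustment
# ---------------------------------------------------------------------------

def adjust_covariates(
    fm: FeatureMatrix,
    records: list[SubjectRecord],
    covariates: tuple[str, ...] = ("age", "sex", "education"),
) -> FeatureMatrix:
    """Replace each feature by its OLS residual on the covariates.

    The fit (intercept included) is performed once on the full cohort.
    Subjects with a missing covariate are dropped with a logged count;
    constant covariates are dropped with a warning.
    """
    by_id = {r.id: r for r in records}
    rows, design_rows = [], []
    for i, sid in enumerate(fm.subjects):
        rec = by_id.get(sid)
        if rec is None:
            continue
        vals = [getattr(rec, c) for c in covariates]
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
            continue
        rows.append(i)
        design_rows.append([float(v) for v in vals])
    dropped = len(fm.subjects) - len(rows)
    if dropped:
        log.info("adjust_covariates: dropped %d subject(s) with missing covariates", dropped)
    if len(rows) <= len(covariates) + 1:
        raise ValueError("too few complete subjects for covariate adjustment")
    X = np.asarray(design_rows)
    keep_cov = X.std(axis=0) > 0
    for name, ok in zip(covariates, keep_cov):
        if not ok:
            log.warning("adjust_covariates: covariate %r is constant; dropped", name)
    X = X[:, keep_cov]
    design = np.column_stack([np.ones(len(rows)), X])
    Y = fm.values[rows]
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    residuals = Y - design @ beta
    return FeatureMatrix([fm.subjects[i] for i in rows], fm.keys, residuals)


# ---------------------------------------------------------------------------
# Chain stages (array level)
# ---------------------------------------------------------------------------

def ttest_pvalues(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-sided equal-variance two-sample t-test p-value per column.

    Columns with zero variance in both groups get p = NaN (undefined t).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both groups must be present")
    x0, x1 = values[labels == 0], values[labels == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("both groups need >= 2 subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x0, x1, axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    both_const = (x0.std(axis=0) == 0) & (x1.std(axis=0) == 0)
    separated = both_const & (x0.mean(axis=0) != x1.mean(axis=0))
    p[both_const] = np.nan   # t undefined: constant within both groups
    p[separated] = 0.0       # ... but perfectly separated -> maximally significant
    return p


def ttest_filter(fm: FeatureMatrix, labels, alpha: float = 0.05) -> list[FeatureKey]:
    p = ttest_pvalues(fm.values, np.asarray(labels))
    keep = np.where(np.nan_to_num(p, nan=np.inf) < alpha)[0]
    return [fm.keys[i] for i in keep]


def _decorrelate_idx(values: np.ndarray, candidates: np.ndarray, threshold: float) -> np.ndarray:
    """Greedy decorrelation over columns, in the order given by ``candidates``.

    Keeps a column iff |Pearson r| with every kept column is <= threshold.
    Zero-variance columns correlate with nothing and are always kept.
    """
    n = values.shape[0]
    Z = values[:, candidates].astype(float)
    sd = Z.std(axis=0)
    nonconst = sd > 0
    Z = (Z - Z.mean(axis=0)) / np.where(nonconst, sd, 1.0)
    Z[:, ~nonconst] = 0.0
    kept: list[int] = []
    kept_z: list[np.ndarray] = []
    for j in range(len(candidates)):
        z = Z[:, j]
        if kept_z:
            r = np.abs(np.array(kept_z) @ z) / n
            if (r > threshold).any():
                continue
        kept.append(j)
        kept_z.append(z)
    return candidates[np.array(kept, dtype=int)]


def decorrelate(
    fm: FeatureMatrix, subset: list[FeatureKey], labels, corr_threshold: float = 0.8
) -> list[FeatureKey]:
    """Decorrelate a candidate subset, scanning in ascending t-test p order."""
    if not subset:
        raise ValueError("empty candidate subset")
    idx_map = fm.key_index()
    cols = np.array([idx_map[k.canonical()] for k in subset])
    p = ttest_pvalues(fm.values, np.asarray(labels))[cols]
    order = np.argsort(np.nan_to_num(p, nan=np.inf), kind="stable")
    kept = _decorrelate_idx(fm.values, cols[order], corr_threshold)
    kept_set = set(kept.tolist())
    return [k for k, c in zip(subset, cols) if c in kept_set]


def fisher_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Fisher score per column with population variances.

    F = [n1 (mu1 - mu)^2 + n2 (mu2 - mu)^2] / [n1 s1^2 + n2 s2^2];
    zero denominator with nonzero numerator -> +inf (perfect separation);
    0/0 -> 0.
    """
    labels = np.asarray(labels)
    x0, x1 = values[labels == 0], values[labels == 1]
    n0, n1 = len(x0), len(x1)
    mu = values.mean(axis=0)
    num = n0 * (x0.mean(axis=0) - mu) ** 2 + n1 * (x1.mean(axis=0) - mu) ** 2
    den = n0 * np.var(x0, axis=0) + n1 * np.var(x1, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    f[(den == 0) & (num > 0)] = np.inf
    f[(den == 0) & (num == 0)] = 0.0
    return f


def _top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, ties broken by ascending index."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order[: min(k, len(scores))]


def fisher_rank(fm: FeatureMatrix, labels, k: int = 50) -> list[FeatureKey]:
    f = fisher_scores(fm.values, np.asarray(labels))
    if np.isinf(f).any():
        log.warning("fisher_rank: %d feature(s) with zero within-class variance", int(np.isinf(f).sum()))
    if k > len(fm.keys):
        log.info("fisher_rank: k=%d exceeds %d features; returning all", k, len(fm.keys))
    return [fm.keys[i] for i in _top_k(f, k)]


def _standardize(train: np.ndarray) -> np.ndarray:
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - train.mean(axis=0)) / sd


def _lasso_select_idx(
    values: np.ndarray, labels: np.ndarray, config: SelectionConfig,
    seed: int, C: float | None = None,
) -> np.ndarray:
    X = _standardize(values)
    y = np.asarray(labels)
    if C is None:
        # inner stratified CV minimizing deviance (summed log loss); ties go
        # to the smaller C (sparser model)
        Cs = np.sort(np.asarray(config.lasso_Cs))
        losses = np.zeros(len(Cs))
        skf = StratifiedKFold(config.lasso_inner_folds, shuffle=True, random_state=seed)
        for tr, va in skf.split(X, y):
            for i, c in enumerate(Cs):
                m = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear", max_iter=500)
                m.fit(X[tr], y[tr])
                losses[i] += log_loss(y[va], m.predict_proba(X[va])[:, 1], labels=[0, 1])
        C = float(Cs[int(np.argmin(losses))])
    model = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=500)
    model.fit(X, y)
    coef = model.coef_.ravel()
    sel = np.where(np.abs(coef) > 1e-8)[0]
    if len(sel) == 0:
        log.debug("lasso: all coefficients shrunk to zero (empty selection)")
    return sel


def lasso_select(
    fm: FeatureMatrix, labels, config: SelectionConfig = SelectionConfig(),
    C: float | None = None,
) -> list[FeatureKey]:
    """Features with nonzero coefficients in an L1-penalized logistic model.

    The penalty is chosen by inner cross-validation minimizing deviance
    unless a fixed inverse-penalty ``C`` is supplied.
    """
    idx = _lasso_select_idx(fm.values, np.asarray(labels), config, config.seed, C)
    return [fm.keys[i] for i in idx]


def _discretize_terciles(values: np.ndarray) -> np.ndarray:
    """Per-column tercile binning into {0, 1, 2} by the column's own quantiles."""
    q = np.quantile(values, [1 / 3, 2 / 3], axis=0)
    return (values > q[0]) .astype(np.int64) + (values > q[1]).astype(np.int64)


def _mi_with_label(d: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mutual information (nats) of each tercile-binned column with binary y."""
    n = len(y)
    mi = np.zeros(d.shape[1])
    py = np.bincount(y, minlength=2) / n
    for b in range(3):
        mb = d == b
        pb = mb.mean(axis=0)
        for c in (0, 1):
            pj = (mb & (y == c)[:, None]).mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = pj * np.log(pj / (pb * py[c]))
            mi += np.nan_to_num(term)
    return mi


def _mi_between(d: np.ndarray, col: np.ndarray) -> np.ndarray:
    """MI (nats) of each tercile-binned column with one tercile-binned column."""
    n = len(col)
    mi = np.zeros(d.shape[1])
    for b in range(3):
        mb = d == b
        pb = mb.mean(axis=0)
        for c in range(3):
            mc = col == c
            pc = mc.mean()
            pj = (mb & mc[:, None]).mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = pj * np.log(pj / (pb * pc))
            mi += np.nan_to_num(term)
    return mi


def _mrmr_select_idx(values: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Greedy mRMR with the difference (MID) criterion on tercile bins."""
    d = _discretize_terciles(values)
    y = np.asarray(labels)
    m = d.shape[1]
    relevance = _mi_with_label(d, y)
    selected: list[int] = []
    redundancy = np.zeros(m)
    available = np.ones(m, dtype=bool)
    for _ in range(min(k, m)):
        score = relevance - (redundancy / len(selected) if selected else 0.0)
        score = np.where(available, score, -np.inf)
        best = int(np.argmax(score))  # argmax takes the first max: canonical tie-break
        selected.append(best)
        available[best] = False
        if available.any():
            redundancy += _mi_between(d, d[:, best])
    return np.array(selected, dtype=int)


def mrmr_select(fm: FeatureMatrix, labels, k: int = 50) -> list[FeatureKey]:
    idx = _mrmr_select_idx(fm.values, np.asarray(labels), k)
    return [fm.keys[i] for i in idx]


# ---------------------------------------------------------------------------
# Resampling driver
# ---------------------------------------------------------------------------

def _run_chain(
    values: np.ndarray, labels: np.ndarray, config: SelectionConfig, seed: int
) -> dict[str, np.ndarray]:
    """One resample: t-test -> decorrelate -> three selectors.

    Returns branch -> selected column indices (into the full matrix).
    """
    p = ttest_pvalues(values, labels)
    candidates = np.where(np.nan_to_num(p, nan=np.inf) < config.alpha)[0]
    out: dict[str, np.ndarray] = {}
    if len(candidates) == 0:
        return {b: np.array([], dtype=int) for b in BRANCHES}
    order = np.argsort(np.nan_to_num(p[candidates], nan=np.inf), kind="stable")
    kept = _decorrelate_idx(values, candidates[order], config.corr_threshold)
    sub = values[:, kept]
    out["fisher"] = kept[_top_k(fisher_scores(sub, labels), config.top_k_fisher)]
    out["lasso"] = kept[_lasso_select_idx(sub, labels, config, seed)]
    out["mrmr"] = kept[_mrmr_select_idx(sub, labels, config.top_k_mrmr)]
    return out


def stability_run(fm: FeatureMatrix, labels, config: SelectionConfig) -> StabilityResult:
    """Tally feature selections over stratified k-fold splits x repetitions.

    Fold splits are shared by the three branches; fold assignments and the
    per-run selected sets are kept for reuse by the classification stage.
    """
    values = np.ascontiguousarray(fm.values)
    labels = np.asarray(labels)
    n = len(labels)
    counts = {b: np.zeros(values.shape[1], dtype=np.int64) for b in BRANCHES}
    fold_assignments = np.zeros((config.repetitions, n), dtype=np.int64)
    run_selections: list[dict[str, np.ndarray]] = []
    run_folds: list[tuple[int, int]] = []
    ss = np.random.SeedSequence(config.seed)
    for rep in range(config.repetitions):
        child = ss.spawn(1)[0]
        for attempt in range(10):
            split_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=split_seed)
            splits = list(skf.split(np.zeros(n), labels))
            ok = all(len(np.unique(labels[tr])) == 2 for tr, _ in splits)
            if ok:
                break
            log.warning("repetition %d: a fold lost a class; redrawing split", rep)
            child = child.spawn(1)[0]
        for fold, (train, test) in enumerate(splits):
            fold_assignments[rep, test] = fold
            chain_seed = int(np.random.SeedSequence((config.seed, rep, fold)).generate_state(1)[0] % (2**31 - 1))
            sel = _run_chain(values[train], labels[train], config, chain_seed)
            for b in BRANCHES:
                counts[b][sel[b]] += 1
            run_selections.append(sel)
            run_folds.append((rep, fold))
    tallies = {
        b: SelectionTally(
            branch=b,
            counts={fm.keys[i]: int(c) for i, c in enumerate(counts[b]) if c > 0},
            max_possible=config.max_possible,
        )
        for b in BRANCHES
    }
    return StabilityResult(
        tallies=tallies,
        fold_assignments=fold_assignments,
        run_selections=run_selections,
        run_folds=run_folds,
        keys=list(fm.keys),
    )


def high_frequency(tally: SelectionTally, n: int = 10) -> list[tuple[FeatureKey, int]]:
    """Top-n features by occurrence count; ties broken by canonical key order."""
    if not tally.counts:
        raise ValueError("empty tally")
    items = sorted(
        ((k, c) for k, c in tally.counts.items() if c > 0),
        key=lambda kv: (-kv[1], kv[0].sort_tuple()),
    )
    if len(items) < n:
        log.info("high_frequency: only %d nonzero count(s), fewer than %d", len(items), n)
    return items[:n]


def stable_overlap(tallies: dict[str, SelectionTally], n: int = 10, threshold: int = 300) -> StableReport:
    """Intersect per-branch high-frequency lists and the >threshold counts."""
    hf = {b: high_frequency(tallies[b], n) for b in BRANCHES}
    hf_sets = [set(k for k, _ in hf[b]) for b in BRANCHES]
    stable = sorted(set.intersection(*hf_sets), key=lambda k: k.sort_tuple())
    over = [
        set(k for k, c in tallies[b].counts.items() if c > threshold) for b in BRANCHES
    ]
    stable_300 = sorted(set.intersection(*over), key=lambda k: k.sort_tuple())
    interesting = set(stable) | set(stable_300)
    mean_counts = {
        k: float(np.mean([tallies[b].counts.get(k, 0) for b in BRANCHES]))
        for k in sorted(interesting, key=lambda k: k.sort_tuple())
    }
    return StableReport(high_frequency=hf, stable=stable, stable_300=stable_300, mean_counts=mean_counts)
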