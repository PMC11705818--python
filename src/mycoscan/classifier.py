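"""Disease-state classification from abundance profiles.

Random-forest and LASSO (L1 logistic) models evaluated with repeated,
stratified k-fold cross-validation. The module's own content is the CV
scaffolding: fold construction, out-of-fold score discipline, AUC with a
rank-statistic estimator, stratified-bootstrap confidence intervals, and
importance aggregation across folds; the model fits are delegated to
scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .tables import AbundanceTable


@dataclass
class CvScheme:
    n_folds: int = 10
    n_repeats: int = 5
    stratified: bool = True
    seed: int = 0


@dataclass
class ClassifierReport:
    model: str
    auc: float
    auc_ci: tuple[float, float]
    per_sample_scores: pd.DataFrame  # out-of-fold scores, one column per repeat
    importance: pd.Series  # ranked taxa
    scheme: CvScheme
    auc_per_repeat: list[float] = field(default_factory=list)


def make_folds(labels, scheme: CvScheme) -> list[np.ndarray]:
    """Stratified fold assignment per repeat.

    Returns one integer array per repeat mapping each sample to its test
    fold; repeats use sub-seeds derived from the scheme seed, so the
    whole plan is reproducible. Per-fold class counts differ from exact
    proportionality by at most one sample (scikit-learn stratification).
    """
    y = pd.Series(labels).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < scheme.n_folds:
        raise ValueError(
            f"smallest class ({counts.min()}) has fewer samples than folds"
        )
    plans = []
    for rep in range(scheme.n_repeats):
        skf = StratifiedKFold(
            n_splits=scheme.n_folds,
            shuffle=True,
            random_state=(scheme.seed + 7919 * rep) % (2**31 - 1),
        )
        assign = np.empty(len(y), dtype=int)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            assign[test_idx] = fold
        plans.append(assign)
    return plans


def auc_from_scores(scores, labels) -> float:
    """AUC by the rank-statistic (Mann–Whitney) formula with midranks,
    identical to the trapezoidal ROC area under ties."""
    s = np.asarray(scores, dtype=float)
    y = pd.Series(labels).to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    pos = y == classes[1]  # larger label value = positive class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("one class absent")
    r = rankdata(s)
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_ci(
    scores, labels, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling within each class
    (so no resample degenerates to a single class)."""
    s = np.asarray(scores, dtype=float)
    y = pd.Series(labels).to_numpy()
    classes = np.unique(y)
    pos_idx = np.flatnonzero(y == classes[1])
    neg_idx = np.flatnonzero(y != classes[1])
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        boots[b] = auc_from_scores(s[idx], y[idx])
    alpha = (1 - level) / 2
    lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    return float(lo), float(hi)


def _fit_score(model: str, x_tr, y_tr, x_te, seed: int, hyper: dict):
    """Fit one fold's model; returns (test scores, importance vector)."""
    if model == "rf":
        clf = RandomForestClassifier(
            n_estimators=hyper.get("n_trees", 500),
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(x_tr, y_tr)
        scores = clf.predict_proba(x_te)[:, 1]
        return scores, clf.feature_importances_
    if model == "lasso":
        keep = x_tr.std(axis=0) > 0
        scaler = StandardScaler().fit(x_tr[:, keep])
        clf = LogisticRegressionCV(
            Cs=10,
            cv=hyper.get("inner_folds", 5),
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            random_state=seed,
            max_iter=2000,
        )
        with warnings.catch_warnings():
            # sklearn 1.9 deprecation chatter about the future l1_ratios API
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(scaler.transform(x_tr[:, keep]), y_tr)
        scores = clf.predict_proba(scaler.transform(x_te[:, keep]))[:, 1]
        imp = np.zeros(x_tr.shape[1])
        imp[keep] = np.abs(clf.coef_[0])
        return scores, imp
    raise ValueError("model must be 'rf' or 'lasso'")


def crossval_model(
    table: AbundanceTable,
    labels,
    model: str = "rf",
    scheme: CvScheme | None = None,
    hyper: dict | None = None,
) -> ClassifierReport:
    """Repeated stratified cross-validation of one classifier.

    Defaults follow the study design: RF at 10-fold × 5 repeats with 500
    trees; LASSO at 5-fold × 5 repeats with the penalty chosen by inner
    5-fold CV on each training split. Features enter on the fraction
    scale. Per repeat, out-of-fold scores are pooled into one AUC; the
    reported AUC is the mean over repeats, with a stratified-bootstrap CI
    on the first repeat's pooled scores. Importance is the mean rank of
    per-fold importance vectors (impurity decrease for RF, |standardized
    coefficient| for LASSO).
    """
    hyper = hyper or {}
    if scheme is None:
        scheme = CvScheme(n_folds=10 if model == "rf" else 5, n_repeats=5)
    labels = pd.Series(labels).reindex(table.samples)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    y = (labels == sorted(labels.unique())[1]).to_numpy().astype(int)
    x = table.to_fraction().to_numpy()
    taxa = table.taxa

    plans = make_folds(y, scheme)
    oof = np.full((len(y), scheme.n_repeats), np.nan)
    rank_sums = np.zeros(len(taxa))
    n_fits = 0
    for rep, assign in enumerate(plans):
        for fold in range(scheme.n_folds):
            test = assign == fold
            seed = (scheme.seed + 104729 * rep + fold) % (2**31 - 1)
            scores, imp = _fit_score(model, x[~test], y[~test], x[test], seed, hyper)
            oof[test, rep] = scores
            # rank 1 = most important
            rank_sums += rankdata(-imp, method="average")
            n_fits += 1
    auc_per_repeat = [auc_from_scores(oof[:, r], y) for r in range(scheme.n_repeats)]
    auc = float(np.mean(auc_per_repeat))
    ci = auc_ci(oof[:, 0], y, seed=scheme.seed)
    importance = pd.Series(rank_sums / n_fits, index=taxa, name="mean_rank")
    importance = importance.sort_values()  # best (lowest mean rank) first
    scores_df = pd.DataFrame(
        oof, index=table.samples, columns=[f"rep{r + 1}" for r in range(scheme.n_repeats)]
    )
    return ClassifierReport(
        model=model,
        auc=auc,
        auc_ci=ci,
        per_sample_scores=scores_df,
        importance=importance,
        scheme=scheme,
        auc_per_repeat=auc_per_repeat,
    )


def combined_model(
    fungal: AbundanceTable,
    bacterial: AbundanceTable,
    labels,
    scheme: CvScheme | None = None,
    model: str = "rf",
    hyper: dict | None = None,
) -> ClassifierReport:
    """Joint prediction from kingdom-prefixed feature concatenation."""
    if list(fungal.samples) != list(bacterial.samples):
        raise ValueError("fungal and bacterial tables must share samples in order")
    f = fungal.data.add_prefix("fungal|")
    b = bacterial.data.add_prefix("bacterial|")
    joint = AbundanceTable(pd.concat([f, b], axis=1))
    return crossval_model(joint, labels, model=model, scheme=scheme, hyper=hyper)
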