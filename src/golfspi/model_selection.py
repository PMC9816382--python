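"""Metric-subset selection: KMO screening and LOOCV logistic AUC.

Every combination of up to three of the nine candidate metrics is
considered.  A subset first passes a factorability screen — its overall
Kaiser-Meyer-Olkin value must reach the threshold (0.6, inclusive; the
screen applies to the overall value only, since individual variables
below 0.6 may still belong to an adequate set).  Surviving subsets get a
fitted SPI model, and the resulting one-dimensional score is evaluated as
a pro/amateur classifier: leave-one-row-out logistic regression, with the
held-out predicted probabilities pooled into a Mann-Whitney AUC.  Subsets
are ranked by AUC (ties: smaller subset, then canonical order).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .spi_model import LabeledDataset, SPIModel, fit_spi_model, kmo
from .swing_metrics import METRIC_ORDER, MetricName


class SelectionError(ValueError):
    pass


@dataclass
class SubsetResult:
    subset: tuple[MetricName, ...]
    overall_kmo: float
    per_variable_kmo: np.ndarray
    auc: float | None  # None when screened out
    model: SPIModel | None = None

    @property
    def screened_out(self) -> bool:
        return self.auc is None


def enumerate_subsets(
    names: tuple[MetricName, ...] = METRIC_ORDER, max_size: int = 3
) -> list[tuple[MetricName, ...]]:
    """All subsets of size 1..max_size, canonically ordered, no duplicates."""
    if max_size < 1:
        raise SelectionError("max_size must be >= 1")
    out: list[tuple[MetricName, ...]] = []
    for k in range(1, max_size + 1):
        out.extend(itertools.combinations(names, k))
    return out


def standardized_mean_difference(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cohen's d between pro and amateur scores, pooled sample SDs."""
    a = np.asarray(scores)[np.asarray(labels) == "pro"]
    b = np.asarray(scores)[np.asarray(labels) == "amateur"]
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((a.mean() - b.mean()) / pooled)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic (ties counted one half)."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == "pro"
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise SelectionError("both classes must be present")
    r = rankdata(scores)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _fit_fold(x: np.ndarray, y: np.ndarray) -> LogisticRegression | float:
    """Fit a near-unpenalised one-feature logistic regression.

    Returns the class-1 prior when the training fold has a single class.
    Under perfect separation the bounded-coefficient fit still produces
    probabilities monotone in the score, which is the intended fallback.
    """
    if len(np.unique(y)) < 2:
        return float(y.mean())
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10_000)
    lr.fit(x.reshape(-1, 1), y)
    return lr


def loocv_logistic_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    group_ids: np.ndarray | None = None,
) -> float:
    """Leave-one-out cross-validated logistic-regression AUC of one score.

    Each fold leaves out one row (or, with ``group_ids``, all rows of one
    subject), fits intercept + slope by maximum likelihood on the rest and
    records the held-out predicted probability of the "pro" class; the
    pooled probabilities give the Mann-Whitney AUC.
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == "pro").astype(int)
    n = len(scores)
    if n < 3:
        raise SelectionError("need at least 3 rows for LOOCV")
    if len(np.unique(y)) < 2:
        raise SelectionError("both classes must be present")
    folds = (
        [np.flatnonzero(np.asarray(group_ids) == g) for g in np.unique(group_ids)]
        if group_ids is not None
        else [np.array([i]) for i in range(n)]
    )
    probs = np.empty(n)
    for held in folds:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        fit = _fit_fold(scores[mask], y[mask])
        if isinstance(fit, float):
            probs[held] = fit
        else:
            probs[held] = fit.predict_proba(scores[held].reshape(-1, 1))[:, 1]
    return mann_whitney_auc(probs, np.asarray(labels))


def select_best(
    ds: LabeledDataset,
    seed: int,
    kmo_threshold: float = 0.6,
    max_size: int = 3,
    kmo_population: str = "original",
    group_by_subject: bool = False,
    nested: bool = False,
) -> list[SubsetResult]:
    """Rank all metric subsets by LOOCV AUC after KMO screening.

    ``kmo_population`` selects which rows enter the KMO computation:
    ``original`` (default; pre-oversampling rows of both groups),
    ``balanced`` (including synthetic rows) or ``pro_only``.  The SPI
    model is fitted once on the full dataset per subset (the classifier
    alone is cross-validated); ``nested=True`` refits the SPI per fold as
    a sensitivity analysis.  Deterministic given (dataset, seed).
    """
    if kmo_population not in ("original", "balanced", "pro_only"):
        raise SelectionError(f"unknown kmo_population {kmo_population!r}")
    results: list[SubsetResult] = []
    for subset in enumerate_subsets(max_size=max_size):
        sub = ds.select(subset)
        kmo_rows = _kmo_rows(sub, subset, seed, kmo_population)
        if len(subset) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                overall, per_var = kmo(kmo_rows)
        else:
            overall, per_var = 1.0, np.ones(1)  # singletons are trivially factorable
        if overall < kmo_threshold:
            results.append(SubsetResult(subset, overall, per_var, auc=None))
            continue
        model, balanced, scores = fit_spi_model(ds, subset, seed)
        groups = balanced.subject_ids if group_by_subject else None
        if nested:
            auc = _nested_loocv_auc(ds, subset, seed, balanced, groups)
        else:
            auc = loocv_logistic_auc(scores, balanced.groups, group_ids=groups)
        results.append(SubsetResult(subset, overall, per_var, auc=auc, model=model))
    if all(r.screened_out for r in results):
        raise SelectionError("nothing factorable: every subset fell below the KMO threshold")
    order = {s: i for i, s in enumerate(enumerate_subsets(max_size=max_size))}
    results.sort(
        key=lambda r: (
            -(r.auc if r.auc is not None else -np.inf),
            len(r.subset),
            order[r.subset],
        )
    )
    return results


def _kmo_rows(sub: LabeledDataset, subset, seed: int, population: str) -> np.ndarray:
    from .spi_model import normalize, pro_stats, smote_balance
    from dataclasses import replace

    if population == "pro_only":
        return sub.X[sub.is_pro]
    if population == "balanced":
        mean, sd = pro_stats(sub.X, sub.is_pro, [m.value for m in subset])
        balanced = smote_balance(replace(sub, X=normalize(sub.X, mean, sd)), seed)
        return balanced.X * sd + mean
    return sub.X[~sub.synthetic]


def _nested_loocv_auc(ds, subset, seed, balanced, groups) -> float:
    """Refit the SPI model without the held-out rows in every fold."""
    n = balanced.X.shape[0]
    # nested mode refits from the original rows only; synthetic rows are
    # regenerated inside each fold's fit
    from dataclasses import replace

    orig = ~ds.synthetic
    base = replace(ds.select(subset), metric_names=tuple(m.value for m in subset))
    X, g = base.X[orig], ds.groups[orig]
    sid, wid = ds.subject_ids[orig], ds.swing_ids[orig]
    m = len(X)
    fold_ids = sid if groups is not None else np.arange(m).astype(str)
    probs, labels = [], []
    for fid in np.unique(fold_ids):
        mask = fold_ids != fid
        train = LabeledDataset(
            X=X[mask], groups=g[mask], subject_ids=sid[mask], swing_ids=wid[mask],
            synthetic=np.zeros(mask.sum(), dtype=bool), metric_names=base.metric_names,
        )
        model, bal_train, train_scores = fit_spi_model(train, subset, seed)
        from .spi_model import score_metrics

        held_scores = score_metrics(model, X[~mask], base.metric_names)
        fit = _fit_fold(train_scores, (bal_train.groups == "pro").astype(int))
        if isinstance(fit, float):
            p = np.full(len(held_scores), fit)
        else:
            p = fit.predict_proba(held_scores.reshape(-1, 1))[:, 1]
        probs.extend(p)
        labels.extend(g[~mask])
    return mann_whitney_auc(np.array(probs), np.array(labels))
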