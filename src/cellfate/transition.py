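"""Directional cluster-to-cluster transition scoring.

For a source cluster, a one-vs-rest L1-penalized logistic classifier is
trained within the source dataset: the response is membership of the source
cluster, the predictors are gene expression values, and the penalty weight
is chosen by stratified cross-validation to minimize misclassification. The
L1 penalty shrinks uninformative genes to exactly zero; the surviving genes
are the transition's driver genes.

Cells of any target cluster — in the same dataset or another one with an
aligned gene universe — are then pushed through the fitted classifier. The
transition score from source to target is the fraction of target cells whose
posterior probability of the source class exceeds a threshold (default 0.5).
Scores live in [0, 1] and are directional: score(A -> B) is estimated with a
model trained on A and generally differs from score(B -> A).

An unpenalized linear-discriminant classifier over the full gene set is
provided as a control for the shrunken model, and a bootstrap mode refits
the classifier on random subsets of the source cells to attach an
uncertainty to each score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .data import ClusterAssignment, ExpressionMatrix

__all__ = [
    "TrainingSet",
    "TransitionModel",
    "TransitionScore",
    "TransitionClassifier",
    "make_binary_labels",
    "make_training_set",
    "fit_transition_model",
    "class_probability",
    "transition_score",
    "bootstrap_transition",
    "lda_control",
    "pairwise_transition_matrix",
    "driver_genes",
]


@dataclass(frozen=True)
class TrainingSet:
    """One-vs-rest design: cells x genes predictors and binary membership."""

    X: np.ndarray
    y: np.ndarray
    source_cluster: object
    gene_ids: list[str]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.shape[0] != len(y):
            raise ValueError("X and y differ in length")
        if X.shape[1] != len(self.gene_ids):
            raise ValueError("X width does not match gene_ids")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")


@dataclass(frozen=True)
class TransitionModel:
    """A fitted one-vs-rest classifier for one source cluster.

    ``intercept`` and ``coefficients`` are on the original (unscaled)
    expression scale, so the class probability of a cell x is
    sigmoid(intercept + sum_j coefficients[g_j] * x_j); genes absent from
    ``coefficients`` were shrunk to exactly zero. ``scaling`` records the
    per-gene (center, scale) standardization applied at fit time.
    """

    intercept: float
    coefficients: dict[str, float]
    lam: float
    cv_error: float
    scaling: pd.DataFrame
    gene_ids: list[str]
    source_cluster: object = None
    source_dataset: str = ""
    train_error: float | None = None

    def coefficient_vector(self) -> np.ndarray:
        return np.array([self.coefficients.get(g, 0.0) for g in self.gene_ids])


@dataclass(frozen=True)
class TransitionScore:
    """A directed source -> target transition potential in [0, 1]."""

    source: tuple[str, object]
    target: tuple[str, object]
    score: float
    n_target_cells: int
    per_cell_probabilities: np.ndarray
    threshold: float = 0.5
    bootstrap_scores: np.ndarray | None = None

    @property
    def boot_mean(self) -> float | None:
        if self.bootstrap_scores is None:
            return None
        return float(np.mean(self.bootstrap_scores))

    @property
    def boot_sd(self) -> float | None:
        if self.bootstrap_scores is None:
            return None
        return float(np.std(self.bootstrap_scores, ddof=1)) \
            if len(self.bootstrap_scores) > 1 else 0.0

    @property
    def headline(self) -> float:
        """Bootstrap mean when available, otherwise the single-fit score."""
        return self.boot_mean if self.bootstrap_scores is not None else self.score


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    et = np.exp(t[~pos])
    out[~pos] = et / (1.0 + et)
    return out


class TransitionClassifier(ClassifierMixin, BaseEstimator):
    """L1-penalized logistic classifier with a cross-validated penalty path.

    Minimizes (1/N) sum_i l(y_i, b0 + x_i . b) + lam * ||b||_1 over a
    log-spaced grid of ``n_lambda`` penalties from lam_max (the smallest
    penalty yielding the all-zero coefficient vector) down to
    ``lambda_min_ratio`` * lam_max. The penalty minimizing stratified K-fold
    misclassification error is selected (ties to the larger penalty, i.e. the
    sparser model) and the model is refit on all data at that penalty.

    Genes are centered and scaled to unit variance before fitting; constant
    genes are dropped with a warning. ``coef_`` is reported back on the
    original expression scale. ``l1_ratio`` < 1 mixes in a ridge term
    (elastic net); the default 1.0 is the pure LASSO.

    Attributes
    ----------
    coef_ : ndarray of shape (n_genes,)
        Original-scale coefficients (exact zeros for shrunk genes).
    intercept_ : float
        Original-scale intercept.
    lambda_ : float
        Selected penalty weight.
    cv_error_ : float
        Minimal mean cross-validated misclassification rate.
    lambda_path_, cv_error_path_, path_n_nonzero_ : ndarray
        The penalty grid (descending), its CV error profile and the
        full-data non-zero coefficient count along it.
    center_, scale_ : ndarray
        Standardization applied at fit time.
    """

    def __init__(self, n_folds: int = 10, n_lambda: int = 100,
                 lambda_min_ratio: float = 0.01, l1_ratio: float = 1.0,
                 class_weight=None, max_iter: int = 1000, tol: float = 1e-4,
                 random_state: int | None = None):
        self.n_folds = n_folds
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.l1_ratio = l1_ratio
        self.class_weight = class_weight
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # liblinear handles the pure-L1 case fastest; elastic net needs saga
    def _base_clf(self, lam: float, n: int) -> LogisticRegression:
        common = dict(C=1.0 / (n * lam), l1_ratio=self.l1_ratio,
                      class_weight=self.class_weight, tol=self.tol,
                      max_iter=self.max_iter, random_state=0)
        if self.l1_ratio == 1.0:
            return LogisticRegression(solver="liblinear",
                                      intercept_scaling=100.0, **common)
        return LogisticRegression(solver="saga", **common)

    def fit(self, X, y) -> "TransitionClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[1] == 0:
            raise ValueError("empty gene set")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("exactly two classes required")
        n, p = X.shape

        center = X.mean(axis=0)
        scale = X.std(axis=0)
        constant = scale == 0
        if constant.any():
            warnings.warn(f"dropping {int(constant.sum())} constant gene(s)")
            scale = np.where(constant, 1.0, scale)
        Xs = (X - center) / scale
        Xs[:, constant] = 0.0
        self.center_, self.scale_, self.constant_ = center, scale, constant

        ybar = y.mean()
        lam_max = np.abs(Xs.T @ (y - ybar)).max() / n
        if lam_max == 0:
            lam_max = 1e-3  # no marginal signal at all; penalty scale arbitrary
        lams = np.geomspace(lam_max, self.lambda_min_ratio * lam_max,
                            self.n_lambda)
        self.lambda_path_ = lams

        min_class = int(counts.min())
        n_folds = self.n_folds
        if min_class < n_folds:
            n_folds = max(3, min_class)
            warnings.warn(
                f"reducing CV folds to {n_folds} (smallest class has "
                f"{min_class} cells)")
        if min_class < n_folds:
            raise ValueError("a class has too few cells for cross-validation")

        seeds = np.random.SeedSequence(self.random_state).spawn(1)
        fold_seed = int(seeds[0].generate_state(1)[0] % (2 ** 31))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=fold_seed)
        errors = np.zeros((n_folds, len(lams)))
        for f, (tr, te) in enumerate(skf.split(Xs, y)):
            for j, lam in enumerate(lams):
                clf = self._base_clf(lam, len(tr)).fit(Xs[tr], y[tr])
                pred = (clf.predict_proba(Xs[te])[:, 1] > 0.5).astype(int)
                errors[f, j] = np.mean(pred != y[te])
        mean_err = errors.mean(axis=0)
        best_j = int(np.argmin(mean_err))  # first minimum = largest penalty
        self.cv_error_path_ = mean_err
        self.cv_error_ = float(mean_err[best_j])
        self.lambda_ = float(lams[best_j])

        nnz = np.zeros(len(lams), dtype=int)
        final = None
        for j, lam in enumerate(lams):
            clf = self._base_clf(lam, n).fit(Xs, y)
            nnz[j] = int(np.sum(clf.coef_ != 0))
            if j == best_j:
                final = clf
        self.path_n_nonzero_ = nnz

        coef_s = final.coef_.ravel().copy()
        coef_s[self.constant_] = 0.0
        b0_s = float(final.intercept_[0])
        self.coef_ = coef_s / scale
        self.coef_[self.constant_] = 0.0
        self.intercept_ = b0_s - float(np.sum(coef_s * center / scale))
        self.classes_ = classes
        self.n_features_in_ = p
        pred = (self.predict_proba(X)[:, 1] > 0.5).astype(int)
        self.train_error_ = float(np.mean(pred != y))
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


# ---------------------------------------------------------------------------
# Domain-typed operations
# ---------------------------------------------------------------------------

def make_binary_labels(assignment: ClusterAssignment, cluster) -> np.ndarray:
    """1 for cells of ``cluster``, 0 otherwise, in assignment order."""
    labels = np.asarray([1 if lab == cluster else 0
                         for lab in assignment.labels], dtype=int)
    if labels.sum() == 0:
        raise ValueError(f"cluster {cluster!r} not present in assignment")
    if labels.sum() == len(labels):
        raise ValueError(f"cluster {cluster!r} contains every cell")
    return labels


def make_training_set(expr: ExpressionMatrix, assignment: ClusterAssignment,
                      cluster, genes: Sequence[str]) -> TrainingSet:
    """Assemble the one-vs-rest design for one source cluster."""
    if list(expr.cell_ids) != list(assignment.cell_ids):
        expr = expr.subset_cells(assignment.cell_ids)
    sub = expr.subset_genes(list(genes))
    y = make_binary_labels(assignment, cluster)
    return TrainingSet(sub.values, y, cluster, sub.gene_ids)


def fit_transition_model(train: TrainingSet, n_folds: int = 10,
                         n_lambda: int = 100, seed: int | None = None,
                         l1_ratio: float = 1.0,
                         source_dataset: str = "") -> TransitionModel:
    """Fit the penalized one-vs-rest classifier for a source cluster."""
    est = TransitionClassifier(n_folds=n_folds, n_lambda=n_lambda,
                               l1_ratio=l1_ratio, random_state=seed)
    est.fit(train.X, train.y)
    coefs = {g: float(c) for g, c in zip(train.gene_ids, est.coef_) if c != 0}
    scaling = pd.DataFrame({"center": est.center_, "scale": est.scale_},
                           index=train.gene_ids)
    return TransitionModel(
        intercept=float(est.intercept_), coefficients=coefs,
        lam=float(est.lambda_), cv_error=float(est.cv_error_),
        scaling=scaling, gene_ids=list(train.gene_ids),
        source_cluster=train.source_cluster, source_dataset=source_dataset,
        train_error=est.train_error_,
    )


def class_probability(model: TransitionModel, x) -> float:
    """Posterior probability that one cell belongs to the source class.

    ``x`` is either a mapping gene -> expression or an array ordered like
    ``model.gene_ids``. Equals sigmoid(b0 + sum_j b_j x_j), strictly in
    (0, 1).
    """
    if isinstance(x, dict):
        missing = [g for g in model.gene_ids if g not in x]
        if missing:
            raise KeyError(f"missing gene value(s): {missing[:5]}")
        xv = np.array([x[g] for g in model.gene_ids], dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        if xv.shape != (len(model.gene_ids),):
            raise ValueError("x length does not match model genes")
    t = model.intercept + float(xv @ model.coefficient_vector())
    return float(_sigmoid(np.array([t]))[0])


def _score_probs(probs: np.ndarray, threshold: float) -> float:
    return float(np.count_nonzero(probs > threshold) / len(probs))


def transition_score(model: TransitionModel, target_expr: ExpressionMatrix,
                     target_cells: Sequence[str], threshold: float = 0.5,
                     target_dataset: str = "",
                     target_cluster=None) -> TransitionScore:
    """Fraction of target cells classified into the source cluster's class."""
    target_cells = list(target_cells)
    if not target_cells:
        raise ValueError("empty target cell set")
    sub = target_expr.subset_cells(target_cells).subset_genes(model.gene_ids)
    t = model.intercept + sub.values @ model.coefficient_vector()
    probs = _sigmoid(t)
    return TransitionScore(
        source=(model.source_dataset, model.source_cluster),
        target=(target_dataset, target_cluster),
        score=_score_probs(probs, threshold),
        n_target_cells=len(target_cells),
        per_cell_probabilities=probs,
        threshold=threshold,
    )


def bootstrap_transition(source_expr: ExpressionMatrix,
                         source_assignment: ClusterAssignment,
                         source_cluster,
                         target_expr: ExpressionMatrix,
                         target_cells: Sequence[str],
                         genes: Sequence[str],
                         n_boot: int = 100, subsample: float = 0.8,
                         seed: int | None = None, threshold: float = 0.5,
                         n_folds: int = 10, n_lambda: int = 100,
                         l1_ratio: float = 1.0,
                         source_dataset: str = "", target_dataset: str = "",
                         target_cluster=None) -> TransitionScore:
    """Transition score with a bootstrap distribution.

    Each run refits the classifier (penalty selection included) on
    ``ceil(subsample * n)`` source cells drawn without replacement — redrawn
    if a class vanishes — and rescores the full target set. The headline
    score is the mean over runs; the single full-data fit provides the
    per-cell probabilities.
    """
    ss = np.random.SeedSequence(seed)
    fit_seed, *boot_seeds = ss.spawn(n_boot + 1)

    full_train = make_training_set(source_expr, source_assignment,
                                   source_cluster, genes)
    fit_seed_i = int(fit_seed.generate_state(1)[0] % (2 ** 31))
    full_model = fit_transition_model(
        full_train, n_folds=n_folds, n_lambda=n_lambda, seed=fit_seed_i,
        l1_ratio=l1_ratio, source_dataset=source_dataset)
    base = transition_score(full_model, target_expr, target_cells,
                            threshold=threshold, target_dataset=target_dataset,
                            target_cluster=target_cluster)

    n = len(source_assignment.cell_ids)
    m = int(np.ceil(subsample * n))
    scores = np.empty(n_boot)
    for b, s in enumerate(boot_seeds):
        rng = np.random.default_rng(s)
        for _ in range(100):
            idx = rng.choice(n, size=m, replace=False)
            ysub = full_train.y[idx]
            if 0 < ysub.sum() < m:
                break
        else:
            raise RuntimeError("could not draw a subsample with both classes")
        sub_train = TrainingSet(full_train.X[idx], ysub, source_cluster,
                                full_train.gene_ids)
        boot_seed_i = int(s.generate_state(1)[0] % (2 ** 31))
        model = fit_transition_model(
            sub_train, n_folds=n_folds, n_lambda=n_lambda, seed=boot_seed_i,
            l1_ratio=l1_ratio, source_dataset=source_dataset)
        scores[b] = transition_score(
            model, target_expr, target_cells, threshold=threshold).score
    return TransitionScore(
        source=base.source, target=base.target, score=base.score,
        n_target_cells=base.n_target_cells,
        per_cell_probabilities=base.per_cell_probabilities,
        threshold=threshold, bootstrap_scores=scores,
    )


def lda_control(train: TrainingSet, target_expr: ExpressionMatrix,
                target_cells: Sequence[str], threshold: float = 0.5,
                target_dataset: str = "",
                target_cluster=None) -> TransitionScore:
    """Unpenalized linear-discriminant control over the full gene set.

    A two-class linear discriminant with a pooled within-class covariance,
    ridge-regularized by 1e-6 * trace / p so the estimate is invertible when
    genes outnumber cells. Target cells are scored by the posterior of the
    source class with empirical priors and thresholded as for the penalized
    model.
    """
    X, y = train.X, train.y
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 cells for LDA")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Xs = (X - center) / scale
    p = X.shape[1]

    mu = {c: Xs[y == c].mean(axis=0) for c in classes}
    pooled = np.zeros((p, p))
    for c in classes:
        d = Xs[y == c] - mu[c]
        pooled += d.T @ d
    pooled /= (len(y) - len(classes))
    pooled += np.eye(p) * (1e-6 * np.trace(pooled) / p)
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError as exc:
        raise ValueError("within-class covariance is singular") from exc

    priors = {c: k / len(y) for c, k in zip(classes, counts)}
    target_cells = list(target_cells)
    if not target_cells:
        raise ValueError("empty target cell set")
    sub = target_expr.subset_cells(target_cells).subset_genes(train.gene_ids)
    Zs = (sub.values - center) / scale
    disc = np.column_stack([
        Zs @ inv @ mu[c] - 0.5 * mu[c] @ inv @ mu[c] + np.log(priors[c])
        for c in classes
    ])
    disc -= disc.max(axis=1, keepdims=True)
    post = np.exp(disc)
    post /= post.sum(axis=1, keepdims=True)
    probs = post[:, list(classes).index(1)]
    return TransitionScore(
        source=("", train.source_cluster), target=(target_dataset, target_cluster),
        score=_score_probs(probs, threshold),
        n_target_cells=len(target_cells),
        per_cell_probabilities=probs, threshold=threshold,
    )


def pairwise_transition_matrix(pop1: tuple[ExpressionMatrix, ClusterAssignment],
                               pop2: tuple[ExpressionMatrix,
                                           ClusterAssignment] | None = None,
                               genes: Sequence[str] | None = None,
                               n_boot: int = 0, subsample: float = 0.8,
                               threshold: float = 0.5, min_cells: int = 10,
                               n_folds: int = 10, n_lambda: int = 100,
                               l1_ratio: float = 1.0,
                               seed: int | None = None,
                               include_reverse: bool = False) -> pd.DataFrame:
    """Directed transition scores between every eligible cluster pair.

    With one population, every ordered non-self pair within it is scored.
    With two, every pop1 cluster is the source and every pop2 cluster the
    target (``include_reverse`` adds the pop2 -> pop1 direction). Each source
    model is trained once per (source, bootstrap) and reused across targets
    when ``n_boot`` is 0. Clusters smaller than ``min_cells`` are skipped
    with a warning.
    """
    expr1, assign1 = pop1
    if genes is None:
        genes = list(expr1.gene_ids)
    genes = list(genes)

    if pop2 is None:
        jobs = [(("pop1", expr1, assign1), ("pop1", expr1, assign1))]
    else:
        expr2, assign2 = pop2
        jobs = [(("pop1", expr1, assign1), ("pop2", expr2, assign2))]
        if include_reverse:
            jobs.append((("pop2", expr2, assign2), ("pop1", expr1, assign1)))

    ss = np.random.SeedSequence(seed)
    rows = []
    for (sname, sexpr, sassign), (tname, texpr, tassign) in jobs:
        for sc in sassign.clusters:
            if len(sassign.members(sc)) < min_cells:
                warnings.warn(f"skipping small source cluster {sc!r} in {sname}")
                continue
            job_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            model = None
            if n_boot == 0:
                train = make_training_set(sexpr, sassign, sc, genes)
                model = fit_transition_model(
                    train, n_folds=n_folds, n_lambda=n_lambda, seed=job_seed,
                    l1_ratio=l1_ratio, source_dataset=sname)
            for tc in tassign.clusters:
                if sname == tname and sc == tc:
                    continue
                tcells = tassign.members(tc)
                if len(tcells) < min_cells:
                    warnings.warn(
                        f"skipping small target cluster {tc!r} in {tname}")
                    continue
                if n_boot == 0:
                    sc_score = transition_score(
                        model, texpr, tcells, threshold=threshold,
                        target_dataset=tname, target_cluster=tc)
                else:
                    sc_score = bootstrap_transition(
                        sexpr, sassign, sc, texpr, tcells, genes,
                        n_boot=n_boot, subsample=subsample, seed=job_seed,
                        threshold=threshold, n_folds=n_folds,
                        n_lambda=n_lambda, l1_ratio=l1_ratio,
                        source_dataset=sname, target_dataset=tname,
                        target_cluster=tc)
                rows.append({
                    "source_dataset": sname, "source_cluster": sc,
                    "target_dataset": tname, "target_cluster": tc,
                    "score": sc_score.score,
                    "boot_mean": sc_score.boot_mean,
                    "boot_sd": sc_score.boot_sd,
                    "n_boot": n_boot,
                    "n_target_cells": sc_score.n_target_cells,
                })
    return pd.DataFrame(rows)


def driver_genes(model: TransitionModel,
                 top_n: int | None = None) -> pd.DataFrame:
    """Genes surviving the L1 penalty, ranked by |coefficient| descending.

    Coefficients are on the original expression scale with sign retained;
    positive coefficients mark genes whose expression pushes a cell toward
    the source cluster's class.
    """
    items = sorted(model.coefficients.items(),
                   key=lambda kv: (-abs(kv[1]), kv[0]))
    if top_n is not None:
        items = items[:top_n]
    return pd.DataFrame(items, columns=["gene", "coefficient"])
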