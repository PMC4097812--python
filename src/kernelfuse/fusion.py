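"""Four strategies for integrating multimodal kernels in SVM classification.

Kernel-level fusion:

* **SK** -- un-weighted sum of normalized base kernels feeding one SVM;
  every modality contributes equally to the separating hyperplane.
* **MKL** -- multi-kernel learning: non-negative per-kernel weights
  ``beta_k`` are learned jointly with the SVM under an elastic-net penalty
  on the per-kernel weight-vector blocks, ``(1 - lam) * sum_k ||w_k|| +
  lam/2 * sum_k ||w_k||^2``.  ``lam = 0`` is the sparse L1 limit (weights of
  uninformative kernels are driven to zero); ``lam = 1`` is the uniform
  limit where every kernel gets weight one and MKL coincides with SK.
  Note this lambda convention (0 = sparse, 1 = uniform) is the opposite of
  some of the MKL literature.

Prediction-level (label) fusion, from one SVM per modality:

* **AV** -- prediction averaging: label = sign of the mean of the base
  classifiers' real-valued decision functions.
* **MV** -- majority voting: label = modal class among the base
  classifiers' binary predictions; ties (possible for even numbers of
  base classifiers) are broken by an a-priori rule.

The MKL penalty interpolates between the squared block-L1 norm -- the
classic sparse (simplex) MKL regularizer -- and the block-L2 norm that
corresponds to an un-weighted kernel sum::

    penalty(w) = 1/2 * [ (1 - lam) * (sum_k ||w_k||)^2 + lam * sum_k ||w_k||^2 ]

Optimization uses the variational identity ``(sum_k ||w_k||)^2 =
min_{gamma in simplex} sum_k ||w_k||^2 / gamma_k`` and alternates two
exact minimizations of the jointly convex objective ``C * sum_i hinge_i
+ 1/2 * sum_k ||w_k||^2 * ((1-lam)/gamma_k + lam)``:
(1) for fixed gamma, an SVM dual solve on ``sum_k eta_k K_k`` with
``eta_k = gamma_k / ((1-lam) + lam * gamma_k)``; (2) for fixed weights,
the closed-form update ``gamma_k = ||w_k|| / sum_j ||w_j||``.  Both steps
decrease the objective, so descent is monotone.  The reported kernel
weights are ``beta_k = eta_k``; because gamma is simplex-normalized the
weight profile depends on the *relative* informativeness of the kernels,
not on the overall scale of the dual solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, ConvergenceError, ValidationError
from .kernels import KernelMatrix, sum_normalized_kernels, normalize_kernel
from .svm import KernelSVC, predict_labels, train_svm

#: decade C grid 0.001 ... 1000 (seven values)
C_GRID_DEFAULT = tuple(10.0 ** k for k in range(-3, 4))
#: six-decade variant 0.001 ... 100
C_GRID_SIX = tuple(10.0 ** k for k in range(-3, 3))
#: lambda grid 0.1 ... 1.0 in steps of 0.1
LAMBDA_GRID_DEFAULT = tuple(round(0.1 * k, 1) for k in range(1, 11))

TIE_RULES = ("av-sign", "fixed-negative", "fixed-positive")


@dataclass
class FusionPrediction:
    """Outcome of a prediction-level fusion step.

    ``decision_values`` is None for majority voting, which discards
    magnitudes; ``tie_events`` counts broken voting ties.
    """

    method: str
    labels: np.ndarray
    decision_values: np.ndarray | None = None
    sources: tuple = ()
    tie_events: int = 0


def _stack_kernels(kernels, square: bool = True) -> np.ndarray:
    """Stack kernels into a (q, m, m) (or (q, t, m)) float array."""
    if isinstance(kernels, np.ndarray) and kernels.ndim == 3:
        Ks = kernels.astype(float, copy=False)
    else:
        if isinstance(kernels, (np.ndarray, KernelMatrix)):
            kernels = [kernels]
        mats = [K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float) for K in kernels]
        if not mats:
            raise ValidationError("need at least one kernel")
        shape = mats[0].shape
        for M in mats:
            if M.shape != shape:
                raise ValidationError(f"kernel shapes differ: {M.shape} vs {shape}")
        Ks = np.stack(mats)
    if Ks.ndim != 3 or (square and Ks.shape[1] != Ks.shape[2]):
        raise ValidationError(f"expected stacked kernels of shape (q, m, m), got {Ks.shape}")
    if not np.isfinite(Ks).all():
        raise ValidationError("kernels contain non-finite entries")
    return Ks


# ---------------------------------------------------------------------------
# SK: un-weighted sum of normalized kernels
# ---------------------------------------------------------------------------


class SumKernelSVC(BaseEstimator, ClassifierMixin):
    """SVM on the element-wise sum of the base kernels (SK fusion).

    ``normalize=True`` normalizes each training kernel to unit diagonal
    before summing.  When predicting for held-out subjects the cross
    blocks must come from the same normalization (e.g. slices of a full
    normalized kernel); with ``normalize=True`` the square training
    kernels passed to :meth:`fit` are normalized in place of that.
    """

    kind = "sk-fused"

    def __init__(self, C: float = 1.0, normalize: bool = True):
        self.C = C
        self.normalize = normalize

    def fit(self, Ks, y):
        Ks = _stack_kernels(Ks)
        if self.normalize:
            K = sum_normalized_kernels(list(Ks)).values
        else:
            K = Ks.sum(axis=0)
        self.svc_ = KernelSVC(C=self.C).fit(K, y)
        self.n_kernels_ = Ks.shape[0]
        self.classes_ = np.array([-1, 1])
        return self

    def decision_function(self, Ks_cross) -> np.ndarray:
        Ks_cross = _stack_kernels(Ks_cross, square=False)
        return self.svc_.decision_function(Ks_cross.sum(axis=0))

    def predict(self, Ks_cross) -> np.ndarray:
        return predict_labels(self.decision_function(Ks_cross))


def fuse_sk(kernels, labels, C: float = 1.0) -> KernelSVC:
    """Train one SVM on the un-weighted sum of the normalized kernels."""
    return train_svm(sum_normalized_kernels(kernels), labels, C=C)


# ---------------------------------------------------------------------------
# MKL: elastic-net multi-kernel learning
# ---------------------------------------------------------------------------


class ElasticNetMKLSVC(BaseEstimator, ClassifierMixin):
    """Elastic-net multi-kernel learning SVM.

    Parameters
    ----------
    C : float, default 1.0
        SVM regularization parameter.
    lam : float in [0, 1], default 0.5
        Elastic-net mixing: 0 = sparse (L1) limit, 1 = uniform kernel
        weights (identical to SK).
    max_outer : int, default 500
        Outer alternating-descent iteration budget; exceeding it raises
        :class:`ConvergenceError` with the trailing objective values.
    rel_tol : float, default 1e-6
        Relative objective-decrease threshold for convergence.

    Attributes
    ----------
    betas_ : (q,) non-negative learned kernel weights.
    svc_ : the inner :class:`KernelSVC` trained on ``sum_k beta_k K_k``.
    objective_path_ : per-iteration joint objective (non-increasing).
    """

    kind = "mkl"

    def __init__(
        self,
        C: float = 1.0,
        lam: float = 0.5,
        max_outer: int = 500,
        rel_tol: float = 1e-6,
        inner_tol: float = 1e-10,
    ):
        self.C = C
        self.lam = lam
        self.max_outer = max_outer
        self.rel_tol = rel_tol
        self.inner_tol = inner_tol

    def fit(self, Ks, y, kernel_sources=None):
        if not 0.0 <= self.lam <= 1.0:
            raise ValidationError(f"lam must lie in [0, 1], got {self.lam}")
        Ks = _stack_kernels(Ks)
        q = Ks.shape[0]
        y = np.asarray(y, dtype=int)
        lam = float(self.lam)

        gamma = np.full(q, 1.0 / q)
        warm = None
        path: list[float] = []
        J_prev = np.inf
        converged = False
        for _ in range(self.max_outer):
            with np.errstate(invalid="ignore"):
                eta = np.where(gamma > 0, gamma / ((1.0 - lam) + lam * gamma), 0.0)
            K = np.tensordot(eta, Ks, axes=1)
            svc = KernelSVC(C=self.C, tol=self.inner_tol).fit(K, y, warm_alpha=warm)
            ay = svc.dual_coef_
            S = np.clip(np.einsum("i,kij,j->k", ay, Ks, ay), 0.0, None)
            f = K @ ay + svc.intercept_
            hinge = np.maximum(0.0, 1.0 - y * f).sum()
            J = self.C * hinge + 0.5 * float(eta @ S)
            path.append(J)
            if len(path) > 1 and J_prev - J <= self.rel_tol * max(1.0, abs(J_prev)):
                converged = True
                break
            J_prev = J
            wnorm = eta * np.sqrt(S)  # ||w_k||
            if wnorm.sum() > 0:
                gamma = wnorm / wnorm.sum()
            warm = svc.alpha_
        if not converged:
            raise ConvergenceError(
                f"MKL alternating descent did not converge in {self.max_outer} outer "
                f"iterations; last objective values: {[round(v, 8) for v in path[-5:]]}"
            )

        self.betas_ = eta
        self.svc_ = svc
        self.objective_path_ = np.asarray(path)
        self.n_iter_ = len(path)
        self.n_kernels_ = q
        self.kernel_sources_ = tuple(kernel_sources) if kernel_sources else tuple(range(q))
        self.classes_ = np.array([-1, 1])
        return self

    def combined_kernel(self, Ks) -> np.ndarray:
        Ks = _stack_kernels(Ks, square=False)
        if Ks.shape[0] != len(self.betas_):
            raise ValidationError(
                f"{Ks.shape[0]} kernels passed to a model fitted on {len(self.betas_)}"
            )
        return np.tensordot(self.betas_, Ks, axes=1)

    def decision_function(self, Ks_cross) -> np.ndarray:
        return self.svc_.decision_function(self.combined_kernel(Ks_cross))

    def predict(self, Ks_cross) -> np.ndarray:
        return predict_labels(self.decision_function(Ks_cross))


def train_mkl(kernels, labels, C: float = 1.0, lam: float = 0.5, normalize: bool = True) -> ElasticNetMKLSVC:
    """Fit elastic-net MKL on the (by default normalized) base kernels."""
    kernels = list(kernels)
    sources = tuple(
        K.source if isinstance(K, KernelMatrix) and K.source else str(i)
        for i, K in enumerate(kernels)
    )
    if normalize:
        kernels = [normalize_kernel(K) for K in kernels]
    Ks = _stack_kernels(kernels)
    return ElasticNetMKLSVC(C=C, lam=lam).fit(Ks, labels, kernel_sources=sources)


class MKLGridSearchCV(BaseEstimator, ClassifierMixin):
    """Nested grid search over (C, lambda) for :class:`ElasticNetMKLSVC`.

    The grid point maximizing inner-CV balanced accuracy *on the training
    subjects only* is selected; ties are broken toward larger lambda, then
    smaller C (the simpler, more uniform model).  ``inner_cv`` is ``"loo"``
    for leave-one-out over the training subjects (matching the outer
    scheme) or an integer k for stratified k-fold (faster).
    """

    kind = "mkl"

    def __init__(self, C_grid=C_GRID_DEFAULT, lam_grid=LAMBDA_GRID_DEFAULT, inner_cv="loo"):
        self.C_grid = C_grid
        self.lam_grid = lam_grid
        self.inner_cv = inner_cv

    def _inner_folds(self, y: np.ndarray):
        m = len(y)
        if self.inner_cv == "loo":
            for i in range(m):
                test = np.zeros(m, dtype=bool)
                test[i] = True
                yield ~test, test
        else:
            skf = StratifiedKFold(n_splits=int(self.inner_cv), shuffle=False)
            for tr, te in skf.split(np.zeros(m), y):
                train = np.zeros(m, dtype=bool)
                train[tr] = True
                yield train, ~train

    def fit(self, Ks, y, kernel_sources=None):
        if not len(self.C_grid) or not len(self.lam_grid):
            raise ValidationError("C and lambda grids must be non-empty")
        Ks = _stack_kernels(Ks)
        y = np.asarray(y, dtype=int)
        grid = list(product(self.C_grid, self.lam_grid))
        scores: dict[tuple, float] = {}
        if len(grid) == 1:
            best_C, best_lam = grid[0]
        else:
            folds = list(self._inner_folds(y))
            usable = []
            for tr, te in folds:
                if len(np.unique(y[tr])) < 2:
                    warnings.warn("inner fold with a single training class skipped", stacklevel=2)
                    continue
                usable.append((tr, te))
            if not usable:
                raise ValidationError("all inner folds collapsed to a single class")
            for C, lam in grid:
                y_true, y_pred = [], []
                for tr, te in usable:
                    model = ElasticNetMKLSVC(C=C, lam=lam).fit(Ks[:, tr][:, :, tr], y[tr])
                    pred = model.predict(Ks[:, te, :][:, :, tr])
                    y_true.extend(y[te])
                    y_pred.extend(pred)
                y_true = np.asarray(y_true)
                y_pred = np.asarray(y_pred)
                sens = np.mean(y_pred[y_true == 1] == 1) if (y_true == 1).any() else np.nan
                spec = np.mean(y_pred[y_true == -1] == -1) if (y_true == -1).any() else np.nan
                scores[(C, lam)] = float(np.nanmean([sens, spec]))
            best_C, best_lam = max(grid, key=lambda p: (scores[p], p[1], -p[0]))
        self.best_C_ = best_C
        self.best_lambda_ = best_lam
        self.inner_scores_ = scores
        self.best_estimator_ = ElasticNetMKLSVC(C=best_C, lam=best_lam).fit(
            Ks, y, kernel_sources=kernel_sources
        )
        self.betas_ = self.best_estimator_.betas_
        self.classes_ = np.array([-1, 1])
        return self

    def decision_function(self, Ks_cross):
        return self.best_estimator_.decision_function(Ks_cross)

    def predict(self, Ks_cross):
        return self.best_estimator_.predict(Ks_cross)


def tune_mkl(kernels, labels, C_grid=C_GRID_DEFAULT, lambda_grid=LAMBDA_GRID_DEFAULT, inner_cv="loo"):
    """Grid-search (C, lambda) by inner CV; returns the selected pair."""
    search = MKLGridSearchCV(C_grid=C_grid, lam_grid=lambda_grid, inner_cv=inner_cv)
    search.fit(_stack_kernels(list(kernels)), np.asarray(labels, dtype=int))
    return search.best_C_, search.best_lambda_


# ---------------------------------------------------------------------------
# Prediction-level fusion: AV and MV
# ---------------------------------------------------------------------------


def predict_av(decision_value_vectors, sources=()) -> FusionPrediction:
    """Prediction averaging: sign of the per-subject mean decision value."""
    vecs = [np.asarray(v, dtype=float) for v in decision_value_vectors]
    if not vecs:
        raise ValidationError("need at least one decision-value vector")
    n = len(vecs[0])
    for v in vecs:
        if len(v) != n:
            raise ValidationError("decision-value vectors have mismatched lengths")
    mean = np.mean(vecs, axis=0)
    return FusionPrediction("AV", predict_labels(mean), mean, tuple(sources))


def predict_mv(label_vectors, tie_break: str = "av-sign", decision_values=None, sources=()) -> FusionPrediction:
    """Majority voting over base-classifier labels.

    Ties (zero vote sum, possible for even numbers of voters) are broken
    by the a-priori ``tie_break`` rule: ``"av-sign"`` falls back to the
    sign of the summed decision values (which must then be supplied),
    ``"fixed-negative"`` / ``"fixed-positive"`` assign a fixed class.
    """
    if tie_break not in TIE_RULES:
        raise ConfigurationError(f"unknown tie_break rule '{tie_break}'; options: {TIE_RULES}")
    labs = [np.asarray(v, dtype=int) for v in label_vectors]
    if not labs:
        raise ValidationError("need at least one label vector")
    n = len(labs[0])
    for v in labs:
        if len(v) != n:
            raise ValidationError("label vectors have mismatched lengths")
        if not np.isin(v, (-1, 1)).all():
            raise ValidationError("base labels must take values in {-1, +1}")
    votes = np.sum(labs, axis=0)
    ties = votes == 0
    out = predict_labels(np.sign(votes))
    if ties.any():
        if tie_break == "av-sign":
            if decision_values is None:
                raise ConfigurationError("tie_break='av-sign' requires decision values for tie-breaking")
            mean = np.mean([np.asarray(v, dtype=float) for v in decision_values], axis=0)
            out[ties] = predict_labels(mean[ties])
        elif tie_break == "fixed-negative":
            out[ties] = -1
        else:
            out[ties] = 1
    return FusionPrediction("MV", out, None, tuple(sources), tie_events=int(ties.sum()))


class _BaseEnsembleSVC(BaseEstimator, ClassifierMixin):
    """Shared machinery: one KernelSVC per base kernel."""

    def fit(self, Ks, y):
        Ks = _stack_kernels(Ks)
        self.base_estimators_ = [KernelSVC(C=self.C).fit(K, y) for K in Ks]
        self.n_kernels_ = Ks.shape[0]
        self.classes_ = np.array([-1, 1])
        return self

    def base_decision_values(self, Ks_cross) -> np.ndarray:
        Ks_cross = _stack_kernels(Ks_cross, square=False)
        if Ks_cross.shape[0] != self.n_kernels_:
            raise ValidationError(
                f"{Ks_cross.shape[0]} cross kernels for {self.n_kernels_} base classifiers"
            )
        return np.stack(
            [est.decision_function(K) for est, K in zip(self.base_estimators_, Ks_cross)]
        )


class AveragingFusionSVC(_BaseEnsembleSVC):
    """Prediction-averaging ensemble: mean base decision value, then sign."""

    kind = "av"

    def __init__(self, C: float = 1.0):
        self.C = C

    def decision_function(self, Ks_cross) -> np.ndarray:
        return self.base_decision_values(Ks_cross).mean(axis=0)

    def predict(self, Ks_cross) -> np.ndarray:
        return predict_labels(self.decision_function(Ks_cross))


class MajorityVotingSVC(_BaseEnsembleSVC):
    """Majority-voting ensemble over base-classifier predicted labels.

    Exposes no decision_function: voting discards decision magnitudes.
    ``tie_events_`` records the number of broken ties in the last
    :meth:`predict` call.
    """

    kind = "mv"

    def __init__(self, C: float = 1.0, tie_break: str = "av-sign"):
        self.C = C
        self.tie_break = tie_break

    def predict(self, Ks_cross) -> np.ndarray:
        values = self.base_decision_values(Ks_cross)
        result = predict_mv(
            [predict_labels(v) for v in values],
            tie_break=self.tie_break,
            decision_values=values,
        )
        self.tie_events_ = result.tie_events
        return result.labels
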