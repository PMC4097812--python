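"""Soft-margin binary SVM on a precomputed kernel matrix.

The classifier is trained in the dual::

    maximize    sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K_ij
    subject to  0 <= alpha_i <= C,   sum_i y_i alpha_i = 0

solved by sequential minimal optimization with first-order (maximal
violating pair) working-set selection.  The decision function for a test
subject with cross-kernel row ``k`` is ``f = sum_i alpha_i y_i k_i + b``;
the predicted label is its sign, with ``sign(0) = +1`` by convention
(applied consistently everywhere a sign is taken in this package).

The bias ``b`` is the mean of ``y_i - sum_j alpha_j y_j K_ij`` over margin
support vectors (``tol < alpha_i < C - tol``); when none exist it falls
back to the midpoint of the interval allowed by the box-bound KKT
conditions.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ConvergenceError, ValidationError
from .kernels import KernelMatrix

#: alphas above ``SUPPORT_TOL_FACTOR * C`` count as support vectors
SUPPORT_TOL_FACTOR = 1e-8


def predict_labels(decision_values) -> np.ndarray:
    """Map decision values to labels in {-1, +1}; ``sign(0) = +1``."""
    v = np.asarray(decision_values, dtype=float)
    return np.where(v >= 0.0, 1, -1).astype(int)


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValidationError(f"labels must be 1-d, got shape {y.shape}")
    y = y.astype(int)
    if not np.isin(y, (-1, 1)).all():
        raise ValidationError("labels must take values in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class; need both -1 and +1")
    return y


def _solve_dual(K, y, C, tol=1e-10, max_iter=500_000, alpha0=None):
    """SMO solve of the dual; returns ``(alpha, bias, info)``.

    ``alpha0`` optionally warm-starts the solver (used by the MKL
    alternating optimizer); it is clipped to the box and repaired to
    satisfy the equality constraint before iterating.
    """
    m = len(y)
    yf = y.astype(float)
    eps = 1e-12 * max(C, 1.0)

    if alpha0 is None:
        alpha = np.zeros(m)
        G = -np.ones(m)  # gradient of 1/2 a'Qa - e'a at a = 0
    else:
        alpha = np.clip(np.asarray(alpha0, dtype=float), 0.0, C)
        v = float(yf @ alpha)
        for i in range(m):  # repair equality-constraint drift coordinate-wise
            if v == 0.0:
                break
            step = np.clip(alpha[i] - yf[i] * v, 0.0, C) - alpha[i]
            alpha[i] += step
            v += yf[i] * step
        if abs(v) > 1e-9 * max(C, 1.0):
            alpha = np.zeros(m)
        G = yf * (K @ (alpha * yf)) - 1.0

    Kd = np.ascontiguousarray(np.diag(K))
    n_iter = 0
    gap = np.inf
    while n_iter < max_iter:
        crit = -yf * G  # = y_i - sum_j alpha_j y_j K_ij at the current point
        up = ((yf > 0) & (alpha < C - eps)) | ((yf < 0) & (alpha > eps))
        low = ((yf < 0) & (alpha < C - eps)) | ((yf > 0) & (alpha > eps))
        if not up.any() or not low.any():
            gap = 0.0
            break
        ci = np.where(up, crit, -np.inf)
        cj = np.where(low, crit, np.inf)
        i = int(np.argmax(ci))
        j = int(np.argmin(cj))
        gap = ci[i] - cj[j]
        if gap < tol:
            break
        a = Kd[i] + Kd[j] - 2.0 * K[i, j]
        t = gap / max(a, 1e-12)
        t_i = (C - alpha[i]) if yf[i] > 0 else alpha[i]
        t_j = alpha[j] if yf[j] > 0 else (C - alpha[j])
        t = min(t, t_i, t_j)
        if t <= 0.0:
            break
        alpha[i] += yf[i] * t
        alpha[j] -= yf[j] * t
        G += t * yf * (K[:, i] - K[:, j])
        n_iter += 1

    if n_iter >= max_iter:
        raise ConvergenceError(
            f"SMO did not converge in {max_iter} iterations (KKT gap {gap:.3e}, "
            f"m={m}, C={C})"
        )

    # bias: margin support vectors first, KKT midpoint as fallback
    s = K @ (alpha * yf)  # decision values without bias
    sv_tol = SUPPORT_TOL_FACTOR * C
    free = (alpha > sv_tol) & (alpha < C - sv_tol)
    resid = yf - s
    if free.any():
        bias = float(resid[free].mean())
    else:
        up = ((yf > 0) & (alpha < C - eps)) | ((yf < 0) & (alpha > eps))
        low = ((yf < 0) & (alpha < C - eps)) | ((yf > 0) & (alpha > eps))
        hi = resid[up].max() if up.any() else 0.0
        lo = resid[low].min() if low.any() else 0.0
        bias = float((hi + lo) / 2.0)

    objective = float(alpha.sum() - 0.5 * (alpha * yf) @ s)
    info = {"n_iter": n_iter, "kkt_gap": float(gap), "objective": objective}
    return alpha, bias, info


class KernelSVC(BaseEstimator, ClassifierMixin):
    """Binary SVM classifier on a precomputed (linear) kernel.

    Parameters
    ----------
    C : float, default 1.0
        Soft-margin regularization parameter.  The default of 1 is the
        conventional fixed choice for small-sample neuroimaging kernels.
    tol : float, default 1e-10
        KKT-gap stopping tolerance of the SMO solver.
    max_iter : int, default 500_000
        Iteration budget; exceeding it raises :class:`ConvergenceError`.

    Attributes (after :meth:`fit`)
    ------------------------------
    alpha_ : (m,) ndarray of dual weights in ``[0, C]``.
    dual_coef_ : (m,) ndarray, ``alpha_ * y``.
    intercept_ : float bias ``b``.
    support_ : indices with ``alpha_ > 1e-8 * C``.
    dual_objective_ : value of the dual objective at the solution.
    """

    kind = "single-kernel"

    def __init__(self, C: float = 1.0, tol: float = 1e-10, max_iter: int = 500_000):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting -----------------------------------------------------------
    def fit(self, K, y, warm_alpha=None):
        if self.C <= 0:
            raise ValidationError(f"C must be positive, got {self.C}")
        if isinstance(K, KernelMatrix):
            self.train_subject_ids_ = K.subject_ids
            K = K.values
        else:
            self.train_subject_ids_ = None
            K = np.asarray(K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValidationError(f"training kernel must be square, got shape {K.shape}")
        if not np.isfinite(K).all():
            raise ValidationError("training kernel contains non-finite entries")
        y = _check_labels(y)
        if len(y) != K.shape[0]:
            raise ValidationError(f"{len(y)} labels for a {K.shape[0]}-subject kernel")

        alpha, bias, info = _solve_dual(K, y, self.C, self.tol, self.max_iter, alpha0=warm_alpha)
        self.y_ = y
        self.alpha_ = alpha
        self.dual_coef_ = alpha * y
        self.intercept_ = bias
        self.support_ = np.flatnonzero(alpha > SUPPORT_TOL_FACTOR * self.C)
        self.dual_objective_ = info["objective"]
        self.n_iter_ = info["n_iter"]
        self.kkt_gap_ = info["kkt_gap"]
        self.classes_ = np.array([-1, 1])
        return self

    # -- prediction --------------------------------------------------------
    def _check_cross(self, K_cross) -> np.ndarray:
        if isinstance(K_cross, KernelMatrix):
            K_cross = K_cross.values
        K_cross = np.asarray(K_cross, dtype=float)
        if K_cross.ndim == 1:
            K_cross = K_cross[None, :]
        m = len(self.alpha_)
        if K_cross.ndim != 2 or K_cross.shape[1] != m:
            raise ValidationError(
                f"cross kernel has {K_cross.shape[-1] if K_cross.ndim else 0} columns; "
                f"model was trained on {m} subjects"
            )
        return K_cross

    def decision_function(self, K_cross) -> np.ndarray:
        """``f_t = sum_i alpha_i y_i K_cross[t, i] + b`` per test subject."""
        K_cross = self._check_cross(K_cross)
        return K_cross @ self.dual_coef_ + self.intercept_

    def predict(self, K_cross) -> np.ndarray:
        return predict_labels(self.decision_function(K_cross))

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        state = {
            "kind": self.kind,
            "C": self.C,
            "alphas": self.alpha_.tolist(),
            "labels": self.y_.tolist(),
            "bias": self.intercept_,
            "subject_ids": list(self.train_subject_ids_) if self.train_subject_ids_ else None,
        }
        return json.dumps(state, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "KernelSVC":
        state = json.loads(text)
        model = cls(C=state["C"])
        model.y_ = np.asarray(state["labels"], dtype=int)
        model.alpha_ = np.asarray(state["alphas"], dtype=float)
        model.dual_coef_ = model.alpha_ * model.y_
        model.intercept_ = float(state["bias"])
        model.support_ = np.flatnonzero(model.alpha_ > SUPPORT_TOL_FACTOR * model.C)
        model.train_subject_ids_ = tuple(state["subject_ids"]) if state.get("subject_ids") else None
        model.classes_ = np.array([-1, 1])
        return model


def train_svm(K, labels, C: float = 1.0, **kwargs) -> KernelSVC:
    """Train a :class:`KernelSVC` on a precomputed kernel (default C = 1)."""
    return KernelSVC(C=C, **kwargs).fit(K, labels)


def decision_values(model: KernelSVC, K_cross, train_subject_ids=None) -> np.ndarray:
    """Decision values for a test x train cross-kernel block.

    If ``train_subject_ids`` is given (or the cross block is a
    :class:`KernelMatrix`), the column ordering is checked against the
    subjects the model was trained on.
    """
    ids = train_subject_ids
    if ids is not None and model.train_subject_ids_ is not None:
        if tuple(ids) != tuple(model.train_subject_ids_):
            raise ValidationError("cross-kernel columns are not aligned with the training subjects")
    return model.decision_function(K_cross)
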