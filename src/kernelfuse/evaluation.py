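"""Evaluation machinery: LOOCV, accuracy metrics, permutation significance,
Holm-Bonferroni correction, and McNemar paired-classifier comparisons.

Accuracy is the proportion of correct out-of-fold predictions; balanced
accuracy is the mean of sensitivity and specificity (positive class = +1)
and coincides with plain accuracy for equal group sizes.  Permutation
tests rebuild the full leave-one-out cycle under randomly permuted labels
to form a null distribution of accuracies; the p-value is the fraction of
permuted accuracies at least as large as the true one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .fusion import _stack_kernels
from .svm import KernelSVC

#: discordant-pair count at which McNemar switches from the exact binomial
#: to the continuity-corrected chi-square approximation
MCNEMAR_EXACT_THRESHOLD = 25


# ---------------------------------------------------------------------------
# Cross-validated results and metrics
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Per-subject out-of-fold predictions with summary metrics.

    ``decision_values`` is None for majority voting (no real-valued
    output).  For equal class sizes ``accuracy == balanced_accuracy``
    exactly; this identity is asserted on construction.
    """

    subject_ids: tuple
    y_true: np.ndarray
    y_pred: np.ndarray
    decision_values: np.ndarray | None = None
    method: str = ""
    sources: tuple = ()
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    balanced_accuracy: float = field(init=False)

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true, dtype=int)
        self.y_pred = np.asarray(self.y_pred, dtype=int)
        if self.y_true.shape != self.y_pred.shape:
            raise ValidationError("y_true and y_pred have different lengths")
        n = len(self.y_true)
        if n == 0:
            raise ValidationError("empty result")
        correct = self.y_true == self.y_pred
        self.accuracy = float(correct.sum() / n)
        pos = self.y_true == 1
        neg = ~pos
        self.sensitivity = float(correct[pos].mean()) if pos.any() else float("nan")
        self.specificity = float(correct[neg].mean()) if neg.any() else float("nan")
        self.balanced_accuracy = balanced_accuracy(self.sensitivity, self.specificity)
        if pos.sum() == neg.sum():
            assert abs(self.accuracy - self.balanced_accuracy) < 1e-12, (
                "accuracy and balanced accuracy must coincide for equal groups"
            )

    @property
    def correct(self) -> np.ndarray:
        return self.y_true == self.y_pred

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": list(self.subject_ids),
                "y_true": self.y_true,
                "y_pred": self.y_pred,
                "decision_value": (
                    self.decision_values if self.decision_values is not None else np.nan
                ),
            }
        )
        df["method"] = self.method
        df["sources"] = "+".join(map(str, self.sources))
        return df


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


def loocv(estimator, kernels, labels, subject_ids=None, method: str = "", sources=()) -> CVResult:
    """Leave-one-out cross-validation on precomputed kernels.

    Each subject in turn is held out; a clone of ``estimator`` is fitted
    on the remaining rows/columns of the (stacked) kernels and scores the
    held-out subject from the corresponding cross-kernel row.  For linear
    kernels, slicing the full-data kernel is identical to recomputing the
    kernel on the fold.

    ``estimator`` is an unfitted classifier taking stacked kernels
    (q, m, m) -- or a plain (m, m) kernel for :class:`KernelSVC`.
    """
    Ks = _stack_kernels(kernels)
    y = np.asarray(labels, dtype=int)
    m = len(y)
    if Ks.shape[1] != m:
        raise ValidationError(f"{m} labels for kernels of {Ks.shape[1]} subjects")
    if m < 3:
        raise ValidationError("need at least 3 subjects for leave-one-out")
    if subject_ids is None:
        subject_ids = tuple(f"s{i:03d}" for i in range(m))
    single = isinstance(estimator, KernelSVC)
    if single and Ks.shape[0] != 1:
        raise ValidationError("KernelSVC expects exactly one kernel")

    preds = np.empty(m, dtype=int)
    decs = np.empty(m, dtype=float)
    has_decision = hasattr(estimator, "decision_function")
    for i in range(m):
        tr = np.ones(m, dtype=bool)
        tr[i] = False
        y_tr = y[tr]
        if len(np.unique(y_tr)) < 2:
            raise ValidationError(
                f"training fold without subject '{subject_ids[i]}' contains a single class"
            )
        K_tr = Ks[:, tr][:, :, tr]
        K_te = Ks[:, i : i + 1, :][:, :, tr]
        model = clone(estimator)
        if single:
            model.fit(K_tr[0], y_tr)
            K_te_in = K_te[0]
        else:
            model.fit(K_tr, y_tr)
            K_te_in = K_te
        if has_decision:
            decs[i] = model.decision_function(K_te_in)[0]
            preds[i] = 1 if decs[i] >= 0 else -1
        else:
            preds[i] = model.predict(K_te_in)[0]
    return CVResult(
        tuple(subject_ids),
        y,
        preds,
        decs if has_decision else None,
        method=method,
        sources=tuple(sources),
    )


def loocv_dataset(estimator, dataset, kernel_names=None, normalize: bool = True, method: str = "") -> CVResult:
    """LOOCV convenience wrapper building kernels from a MultimodalDataset."""
    names = tuple(kernel_names) if kernel_names is not None else dataset.modality_names
    mats = [dataset.kernel(n, normalize=normalize).values for n in names]
    return loocv(
        estimator,
        np.stack(mats),
        dataset.labels,
        subject_ids=dataset.subject_ids,
        method=method,
        sources=names,
    )


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    true_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def permutation_test(
    estimator,
    kernels,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "permute",
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation null distribution of the LOOCV accuracy.

    Labels are shuffled per replicate -- by default a count-preserving
    permutation of the label vector (``scheme="permute"``); independent
    uniform reassignment (``scheme="independent"``) is available, redrawn
    if it produces a single class.  Replicate r uses the deterministic
    seed ``seed + r``, so runs are bitwise reproducible.  The p-value is
    ``#(null >= true) / n_perm``; ``plus_one`` switches to the
    ``(count + 1) / (n_perm + 1)`` variant.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if scheme not in ("permute", "independent"):
        raise ValidationError(f"unknown permutation scheme '{scheme}'")
    Ks = _stack_kernels(kernels)
    y = np.asarray(labels, dtype=int)
    true_acc = loocv(estimator, Ks, y).accuracy
    null = np.empty(n_perm)
    for r in range(n_perm):
        rng = np.random.default_rng(seed + r)
        if scheme == "permute":
            y_perm = rng.permutation(y)
        else:
            while True:
                y_perm = rng.choice((-1, 1), size=len(y))
                if len(np.unique(y_perm)) == 2:
                    break
        null[r] = loocv(estimator, Ks, y_perm).accuracy
    count = int(np.sum(null >= true_acc - 1e-12))
    p = (count + 1) / (n_perm + 1) if plus_one else count / n_perm
    return PermutationResult(true_acc, null, float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# Multiple-comparison correction and paired tests
# ---------------------------------------------------------------------------


def holm_bonferroni(p_values, alpha: float = 0.05):
    """Holm-Bonferroni step-down correction.

    Returns ``(reject, adjusted)``: boolean rejection flags at level
    ``alpha`` and monotone adjusted p-values capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, adjusted


@dataclass
class McNemarResult:
    statistic: float
    p_value: float
    b: int  #: a correct, b wrong
    c: int  #: a wrong, b correct
    method: str  #: 'exact', 'chi2', or 'none'
    note: str = ""


def mcnemar(preds_a, preds_b, truth) -> McNemarResult:
    """McNemar's test on the discordant correct/incorrect pairs.

    ``b`` counts subjects classifier *a* gets right and *b* wrong, ``c``
    the reverse.  For ``b + c < 25`` an exact two-sided binomial p-value
    is used, otherwise the chi-square approximation with continuity
    correction.  ``b = c = 0`` (no discordant pairs) yields p = 1 by
    convention, flagged in ``note``.
    """
    a = np.asarray(preds_a, dtype=int)
    bb = np.asarray(preds_b, dtype=int)
    t = np.asarray(truth, dtype=int)
    if not (a.shape == bb.shape == t.shape):
        raise ValidationError("prediction and truth vectors have mismatched lengths")
    a_ok = a == t
    b_ok = bb == t
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    n = b + c
    if n == 0:
        return McNemarResult(0.0, 1.0, b, c, "none", note="no discordant pairs")
    if n < MCNEMAR_EXACT_THRESHOLD:
        k = min(b, c)
        p = min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5))
        return McNemarResult(float(k), float(p), b, c, "exact")
    stat = (abs(b - c) - 1.0) ** 2 / n
    p = float(stats.chi2.sf(stat, df=1))
    return McNemarResult(float(stat), min(1.0, p), b, c, "chi2")


def pooled_mcnemar(results_by_context) -> McNemarResult:
    """McNemar on correctness indicators concatenated across contexts.

    Each context is a ``(preds_a, preds_b, truth)`` triple; discordant
    counts add across contexts.
    """
    contexts = list(results_by_context)
    if not contexts:
        raise ValidationError("pooled_mcnemar needs at least one context")
    a = np.concatenate([np.asarray(x[0], dtype=int) for x in contexts])
    b = np.concatenate([np.asarray(x[1], dtype=int) for x in contexts])
    t = np.concatenate([np.asarray(x[2], dtype=int) for x in contexts])
    return mcnemar(a, b, t)


# ---------------------------------------------------------------------------
# Best single-modality classification accuracy
# ---------------------------------------------------------------------------


@dataclass
class BSMCAResult:
    kernel: str
    accuracy: float
    tied: bool = False


def compute_bsmca(single_kernel_results: dict, combination) -> BSMCAResult:
    """Best single-modality classification accuracy within a combination.

    ``single_kernel_results`` maps kernel name to its single-kernel
    :class:`CVResult`.  Ties are broken by first appearance in the
    combination's (canonical) order and flagged.
    """
    combination = tuple(combination)
    if not combination:
        raise ValidationError("empty kernel combination")
    missing = [k for k in combination if k not in single_kernel_results]
    if missing:
        raise ValidationError(f"no single-kernel result for {missing}")
    accs = [single_kernel_results[k].accuracy for k in combination]
    best = int(np.argmax(accs))  # argmax keeps the first of tied maxima
    tied = sum(a == accs[best] for a in accs) > 1
    return BSMCAResult(combination[best], accs[best], tied)
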