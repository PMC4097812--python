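"""Config-driven comparison of fusion methods against single-modality baselines.

:func:`run_comparison` reproduces the full experimental design on one
dataset: single-kernel LOOCV baselines, every kernel subset of each
requested size under each applicable fusion method, the delta of each
integrated accuracy against the best single-modality classification
accuracy (BSMCA) among its constituent kernels, optional permutation
p-values, per-row McNemar tests against the BSMCA classifier with
Holm-Bonferroni adjustment, and pairwise method-vs-method McNemar tests
pooled across the subsets of each size.

Prediction-level methods (AV, MV) are derived from the stored per-fold
single-kernel decision values -- in leave-one-out, the ensemble's base
classifiers for fold i are exactly the single-kernel fold-i classifiers,
so no refitting is needed.  Majority voting is skipped for even-size
subsets unless a tie rule is configured explicitly, since ties would then
be decided by the heuristic rather than the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .evaluation import (
    CVResult,
    compute_bsmca,
    holm_bonferroni,
    loocv,
    mcnemar,
    permutation_test,
    pooled_mcnemar,
)
from .fusion import (
    AveragingFusionSVC,
    ElasticNetMKLSVC,
    MajorityVotingSVC,
    MKLGridSearchCV,
    SumKernelSVC,
    predict_av,
    predict_mv,
)
from .kernels import MultimodalDataset
from .svm import KernelSVC, predict_labels

logger = logging.getLogger(__name__)

METHODS = ("sk", "mkl", "av", "mv")


@dataclass
class ComparisonTable:
    """Method x kernel-combination grid of integrated accuracies.

    ``rows`` has one line per (combination, method); ``baselines`` one per
    kernel; ``method_mcnemar`` maps combination size to a p-value matrix
    of pairwise pooled McNemar tests between methods.
    """

    rows: pd.DataFrame
    baselines: pd.DataFrame
    method_mcnemar: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)  #: (combo, method) -> CVResult
    baseline_results: dict = field(default_factory=dict)  #: kernel -> CVResult
    contrast: str = "groupA-vs-groupB"
    seed: int = 0


def _method_estimator(method, C, mkl_lambda, mkl_tune, C_grid, lambda_grid, inner_cv, tie_break):
    if method == "sk":
        # kernels are pre-normalized once at the pipeline level
        return SumKernelSVC(C=C, normalize=False)
    if method == "mkl":
        if mkl_tune:
            kw = {}
            if C_grid is not None:
                kw["C_grid"] = tuple(C_grid)
            if lambda_grid is not None:
                kw["lam_grid"] = tuple(lambda_grid)
            return MKLGridSearchCV(inner_cv=inner_cv, **kw)
        return ElasticNetMKLSVC(C=C, lam=mkl_lambda)
    if method == "av":
        return AveragingFusionSVC(C=C)
    if method == "mv":
        return MajorityVotingSVC(C=C, tie_break=tie_break or "av-sign")
    raise ConfigurationError(f"unknown method '{method}'; options: {METHODS}")


def run_comparison(
    dataset: MultimodalDataset,
    methods=METHODS,
    combination_sizes=(2, 3),
    kernel_names=None,
    C: float = 1.0,
    mkl_lambda: float = 0.5,
    mkl_tune: bool = False,
    C_grid=None,
    lambda_grid=None,
    inner_cv=5,
    n_perm: int = 0,
    seed: int = 0,
    tie_break: str | None = None,
    alpha: float = 0.05,
    contrast: str = "groupA-vs-groupB",
) -> ComparisonTable:
    """Full baseline + fusion sweep on one dataset; see module docstring."""
    methods = tuple(m.lower() for m in methods)
    for m in methods:
        if m not in METHODS:
            raise ConfigurationError(f"unknown method '{m}'; options: {METHODS}")
    names = tuple(kernel_names) if kernel_names is not None else dataset.modality_names
    if len(names) < 2:
        raise ValidationError("need at least 2 kernels for a comparison sweep")
    y = dataset.labels
    ids = dataset.subject_ids

    # normalized full-data kernels, canonical (config) order
    kernels = {n: dataset.kernel(n, normalize=True).values for n in names}

    # single-kernel baselines, computed once
    logger.info("computing %d single-kernel baselines", len(names))
    base_results: dict[str, CVResult] = {}
    for n in names:
        base_results[n] = loocv(
            KernelSVC(C=C), kernels[n][None], y, subject_ids=ids, method="single", sources=(n,)
        )
    baselines = pd.DataFrame(
        {
            "kernel": list(names),
            "accuracy": [base_results[n].accuracy for n in names],
            "sensitivity": [base_results[n].sensitivity for n in names],
            "specificity": [base_results[n].specificity for n in names],
            "balanced_accuracy": [base_results[n].balanced_accuracy for n in names],
        }
    )
    base_decisions = np.stack([base_results[n].decision_values for n in names])  # (q, m)

    rows = []
    results: dict[tuple, CVResult] = {}
    for size in sorted(set(int(s) for s in combination_sizes)):
        if not 2 <= size <= len(names):
            raise ValidationError(f"combination size {size} out of range for {len(names)} kernels")
        for combo in combinations(names, size):
            Ks = np.stack([kernels[n] for n in combo])
            sel = np.array([names.index(n) for n in combo])
            for method in methods:
                if method == "mv" and size % 2 == 0 and tie_break is None:
                    logger.warning(
                        "skipping MV for even-size combination %s (no tie rule configured)",
                        "+".join(combo),
                    )
                    continue
                if method in ("av", "mv"):
                    res = _label_fusion_from_baselines(
                        method, base_decisions[sel], y, ids, combo, tie_break
                    )
                else:
                    est = _method_estimator(
                        method, C, mkl_lambda, mkl_tune, C_grid, lambda_grid, inner_cv, tie_break
                    )
                    res = loocv(est, Ks, y, subject_ids=ids, method=method, sources=combo)
                results[(combo, method)] = res
                bsmca = compute_bsmca(base_results, combo)
                row = {
                    "contrast": contrast,
                    "combination": "+".join(combo),
                    "size": size,
                    "method": method,
                    "accuracy": res.accuracy,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "balanced_accuracy": res.balanced_accuracy,
                    "bsmca": bsmca.accuracy,
                    "bsmca_kernel": bsmca.kernel,
                    "bsmca_tied": bsmca.tied,
                    "delta": res.accuracy - bsmca.accuracy,
                }
                mc = mcnemar(res.y_pred, base_results[bsmca.kernel].y_pred, y)
                row["mcnemar_vs_bsmca_p"] = mc.p_value
                row["mcnemar_b"] = mc.b
                row["mcnemar_c"] = mc.c
                if n_perm > 0:
                    if method in ("av", "mv"):
                        est = _method_estimator(
                            method, C, mkl_lambda, mkl_tune, C_grid, lambda_grid, inner_cv, tie_break
                        )
                    perm = permutation_test(est, Ks, y, n_perm=n_perm, seed=seed)
                    row["perm_p"] = perm.p_value
                rows.append(row)
    rows = pd.DataFrame(rows)
    if len(rows):
        reject, adjusted = holm_bonferroni(rows["mcnemar_vs_bsmca_p"].to_numpy(), alpha=alpha)
        rows["mcnemar_vs_bsmca_p_holm"] = adjusted
        rows["mcnemar_vs_bsmca_reject"] = reject

    # pairwise method-vs-method pooled McNemar per combination size
    method_mcnemar: dict[int, pd.DataFrame] = {}
    for size in sorted(set(rows["size"])) if len(rows) else []:
        present = [m for m in methods if ((rows["size"] == size) & (rows["method"] == m)).any()]
        mat = pd.DataFrame(np.nan, index=present, columns=present)
        for a in present:
            for b in present:
                if a == b:
                    mat.loc[a, b] = 1.0
                    continue
                contexts = []
                for combo in combinations(names, size):
                    ra, rb = results.get((combo, a)), results.get((combo, b))
                    if ra is not None and rb is not None:
                        contexts.append((ra.y_pred, rb.y_pred, y))
                if contexts:
                    mat.loc[a, b] = pooled_mcnemar(contexts).p_value
        method_mcnemar[int(size)] = mat

    return ComparisonTable(
        rows=rows,
        baselines=baselines,
        method_mcnemar=method_mcnemar,
        results=results,
        baseline_results=base_results,
        contrast=contrast,
        seed=seed,
    )


def _label_fusion_from_baselines(method, decisions, y, ids, combo, tie_break) -> CVResult:
    """AV/MV out-of-fold predictions from stored single-kernel decisions."""
    if method == "av":
        fused = predict_av(list(decisions), sources=combo)
        return CVResult(ids, y, fused.labels, fused.decision_values, method="av", sources=combo)
    fused = predict_mv(
        [predict_labels(v) for v in decisions],
        tie_break=tie_break or "av-sign",
        decision_values=list(decisions),
        sources=combo,
    )
    return CVResult(ids, y, fused.labels, None, method="mv", sources=combo)


def report(table: ComparisonTable, out_dir, make_plots: bool = True) -> list:
    """Write the comparison table, McNemar matrices and delta bar charts.

    File names are deterministic; every CSV starts with a header comment
    recording the master seed (read them back with ``comment='#'``).
    Reruns on identical inputs produce byte-identical CSVs.
    """
    from pathlib import Path

    if table.rows is None or not len(table.rows):
        raise ValidationError("comparison table is empty; nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _write_csv(df: pd.DataFrame, path, index=False):
        with open(path, "w") as fh:
            fh.write(f"# seed={table.seed} contrast={table.contrast}\n")
            df.to_csv(fh, index=index)
        written.append(path)

    _write_csv(table.rows, out / "comparison.csv")
    _write_csv(table.baselines, out / "baselines.csv")
    for size, mat in table.method_mcnemar.items():
        _write_csv(mat, out / f"mcnemar_methods_{size}way.csv", index=True)

    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for size in sorted(set(table.rows["size"])):
            sub = table.rows[table.rows["size"] == size]
            combos = sorted(set(sub["combination"]))
            methods = [m for m in METHODS if (sub["method"] == m).any()]
            fig, ax = plt.subplots(figsize=(max(6, 1.8 * len(combos)), 4))
            width = 0.8 / max(len(methods), 1)
            xs = np.arange(len(combos))
            for k, m in enumerate(methods):
                deltas = [
                    100 * sub[(sub["combination"] == c) & (sub["method"] == m)]["delta"].squeeze()
                    if ((sub["combination"] == c) & (sub["method"] == m)).any()
                    else np.nan
                    for c in combos
                ]
                ax.bar(xs + k * width, deltas, width, label=m.upper())
            ax.axhline(0, color="k", lw=0.8)
            ax.set_xticks(xs + 0.4 - width / 2)
            ax.set_xticklabels(combos, rotation=30, ha="right", fontsize=8)
            ax.set_ylabel("integrated accuracy - BSMCA (points)")
            ax.set_title(f"{table.contrast}: {size}-way combinations")
            ax.legend()
            fig.tight_layout()
            path = out / f"delta_vs_bsmca_{size}way.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written
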