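"""Linear subject-similarity kernels over multimodal feature matrices.

Each imaging (or other) modality provides a subjects x features matrix.
A linear kernel ``K[i, j] = <x_i, x_j>`` represents the data for kernel
machines; kernels from different modalities are made commensurable by
*normalization* -- dividing ``K[i, j]`` by ``sqrt(K[i, i] * K[j, j])`` so
every subject has unit self-similarity, which is the same as rescaling
each subject's feature vector to unit Euclidean norm.  Normalized kernels
can then be summed to give a single kernel representing all modalities,
equal to the linear kernel of the unit-norm feature vectors concatenated
across modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ValidationError

#: default tolerance for symmetry checks (relative to the largest entry)
SYMMETRY_TOL = 1e-10
#: kernels are accepted as PSD when ``lambda_min >= -PSD_TOL * lambda_max``
PSD_TOL = 1e-8


def _check_features(X, name: str = "features") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"{name} must be a 2-d subjects x features matrix, got shape {X.shape}")
    finite_rows = np.isfinite(X).all(axis=1)
    if not finite_rows.all():
        bad = np.flatnonzero(~finite_rows)
        raise ValidationError(f"{name} contains non-finite values in row(s) {bad.tolist()}")
    return X


def _default_ids(m: int) -> tuple:
    return tuple(f"s{i:03d}" for i in range(m))


@dataclass
class KernelMatrix:
    """A symmetric positive-semidefinite subject-similarity matrix.

    Parameters
    ----------
    values : (m, m) ndarray
        Kernel entries.
    subject_ids : tuple of str
        Subject order shared by rows and columns.
    normalized : bool
        True when every diagonal entry is 1 (unit self-similarity).
    source : str
        Modality name or combination descriptor.
    """

    values: np.ndarray
    subject_ids: tuple = ()
    normalized: bool = False
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(f"kernel must be square, got shape {self.values.shape}")
        if not self.subject_ids:
            self.subject_ids = _default_ids(self.values.shape[0])
        self.subject_ids = tuple(self.subject_ids)
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.subject_ids)} subject ids for a {self.values.shape[0]}-subject kernel"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def validate(self, symmetry_tol: float = SYMMETRY_TOL, psd_tol: float = PSD_TOL) -> "KernelMatrix":
        """Check symmetry, PSD-ness and (if flagged) the unit diagonal.

        Raises :class:`ValidationError` on failure; returns ``self`` so the
        call can be chained.
        """
        K = self.values
        if not np.isfinite(K).all():
            raise ValidationError(f"kernel '{self.source}' contains non-finite entries")
        scale = max(np.abs(K).max(), 1.0) if K.size else 1.0
        if K.size and np.abs(K - K.T).max() > symmetry_tol * scale:
            raise ValidationError(f"kernel '{self.source}' is not symmetric within tolerance")
        if K.size:
            eig = np.linalg.eigvalsh((K + K.T) / 2.0)
            lo, hi = eig[0], max(eig[-1], 1.0)
            if lo < -psd_tol * hi:
                raise ValidationError(
                    f"kernel '{self.source}' is not positive semidefinite "
                    f"(lambda_min={lo:.3e}, lambda_max={eig[-1]:.3e})"
                )
        if self.normalized and K.size and np.abs(np.diag(K) - 1.0).max() > 1e-8:
            raise ValidationError(f"kernel '{self.source}' flagged normalized but diagonal is not 1")
        return self


@dataclass
class MultimodalDataset:
    """Labeled subjects with one feature matrix per named modality.

    ``labels`` take values in {-1, +1}.  All modality matrices share the
    same row order given by ``subject_ids``.  ``masks`` optionally records,
    per modality, the boolean feature mask applied at load time (e.g. a
    flattened brain mask for voxel features).
    """

    subject_ids: tuple
    labels: np.ndarray
    modalities: dict  # name -> (m, p_k) ndarray, insertion order is canonical
    masks: dict | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.subject_ids = tuple(self.subject_ids)
        m = len(self.subject_ids)
        if len(set(self.subject_ids)) != m:
            raise ValidationError("subject ids are not unique")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (m,):
            raise ValidationError(f"labels shape {self.labels.shape} does not match {m} subjects")
        if not np.isin(self.labels, (-1, 1)).all():
            raise ValidationError("labels must take values in {-1, +1}")
        if not self.modalities:
            raise ValidationError("dataset has no modalities")
        self.modalities = {
            name: _check_features(X, name=f"modality '{name}'") for name, X in self.modalities.items()
        }
        for name, X in self.modalities.items():
            if X.shape[0] != m:
                raise ValidationError(
                    f"modality '{name}' has {X.shape[0]} rows for {m} subjects"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def modality_names(self) -> tuple:
        return tuple(self.modalities)

    def kernel(self, name: str, normalize: bool = False) -> KernelMatrix:
        """Linear kernel of one modality, optionally normalized."""
        if name not in self.modalities:
            raise KeyError(f"unknown modality '{name}'; have {list(self.modalities)}")
        K = linear_kernel(self.modalities[name], subject_ids=self.subject_ids, source=name)
        return normalize_kernel(K) if normalize else K

    def kernels(self, names=None, normalize: bool = False) -> list:
        names = self.modality_names if names is None else tuple(names)
        return [self.kernel(n, normalize=normalize) for n in names]


def linear_kernel(
    features,
    subject_ids=None,
    source: str = "",
    center: bool = False,
    standardize: bool = False,
) -> KernelMatrix:
    """Linear (dot-product) kernel of a subjects x features matrix.

    Parameters
    ----------
    features : (m, p) array-like
        One row per subject.  Must be finite.
    center, standardize : bool
        Opt-in per-feature mean-centering / unit-variance scaling applied
        before taking dot products.  Both default to off: the only
        rescaling applied by default anywhere in this package is the
        per-subject kernel normalization.
    """
    X = _check_features(features)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if standardize:
        sd = X.std(axis=0, keepdims=True)  # std is centering-invariant
        sd[sd == 0.0] = 1.0
        X = X / sd
    K = X @ X.T
    K = (K + K.T) / 2.0  # exact symmetry despite float round-off
    if subject_ids is None:
        subject_ids = _default_ids(X.shape[0])
    return KernelMatrix(K, tuple(subject_ids), normalized=False, source=source)


def normalize_kernel(kernel) -> KernelMatrix:
    """Rescale a kernel to unit diagonal: ``K_ij / sqrt(K_ii * K_jj)``.

    Equivalent to dividing each subject's feature vector by its Euclidean
    norm before taking dot products.  Subjects with zero self-similarity
    (zero feature vectors) are a hard error -- the operation is undefined
    for them.
    """
    K = kernel if isinstance(kernel, KernelMatrix) else KernelMatrix(np.asarray(kernel, dtype=float))
    d = np.diag(K.values).copy()
    if K.values.size and d.min() <= 0.0:
        bad = [K.subject_ids[i] for i in np.flatnonzero(d <= 0.0)]
        raise ValidationError(
            f"kernel '{K.source}' has non-positive self-similarity for subject(s) {bad}; "
            "zero-norm feature vectors cannot be normalized"
        )
    inv = 1.0 / np.sqrt(d)
    V = K.values * np.outer(inv, inv)
    np.fill_diagonal(V, 1.0)
    return KernelMatrix(V, K.subject_ids, normalized=True, source=K.source)


def sum_normalized_kernels(kernels) -> KernelMatrix:
    """Un-weighted sum of the normalized input kernels.

    Every kernel is normalized first, so each modality contributes with
    equal weight; the result has diagonal entries equal to the number of
    kernels ``q`` and equals the linear kernel of the unit-norm feature
    vectors concatenated across modalities.
    """
    kernels = list(kernels)
    if not kernels:
        raise ValidationError("need at least one kernel to sum")
    normed = [normalize_kernel(K) for K in kernels]
    ids = normed[0].subject_ids
    for K in normed[1:]:
        if K.subject_ids != ids:
            raise AlignmentError(
                f"kernel '{K.source}' subject order differs from '{normed[0].source}'"
            )
    V = np.sum([K.values for K in normed], axis=0)
    source = "+".join(K.source or "?" for K in normed)
    return KernelMatrix(V, ids, normalized=False, source=source)


def normalize_cross(K_cross, diag_train, diag_test) -> np.ndarray:
    """Normalize a test x train kernel block given both sets of self-similarities.

    ``K_cross[t, i] / sqrt(diag_test[t] * diag_train[i])`` -- the cross-block
    counterpart of :func:`normalize_kernel`, for scoring subjects that were
    not part of the training kernel.
    """
    K_cross = np.asarray(K_cross, dtype=float)
    dtr = np.asarray(diag_train, dtype=float)
    dte = np.asarray(diag_test, dtype=float)
    if (dtr <= 0).any() or (dte <= 0).any():
        raise ValidationError("non-positive self-similarity; cannot normalize cross block")
    return K_cross / np.sqrt(np.outer(dte, dtr))
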