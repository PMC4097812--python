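"""Reading and writing the delimited-text formats used by the package.

A dataset directory holds one TSV per modality (first column subject ID,
remaining columns features), a two-column ``labels.tsv`` and a
``dataset.json`` recording the canonical modality order (and, for
synthetic data, the generating config).  Kernels persist as TSV plus a
JSON sidecar recording subject order, source and normalization state.
Subjects are aligned across files by explicit ID match, never by
position.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .kernels import KernelMatrix, MultimodalDataset

DATASET_META = "dataset.json"
LABELS_FILE = "labels.tsv"


def read_feature_table(path) -> tuple[tuple, np.ndarray]:
    """TSV with subject IDs in the first column; returns (ids, matrix)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return tuple(df.index.astype(str)), df.to_numpy(dtype=float)


def read_labels(path, label_map: dict | None = None) -> tuple[tuple, np.ndarray]:
    """Two-column TSV (subject ID, label); labels in {-1, +1} or mapped.

    ``label_map`` maps class names to -1/+1 when the file uses names.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    raw = df.iloc[:, 0]
    if label_map:
        unknown = set(raw.astype(str)) - set(map(str, label_map))
        if unknown:
            raise ValidationError(f"labels not covered by label_map: {sorted(unknown)}")
        values = raw.astype(str).map({str(k): v for k, v in label_map.items()}).to_numpy()
    else:
        values = raw.to_numpy()
    values = np.asarray(values, dtype=int)
    return tuple(df.index.astype(str)), values


def save_dataset(dataset: MultimodalDataset, out_dir) -> Path:
    """Write a dataset directory (per-modality TSV + labels + JSON echo)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = list(dataset.subject_ids)
    for name, X in dataset.modalities.items():
        df = pd.DataFrame(X, index=ids)
        df.columns = [f"f{j}" for j in range(X.shape[1])]
        df.index.name = "subject_id"
        df.to_csv(out / f"{name}.features.tsv", sep="\t")
    lab = pd.DataFrame({"label": dataset.labels}, index=ids)
    lab.index.name = "subject_id"
    lab.to_csv(out / LABELS_FILE, sep="\t")
    meta = {"modalities": list(dataset.modality_names), "config": dataset.config}
    (out / DATASET_META).write_text(json.dumps(meta, indent=2))
    return out


def load_dataset(data_dir) -> MultimodalDataset:
    """Load a dataset directory, aligning every modality to the label order."""
    data = Path(data_dir)
    meta_path = data / DATASET_META
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        names = meta["modalities"]
        config = meta.get("config", {})
    else:
        names = sorted(p.name[: -len(".features.tsv")] for p in data.glob("*.features.tsv"))
        config = {}
    if not names:
        raise ValidationError(f"no modalities found under {data}")
    ids, labels = read_labels(data / LABELS_FILE)
    modalities = {}
    for name in names:
        mids, X = read_feature_table(data / f"{name}.features.tsv")
        modalities[name] = _align(X, mids, ids, what=f"modality '{name}'")
    return MultimodalDataset(ids, labels, modalities, config=config)


def _align(X: np.ndarray, row_ids, target_ids, what: str) -> np.ndarray:
    index = {sid: i for i, sid in enumerate(row_ids)}
    missing = [sid for sid in target_ids if sid not in index]
    if missing:
        raise AlignmentError(f"{what} is missing subject(s) {missing}")
    return X[[index[sid] for sid in target_ids]]


def save_kernel(kernel: KernelMatrix, path) -> Path:
    """Kernel TSV + JSON sidecar (subject order, source, normalized flag)."""
    path = Path(path)
    ids = list(kernel.subject_ids)
    df = pd.DataFrame(kernel.values, index=ids, columns=ids)
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")
    sidecar = {
        "subject_ids": ids,
        "source": kernel.source,
        "normalized": kernel.normalized,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_kernel(path) -> KernelMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        ids = tuple(sidecar["subject_ids"])
        if tuple(df.index.astype(str)) != ids:
            raise AlignmentError(f"kernel rows of {path} disagree with sidecar subject order")
        return KernelMatrix(
            df.to_numpy(dtype=float), ids, normalized=sidecar["normalized"], source=sidecar["source"]
        )
    return KernelMatrix(df.to_numpy(dtype=float), tuple(df.index.astype(str)))


def load_nifti_modality(image_paths, mask_path, name: str = "nifti") -> tuple[tuple, np.ndarray]:
    """Flatten NIfTI volumes inside a binary mask into voxel feature rows.

    One image per subject; voxels where the mask is nonzero, in C
    (row-major) flattening order, become the feature vector.  Returns
    (subject ids derived from file stems, features matrix).
    """
    import nibabel as nib  # heavyweight import kept local

    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    rows, ids = [], []
    for p in image_paths:
        p = Path(p)
        vol = np.asanyarray(nib.load(str(p)).dataobj, dtype=float)
        if vol.shape != mask.shape:
            raise ValidationError(f"{p.name}: image shape {vol.shape} != mask shape {mask.shape}")
        rows.append(vol[mask])  # boolean indexing flattens in C order
        ids.append(p.name.split(".")[0])
    if not rows:
        raise ValidationError("no NIfTI images supplied")
    return tuple(ids), np.vstack(rows)
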