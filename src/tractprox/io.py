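"""Readers and writers for the pipeline's on-disk formats.

NIfTI volumes go through nibabel; gradient tables use the FSL convention
(bvals: one whitespace-separated row; bvecs: three rows of x, y, z
components); tables are TSV via pandas; ground truth and provenance are
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .tensor import DWIDataset, TensorField


def save_nifti(path, data: np.ndarray, affine: np.ndarray) -> None:
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int32)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_bvals_bvecs(bvals: np.ndarray, bvecs: np.ndarray, bval_path, bvec_path) -> None:
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in np.asarray(bvals).ravel()) + "\n")
    rows = np.asarray(bvecs).T  # 3 rows: x, y, z
    Path(bvec_path).write_text(
        "\n".join(" ".join(f"{v:.8f}" for v in row) for row in rows) + "\n"
    )


def load_bvals_bvecs(bval_path, bvec_path):
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def save_dwi(dwi: DWIDataset, directory, stem: str = "dwi") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_nifti(directory / f"{stem}.nii.gz", dwi.signal, dwi.affine)
    save_nifti(directory / f"{stem}_mask.nii.gz", dwi.brain_mask, dwi.affine)
    save_bvals_bvecs(dwi.bvals, dwi.bvecs, directory / f"{stem}.bval", directory / f"{stem}.bvec")


def load_dwi(directory, stem: str = "dwi") -> DWIDataset:
    directory = Path(directory)
    signal, affine = load_nifti(directory / f"{stem}.nii.gz")
    mask, _ = load_nifti(directory / f"{stem}_mask.nii.gz")
    bvals, bvecs = load_bvals_bvecs(directory / f"{stem}.bval", directory / f"{stem}.bvec")
    return DWIDataset(signal=signal, bvals=bvals, bvecs=bvecs,
                      brain_mask=mask.astype(bool), affine=affine)


def save_tensor_field(field: TensorField, directory, stem: str = "tensor") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_nifti(directory / f"{stem}_fa.nii.gz", field.fa, field.affine)
    save_nifti(directory / f"{stem}_evals.nii.gz", field.eigenvalues, field.affine)
    save_nifti(directory / f"{stem}_evecs.nii.gz",
               field.eigenvectors.reshape(field.shape + (9,)), field.affine)
    save_nifti(directory / f"{stem}_valid.nii.gz", field.valid_mask, field.affine)
    save_nifti(directory / f"{stem}_d.nii.gz",
               field.tensors.reshape(field.shape + (9,)), field.affine)


def load_tensor_field(directory, stem: str = "tensor") -> TensorField:
    directory = Path(directory)
    fa_map, affine = load_nifti(directory / f"{stem}_fa.nii.gz")
    evals, _ = load_nifti(directory / f"{stem}_evals.nii.gz")
    evecs, _ = load_nifti(directory / f"{stem}_evecs.nii.gz")
    valid, _ = load_nifti(directory / f"{stem}_valid.nii.gz")
    tens, _ = load_nifti(directory / f"{stem}_d.nii.gz")
    shape = fa_map.shape
    return TensorField(
        eigenvalues=evals, eigenvectors=evecs.reshape(shape + (3, 3)),
        fa=fa_map, valid_mask=valid.astype(bool), affine=affine,
        tensors=tens.reshape(shape + (3, 3)),
    )


def save_table(df: pd.DataFrame, path) -> None:
    # enough digits that electrode geometry survives a round trip within
    # the 1e-6 colinearity tolerance
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())


def save_streamlines_json(streamlines, path) -> None:
    """Polyline JSON: {"streamlines": [{"points": [[x,y,z], ...],
    "accepted": bool}, ...]} — a documented plain-text exchange format."""
    payload = {
        "format": "tractprox-polylines-v1",
        "streamlines": [
            {"points": np.round(s.points, 4).tolist(), "accepted": bool(s.accepted)}
            for s in streamlines
        ],
    }
    save_json(payload, path)
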