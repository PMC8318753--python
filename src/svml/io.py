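"""Readers and writers for images, masks, curves and model bundles.

Images and masks travel as 8/16-bit PNG or single-slice NIfTI; curves and
DWI series as two-column CSV (``time_s,signal`` / ``b_value,signal``);
trained models as a single ``.svml`` archive (a NumPy zip holding the
support vectors, multipliers, threshold and standardization statistics).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .dce import DWISeries, TimeSignalCurve
from .exceptions import FormatError, ValidationError
from .svm import KernelSpec, SVMModel

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_curve",
    "write_curve",
    "read_dwi",
    "write_dwi",
    "save_model",
    "load_model",
]

_PNG = {".png"}


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def read_image(path) -> np.ndarray:
    """Read a 2D grayscale image (PNG 8/16-bit or single-slice NIfTI)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in _PNG:
        arr = iio.imread(path)
        if arr.ndim == 3 and arr.shape[2] in (3, 4):  # collapse accidental RGB(A)
            arr = arr[..., 0]
    elif _is_nifti(path):
        arr = np.asanyarray(nib.load(path).dataobj)
        arr = np.squeeze(arr)
    else:
        raise FormatError(f"unsupported image format: {path} (use .png/.nii/.nii.gz)")
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single 2D slice, got shape {arr.shape}")
    return np.asarray(arr)


def write_image(image: np.ndarray, path) -> None:
    """Write a 2D image; PNG requires uint8/uint16, NIfTI takes any dtype."""
    path = Path(path)
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError(f"image must be 2D, got shape {image.shape}")
    if path.suffix.lower() in _PNG:
        if image.dtype not in (np.uint8, np.uint16):
            raise ValidationError(
                f"PNG output needs uint8/uint16 pixels, got {image.dtype}; "
                "quantize explicitly first"
            )
        iio.imwrite(path, image)
    elif _is_nifti(path):
        nib.save(nib.Nifti1Image(image.astype(np.float32), np.eye(4)), path)
    else:
        raise FormatError(f"unsupported image format: {path}")


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as {0,255} 8-bit PNG or {0,1} NIfTI."""
    path = Path(path)
    mask = np.asarray(mask)
    bad = np.setdiff1d(np.unique(mask), [0, 1])
    if bad.size:
        raise ValidationError(f"mask is not binary; found values {bad.tolist()}")
    if path.suffix.lower() in _PNG:
        iio.imwrite(path, (mask.astype(np.uint8) * 255))
    elif _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), path)
    else:
        raise FormatError(f"unsupported mask format: {path}")


def read_mask(path) -> np.ndarray:
    """Read a mask written by :func:`write_mask`; returns uint8 {0,1}."""
    arr = read_image(path)
    values = np.unique(arr)
    if set(values.tolist()) <= {0, 1}:
        return arr.astype(np.uint8)
    if set(values.tolist()) <= {0, 255}:
        return (arr > 0).astype(np.uint8)
    bad = np.setdiff1d(values, [0, 1, 255])
    raise ValidationError(f"mask file {path} is not binary; found values {bad.tolist()[:10]}")


def write_curve(curve: TimeSignalCurve, path) -> None:
    pd.DataFrame({"time_s": curve.times, "signal": curve.signal}).to_csv(path, index=False)


def read_curve(path, baseline_index_count: int = 1) -> TimeSignalCurve:
    df = pd.read_csv(path)
    if not {"time_s", "signal"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns time_s,signal, got {list(df.columns)}")
    return TimeSignalCurve(
        times=df["time_s"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        baseline_index_count=baseline_index_count,
    )


def write_dwi(series: DWISeries, path) -> None:
    pd.DataFrame({"b_value": series.b_values, "signal": series.signals}).to_csv(path, index=False)


def read_dwi(path) -> DWISeries:
    df = pd.read_csv(path)
    if not {"b_value", "signal"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns b_value,signal, got {list(df.columns)}")
    return DWISeries(b_values=df["b_value"].to_numpy(float), signals=df["signal"].to_numpy(float))


def save_model(model: SVMModel, path) -> None:
    """Persist a trained model as a single ``.svml`` (NumPy zip) bundle."""
    meta = {
        "gamma": model.kernel.gamma,
        "C": model.C,
        "bias": model.bias,
        "n_train": model.n_train,
        "standardized": model.feature_mean is not None,
    }
    arrays = {
        "support_vectors": model.support_vectors,
        "dual_coef": model.dual_coef,
        "support_labels": model.support_labels,
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if model.feature_mean is not None:
        arrays["feature_mean"] = model.feature_mean
        arrays["feature_scale"] = model.feature_scale
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> SVMModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        return SVMModel(
            support_vectors=z["support_vectors"],
            dual_coef=z["dual_coef"],
            support_labels=z["support_labels"],
            bias=float(meta["bias"]),
            kernel=KernelSpec(float(meta["gamma"])),
            C=float(meta["C"]),
            n_train=int(meta["n_train"]),
            feature_mean=z["feature_mean"] if meta["standardized"] else None,
            feature_scale=z["feature_scale"] if meta["standardized"] else None,
        )
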