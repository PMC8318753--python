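"""End-to-end lung-field segmentation: parenchyma ROI -> GLGCM features ->
self-paced SVM pixel classification -> 2D morphological clean-up.

Training samples pixels inside a band around the pre-extracted parenchyma
(the parenchyma mask dilated by ``roi_margin_px``): the band supplies true
negatives at the lung boundary, which is where the classifier earns its
keep.  Inference is likewise restricted to that band plus the parenchyma;
everything outside is background by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

from .exceptions import TrainingError, ValidationError
from .glgcm import feature_stack
from .metrics import MetricsReport, evaluate
from .self_paced import SelfPacedConfig, SelfPacedState, self_paced_train
from .svm import KernelSpec, SVMModel, predict, train_weighted_svm

__all__ = [
    "PipelineConfig",
    "extract_parenchyma",
    "fit",
    "segment",
    "postprocess",
    "run",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the segmentation pipeline.

    ``train_fraction`` is the fraction of labelled ROI pixels sampled
    (balanced across classes, seeded) for training; ``max_train_per_class``
    bounds the kernel problem regardless of image count.  ``self_paced``
    selects the curriculum trainer; switching it off gives the plain-SVM
    baseline.
    """

    levels_gray: int = 16
    levels_grad: int = 16
    sp: SelfPacedConfig = field(default_factory=SelfPacedConfig)
    self_paced: bool = True
    min_component_px: int = 50
    closing_radius: int = 1
    train_fraction: float = 0.1
    max_train_per_class: int = 800
    roi_margin_px: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_component_px < 0:
            raise ValidationError(f"min_component_px must be >= 0, got {self.min_component_px}")
        if not 0 < self.train_fraction <= 1:
            raise ValidationError(f"train_fraction must be in (0, 1], got {self.train_fraction}")
        if self.closing_radius < 0:
            raise ValidationError(f"closing_radius must be >= 0, got {self.closing_radius}")
        if self.roi_margin_px < 0:
            raise ValidationError(f"roi_margin_px must be >= 0, got {self.roi_margin_px}")
        if self.max_train_per_class < 1:
            raise ValidationError(f"max_train_per_class must be >= 1, got {self.max_train_per_class}")


def extract_parenchyma(image: np.ndarray) -> np.ndarray:
    """Candidate lung-field region: Otsu threshold, drop border-touching
    components, keep the two largest, fill holes.

    Returns a uint8 {0,1} mask; an image with no usable foreground (e.g. a
    constant image) yields an empty mask and a warning.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 32:
        raise ValidationError(f"image must be at least 32x32, got shape {image.shape}")
    if image.max() == image.min():
        warnings.warn("constant image: no parenchyma candidate found", RuntimeWarning)
        return np.zeros(image.shape, dtype=np.uint8)
    thresh = filters.threshold_otsu(image)
    fg = image > thresh
    fg = segmentation.clear_border(fg)
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        warnings.warn("no parenchyma component after border clearing", RuntimeWarning)
        return np.zeros(image.shape, dtype=np.uint8)
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.argsort(sizes)[::-1][:2] + 1
    mask = np.isin(labels, keep)
    mask = ndimage.binary_fill_holes(mask)
    return mask.astype(np.uint8)


def _working_roi(image: np.ndarray, config: PipelineConfig) -> np.ndarray:
    roi = extract_parenchyma(image).astype(bool)
    if config.roi_margin_px > 0 and roi.any():
        roi = ndimage.binary_dilation(roi, structure=morphology.disk(config.roi_margin_px))
    return roi


def fit(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[SVMModel, SelfPacedState | None]:
    """Train the pixel classifier from image/reference-mask pairs.

    Pixels inside each image's working ROI are labelled +1 (lung, from the
    reference mask) or -1 (other); a balanced, seeded subset of
    ``train_fraction`` of them (at most ``max_train_per_class`` per class)
    is z-scored and fed to the self-paced trainer (or the plain weighted
    SVM when ``config.self_paced`` is off).
    """
    if len(images) == 0 or len(images) != len(masks):
        raise ValidationError("fit needs >= 1 image/mask pair of equal count")
    feats_pos, feats_neg = [], []
    for img, msk in zip(images, masks):
        img = np.asarray(img, dtype=float)
        msk = np.asarray(msk)
        if msk.shape != img.shape:
            raise ValidationError(f"mask shape {msk.shape} != image shape {img.shape}")
        if np.setdiff1d(np.unique(msk), [0, 1]).size:
            raise ValidationError("reference masks must be binary {0,1}")
        roi = _working_roi(img, config)
        fmap = feature_stack(img, config.levels_gray, config.levels_grad)
        lung = roi & msk.astype(bool)
        other = roi & ~msk.astype(bool)
        feats_pos.append(fmap[lung])
        feats_neg.append(fmap[other])
    Xp = np.concatenate(feats_pos)
    Xn = np.concatenate(feats_neg)
    if len(Xp) == 0 or len(Xn) == 0:
        raise TrainingError("a class is absent inside the working ROI")

    n_labeled = len(Xp) + len(Xn)
    n_per_class = max(1, int(round(config.train_fraction * n_labeled / 2)))
    n_per_class = min(n_per_class, config.max_train_per_class)
    rng = np.random.default_rng(config.seed)
    idx_p = rng.choice(len(Xp), size=min(n_per_class, len(Xp)), replace=False)
    idx_n = rng.choice(len(Xn), size=min(n_per_class, len(Xn)), replace=False)
    X = np.concatenate([Xp[idx_p], Xn[idx_n]])
    y = np.concatenate([np.ones(len(idx_p)), -np.ones(len(idx_n))])

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xz = (X - mean) / scale

    if config.self_paced:
        model, state = self_paced_train(Xz, y, config.sp)
    else:
        model, report = train_weighted_svm(
            Xz, y, None, config.sp.inner_C, KernelSpec(config.sp.gamma), tol=config.sp.tol
        )
        state = None
    model.feature_mean = mean
    model.feature_scale = scale
    return model, state


def segment(
    image: np.ndarray, model: SVMModel, config: PipelineConfig = PipelineConfig()
) -> np.ndarray:
    """Per-pixel classification inside the working ROI; outside is 0."""
    image = np.asarray(image, dtype=float)
    roi = _working_roi(image, config)
    out = np.zeros(image.shape, dtype=np.uint8)
    if not roi.any():
        return out
    fmap = feature_stack(image, config.levels_gray, config.levels_grad)
    labels = predict(model, fmap[roi])
    out[roi] = (labels > 0).astype(np.uint8)
    return out


def postprocess(mask: np.ndarray, config: PipelineConfig = PipelineConfig()) -> np.ndarray:
    """2D morphological clean-up: closing, hole filling, small-object removal."""
    mask = np.asarray(mask).astype(bool)
    if config.closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=morphology.disk(config.closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    if config.min_component_px > 0:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        if n:
            sizes = np.bincount(labels.ravel())
            mask &= sizes[labels] >= config.min_component_px
    return mask.astype(np.uint8)


def run(
    image: np.ndarray,
    model: SVMModel,
    config: PipelineConfig = PipelineConfig(),
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, MetricsReport | None]:
    """Full flow: ROI -> features -> classify -> morphology (+ metrics).

    Metrics are computed against ``reference`` when one is supplied.
    """
    raw = segment(image, model, config)
    clean = postprocess(raw, config)
    report = None
    if reference is not None:
        report = evaluate(clean, np.asarray(reference))
    return clean, report
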