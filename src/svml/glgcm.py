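"""Gray-level / gradient-level co-occurrence (GLGCM) texture features.

A pixel's texture is summarised from the joint distribution of its
quantized intensity level i and quantized Sobel gradient-magnitude level j
inside the 5x5 window centred on it.  With H(i, j) the co-occurrence counts
and P = H / sum(H), the two statistics used as features are

    small-gradient advantage   mu1 = sum_ij H(i,j) / j^2  /  sum_ij H(i,j)
    inverse difference moment  mu2 = - sum_ij P(i,j) / (1 + (i - j)^2)

Levels are 1-based (mu1 divides by j^2, so j must start at 1).  mu2 carries
a leading minus sign here; since the features are z-scored before training
the sign is a constant factor and does not affect the classifier.  mu1 lies
in (0, 1] and mu2 in [-1, 0).

The per-pixel feature vector is ``[i/Lg, j/Lv, mu1, mu2]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError

__all__ = [
    "GLGCMatrix",
    "quantize",
    "gradient_magnitude",
    "window_glgcm",
    "small_gradient_advantage",
    "inverse_difference_moment",
    "feature_stack",
]

WINDOW = 5  # side of the co-occurrence window, pixels


@dataclass(frozen=True)
class GLGCMatrix:
    """Co-occurrence counts H and probabilities P for one window."""

    H: np.ndarray  # (Lg, Lv) non-negative integer counts
    P: np.ndarray  # (Lg, Lv) probabilities, sums to 1

    def __post_init__(self) -> None:
        if self.H.ndim != 2:
            raise ValidationError("H must be 2D")
        if np.any(self.H < 0):
            raise ValidationError("H counts must be non-negative")

    @classmethod
    def from_counts(cls, H: np.ndarray) -> "GLGCMatrix":
        H = np.asarray(H)
        total = H.sum()
        if total <= 0:
            raise ValidationError("empty co-occurrence matrix (sum(H) == 0)")
        return cls(H=H, P=H / total)


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max binning of an image into integer levels 1..levels.

    The minimum maps to level 1 and the maximum to ``levels``; a constant
    image maps everywhere to level 1.
    """
    if levels < 2:
        raise ValidationError(f"levels must be >= 2, got {levels}")
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite values")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.ones(image.shape, dtype=np.int64)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int64) + 1
    return np.minimum(q, levels)


def gradient_magnitude(image: np.ndarray) -> np.ndarray:
    """Sobel 3x3 gradient magnitude with reflect-padded borders."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValidationError(f"image must be at least 3x3, got shape {image.shape}")
    gx = ndimage.sobel(image, axis=1, mode="mirror")
    gy = ndimage.sobel(image, axis=0, mode="mirror")
    return np.hypot(gx, gy)


def _reflect_window(grid: np.ndarray, row: int, col: int) -> np.ndarray:
    half = WINDOW // 2
    padded = np.pad(grid, half, mode="reflect")
    return padded[row : row + WINDOW, col : col + WINDOW]


def window_glgcm(gray_q: np.ndarray, grad_q: np.ndarray, row: int, col: int,
                 Lg: int | None = None, Lv: int | None = None) -> GLGCMatrix:
    """Co-occurrence matrix of the 5x5 reflect-padded window at (row, col).

    ``gray_q`` and ``grad_q`` are 1-based quantized grids of equal shape.
    H(i, j) counts window pixels with gray level i and gradient level j;
    P = H / 25.
    """
    gray_q = np.asarray(gray_q)
    grad_q = np.asarray(grad_q)
    if gray_q.shape != grad_q.shape:
        raise ValidationError("gray_q and grad_q must have the same shape")
    h, w = gray_q.shape
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"window centre ({row}, {col}) outside {h}x{w} grid")
    Lg = int(gray_q.max()) if Lg is None else Lg
    Lv = int(grad_q.max()) if Lv is None else Lv
    gw = _reflect_window(gray_q, row, col)
    vw = _reflect_window(grad_q, row, col)
    H = np.zeros((Lg, Lv), dtype=np.int64)
    np.add.at(H, (gw.ravel() - 1, vw.ravel() - 1), 1)
    return GLGCMatrix.from_counts(H)


def small_gradient_advantage(m: GLGCMatrix) -> float:
    """mu1 = [sum_ij H(i,j)/j^2] / [sum_ij H(i,j)]; always in (0, 1]."""
    H = np.asarray(m.H, dtype=float)
    total = H.sum()
    if total <= 0:
        raise ValidationError("empty co-occurrence matrix")
    j = np.arange(1, H.shape[1] + 1, dtype=float)
    return float((H / j**2).sum() / total)


def inverse_difference_moment(m: GLGCMatrix) -> float:
    """mu2 = -sum_ij P(i,j) / (1 + (i-j)^2); always in [-1, 0)."""
    P = np.asarray(m.P, dtype=float)
    if abs(P.sum() - 1.0) > 1e-9:
        raise ValidationError(f"P is not normalized (sum = {P.sum()})")
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    return float(-(P / (1.0 + (i - j) ** 2)).sum())


def feature_stack(image: np.ndarray, Lg: int = 16, Lv: int = 16) -> np.ndarray:
    """Per-pixel 4-vector feature map ``[i/Lg, j/Lv, mu1, mu2]``.

    mu1 and mu2 are computed from the pixel's 5x5 window.  Because both
    statistics reduce to window means of per-pixel terms —
    mu1 = mean(1/j^2) and mu2 = -mean(1/(1+(i-j)^2)) over the window — the
    whole map is evaluated with two uniform filters rather than an explicit
    window loop; the result is identical to per-window evaluation.

    Returns float64 of shape ``image.shape + (4,)``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < WINDOW:
        raise ValidationError(
            f"image must be at least {WINDOW}x{WINDOW}, got shape {image.shape}"
        )
    gray_q = quantize(image, Lg)
    grad_q = quantize(gradient_magnitude(image), Lv)
    inv_j2 = 1.0 / grad_q.astype(float) ** 2
    idm = 1.0 / (1.0 + (gray_q - grad_q).astype(float) ** 2)
    # "mirror" matches the edge-excluding reflect convention of the
    # per-window path (np.pad mode="reflect")
    mu1 = ndimage.uniform_filter(inv_j2, size=WINDOW, mode="mirror")
    mu2 = -ndimage.uniform_filter(idm, size=WINDOW, mode="mirror")
    return np.stack([gray_q / Lg, grad_q / Lv, mu1, mu2], axis=-1)
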