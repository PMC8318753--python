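"""Segmentation-quality metrics: Dice, sensitivity, specificity, MSE.

Conventions follow the A/B roles used throughout the package: A is the
reference mask (expert standard) and B the predicted mask.  SE and SP are
implemented exactly as printed in the source formulation —

    SE = |A ∩ B| / |B|,      SP = |A1 ∩ B1| / |B1|

with A1, B1 the complements — which under these roles are the precision and
the negative predictive value.  Because the prose intent ("proportion of the
correctly detected target area") suggests the standard recall/specificity
reading, the report also carries ``se_standard = |A ∩ B| / |A|`` and
``sp_standard = |A1 ∩ B1| / |A1|``, clearly labelled.

Undefined denominators yield missing values (None), never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedMetricError, ValidationError

__all__ = ["MetricsReport", "dice", "sensitivity", "specificity", "mse", "evaluate"]


def _as_bool_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    for name, m in (("first", a), ("second", b)):
        bad = np.setdiff1d(np.unique(m), [0, 1])
        if bad.size:
            raise ValidationError(f"{name} mask is not binary; found values {bad.tolist()}")
    return a.astype(bool), b.astype(bool)


@dataclass
class MetricsReport:
    """All four metrics plus the raw pixel tallies they derive from."""

    dice: float
    se: float | None
    sp: float | None
    mse: float
    se_standard: float | None
    sp_standard: float | None
    n_ref: int       # |A|
    n_pred: int      # |B|
    n_overlap: int   # |A ∩ B|
    n_pixels: int    # M*N

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "se": self.se,
            "sp": self.sp,
            "mse": self.mse,
            "se_standard": self.se_standard,
            "sp_standard": self.sp_standard,
            "n_ref": self.n_ref,
            "n_pred": self.n_pred,
            "n_overlap": self.n_overlap,
            "n_pixels": self.n_pixels,
        }


def dice(a, b, denominator: str = "standard") -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty.

    ``denominator="union"`` selects the variant 2|A∩B| / |A∪B| instead
    (which equals 2 for identical non-empty masks and exceeds [0, 1]).
    """
    A, B = _as_bool_pair(a, b)
    inter = int((A & B).sum())
    if denominator == "standard":
        denom = int(A.sum()) + int(B.sum())
    elif denominator == "union":
        denom = int((A | B).sum())
    else:
        raise ValidationError(f"denominator must be 'standard' or 'union', got {denominator!r}")
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom


def sensitivity(a, b) -> float:
    """SE = |A∩B| / |B| with A the reference and B the prediction."""
    A, B = _as_bool_pair(a, b)
    nb = int(B.sum())
    if nb == 0:
        raise UndefinedMetricError("SE undefined: predicted mask is empty (|B| = 0)")
    return int((A & B).sum()) / nb


def specificity(a, b) -> float:
    """SP = |A1∩B1| / |B1| over the complements of reference and prediction."""
    A, B = _as_bool_pair(a, b)
    nb1 = int((~B).sum())
    if nb1 == 0:
        raise UndefinedMetricError("SP undefined: predicted mask covers every pixel (|B1| = 0)")
    return int((~A & ~B).sum()) / nb1


def mse(f, g) -> float:
    """Mean squared pixel difference (1/MN) Σ (f - g)^2.

    For binary masks this is exactly the fraction of disagreeing pixels.
    """
    F, G = _as_bool_pair(f, g)
    return float(np.mean((F.astype(float) - G.astype(float)) ** 2))


def evaluate(pred, ref, dice_denominator: str = "standard") -> MetricsReport:
    """All four metrics in one report; undefined metrics become None.

    ``ref`` plays A (expert standard) and ``pred`` plays B.
    """
    A, B = _as_bool_pair(ref, pred)

    def _try(fn, *args):
        try:
            return fn(*args)
        except UndefinedMetricError:
            return None

    na, nb = int(A.sum()), int(B.sum())
    na1, inter = int((~A).sum()), int((A & B).sum())
    return MetricsReport(
        dice=dice(A, B, denominator=dice_denominator),
        se=_try(sensitivity, A, B),
        sp=_try(specificity, A, B),
        mse=mse(A, B),
        se_standard=(inter / na) if na else None,
        sp_standard=(int((~A & ~B).sum()) / na1) if na1 else None,
        n_ref=na,
        n_pred=nb,
        n_overlap=inter,
        n_pixels=int(A.size),
    )
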