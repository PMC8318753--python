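"""Synthetic lung-slice phantoms, enhancement curves and DWI decays.

Real thoracic MR images of the kind this package segments are not publicly
available, so every test and demonstration runs on synthetic data produced
here.  The image phantom renders two elliptical "lung fields" on a darker
background; note that on real T1/T2 lung MRI the air-filled lung is *dark* —
the bright-lung convention is purely a phantom convenience (the classifier
only needs contrast) and can be reversed by swapping the two intensities.

All generators are deterministic under a fixed seed: identical spec + seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError

__all__ = [
    "PhantomSpec",
    "CurveSpec",
    "DWISpec",
    "generate_lung_phantom",
    "generate_tic",
    "generate_dwi",
    "make_noisy_blobs",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of a synthetic lung slice.

    Intensities are on an arbitrary 0-255 gray scale.  ``texture_scale`` is
    the width (pixels) of the uniform smoothing filter that correlates the
    in-lung texture; ``nodule_radius = 0`` disables the nodule.
    """

    height: int = 128
    width: int = 128
    lung_intensity: float = 200.0
    background_intensity: float = 50.0
    noise_sigma: float = 10.0
    texture_scale: int = 4
    nodule_radius: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValidationError(
                f"height/width must be >= 32, got {self.height}x{self.width}"
            )
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.texture_scale < 1:
            raise ValidationError(f"texture_scale must be >= 1, got {self.texture_scale}")
        if not self.nodule_radius >= 0:
            raise ValidationError(f"nodule_radius must be >= 0, got {self.nodule_radius}")
        if self.nodule_radius >= min(self.height, self.width) / 4:
            raise ValidationError(
                f"nodule_radius must be < min(height,width)/4, got {self.nodule_radius}"
            )


def lung_ellipses(spec: PhantomSpec):
    """Centres and semi-axes of the two lung-field ellipses.

    Returns a list of ``(cy, cx, semi_y, semi_x)`` tuples in pixel units.
    Each lung spans roughly width/5 horizontally and height/3 vertically,
    mirrored about the vertical midline.
    """
    semi_x = spec.width / 5.0
    semi_y = spec.height / 3.0
    cy = (spec.height - 1) / 2.0
    return [
        (cy, 0.28 * (spec.width - 1), semi_y, semi_x),
        (cy, 0.72 * (spec.width - 1), semi_y, semi_x),
    ]


def generate_lung_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a synthetic lung slice and its ground-truth mask.

    The mask is the union of two ellipses (plus a nodule disc inside the
    left lung when ``nodule_radius > 0``).  Lung pixels are drawn from
    N(lung_intensity, noise_sigma) plus a smoothed texture field of
    amplitude ``noise_sigma / 2``; background pixels from
    N(background_intensity, noise_sigma).

    Returns
    -------
    (image, mask)
        ``image`` is float64 ``(height, width)``; ``mask`` is uint8 {0, 1}.
    """
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for cy, cx, sy, sx in lung_ellipses(spec):
        mask |= ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2 <= 1.0
    if spec.nodule_radius > 0:
        cy, cx, _, _ = lung_ellipses(spec)[0]
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.nodule_radius**2

    rng = np.random.default_rng(spec.seed)
    image = np.where(mask, spec.lung_intensity, spec.background_intensity).astype(float)
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, size=image.shape)
        # correlated class texture, confined to the lung fields
        white = rng.standard_normal(image.shape)
        texture = ndimage.uniform_filter(white, size=spec.texture_scale, mode="reflect")
        sd = texture.std()
        if sd > 0:
            texture /= sd
        image += np.where(mask, texture * (spec.noise_sigma / 2.0), 0.0)
    return image, mask.astype(np.uint8)


def make_noisy_blobs(
    seed: int,
    n: int = 100,
    separation: float = 3.0,
    flip_fraction: float = 0.1,
    dim: int = 2,
):
    """Two unit-variance Gaussian blobs with a fraction of flipped labels.

    The classifier-robustness toy: blob centres sit ``separation`` apart
    along the first axis, labels are -1/+1 by blob, and ``flip_fraction``
    of the samples get their label inverted (the known outliers).

    Returns ``(X, y_noisy, flipped_indices, y_clean)``.
    """
    if n < 4:
        raise ValidationError(f"n must be >= 4, got {n}")
    if not 0 <= flip_fraction < 0.5:
        raise ValidationError(f"flip_fraction must be in [0, 0.5), got {flip_fraction}")
    rng = np.random.default_rng(seed)
    half = n // 2
    centre = np.zeros(dim)
    centre[0] = separation / 2.0
    X = np.concatenate(
        [rng.normal(-centre, 1.0, (half, dim)), rng.normal(centre, 1.0, (n - half, dim))]
    )
    y_clean = np.concatenate([-np.ones(half), np.ones(n - half)])
    flipped = rng.choice(n, int(round(n * flip_fraction)), replace=False)
    y = y_clean.copy()
    y[flipped] *= -1
    return X, y, flipped, y_clean


@dataclass(frozen=True)
class CurveSpec:
    """Piecewise-linear dynamic-enhancement curve.

    The signal rises linearly from ``baseline_signal`` to
    ``baseline_signal * (1 + peak_enhancement)`` at ``time_to_peak`` and then
    changes linearly by ``late_slope_fraction`` of the peak enhancement over
    the remaining acquisition: a positive fraction keeps enhancing
    (persistent), ~0 holds (plateau), negative loses signal (washout).
    """

    curve_type: str = "washout"
    baseline_signal: float = 100.0
    peak_enhancement: float = 0.5
    time_to_peak: float = 60.0
    late_slope_fraction: float = -0.4
    duration: float = 180.0
    sampling_interval: float = 6.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.curve_type not in ("persistent", "plateau", "washout"):
            raise ValidationError(f"curve_type must be persistent/plateau/washout, got {self.curve_type!r}")
        if self.baseline_signal <= 0:
            raise ValidationError(f"baseline_signal must be > 0, got {self.baseline_signal}")
        if not 0 < self.time_to_peak < self.duration:
            raise ValidationError(
                f"time_to_peak must lie in (0, duration), got {self.time_to_peak} vs {self.duration}"
            )
        if self.sampling_interval <= 0:
            raise ValidationError(f"sampling_interval must be > 0, got {self.sampling_interval}")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.peak_enhancement < 0:
            raise ValidationError(f"peak_enhancement must be >= 0, got {self.peak_enhancement}")

    @classmethod
    def typed(cls, curve_type: str, **kwargs) -> "CurveSpec":
        """Spec with a late slope conventional for the requested type."""
        slope = {"persistent": 0.3, "plateau": 0.0, "washout": -0.4}[curve_type]
        kwargs.setdefault("late_slope_fraction", slope)
        return cls(curve_type=curve_type, **kwargs)


def generate_tic(spec: CurveSpec):
    """Sample a time-intensity curve at t = 0, dt, ... <= duration.

    Returns a :class:`~svml.dce.TimeSignalCurve` whose single pre-peak
    baseline sample is the t = 0 point.
    """
    from .dce import TimeSignalCurve  # avoid import cycle at module load

    n = int(np.floor(spec.duration / spec.sampling_interval + 1e-9)) + 1
    times = np.arange(n) * spec.sampling_interval
    peak = spec.baseline_signal * (1.0 + spec.peak_enhancement)
    rise = spec.baseline_signal + (peak - spec.baseline_signal) * (times / spec.time_to_peak)
    tail_span = spec.duration - spec.time_to_peak
    late = peak + spec.late_slope_fraction * (spec.baseline_signal * spec.peak_enhancement) * (
        (times - spec.time_to_peak) / tail_span
    )
    signal = np.where(times <= spec.time_to_peak, rise, late)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sigma, size=signal.shape)
    return TimeSignalCurve(times=times, signal=signal, baseline_index_count=1)


@dataclass(frozen=True)
class DWISpec:
    """Mono-exponential diffusion decay: S(b) = s0 * exp(-b * adc_true) + noise."""

    s0: float = 1000.0
    adc_true: float = 1.2e-3
    b_values: tuple = (0.0, 500.0, 1000.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValidationError(f"s0 must be > 0, got {self.s0}")
        if self.adc_true <= 0:
            raise ValidationError(f"adc_true must be > 0, got {self.adc_true}")
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2:
            raise ValidationError("b_values needs >= 2 entries")
        if np.any(b < 0):
            raise ValidationError("b_values must be non-negative")
        if np.any(np.diff(b) <= 0):
            raise ValidationError("b_values must be strictly increasing")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


def generate_dwi(spec: DWISpec):
    """Generate a noisy mono-exponential DWI series."""
    from .dce import DWISeries

    b = np.asarray(spec.b_values, dtype=float)
    signal = spec.s0 * np.exp(-b * spec.adc_true)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sigma, size=signal.shape)
    return DWISeries(b_values=b, signals=signal)
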