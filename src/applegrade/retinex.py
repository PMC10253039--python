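"""Single-scale Retinex illumination correction.

A camera frame is modelled as the product ``S(x, y) = R(x, y) * L(x, y)`` of a
reflectance image ``R`` (the surface property we want) and an illumination
field ``L`` that varies slowly across the scene.  Because ``L`` is smooth, it
is well approximated by a Gaussian-surround weighted average of the frame
itself; subtracting the two in the log domain,

    log R = log S - log(F * S),

leaves an image dominated by reflectance, which is what the downstream fruit
graders consume.  Glossy fruit on an unevenly lit conveyor is exactly the
regime this transform targets: specular sheen and lamp fall-off live in ``L``.

Conventions (fixed here, referenced by the rest of the package):

* natural logarithm — the base cancels in the affine display normalization;
* channels processed independently, order (red, green, blue);
* Gaussian surround truncated at ``radius = ceil(3 * sigma)``, reflection
  padding at the borders;
* an additive offset ``epsilon`` (default 1.0 on the 0–255 scale) guards
  ``log 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "SurroundKernel",
    "build_surround_kernel",
    "single_scale_retinex",
    "normalize_reflectance",
    "enhance_image",
]

DEFAULT_SIGMA = 80.0
DEFAULT_EPSILON = 1.0


@dataclass(frozen=True)
class SurroundKernel:
    """Normalized Gaussian surround used to estimate the illumination field.

    ``weights`` is the full ``(2 * radius + 1)``-square grid; ``weights_1d``
    is the separable factor actually used for filtering (the 2-D grid is its
    outer product).
    """

    sigma: float
    radius: int
    weights: np.ndarray
    weights_1d: np.ndarray


def build_surround_kernel(sigma: float) -> SurroundKernel:
    """Build the unit-sum Gaussian surround ``F`` for scale ``sigma`` (pixels).

    The grid holds ``exp(-(x^2 + y^2) / (2 sigma^2))`` truncated at
    ``radius = ceil(3 sigma)`` and normalized to sum to one, so convolving a
    constant image leaves it unchanged.
    """
    if not (sigma > 0):
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    radius = max(1, math.ceil(3.0 * sigma))
    coords = np.arange(-radius, radius + 1, dtype=np.float64)
    w1d = np.exp(-(coords**2) / (2.0 * sigma**2))
    w1d /= w1d.sum()
    weights = np.outer(w1d, w1d)
    weights /= weights.sum()
    return SurroundKernel(sigma=float(sigma), radius=radius, weights=weights, weights_1d=w1d)


def _as_float_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3 or arr.shape[0] < 1 or arr.shape[1] < 1 or arr.shape[2] < 1:
        raise ValueError(f"expected an H x W x C image, got shape {np.shape(image)}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def _surround_average(channel: np.ndarray, kernel: SurroundKernel) -> np.ndarray:
    # Separable Gaussian: two 1-D passes with reflection padding are exactly
    # the 2-D outer-product kernel, at O(radius) instead of O(radius^2) cost.
    out = convolve1d(channel, kernel.weights_1d, axis=0, mode="reflect")
    out = convolve1d(out, kernel.weights_1d, axis=1, mode="reflect")
    return out


def single_scale_retinex(
    image: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Log-domain reflectance ``log(S + eps) - log(F * S + eps)`` per channel.

    Parameters
    ----------
    image
        H x W x 3 (or H x W) intensities on the 0–255 scale.
    sigma
        Scale of the Gaussian surround, in pixels.  Larger values attribute
        broader structures to illumination.
    epsilon
        Positive offset guarding the logarithm at zero intensity.

    Returns
    -------
    Array of the same shape as ``image`` (channel axis preserved), finite
    everywhere, unbounded (log-domain).
    """
    if not (epsilon > 0):
        raise ValueError(f"epsilon must be positive, got {epsilon!r}")
    arr = _as_float_image(image)
    kernel = build_surround_kernel(sigma)
    out = np.empty_like(arr)
    for c in range(arr.shape[2]):
        surround = _surround_average(arr[:, :, c], kernel)
        out[:, :, c] = np.log(arr[:, :, c] + epsilon) - np.log(surround + epsilon)
    if image.ndim == 2:
        return out[:, :, 0]
    return out


def normalize_reflectance(
    rmap: np.ndarray,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
) -> np.ndarray:
    """Map a log-reflectance array to a displayable 0–255 uint8 image.

    Values are clipped per channel to the ``[low_pct, high_pct]`` percentile
    interval, then mapped affinely onto [0, 255].  A channel with no dynamic
    range (constant reflectance) maps to mid-gray 128 rather than failing.
    """
    if not (low_pct < high_pct):
        raise ValueError(f"need low_pct < high_pct, got ({low_pct}, {high_pct})")
    arr = np.asarray(rmap, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    out = np.empty_like(arr)
    for c in range(arr.shape[2]):
        ch = arr[:, :, c]
        lo, hi = np.percentile(ch, [low_pct, high_pct])
        if hi - lo < 1e-12:
            out[:, :, c] = 128.0
            continue
        out[:, :, c] = (np.clip(ch, lo, hi) - lo) / (hi - lo) * 255.0
    result = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if squeeze:
        return result[:, :, 0]
    return result


def enhance_image(
    image: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    epsilon: float = DEFAULT_EPSILON,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
) -> np.ndarray:
    """Full enhancement: Retinex followed by percentile display normalization."""
    return normalize_reflectance(
        single_scale_retinex(image, sigma=sigma, epsilon=epsilon),
        low_pct=low_pct,
        high_pct=high_pct,
    )
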