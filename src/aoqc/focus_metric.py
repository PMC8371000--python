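"""Energy-of-Laplacian (LAPE) focus measure.

LAPE is a no-reference sharpness metric: the image is normalized for
brightness, convolved with a discrete Laplacian kernel, and the energy (sum
of squared filter responses) is reduced to a single number. Sharp, well
focused cone mosaics have strong local curvature at every cone reflex and
score high; defocused or washed-out patches score low. On the instrument's
calibrated scale the score ranges over roughly [0, 75].

Conventions chosen here (each exposed as an argument):

* kernel — the 5-point Laplacian ``[[0,1,0],[1,-4,1],[0,1,0]]``;
* boundary — energy is summed over *valid* (interior) pixels only, so no
  fabricated border response enters the score; the same rule extends to
  mosaic-blank regions (exact-zero pixels where the window fell off the
  mosaic edge): blank pixels are excluded from the brightness statistics
  and any 3x3 neighbourhood touching one is excluded from the energy,
  otherwise the artificial content/blank edge would dominate the score;
* normalization — multiplicative mean-matching to a reference level, which
  makes the score invariant to multiplying the input by any positive
  constant;
* scale — mean per-pixel energy times a fixed calibration constant
  (:data:`aoqc.config.LAPE_CALIBRATION`) maps onto the 0-75 range.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import convolve2d

from . import config
from .patch import Patch

__all__ = ["normalize_brightness", "lape", "lape_blur_profile"]


def normalize_brightness(
    patch: Patch, reference: float = config.BRIGHTNESS_REFERENCE
) -> Patch:
    """Rescale a patch multiplicatively so its mean equals ``reference``.

    Raises
    ------
    ValueError
        If the patch is all zero (mean 0). Such a patch is fully truncated
        and should be classified as category 1, not focus-scored.
    """
    mean = patch.intensities.mean()
    if mean <= 0:
        raise ValueError("cannot normalize an all-zero patch (fully truncated?)")
    return Patch(
        intensities=patch.intensities * (reference / mean),
        pixel_scale=patch.pixel_scale,
        provenance=patch.provenance,
    )


def lape(
    patch: Patch,
    kernel: Sequence[Sequence[float]] = config.LAPLACIAN_5PT,
    calibration: float = config.LAPE_CALIBRATION,
    blank_threshold: float = config.BLANK_THRESHOLD,
) -> float:
    """LAPE focus score of a patch.

    The patch is brightness-normalized (multiplicatively, over non-blank
    pixels), convolved with ``kernel``, and the mean squared response over
    valid interior pixels whose kernel support contains no blank pixel is
    scaled by ``calibration``.

    Raises
    ------
    ValueError
        If the patch is smaller than the kernel support, or no valid
        response pixel remains (patch entirely blank — classify such a
        patch as truncated instead of scoring it).
    """
    k = np.asarray(kernel, dtype=float)
    arr = patch.intensities
    if arr.shape[0] < k.shape[0] or arr.shape[1] < k.shape[1]:
        raise ValueError(f"patch {arr.shape} smaller than kernel {k.shape}")
    blank = arr <= blank_threshold
    mean = arr[~blank].mean() if (~blank).any() else 0.0
    if mean <= 0:
        raise ValueError("cannot score an all-blank patch (fully truncated?)")
    normalized = arr * (config.BRIGHTNESS_REFERENCE / mean)
    response = convolve2d(normalized, k, mode="valid")
    touched = convolve2d(blank.astype(float), np.ones_like(k), mode="valid")
    valid = touched == 0
    if not valid.any():
        raise ValueError("no valid response pixels: patch is dominated by blank area")
    return calibration * float(np.mean(response[valid] ** 2))


def lape_blur_profile(
    patch: Patch,
    sigmas_um: Sequence[float],
    kernel: Sequence[Sequence[float]] = config.LAPLACIAN_5PT,
    calibration: float = config.LAPE_CALIBRATION,
) -> list[float]:
    """LAPE scores of the patch after Gaussian blur at each sigma (µm).

    A diagnostic: on cone-mosaic content the score decreases monotonically
    with defocus blur. Sigmas must be nonnegative and nondecreasing.
    """
    sigmas = list(sigmas_um)
    if any(s < 0 for s in sigmas):
        raise ValueError("blur sigmas must be nonnegative")
    if any(b < a for a, b in zip(sigmas, sigmas[1:])):
        raise ValueError("blur sigmas must be nondecreasing")
    scores = []
    for s in sigmas:
        if s == 0:
            blurred = patch
        else:
            blurred = Patch(
                intensities=gaussian_filter(
                    patch.intensities, sigma=s / patch.pixel_scale, mode="nearest"
                ),
                pixel_scale=patch.pixel_scale,
                provenance=patch.provenance,
            )
        scores.append(lape(blurred, kernel=kernel, calibration=calibration))
    return scores
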