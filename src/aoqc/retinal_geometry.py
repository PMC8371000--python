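"""Retinal geometry: magnification correction, window extraction, truncation.

Visual angle (degrees of visual field) maps to retinal distance through a
per-eye magnification factor, computed from axial length with Bennett's
adjusted Littmann method::

    q = 0.013063 * (AL - 1.82)   [mm per degree]

Regions of interest are laid out 1°-10° from the foveal center along the
four principal meridians, and each ROI is sampled by five overlapping
50 x 50 µm windows: Mid, centered on the ROI, plus TL/TR/BL/BR displaced
diagonally. Patches with more than 5% of their area off the mosaic edge
(blank pixels) are automatically assigned quality category 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import config
from .patch import Patch, Provenance

__all__ = [
    "EyeBiometry",
    "RoiSpec",
    "magnification_factor",
    "degrees_to_micrometers",
    "extract_windows",
    "truncation_fraction",
    "auto_category1",
]

MERIDIANS = ("superior", "inferior", "nasal", "temporal")

#: Littmann zero point: q vanishes at this axial length (mm).
_AL_ZERO = 1.82
_Q_SLOPE = 0.013063  # mm/deg per mm of axial length


@dataclass(frozen=True)
class EyeBiometry:
    """Axial length (mm) and the derived magnification factor q (mm/deg)."""

    axial_length: float

    def __post_init__(self) -> None:
        if not self.axial_length > _AL_ZERO:
            raise ValueError(
                f"axial length must exceed {_AL_ZERO} mm, got {self.axial_length}"
            )

    @property
    def q(self) -> float:
        return magnification_factor(self.axial_length)


@dataclass(frozen=True)
class RoiSpec:
    """One grid locus: integer eccentricity 1-10° on a named meridian."""

    eccentricity: int
    meridian: str
    window: str = "Mid"

    def __post_init__(self) -> None:
        if not (1 <= self.eccentricity <= 10):
            raise ValueError(f"eccentricity must be in [1, 10], got {self.eccentricity}")
        if self.meridian not in MERIDIANS:
            raise ValueError(f"meridian must be one of {MERIDIANS}")


def magnification_factor(axial_length: float) -> float:
    """Retinal magnification q in mm per degree, from axial length in mm."""
    if not axial_length > _AL_ZERO:
        raise ValueError(
            f"axial length must exceed {_AL_ZERO} mm, got {axial_length}"
        )
    return _Q_SLOPE * (axial_length - _AL_ZERO)


def degrees_to_micrometers(angle_deg: float, biometry: EyeBiometry) -> float:
    """Convert visual angle to retinal distance (µm) for one eye."""
    if angle_deg < 0:
        raise ValueError("angle must be nonnegative")
    return biometry.q * angle_deg * 1000.0


def extract_windows(
    roi_image: Patch,
    window_side_um: float = config.WINDOW_SIDE_UM,
    offset_um: float = config.WINDOW_OFFSET_UM,
) -> dict[str, Patch]:
    """Cut the five overlapping sampling windows out of an ROI image.

    Mid is centered on the ROI center; TL/TR/BL/BR are displaced by
    (±offset, ±offset). Returned patches are sub-views of ``roi_image`` (no
    copy), keyed by window tag.

    Raises
    ------
    ValueError
        If the ROI image is too small to contain all five windows.
    """
    scale = roi_image.pixel_scale
    side_px = round(window_side_um / scale)
    off_px = round(offset_um / scale)
    rows, cols = roi_image.shape
    cr, cc = rows // 2, cols // 2

    required = side_px + 2 * off_px
    if required > rows or required > cols:
        raise ValueError(
            f"ROI image {rows}x{cols} px cannot contain five {side_px} px windows "
            f"at offset {off_px} px (needs {required} px)"
        )

    half = side_px // 2
    displacements = {
        "Mid": (0, 0),
        "TL": (-off_px, -off_px),
        "TR": (-off_px, +off_px),
        "BL": (+off_px, -off_px),
        "BR": (+off_px, +off_px),
    }
    out: dict[str, Patch] = {}
    for tag, (dr, dc) in displacements.items():
        r0 = cr + dr - half
        c0 = cc + dc - half
        if r0 < 0 or c0 < 0 or r0 + side_px > rows or c0 + side_px > cols:
            raise ValueError(
                f"window {tag} at ({r0},{c0}) size {side_px} exceeds ROI {rows}x{cols}"
            )
        prov = roi_image.provenance
        out[tag] = Patch(
            intensities=roi_image.intensities[r0 : r0 + side_px, c0 : c0 + side_px],
            pixel_scale=scale,
            provenance=Provenance(
                subject_id=prov.subject_id if prov else None,
                eccentricity_deg=prov.eccentricity_deg if prov else None,
                meridian=prov.meridian if prov else None,
                window=tag,
            ),
        )
    return out


def truncation_fraction(
    patch: Patch, blank_threshold: float = config.BLANK_THRESHOLD
) -> float:
    """Fraction of pixels lying outside the mosaic (intensity <= threshold).

    Mosaic compositors write exact zeros outside coverage, so the default
    threshold is 0; raise it for formats with a noise floor.
    """
    return float(np.mean(patch.intensities <= blank_threshold))


def auto_category1(
    patch: Patch,
    blank_threshold: float = config.BLANK_THRESHOLD,
    limit: float = config.TRUNCATION_LIMIT,
) -> bool:
    """True iff strictly more than ``limit`` of the patch area is truncated."""
    return truncation_fraction(patch, blank_threshold) > limit
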