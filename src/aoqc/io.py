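"""Reading and writing patches, manifests, labels and scores.

Patches travel as 16-bit grayscale TIFF (intensities in [0, 1] scaled to
the uint16 range) next to a CSV manifest with one row per patch: path,
true category, scene parameters, and subject covariates.
"""

from __future__ import annotations

from pathlib import Path as FsPath
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import tifffile

from . import config
from .patch import Patch, Provenance
from .synthetic_mosaic import LabeledPatch, cohort_frame
from .quality_factors import SubjectMeta

__all__ = ["write_patch", "read_patch", "write_cohort", "read_manifest"]

_U16 = 65535.0


def write_patch(patch: Patch, path: FsPath | str) -> None:
    """Write intensities (expected in [0, 1]) as 16-bit grayscale TIFF."""
    arr = np.clip(patch.intensities, 0.0, 1.0)
    tifffile.imwrite(str(path), np.round(arr * _U16).astype(np.uint16))


def read_patch(
    path: FsPath | str,
    pixel_scale: float = config.PIXEL_SCALE_UM,
    provenance: Optional[Provenance] = None,
) -> Patch:
    """Read a grayscale TIFF/PNG patch back onto the [0, 1] scale."""
    arr = tifffile.imread(str(path)).astype(float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    if arr.max() > 1.0:
        arr = arr / _U16
    return Patch(intensities=arr, pixel_scale=pixel_scale, provenance=provenance)


def write_cohort(
    cohort: Iterable[tuple[LabeledPatch, SubjectMeta]],
    out_dir: FsPath | str,
) -> pd.DataFrame:
    """Write rendered patches plus ``manifest.csv``; returns the manifest."""
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = list(cohort)
    frame = cohort_frame(cohort)
    paths = []
    for i, (lp, _meta) in enumerate(cohort):
        if lp.patch is None:
            paths.append("")
            continue
        rel = f"patch_{i:05d}.tif"
        write_patch(lp.patch, out / rel)
        paths.append(rel)
    frame.insert(0, "patch_path", paths)
    frame.to_csv(out / "manifest.csv", index=False)
    return frame


def read_manifest(manifest_path: FsPath | str) -> pd.DataFrame:
    """Read a cohort manifest; patch paths resolve relative to the CSV."""
    path = FsPath(manifest_path)
    frame = pd.read_csv(path)
    if "patch_path" in frame.columns:
        frame["patch_path"] = [
            str(path.parent / p) if p else "" for p in frame["patch_path"].fillna("")
        ]
    return frame
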