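"""Infarct volumetry normalized to supratentorial brain volume (SBV).

Infarct volume is the number of masked supratentorial non-ventricular voxels
times the voxel volume; SBV is the full supratentorial non-ventricular
compartment (ventricular CSF excluded).  The prognostically relevant size
classes are *large* (infarct >= 5% of SBV, a threshold associated with
hemorrhagic transformation and poor outcome) and *small* (< 5%); the
boundary at exactly 5% is inclusive on the large side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .atlas import LesionMask, RegionAtlas, check_same_grid

#: large/small volume-fraction threshold (infarct / SBV)
LARGE_FRACTION_THRESHOLD = 0.05


class DegenerateAtlasError(ValueError):
    """The atlas has no supratentorial brain voxels (SBV = 0)."""


@dataclass(frozen=True)
class VolumeReport:
    infarct_ml: float
    sbv_ml: float
    fraction: float
    size_class: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.fraction <= 1.0
        assert self.size_class == classify_size(self.fraction)

    def to_dict(self) -> dict:
        return {
            "infarct_ml": round(self.infarct_ml, 4),
            "sbv_ml": round(self.sbv_ml, 4),
            "fraction": round(self.fraction, 6),
            "size_class": self.size_class,
        }


def classify_size(fraction: float) -> str:
    """``large`` iff the infarct is >= 5% of SBV (boundary inclusive)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"volume fraction must be in [0, 1], got {fraction}")
    return "large" if fraction >= LARGE_FRACTION_THRESHOLD else "small"


def measure(mask: LesionMask | np.ndarray, atlas: RegionAtlas) -> VolumeReport:
    """Measure infarct volume, SBV and their ratio by voxel counting.

    Mask voxels on ventricle, infratentorial or background labels cannot be
    infarcted brain and are excluded from the numerator (with a data-quality
    warning); SBV is a property of the atlas alone.
    """
    if not isinstance(mask, LesionMask):
        mask = LesionMask(data=mask, voxel_size=atlas.voxel_size)
    check_same_grid(mask, atlas)

    supra = atlas.supratentorial_mask
    n_sbv = int(supra.sum())
    if n_sbv == 0:
        raise DegenerateAtlasError("atlas has zero supratentorial brain volume")

    n_in = int((mask.data & supra).sum())
    n_out = int(mask.data.sum()) - n_in
    if n_out:
        warnings.warn(
            f"{n_out} mask voxels fall on ventricle/background/infratentorial labels "
            "and are excluded from infarct volume",
            stacklevel=2,
        )
    vox = atlas.voxel_volume_ml
    fraction = n_in / n_sbv
    return VolumeReport(
        infarct_ml=n_in * vox,
        sbv_ml=n_sbv * vox,
        fraction=fraction,
        size_class=classify_size(fraction),
    )
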