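"""The modified pediatric ASPECTS: one point per involved region, maximum 30.

Unlike the adult ASPECTS (which subtracts from a normal-territory total of
10), the pediatric modification *adds* one point for each of 15 regions per
hemisphere showing acute infarction.  A region counts as involved even if
only a small portion of it is affected — including watershed bands and
punctate foci — which is what the default ``min_voxels=1`` implements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .atlas import (
    BACKGROUND,
    INFRATENTORIAL,
    VENTRICLE,
    LesionMask,
    RegionAtlas,
    check_same_grid,
    region_label,
)
from .regions import RegionName, all_regions, parse_regions


@dataclass(frozen=True)
class ModAspectsResult:
    """Score result: the involved-region set, per-hemisphere subscores, total."""

    involved: frozenset[RegionName]
    per_hemisphere: dict
    total: int
    involvement_fraction: dict = field(default_factory=dict)
    min_voxels: int = 1

    def __post_init__(self) -> None:
        assert self.total == len(self.involved)
        assert self.total == self.per_hemisphere["left"] + self.per_hemisphere["right"]
        assert 0 <= self.total <= 30

    def to_dict(self) -> dict:
        d = {
            "total": self.total,
            "left": self.per_hemisphere["left"],
            "right": self.per_hemisphere["right"],
            "involved": sorted(r.token for r in self.involved),
            "involvement_fraction": {
                k: round(v, 4) for k, v in sorted(self.involvement_fraction.items())
            },
        }
        if self.min_voxels != 1:
            d["min_voxels"] = self.min_voxels  # non-default rule is flagged
        return d


def score_from_regions(involved: Iterable[RegionName] | Iterable[str] | str) -> ModAspectsResult:
    """Score a set of involved regions (duplicates collapse; order irrelevant).

    Accepts :class:`RegionName` objects, ``L_M1``-style tokens, or a single
    comma-separated token string.  Unknown tokens raise ``ValueError`` listing
    the valid codes.
    """
    if isinstance(involved, str):
        regions = parse_regions(involved)
    else:
        items = list(involved)
        if items and isinstance(items[0], str):
            regions = parse_regions(items)
        else:
            regions = frozenset(items)
    bad = regions - all_regions()
    if bad:
        raise ValueError(f"unknown regions: {sorted(r.token for r in bad)}")
    per_hemi = {
        side: sum(1 for r in regions if r.side == side) for side in ("left", "right")
    }
    return ModAspectsResult(
        involved=frozenset(regions), per_hemisphere=per_hemi, total=len(regions)
    )


def score_from_mask(
    mask: LesionMask | np.ndarray,
    atlas: RegionAtlas,
    min_voxels: int = 1,
) -> ModAspectsResult:
    """Score an infarct mask against a region atlas.

    A region is counted as involved iff at least ``min_voxels`` of its voxels
    fall inside the mask; the default of one voxel implements the rule that a
    region scores even when only a small portion is involved.  Mask voxels
    outside supratentorial tissue never score and trigger a warning.
    """
    if not isinstance(mask, LesionMask):
        mask = LesionMask(data=mask, voxel_size=atlas.voxel_size)
    check_same_grid(mask, atlas)
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")

    hit = np.bincount(atlas.labels[mask.data].ravel(), minlength=34)
    outside = int(hit[BACKGROUND] + hit[VENTRICLE] + hit[INFRATENTORIAL])
    if outside:
        warnings.warn(
            f"{outside} mask voxels lie outside supratentorial tissue and do not score",
            stacklevel=2,
        )

    sizes = np.bincount(atlas.labels.ravel(), minlength=34)
    involved = set()
    fractions: dict[str, float] = {}
    for r in all_regions():
        lab = region_label(r)
        if hit[lab] >= min_voxels:
            involved.add(r)
            fractions[r.token] = float(hit[lab]) / float(sizes[lab])
    per_hemi = {
        side: sum(1 for r in involved if r.side == side) for side in ("left", "right")
    }
    return ModAspectsResult(
        involved=frozenset(involved),
        per_hemisphere=per_hemi,
        total=len(involved),
        involvement_fraction=fractions,
        min_voxels=min_voxels,
    )
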