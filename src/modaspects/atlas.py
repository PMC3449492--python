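"""Synthetic brain phantom atlases for region-based infarct scoring.

A :class:`RegionAtlas` is a dense 3D integer label volume in which every voxel
belongs to exactly one of: a scoring region (30 labels), the ventricles,
non-scored supratentorial tissue, infratentorial tissue, or background.
:func:`build_phantom_atlas` constructs a geometrically plausible layered
phantom (ellipsoidal brain, medial ventricles, deep-gray nuclei, an insular
shell, and an angularly parcellated cortical ribbon) whose supratentorial
non-ventricular volume is calibrated to a requested target.

Axis convention: axis 0 is lateral (lower index = left), axis 1 is
anterior-posterior (lower index = anterior), axis 2 is inferior-superior.
Voxel indices are 0-based; the left hemisphere is ``x < hemisphere_plane``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .regions import CODES, SIDES, RegionName, all_regions

# -- label integers ---------------------------------------------------------
BACKGROUND = 0
#: left-hemisphere regions take labels 1..15 in CODES order, right 16..30
VENTRICLE = 31
SUPRATENTORIAL_OTHER = 32
INFRATENTORIAL = 33

SPECIAL_NAMES = {
    BACKGROUND: "BACKGROUND",
    VENTRICLE: "VENTRICLE",
    SUPRATENTORIAL_OTHER: "SUPRATENTORIAL_OTHER",
    INFRATENTORIAL: "INFRATENTORIAL",
}


def region_label(region: RegionName) -> int:
    """Canonical label integer for a scoring region (1..30)."""
    return CODES.index(region.code) + 1 + (0 if region.side == "left" else 15)


def canonical_label_table() -> dict[int, str]:
    table = {k: v for k, v in SPECIAL_NAMES.items()}
    for r in all_regions():
        table[region_label(r)] = r.token
    return table


class AtlasSizingError(ValueError):
    """The grid is too small (or the volume target unreachable) for a valid phantom."""


class GridMismatchError(ValueError):
    """Mask and atlas do not share the same voxel grid."""


LabelEntry = Union[str, tuple]  # composite tuples arise from wrongly merged volumes


@dataclass
class LesionMask:
    """Binary acute-infarct mask on the same voxel grid as its atlas."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def volume_ml(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.voxel_size)) / 1000.0


@dataclass
class RegionAtlas:
    """Label volume + table defining the 30 scoring regions and tissue classes."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    label_table: dict[int, LabelEntry] = field(default_factory=canonical_label_table)
    hemisphere_plane: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    # -- geometry helpers ---------------------------------------------------
    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def region_mask(self, region: RegionName) -> np.ndarray:
        return self.labels == region_label(region)

    def regions_mask(self, regions) -> np.ndarray:
        labs = sorted(region_label(r) for r in regions)
        return np.isin(self.labels, labs)

    @property
    def supratentorial_mask(self) -> np.ndarray:
        """All supratentorial voxels excluding ventricles (the SBV compartment)."""
        return ((self.labels >= 1) & (self.labels <= 30)) | (
            self.labels == SUPRATENTORIAL_OTHER
        )

    @property
    def sbv_ml(self) -> float:
        """Supratentorial brain volume excluding the ventricles, in ml."""
        return float(self.supratentorial_mask.sum()) * self.voxel_volume_ml

    def region_voxel_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=34)
        return {
            RegionName(side=s, code=c).token: int(
                counts[region_label(RegionName(side=s, code=c))]
            )
            for s in SIDES
            for c in CODES
        }

    # -- persistence --------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        """Write the label volume as NIfTI with a JSON sidecar for the table."""
        import nibabel as nib

        path = Path(path)
        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), path)
        sidecar = {
            "label_table": {str(k): v for k, v in self.label_table.items()},
            "hemisphere_plane": int(self.hemisphere_plane),
            "voxel_size": list(self.voxel_size),
            "axes": "0=lateral (low index = left), 1=anterior-posterior, 2=inferior-superior",
        }
        sidecar_path = path.with_name(path.name.split(".")[0] + "_labels.json")
        sidecar_path.write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "RegionAtlas":
        import nibabel as nib

        path = Path(path)
        img = nib.load(path)
        sidecar_path = path.with_name(path.name.split(".")[0] + "_labels.json")
        meta = json.loads(sidecar_path.read_text())
        table: dict[int, LabelEntry] = {
            int(k): (tuple(v) if isinstance(v, list) else v)
            for k, v in meta["label_table"].items()
        }
        return cls(
            labels=np.asarray(img.dataobj, dtype=np.int16),
            voxel_size=tuple(meta["voxel_size"]),
            label_table=table,
            hemisphere_plane=int(meta["hemisphere_plane"]),
        )


def save_mask(mask: LesionMask, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(mask.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), Path(path))


def load_mask(path: str | Path, voxel_size: Sequence[float] | None = None) -> LesionMask:
    import nibabel as nib

    img = nib.load(Path(path))
    if voxel_size is None:
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LesionMask(data=np.asarray(img.dataobj) > 0, voxel_size=tuple(voxel_size))


# -- phantom construction ---------------------------------------------------

def _ellipsoid(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _phantom_masks(shape, scale, jitter):
    """Brain / supratentorial / ventricle masks plus helper fields at one scale."""
    nx, ny, nz = shape
    coords = np.ogrid[0:nx, 0:ny, 0:nz]
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    semi = (
        scale * (nx - 2) / 2.0,
        scale * (ny - 2) / 2.0,
        scale * (nz - 2) / 2.0,
    )
    brain = _ellipsoid(coords, center, semi)
    z = coords[2]
    z_tent = center[2] - 0.55 * semi[2]  # tentorium height
    supra = brain & (z >= z_tent)

    # one medial ventricle per side, mirrored exactly
    hp = nx // 2
    vx = center[0] - (0.13 + jitter[0]) * semi[0]
    vent_left = _ellipsoid(
        coords,
        (vx, center[1], center[2] + 0.05 * semi[2]),
        (0.07 * semi[0], 0.38 * semi[1], 0.22 * semi[2]),
    )
    vent_left[hp:, :, :] = False
    vent = vent_left | vent_left[::-1, :, :]
    vent &= supra
    return brain, supra, vent, center, semi, z_tent, coords


def build_phantom_atlas(
    grid_shape: Sequence[int],
    voxel_size: Sequence[float] = (2.0, 2.0, 2.0),
    sbv_target_ml: float = 320.0,
    seed: int = 0,
    min_region_voxels: int = 8,
) -> RegionAtlas:
    """Build a deterministic layered phantom atlas.

    The brain is an ellipsoid; the bottom slab below the tentorium level is
    infratentorial. Supratentorial tissue holds mirrored medial ventricles,
    four deep-gray nuclei per side (caudate, lentiform, internal capsule,
    thalamus), an insular shell between deep gray and cortex, and a cortical
    ribbon split angularly into ACA / MCA / PCA sectors and vertically into
    lower (M1-M3, A1, P1) and upper (M4-M6, A2, P2) tiers.  The global brain
    scale is bisected so the supratentorial non-ventricular volume lands
    within 2% of ``sbv_target_ml``.  The right hemisphere is an exact mirror
    of the left, so homologous region voxel counts match.

    Raises
    ------
    AtlasSizingError
        If the target volume is unreachable on this grid, or any of the 30
        regions ends up with fewer than ``min_region_voxels`` voxels.
    """
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or min(shape) < 12:
        raise AtlasSizingError(f"grid {shape} too small for a 30-region phantom")
    voxel_size = tuple(float(v) for v in voxel_size)
    if min(voxel_size) <= 0 or sbv_target_ml <= 0:
        raise AtlasSizingError("voxel size and SBV target must be positive")
    vox_ml = float(np.prod(voxel_size)) / 1000.0

    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.015, 0.015, size=6)

    def sbv_at(scale: float) -> float:
        _, supra, vent, *_ = _phantom_masks(shape, scale, jitter)
        return float((supra & ~vent).sum()) * vox_ml

    lo, hi = 0.25, 1.0
    if sbv_at(hi) < 0.98 * sbv_target_ml:
        raise AtlasSizingError(
            f"grid {shape} at voxel {voxel_size} cannot reach SBV {sbv_target_ml} ml "
            f"(max {sbv_at(hi):.0f} ml)"
        )
    scale = hi
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if sbv_at(mid) < sbv_target_ml:
            lo = mid
        else:
            hi = mid
        scale = 0.5 * (lo + hi)
        if abs(sbv_at(scale) - sbv_target_ml) <= 0.015 * sbv_target_ml:
            break
    if abs(sbv_at(scale) - sbv_target_ml) > 0.02 * sbv_target_ml:
        raise AtlasSizingError(
            f"could not calibrate SBV to within 2% of {sbv_target_ml} ml on grid {shape}"
        )

    brain, supra, vent, center, semi, z_tent, coords = _phantom_masks(
        shape, scale, jitter
    )
    nx, ny, nz = shape
    hp = nx // 2

    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = INFRATENTORIAL
    labels[supra] = SUPRATENTORIAL_OTHER
    labels[vent] = VENTRICLE

    # dense coordinate fields (left hemisphere only is assigned, then mirrored)
    X, Y, Z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    lat = center[0] - X  # positive toward the left surface
    ant = center[1] - Y  # positive toward the anterior pole
    rho = np.sqrt(
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    )
    psi = np.degrees(np.arctan2(lat, ant))  # 0 = anterior, 90 = lateral, 180 = posterior

    left = X < hp
    assignable = supra & ~vent & left
    free = assignable.copy()

    def take(mask: np.ndarray, region_code: str) -> None:
        m = mask & free
        labels[m] = region_label(RegionName(side="left", code=region_code))
        free[m] = False

    def nucleus(off_lat, off_ant, off_z, semis) -> np.ndarray:
        c = (
            center[0] - off_lat * semi[0],
            center[1] - off_ant * semi[1],
            center[2] + off_z * semi[2],
        )
        s = (semis[0] * semi[0], semis[1] * semi[1], semis[2] * semi[2])
        return _ellipsoid((X, Y, Z), c, s)

    j = jitter
    # deep gray: internal capsule first (thin slab between caudate and lentiform)
    take(nucleus(0.33 + j[1], 0.12, 0.0, (0.050, 0.15, 0.11)), "IC")
    take(nucleus(0.24 + j[2], 0.20, 0.05, (0.085, 0.10, 0.11)), "C")
    take(nucleus(0.42 + j[3], 0.06, 0.0, (0.100, 0.12, 0.12)), "L")
    take(nucleus(0.22 + j[4], -0.20, 0.03, (0.110, 0.13, 0.12)), "T")

    # insular shell: mid-depth lateral band around the deep nuclei
    z_mid = (Z >= center[2] - 0.28 * semi[2]) & (Z < center[2] + 0.22 * semi[2])
    take((rho > 0.46) & (rho <= 0.62) & (psi >= 55) & (psi < 115) & z_mid, "I")

    # cortical ribbon: outer shell, angular sectors x two vertical tiers
    ribbon = rho > 0.72
    upper = Z >= center[2] + 0.20 * semi[2]
    lower = ~upper
    aca = psi < 40
    pca = psi >= 132
    m_edges = np.linspace(40, 132, 4)
    m_sector = [
        (psi >= m_edges[k]) & (psi < m_edges[k + 1]) for k in range(3)
    ]
    take(ribbon & lower & aca, "A1")
    take(ribbon & upper & aca, "A2")
    take(ribbon & lower & pca, "P1")
    take(ribbon & upper & pca, "P2")
    for k, code in enumerate(("M1", "M2", "M3")):
        take(ribbon & lower & m_sector[k], code)
    for k, code in enumerate(("M4", "M5", "M6")):
        take(ribbon & upper & m_sector[k], code)

    # mirror left labels onto the right hemisphere
    flipped = labels[::-1, :, :]
    right_regions = (flipped >= 1) & (flipped <= 15) & (X >= nx - hp)
    labels[right_regions] = flipped[right_regions] + 15

    atlas = RegionAtlas(
        labels=labels,
        voxel_size=voxel_size,
        label_table=canonical_label_table(),
        hemisphere_plane=hp,
    )
    counts = atlas.region_voxel_counts()
    small = {t: c for t, c in counts.items() if c < min_region_voxels}
    if small:
        raise AtlasSizingError(
            f"grid {shape} too small: regions below {min_region_voxels} voxels: {small}"
        )
    return atlas


# -- validation -------------------------------------------------------------

def validate_atlas(atlas: RegionAtlas) -> list[str]:
    """Diagnostic check of atlas invariants; returns a list of violations.

    Checks: every scoring region nonempty; label-table bijectivity (no two
    labels naming the same region, no unknown names); hemisphere consistency
    of region voxels relative to ``hemisphere_plane``; ventricles disjoint
    from scoring regions (composite label entries that mix a scoring region
    with VENTRICLE or another region are exclusivity violations).
    """
    problems: list[str] = []
    valid_names = {r.token for r in all_regions()} | set(SPECIAL_NAMES.values())

    seen: dict[str, int] = {}
    region_labels: dict[str, int] = {}
    for lab, entry in atlas.label_table.items():
        names = entry if isinstance(entry, tuple) else (entry,)
        scoring = [n for n in names if n in valid_names - set(SPECIAL_NAMES.values())]
        if len(names) > 1:
            if scoring and (set(names) - set(scoring) or len(scoring) > 1):
                problems.append(
                    f"exclusivity violation: label {lab} maps to merged memberships {names}"
                )
        for n in names:
            if n not in valid_names:
                problems.append(f"label {lab} maps to unknown name {n!r}")
            elif n in seen and n not in SPECIAL_NAMES.values():
                problems.append(
                    f"bijectivity violation: {n} mapped by labels {seen[n]} and {lab}"
                )
            else:
                seen[n] = lab
                if n not in SPECIAL_NAMES.values():
                    region_labels[n] = lab

    counts = np.bincount(atlas.labels.ravel(), minlength=max(atlas.label_table, default=0) + 1)
    for r in sorted(all_regions()):
        lab = region_labels.get(r.token)
        if lab is None:
            problems.append(f"empty region: {r.token} has no label-table entry")
        elif lab >= len(counts) or counts[lab] == 0:
            problems.append(f"empty region: {r.token} (label {lab}) has no voxels")

    hp = atlas.hemisphere_plane
    xs = np.arange(atlas.labels.shape[0])[:, None, None]
    for r in sorted(all_regions()):
        lab = region_labels.get(r.token)
        if lab is None:
            continue
        m = atlas.labels == lab
        if not m.any():
            continue
        if r.side == "left" and (m & (xs >= hp)).any():
            problems.append(f"hemisphere violation: {r.token} has voxels right of plane {hp}")
        if r.side == "right" and (m & (xs < hp)).any():
            problems.append(f"hemisphere violation: {r.token} has voxels left of plane {hp}")
    return problems


def check_same_grid(mask: LesionMask, atlas: RegionAtlas) -> None:
    if tuple(mask.data.shape) != tuple(atlas.labels.shape):
        raise GridMismatchError(
            f"mask grid {mask.data.shape} != atlas grid {atlas.labels.shape}"
        )
    if not np.allclose(mask.voxel_size, atlas.voxel_size):
        raise GridMismatchError(
            f"mask voxel size {mask.voxel_size} != atlas voxel size {atlas.voxel_size}"
        )
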