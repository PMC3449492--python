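"""Synthetic lesion and cohort generation.

No public imaging accompanies the study this pipeline emulates, so cohorts
are simulated on phantom atlases.  Three lesion mechanisms are modeled:

* ``territorial`` — connected region growth seeded inside an arterial
  territory (MCA / ACA / PCA parcels), filling a *severity* fraction of the
  territory's volume;
* ``watershed`` — infarction confined to thin borderzone bands between
  adjacent cortical territories (ACA-MCA, MCA-PCA) and the deep MCA border;
* ``punctate`` — many tiny scattered foci (1-3 voxels each) across several
  regions, the multifocal-punctate pattern known to inflate a region-count
  score relative to its tiny volume.

Cohort mechanism/territory/laterality frequencies follow the published
perinatal (N=31) and childhood (N=40) stroke-distribution table, and
per-subject target volume fractions are drawn from log-normal distributions
fitted once to the published medians and interquartile ranges (perinatal
6.9% of SBV, IQR 2.4-17.2%; childhood 2%, IQR 0.4-9.8%).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, stats

from .atlas import (
    SUPRATENTORIAL_OTHER,
    LesionMask,
    RegionAtlas,
    region_label,
)
from .regions import RegionName, all_regions, territory_regions
from .scoring import score_from_mask
from .volumetrics import classify_size, measure

_STEP_PREFERRED = 1.0
_STEP_OUTSIDE = 60.0  # cost of stepping through non-target tissue


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of one simulated lesion."""

    mechanism: str
    territories: tuple = ()  # ((territory, side), ...)
    severity: float = 0.2
    punctate_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("territorial", "watershed", "punctate"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism in ("territorial", "watershed") and not self.territories:
            raise ValueError(f"{self.mechanism} lesions need at least one territory")
        if self.mechanism == "punctate" and self.punctate_count < 2:
            raise ValueError("punctate lesions need punctate_count >= 2")
        if not 0.0 < self.severity <= 1.0:
            raise ValueError("severity must be in (0, 1]")


@dataclass(frozen=True)
class RaterModel:
    """Bernoulli reader model for the three independent blinded raters."""

    detect_prob: float = 0.9
    false_pos_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.detect_prob <= 1.0:
            raise ValueError("detect_prob must be in (0, 1]")
        if not 0.0 <= self.false_pos_prob < 1.0:
            raise ValueError("false_pos_prob must be in [0, 1)")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    lesion_spec: LesionSpec
    volume_fraction: float
    size_class: str
    true_regions: frozenset = frozenset()
    rater_scores: tuple = ()

    def __post_init__(self) -> None:
        assert self.size_class == classify_size(self.volume_fraction)
        assert all(0 <= s <= 30 for s in self.rater_scores)

    @property
    def true_score(self) -> int:
        return len(self.true_regions)


# -- lesion simulation ------------------------------------------------------

def _grow(
    allowed: np.ndarray,
    preferred: np.ndarray,
    target: int,
    rng: np.random.Generator,
    countable: np.ndarray | None = None,
) -> np.ndarray:
    """Randomized Dijkstra growth from a seed voxel inside ``preferred``.

    Steps inside ``preferred`` are cheap; steps through other allowed tissue
    are expensive, so growth fills the target compartment before leaking.
    Voxels are accumulated in pop order until ``target`` countable voxels are
    collected, which makes the grown mask a prefix of a deterministic
    sequence — hence monotone in the target (and in severity).
    """
    nx, ny, nz = allowed.shape
    strides = (ny * nz, nz, 1)
    offsets = (strides[0], -strides[0], strides[1], -strides[1], 1, -1)

    allowed_f = allowed.ravel()
    pref_f = preferred.ravel()
    count_f = allowed_f if countable is None else countable.ravel()
    pref_idx = np.flatnonzero(pref_f)
    if pref_idx.size == 0:
        raise ValueError("territory/band has no voxels in this atlas")
    start = int(rng.choice(pref_idx))

    visited = np.zeros(allowed_f.size, dtype=bool)
    out = np.zeros(allowed_f.size, dtype=bool)
    tie = rng.random  # random tie-breaks make growth fronts irregular
    heap = [(0.0, tie(), start)]
    visited[start] = True
    collected = 0
    while heap and collected < target:
        cost, _, idx = heapq.heappop(heap)
        if count_f[idx]:
            out[idx] = True
            collected += 1
        for off in offsets:
            j = idx + off
            if 0 <= j < allowed_f.size and not visited[j] and allowed_f[j]:
                visited[j] = True
                step = _STEP_PREFERRED if pref_f[j] else _STEP_OUTSIDE
                heapq.heappush(heap, (cost + step, tie(), j))
    return out.reshape(allowed.shape)


def _territory_mask(atlas: RegionAtlas, territories: Iterable[tuple[str, str]]) -> np.ndarray:
    regions: set[RegionName] = set()
    for terr, side in territories:
        regions |= territory_regions(terr, side)
    return atlas.regions_mask(regions)


_CORTICAL = {"ACA": ("A1", "A2"), "MCA": tuple(f"M{i}" for i in range(1, 7)), "PCA": ("P1", "P2")}
_ADJACENT = {"ACA": ("MCA",), "MCA": ("ACA", "PCA"), "PCA": ("MCA",)}
_STRUCT = ndimage.generate_binary_structure(3, 1)


def watershed_band(atlas: RegionAtlas, territories: Iterable[tuple[str, str]]) -> np.ndarray:
    """Thin borderzone bands for the listed territories.

    Cortical bands straddle the boundary between a listed territory's ribbon
    parcels and each adjacent territory's parcels; for the MCA the deep
    borderzone (white matter rimming caudate/lentiform/internal capsule) is
    added.
    """
    band = np.zeros_like(atlas.labels, dtype=bool)
    pairs: set[tuple[str, str, str]] = set()
    for terr, side in territories:
        for nb in _ADJACENT[terr]:
            pairs.add((side,) + tuple(sorted((terr, nb))))
    for side, ta, tb in pairs:
        ma = atlas.regions_mask(RegionName(side=side, code=c) for c in _CORTICAL[ta])
        mb = atlas.regions_mask(RegionName(side=side, code=c) for c in _CORTICAL[tb])
        da = ndimage.binary_dilation(ma, _STRUCT, iterations=3)
        db = ndimage.binary_dilation(mb, _STRUCT, iterations=3)
        band |= (da & mb) | (db & ma)
    for terr, side in territories:
        if terr == "MCA":
            deep = atlas.regions_mask(
                RegionName(side=side, code=c) for c in ("C", "L", "IC")
            )
            rim = ndimage.binary_dilation(deep, _STRUCT, iterations=2)
            band |= rim & (atlas.labels == SUPRATENTORIAL_OTHER)
    return band & atlas.supratentorial_mask


def _punctate(
    atlas: RegionAtlas, count: int, rng: np.random.Generator
) -> np.ndarray:
    allowed = atlas.supratentorial_mask
    n_regions = int(min(count, max(3, count // 4 + 2)))
    region_list = sorted(all_regions())
    chosen = [region_list[i] for i in rng.choice(len(region_list), n_regions, replace=False)]
    out = np.zeros_like(allowed)
    nx, ny, nz = allowed.shape
    for b in range(count):
        region = chosen[b % n_regions]
        vox = np.flatnonzero((atlas.labels == region_label(region)).ravel() & ~out.ravel())
        if vox.size == 0:
            continue
        center = int(vox[rng.integers(vox.size)])
        blob = [center]
        for _ in range(int(rng.integers(0, 3))):  # blob size 1-3 voxels
            base = blob[int(rng.integers(len(blob)))]
            off = [ny * nz, -ny * nz, nz, -nz, 1, -1][int(rng.integers(6))]
            j = base + off
            if 0 <= j < allowed.size and allowed.ravel()[j] and not out.ravel()[j] and j not in blob:
                blob.append(j)
        flat = out.ravel()
        flat[blob] = True
    return out


def simulate_lesion(atlas: RegionAtlas, spec: LesionSpec) -> LesionMask:
    """Generate a binary lesion mask on the atlas grid (deterministic by seed).

    Masks never intersect ventricles, infratentorial tissue or background,
    and for a fixed seed and territory the grown mask at a lower severity is
    a subset of the mask at a higher severity.
    """
    rng = np.random.default_rng(spec.seed)
    allowed = atlas.supratentorial_mask
    out = np.zeros_like(allowed)

    if spec.mechanism == "territorial":
        sides = sorted({side for _, side in spec.territories})
        for side in sides:
            terr = [(t, s) for t, s in spec.territories if s == side]
            tmask = _territory_mask(atlas, terr)
            if not tmask.any():
                raise ValueError(f"territories {terr} have no parcels in this atlas")
            target = max(1, round(spec.severity * int(tmask.sum())))
            out |= _grow(allowed, tmask, target, rng)
    elif spec.mechanism == "watershed":
        band = watershed_band(atlas, spec.territories)
        if not band.any():
            raise ValueError(f"no watershed band for territories {spec.territories}")
        target = max(1, round(spec.severity * int(band.sum())))
        out |= _grow(allowed, band, target, rng, countable=band)
    else:  # punctate
        out |= _punctate(atlas, spec.punctate_count, rng)

    return LesionMask(data=out & allowed, voxel_size=atlas.voxel_size)


# -- cohort simulation ------------------------------------------------------

#: published stroke-distribution table: (territories, subjects, of-which-watershed)
TABLE1 = {
    "perinatal": {
        "laterality": (("left", 14), ("right", 7), ("bilateral", 10)),
        "rows": (
            (("MCA",), 20, 2),
            (("PCA",), 1, 0),
            (("ACA", "MCA"), 2, 1),
            (("MCA", "PCA"), 5, 1),
            (("ACA", "MCA", "PCA"), 2, 0),
            ("punctate", 1, 0),
            ("watershed_only", 0, 0),
        ),
    },
    "childhood": {
        "laterality": (("left", 20), ("right", 14), ("bilateral", 6)),
        "rows": (
            (("MCA",), 29, 3),
            (("PCA",), 4, 1),
            (("ACA",), 1, 0),
            (("MCA", "PCA"), 1, 1),
            (("ACA", "MCA", "PCA"), 1, 0),
            ("punctate", 2, 0),
            ("watershed_only", 2, 0),
        ),
    },
}

#: published volume-fraction medians and IQRs (fraction of SBV)
VOLUME_FRACTION_QUARTILES = {
    "perinatal": (0.024, 0.069, 0.172),
    "childhood": (0.004, 0.02, 0.098),
}


def _lognormal_params(group: str) -> tuple[float, float]:
    q1, med, q3 = VOLUME_FRACTION_QUARTILES[group]
    z75 = stats.norm.ppf(0.75)
    return math.log(med), math.log(q3 / q1) / (2.0 * z75)


def simulate_cohort(
    atlas: RegionAtlas, group: str, n: int, seed: int
) -> list[SubjectRecord]:
    """Simulate ``n`` subjects of one age group (rater scores not yet filled).

    Mechanisms, territories and laterality are drawn with the published
    frequencies; each subject's target volume fraction is drawn from the
    group's fitted log-normal and converted into a territory severity.  The
    realized volume fraction and involved-region set are measured from the
    generated mask by the volumetrics and scoring modules.
    """
    if group not in TABLE1:
        raise ValueError(f"group must be one of {sorted(TABLE1)}")
    if n < 1:
        raise ValueError("n must be >= 1")

    cfg = TABLE1[group]
    rows = cfg["rows"]
    row_w = np.array([r[1] for r in rows], dtype=float)
    row_p = row_w / row_w.sum()
    lat_names = [l for l, _ in cfg["laterality"]]
    lat_w = np.array([w for _, w in cfg["laterality"]], dtype=float)
    lat_p = lat_w / lat_w.sum()
    mu, sigma = _lognormal_params(group)

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]

    sbv_vox = int(atlas.supratentorial_mask.sum())
    records: list[SubjectRecord] = []
    for i in range(n):
        terr_row, n_row, n_ws = rows[int(rng.choice(len(rows), p=row_p))]
        v_target = float(np.clip(rng.lognormal(mu, sigma), 5e-4, 0.6))

        if terr_row == "punctate":
            spec = LesionSpec(
                mechanism="punctate",
                punctate_count=int(rng.integers(6, 18)),
                severity=0.01,
                seed=child_seeds[i],
            )
        else:
            lat = lat_names[int(rng.choice(len(lat_names), p=lat_p))]
            sides = ("left", "right") if lat == "bilateral" else (lat,)
            if terr_row == "watershed_only":
                terrs = tuple(("MCA", s) for s in sides)
                band_vox = int(watershed_band(atlas, terrs).sum())
                sev = float(np.clip(v_target * sbv_vox / max(band_vox, 1), 0.05, 1.0))
                spec = LesionSpec(
                    mechanism="watershed", territories=terrs, severity=sev,
                    seed=child_seeds[i],
                )
            else:
                terrs = tuple((t, s) for s in sides for t in terr_row)
                is_ws = n_row > 0 and rng.random() < (n_ws / n_row)
                if is_ws:
                    band_vox = int(watershed_band(atlas, terrs).sum())
                    sev = float(np.clip(v_target * sbv_vox / max(band_vox, 1), 0.05, 1.0))
                    spec = LesionSpec(
                        mechanism="watershed", territories=terrs, severity=sev,
                        seed=child_seeds[i],
                    )
                else:
                    terr_vox = int(_territory_mask(atlas, terrs).sum())
                    sev = float(np.clip(v_target * sbv_vox / max(terr_vox, 1), 0.01, 1.0))
                    spec = LesionSpec(
                        mechanism="territorial", territories=terrs, severity=sev,
                        seed=child_seeds[i],
                    )

        mask = simulate_lesion(atlas, spec)
        vol = measure(mask, atlas)
        result = score_from_mask(mask, atlas)
        records.append(
            SubjectRecord(
                subject_id=f"{group[:4]}_{i:04d}",
                group=group,
                lesion_spec=spec,
                volume_fraction=vol.fraction,
                size_class=vol.size_class,
                true_regions=result.involved,
            )
        )
    return records


def simulate_raters(
    records: Sequence[SubjectRecord], model: RaterModel, k: int = 3
) -> list[SubjectRecord]:
    """Fill in ``k`` independent noisy rater scores for every subject.

    Each rater marks each truly involved region with probability
    ``detect_prob`` and each uninvolved region with ``false_pos_prob``; the
    rater's score is the number of marked regions.
    """
    if k < 2:
        raise ValueError("need at least 2 raters")
    rng = np.random.default_rng(model.seed)
    out = []
    for rec in records:
        n_true = len(rec.true_regions)
        scores = tuple(
            int(
                rng.binomial(n_true, model.detect_prob)
                + rng.binomial(30 - n_true, model.false_pos_prob)
            )
            for _ in range(k)
        )
        out.append(replace(rec, rater_scores=scores))
    return out


def cohort_to_frame(records: Sequence[SubjectRecord]):
    """Tabulate a cohort as a pandas DataFrame (one row per subject)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "mechanism": r.lesion_spec.mechanism,
            "territories": ";".join(f"{t}_{s[0].upper()}" for t, s in r.lesion_spec.territories),
            "severity": round(r.lesion_spec.severity, 4),
            "punctate_count": r.lesion_spec.punctate_count,
            "lesion_seed": r.lesion_spec.seed,
            "volume_fraction": r.volume_fraction,
            "size_class": r.size_class,
            "true_score": r.true_score,
            "true_regions": ";".join(sorted(x.token for x in r.true_regions)),
        }
        for j, s in enumerate(r.rater_scores, start=1):
            row[f"rater{j}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
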