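"""Region taxonomy for the modified pediatric ASPECTS.

The score covers 15 territories per hemisphere (30 total): six cortical MCA
ribbon parcels M1-M6 plus the insula, two cortical ACA parcels A1-A2, two
cortical PCA parcels P1-P2, and four subcortical structures (caudate,
lentiform nucleus, internal capsule, thalamus). One point is *added* per
involved region, so the maximum total is 30 (15 per hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

#: region codes in canonical order within a hemisphere
CODES: tuple[str, ...] = (
    "M1", "M2", "M3", "M4", "M5", "M6", "I",
    "A1", "A2",
    "P1", "P2",
    "C", "L", "IC", "T",
)

SIDES: tuple[str, ...] = ("left", "right")

#: category -> codes; the insula is counted with the cortical MCA regions
#: (the four subcortical regions are exactly C, L, IC, T)
CATEGORIES: dict[str, tuple[str, ...]] = {
    "cortical_mca": ("M1", "M2", "M3", "M4", "M5", "M6", "I"),
    "cortical_aca": ("A1", "A2"),
    "cortical_pca": ("P1", "P2"),
    "subcortical": ("C", "L", "IC", "T"),
}

_CODE_TO_CATEGORY = {c: cat for cat, codes in CATEGORIES.items() for c in codes}

#: arterial territory -> member region codes (per hemisphere).  Deep gray
#: nuclei other than the thalamus take middle cerebral artery supply
#: (lenticulostriate); the thalamus is posterior-circulation supply.
TERRITORY_PARCELS: dict[str, tuple[str, ...]] = {
    "MCA": ("M1", "M2", "M3", "M4", "M5", "M6", "I", "C", "L", "IC"),
    "ACA": ("A1", "A2"),
    "PCA": ("P1", "P2", "T"),
}


@dataclass(frozen=True, order=True)
class RegionName:
    """One of the 30 scoring regions: a code and a hemisphere side."""

    side: str
    code: str

    def __post_init__(self) -> None:
        if self.code not in CODES:
            raise ValueError(
                f"unknown region code {self.code!r}; valid codes: {', '.join(CODES)}"
            )
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def category(self) -> str:
        return _CODE_TO_CATEGORY[self.code]

    @property
    def token(self) -> str:
        """Compact text form, e.g. ``L_M1`` or ``R_IC``."""
        return f"{self.side[0].upper()}_{self.code}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.token


def parse_region(token: str) -> RegionName:
    """Parse ``L_M1`` / ``R_IC`` style tokens (case-insensitive).

    Raises
    ------
    ValueError
        If the token does not name one of the 30 regions; the message lists
        the valid codes.
    """
    t = token.strip().upper()
    if "_" not in t:
        raise ValueError(
            f"cannot parse region token {token!r}; expected SIDE_CODE, e.g. L_M1 "
            f"with codes {', '.join(CODES)}"
        )
    side_c, code = t.split("_", 1)
    side = {"L": "left", "R": "right", "LEFT": "left", "RIGHT": "right"}.get(side_c)
    if side is None:
        raise ValueError(f"unknown side {side_c!r} in token {token!r} (use L or R)")
    return RegionName(side=side, code=code)


def parse_regions(tokens: Iterable[str] | str) -> frozenset[RegionName]:
    """Parse a comma-separated string or iterable of tokens into a region set."""
    if isinstance(tokens, str):
        tokens = [t for t in tokens.split(",") if t.strip()]
    return frozenset(parse_region(t) for t in tokens)


def region_table() -> list[dict[str, str]]:
    """Ordered listing of all 30 scoring regions.

    Returns one row per region (left hemisphere first, canonical code order)
    with keys ``token``, ``code``, ``side`` and ``category``.  Per hemisphere
    the categories partition into 7 cortical-MCA, 2 cortical-ACA,
    2 cortical-PCA and 4 subcortical regions.
    """
    rows = []
    for side in SIDES:
        for code in CODES:
            r = RegionName(side=side, code=code)
            rows.append(
                {"token": r.token, "code": code, "side": side, "category": r.category}
            )
    return rows


def all_regions() -> frozenset[RegionName]:
    return frozenset(RegionName(side=s, code=c) for s in SIDES for c in CODES)


def territory_regions(territory: str, side: str) -> frozenset[RegionName]:
    """Scoring regions supplied by an arterial territory on one side."""
    if territory not in TERRITORY_PARCELS:
        raise ValueError(
            f"unknown territory {territory!r}; valid: {sorted(TERRITORY_PARCELS)}"
        )
    return frozenset(RegionName(side=side, code=c) for c in TERRITORY_PARCELS[territory])
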