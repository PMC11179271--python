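"""Factorial management-technology grid and basin-crop study designs.

A *technology* in the integrated-assessment sense is a discrete way of
producing a crop.  Here it is the combination of four management
dimensions: water source (irrigated ``IRR`` / rainfed ``RFD``),
fertilizer rate (``hi`` / ``lo``), tillage (conventional ``C`` /
no-till ``N``) and cover crop (fallow ``F``, non-legume ``NonLgm``,
legume ``Lgm``).  With the default dimensions every crop has
2 x 2 x 2 x 3 = 24 technologies.

Technologies cross with *basin-crop systems* — (water basin, crop)
pairs with a cultivated area — to form the run list of a study design.
The reference design of 30 systems yields 720 runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import pandas as pd

#: Default crop vocabulary: the five major-crop groups of the study design.
DEFAULT_CROPS: tuple[str, ...] = (
    "corn",
    "soybean",
    "wheat",
    "other-grain",
    "fiber-crop",
)

#: Canonical dimension orders.  Enumeration varies the last dimension fastest.
DEFAULT_DIMENSIONS: dict[str, tuple[str, ...]] = {
    "water": ("IRR", "RFD"),
    "fertilizer": ("hi", "lo"),
    "tillage": ("C", "N"),
    "cover": ("F", "NonLgm", "Lgm"),
}

_CODE_SEP = "_"


@dataclass(frozen=True, order=True)
class ManagementTechnology:
    """One management-technology option for a crop.

    The canonical string code is ``crop_WATER_fert_TILL_COVER``, e.g.
    ``corn_IRR_hi_C_F``.  Crop names may contain hyphens but not
    underscores.
    """

    crop: str
    water: str
    fertilizer: str
    tillage: str
    cover: str

    @property
    def code(self) -> str:
        return _CODE_SEP.join(
            (self.crop, self.water, self.fertilizer, self.tillage, self.cover)
        )

    @classmethod
    def from_code(cls, code: str) -> "ManagementTechnology":
        parts = code.rsplit(_CODE_SEP, 4)
        if len(parts) != 5:
            raise ValueError(f"malformed technology code: {code!r}")
        return cls(*parts)

    @property
    def class_label(self) -> str:
        """Tillage x cover aggregation label (C_F, N_Lgm, ...)."""
        return f"{self.tillage}_{self.cover}"

    @property
    def is_conservation(self) -> bool:
        """True for any no-till and/or cover-crop technology."""
        return self.tillage == "N" or self.cover != "F"

    def reference(self) -> "ManagementTechnology":
        """The conventional-fallow counterpart (same crop/water/fertilizer)."""
        return replace(self, tillage="C", cover="F")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


@dataclass(frozen=True)
class BasinCropSystem:
    """A (water basin, crop) unit with its cultivated area.

    Basins are opaque identifiers; areas are in thousand km^2.
    """

    basin_id: str
    crop: str
    area: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(
                f"area must be positive for {self.basin_id}/{self.crop}, "
                f"got {self.area}"
            )


def enumerate_technologies(
    crop: str,
    dimensions: Mapping[str, Sequence[str]] | None = None,
    crops: Sequence[str] | None = None,
) -> list[ManagementTechnology]:
    """Enumerate the full factorial technology grid for one crop.

    Order is deterministic: water, then fertilizer, then tillage, then
    cover, each in its canonical dimension order, with the cover
    dimension varying fastest.

    Parameters
    ----------
    crop:
        Crop name; must be in *crops* (default: the five study crops).
    dimensions:
        Override one or more management dimensions, e.g. restrict
        ``cover`` to ``("F",)`` for a reduced grid.
    crops:
        Crop vocabulary accepted, for extensions beyond the defaults.
    """
    known = tuple(crops) if crops is not None else DEFAULT_CROPS
    if crop not in known:
        raise ValueError(f"unknown crop: {crop!r} (known: {', '.join(known)})")
    dims = dict(DEFAULT_DIMENSIONS)
    if dimensions:
        for key, values in dimensions.items():
            if key not in dims:
                raise ValueError(f"unknown management dimension: {key!r}")
            dims[key] = tuple(values)
    return [
        ManagementTechnology(crop, w, f, t, c)
        for w, f, t, c in product(
            dims["water"], dims["fertilizer"], dims["tillage"], dims["cover"]
        )
    ]


def enumerate_runs(
    systems: Sequence[BasinCropSystem],
    dimensions: Mapping[str, Sequence[str]] | None = None,
    crops: Sequence[str] | None = None,
) -> list[tuple[BasinCropSystem, ManagementTechnology]]:
    """Cross each basin-crop system with its crop's technology grid.

    The reference 30-system design yields 720 runs under the default
    dimensions.
    """
    if not systems:
        raise ValueError("systems must be non-empty")
    seen: dict[tuple[str, str], int] = {}
    for s in systems:
        seen[(s.basin_id, s.crop)] = seen.get((s.basin_id, s.crop), 0) + 1
    dupes = sorted(k for k, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate (basin_id, crop) pairs: {dupes}")
    runs: list[tuple[BasinCropSystem, ManagementTechnology]] = []
    for system in systems:
        for tech in enumerate_technologies(system.crop, dimensions, crops):
            runs.append((system, tech))
    return runs


# Cultivated area placeholders per crop (thousand km^2), split across basins.
# Totals are of the order of the US areas of the five crop groups.
_CROP_AREAS = {
    "corn": 330.0,
    "soybean": 330.0,
    "wheat": 150.0,
    "other-grain": 60.0,
    "fiber-crop": 40.0,
}


def default_study_design(
    basins_per_crop: int = 6,
    crops: Sequence[str] = DEFAULT_CROPS,
) -> list[BasinCropSystem]:
    """The reference study design: 30 basin-crop systems (6 per crop).

    Basin identifiers are synthetic placeholders ("B01", "B02", ...);
    the study this emulates selected real water basins from census
    geodata, which is out of scope here.  Areas are deterministic and
    sum to a plausible national total per crop, with a spread across
    basins so area-weighted aggregation is exercised.
    """
    systems: list[BasinCropSystem] = []
    for ci, crop in enumerate(crops):
        total = _CROP_AREAS.get(crop, 50.0)
        # Descending weights 6,5,...,1 scaled to the crop total.
        weights = list(range(basins_per_crop, 0, -1))
        wsum = sum(weights)
        for bi in range(basins_per_crop):
            systems.append(
                BasinCropSystem(
                    basin_id=f"B{ci * basins_per_crop + bi + 1:02d}",
                    crop=crop,
                    area=total * weights[bi] / wsum,
                )
            )
    return systems


def technologies_to_frame(techs: Sequence[ManagementTechnology]) -> pd.DataFrame:
    """Serialize a technology list to a table, one row per combination."""
    return pd.DataFrame(
        {
            "code": [t.code for t in techs],
            "crop": [t.crop for t in techs],
            "water": [t.water for t in techs],
            "fertilizer": [t.fertilizer for t in techs],
            "tillage": [t.tillage for t in techs],
            "cover": [t.cover for t in techs],
        }
    )


def runs_to_frame(
    runs: Sequence[tuple[BasinCropSystem, ManagementTechnology]]
) -> pd.DataFrame:
    """Serialize a run list (system x technology) to a table."""
    return pd.DataFrame(
        {
            "basin_id": [s.basin_id for s, _ in runs],
            "crop": [s.crop for s, _ in runs],
            "area": [s.area for s, _ in runs],
            "technology": [t.code for _, t in runs],
        }
    )
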