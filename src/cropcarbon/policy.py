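"""Carbon price pathway, annuity incentive and scenario definitions.

The price pathway starts at $183.50 per tCO2 in 2020 — a social-cost-of
-carbon anchor — and grows 5% per year through 2100.  Land uses that
increase and hold terrestrial carbon above a reference receive an
annuity proportional to the prevailing price; which pools are eligible
depends on the scenario:

- ``AC``   (All Carbon): all terrestrial carbon, vegetation and soil,
  on every land type.
- ``CC``   (Cropland Carbon): soil carbon on cropland only.
- ``REF``  (Reference with Protected Land): no incentive; 90% of the
  initial natural land is protected from conversion.
- ``CCPL`` (Cropland Carbon with Protected Land): cropland soil carbon
  incentive plus the 90% protection.

The annuitization rate ``rho`` (default 0.05/yr) converts a one-time
price per tCO2 into a recurring payment per tCO2 held per year; the
source analysis states that an annuity is paid without fixing its
formula, so rho is exposed in configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

CROPLAND = "cropland"

IncentiveScope = Literal["all-terrestrial", "cropland-soil", "none"]
Pool = Literal["soil", "vegetation"]


@dataclass(frozen=True)
class CarbonPricePath:
    """Exponential carbon price path in USD per tCO2, 2020-2100."""

    p0: float = 183.50
    growth: float = 0.05
    start: int = 2020
    end: int = 2100

    def __post_init__(self) -> None:
        if self.p0 <= 0:
            raise ValueError(f"p0 must be positive, got {self.p0}")
        if self.growth < 0:
            raise ValueError(f"growth must be >= 0, got {self.growth}")

    def price(self, year: int) -> float:
        """Price in ``year``: p0 * (1 + growth)^(year - start)."""
        if not (self.start <= year <= self.end):
            raise ValueError(
                f"year {year} outside price horizon "
                f"[{self.start}, {self.end}]"
            )
        return self.p0 * (1.0 + self.growth) ** (year - self.start)

    def scaled(self, factor: float) -> "CarbonPricePath":
        """A path with the starting price scaled by ``factor``."""
        return CarbonPricePath(self.p0 * factor, self.growth, self.start, self.end)


@dataclass(frozen=True)
class Scenario:
    """A named policy scenario."""

    name: str
    incentive_scope: IncentiveScope
    protected_fraction: float = 0.0
    price_path: CarbonPricePath | None = None
    rho: float = 0.05  # annuitization rate, per year

    def __post_init__(self) -> None:
        if not (0.0 <= self.protected_fraction <= 1.0):
            raise ValueError(
                f"protected_fraction must be in [0, 1], "
                f"got {self.protected_fraction}"
            )
        if self.incentive_scope != "none" and self.price_path is None:
            raise ValueError(
                f"scenario {self.name!r} has an incentive scope but no "
                "price path"
            )

    def pool_eligible(self, land_type: str, pool: str) -> bool:
        """Whether a (land type, carbon pool) earns the annuity."""
        if self.incentive_scope == "none" or self.price_path is None:
            return False
        if self.incentive_scope == "all-terrestrial":
            return True
        # cropland-soil: exclusively soil carbon on cropland
        return land_type == CROPLAND and pool == "soil"


def default_price_path() -> CarbonPricePath:
    return CarbonPricePath()


def scenario_presets() -> dict[str, Scenario]:
    """The four named scenarios, keyed by name."""
    price = default_price_path()
    return {
        "AC": Scenario("AC", "all-terrestrial", 0.0, price),
        "CC": Scenario("CC", "cropland-soil", 0.0, price),
        "REF": Scenario("REF", "none", 0.90, None),
        "CCPL": Scenario("CCPL", "cropland-soil", 0.90, price),
    }


def price(path: CarbonPricePath, year: int) -> float:
    """Carbon price (USD/tCO2) in a given year."""
    return path.price(year)


def annuity_payment(
    scenario: Scenario,
    year: int,
    land_type: str,
    pool: str,
    delta_c: float,
) -> float:
    """Annuity (USD/ha/yr) for carbon held above the reference level.

    ``delta_c`` is the carbon held above reference in tCO2/ha; only
    positive deltas in scope-eligible (land type, pool) combinations are
    paid: rho * price(year) * delta_c.
    """
    if not scenario.pool_eligible(land_type, pool):
        return 0.0
    if delta_c <= 0:
        return 0.0
    assert scenario.price_path is not None
    return scenario.rho * scenario.price_path.price(year) * delta_c
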