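"""Synthetic process-model trajectories with known ground truth.

Emulates the *statistical shape* of biogeochemical-model output — annual
crop yield (Mg/ha) and soil organic carbon (Mg C/ha) for 2016-2100 per
(basin, crop, technology) — so the downstream harmonization and
land-allocation stages can be tested against known parameters.  It does
not implement any soil biogeochemistry (carbon/nitrogen pools, spin-up,
weather forcing): SOC follows a saturating exponential toward a
technology-specific equilibrium, and yield is a flat technology effect
on a conventional-fallow base, both with optional Gaussian annual noise.

Ground truth for every run (true equilibrium SOC, true equilibrium
year, true yield effect) is emitted alongside the trajectories in a
ledger table so parameter recovery can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .technologies import (
    BasinCropSystem,
    ManagementTechnology,
    default_study_design,
    enumerate_runs,
)

#: Simulation horizon, annual grid.
START_YEAR = 2016
END_YEAR = 2100
YEARS = np.arange(START_YEAR, END_YEAR + 1)

#: Soil texture configuration echoed in study metadata.  A loam texture
#: is assumed for every run; it does not enter the emulator's math.
SOIL_TEXTURE = {"sand": 0.40, "silt": 0.40, "clay": 0.20}


@dataclass(frozen=True)
class TrajectoryParams:
    """Ground-truth parameters for one synthetic run.

    year_eq_true follows the 99%-of-asymptote convention: the SOC curve
    reaches 99% of its total change (soc_eq_true - soc_init) in that
    calendar year.
    """

    yield_base: float            # Mg/ha, conventional-fallow mean yield
    yield_effect: float          # fractional yield change vs conventional-fallow
    soc_init: float              # Mg C/ha at 2016
    soc_eq_true: float           # Mg C/ha, true equilibrium
    year_eq_true: int            # calendar year equilibrium effectively reached
    noise_sd_yield: float = 0.0  # Mg/ha
    noise_sd_soc: float = 0.0    # Mg C/ha
    seed: int = 0

    def __post_init__(self) -> None:
        if self.yield_base <= 0:
            raise ValueError(f"yield_base must be > 0, got {self.yield_base}")
        if self.soc_init <= 0:
            raise ValueError(f"soc_init must be > 0, got {self.soc_init}")
        if self.soc_eq_true < 0:
            raise ValueError(f"soc_eq_true must be >= 0, got {self.soc_eq_true}")
        if not (START_YEAR < self.year_eq_true <= END_YEAR):
            raise ValueError(
                f"year_eq_true must lie in ({START_YEAR}, {END_YEAR}], "
                f"got {self.year_eq_true}"
            )
        if self.noise_sd_yield < 0 or self.noise_sd_soc < 0:
            raise ValueError("noise standard deviations must be >= 0")


def generate_soc_trajectory(params: TrajectoryParams) -> pd.Series:
    """Annual SOC series 2016-2100 (Mg C/ha), indexed by year.

    S(t) = soc_init + (soc_eq_true - soc_init) * (1 - exp(-k (t - 2016)))
    with k set so that 99% of the asymptotic change is reached at
    ``year_eq_true``, plus N(0, noise_sd_soc) annual noise.  Negative
    values (possible only under large noise) are clipped at zero.
    """
    span = params.year_eq_true - START_YEAR
    k = -math.log(0.01) / span
    t = YEARS - START_YEAR
    soc = params.soc_init + (params.soc_eq_true - params.soc_init) * (
        1.0 - np.exp(-k * t)
    )
    if params.noise_sd_soc > 0:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
        soc = soc + rng.normal(0.0, params.noise_sd_soc, soc.size)
    return pd.Series(np.clip(soc, 0.0, None), index=YEARS, name="soc")


def generate_yield_trajectory(
    params: TrajectoryParams,
    trend: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.Series:
    """Annual yield series 2016-2100 (Mg/ha), indexed by year.

    Y(t) = yield_base * (1 + yield_effect) * g(t) + noise, where g is a
    background productivity trend (default: constant 1).  Negative
    values are clipped at zero.
    """
    g = trend(YEARS.astype(float)) if trend is not None else np.ones(YEARS.size)
    y = params.yield_base * (1.0 + params.yield_effect) * g
    y = np.broadcast_to(np.asarray(y, dtype=float), YEARS.shape).copy()
    if params.noise_sd_yield > 0:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
        y = y + rng.normal(0.0, params.noise_sd_yield, y.size)
    return pd.Series(np.clip(y, 0.0, None), index=YEARS, name="yield")


@dataclass(frozen=True)
class EffectEntry:
    """Technology-class effects relative to conventional-fallow.

    yield_effect and soc_uplift are fractional changes; years_to_eq is
    the true time from 2015 to SOC equilibrium (99% convention).
    """

    yield_effect: float
    soc_uplift: float
    years_to_eq: int


# Default effect table keyed by (crop, tillage, cover).  Anchors: wheat
# no-till + legume cover has the largest yield gain (+33%) and the
# largest SOC uplift (up to +80%); no-till corn gains far more SOC than
# no-till soybean; soybean yields drop slightly without a legume cover.
# Times to equilibrium are anchored at the IAM's 50-year default for
# no-till, shorter for conventional systems already near steady state,
# longer when cover-crop inputs keep accumulating carbon.
DEFAULT_EFFECTS: dict[tuple[str, str, str], EffectEntry] = {
    # corn: every option improves yield; no-till adds large SOC gains
    ("corn", "C", "F"): EffectEntry(0.00, 0.00, 40),
    ("corn", "C", "NonLgm"): EffectEntry(0.03, 0.08, 45),
    ("corn", "C", "Lgm"): EffectEntry(0.05, 0.10, 45),
    ("corn", "N", "F"): EffectEntry(0.08, 0.45, 50),
    ("corn", "N", "NonLgm"): EffectEntry(0.10, 0.55, 55),
    ("corn", "N", "Lgm"): EffectEntry(0.12, 0.60, 55),
    # soybean: small yield gain only with a legume cover; moderate SOC
    ("soybean", "C", "F"): EffectEntry(0.00, 0.00, 40),
    ("soybean", "C", "NonLgm"): EffectEntry(-0.03, 0.05, 45),
    ("soybean", "C", "Lgm"): EffectEntry(0.03, 0.08, 45),
    ("soybean", "N", "F"): EffectEntry(-0.02, 0.15, 50),
    ("soybean", "N", "NonLgm"): EffectEntry(-0.03, 0.18, 55),
    ("soybean", "N", "Lgm"): EffectEntry(0.04, 0.22, 55),
    # wheat: the headline case — +33% yield, +80% SOC for N_Lgm
    ("wheat", "C", "F"): EffectEntry(0.00, 0.00, 40),
    ("wheat", "C", "NonLgm"): EffectEntry(0.04, 0.08, 45),
    ("wheat", "C", "Lgm"): EffectEntry(0.10, 0.12, 45),
    ("wheat", "N", "F"): EffectEntry(0.12, 0.35, 50),
    ("wheat", "N", "NonLgm"): EffectEntry(0.20, 0.55, 55),
    ("wheat", "N", "Lgm"): EffectEntry(0.33, 0.80, 55),
    # other grain: wheat-like with slightly lower yield gains
    ("other-grain", "C", "F"): EffectEntry(0.00, 0.00, 40),
    ("other-grain", "C", "NonLgm"): EffectEntry(0.03, 0.07, 45),
    ("other-grain", "C", "Lgm"): EffectEntry(0.08, 0.10, 45),
    ("other-grain", "N", "F"): EffectEntry(0.10, 0.30, 50),
    ("other-grain", "N", "NonLgm"): EffectEntry(0.15, 0.50, 55),
    ("other-grain", "N", "Lgm"): EffectEntry(0.25, 0.70, 55),
    # fiber crop: modest effects throughout
    ("fiber-crop", "C", "F"): EffectEntry(0.00, 0.00, 40),
    ("fiber-crop", "C", "NonLgm"): EffectEntry(0.02, 0.05, 45),
    ("fiber-crop", "C", "Lgm"): EffectEntry(0.04, 0.08, 45),
    ("fiber-crop", "N", "F"): EffectEntry(0.05, 0.25, 50),
    ("fiber-crop", "N", "NonLgm"): EffectEntry(0.07, 0.30, 55),
    ("fiber-crop", "N", "Lgm"): EffectEntry(0.10, 0.40, 55),
}

#: Conventional-fallow base yields by crop, Mg/ha (order of US means).
BASE_YIELDS: dict[str, float] = {
    "corn": 10.5,
    "soybean": 3.3,
    "wheat": 3.1,
    "other-grain": 4.0,
    "fiber-crop": 2.3,
}

#: Multiplicative yield modifiers for the water and fertilizer dimensions.
WATER_YIELD_FACTOR = {"IRR": 1.15, "RFD": 1.00}
FERTILIZER_YIELD_FACTOR = {"hi": 1.00, "lo": 0.90}

#: Conventional-fallow equilibrium SOC gain over the 2016 stock (small
#: drift under consistent management).
CF_SOC_GAIN = 0.05


def _basin_soc_init(basin_index: int) -> float:
    """Deterministic 2016 SOC stock per basin, Mg C/ha (45-75 range)."""
    return 45.0 + 5.0 * (basin_index % 7)


@dataclass
class StudyData:
    """One synthetic study: trajectories, ground truth, baseline tables.

    trajectories: long table (basin_id, crop, area, technology, year,
    yield, soc).  truth: one row per run with the generator's true
    parameters.  baseline: per (basin_id, crop) the IAM-side defaults the
    harmonization scales to (baseline per-period yield change, default
    maximum soil-carbon density, default 50-year time to equilibrium).
    """

    trajectories: pd.DataFrame
    truth: pd.DataFrame
    baseline: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def trajectory(self, basin_id: str, technology: str) -> pd.DataFrame:
        sel = self.trajectories[
            (self.trajectories.basin_id == basin_id)
            & (self.trajectories.technology == technology)
        ]
        return sel.set_index("year")

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.trajectories.to_csv(out / "trajectories.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.baseline.to_csv(out / "baseline.csv", index=False)

    @classmethod
    def read(cls, indir) -> "StudyData":
        from pathlib import Path

        d = Path(indir)
        return cls(
            trajectories=pd.read_csv(d / "trajectories.csv"),
            truth=pd.read_csv(d / "truth.csv"),
            baseline=pd.read_csv(d / "baseline.csv"),
        )


#: Default per-5-year-period baseline (IAM-side) fractional yield change —
#: a modest intrinsic technology-improvement trend.
BASELINE_YIELD_CHANGE = 0.01
#: The IAM's default time to maximum soil-carbon density (years).
BASELINE_YEARS_TO_EQ = 50
#: Ratio of the IAM default maximum soil-carbon density to the
#: process-model conventional-fallow equilibrium (the scaling stage
#: reconciles the two; a value != 1 keeps the scaling non-trivial).
BASELINE_SOC_RATIO = 0.9


def generate_study(
    design: Sequence[BasinCropSystem] | None = None,
    effects: Mapping[tuple[str, str, str], EffectEntry] | None = None,
    seed: int = 0,
    noise_cv_yield: float = 0.05,
    noise_cv_soc: float = 0.01,
) -> StudyData:
    """Generate a full synthetic study with ground truth.

    Parameters
    ----------
    design:
        Basin-crop systems; default is the 30-system reference design
        (720 runs).
    effects:
        Effect table keyed by (crop, tillage, cover); every class
        present in the design must have an entry.
    seed:
        Base seed; per-run seeds are derived deterministically from it,
        so regeneration is bit-identical.
    noise_cv_yield, noise_cv_soc:
        Annual noise standard deviations as fractions of the run's base
        yield and initial SOC.  Set to 0 for noiseless closed forms.
    """
    design = list(design) if design is not None else default_study_design()
    effects = dict(effects) if effects is not None else DEFAULT_EFFECTS
    runs = enumerate_runs(design)

    basin_index = {b: i for i, b in enumerate(sorted({s.basin_id for s in design}))}

    rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    run_seed = {}
    for i, (system, tech) in enumerate(runs):
        run_seed[(system.basin_id, tech.code)] = (seed * 1_000_003 + i) % (2**31)

    for system, tech in runs:
        key = (tech.crop, tech.tillage, tech.cover)
        if key not in effects:
            raise KeyError(
                f"effect table has no entry for technology class {key}"
            )
        eff = effects[key]
        soc_init = _basin_soc_init(basin_index[system.basin_id])
        soc_eq_cf = soc_init * (1.0 + CF_SOC_GAIN)
        yield_base = (
            BASE_YIELDS[tech.crop]
            * WATER_YIELD_FACTOR[tech.water]
            * FERTILIZER_YIELD_FACTOR[tech.fertilizer]
        )
        params = TrajectoryParams(
            yield_base=yield_base,
            yield_effect=eff.yield_effect,
            soc_init=soc_init,
            soc_eq_true=soc_eq_cf * (1.0 + eff.soc_uplift),
            year_eq_true=2015 + eff.years_to_eq,
            noise_sd_yield=noise_cv_yield * yield_base,
            noise_sd_soc=noise_cv_soc * soc_init,
            seed=run_seed[(system.basin_id, tech.code)],
        )
        y = generate_yield_trajectory(params)
        s = generate_soc_trajectory(params)
        rows.append(
            pd.DataFrame(
                {
                    "basin_id": system.basin_id,
                    "crop": system.crop,
                    "area": system.area,
                    "technology": tech.code,
                    "year": YEARS,
                    "yield": y.to_numpy(),
                    "soc": s.to_numpy(),
                }
            )
        )
        truth_rows.append(
            {
                "basin_id": system.basin_id,
                "crop": system.crop,
                "technology": tech.code,
                "class": tech.class_label,
                "yield_base": params.yield_base,
                "yield_effect": params.yield_effect,
                "soc_init": params.soc_init,
                "soc_eq_true": params.soc_eq_true,
                "year_eq_true": params.year_eq_true,
                "seed": params.seed,
            }
        )

    baseline_rows = []
    for system in design:
        soc_init = _basin_soc_init(basin_index[system.basin_id])
        baseline_rows.append(
            {
                "basin_id": system.basin_id,
                "crop": system.crop,
                "yield_change": BASELINE_YIELD_CHANGE,
                "soc_max_default": soc_init * (1.0 + CF_SOC_GAIN) * BASELINE_SOC_RATIO,
                "years_to_eq_default": BASELINE_YEARS_TO_EQ,
            }
        )

    return StudyData(
        trajectories=pd.concat(rows, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        baseline=pd.DataFrame(baseline_rows),
        metadata={"seed": seed, "soil_texture": dict(SOIL_TEXTURE)},
    )
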