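"""Yield harmonization between annual process-model output and 5-year
integrated-assessment periods.

The IAM carries per-technology *yield change* — the fractional growth of
yield from one 5-year period to the next — while the process model
reports yields annually in Mg/ha.  Harmonization proceeds through a
dimensionless *yield index* anchored at 1.0 in 2015:

1. compound the baseline per-period yield changes into an index;
2. form the annual ratio of each technology's yield to its
   conventional-fallow reference, minus one (the technology delta);
3. average the annual deltas onto the 5-year period grid;
4. add the period deltas to the baseline index;
5. difference the modified index back into per-period yield changes
   for the new technologies.

Steps 1 and 5 are exact inverses, so a zero-delta technology reproduces
the baseline table bit-for-bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import StudyData
from .technologies import ManagementTechnology

#: Base year of the index and the 5-year period grid (period end-years).
BASE_YEAR = 2015
PERIOD_ENDS = tuple(range(2020, 2101, 5))


def build_yield_index(
    yield_change: pd.Series, base_year: int = BASE_YEAR
) -> pd.Series:
    """Compound per-period yield changes into an index anchored at 1.0.

    ``yield_change`` is indexed by period end-year (2020, 2025, ...);
    the result additionally carries the base year with value 1.0:
    index(p) = index(p-1) * (1 + yield_change(p)).
    """
    changes = yield_change.sort_index()
    if (changes <= -1).any():
        bad = changes.index[changes <= -1].tolist()
        raise ValueError(
            f"yield change <= -1 (non-positive yield) in periods {bad}"
        )
    values = np.concatenate(([1.0], np.cumprod(1.0 + changes.to_numpy())))
    return pd.Series(
        values, index=[base_year, *changes.index], name="yield_index"
    )


def index_to_yield_change(index: pd.Series) -> pd.Series:
    """Difference a yield index back into per-period fractional changes.

    Exact inverse of :func:`build_yield_index`; the base year is
    consumed, so the result is indexed by period end-years only.
    """
    idx = index.sort_index()
    if (idx <= 0).any():
        bad = idx.index[idx <= 0].tolist()
        raise ValueError(f"yield index must be positive, non-positive at {bad}")
    vals = idx.to_numpy()
    return pd.Series(
        vals[1:] / vals[:-1] - 1.0, index=idx.index[1:], name="yield_change"
    )


def period_average(
    annual: pd.Series,
    period_ends=PERIOD_ENDS,
    window: int = 5,
) -> pd.Series:
    """Average an annual series onto the period grid.

    The value at period end-year p is the arithmetic mean of the annual
    values in the calendar years p-window+1 .. p.  Every year of every
    window must be present.
    """
    out = {}
    for p in period_ends:
        years = range(p - window + 1, p + 1)
        missing = [y for y in years if y not in annual.index]
        if missing:
            raise ValueError(
                f"annual series missing years {missing} for period window "
                f"{p - window + 1}..{p}"
            )
        out[p] = float(annual.loc[list(years)].mean())
    return pd.Series(out, name=annual.name)


def compute_tech_delta(traj_yield: pd.Series, ref_yield: pd.Series) -> pd.Series:
    """Annual fractional yield delta of a technology vs its
    conventional-fallow reference: delta(t) = Y_tech(t)/Y_ref(t) - 1.

    Positive deltas mean the technology out-yields conventional-fallow.
    """
    ref = ref_yield.reindex(traj_yield.index)
    nonpos = ref.index[(ref <= 0) | ref.isna()]
    if len(nonpos):
        raise ValueError(
            f"reference yield non-positive or missing at years "
            f"{nonpos.tolist()[:5]}"
        )
    return (traj_yield / ref - 1.0).rename("delta")


def apply_delta_to_index(index: pd.Series, delta: pd.Series) -> pd.Series:
    """Add per-period deltas to a baseline index (base year untouched).

    The delta is applied additively, so a technology with a constant
    +0.33 delta lifts an all-ones index to 1.33 in every projected
    period.
    """
    periods = [p for p in index.index if p != BASE_YEAR]
    missing = [p for p in periods if p not in delta.index]
    if missing:
        raise ValueError(f"delta missing periods {missing}")
    out = index.copy()
    out.loc[periods] = index.loc[periods] + delta.loc[periods].to_numpy()
    if (out <= 0).any():
        bad = out.index[out <= 0].tolist()
        raise ValueError(f"modified index non-positive at periods {bad}")
    return out


def harmonize_yields(study: StudyData) -> pd.DataFrame:
    """Harmonize every technology in a study to per-period yield changes.

    Returns a long table (basin_id, crop, technology, period,
    yield_index, yield_change) where conventional-fallow technologies
    reproduce the baseline table exactly and the other technologies
    carry the process-model deltas on top of it.
    """
    baseline = study.baseline.set_index(["basin_id", "crop"])
    traj = study.trajectories

    # Reference (conventional-fallow) annual yields per basin/water/fert.
    ref_cache: dict[tuple[str, str], pd.Series] = {}
    for (basin, tech_code), group in traj.groupby(["basin_id", "technology"]):
        tech = ManagementTechnology.from_code(tech_code)
        if tech.tillage == "C" and tech.cover == "F":
            ref_cache[(basin, tech_code)] = group.set_index("year")["yield"]

    out_rows = []
    for (basin, tech_code), group in traj.groupby(["basin_id", "technology"]):
        tech = ManagementTechnology.from_code(tech_code)
        crop = tech.crop
        base = baseline.loc[(basin, crop)]
        base_changes = pd.Series(
            float(base["yield_change"]), index=list(PERIOD_ENDS)
        )
        index = build_yield_index(base_changes)

        ref = ref_cache[(basin, tech.reference().code)]
        delta_annual = compute_tech_delta(group.set_index("year")["yield"], ref)
        delta_period = period_average(delta_annual)
        modified = apply_delta_to_index(index, delta_period)
        changes = index_to_yield_change(modified)

        out_rows.append(
            pd.DataFrame(
                {
                    "basin_id": basin,
                    "crop": crop,
                    "technology": tech_code,
                    "period": modified.index,
                    "yield_index": modified.to_numpy(),
                    "yield_change": [np.nan, *changes.to_numpy()],
                }
            )
        )
    return pd.concat(out_rows, ignore_index=True)
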