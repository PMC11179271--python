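"""Soil-organic-carbon harmonization: smoothing, equilibrium detection
and scaling to the integrated-assessment baseline.

Each technology's annual SOC series is smoothed with a least-squares
cubic polynomial over the full 2016-2100 window.  The equilibrium point
is then read off the smoothed curve as either (rule 1) the earliest year
the fitted curve attains its maximum, when that maximum is interior to
the window, or (rule 2) the earliest year at which the fitted rate of
change — the cubic's analytic derivative sampled on the annual grid —
is closest to zero without being negative.  Trajectories whose fitted
rate is negative everywhere are flagged as declining and assigned the
first year.

Years-to-equilibrium is the equilibrium year minus 2015.  Finally, the
conventional-fallow equilibrium SOC is scaled to match the IAM's
default maximum soil-carbon density, and every other technology for the
same (basin, crop) is scaled by that same factor, so relative SOC
differences between technologies are preserved while the conventional
baseline agrees with the IAM exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthetic import START_YEAR, YEARS, StudyData
from .technologies import ManagementTechnology

ONSET_YEAR = 2015  # reference year for years-to-equilibrium


@dataclass(frozen=True)
class SmoothFit:
    """A fitted cubic and its values on the annual grid."""

    poly: np.polynomial.Polynomial
    fitted: pd.Series

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients in the standard (unscaled) basis, low to high."""
        return self.poly.convert().coef


@dataclass(frozen=True)
class SOCEquilibrium:
    """Equilibrium SOC and timing for one technology.

    soc_max is read from the smoothed curve at the equilibrium year;
    soc_max_scaled is populated by the scaling stage.  ``declining`` is
    set when the smoothed rate of change is negative over the whole
    window.
    """

    soc_max: float
    year_eq: int
    years_to_eq: int
    declining: bool = False
    soc_max_scaled: float | None = None


def smooth_soc(annual: pd.Series, degree: int = 3) -> SmoothFit:
    """Least-squares cubic fit of an annual SOC series.

    Requires at least degree+1 points.  Returns the polynomial and the
    fitted values on the input's annual grid.
    """
    if len(annual) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} annual points, got {len(annual)}"
        )
    years = annual.index.to_numpy(dtype=float)
    poly = np.polynomial.Polynomial.fit(years, annual.to_numpy(dtype=float), degree)
    fitted = pd.Series(poly(years), index=annual.index, name="soc_smoothed")
    return SmoothFit(poly=poly, fitted=fitted)


def find_equilibrium(fit: SmoothFit) -> SOCEquilibrium:
    """Locate the SOC equilibrium point on a smoothed trajectory.

    Rule 1: if the fitted curve attains its maximum at an interior grid
    year, the equilibrium year is the earliest such year.  Rule 2
    (fallback, used when the curve is still rising at the end of the
    window): the earliest grid year whose fitted rate of change is the
    smallest non-negative rate.  All-negative rates mark a declining
    trajectory (flagged, equilibrium at the first year).  Ties always
    break to the earliest year.
    """
    years = fit.fitted.index.to_numpy()
    values = fit.fitted.to_numpy(dtype=float)
    rates = fit.poly.deriv()(years.astype(float))

    if np.all(rates < 0):
        year_eq = int(years[0])
        return SOCEquilibrium(
            soc_max=float(values[0]),
            year_eq=year_eq,
            years_to_eq=year_eq - ONSET_YEAR,
            declining=True,
        )

    # Rule 1 — earliest attainment of the window maximum, if interior.
    vmax = values.max()
    tol = 1e-9 * max(1.0, abs(vmax))
    imax = int(np.argmax(values >= vmax - tol))
    if imax < len(years) - 1:
        year_eq = int(years[imax])
        soc_max = float(values[imax])
    else:
        # Rule 2 — smallest non-negative fitted rate, earliest on ties.
        nonneg = np.where(rates >= 0)[0]
        rmin = rates[nonneg].min()
        rtol = 1e-12 * max(1.0, abs(rmin))
        j = int(nonneg[np.argmax(rates[nonneg] <= rmin + rtol)])
        year_eq = int(years[j])
        soc_max = float(values[j])

    return SOCEquilibrium(
        soc_max=soc_max,
        year_eq=year_eq,
        years_to_eq=year_eq - ONSET_YEAR,
    )


def compute_scaling_factor(
    daycent_conv_soc_max: float, iam_default_soc_max: float
) -> float:
    """Factor aligning the process model's conventional equilibrium SOC
    with the IAM default density.

    Chosen so that ``daycent_conv_soc_max * factor == iam_default``:
    applying the factor to every technology leaves the conventional
    technology exactly on the IAM baseline.
    """
    if daycent_conv_soc_max <= 0 or iam_default_soc_max <= 0:
        raise ValueError(
            "equilibrium SOC values must be positive, got "
            f"{daycent_conv_soc_max} and {iam_default_soc_max}"
        )
    return iam_default_soc_max / daycent_conv_soc_max


def scale_technologies(
    equilibria: dict[str, SOCEquilibrium], factor: float
) -> dict[str, SOCEquilibrium]:
    """Apply one (basin, crop) scaling factor to all technologies.

    soc_max_scaled = soc_max * factor; years_to_eq is unchanged.
    """
    if factor <= 0:
        raise ValueError(f"scaling factor must be positive, got {factor}")
    return {
        code: replace(eq, soc_max_scaled=eq.soc_max * factor)
        for code, eq in equilibria.items()
    }


def _conventional_fallow_codes(codes) -> list[str]:
    out = []
    for code in codes:
        t = ManagementTechnology.from_code(code)
        if t.tillage == "C" and t.cover == "F":
            out.append(code)
    return out


def harmonize_soc(study: StudyData) -> pd.DataFrame:
    """Smooth, detect and scale SOC equilibria for a whole study.

    The conventional equilibrium used for the scaling factor is the
    area-less mean over the (up to four) conventional-fallow
    water x fertilizer variants of each (basin, crop).  Returns a long
    table (basin_id, crop, technology, soc_max, year_eq, years_to_eq,
    soc_max_scaled, scaling_factor, declining).
    """
    baseline = study.baseline.set_index(["basin_id", "crop"])
    rows = []
    for (basin, crop), group in study.trajectories.groupby(["basin_id", "crop"]):
        equilibria: dict[str, SOCEquilibrium] = {}
        for tech_code, tgroup in group.groupby("technology"):
            series = tgroup.set_index("year")["soc"]
            equilibria[tech_code] = find_equilibrium(smooth_soc(series))

        cf_codes = _conventional_fallow_codes(equilibria)
        if not cf_codes:
            raise ValueError(
                f"no conventional-fallow technology for {basin}/{crop}"
            )
        conv_soc_max = float(np.mean([equilibria[c].soc_max for c in cf_codes]))
        iam_default = float(baseline.loc[(basin, crop), "soc_max_default"])
        factor = compute_scaling_factor(conv_soc_max, iam_default)
        scaled = scale_technologies(equilibria, factor)

        for code, eq in sorted(scaled.items()):
            rows.append(
                {
                    "basin_id": basin,
                    "crop": crop,
                    "technology": code,
                    "soc_max": eq.soc_max,
                    "year_eq": eq.year_eq,
                    "years_to_eq": eq.years_to_eq,
                    "soc_max_scaled": eq.soc_max_scaled,
                    "scaling_factor": factor,
                    "declining": eq.declining,
                }
            )
    return pd.DataFrame(rows)
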