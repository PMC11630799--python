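"""Survival-curve extrapolation and time-to-inactivation under chronic dose.

The inactivation model is single-hit exponential (log-linear): the
surviving fraction after accumulated dose D is S(D) = 10**(-D/D10), where
D10 is the decimal-reduction dose.  A population is considered inactivated
once S reaches 1e-6, i.e. at an accumulated dose of 6 * D10.  Dividing
that threshold dose by a scenario's weighted dose rate gives the time to
inactivation for a dormant, non-repairing population.  Metabolically
active cells performing continuous DNA repair would survive longer; every
result carries that assumption explicitly.

Published 1e-6 thresholds for three reference organisms spanning the
radiotolerance range ship as constants: E. coli 1000 Gy, B. subtilis
8400 Gy, D. radiodurans 15000 Gy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dose import DEFAULT_WEIGHTS, DoseScenario, ParticleWeights, effective_dose_rate
from .errors import DataError, NonInactivatingCurveError, ValidationError

__all__ = [
    "SurvivalCurve",
    "LogLinearFit",
    "InactivationThreshold",
    "SurvivalResult",
    "PUBLISHED_THRESHOLDS",
    "INACTIVATION_FRACTION",
    "fit_loglinear",
    "dose_to_fraction",
    "threshold_from_curve",
    "time_to_inactivation",
    "survival_table",
    "read_survival_curves",
    "write_survival_table",
    "format_years",
]

#: Surviving fraction at which a population counts as inactivated.
INACTIVATION_FRACTION = 1e-6


@dataclass(frozen=True)
class SurvivalCurve:
    """Dose-response points for one organism.

    ``points`` are (dose_gy, surviving_fraction) pairs with strictly
    increasing doses and surviving fractions in (0, 1].  A leading (0, 1)
    point represents the unirradiated control.
    """

    organism: str
    points: tuple[tuple[float, float], ...]

    def __init__(self, organism: str, points: Iterable[Sequence[float]]):
        object.__setattr__(self, "organism", organism)
        object.__setattr__(
            self, "points", tuple((float(d), float(s)) for d, s in points)
        )
        if len(self.points) < 2:
            raise ValidationError(
                f"survival curve for {organism!r} needs >= 2 points, got {len(self.points)}"
            )
        doses = [d for d, _ in self.points]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValidationError(
                f"survival curve for {organism!r}: doses must be strictly increasing"
            )
        if doses[0] < 0:
            raise ValidationError(f"survival curve for {organism!r}: doses must be >= 0")
        for d, s in self.points:
            if not (0.0 < s <= 1.0):
                raise ValidationError(
                    f"survival curve for {organism!r}: surviving fraction at "
                    f"dose {d} must be in (0, 1], got {s!r}"
                )

    @property
    def starts_at_control(self) -> bool:
        """True when the first point is the unirradiated control (0, 1)."""
        d0, s0 = self.points[0]
        return d0 == 0.0 and s0 == 1.0


@dataclass(frozen=True)
class LogLinearFit:
    """Least-squares log-linear fit of a survival curve.

    ``slope`` is b in log10(S) = a + b*D (per Gy, negative for an
    inactivating curve); ``d10 = -1/b``.  ``r_squared`` is the coefficient
    of determination of the log-linear fit, a shoulder diagnostic: values
    well below 1 indicate the single-hit model is a poor description.
    """

    organism: str
    d10: float
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def fit_loglinear(curve: SurvivalCurve) -> LogLinearFit:
    """Fit log10(S) vs dose and return the decimal-reduction dose D10.

    The intercept is fixed at 0 when the curve starts at the (0, 1)
    control point (published curves are usually normalised to the
    unirradiated control); otherwise it is free.  Raises
    :class:`NonInactivatingCurveError` when survival does not decrease
    with dose (fitted slope >= 0).
    """
    d = np.array([p[0] for p in curve.points], dtype=float)
    y = np.log10([p[1] for p in curve.points])
    if not np.any(y < 0):
        raise NonInactivatingCurveError(
            f"curve for {curve.organism!r} has no point with surviving fraction < 1"
        )
    if curve.starts_at_control:
        slope = float(d @ y / (d @ d))
        intercept = 0.0
    else:
        if len(d) < 2:
            raise DataError(f"curve for {curve.organism!r}: fewer than 2 usable points")
        slope_arr, intercept_arr = np.polyfit(d, y, 1)
        slope, intercept = float(slope_arr), float(intercept_arr)
    if slope >= 0:
        raise NonInactivatingCurveError(
            f"curve for {curve.organism!r} is non-inactivating "
            f"(fitted slope {slope:.3g} >= 0 per Gy)"
        )
    resid = y - (intercept + slope * d)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) @ (y - y.mean())))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LogLinearFit(
        organism=curve.organism,
        d10=-1.0 / slope,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        n_points=len(curve.points),
    )


def dose_to_fraction(d10: float, target_fraction: float) -> float:
    """Accumulated dose (Gy) at which survival falls to ``target_fraction``.

    D = D10 * log10(1/target); for the 1e-6 threshold this is 6 * D10.
    """
    if d10 <= 0:
        raise ValidationError(f"d10 must be > 0, got {d10!r}")
    if not (0.0 < target_fraction <= 1.0):
        raise ValidationError(
            f"target_fraction must be in (0, 1], got {target_fraction!r}"
        )
    return d10 * math.log10(1.0 / target_fraction)


@dataclass(frozen=True)
class InactivationThreshold:
    """Accumulated dose (Gy) at which a 1e-6 population fraction remains."""

    organism: str
    threshold_dose_gy: float
    source: str = "fitted"  # "fitted" | "published"

    def __post_init__(self) -> None:
        if self.threshold_dose_gy <= 0:
            raise ValidationError(
                f"threshold_dose_gy must be > 0, got {self.threshold_dose_gy!r}"
            )
        if self.source not in ("fitted", "published"):
            raise ValidationError(
                f"source must be 'fitted' or 'published', got {self.source!r}"
            )


#: Published 1e-6 survival thresholds for the three reference organisms,
#: ordered from radio-sensitive to radio-resistant.
PUBLISHED_THRESHOLDS: tuple[InactivationThreshold, ...] = (
    InactivationThreshold("E. coli", 1000.0, source="published"),
    InactivationThreshold("B. subtilis", 8400.0, source="published"),
    InactivationThreshold("D. radiodurans", 15000.0, source="published"),
)


def threshold_from_curve(
    curve: SurvivalCurve, target_fraction: float = INACTIVATION_FRACTION
) -> InactivationThreshold:
    """Fit a curve and convert its D10 to an inactivation threshold."""
    fit = fit_loglinear(curve)
    return InactivationThreshold(
        organism=curve.organism,
        threshold_dose_gy=dose_to_fraction(fit.d10, target_fraction),
        source="fitted",
    )


@dataclass(frozen=True)
class SurvivalResult:
    """Time to inactivation of one organism under one scenario.

    ``time_to_inactivation_yr`` is ``math.inf`` when the effective dose
    rate is zero (the "never" sentinel).  Times assume dormant,
    non-repairing cells; actively repairing populations would last longer.
    """

    organism: str
    scenario: str
    time_to_inactivation_yr: float
    effective_dose_rate: float  # Gy-eq / yr
    assumes_dormant_cells: bool = field(default=True)

    @property
    def never(self) -> bool:
        return math.isinf(self.time_to_inactivation_yr)


def time_to_inactivation(
    threshold: InactivationThreshold,
    scenario: DoseScenario,
    weights: ParticleWeights = DEFAULT_WEIGHTS,
) -> SurvivalResult:
    """Years until the accumulated weighted dose reaches the threshold.

    t = D_thresh / D_eff.  A zero effective rate yields the "never"
    sentinel (infinite time), not an error.
    """
    rate = effective_dose_rate(scenario, weights)
    time = math.inf if rate == 0 else threshold.threshold_dose_gy / rate
    return SurvivalResult(
        organism=threshold.organism,
        scenario=scenario.name,
        time_to_inactivation_yr=time,
        effective_dose_rate=rate,
    )


def survival_table(
    thresholds: Sequence[InactivationThreshold],
    scenarios: Sequence[DoseScenario],
    weights: ParticleWeights = DEFAULT_WEIGHTS,
) -> pd.DataFrame:
    """One row per (organism, scenario) pair.

    Columns: organism, scenario, effective_rate_gy_eq_per_yr, years.
    Duplicate organism or scenario labels are rejected — they would make
    rows un-attributable.
    """
    if not thresholds or not scenarios:
        raise ValidationError("thresholds and scenarios must both be non-empty")
    organisms = [t.organism for t in thresholds]
    if len(set(organisms)) != len(organisms):
        raise ValidationError(f"duplicate organism labels in thresholds: {organisms}")
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate scenario labels: {names}")
    rows = []
    for scenario in scenarios:
        for threshold in thresholds:
            res = time_to_inactivation(threshold, scenario, weights)
            rows.append(
                {
                    "organism": res.organism,
                    "scenario": res.scenario,
                    "effective_rate_gy_eq_per_yr": res.effective_dose_rate,
                    "years": res.time_to_inactivation_yr,
                }
            )
    return pd.DataFrame(rows)


def format_years(years: float) -> str:
    """Report a survival time at 2 significant figures ('never' for inf)."""
    if math.isinf(years):
        return "never"
    if years == 0:
        return "0"
    rounded = float(f"{years:.2g}")
    if rounded >= 1:
        return f"{rounded:,.0f}".replace(",", " ")
    return f"{rounded:g}"


def read_survival_curves(path: str | Path) -> list[SurvivalCurve]:
    """Read curves from a delimited file (organism, dose_gy, surviving_fraction)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    expected = {"organism", "dose_gy", "surviving_fraction"}
    if not expected.issubset(df.columns):
        raise DataError(
            f"{path}: survival-curve file needs columns {sorted(expected)}, "
            f"got {list(df.columns)}"
        )
    curves = []
    for organism, grp in df.groupby("organism", sort=False):
        grp = grp.sort_values("dose_gy")
        curves.append(
            SurvivalCurve(str(organism), list(zip(grp["dose_gy"], grp["surviving_fraction"])))
        )
    return curves


def write_survival_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a survival table as a single-header TSV."""
    table.to_csv(path, sep="\t", index=False)
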