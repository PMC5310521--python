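"""Pairwise comparison of aggregate dose-survival curves by area under the curve.

Two curves for the same experimental conditions but different dosing vehicles
are compared by the area under the piecewise-linear survival curve (AUC) over
a common dose window; the vehicle with the larger area kept more animals
alive over that window, i.e. is the less toxic vehicle.  Because the two
curves rarely share a dose grid, three alignment strategies are supported:

* ``INTERPOLATION_ONLY`` - the window is the intersection of the two dose
  ranges, with survival at the window boundaries obtained by linear
  interpolation.
* ``EXTRAPOLATE_HIGH`` - additionally, a curve whose survival has already
  fallen to zero at its own top dose is extended flat (at zero) up to the
  other curve's top dose: once every animal dies, still-higher doses cannot
  rescue them.
* ``EXTRAPOLATE_HIGH_LOW`` - additionally, a curve whose survival at its own
  lowest recorded dose is 100% is extended flat (at one) down to the other
  curve's lowest dose.

All areas are computed on the LINEAR dose axis (log axes in survival plots
are cosmetic only).  The relative AUC difference is expressed in percent of
the larger area, so it is symmetric in the two curves and bounded by 100.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .records_io import AggregateCurve, ConditionKey

__all__ = [
    "Strategy",
    "Verdict",
    "ComparisonVerdict",
    "IncomparableCurves",
    "interpolate_at",
    "extend",
    "common_window",
    "auc",
    "compare_pair",
    "compare_conditions",
]

#: Tolerance on "survival exactly 0 / exactly 1" when testing extrapolation
#: eligibility (aggregated means are floats).
EDGE_TOL = 1e-9

#: Relative AUC difference below which two areas count as equal under the
#: no-threshold (strict sign) regime, in percent.
EQUAL_RTOL_PCT = 1e-7


class Strategy(enum.Enum):
    """How the two dose windows are aligned before computing areas."""

    INTERPOLATION_ONLY = "interp"
    EXTRAPOLATE_HIGH = "high"
    EXTRAPOLATE_HIGH_LOW = "highlow"

    @classmethod
    def parse(cls, value: "str | Strategy") -> "Strategy":
        if isinstance(value, cls):
            return value
        aliases = {
            "interp": cls.INTERPOLATION_ONLY,
            "interpolation_only": cls.INTERPOLATION_ONLY,
            "high": cls.EXTRAPOLATE_HIGH,
            "extrapolate_high": cls.EXTRAPOLATE_HIGH,
            "highlow": cls.EXTRAPOLATE_HIGH_LOW,
            "extrapolate_high_low": cls.EXTRAPOLATE_HIGH_LOW,
        }
        try:
            return aliases[str(value).lower()]
        except KeyError:
            raise ValueError(f"unknown strategy {value!r}") from None


ALL_STRATEGIES = (
    Strategy.INTERPOLATION_ONLY,
    Strategy.EXTRAPOLATE_HIGH,
    Strategy.EXTRAPOLATE_HIGH_LOW,
)


class Verdict(enum.Enum):
    A_LESS_TOXIC = "a_less_toxic"
    B_LESS_TOXIC = "b_less_toxic"
    NO_DIFFERENCE = "no_difference"


class IncomparableCurves(Exception):
    """The pair cannot be compared (no dose overlap, or a single-point curve)."""


@dataclass(frozen=True)
class ComparisonVerdict:
    """Outcome of one AUC comparison between two vehicles under one condition key."""

    key: ConditionKey
    vehicle_a: str
    vehicle_b: str
    strategy: Strategy
    threshold_pct: float
    auc_a: float
    auc_b: float
    rel_diff: float  # percent of the larger area
    verdict: Verdict
    window: tuple[float, float]


def interpolate_at(curve: AggregateCurve, dose: float) -> float:
    """Survival at ``dose`` by linear interpolation on the linear dose axis.

    ``dose`` must lie within the curve's recorded dose range; an exact grid
    dose returns that point's survival.
    """
    if not (curve.min_dose <= dose <= curve.max_dose):
        raise ValueError(
            f"dose {dose} outside curve range [{curve.min_dose}, {curve.max_dose}]"
        )
    return float(np.interp(dose, curve.doses, curve.survivals))


def extend(curve: AggregateCurve, other_curve: AggregateCurve, strategy: Strategy) -> AggregateCurve:
    """Flat extrapolation of ``curve`` towards ``other_curve``'s dose range.

    High-dose end (EXTRAPOLATE_HIGH and EXTRAPOLATE_HIGH_LOW): if survival at
    the curve's own top dose is zero and the other curve reaches higher doses,
    a point (other max dose, 0) is appended.  Low-dose end
    (EXTRAPOLATE_HIGH_LOW only): if survival at the curve's own lowest dose is
    100% and the other curve starts lower, a point (other min dose, 1) is
    prepended.  Ineligible curves pass through unchanged, as does any curve
    under INTERPOLATION_ONLY.  Survival inside the original range is never
    altered.
    """
    strategy = Strategy.parse(strategy)
    if strategy is Strategy.INTERPOLATION_ONLY:
        return curve
    points = list(curve.points)
    if (
        abs(points[-1][1]) <= EDGE_TOL
        and other_curve.max_dose > curve.max_dose
    ):
        points.append((other_curve.max_dose, points[-1][1]))
    if (
        strategy is Strategy.EXTRAPOLATE_HIGH_LOW
        and abs(points[0][1] - 1.0) <= EDGE_TOL
        and other_curve.min_dose < curve.min_dose
    ):
        points.insert(0, (other_curve.min_dose, points[0][1]))
    if len(points) == len(curve.points):
        return curve
    return AggregateCurve(
        key=curve.key, vehicle=curve.vehicle, points=tuple(points), n_experiments=curve.n_experiments
    )


def common_window(curve_a: AggregateCurve, curve_b: AggregateCurve) -> tuple[float, float]:
    """Intersection of the two (possibly extended) dose ranges.

    Raises :class:`IncomparableCurves` when the ranges do not overlap with
    positive width.
    """
    lo = max(curve_a.min_dose, curve_b.min_dose)
    hi = min(curve_a.max_dose, curve_b.max_dose)
    if not lo < hi:
        raise IncomparableCurves(
            f"dose ranges [{curve_a.min_dose}, {curve_a.max_dose}] and "
            f"[{curve_b.min_dose}, {curve_b.max_dose}] do not overlap"
        )
    return lo, hi


def auc(curve: AggregateCurve, lo: float, hi: float) -> float:
    """Trapezoidal area of the piecewise-linear survival curve over [lo, hi].

    Boundary survivals are obtained by :func:`interpolate_at`; interior grid
    points inside the window contribute their recorded values, so the result
    is exact for the piecewise-linear curve.
    """
    if not lo < hi:
        raise ValueError(f"window [{lo}, {hi}] is empty")
    if not (curve.min_dose <= lo and hi <= curve.max_dose):
        raise ValueError(
            f"window [{lo}, {hi}] not spanned by curve range "
            f"[{curve.min_dose}, {curve.max_dose}]"
        )
    doses = np.asarray(curve.doses)
    inside = (doses > lo) & (doses < hi)
    xs = np.concatenate(([lo], doses[inside], [hi]))
    ys = np.interp(xs, curve.doses, curve.survivals)
    return float(np.trapezoid(ys, xs))


def compare_pair(
    curve_a: AggregateCurve,
    curve_b: AggregateCurve,
    strategy: Strategy | str,
    threshold_pct: float,
) -> ComparisonVerdict:
    """Compare two vehicles' curves for one condition key.

    The relative difference is ``100 * |auc_a - auc_b| / max(auc_a, auc_b)``.
    With ``threshold_pct > 0`` the larger-area vehicle is called less toxic
    when the relative difference reaches the threshold; with
    ``threshold_pct == 0`` a strict sign comparison is used (areas equal
    within :data:`EQUAL_RTOL_PCT` percent count as no difference).  Both
    areas zero is no difference.  Single-point curves and non-overlapping
    windows raise :class:`IncomparableCurves`.
    """
    strategy = Strategy.parse(strategy)
    if threshold_pct < 0:
        raise ValueError("threshold_pct must be non-negative")
    if curve_a.key != curve_b.key:
        raise ValueError("curves to compare must share a condition key")
    if len(curve_a.points) < 2 or len(curve_b.points) < 2:
        raise IncomparableCurves("single-point curve has no area")
    ext_a = extend(curve_a, curve_b, strategy)
    ext_b = extend(curve_b, curve_a, strategy)
    lo, hi = common_window(ext_a, ext_b)
    auc_a = auc(ext_a, lo, hi)
    auc_b = auc(ext_b, lo, hi)
    larger = max(auc_a, auc_b)
    if larger == 0.0:
        rel_diff = 0.0
    else:
        rel_diff = 100.0 * abs(auc_a - auc_b) / larger
    if larger == 0.0:
        verdict = Verdict.NO_DIFFERENCE
    elif threshold_pct == 0:
        if rel_diff < EQUAL_RTOL_PCT:
            verdict = Verdict.NO_DIFFERENCE
        else:
            verdict = Verdict.A_LESS_TOXIC if auc_a > auc_b else Verdict.B_LESS_TOXIC
    elif rel_diff >= threshold_pct:
        verdict = Verdict.A_LESS_TOXIC if auc_a > auc_b else Verdict.B_LESS_TOXIC
    else:
        verdict = Verdict.NO_DIFFERENCE
    return ComparisonVerdict(
        key=curve_a.key,
        vehicle_a=curve_a.vehicle,
        vehicle_b=curve_b.vehicle,
        strategy=strategy,
        threshold_pct=float(threshold_pct),
        auc_a=auc_a,
        auc_b=auc_b,
        rel_diff=rel_diff,
        verdict=verdict,
        window=(lo, hi),
    )


def compare_conditions(
    curves: list[AggregateCurve],
    vehicle_a: str,
    vehicle_b: str,
    strategy: Strategy | str,
    threshold_pct: float,
) -> tuple[list[ComparisonVerdict], list[tuple[ConditionKey, str]]]:
    """Compare every condition key tested in both vehicles.

    Returns the comparison verdicts plus a log of skipped keys (single-point
    curve or non-overlapping dose ranges) with the reason.
    """
    by_key: dict[ConditionKey, dict[str, AggregateCurve]] = {}
    for curve in curves:
        by_key.setdefault(curve.key, {})[curve.vehicle] = curve
    verdicts: list[ComparisonVerdict] = []
    skipped: list[tuple[ConditionKey, str]] = []
    for key, vehicles in by_key.items():
        if vehicle_a not in vehicles or vehicle_b not in vehicles:
            continue
        try:
            verdicts.append(
                compare_pair(vehicles[vehicle_a], vehicles[vehicle_b], strategy, threshold_pct)
            )
        except IncomparableCurves as exc:
            skipped.append((key, str(exc)))
    return verdicts, skipped
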