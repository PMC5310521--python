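"""Schema, tabular I/O and aggregation for dose-survival toxicity records.

One :class:`ToxicityRecord` is a single dose group of a single experiment:
a compound given at one dose in one vehicle to a set of animals, with the
fraction surviving on the assessment day.  Experiments are comparable only
when every field of their :class:`ConditionKey` matches exactly; comparable
replicate experiments in the same vehicle are averaged into an
:class:`AggregateCurve` (mean survival per dose, doses strictly increasing).

Survival is stored internally as a fraction in [0, 1]; percent input
(``"83%"`` or bare values above 1) is converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "ConditionKey",
    "ToxicityRecord",
    "AggregateCurve",
    "RowIssue",
    "ReadResult",
    "SchemaError",
    "RowValidationError",
    "read_records",
    "write_records",
    "write_rejects",
    "aggregate",
    "write_curves",
    "read_curves",
]

#: Canonical column names of the records table.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "compound_id",
    "route",
    "species",
    "n_injections",
    "injection_interval",
    "first_injection_day",
    "n_repetitions",
    "assessment_day",
    "restart_days",
    "vehicle",
    "screener",
    "experiment_id",
    "dose_mg_per_kg_per_injection",
    "survival",
    "n_animals",
)

#: Relative tolerance under which two doses count as the same dose level.
DOSE_RTOL = 1e-9


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class RowValidationError(ValueError):
    """A row violates a record invariant (non-positive dose, survival out of range...)."""


@dataclass(frozen=True, order=True)
class ConditionKey:
    """The experimental factors that must match exactly for two experiments to be comparable.

    ``restart_days`` is the (possibly empty) ascending tuple of days on which
    the dosing schedule was restarted.
    """

    compound_id: str
    route: str
    species: str
    n_injections: int
    injection_interval: int
    first_injection_day: int
    n_repetitions: int
    assessment_day: int
    restart_days: tuple[int, ...] = ()


@dataclass(frozen=True)
class ToxicityRecord:
    """One dose group of one experiment.

    dose is in mg per kg per injection; survival is the fraction of the
    ``n_animals`` animals alive on the assessment day.
    """

    key: ConditionKey
    vehicle: str
    screener: str
    experiment_id: str
    dose: float
    survival: float
    n_animals: int

    def validate(self) -> None:
        if not self.dose > 0:
            raise RowValidationError(f"dose must be positive, got {self.dose}")
        if not (0.0 <= self.survival <= 1.0):
            raise RowValidationError(f"survival must be in [0, 1], got {self.survival}")
        if self.n_animals < 1:
            raise RowValidationError(f"n_animals must be positive, got {self.n_animals}")
        # survival x n_animals must be an integer up to percent-rounding of survival
        deaths = self.survival * self.n_animals
        tol = 0.005 * self.n_animals + 1e-9
        if abs(deaths - round(deaths)) > tol:
            raise RowValidationError(
                f"survival {self.survival} x n_animals {self.n_animals} "
                "is not within rounding of an animal count"
            )


@dataclass(frozen=True)
class AggregateCurve:
    """Mean dose-survival curve for one (condition key, vehicle) group.

    ``points`` are (dose, mean survival fraction) sorted by strictly
    increasing dose; ``n_experiments`` counts the distinct experiments merged.
    """

    key: ConditionKey
    vehicle: str
    points: tuple[tuple[float, float], ...]
    n_experiments: int = 1

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("a curve needs at least one point")
        doses = [d for d, _ in self.points]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if any(not (0.0 <= s <= 1.0) for _, s in self.points):
            raise ValueError("survival values must lie in [0, 1]")

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(d for d, _ in self.points)

    @property
    def survivals(self) -> tuple[float, ...]:
        return tuple(s for _, s in self.points)

    @property
    def min_dose(self) -> float:
        return self.points[0][0]

    @property
    def max_dose(self) -> float:
        return self.points[-1][0]


@dataclass(frozen=True)
class RowIssue:
    """A rejected input row and the reason it failed validation."""

    row: int
    reason: str


@dataclass
class ReadResult:
    """Validated records plus the rows that were rejected (reported, not dropped silently)."""

    records: list[ToxicityRecord]
    rejected: list[RowIssue] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_survival(value) -> float:
    """Survival as a fraction; accepts '83%', 83 (percent) or 0.83 (fraction)."""
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            return float(text[:-1]) / 100.0
        value = float(text)
    value = float(value)
    if value > 1.0:
        return value / 100.0
    return value


def _parse_restart_days(value) -> tuple[int, ...]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ()
    text = str(value).strip()
    if not text:
        return ()
    return tuple(sorted(int(part) for part in text.split(";")))


def _format_restart_days(days: Sequence[int]) -> str:
    return ";".join(str(d) for d in sorted(days))


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_records(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ReadResult:
    """Read a CSV/TSV of toxicity records.

    Parameters
    ----------
    path:
        CSV (or TSV, by extension or explicit ``sep``) with the columns of
        :data:`CANONICAL_COLUMNS`.
    dialect:
        Optional map from canonical column name to the header actually used
        in the file, for tables with foreign headers.

    Returns
    -------
    ReadResult
        ``records`` in file order; ``rejected`` lists rows that failed an
        invariant together with the reason.

    Raises
    ------
    SchemaError
        If a required column is absent (named in the message).
    """
    dialect = dict(dialect or {})
    frame = _read_table(path, sep)
    colmap = {name: dialect.get(name, name) for name in CANONICAL_COLUMNS}
    missing = [actual for actual in colmap.values() if actual not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[ToxicityRecord] = []
    rejected: list[RowIssue] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        get = lambda name: row[colmap[name]]  # noqa: E731 - row accessor
        try:
            key = ConditionKey(
                compound_id=str(get("compound_id")),
                route=str(get("route")),
                species=str(get("species")),
                n_injections=int(get("n_injections")),
                injection_interval=int(get("injection_interval")),
                first_injection_day=int(get("first_injection_day")),
                n_repetitions=int(get("n_repetitions")),
                assessment_day=int(str(get("assessment_day")).removeprefix("day")),
                restart_days=_parse_restart_days(get("restart_days")),
            )
            record = ToxicityRecord(
                key=key,
                vehicle=str(get("vehicle")),
                screener=str(get("screener")),
                experiment_id=str(get("experiment_id")),
                dose=float(get("dose_mg_per_kg_per_injection")),
                survival=_parse_survival(get("survival")),
                n_animals=int(get("n_animals")),
            )
            record.validate()
        except (RowValidationError, ValueError) as exc:
            rejected.append(RowIssue(row=i, reason=str(exc)))
            continue
        records.append(record)
    return ReadResult(records=records, rejected=rejected)


def _record_row(record: ToxicityRecord) -> dict:
    key = record.key
    return {
        "compound_id": key.compound_id,
        "route": key.route,
        "species": key.species,
        "n_injections": key.n_injections,
        "injection_interval": key.injection_interval,
        "first_injection_day": key.first_injection_day,
        "n_repetitions": key.n_repetitions,
        "assessment_day": key.assessment_day,
        "restart_days": _format_restart_days(key.restart_days),
        "vehicle": record.vehicle,
        "screener": record.screener,
        "experiment_id": record.experiment_id,
        "dose_mg_per_kg_per_injection": repr(record.dose),
        "survival": repr(record.survival),
        "n_animals": record.n_animals,
    }


def write_records(records: Iterable[ToxicityRecord], path: str | Path) -> None:
    """Write records as CSV with the canonical columns (floats kept lossless)."""
    frame = pd.DataFrame([_record_row(r) for r in records], columns=list(CANONICAL_COLUMNS))
    frame.to_csv(path, index=False)


def write_rejects(rejected: Iterable[RowIssue], path: str | Path) -> None:
    """Sidecar report of rejected rows: row index and reason."""
    frame = pd.DataFrame(
        [{"row": issue.row, "reason": issue.reason} for issue in rejected],
        columns=["row", "reason"],
    )
    frame.to_csv(path, index=False)


def _merge_dose_levels(values: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Mean survival per dose level, doses equal within DOSE_RTOL merged."""
    values = sorted(values, key=lambda p: p[0])
    merged: list[tuple[float, list[float]]] = []
    for dose, survival in values:
        if merged and dose <= merged[-1][0] * (1.0 + DOSE_RTOL):
            merged[-1][1].append(survival)
        else:
            merged.append((dose, [survival]))
    return [(dose, sum(group) / len(group)) for dose, group in merged]


def aggregate(records: Iterable[ToxicityRecord]) -> list[AggregateCurve]:
    """Combine replicate experiments into mean dose-survival curves.

    Records are grouped by (condition key, vehicle); within a group the
    survival at each distinct dose level is the arithmetic mean over every
    record observed at that dose (the union of the groups' dose levels is
    kept - each dose averages only the experiments that tested it).
    Group order follows first appearance in the input.
    """
    groups: dict[tuple[ConditionKey, str], list[ToxicityRecord]] = {}
    for record in records:
        groups.setdefault((record.key, record.vehicle), []).append(record)
    curves = []
    for (key, vehicle), members in groups.items():
        points = _merge_dose_levels([(r.dose, r.survival) for r in members])
        n_experiments = len({r.experiment_id for r in members})
        curves.append(
            AggregateCurve(key=key, vehicle=vehicle, points=tuple(points), n_experiments=n_experiments)
        )
    return curves


_CURVE_COLUMNS = (
    "compound_id",
    "route",
    "species",
    "n_injections",
    "injection_interval",
    "first_injection_day",
    "n_repetitions",
    "assessment_day",
    "restart_days",
    "vehicle",
    "n_experiments",
    "dose_mg_per_kg_per_injection",
    "survival",
)


def write_curves(curves: Iterable[AggregateCurve], path: str | Path) -> None:
    """Write aggregate curves as CSV, one row per curve point (lossless floats)."""
    rows = []
    for curve in curves:
        key = curve.key
        for dose, survival in curve.points:
            rows.append(
                {
                    "compound_id": key.compound_id,
                    "route": key.route,
                    "species": key.species,
                    "n_injections": key.n_injections,
                    "injection_interval": key.injection_interval,
                    "first_injection_day": key.first_injection_day,
                    "n_repetitions": key.n_repetitions,
                    "assessment_day": key.assessment_day,
                    "restart_days": _format_restart_days(key.restart_days),
                    "vehicle": curve.vehicle,
                    "n_experiments": curve.n_experiments,
                    "dose_mg_per_kg_per_injection": repr(dose),
                    "survival": repr(survival),
                }
            )
    pd.DataFrame(rows, columns=list(_CURVE_COLUMNS)).to_csv(path, index=False)


def read_curves(path: str | Path) -> list[AggregateCurve]:
    """Read curves written by :func:`write_curves` (lossless round trip)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    groups: dict[tuple[ConditionKey, str, int], list[tuple[float, float]]] = {}
    for _, row in frame.iterrows():
        key = ConditionKey(
            compound_id=row["compound_id"],
            route=row["route"],
            species=row["species"],
            n_injections=int(row["n_injections"]),
            injection_interval=int(row["injection_interval"]),
            first_injection_day=int(row["first_injection_day"]),
            n_repetitions=int(row["n_repetitions"]),
            assessment_day=int(row["assessment_day"]),
            restart_days=_parse_restart_days(row["restart_days"]),
        )
        group = (key, row["vehicle"], int(row["n_experiments"]))
        groups.setdefault(group, []).append(
            (float(row["dose_mg_per_kg_per_injection"]), float(row["survival"]))
        )
    return [
        AggregateCurve(key=key, vehicle=vehicle, points=tuple(points), n_experiments=n_exp)
        for (key, vehicle, n_exp), points in groups.items()
    ]
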