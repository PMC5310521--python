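"""Roll per-condition AUC verdicts up to compound labels and modelling datasets.

A compound tested under several comparable-condition sets can behave
consistently (always less toxic in one vehicle, or never different) or not:

* *equivocal* - a preference for one vehicle in some condition sets but no
  difference in others;
* *contradictory* - opposite preferences in different condition sets.

Only compounds with a consistent preference enter the modelling dataset
(label 0 = less toxic in the first vehicle of the pair, 1 = the second);
equivocal, contradictory and no-preference compounds are excluded but
counted.  Datasets below a minimum size (50 compounds by default) are
rejected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curves import ComparisonVerdict, Strategy, Verdict

__all__ = [
    "CompoundLabel",
    "CompoundVerdict",
    "DatasetCounts",
    "ModellingDataset",
    "DatasetTooSmall",
    "UndefinedBias",
    "compound_verdict",
    "roll_up",
    "build_dataset",
    "class_bias",
]


class CompoundLabel(enum.Enum):
    PREFERS_A = "prefers_a"
    PREFERS_B = "prefers_b"
    NO_PREFERENCE = "no_preference"
    EQUIVOCAL = "equivocal"
    CONTRADICTORY = "contradictory"


@dataclass(frozen=True)
class CompoundVerdict:
    """Compound-level label over all of its per-condition comparisons."""

    compound_id: str
    vehicle_a: str
    vehicle_b: str
    n_conditions: int
    label: CompoundLabel


class DatasetTooSmall(Exception):
    """Fewer labelled compounds than the minimum dataset size."""

    def __init__(self, n: int, min_n: int, counts: "DatasetCounts | None" = None):
        super().__init__(f"only {n} labelled compounds (< {min_n} required)")
        self.n = n
        self.min_n = min_n
        self.counts = counts


class UndefinedBias(Exception):
    """Class bias is undefined because one class is empty."""


def compound_verdict(condition_verdicts: Sequence[ComparisonVerdict]) -> CompoundVerdict:
    """Deterministic compound label from the multiset of condition verdicts.

    Contradictory if both directions occur (this takes precedence even when
    no-difference verdicts are also present); equivocal if exactly one
    direction occurs together with at least one no-difference; a plain
    preference if only one direction occurs; no preference otherwise.
    """
    if not condition_verdicts:
        raise ValueError("need at least one condition verdict")
    compound_ids = {v.key.compound_id for v in condition_verdicts}
    if len(compound_ids) != 1:
        raise ValueError(f"verdicts mix compound ids: {sorted(compound_ids)}")
    pairs = {(v.vehicle_a, v.vehicle_b) for v in condition_verdicts}
    if len(pairs) != 1:
        raise ValueError(f"verdicts mix vehicle pairs: {sorted(pairs)}")
    outcomes = {v.verdict for v in condition_verdicts}
    has_a = Verdict.A_LESS_TOXIC in outcomes
    has_b = Verdict.B_LESS_TOXIC in outcomes
    has_nd = Verdict.NO_DIFFERENCE in outcomes
    if has_a and has_b:
        label = CompoundLabel.CONTRADICTORY
    elif (has_a or has_b) and has_nd:
        label = CompoundLabel.EQUIVOCAL
    elif has_a:
        label = CompoundLabel.PREFERS_A
    elif has_b:
        label = CompoundLabel.PREFERS_B
    else:
        label = CompoundLabel.NO_PREFERENCE
    (vehicle_a, vehicle_b) = next(iter(pairs))
    return CompoundVerdict(
        compound_id=next(iter(compound_ids)),
        vehicle_a=vehicle_a,
        vehicle_b=vehicle_b,
        n_conditions=len(condition_verdicts),
        label=label,
    )


def roll_up(comparisons: Iterable[ComparisonVerdict]) -> list[CompoundVerdict]:
    """Group condition verdicts by compound and label each compound."""
    by_compound: dict[str, list[ComparisonVerdict]] = {}
    for verdict in comparisons:
        by_compound.setdefault(verdict.key.compound_id, []).append(verdict)
    return [compound_verdict(group) for group in by_compound.values()]


@dataclass(frozen=True)
class DatasetCounts:
    n_a: int
    n_b: int
    n_equivocal: int
    n_contradictory: int
    n_no_preference: int


@dataclass
class ModellingDataset:
    """Labelled compounds with their descriptors, ready for classification.

    Label encoding: 0 = less toxic in ``vehicle_a``, 1 = less toxic in
    ``vehicle_b`` (pair order as given by the caller).
    """

    vehicle_a: str
    vehicle_b: str
    strategy: Strategy | None
    threshold_pct: float | None
    compound_ids: list[str]
    labels: np.ndarray
    features: np.ndarray
    feature_names: list[str]
    counts: DatasetCounts

    def __len__(self) -> int:
        return len(self.compound_ids)


def build_dataset(
    verdicts: Iterable[CompoundVerdict],
    features: pd.DataFrame,
    min_n: int = 50,
    strategy: Strategy | None = None,
    threshold_pct: float | None = None,
) -> ModellingDataset:
    """Assemble a modelling dataset from compound verdicts and a descriptor table.

    Only prefers-a / prefers-b compounds are kept; the excluded equivocal,
    contradictory and no-preference counts are recorded.  Raises
    :class:`DatasetTooSmall` below ``min_n`` labelled compounds and
    ``KeyError`` naming any labelled compound missing from ``features``.
    """
    verdicts = list(verdicts)
    pairs = {(v.vehicle_a, v.vehicle_b) for v in verdicts}
    if len(pairs) > 1:
        raise ValueError(f"verdicts mix vehicle pairs: {sorted(pairs)}")
    tally = {label: 0 for label in CompoundLabel}
    kept: list[CompoundVerdict] = []
    for verdict in verdicts:
        tally[verdict.label] += 1
        if verdict.label in (CompoundLabel.PREFERS_A, CompoundLabel.PREFERS_B):
            kept.append(verdict)
    counts = DatasetCounts(
        n_a=tally[CompoundLabel.PREFERS_A],
        n_b=tally[CompoundLabel.PREFERS_B],
        n_equivocal=tally[CompoundLabel.EQUIVOCAL],
        n_contradictory=tally[CompoundLabel.CONTRADICTORY],
        n_no_preference=tally[CompoundLabel.NO_PREFERENCE],
    )
    if len(kept) < min_n:
        raise DatasetTooSmall(len(kept), min_n, counts)
    missing = [v.compound_id for v in kept if v.compound_id not in features.index]
    if missing:
        raise KeyError(f"no descriptor row for compound(s): {', '.join(missing)}")
    vehicle_a, vehicle_b = pairs.pop() if pairs else ("", "")
    compound_ids = [v.compound_id for v in kept]
    labels = np.array(
        [0 if v.label is CompoundLabel.PREFERS_A else 1 for v in kept], dtype=np.int64
    )
    matrix = features.loc[compound_ids].to_numpy(dtype=float)
    return ModellingDataset(
        vehicle_a=vehicle_a,
        vehicle_b=vehicle_b,
        strategy=strategy,
        threshold_pct=threshold_pct,
        compound_ids=compound_ids,
        labels=labels,
        features=matrix,
        feature_names=list(features.columns),
        counts=counts,
    )


def class_bias(dataset: ModellingDataset) -> float:
    """Class imbalance max(n_a, n_b) / min(n_a, n_b) (>= 1)."""
    n_a, n_b = dataset.counts.n_a, dataset.counts.n_b
    if n_a == 0 or n_b == 0:
        raise UndefinedBias("one class is empty; bias is undefined")
    return max(n_a, n_b) / min(n_a, n_b)


def verdicts_to_frame(verdicts: Iterable[CompoundVerdict], strategy=None, threshold_pct=None) -> pd.DataFrame:
    """Labels table: compound_id, pair, strategy, threshold, verdict, n_conditions."""
    strategy_name = Strategy.parse(strategy).value if strategy is not None else ""
    rows = [
        {
            "compound_id": v.compound_id,
            "vehicle_a": v.vehicle_a,
            "vehicle_b": v.vehicle_b,
            "strategy": strategy_name,
            "threshold": "" if threshold_pct is None else threshold_pct,
            "verdict": v.label.value,
            "n_conditions": v.n_conditions,
        }
        for v in verdicts
    ]
    return pd.DataFrame(
        rows,
        columns=["compound_id", "vehicle_a", "vehicle_b", "strategy", "threshold", "verdict", "n_conditions"],
    )
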