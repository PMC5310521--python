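"""Generator of screening-like dose-survival records with known vehicle effects.

The generator emulates the structure of the historical NCI anticancer
screening records: each compound is tested in each vehicle in one or more
replicate experiments, every experiment uses a geometric dose grid (grids
may differ between experiments), each dose group holds 6-10 animals, and the
observed survival fraction is a binomial draw around an underlying logistic
dose-survival model

    s(d) = 1 - 1 / (1 + exp(-slope * (ln d - ln LD50)))

so survival is ~100% well below the median lethal dose LD50 and ~0% well
above it.  Dose-vehicle interaction enters as a shift of ln LD50: binary
structural keys ("causal features") move a compound's LD50 up or down in a
specific vehicle, so the vehicle with the larger shifted LD50 is, by
construction, the less toxic one.  Apparent non-monotonicity from individual
animal deaths arises naturally from the binomial draw; no extra noise term
is added.

Every run returns a :class:`TruthTable` naming the true less-toxic vehicle
for every compound and vehicle pair, so downstream stages have a recoverable
target.  ``null_mode`` zeroes all shifts, giving data with no vehicle effect
at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records_io import ConditionKey, ToxicityRecord

__all__ = ["SimulationConfig", "TruthTable", "default_vehicle_shift", "simulate", "degrade_to_equivocal"]

#: ln-LD50 differences below this count as "no true effect".
_TRUTH_TOL = 1e-12


def default_vehicle_shift(
    vehicles: Sequence[str],
    n_causal: int = 10,
    magnitude: float = 2.0,
) -> dict[int, dict[str, float]]:
    """Two groups of causal structural keys with opposite-direction shifts.

    The first half of the keys raises the second vehicle's ln LD50 by
    ``magnitude`` (less toxic in that vehicle), the second half lowers it.
    """
    if len(vehicles) < 2:
        raise ValueError("need at least two vehicles")
    target = vehicles[1]
    shift: dict[int, dict[str, float]] = {}
    for f in range(n_causal):
        sign = 1.0 if f < n_causal // 2 else -1.0
        shift[f] = {target: sign * magnitude}
    return shift


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the screening data being emulated where it constrains
    them (6-10 animals per dose group, a handful of geometric dose levels
    per experiment, replicate experiments within and across screeners) and
    otherwise use values a dose-range-finding screen would consider
    realistic (LD50s spread over one decade around a few hundred mg/kg,
    fairly steep logistic slope).
    """

    n_compounds: int = 120
    n_features: int = 100
    vehicles: tuple[str, ...] = ("saline", "CMC")
    #: feature index -> vehicle -> ln-LD50 shift; None = default_vehicle_shift
    vehicle_shift: Mapping[int, Mapping[str, float]] | None = None
    effect_fraction: float = 0.5
    slope: float = 4.0
    base_log_ld50_range: tuple[float, float] = (math.log(100.0), math.log(1000.0))
    doses_per_experiment: int = 5
    #: natural-log width of the geometric dose grid
    dose_span_log: float = 5.0
    animals_per_dose: tuple[int, int] = (6, 10)
    replicates_per_condition: tuple[int, int] = (1, 3)
    n_screeners: int = 4
    #: probability a causal key of the chosen group is carried (>=1 enforced)
    carrier_probability: float = 0.6
    null_mode: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 1 or self.n_features < 1:
            raise ValueError("n_compounds and n_features must be positive")
        if len(self.vehicles) < 2:
            raise ValueError("at least 2 vehicles required")
        if not (0.0 <= self.effect_fraction <= 1.0):
            raise ValueError("effect_fraction must be in [0, 1]")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.doses_per_experiment < 2:
            raise ValueError("doses_per_experiment must be >= 2")
        lo, hi = self.animals_per_dose
        if not (1 <= lo <= hi):
            raise ValueError("animals_per_dose range is empty")
        rlo, rhi = self.replicates_per_condition
        if not (1 <= rlo <= rhi):
            raise ValueError("replicates_per_condition range is empty")
        if self.base_log_ld50_range[0] > self.base_log_ld50_range[1]:
            raise ValueError("base_log_ld50_range is empty")

    def resolved_shift(self) -> dict[int, dict[str, float]]:
        if self.vehicle_shift is None:
            return default_vehicle_shift(self.vehicles)
        resolved = {int(f): dict(m) for f, m in self.vehicle_shift.items()}
        for f in resolved:
            if not (0 <= f < self.n_features):
                raise ValueError(f"causal feature index {f} outside feature matrix")
        return resolved


@dataclass
class TruthTable:
    """Ground truth for one simulation.

    ``less_toxic`` maps (compound_id, (vehicle_a, vehicle_b)) - pair in
    configured vehicle order - to the true less-toxic vehicle name or
    ``"none"``.  Carries enough of the generative state (config, per-compound
    baseline LD50s) for follow-up record generation such as
    :func:`degrade_to_equivocal`.
    """

    config: SimulationConfig
    features: pd.DataFrame  # compounds x binary structural keys
    less_toxic: dict[tuple[str, tuple[str, str]], str]
    log_ld50: dict[str, dict[str, float]]  # compound -> vehicle -> ln LD50
    base_log_ld50: dict[str, float]
    is_effect: dict[str, bool] = field(default_factory=dict)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.features.index)

    def effect_compounds(self) -> list[str]:
        """Compounds with a true vehicle preference for at least one pair."""
        out = []
        for cid in self.compound_ids:
            if any(
                self.less_toxic[(cid, pair)] != "none"
                for pair in _vehicle_pairs(self.config.vehicles)
            ):
                out.append(cid)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"compound_id": cid, "vehicle_a": a, "vehicle_b": b, "less_toxic": v}
            for (cid, (a, b)), v in self.less_toxic.items()
        ]
        return pd.DataFrame(rows, columns=["compound_id", "vehicle_a", "vehicle_b", "less_toxic"])


def _vehicle_pairs(vehicles: Sequence[str]) -> list[tuple[str, str]]:
    return [(a, b) for i, a in enumerate(vehicles) for b in vehicles[i + 1 :]]


def _group_causal_features(shift: Mapping[int, Mapping[str, float]]) -> list[list[int]]:
    """Causal features grouped by identical shift maps (shifts never cancel)."""
    groups: dict[frozenset, list[int]] = {}
    for f in sorted(shift):
        signature = frozenset(shift[f].items())
        groups.setdefault(signature, []).append(f)
    return list(groups.values())


def _survival_probability(log_dose: float, log_ld50: float, slope: float) -> float:
    return 1.0 - 1.0 / (1.0 + math.exp(-slope * (log_dose - log_ld50)))


def _base_key(compound_id: str, species: str = "mouse") -> ConditionKey:
    return ConditionKey(
        compound_id=compound_id,
        route="ip",
        species=species,
        n_injections=1,
        injection_interval=1,
        first_injection_day=1,
        n_repetitions=1,
        assessment_day=7,
        restart_days=(),
    )


def _compound_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    # per-compound substream: stable under changes of n_compounds
    return np.random.default_rng([seed, stream, index])


def _experiment_records(
    rng: np.random.Generator,
    key: ConditionKey,
    vehicle: str,
    experiment_id: str,
    screener: str,
    log_ld50: float,
    grid_center_log: float,
    config: SimulationConfig,
) -> list[ToxicityRecord]:
    n_doses = config.doses_per_experiment
    jitter = rng.uniform(-0.3, 0.3)
    log_doses = np.linspace(
        grid_center_log + jitter - config.dose_span_log / 2.0,
        grid_center_log + jitter + config.dose_span_log / 2.0,
        n_doses,
    )
    lo, hi = config.animals_per_dose
    records = []
    for log_dose in log_doses:
        n_animals = int(rng.integers(lo, hi + 1))
        p = _survival_probability(float(log_dose), log_ld50, config.slope)
        survived = int(rng.binomial(n_animals, p))
        records.append(
            ToxicityRecord(
                key=key,
                vehicle=vehicle,
                screener=screener,
                experiment_id=experiment_id,
                dose=float(math.exp(log_dose)),
                survival=survived / n_animals,
                n_animals=n_animals,
            )
        )
    return records


def simulate(config: SimulationConfig) -> tuple[list[ToxicityRecord], TruthTable, pd.DataFrame]:
    """Generate records, ground truth and the compound x feature matrix.

    Deterministic given ``config.seed``; compound substreams are independent,
    so the first k compounds are identical for any ``n_compounds >= k``.
    """
    config.validate()
    shift = config.resolved_shift()
    groups = _group_causal_features(shift)
    causal = sorted(shift)
    pairs = _vehicle_pairs(config.vehicles)

    feature_names = [f"f{j:03d}" for j in range(config.n_features)]
    feature_rows = []
    compound_ids = []
    records: list[ToxicityRecord] = []
    less_toxic: dict[tuple[str, tuple[str, str]], str] = {}
    log_ld50_map: dict[str, dict[str, float]] = {}
    base_map: dict[str, float] = {}
    is_effect: dict[str, bool] = {}

    for i in range(config.n_compounds):
        rng = _compound_rng(config.seed, i)
        cid = f"C{i:05d}"
        compound_ids.append(cid)

        features = (rng.random(config.n_features) < 0.5).astype(np.int64)
        features[causal] = 0
        effect = bool(rng.random() < config.effect_fraction) and bool(groups)
        if effect:
            group = groups[int(rng.integers(len(groups)))]
            carry = rng.random(len(group)) < config.carrier_probability
            if not carry.any():
                carry[int(rng.integers(len(group)))] = True
            for f, c in zip(group, carry):
                features[f] = int(c)
        is_effect[cid] = effect
        feature_rows.append(features)

        base = float(rng.uniform(*config.base_log_ld50_range))
        base_map[cid] = base
        per_vehicle = {}
        for vehicle in config.vehicles:
            delta = 0.0
            if not config.null_mode:
                delta = sum(shift[f].get(vehicle, 0.0) for f in causal if features[f])
            per_vehicle[vehicle] = base + delta
        log_ld50_map[cid] = per_vehicle

        for a, b in pairs:
            diff = per_vehicle[a] - per_vehicle[b]
            if diff > _TRUTH_TOL:
                less_toxic[(cid, (a, b))] = a  # larger LD50 = survives higher doses
            elif diff < -_TRUTH_TOL:
                less_toxic[(cid, (a, b))] = b
            else:
                less_toxic[(cid, (a, b))] = "none"

        key = _base_key(cid)
        grid_center = float(np.mean(list(per_vehicle.values())))
        rlo, rhi = config.replicates_per_condition
        for vehicle in config.vehicles:
            n_rep = int(rng.integers(rlo, rhi + 1))
            for r in range(n_rep):
                screener = f"s{int(rng.integers(config.n_screeners)) + 1:02d}"
                records.extend(
                    _experiment_records(
                        rng,
                        key,
                        vehicle,
                        experiment_id=f"{cid}-{vehicle}-{r}",
                        screener=screener,
                        log_ld50=per_vehicle[vehicle],
                        grid_center_log=grid_center,
                        config=config,
                    )
                )

    features_df = pd.DataFrame(
        np.vstack(feature_rows), index=pd.Index(compound_ids, name="compound_id"), columns=feature_names
    )
    truth = TruthTable(
        config=replace(config),
        features=features_df,
        less_toxic=less_toxic,
        log_ld50=log_ld50_map,
        base_log_ld50=base_map,
        is_effect=is_effect,
    )
    return records, truth, features_df


def degrade_to_equivocal(
    records: list[ToxicityRecord],
    truth: TruthTable,
    fraction: float,
    rng: np.random.Generator,
) -> list[ToxicityRecord]:
    """Add a vehicle-effect-free extra condition for a fraction of effect compounds.

    The chosen compounds get one additional set of experiments per vehicle
    under a different host species in which the configured shift does not
    apply (ln LD50 = compound baseline for every vehicle), so a consistent
    preference in the original condition becomes a preference-plus-no-
    difference pattern: downstream labelling should call these compounds
    equivocal.  Input records are returned unchanged plus the extra ones.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    config = truth.config
    effect_ids = sorted(truth.effect_compounds())
    n_chosen = int(round(fraction * len(effect_ids)))
    chosen = sorted(rng.choice(effect_ids, size=n_chosen, replace=False)) if n_chosen else []
    extra: list[ToxicityRecord] = []
    for cid in chosen:
        key = _base_key(cid, species="hamster")
        base = truth.base_log_ld50[cid]
        for vehicle in config.vehicles:
            extra.extend(
                _experiment_records(
                    rng,
                    key,
                    vehicle,
                    experiment_id=f"{cid}-{vehicle}-alt0",
                    screener="s01",
                    log_ld50=base,
                    grid_center_log=base,
                    config=config,
                )
            )
    return list(records) + extra
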