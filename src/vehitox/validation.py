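"""Significance testing of classifiers by y-randomisation (target shuffling).

The question asked of every model is: could this performance have arisen
with no relationship between descriptors and vehicle preference?  The null
is built by shuffling the 0/1 labels, re-selecting descriptors against the
shuffled labels and re-running the identical cross-validation protocol.

* DT/PLS: 300 null models by default; the real model is significant when
  its balanced accuracy sits in or above the 99th percentile of the null
  distribution, measured by the empirical cumulative distribution function
  (weak inequality, so ties with the 99th-percentile null count).
* RF: the real model is a distribution of 100 balanced accuracies (one per
  forest seed); it is compared with 100 null distributions (100
  y-randomisations, each modelled 100 times).  Two statistics are computed
  per null distribution: the histogram overlap coefficient (shared 20-bin
  partition of [0, 1]; sum of per-bin minimum proportions; 1 for identical
  samples, 0 for disjoint ones) and the exceedance probability that a
  random real value beats a random null value (exhaustive over all pairs,
  ties counted half; a standard error accompanies each estimate).  The RF
  collection is significant when the mean exceedance probability is above
  80%; the overlap is recorded but never used as the criterion by itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .labelling import ModellingDataset
from .modelling import ModelConfig, ModelRun, cross_validate, rf_distribution

__all__ = [
    "ValidationReport",
    "y_randomise",
    "null_distribution",
    "ecdf_percentile",
    "overlap",
    "exceedance_probability",
    "validate_dt_pls",
    "validate_rf",
]

PERCENTILE_CUTOFF = 99.0
PROBABILITY_CUTOFF = 0.80
DEFAULT_BINS = 20


@dataclass
class ValidationReport:
    """Real-vs-null performance statistics and the resulting significance call."""

    method: str
    significant: bool
    n_random: int
    #: DT/PLS: real balanced accuracy and its percentile in the null ECDF
    real_statistic: float | None = None
    null_statistics: list[float] = field(default_factory=list)
    percentile: float | None = None
    percentile_cutoff: float = PERCENTILE_CUTOFF
    #: RF: per-null-distribution overlaps and exceedance probabilities
    real_distribution: list[float] = field(default_factory=list)
    overlaps: list[float] = field(default_factory=list)
    exceedance_probabilities: list[float] = field(default_factory=list)
    exceedance_standard_errors: list[float] = field(default_factory=list)
    mean_exceedance_probability: float | None = None
    sd_exceedance_probability: float | None = None
    mean_overlap: float | None = None
    sd_overlap: float | None = None
    probability_cutoff: float = PROBABILITY_CUTOFF
    n_bins: int = DEFAULT_BINS

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "significant": self.significant,
            "n_random": self.n_random,
            "real_statistic": self.real_statistic,
            "percentile": self.percentile,
            "percentile_cutoff": self.percentile_cutoff,
            "null_statistics": list(self.null_statistics),
            "real_distribution": list(self.real_distribution),
            "overlaps": list(self.overlaps),
            "exceedance_probabilities": list(self.exceedance_probabilities),
            "exceedance_standard_errors": list(self.exceedance_standard_errors),
            "mean_exceedance_probability": self.mean_exceedance_probability,
            "sd_exceedance_probability": self.sd_exceedance_probability,
            "mean_overlap": self.mean_overlap,
            "sd_overlap": self.sd_overlap,
            "probability_cutoff": self.probability_cutoff,
            "n_bins": self.n_bins,
        }


def y_randomise(labels: Sequence[int], rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of the label multiset (class counts conserved)."""
    return rng.permutation(np.asarray(labels))


def null_distribution(
    dataset: ModellingDataset,
    config: ModelConfig,
    n_random: int = 300,
) -> np.ndarray:
    """Balanced accuracies of ``n_random`` y-randomised models.

    Every null model re-selects descriptors against its shuffled labels
    (inside each training fold) and runs the identical CV protocol.
    """
    out = np.empty(n_random)
    for i in range(n_random):
        rng = np.random.default_rng([config.seed, 404, i])
        shuffled = y_randomise(dataset.labels, rng)
        out[i] = cross_validate(dataset, config, labels=shuffled).balanced_accuracy
    return out


def ecdf_percentile(value: float, distribution: Sequence[float]) -> float:
    """ECDF percentile of ``value``: 100 x proportion of the distribution <= value."""
    distribution = np.asarray(distribution)
    if distribution.size == 0:
        raise ValueError("empty distribution")
    return float(100.0 * np.mean(distribution <= value))


def overlap(
    dist_real: Sequence[float],
    dist_null: Sequence[float],
    n_bins: int = DEFAULT_BINS,
) -> float:
    """Histogram overlap coefficient on a shared equal-width partition of [0, 1].

    Each distribution is binned into per-bin proportions (summing to one);
    the overlap is the sum of per-bin minima: 1 for identical samples, 0 for
    samples occupying disjoint bins.
    """
    a = np.asarray(dist_real, dtype=float)
    b = np.asarray(dist_null, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both distributions must be non-empty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    pa = np.histogram(np.clip(a, 0.0, 1.0), bins=edges)[0] / a.size
    pb = np.histogram(np.clip(b, 0.0, 1.0), bins=edges)[0] / b.size
    return float(np.minimum(pa, pb).sum())


def exceedance_probability(
    dist_real: Sequence[float],
    dist_null: Sequence[float],
) -> tuple[float, float]:
    """P(random real value > random null value), exhaustively over all pairs.

    Ties count one half, which makes the statistic antisymmetric
    (p(A,B) + p(B,A) = 1 exactly).  The standard error of the estimate,
    sqrt(p(1-p)/N_pairs), is returned alongside.
    """
    a = np.asarray(dist_real, dtype=float)
    b = np.asarray(dist_null, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both distributions must be non-empty")
    diff = a[:, None] - b[None, :]
    n_pairs = diff.size
    p = float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / n_pairs)
    se = float(np.sqrt(p * (1.0 - p) / n_pairs))
    return p, se


def validate_dt_pls(
    real_run: ModelRun,
    dataset: ModellingDataset,
    config: ModelConfig,
    n_random: int = 300,
) -> ValidationReport:
    """Percentile criterion for a DT or PLS model against ``n_random`` null models."""
    if config.method not in ("decision_tree", "pls"):
        raise ValueError("validate_dt_pls requires a decision_tree or pls config")
    nulls = null_distribution(dataset, config, n_random=n_random)
    percentile = ecdf_percentile(real_run.balanced_accuracy, nulls)
    return ValidationReport(
        method=config.method,
        significant=percentile >= PERCENTILE_CUTOFF,
        n_random=n_random,
        real_statistic=real_run.balanced_accuracy,
        null_statistics=list(map(float, nulls)),
        percentile=percentile,
    )


def validate_rf(
    real_distribution: Sequence[float],
    dataset: ModellingDataset,
    config: ModelConfig,
    n_shuffles: int = 100,
    n_models_per_shuffle: int = 100,
    n_bins: int = DEFAULT_BINS,
    probability_cutoff: float = PROBABILITY_CUTOFF,
) -> ValidationReport:
    """Exceedance-probability criterion for the RF performance distribution.

    Each of ``n_shuffles`` y-randomisations is modelled
    ``n_models_per_shuffle`` times; the overlap and exceedance probability
    of the real distribution against each null distribution are recorded,
    and the collection is significant when the mean exceedance probability
    exceeds ``probability_cutoff``.
    """
    if config.method != "random_forest":
        raise ValueError("validate_rf requires a random_forest config")
    real = np.asarray(real_distribution, dtype=float)
    overlaps: list[float] = []
    probs: list[float] = []
    ses: list[float] = []
    for s in range(n_shuffles):
        rng = np.random.default_rng([config.seed, 505, s])
        shuffled = y_randomise(dataset.labels, rng)
        null_config = replace(
            config,
            rf_n_seeds=n_models_per_shuffle,
            seed=_shuffle_seed(config.seed, s),
        )
        nulls = rf_distribution(dataset, null_config, labels=shuffled)
        overlaps.append(overlap(real, nulls, n_bins=n_bins))
        p, se = exceedance_probability(real, nulls)
        probs.append(p)
        ses.append(se)
    mean_p = float(np.mean(probs))
    return ValidationReport(
        method="random_forest",
        significant=mean_p > probability_cutoff,
        n_random=n_shuffles * n_models_per_shuffle,
        real_distribution=list(map(float, real)),
        overlaps=overlaps,
        exceedance_probabilities=probs,
        exceedance_standard_errors=ses,
        mean_exceedance_probability=mean_p,
        sd_exceedance_probability=float(np.std(probs)),
        mean_overlap=float(np.mean(overlaps)),
        sd_overlap=float(np.std(overlaps)),
        probability_cutoff=probability_cutoff,
        n_bins=n_bins,
    )


def _shuffle_seed(seed: int, shuffle_index: int) -> int:
    # distinct forest-seed substream per y-randomisation, below 2**31
    return int(np.random.default_rng([seed, 506, shuffle_index]).integers(2**31))
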