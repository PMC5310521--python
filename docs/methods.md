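# Methods

This note documents the models and procedures implemented in `vehitox`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Comparability and aggregation

Two experiments are comparable only if every field of the condition key
matches exactly: compound, route, species, number of injections, injection
interval, first injection day, number of repetitions, assessment day and
restart days. Records sharing a key and a vehicle are aggregated by taking
the arithmetic mean of survival at each distinct dose level; the union of
the replicates' dose levels is kept, each level averaging only the
experiments that tested it. Two doses are treated as the same level when
equal within a relative tolerance of 1e-9 (replicate dose grids in real
tables are nominally identical but float-parsed). Survival is held as a
fraction in [0, 1]; percent notation is accepted on input. Rows violating an
invariant (non-positive dose, survival outside [0, 1], survival × animals
not within rounding of an integer — the rounding tolerance allows
whole-percent reporting) are collected into a reject report rather than
silently dropped.

## AUC comparison

Curves are piecewise linear on the **linear** dose axis; log-dose axes are
treated as display conventions only. The trapezoid rule over the common
window — boundary survivals obtained by linear interpolation — is therefore
exact for the curve being integrated; a unit test checks agreement with a
dense-grid integration oracle at 1e-9 relative tolerance.

Flat extrapolation is applied only where it is toxicologically safe: at the
high-dose end once survival has reached zero (a higher dose cannot revive
the animals) and, under the widest strategy, at the low-dose end when
survival at the curve's lowest recorded dose is 100%. "Exactly 0/100%" is
tested with a 1e-9 tolerance because aggregated means are floats. The
eligibility test uses the curve's own lowest *recorded* dose, not the lowest
common dose. Extension never alters survival inside the original range.

The relative AUC difference is expressed as a percentage of the **larger**
area. The base of the percentage was an open choice; the maximum makes the
statistic symmetric in the two curves and bounded by 100, so a 30/40/60%
threshold means the same thing whichever vehicle is larger. At threshold 0 a
strict sign comparison is used, with areas within 1e-9 relative difference
counting as equal. Single-point curves have no area and are skipped with a
logged reason, as are pairs whose (extended) dose ranges do not overlap.

## Compound labels and datasets

Per-condition verdicts roll up deterministically: both directions present →
contradictory (this precedence over equivocal is our choice; the two
exclusion classes are never ranked elsewhere); one direction plus at least
one no-difference → equivocal; one direction only → a consistent preference;
otherwise no preference. Every condition key contributes one verdict,
including keys that differ only in, say, species. Only consistent compounds
enter the modelling dataset (0 = less toxic in the first-named vehicle),
with a configurable minimum size defaulting to 50.

## Modelling protocol

Stratified 10-fold cross-validation keeps each fold's class counts within
±1 of the proportional share; per-class remainders are dealt to the
currently smallest folds so fold sizes also differ by at most one. Inside
each fold, descriptors are ranked on the training portion only, by absolute
Pearson (point-biserial) correlation with the 0/1 label; constant columns
are excluded and ties break by ascending column index. DT and RF receive
one tenth of the training-set size as their budget; PLS tries 5, 10, 20 and
50 descriptors and reports the grid value with the best cross-validated
balanced accuracy (ties → the smallest, for parsimony), with latent
components capped at one tenth of the number of data points.

Learners are scikit-learn's CART decision tree (default impurity, no depth
cap), a 100-tree random forest, and PLS regression on the 0/1 label with
class assignment by the 0.5 cut; a predicted value of exactly 0.5 maps to
class 1. The headline statistic is the balanced accuracy of the pooled
out-of-fold predictions; the mean of per-fold balanced accuracies is also
recorded, since either convention is defensible. All randomness (fold
shuffling, per-fold and per-forest model seeds) flows from one master seed
through named substreams, so identical configurations reproduce identical
runs.

RF descriptor importance is computed on whole-dataset forests (no
cross-validation), averaged over 100 seeds, as *per-class permutation
importance*: the drop in that class's recall when a descriptor's column is
permuted. This yields one ranking per class direction — a genuinely
predictive descriptor ranks highly in both — which an impurity-based
importance (direction-free) could not provide.

## Significance by y-randomisation

Null models shuffle the label vector (class counts conserved) and repeat
the *entire* protocol, including per-fold descriptor re-selection against
the shuffled labels; selecting descriptors once on the real labels would
leak signal into the null.

For DT/PLS the criterion is an empirical-CDF percentile: the real balanced
accuracy must have ≥99% of the null values at or below it (weak
inequality, so a tie with the 99th-percentile null still counts). With m
null models the rule fires under exchangeability with probability
2/(m + 1) ≈ 1–2% — the real value must be the maximum or runner-up of the
m + 1 exchangeable values — and a calibration test verifies the empirical
firing rate on 200 label-free synthetic datasets against that exact rate.

For RF, the real seed-distribution is compared against each null
distribution with the exceedance probability P(real > null), evaluated
exhaustively over all pairs with ties counted one half. Tie-splitting makes
the statistic exactly antisymmetric (p(A,B) + p(B,A) = 1) and unbiased
under exchangeability; exhaustive pairing replaces Monte-Carlo sampling
because at 100×100 values it is exact and cheap, and the binomial standard
error √(p(1−p)/N) is still reported. The significance criterion is a mean
exceedance probability above 80% — an inherited, admittedly arbitrary
cutoff, kept configurable. The histogram overlap coefficient (shared
equal-width partition of [0, 1], default 20 bins — the bin count is a
config knob recorded in every report; per-distribution bin proportions; sum
of per-bin minima) is recorded for every comparison but never used as the
criterion by itself, because a poor real model can also overlap the null
weakly.

## Cluster vehicle ordering

Cluster membership is SMARTS substructure matching (RDKit); compounds
without parseable structures are skipped with a warning. At the
single-compound level the no-threshold regime demands unanimity: every
(strategy × condition) comparison must agree in sign, all-equal areas give
no difference, and any disagreement excludes the compound. Tallies are per
compound, not per condition set. The preference-ratio rule (a difference is
shown iff one side's count exceeds the other side's count plus the
no-difference count) can never fire in both directions for non-negative
counts; this is exhaustively checked.

Strict edges run less-toxic → more-toxic. Equivalence (no difference shown)
is deliberately **not** treated as transitive for ordering claims; it is
used only for contradiction detection — a pair joined by an equivalence
path that also has a strict path between its endpoints is reported, as is
any directed cycle. A "fully ordered set" rendering (e.g.
`saline > CMC > MC = DWA`) is produced only when there are no findings and
the equivalence classes form a total order under the strict edges'
transitive closure.

## Synthetic data generator

The generator emulates the *structure* of historical screening tables:
matched condition keys, 6–10 animals per dose group, a handful of geometric
dose levels per experiment (grids jittered between experiments and
vehicles), 1–3 replicate experiments per compound-vehicle drawn across a
small pool of screeners, and a configurable fraction of compounds with no
vehicle effect. Survival is binomial around a logistic-in-log-dose model —
the simplest monotone family reproducing sigmoidal dose-survival plots —
so the characteristic "noise" of single-animal deaths (occasionally higher
survival at a higher dose) emerges naturally without an extra noise term.

Vehicle effects are injected through binary structural keys: each causal
key shifts ln LD50 by a configured amount in specific vehicles, and the
vehicle with the larger shifted LD50 is, by construction, the less toxic
one. Effect compounds draw their causal keys from a single group of keys
with identical shift maps (default: two groups of five keys shifting the
second vehicle by ±2 log-units), so injected shifts never cancel and both
label classes occur. Defaults not pinned by the emulated data were chosen
once as realistic for a rodent dose-range-finding screen: baseline LD50s
log-uniform over 100–1000 mg/kg, logistic steepness 4 (survival falls from
~90% to ~10% over about a factor of three in dose), five dose levels
spanning about 2.2 decades centred near the compound's LD50s.

The generator is deterministic given its seed, with per-compound
substreams so the first k compounds are identical for any larger compound
count. `degrade_to_equivocal` adds, for a chosen fraction of effect
compounds, an extra condition (different host species) simulated with zero
shift, creating the preference-plus-no-difference pattern that labelling
must call equivocal.

What the generator does **not** emulate: pharmacokinetics, tumour burden,
dose-schedule interactions, inter-lab systematic bias (screeners differ
only through sampling noise), correlated or continuous descriptors (the
feature matrix doubles as the descriptor table, giving structural-key
semantics without a cheminformatics dependency), and real structure-
activity landscapes. Passing tests therefore demonstrate that the analysis
chain recovers effects of the injected kind at screening-like noise levels
— not that real screening data contain such effects.

## Problem sizes used in the test-suite

Simulation-backed checks run at deliberately modest sizes chosen as the
package's own desk-scale defaults: 200 null datasets × 100 null models for
type-I calibration; one 120-compound planted-signal dataset with 100 null
models (DT/PLS) and 20 y-randomisations × 20 forest seeds (RF); 50 seeds ×
30 compounds for four-vehicle hierarchy recovery; 500–1,000 random curves
or distribution pairs for the numeric and symmetry properties.

## Known limitations

* The AUC is compared, never modelled; no LD50 or probit/logit fit is
  attempted, matching the raw-curve comparison approach.
* Compounds with a single dose point are dropped from comparison rather
  than given a degenerate area.
* The exceedance criterion's 80% cutoff and the 99th-percentile rule are
  conventions, not optimised quantities; both are configurable.
* `degrade_to_equivocal` extends the record set only; truth tables keep the
  original effect directions.
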