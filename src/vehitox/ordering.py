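"""Vehicle ordering over substructure-defined compound clusters.

Individual compound-vehicle data are too sparse to rank vehicles, but a
cluster of related compounds (all matching a SMARTS substructure, e.g. the
diaziridylphosphoramide core) can vote: each member compound is called less
toxic in one vehicle of a pair only if every AUC comparison - all three
interpolation/extrapolation strategies, every comparable condition set,
strict sign with no threshold - points the same way.  The per-pair tallies
(n less toxic in A : n less toxic in B : n no difference) then decide
whether the cluster shows a difference at all, by the preference-ratio rule:

    a difference is shown iff the count preferring one vehicle exceeds the
    count preferring the other PLUS the count showing no difference.

Pairs that show a difference become directed edges (less-toxic -> more-toxic
vehicle); pairs that do not become equivalence edges.  The resulting graph
is checked for consistency: directed cycles among strict edges, and pairs
joined by an equivalence path that also have a strict path between them.
Equivalence is deliberately not treated as transitive for ordering claims;
it only feeds contradiction detection.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .curves import ALL_STRATEGIES, ComparisonVerdict, Verdict

try:  # RDKit is required for SMARTS clustering only
    from rdkit import Chem
except ImportError:  # pragma: no cover
    Chem = None

__all__ = [
    "ClusterCall",
    "PreferenceTally",
    "Finding",
    "VehicleOrder",
    "unordered_pairs",
    "match_cluster",
    "read_sdf",
    "cluster_compound_verdict",
    "preference_shown",
    "tally_cluster",
    "build_order_graph",
    "check_consistency",
    "order_expression",
    "to_dot",
]


def unordered_pairs(items: Sequence) -> list[tuple]:
    """All unordered pairs of distinct items, in input order (n*(n-1)/2 of them)."""
    return list(itertools.combinations(items, 2))


class ClusterCall(enum.Enum):
    """Per-compound outcome of the strategy-unanimous, no-threshold comparison."""

    LESS_TOXIC_A = "less_toxic_a"
    LESS_TOXIC_B = "less_toxic_b"
    NO_DIFFERENCE = "no_difference"
    EXCLUDED = "excluded"


class PatternError(ValueError):
    """The SMARTS pattern could not be parsed."""


def _as_mol(structure):
    if Chem is None:
        raise ImportError("RDKit is required for substructure matching")
    if isinstance(structure, str):
        return Chem.MolFromSmiles(structure)
    return structure


def match_cluster(structures: Mapping[str, object], pattern: str) -> set[str]:
    """Compound ids whose structure contains at least one match of the SMARTS pattern.

    ``structures`` maps compound id to a SMILES string or an RDKit Mol.
    Unparseable structures are skipped with a warning; an unparseable
    pattern raises :class:`PatternError`.
    """
    if Chem is None:
        raise ImportError("RDKit is required for substructure matching")
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise PatternError(f"could not parse SMARTS pattern {pattern!r}")
    members: set[str] = set()
    for cid, structure in structures.items():
        mol = _as_mol(structure)
        if mol is None:
            warnings.warn(f"skipping unparseable structure for compound {cid}", stacklevel=2)
            continue
        if mol.HasSubstructMatch(query):
            members.add(cid)
    return members


def read_sdf(path: str | Path) -> dict[str, object]:
    """Read an SDF into {compound id: Mol}; id from the molecule title or index."""
    if Chem is None:
        raise ImportError("RDKit is required to read SDF files")
    structures: dict[str, object] = {}
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"skipping unparseable SDF entry {i}", stacklevel=2)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        structures[name] = mol
    return structures


def cluster_compound_verdict(comparisons: Sequence[ComparisonVerdict]) -> ClusterCall:
    """Sign-consistent, no-threshold verdict for one compound and vehicle pair.

    ``comparisons`` must cover all three strategies (for however many
    comparable condition sets the compound has), each computed with
    threshold 0.  The compound is called for a vehicle only if every
    (strategy, condition) comparison agrees in sign; all-equal areas give
    NO_DIFFERENCE; any disagreement gives EXCLUDED.
    """
    if not comparisons:
        raise ValueError("need at least one comparison")
    compound_ids = {c.key.compound_id for c in comparisons}
    if len(compound_ids) != 1:
        raise ValueError(f"comparisons mix compound ids: {sorted(compound_ids)}")
    if any(c.threshold_pct != 0 for c in comparisons):
        raise ValueError("cluster verdicts require threshold-0 (strict sign) comparisons")
    covered = {c.strategy for c in comparisons}
    missing = set(ALL_STRATEGIES) - covered
    if missing:
        raise ValueError(
            "missing strategy coverage: " + ", ".join(s.value for s in sorted(missing, key=lambda s: s.value))
        )
    outcomes = {c.verdict for c in comparisons}
    if outcomes == {Verdict.A_LESS_TOXIC}:
        return ClusterCall.LESS_TOXIC_A
    if outcomes == {Verdict.B_LESS_TOXIC}:
        return ClusterCall.LESS_TOXIC_B
    if outcomes == {Verdict.NO_DIFFERENCE}:
        return ClusterCall.NO_DIFFERENCE
    return ClusterCall.EXCLUDED


@dataclass(frozen=True)
class PreferenceTally:
    """Cluster-level vote for one vehicle pair."""

    cluster_id: str
    vehicle_a: str
    vehicle_b: str
    n_less_toxic_a: int
    n_less_toxic_b: int
    n_no_difference: int
    shows_difference: bool | None = None
    direction: str | None = None  # "a" | "b" | "none"


def preference_shown(tally: PreferenceTally) -> PreferenceTally:
    """Apply the preference-ratio rule and set direction.

    Direction "a" iff n_a > n_b + n_nd; "b" iff n_b > n_a + n_nd; both can
    never hold at once for non-negative counts.
    """
    if min(tally.n_less_toxic_a, tally.n_less_toxic_b, tally.n_no_difference) < 0:
        raise ValueError("tally counts must be non-negative")
    a, b, nd = tally.n_less_toxic_a, tally.n_less_toxic_b, tally.n_no_difference
    if a > b + nd:
        return replace(tally, shows_difference=True, direction="a")
    if b > a + nd:
        return replace(tally, shows_difference=True, direction="b")
    return replace(tally, shows_difference=False, direction="none")


def tally_cluster(
    calls: Mapping[str, ClusterCall],
    cluster_id: str,
    vehicle_a: str,
    vehicle_b: str,
) -> PreferenceTally:
    """Tally per-compound cluster calls for one vehicle pair (EXCLUDED not counted)."""
    values = list(calls.values())
    tally = PreferenceTally(
        cluster_id=cluster_id,
        vehicle_a=vehicle_a,
        vehicle_b=vehicle_b,
        n_less_toxic_a=sum(v is ClusterCall.LESS_TOXIC_A for v in values),
        n_less_toxic_b=sum(v is ClusterCall.LESS_TOXIC_B for v in values),
        n_no_difference=sum(v is ClusterCall.NO_DIFFERENCE for v in values),
    )
    return preference_shown(tally)


@dataclass(frozen=True)
class Finding:
    """A consistency problem in a vehicle order graph."""

    kind: str  # "cycle" | "equivalence_conflict"
    vehicles: tuple[str, ...]

    def __str__(self) -> str:
        return f"{self.kind}: {' / '.join(self.vehicles)}"


@dataclass
class VehicleOrder:
    """Vehicles with strict (less-toxic -> more-toxic) and equivalence relations."""

    vehicles: set[str]
    strict: nx.DiGraph
    equivalences: list[tuple[str, str, PreferenceTally]]
    findings: list[Finding] = field(default_factory=list)


def build_order_graph(tallies: Iterable[PreferenceTally]) -> VehicleOrder:
    """Assemble the order graph from per-pair tallies and check its consistency.

    Tallies without the rule applied are passed through
    :func:`preference_shown` first.  Strict edges run from the less-toxic to
    the more-toxic vehicle and carry their tally; no-difference pairs become
    equivalence edges.
    """
    strict = nx.DiGraph()
    equivalences: list[tuple[str, str, PreferenceTally]] = []
    vehicles: set[str] = set()
    for tally in tallies:
        if tally.shows_difference is None:
            tally = preference_shown(tally)
        vehicles.update((tally.vehicle_a, tally.vehicle_b))
        strict.add_nodes_from((tally.vehicle_a, tally.vehicle_b))
        if tally.shows_difference:
            if tally.direction == "a":
                strict.add_edge(tally.vehicle_a, tally.vehicle_b, tally=tally)
            else:
                strict.add_edge(tally.vehicle_b, tally.vehicle_a, tally=tally)
        else:
            equivalences.append((tally.vehicle_a, tally.vehicle_b, tally))
    order = VehicleOrder(vehicles=vehicles, strict=strict, equivalences=equivalences)
    order.findings = check_consistency(order)
    return order


def check_consistency(order: VehicleOrder) -> list[Finding]:
    """Cycles among strict edges, and equivalence paths contradicted by strict paths."""
    findings: list[Finding] = []
    for cycle in nx.simple_cycles(order.strict):
        findings.append(Finding(kind="cycle", vehicles=tuple(cycle)))
    equiv = nx.Graph()
    equiv.add_nodes_from(order.vehicles)
    equiv.add_edges_from((a, b) for a, b, _ in order.equivalences)
    for component in nx.connected_components(equiv):
        for u, v in itertools.combinations(sorted(component), 2):
            if u not in order.strict or v not in order.strict:
                continue
            if nx.has_path(order.strict, u, v) or nx.has_path(order.strict, v, u):
                findings.append(Finding(kind="equivalence_conflict", vehicles=(u, v)))
    return findings


def order_expression(order: VehicleOrder, vehicle_order: Sequence[str] | None = None) -> str | None:
    """Render a fully ordered set as e.g. ``"saline > CMC > MC = DWA"``.

    Vehicles joined by equivalence edges are grouped into classes; classes
    must form a total order under the strict edges' transitive closure.
    Returns None when the graph has findings or is not totally ordered.
    ``vehicle_order`` fixes the name order inside an equivalence class.
    """
    if order.findings:
        return None
    rank = {v: i for i, v in enumerate(vehicle_order)} if vehicle_order else {}
    equiv = nx.Graph()
    equiv.add_nodes_from(order.vehicles)
    equiv.add_edges_from((a, b) for a, b, _ in order.equivalences)
    components = [tuple(sorted(c, key=lambda v: (rank.get(v, 0), v))) for c in nx.connected_components(equiv)]
    class_of = {v: comp for comp in components for v in comp}
    dag = nx.DiGraph()
    dag.add_nodes_from(components)
    for u, v in order.strict.edges:
        if class_of[u] != class_of[v]:
            dag.add_edge(class_of[u], class_of[v])
    if not nx.is_directed_acyclic_graph(dag):
        return None
    closure = nx.transitive_closure(dag)
    chain = list(nx.topological_sort(dag))
    for first, second in zip(chain, chain[1:]):
        if not closure.has_edge(first, second):
            return None  # incomparable classes: not a total order
    return " > ".join(" = ".join(comp) for comp in chain)


def to_dot(order: VehicleOrder) -> str:
    """DOT rendering: strict edges arrowed less-toxic -> more-toxic, labelled a:b:nd."""
    lines = ["digraph vehicle_order {"]
    for vehicle in sorted(order.vehicles):
        lines.append(f'    "{vehicle}";')
    for u, v, data in order.strict.edges(data=True):
        tally: PreferenceTally = data["tally"]
        label = f"{tally.n_less_toxic_a}:{tally.n_less_toxic_b}:{tally.n_no_difference}"
        if tally.direction == "b":
            label = f"{tally.n_less_toxic_b}:{tally.n_less_toxic_a}:{tally.n_no_difference}"
        lines.append(f'    "{u}" -> "{v}" [label="{label}"];')
    for a, b, tally in order.equivalences:
        label = f"{tally.n_less_toxic_a}:{tally.n_less_toxic_b}:{tally.n_no_difference}"
        lines.append(f'    "{a}" -> "{b}" [dir=both, style=dashed, label="{label}"];')
    lines.append("}")
    return "\n".join(lines)
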