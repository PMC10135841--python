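"""Core data model for stoichiometric networks.

Metabolites carry explicit carbon counts so that carbon accounting is exact;
reaction coefficients are stored as :class:`fractions.Fraction` and only
converted to floating point when a linear program is assembled.  A network is
an ordered collection of metabolites and reactions; insertion order is
preserved everywhere so that stoichiometric matrices and reports are
byte-for-byte reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "PathwayModule",
    "ModelError",
    "carbon_imbalance",
    "build_s_matrix",
    "add_module",
    "read_model",
    "write_model",
    "network_to_dict",
    "network_from_dict",
]

MODEL_DIALECT_VERSION = "1"


class ModelError(ValueError):
    """Raised for invalid model construction or serialization input."""


def _as_fraction(value) -> Fraction:
    """Coerce ints, Fractions, exact floats and [num, den] pairs to Fraction."""
    if isinstance(value, Fraction):
        return value
    if isinstance(value, (list, tuple)):
        if len(value) != 2:
            raise ModelError(f"coefficient pair must have two entries, got {value!r}")
        return Fraction(int(value[0]), int(value[1]))
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(value).limit_denominator(10**9)
    raise ModelError(f"cannot interpret coefficient {value!r}")


@dataclass(frozen=True)
class Metabolite:
    """A chemical species with explicit carbon count.

    ``carbon_count`` is the number of carbons *accounted for* in yield
    calculations; for acyl-CoA thioesters only the acyl carbons are counted
    (the CoA moiety is a catalytic carrier), so ``formula``, when present,
    describes the accounted moiety, not the full molecule.
    """

    id: str
    name: str = ""
    carbon_count: int = 0
    formula: Optional[Mapping[str, int]] = None
    compartment: str = "c"

    def __post_init__(self):
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if self.carbon_count < 0:
            raise ModelError(f"metabolite {self.id!r}: carbon_count must be >= 0")
        if self.formula is not None:
            if any(v < 0 for v in self.formula.values()):
                raise ModelError(f"metabolite {self.id!r}: negative element count")
            if self.formula.get("C", 0) != self.carbon_count:
                raise ModelError(
                    f"metabolite {self.id!r}: formula C count "
                    f"{self.formula.get('C', 0)} != carbon_count {self.carbon_count}"
                )


REACTION_KINDS = ("internal", "exchange", "sink")


@dataclass(frozen=True)
class Reaction:
    """Signed stoichiometry over metabolite ids with flux bounds (mmol/gDCW/h).

    Negative coefficients are consumed, positive produced.  ``exchange`` and
    ``sink`` reactions cross the system boundary and must touch exactly one
    metabolite; by convention an import-positive exchange has coefficient +1.
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    kind: str = "internal"

    def __post_init__(self):
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        stoich = {m: _as_fraction(c) for m, c in self.stoichiometry.items()}
        if not stoich:
            raise ModelError(f"reaction {self.id!r}: empty stoichiometry")
        if any(c == 0 for c in stoich.values()):
            raise ModelError(f"reaction {self.id!r}: zero coefficient stored")
        object.__setattr__(self, "stoichiometry", stoich)
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.kind in ("exchange", "sink") and len(stoich) != 1:
            raise ModelError(
                f"reaction {self.id!r}: {self.kind} reactions touch exactly one metabolite"
            )

    @property
    def boundary(self) -> bool:
        return self.kind in ("exchange", "sink")

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass
class PathwayModule:
    """A named, self-contained bundle of reactions and their metabolites."""

    name: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    description: str = ""


class MetabolicNetwork:
    """Ordered collection of metabolites and reactions keyed by id."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
    ):
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    def add_metabolite(self, met: Metabolite) -> None:
        existing = self.metabolites.get(met.id)
        if existing is not None and existing != met:
            raise ModelError(f"metabolite id collision with different definition: {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        existing = self.reactions.get(rxn.id)
        if existing is not None:
            if existing != rxn:
                raise ModelError(f"reaction id collision with different definition: {rxn.id!r}")
            return
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelError(f"reaction {rxn.id!r} references unknown metabolite {met_id!r}")
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicNetwork":
        net = MetabolicNetwork()
        net.metabolites = dict(self.metabolites)
        net.reactions = dict(self.reactions)
        return net

    def replace_reaction(self, rxn: Reaction) -> None:
        if rxn.id not in self.reactions:
            raise KeyError(f"unknown reaction {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    # ordering helpers -----------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return list(self.metabolites)

    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return self.metabolites == other.metabolites and self.reactions == other.reactions

    def __repr__(self) -> str:
        return (
            f"<MetabolicNetwork {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


def add_module(network: MetabolicNetwork, module: PathwayModule) -> MetabolicNetwork:
    """Return a new network containing the union with ``module``.

    Merging is idempotent for identical definitions; an id carrying a
    different stoichiometry or bounds raises :class:`ModelError` naming it.
    """
    net = network.copy()
    for met in module.metabolites:
        net.add_metabolite(met)
    for rxn in module.reactions:
        net.add_reaction(rxn)
    return net


def carbon_imbalance(rxn: Reaction, metabolites: Mapping[str, Metabolite]) -> Fraction:
    """Net carbon produced per unit flux: sum of coefficient x carbon_count.

    Zero means carbon-balanced.  Boundary (exchange/sink) reactions are
    legitimately unbalanced; for them the value is the carbon crossing the
    system boundary per unit flux.
    """
    total = Fraction(0)
    for met_id, coeff in rxn.stoichiometry.items():
        met = metabolites.get(met_id)
        if met is None:
            raise ModelError(f"reaction {rxn.id!r}: unresolved metabolite {met_id!r}")
        total += coeff * met.carbon_count
    return total


def build_s_matrix(network: MetabolicNetwork) -> np.ndarray:
    """Dense stoichiometric matrix, rows = metabolites, cols = reactions.

    Row/column order is the network's insertion order, so the matrix is
    deterministic for a given construction sequence.
    """
    met_index = {m: i for i, m in enumerate(network.metabolite_ids)}
    S = np.zeros((len(met_index), len(network.reactions)))
    for j, rxn in enumerate(network.reactions.values()):
        for met_id, coeff in rxn.stoichiometry.items():
            S[met_index[met_id], j] = float(coeff)
    return S


# -- JSON model dialect ---------------------------------------------------

def network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "version": MODEL_DIALECT_VERSION,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "carbon_count": m.carbon_count,
                "formula": dict(m.formula) if m.formula is not None else None,
                "compartment": m.compartment,
            }
            for m in network.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {
                    m: [c.numerator, c.denominator] for m, c in r.stoichiometry.items()
                },
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "kind": r.kind,
            }
            for r in network.reactions.values()
        ],
    }


def network_from_dict(data: dict, strict: bool = False) -> MetabolicNetwork:
    if not isinstance(data, dict):
        raise ModelError("model document must be a JSON object")
    known = {"version", "metabolites", "reactions", "extensions"}
    extra = set(data) - known
    if extra and strict:
        raise ModelError(f"unknown top-level keys: {sorted(extra)}")
    for key in ("metabolites", "reactions"):
        if key not in data:
            raise ModelError(f"missing mandatory key {key!r}")

    net = MetabolicNetwork()
    seen_m = set()
    for i, entry in enumerate(data["metabolites"]):
        try:
            met = Metabolite(
                id=entry["id"],
                name=entry.get("name", ""),
                carbon_count=int(entry["carbon_count"]),
                formula=entry.get("formula"),
                compartment=entry.get("compartment", "c"),
            )
        except KeyError as exc:
            raise ModelError(f"metabolites[{i}]: missing field {exc}") from exc
        if met.id in seen_m:
            raise ModelError(f"duplicate metabolite id {met.id!r} (metabolites[{i}])")
        seen_m.add(met.id)
        net.add_metabolite(met)
    seen_r = set()
    for i, entry in enumerate(data["reactions"]):
        try:
            rxn = Reaction(
                id=entry["id"],
                name=entry.get("name", ""),
                stoichiometry={m: _as_fraction(c) for m, c in entry["stoichiometry"].items()},
                lower_bound=float(entry["lower_bound"]),
                upper_bound=float(entry["upper_bound"]),
                kind=entry.get("kind", "internal"),
            )
        except KeyError as exc:
            raise ModelError(f"reactions[{i}]: missing field {exc}") from exc
        if rxn.id in seen_r:
            raise ModelError(f"duplicate reaction id {rxn.id!r} (reactions[{i}])")
        seen_r.add(rxn.id)
        net.add_reaction(rxn)
    return net


def write_model(network: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(network), fh, indent=1)
        fh.write("\n")


def read_model(path, strict: bool = False) -> MetabolicNetwork:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelError(f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    return network_from_dict(data, strict=strict)
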