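"""Carbon-yield reporting on flux solutions.

A C-mol yield is carbon moles of product per carbon mole of substrate:
``(v_product * C_product) / (v_substrate * C_substrate)``.  For the PHB
monomer (C4) on methanol (C1) at the study uptake of 6 mmol/gDCW/h this is
4*v/6.  Acetyl-CoA is counted as its 2 acetyl carbons; the CoA carrier is
catalytic.  Yields are carried both as floats and as exact rationals so the
pathway comparison ("a 50% increase") is exact rather than an artifact of
pre-rounded decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from .fba import FluxSolution, boundary_carbon_flows, set_uptake, solve_fba
from .modules import DEFAULT_UPTAKE, MEOH_EXCHANGE, OPEN
from .network import (
    MetabolicNetwork,
    PathwayModule,
    Reaction,
    add_module,
)

__all__ = ["YieldReport", "cmol_yield", "compare_pathways", "accoa_ceiling"]

_RATIONAL_SNAP = 10**6  # denominator limit when snapping LP floats to rationals


@dataclass
class YieldReport:
    substrate_id: str
    product_id: str
    substrate_flux: float  # mmol/gDCW/h
    product_flux: float
    substrate_carbon: int
    product_carbon: int
    cmol_yield: float
    cmol_yield_exact: Fraction
    co2_flux: float

    @property
    def cmol_yield_2dp(self) -> float:
        """Yield rounded to two decimals, the conventional report precision."""
        return round(self.cmol_yield, 2)

    @property
    def percent(self) -> float:
        return 100.0 * self.cmol_yield


def _single_metabolite_carbon(network: MetabolicNetwork, reaction_id: str) -> int:
    rxn = network.reactions[reaction_id]
    if len(rxn.stoichiometry) != 1:
        raise ValueError(f"{reaction_id!r} is not a single-species boundary reaction")
    (met_id,) = rxn.stoichiometry
    return network.metabolites[met_id].carbon_count


def cmol_yield(
    solution: FluxSolution,
    network: MetabolicNetwork,
    substrate_ex: str,
    product_sink: str,
) -> YieldReport:
    """Build a C-mol yield report from an optimal solution.

    A zero *substrate* flux makes the yield undefined and raises; a zero
    *product* flux is a legitimate yield of 0.
    """
    if not solution.optimal:
        raise ValueError("yield requires an optimal solution")
    v_s = solution.fluxes[substrate_ex]
    v_p = solution.fluxes[product_sink]
    if v_s <= 0:
        raise ValueError(f"substrate flux through {substrate_ex!r} is {v_s}; yield undefined")
    c_s = _single_metabolite_carbon(network, substrate_ex)
    c_p = _single_metabolite_carbon(network, product_sink)
    exact = (
        Fraction(v_p).limit_denominator(_RATIONAL_SNAP) * c_p
        / (Fraction(v_s).limit_denominator(_RATIONAL_SNAP) * c_s)
    )
    flows = boundary_carbon_flows(network, solution)
    return YieldReport(
        substrate_id=substrate_ex,
        product_id=product_sink,
        substrate_flux=v_s,
        product_flux=v_p,
        substrate_carbon=c_s,
        product_carbon=c_p,
        cmol_yield=(v_p * c_p) / (v_s * c_s),
        cmol_yield_exact=exact,
        co2_flux=flows["co2_flux"],
    )


def compare_pathways(base: YieldReport, variant: YieldReport) -> Fraction:
    """Relative yield change (variant - base)/base, exact on rationals.

    For the RuMP -> MCC comparison this is (1 - 2/3)/(2/3) = 1/2 exactly.
    """
    if base.cmol_yield_exact <= 0:
        raise ValueError("base yield must be positive for a relative comparison")
    return (variant.cmol_yield_exact - base.cmol_yield_exact) / base.cmol_yield_exact


ACCOA_SINK = "SINK_accoa_tmp"
_COA_SUPPLY = "EX_coa_tmp"


def accoa_ceiling(
    modules: Sequence[PathwayModule],
    uptake: float = DEFAULT_UPTAKE,
    uptake_exchange: str = MEOH_EXCHANGE,
) -> YieldReport:
    """Maximum carbon yield of acetyl-CoA for a pathway stack.

    Assembles the given modules, attaches a temporary acetyl-CoA sink as the
    objective (2 acetyl carbons counted) together with a zero-carbon CoA
    supply exchange (the drained thioester strands its CoA moiety otherwise),
    fixes the substrate uptake, and reports the resulting C-mol yield.
    """
    net = MetabolicNetwork()
    for module in modules:
        net = add_module(net, module)
    if "accoa" not in net.metabolites:
        raise ValueError("module stack has no acetyl-CoA pool")
    net.add_reaction(Reaction(ACCOA_SINK, {"accoa": Fraction(-1)},
                              name="temporary acetyl-CoA sink",
                              lower_bound=0.0, upper_bound=OPEN, kind="sink"))
    net.add_reaction(Reaction(_COA_SUPPLY, {"coa": Fraction(1)},
                              name="temporary CoA supply (carbon-free)",
                              lower_bound=-OPEN, upper_bound=OPEN, kind="exchange"))
    net = set_uptake(net, uptake_exchange, uptake)
    sol = solve_fba(net, ACCOA_SINK, "max")
    if not sol.optimal:
        raise RuntimeError(f"acetyl-CoA ceiling LP not optimal: {sol.status}")
    return cmol_yield(sol, net, uptake_exchange, ACCOA_SINK)
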