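"""Curated pathway modules for methanol-to-PHB yield analysis.

The library ships the reaction chemistry needed to reproduce the theoretical
yield comparison between three methanol assimilation strategies:

* **RuMP** — methanol dehydrogenase (Mdh) plus the Hps-Phi fusion route
  (formaldehyde + Ru5P -> H6P -> F6P), with acetyl-CoA made by pyruvate
  decarboxylation (one CO2 lost per acetyl-CoA).
* **XuMP** — dihydroxyacetone synthase/kinase route, same decarboxylation
  ceiling.
* **MCC** — RuMP plus non-oxidative glycolysis (phosphoketolase, Fxpk),
  which rearranges sugar phosphates into acetyl-phosphate with full carbon
  conservation.

All modules are single-compartment and yield-level: transport is collapsed,
cofactors are closed by lumped pseudo-reactions (see :func:`core_module`),
and every internal reaction is exactly carbon-balanced by construction.
Acyl-CoA species count only their acyl carbons; the CoA moiety is treated
as a catalytic carrier.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Dict, List

from .network import Metabolite, PathwayModule, Reaction

__all__ = [
    "core_module",
    "c1_module",
    "nog_module",
    "phb_module",
    "xump_module",
    "frma_module",
    "MODULES",
    "list_modules",
    "get_module",
    "MEOH_EXCHANGE",
    "CO2_EXCHANGE",
    "PHB_SINK",
    "DEFAULT_UPTAKE",
]

OPEN = 1000.0  # conventional "unconstrained" flux bound, mmol/gDCW/h

MEOH_EXCHANGE = "EX_meoh"
CO2_EXCHANGE = "EX_co2"
PHB_SINK = "SINK_3hb"
DEFAULT_UPTAKE = 6.0  # mmol/gDCW/h methanol, the study condition

# ---------------------------------------------------------------------------
# Metabolite catalog (single cytosolic compartment).
# ---------------------------------------------------------------------------

_CATALOG: Dict[str, Metabolite] = {
    m.id: m
    for m in [
        Metabolite("meoh", "methanol", 1, {"C": 1, "H": 4, "O": 1}),
        Metabolite("fald", "formaldehyde", 1, {"C": 1, "H": 2, "O": 1}),
        Metabolite("for", "formate", 1, {"C": 1, "H": 2, "O": 2}),
        Metabolite("co2", "carbon dioxide", 1, {"C": 1, "O": 2}),
        Metabolite("h6p", "D-arabino-hexulose 6-phosphate", 6),
        Metabolite("f6p", "fructose 6-phosphate", 6),
        Metabolite("fbp", "fructose 1,6-bisphosphate", 6),
        Metabolite("dhap", "dihydroxyacetone phosphate", 3),
        Metabolite("g3p", "glyceraldehyde 3-phosphate", 3),
        Metabolite("dha", "dihydroxyacetone", 3, {"C": 3, "H": 6, "O": 3}),
        Metabolite("pyr", "pyruvate", 3, {"C": 3, "H": 4, "O": 3}),
        Metabolite("e4p", "erythrose 4-phosphate", 4),
        Metabolite("r5p", "ribose 5-phosphate", 5),
        Metabolite("ru5p", "ribulose 5-phosphate", 5),
        Metabolite("xu5p", "xylulose 5-phosphate", 5),
        Metabolite("s7p", "sedoheptulose 7-phosphate", 7),
        # acyl carbons only; CoA carrier is catalytic
        Metabolite("accoa", "acetyl-CoA (acetyl moiety)", 2),
        Metabolite("aacoa", "acetoacetyl-CoA (acyl moiety)", 4),
        Metabolite("3hbcoa", "(R)-3-hydroxybutyryl-CoA (acyl moiety)", 4),
        Metabolite("3hb", "3-hydroxybutyrate (PHB monomer)", 4, {"C": 4, "H": 8, "O": 3}),
        Metabolite("acp", "acetyl phosphate", 2),
        Metabolite("ac", "acetate", 2, {"C": 2, "H": 4, "O": 2}),
        # carbon-free currency species
        Metabolite("nad", "NAD+", 0),
        Metabolite("nadh", "NADH", 0),
        Metabolite("nadp", "NADP+", 0),
        Metabolite("nadph", "NADPH", 0),
        Metabolite("atp", "ATP", 0),
        Metabolite("adp", "ADP", 0),
        Metabolite("pi", "orthophosphate", 0),
        Metabolite("coa", "coenzyme A", 0),
        Metabolite("h2o", "water", 0, {"H": 2, "O": 1}),
    ]
}


def _mets(*ids: str) -> List[Metabolite]:
    return [_CATALOG[i] for i in ids]


def _rxn(rid, name, stoich, lb, ub, kind="internal") -> Reaction:
    return Reaction(
        id=rid,
        name=name,
        stoichiometry={m: Fraction(c) for m, c in stoich.items()},
        lower_bound=lb,
        upper_bound=ub,
        kind=kind,
    )


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

def core_module(atp_per_nadh: float = 2.0, ngam: float = 0.0) -> PathwayModule:
    """Host central carbon metabolism plus lumped cofactor closure.

    Contains EMP glycolysis run as separate kinase/phosphatase steps so flux
    can go both F6P->pyruvate and (gluconeogenically) G3P->F6P, the
    non-oxidative pentose phosphate rearrangements, pyruvate dehydrogenase,
    acetyl-phosphate handling (Pta, AckA), and the cofactor pseudo-reactions:
    a lumped respiration sink (NADH -> NAD+), ATP regeneration from NADH at
    ``atp_per_nadh`` ATP per NADH, a transhydrogenase, and a free ATP
    hydrolysis drain whose lower bound is the non-growth maintenance demand
    ``ngam`` (default 0, the study condition: optima are carbon-limited,
    not energy-limited).

    Parameters
    ----------
    atp_per_nadh:
        Stoichiometry of the lumped oxidative-phosphorylation reaction.
        Carbon-limited optima are insensitive to this value.
    ngam:
        Non-growth-associated maintenance, mmol ATP/gDCW/h (lower bound of
        the ATP drain).
    """
    n = Fraction(atp_per_nadh).limit_denominator(1000)
    reactions = [
        # glycolysis / gluconeogenesis
        _rxn("PFK", "phosphofructokinase",
             {"f6p": -1, "atp": -1, "fbp": 1, "adp": 1}, 0, OPEN),
        _rxn("FBPASE", "fructose-1,6-bisphosphatase",
             {"fbp": -1, "h2o": -1, "f6p": 1, "pi": 1}, 0, OPEN),
        _rxn("FBA", "fructose-bisphosphate aldolase",
             {"fbp": -1, "dhap": 1, "g3p": 1}, -OPEN, OPEN),
        _rxn("TPI", "triose-phosphate isomerase",
             {"dhap": -1, "g3p": 1}, -OPEN, OPEN),
        _rxn("GLYC_LOW", "lower glycolysis (lumped G3P -> pyruvate)",
             {"g3p": -1, "adp": -2, "pi": -2, "nad": -1,
              "pyr": 1, "atp": 2, "nadh": 1, "h2o": 1}, 0, OPEN),
        _rxn("PDH", "pyruvate dehydrogenase",
             {"pyr": -1, "coa": -1, "nad": -1,
              "accoa": 1, "co2": 1, "nadh": 1}, 0, OPEN),
        # acetyl-phosphate node
        _rxn("PTA", "phosphotransacetylase",
             {"acp": -1, "coa": -1, "accoa": 1, "pi": 1}, -OPEN, OPEN),
        _rxn("ACK", "acetate kinase",
             {"acp": -1, "adp": -1, "ac": 1, "atp": 1}, -OPEN, OPEN),
        # non-oxidative pentose phosphate rearrangements
        _rxn("RPI", "ribose-5-phosphate isomerase",
             {"r5p": -1, "ru5p": 1}, -OPEN, OPEN),
        _rxn("RPE", "ribulose-5-phosphate 3-epimerase",
             {"ru5p": -1, "xu5p": 1}, -OPEN, OPEN),
        _rxn("TKT1", "transketolase (Xu5P + R5P <-> S7P + G3P)",
             {"xu5p": -1, "r5p": -1, "s7p": 1, "g3p": 1}, -OPEN, OPEN),
        _rxn("TAL", "transaldolase (S7P + G3P <-> E4P + F6P)",
             {"s7p": -1, "g3p": -1, "e4p": 1, "f6p": 1}, -OPEN, OPEN),
        _rxn("TKT2", "transketolase (Xu5P + E4P <-> F6P + G3P)",
             {"xu5p": -1, "e4p": -1, "f6p": 1, "g3p": 1}, -OPEN, OPEN),
        # lumped cofactor closure
        _rxn("NADH_OX", "lumped respiration (NADH oxidation)",
             {"nadh": -1, "nad": 1}, 0, OPEN),
        _rxn("ATP_SYNTH", "lumped oxidative phosphorylation",
             {"nadh": -1, "adp": -n, "pi": -n,
              "nad": 1, "atp": n, "h2o": n}, 0, OPEN),
        _rxn("THD", "transhydrogenase (NADPH <-> NADH)",
             {"nadph": -1, "nad": -1, "nadp": 1, "nadh": 1}, -OPEN, OPEN),
        _rxn("ATPM", "ATP maintenance / free hydrolysis drain",
             {"atp": -1, "h2o": -1, "adp": 1, "pi": 1}, ngam, OPEN),
        # boundary
        _rxn(MEOH_EXCHANGE, "methanol uptake (import-positive)",
             {"meoh": 1}, 0, 0, kind="exchange"),
        _rxn(CO2_EXCHANGE, "CO2 export", {"co2": -1}, 0, OPEN, kind="exchange"),
        _rxn("EX_for", "formate export", {"for": -1}, 0, OPEN, kind="exchange"),
        _rxn("EX_ac", "acetate export", {"ac": -1}, 0, OPEN, kind="exchange"),
        _rxn("EX_h2o", "water exchange", {"h2o": -1}, -OPEN, OPEN, kind="exchange"),
        _rxn("EX_pi", "phosphate exchange", {"pi": -1}, -OPEN, OPEN, kind="exchange"),
    ]
    mets = _mets(
        "meoh", "co2", "for", "f6p", "fbp", "dhap", "g3p", "pyr", "e4p",
        "r5p", "ru5p", "xu5p", "s7p", "accoa", "acp", "ac",
        "nad", "nadh", "nadp", "nadph", "atp", "adp", "pi", "coa", "h2o",
    )
    return PathwayModule(
        name="core",
        metabolites=mets,
        reactions=reactions,
        description="Host central metabolism with lumped cofactor closure.",
    )


def c1_module() -> PathwayModule:
    """RuMP-type C1 assimilation: Mdh plus the Hps-Phi fusion reactions."""
    reactions = [
        _rxn("MDH", "methanol dehydrogenase",
             {"meoh": -1, "nad": -1, "fald": 1, "nadh": 1}, 0, OPEN),
        _rxn("HPS", "hexulose-6-phosphate synthase",
             {"fald": -1, "ru5p": -1, "h6p": 1}, 0, OPEN),
        _rxn("PHI", "6-phospho-3-hexuloisomerase",
             {"h6p": -1, "f6p": 1}, 0, OPEN),
    ]
    return PathwayModule(
        name="c1",
        metabolites=_mets("meoh", "fald", "h6p", "ru5p", "f6p", "nad", "nadh"),
        reactions=reactions,
        description="Methanol dehydrogenase plus Hps-Phi (RuMP entry).",
    )


def nog_module() -> PathwayModule:
    """Non-oxidative glycolysis: phosphoketolase on F6P and Xu5P."""
    reactions = [
        _rxn("FXPK_F6P", "phosphoketolase (F6P)",
             {"f6p": -1, "pi": -1, "e4p": 1, "acp": 1, "h2o": 1}, 0, OPEN),
        _rxn("FXPK_X5P", "phosphoketolase (Xu5P)",
             {"xu5p": -1, "pi": -1, "g3p": 1, "acp": 1, "h2o": 1}, 0, OPEN),
    ]
    return PathwayModule(
        name="nog",
        metabolites=_mets("f6p", "xu5p", "e4p", "g3p", "acp", "pi", "h2o"),
        reactions=reactions,
        description="Phosphoketolase (Fxpk) reactions forming NOG.",
    )


def phb_module() -> PathwayModule:
    """PHB synthesis from acetyl-CoA, with the 3HB monomer as the product sink.

    PHB is a polymer, so the C4 monomer 3-hydroxybutyrate is the flux
    objective; PhaC is written in monomer-releasing form.
    """
    reactions = [
        _rxn("PHAA", "3-ketothiolase (PhaA)",
             {"accoa": -2, "aacoa": 1, "coa": 1}, 0, OPEN),
        _rxn("PHAB", "acetoacetyl-CoA reductase (PhaB)",
             {"aacoa": -1, "nadph": -1, "3hbcoa": 1, "nadp": 1}, 0, OPEN),
        _rxn("PHAC", "PHB synthase, monomer form (PhaC)",
             {"3hbcoa": -1, "3hb": 1, "coa": 1}, 0, OPEN),
        _rxn(PHB_SINK, "3HB monomer sink (objective)",
             {"3hb": -1}, 0, OPEN, kind="sink"),
    ]
    return PathwayModule(
        name="phb",
        metabolites=_mets("accoa", "aacoa", "3hbcoa", "3hb", "coa", "nadph", "nadp"),
        reactions=reactions,
        description="PhaA/PhaB/PhaC plus the 3HB monomer objective sink.",
    )


def xump_module() -> PathwayModule:
    """XuMP-type C1 assimilation: Mdh (shared id with c1) + Das + Dak."""
    reactions = [
        _rxn("MDH", "methanol dehydrogenase",
             {"meoh": -1, "nad": -1, "fald": 1, "nadh": 1}, 0, OPEN),
        _rxn("DAS", "dihydroxyacetone synthase",
             {"fald": -1, "xu5p": -1, "dha": 1, "g3p": 1}, 0, OPEN),
        _rxn("DAK", "dihydroxyacetone kinase",
             {"dha": -1, "atp": -1, "dhap": 1, "adp": 1}, 0, OPEN),
    ]
    return PathwayModule(
        name="xump",
        metabolites=_mets("meoh", "fald", "dha", "xu5p", "g3p", "dhap",
                          "nad", "nadh", "atp", "adp"),
        reactions=reactions,
        description="Xylulose monophosphate assimilation (Das + Dak).",
    )


def frma_module() -> PathwayModule:
    """Endogenous formaldehyde drain: lumped GSH-dependent dehydrogenase.

    FrmA oxidizes formaldehyde to formate (exported); deleting it keeps
    formaldehyde available to the assimilation pathway.  FBA optima never
    use this drain, so its presence or knockout leaves optima unchanged.
    """
    reactions = [
        _rxn("FRMA", "formaldehyde dehydrogenase (lumped GSH-dependent)",
             {"fald": -1, "nad": -1, "h2o": -1, "for": 1, "nadh": 1}, 0, OPEN),
        _rxn("EX_for", "formate export", {"for": -1}, 0, OPEN, kind="exchange"),
    ]
    return PathwayModule(
        name="frma",
        metabolites=_mets("fald", "for", "nad", "nadh", "h2o"),
        reactions=reactions,
        description="frmA formaldehyde-to-formate drain.",
    )


MODULES = {
    "core": core_module,
    "c1": c1_module,
    "nog": nog_module,
    "phb": phb_module,
    "xump": xump_module,
    "frma": frma_module,
}


def list_modules() -> List[str]:
    return list(MODULES)


def get_module(name: str) -> PathwayModule:
    try:
        return MODULES[name]()
    except KeyError:
        raise KeyError(f"unknown module {name!r}; available: {', '.join(MODULES)}")
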