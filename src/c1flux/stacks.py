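"""Named pathway stacks used throughout the analyses.

A "stack" is an assembled network: host core + assimilation module(s) +
PHB synthesis, with the methanol exchange fixed at the study uptake of
6 mmol/gDCW/h unless told otherwise.
"""

from __future__ import annotations

from typing import Optional

from .fba import FluxSolution, set_uptake, solve_fba
from .modules import (
    DEFAULT_UPTAKE,
    MEOH_EXCHANGE,
    PHB_SINK,
    c1_module,
    core_module,
    frma_module,
    nog_module,
    phb_module,
    xump_module,
)
from .network import MetabolicNetwork, add_module

__all__ = ["build_stack", "solve_stack", "STACKS"]

STACKS = ("rump", "mcc", "xump")


def build_stack(
    name: str,
    uptake: Optional[float] = DEFAULT_UPTAKE,
    fixed: bool = True,
    with_frma: bool = False,
    atp_per_nadh: float = 2.0,
    ngam: float = 0.0,
) -> MetabolicNetwork:
    """Assemble a named pathway stack.

    ``rump`` = core + C1 (Mdh, Hps-Phi) + PHB; ``mcc`` adds the
    phosphoketolase module; ``xump`` swaps the C1 entry for Das/Dak.
    ``uptake=None`` leaves the methanol exchange closed.
    """
    if name not in STACKS:
        raise KeyError(f"unknown stack {name!r}; available: {', '.join(STACKS)}")
    modules = [core_module(atp_per_nadh=atp_per_nadh, ngam=ngam)]
    if name in ("rump", "mcc"):
        modules.append(c1_module())
    if name == "mcc":
        modules.append(nog_module())
    if name == "xump":
        modules.append(xump_module())
    modules.append(phb_module())
    if with_frma:
        modules.append(frma_module())
    net = MetabolicNetwork()
    for module in modules:
        net = add_module(net, module)
    if uptake is not None:
        net = set_uptake(net, MEOH_EXCHANGE, uptake, fixed=fixed)
    return net


def solve_stack(name: str, uptake: float = DEFAULT_UPTAKE, **kwargs) -> FluxSolution:
    """Build a stack and maximize the 3HB monomer sink."""
    net = build_stack(name, uptake=uptake, **kwargs)
    return solve_fba(net, PHB_SINK, "max")
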