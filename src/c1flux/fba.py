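"""Flux balance analysis: LP formulation, solving, and an exhaustive oracle.

The problem solved is the standard one: maximize (or minimize) the flux of a
single objective reaction subject to steady state ``S v = 0`` and box bounds
``lb <= v <= ub``.  The backend is scipy's HiGHS dual simplex with fixed
tolerances; reported fluxes are rounded to 1e-9 so that reports are stable
across runs even when alternate optima exist.  An optional parsimonious
post-step (minimize total absolute flux at the fixed optimum) makes the
reported flux *distribution* deterministic as well.

:func:`vertex_oracle` is a brute-force enumerator of basic feasible
solutions for small, fully bounded problems; it exists purely as an
independent correctness check for :func:`solve_fba`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork, ModelError, build_s_matrix, carbon_imbalance

__all__ = [
    "FluxSolution",
    "set_uptake",
    "knockout",
    "solve_fba",
    "vertex_oracle",
    "boundary_carbon_flows",
]

FEASIBILITY_TOL = 1e-9
REPORT_DECIMALS = 9


@dataclass
class FluxSolution:
    """Result of one LP solve."""

    objective_id: str
    objective_value: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)
    status: str = "optimal"  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def set_uptake(
    network: MetabolicNetwork,
    exchange_id: str,
    rate: float,
    fixed: bool = True,
) -> MetabolicNetwork:
    """Return a variant network with the substrate exchange constrained.

    With ``fixed=True`` (default) both bounds are set to ``rate``: the cell
    consumes exactly that much substrate, the study's "was set to"
    convention.  ``fixed=False`` leaves the lower bound at 0, making the
    rate an upper bound; for substrate-limited production networks the
    optimum is identical under either convention.
    """
    if rate < 0:
        raise ValueError(f"uptake rate must be >= 0, got {rate}")
    rxn = network.reactions.get(exchange_id)
    if rxn is None:
        raise KeyError(f"unknown reaction {exchange_id!r}")
    if rxn.kind != "exchange":
        raise ValueError(f"{exchange_id!r} is not an exchange reaction")
    net = network.copy()
    net.replace_reaction(rxn.with_bounds(rate if fixed else 0.0, rate))
    return net


def knockout(network: MetabolicNetwork, reaction_id: str) -> MetabolicNetwork:
    """Return an independent variant with both bounds of the reaction at 0."""
    rxn = network.reactions.get(reaction_id)
    if rxn is None:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    net = network.copy()
    net.replace_reaction(rxn.with_bounds(0.0, 0.0))
    return net


_HIGHS_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


def _linprog(c, A_eq, b_eq, bounds):
    return linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs-ds",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )


def solve_fba(
    network: MetabolicNetwork,
    objective_id: str,
    direction: str = "max",
    pfba: bool = False,
) -> FluxSolution:
    """Solve the flux balance LP for one objective reaction.

    Parameters
    ----------
    objective_id:
        Reaction whose flux is optimized.
    direction:
        ``"max"`` or ``"min"``.
    pfba:
        If true and the LP is optimal, a secondary LP minimizes the total
        absolute flux with the objective pinned at its optimum, yielding a
        deterministic, parsimonious flux distribution.

    Infeasibility and unboundedness are reported in ``status``, never as a
    silent zero.
    """
    if objective_id not in network.reactions:
        raise KeyError(f"unknown objective reaction {objective_id!r}")
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")

    rxn_ids = network.reaction_ids
    n = len(rxn_ids)
    S = build_s_matrix(network)
    lb = np.array([network.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([network.reactions[r].upper_bound for r in rxn_ids])
    j_obj = rxn_ids.index(objective_id)
    sign = -1.0 if direction == "max" else 1.0
    c = np.zeros(n)
    c[j_obj] = sign

    res = _linprog(c, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    status = _HIGHS_STATUS.get(res.status, "error")
    if status != "optimal":
        if status not in ("infeasible", "unbounded"):
            raise RuntimeError(f"LP solver failure: {res.message}")
        return FluxSolution(objective_id, None, {}, status)

    v = res.x
    if pfba:
        v = _pfba_distribution(S, lb, ub, j_obj, v[j_obj])

    v = np.round(v, REPORT_DECIMALS) + 0.0  # normalize -0.0
    fluxes = dict(zip(rxn_ids, v.tolist()))
    return FluxSolution(objective_id, float(v[j_obj]), fluxes, "optimal")


def _pfba_distribution(S, lb, ub, j_obj, opt):
    """Minimize sum |v| subject to S v = 0, bounds, and v[j_obj] = opt."""
    m, n = S.shape
    # v = p - q with p, q >= 0
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    row = np.zeros(2 * n)
    row[j_obj], row[n + j_obj] = 1.0, -1.0
    A_eq = np.vstack([A_eq, row])
    b_eq = np.append(b_eq, opt)
    bounds = [(0.0, max(u, 0.0)) for u in ub] + [(0.0, max(-l, 0.0)) for l in lb]
    res = _linprog(np.ones(2 * n), A_eq, b_eq, bounds)
    if res.status != 0:  # numerically pinched; fall back to the primal answer
        raise RuntimeError(f"pFBA restep failed: {res.message}")
    return res.x[:n] - res.x[n:]


def vertex_oracle(
    network: MetabolicNetwork,
    objective_id: str,
    direction: str = "max",
    max_reactions: int = 12,
) -> Tuple[str, Optional[float]]:
    """Brute-force LP optimum by enumerating basic feasible solutions.

    Enumerates every choice of non-basic variables pinned at a finite bound
    and solves the remaining square-rank system; the best objective over all
    feasible vertices is the LP optimum (the feasible set is a bounded
    polytope, so an optimum, if the problem is feasible, is at a vertex).
    Intended for tests only; guarded to ``max_reactions`` free reactions
    and to finite bounds.

    Returns ``(status, value)`` with status ``optimal`` or ``infeasible``.
    """
    if objective_id not in network.reactions:
        raise KeyError(f"unknown objective reaction {objective_id!r}")
    rxn_ids = [
        r for r in network.reaction_ids
        if not (network.reactions[r].lower_bound == 0 == network.reactions[r].upper_bound)
    ]
    if len(rxn_ids) > max_reactions:
        raise ValueError(
            f"vertex oracle limited to {max_reactions} active reactions, "
            f"got {len(rxn_ids)}"
        )
    lb = np.array([network.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([network.reactions[r].upper_bound for r in rxn_ids])
    if not (np.isfinite(lb).all() and np.isfinite(ub).all()):
        raise ValueError("vertex oracle requires finite bounds")

    met_index = {m: i for i, m in enumerate(network.metabolite_ids)}
    n = len(rxn_ids)
    S = np.zeros((len(met_index), n))
    for j, rid in enumerate(rxn_ids):
        for met, coeff in network.reactions[rid].stoichiometry.items():
            S[met_index[met], j] = float(coeff)

    if objective_id not in rxn_ids:  # objective fixed to zero
        # feasibility still needs checking; treat as objective column of zeros
        rxn_ids = rxn_ids + [objective_id]
        S = np.hstack([S, np.zeros((S.shape[0], 1))])
        lb = np.append(lb, 0.0)
        ub = np.append(ub, 0.0)
        n += 1
    j_obj = rxn_ids.index(objective_id)

    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    sign = 1.0 if direction == "max" else -1.0
    best = None
    tol = 1e-8
    scale = max(1.0, np.abs(ub).max(), np.abs(lb).max())
    for basic in itertools.combinations(range(n), r):
        S_B = S[:, basic]
        if r and np.linalg.matrix_rank(S_B) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for pattern in itertools.product((0, 1), repeat=len(nonbasic)):
            v = np.empty(n)
            for j, at_ub in zip(nonbasic, pattern):
                v[j] = ub[j] if at_ub else lb[j]
            rhs = -S[:, nonbasic] @ v[nonbasic] if nonbasic else np.zeros(S.shape[0])
            if r:
                sol, *_ = np.linalg.lstsq(S_B, rhs, rcond=None)
                if np.abs(S_B @ sol - rhs).max() > tol * scale:
                    continue
                v[list(basic)] = sol
            if ((v < lb - tol * scale) | (v > ub + tol * scale)).any():
                continue
            val = sign * v[j_obj]
            if best is None or val > best:
                best = val
    if best is None:
        return "infeasible", None
    return "optimal", sign * best


def boundary_carbon_flows(
    network: MetabolicNetwork, solution: FluxSolution
) -> Dict[str, float]:
    """Carbon import/export bookkeeping at an optimal solution.

    Returns ``carbon_in``, ``carbon_out`` (C-mmol/gDCW/h crossing the
    boundary, both non-negative) and ``co2_flux`` (net CO2 export).  For a
    network whose internal reactions are all carbon-balanced, in and out
    agree at steady state.
    """
    if not solution.optimal:
        raise ValueError("carbon flows require an optimal solution")
    carbon_in = carbon_out = 0.0
    co2_flux = 0.0
    for rid, rxn in network.reactions.items():
        if not rxn.boundary:
            continue
        flux = solution.fluxes.get(rid, 0.0)
        net_c = float(carbon_imbalance(rxn, network.metabolites)) * flux
        if net_c > 0:
            carbon_in += net_c
        else:
            carbon_out -= net_c
        (met_id,) = rxn.stoichiometry
        if met_id == "co2":
            co2_flux += -float(rxn.stoichiometry[met_id]) * flux
    return {"carbon_in": carbon_in, "carbon_out": carbon_out, "co2_flux": co2_flux}
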