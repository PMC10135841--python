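"""LP engine: solver vs brute-force vertex oracle, invariants, cross-checks."""

from fractions import Fraction

import numpy as np
import pytest

from c1flux import (
    MEOH_EXCHANGE,
    PHB_SINK,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    add_module,
    boundary_carbon_flows,
    build_stack,
    c1_module,
    core_module,
    knockout,
    make_known_optimum_network,
    nog_module,
    phb_module,
    set_uptake,
    solve_fba,
    vertex_oracle,
    SyntheticNetworkSpec,
)


def test_toy_chain_optimum(toy_chain):
    sol = solve_fba(toy_chain, "SINK_B", "max")
    assert sol.optimal
    assert sol.objective_value == pytest.approx(1.0, abs=1e-9)
    assert sol.fluxes["SINK_B"] == sol.objective_value
    st, val = vertex_oracle(toy_chain, "SINK_B")
    assert st == "optimal" and val == pytest.approx(1.0, abs=1e-7)


def test_solution_satisfies_steady_state_and_bounds(mcc_net):
    from c1flux import build_s_matrix

    sol = solve_fba(mcc_net, PHB_SINK)
    v = np.array([sol.fluxes[r] for r in mcc_net.reaction_ids])
    S = build_s_matrix(mcc_net)
    assert np.abs(S @ v).max() <= 1e-6
    for rid, rxn in mcc_net.reactions.items():
        assert rxn.lower_bound - 1e-9 <= sol.fluxes[rid] <= rxn.upper_bound + 1e-9


def test_set_uptake_validation(mcc_net):
    with pytest.raises(KeyError):
        set_uptake(mcc_net, "EX_nope", 6)
    with pytest.raises(ValueError, match="not an exchange"):
        set_uptake(mcc_net, "MDH", 6)
    with pytest.raises(ValueError, match=">= 0"):
        set_uptake(mcc_net, MEOH_EXCHANGE, -1)


def test_zero_uptake_means_zero_product(mcc_net):
    sol = solve_fba(set_uptake(mcc_net, MEOH_EXCHANGE, 0), PHB_SINK)
    assert sol.optimal and sol.objective_value == pytest.approx(0, abs=1e-9)


def test_optimum_scales_linearly_with_uptake(mcc_net):
    """LP homogeneity: doubling the sole substrate bound doubles the optimum."""
    base = solve_fba(mcc_net, PHB_SINK).objective_value
    doubled = solve_fba(set_uptake(mcc_net, MEOH_EXCHANGE, 12), PHB_SINK).objective_value
    assert doubled == pytest.approx(2 * base, abs=1e-8)
    assert doubled == pytest.approx(3.0, abs=1e-8)


def test_fixed_and_upper_bounded_uptake_agree_on_these_models():
    for name in ("rump", "mcc"):
        fixed = solve_fba(build_stack(name, fixed=True), PHB_SINK).objective_value
        bounded = solve_fba(build_stack(name, fixed=False), PHB_SINK).objective_value
        assert fixed == pytest.approx(bounded, abs=1e-9)


def test_knockout_returns_independent_variant(mcc_net):
    before = mcc_net.reactions["FXPK_F6P"].upper_bound
    variant = knockout(mcc_net, "FXPK_F6P")
    assert variant.reactions["FXPK_F6P"].lower_bound == 0
    assert variant.reactions["FXPK_F6P"].upper_bound == 0
    assert mcc_net.reactions["FXPK_F6P"].upper_bound == before  # original untouched
    # knocking out an already-disabled reaction is the identity
    again = knockout(variant, "FXPK_F6P")
    assert again.reactions["FXPK_F6P"] == variant.reactions["FXPK_F6P"]
    with pytest.raises(KeyError):
        knockout(mcc_net, "NOPE")


def test_hps_knockout_zeroes_production_when_drain_exists(mcc_frma_net):
    """With the sole assimilation entry severed, formaldehyde exits via the
    frmA drain and no product can form."""
    sol = solve_fba(knockout(mcc_frma_net, "HPS"), PHB_SINK)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0, abs=1e-9)


def test_infeasible_reported_as_status_not_silent_zero():
    mets = [Metabolite("A", carbon_count=1)]
    rxns = [
        Reaction("EX_A", {"A": Fraction(1)}, lower_bound=1, upper_bound=1, kind="exchange"),
        Reaction("SINK_A", {"A": Fraction(-1)}, lower_bound=0, upper_bound=0, kind="sink"),
    ]
    net = MetabolicNetwork(mets, rxns)
    sol = solve_fba(net, "SINK_A")
    assert sol.status == "infeasible" and sol.objective_value is None
    st, val = vertex_oracle(net, "SINK_A")
    assert st == "infeasible" and val is None


def test_unknown_objective_raises(mcc_net):
    with pytest.raises(KeyError):
        solve_fba(mcc_net, "NOPE")


def test_oracle_equivalence_on_100_random_networks():
    """solve_fba and the brute-force vertex enumerator agree on status and
    optimum for 100 seeded random networks."""
    for seed in range(100):
        spec = SyntheticNetworkSpec(
            seed=seed,
            n_chain=3 + seed % 3,
            n_branch=seed % 4,
            bound_scale=0.5 + (seed % 5) * 0.5,
        )
        net, known = make_known_optimum_network(spec)
        sol = solve_fba(net, "SINK_out")
        st, val = vertex_oracle(net, "SINK_out")
        assert sol.status == st == "optimal"
        assert sol.objective_value == pytest.approx(known, abs=1e-9)
        assert val == pytest.approx(sol.objective_value, abs=1e-7)


def test_module_addition_is_monotone():
    """Adding reactions can only enlarge the feasible set."""
    core = add_module(MetabolicNetwork(), core_module())
    stages = [c1_module(), phb_module(), nog_module()]
    net = core
    prev = None
    for mod in stages:
        net = add_module(net, mod)
        if PHB_SINK not in net.reactions:
            continue
        opt = solve_fba(
            set_uptake(net, MEOH_EXCHANGE, 6, fixed=False), PHB_SINK
        ).objective_value
        if prev is not None:
            assert opt >= prev - 1e-9
        prev = opt
    assert prev == pytest.approx(1.5, abs=1e-9)


def test_carbon_closure_at_optimum(rump_net, mcc_net):
    """All internal reactions are carbon-balanced, so boundary carbon in
    equals boundary carbon out at any optimum."""
    for net in (rump_net, mcc_net):
        sol = solve_fba(net, PHB_SINK)
        flows = boundary_carbon_flows(net, sol)
        assert flows["carbon_in"] == pytest.approx(flows["carbon_out"], abs=1e-6)
        assert flows["carbon_in"] == pytest.approx(6.0, abs=1e-6)


def test_mcc_optimum_exports_no_co2(mcc_net):
    sol = solve_fba(mcc_net, PHB_SINK)
    assert boundary_carbon_flows(mcc_net, sol)["co2_flux"] == pytest.approx(0, abs=1e-6)


def test_optima_insensitive_to_lumped_atp_stoichiometry():
    """Carbon-limited optima do not depend on the P/O-like ATP:NADH ratio."""
    for name in ("rump", "mcc"):
        opts = {
            solve_fba(build_stack(name, atp_per_nadh=ratio), PHB_SINK).objective_value
            for ratio in (1.0, 2.0)
        }
        assert len({round(o, 9) for o in opts}) == 1


def test_pfba_distribution_is_deterministic_and_same_objective(mcc_net):
    a = solve_fba(mcc_net, PHB_SINK, pfba=True)
    b = solve_fba(mcc_net, PHB_SINK, pfba=True)
    plain = solve_fba(mcc_net, PHB_SINK)
    assert a.objective_value == pytest.approx(plain.objective_value, abs=1e-9)
    assert a.fluxes == b.fluxes
    # the parsimonious distribution carries no futile PFK/FBPase cycling
    assert min(a.fluxes["PFK"], a.fluxes["FBPASE"]) <= 1e-6


def test_cross_check_against_cobrapy(rump_net, mcc_net, toy_chain):
    """Independent solver route: the same LP built in cobrapy (GLPK) gives
    the same optimum."""
    cobra = pytest.importorskip("cobra")

    def to_cobra(net):
        m = cobra.Model("x")
        cmets = {mid: cobra.Metabolite(mid, compartment="c") for mid in net.metabolites}
        rxns = []
        for rid, rxn in net.reactions.items():
            cr = cobra.Reaction(rid)
            cr.lower_bound, cr.upper_bound = rxn.lower_bound, rxn.upper_bound
            rxns.append(cr)
        m.add_reactions(rxns)
        for rid, rxn in net.reactions.items():
            m.reactions.get_by_id(rid).add_metabolites(
                {cmets[mid]: float(c) for mid, c in rxn.stoichiometry.items()}
            )
        return m

    for net, objective, expected in (
        (toy_chain, "SINK_B", 1.0),
        (rump_net, PHB_SINK, 1.0),
        (mcc_net, PHB_SINK, 1.5),
    ):
        ours = solve_fba(net, objective).objective_value
        cm = to_cobra(net)
        cm.objective = objective
        theirs = cm.optimize().objective_value
        assert ours == pytest.approx(expected, abs=1e-9)
        assert theirs == pytest.approx(ours, abs=1e-6)
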