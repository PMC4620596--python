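"""LP assembly: block structure, explicit-solution acceptance, bounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfba import (
    CFBAModel,
    Compound,
    MaintenanceConstraint,
    Reaction,
    assemble_lp,
    binary_light,
    build_toy_model,
    check_solution,
    is_feasible,
    make_grid,
    single_autocatalyst_alpha,
    single_autocatalyst_model,
)


def test_variable_count_matches_block_structure(toy_model):
    grid = make_grid(24, 2, 24)
    lp = assemble_lp(toy_model, grid, 1.0, binary_light(grid))
    n_dynamic, n_reactions = 2, 3
    assert lp.n_vars == n_dynamic * 3 + n_reactions * 2


def test_all_blocks_traceable(toy_model):
    grid = make_grid(24, 4, 24)
    lp = assemble_lp(toy_model, grid, 1.2, binary_light(grid))
    expected = {
        "steady_state", "euler_update", "capacity", "quota",
        "maintenance", "cyclic_growth", "start_biomass",
    }
    assert set(lp.blocks) == expected
    # one capacity row per constraint per interval
    kind, start, stop = lp.blocks["capacity"]
    assert kind == "ub" and stop - start == 4


def test_zero_flux_solution_feasible_without_maintenance():
    """With maintenance off and alpha = 1, holding the start amounts
    constant with zero flux satisfies every block."""
    model = build_toy_model()
    grid = make_grid(24, 4, 24)
    light = binary_light(grid)
    lp = assemble_lp(model, grid, 1.0, light)
    M0 = np.array([0.5, 0.5])  # meets the Z quota and start biomass B0=1
    M = np.tile(M0, (5, 1))
    v = np.zeros((4, 3))
    viol = check_solution(lp, M, v)
    assert max(viol.values()) <= 1e-12
    assert is_feasible(model, grid, light, 1.0)


def test_explicit_euler_recursion_accepted():
    """The closed-form geometric trajectory of the single-autocatalyst
    model is accepted exactly at its maximal alpha."""
    c, n_t = 0.2, 6
    model = single_autocatalyst_model(c)
    grid = make_grid(24, n_t, 24)
    light = binary_light(grid)
    dt = 24 / n_t
    alpha = single_autocatalyst_alpha(c, 24, n_t)
    M = np.array([[(1 + c * dt) ** k] for k in range(n_t + 1)])
    v = np.array([[c * M[k, 0]] for k in range(n_t)])
    lp = assemble_lp(model, grid, alpha, light)
    viol = check_solution(lp, M, v)
    assert max(viol.values()) <= 1e-9


def test_dark_interval_blocks_light_driven_flux():
    model = CFBAModel(
        name="lightbox",
        compounds=[Compound("E", "dynamic", biomass_weight=1.0)],
        reactions=[Reaction("grow", {"E": 1.0}, light_driven=True)],
        externals=(),
    )
    grid = make_grid(24, 4, 12)
    lp = assemble_lp(model, grid, 1.0, binary_light(grid))
    # fluxes of the two dark intervals are fixed to zero
    for k in (3, 4):
        s = lp.v_slice(k)
        assert lp.ub[s.start] == 0.0


def test_invalid_inputs_rejected(toy_model):
    grid = make_grid(24, 4, 24)
    light = binary_light(grid)
    with pytest.raises(ValueError, match="alpha"):
        assemble_lp(toy_model, grid, 0.0, light)
    broken = CFBAModel(
        name="broken",
        compounds=[Compound("E", "dynamic", biomass_weight=1.0)],
        reactions=[Reaction("r", {})],
    )
    with pytest.raises(ValueError, match="validation"):
        assemble_lp(broken, grid, 1.0, binary_light(grid))


def test_maintenance_anchored_to_interval_start_biomass():
    """A biomass-proportional maintenance demand makes the zero-flux
    solution infeasible but a matching constant flux feasible."""
    model = CFBAModel(
        name="maintained",
        compounds=[Compound("G", "dynamic", biomass_weight=1.0)],
        reactions=[Reaction("burn", {"G": -0.0001}),
                   Reaction("make", {"G": 1.0})],
        maintenance_constraints=[
            MaintenanceConstraint({"burn": 1.0}, biomass_coefficient=0.01)
        ],
    )
    grid = make_grid(24, 4, 24)
    light = binary_light(grid)
    lp = assemble_lp(model, grid, 1.0, light)
    M = np.ones((5, 1))
    viol = check_solution(lp, M, np.zeros((4, 2)))
    assert viol["maintenance"] > 0
    v = np.zeros((4, 2))
    v[:, 0] = 0.01  # burn at exactly the demanded rate
    v[:, 1] = 0.0001 * 0.01  # replace the burned material
    M2 = np.ones((5, 1))
    for k in range(4):
        M2[k + 1, 0] = M2[k, 0]  # net change is zero by construction
    assert check_solution(lp, M2, v)["maintenance"] <= 1e-12


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    c=st.floats(0.05, 0.5),
    n_t=st.integers(2, 10),
    eps=st.floats(1e-3, 0.5),
)
def test_feasibility_is_monotone_in_alpha(c, n_t, eps):
    """is_feasible flips from True to False exactly at the closed-form
    optimum of the single-autocatalyst model (bisection's premise)."""
    model = single_autocatalyst_model(c)
    grid = make_grid(24, n_t, 24)
    light = binary_light(grid)
    alpha_star = single_autocatalyst_alpha(c, 24, n_t)
    assert is_feasible(model, grid, light, alpha_star * (1 - eps))
    assert not is_feasible(model, grid, light, alpha_star * (1 + eps))
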