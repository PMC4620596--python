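"""Bisection, representative trajectories and variability analysis."""

import dataclasses

import numpy as np
import pytest

from cfba import (
    CFBAModel,
    Compound,
    MaintenanceConstraint,
    NoGrowthError,
    Reaction,
    binary_light,
    is_feasible,
    make_grid,
    maximize_alpha,
    single_autocatalyst_alpha,
    single_autocatalyst_model,
    variability,
)


@pytest.fixture(scope="module")
def autocat():
    c, n_t = 0.25, 8
    model = single_autocatalyst_model(c)
    grid = make_grid(24, n_t, 24)
    return model, grid, binary_light(grid), single_autocatalyst_alpha(c, 24, n_t)


class TestIsFeasible:
    def test_flips_at_closed_form_optimum(self, autocat):
        model, grid, light, alpha_star = autocat
        assert is_feasible(model, grid, light, alpha_star / (1 + 1e-3))
        assert not is_feasible(model, grid, light, alpha_star * (1 + 1e-3))

    def test_certificate_satisfies_lp(self, autocat):
        model, grid, light, alpha_star = autocat
        ok, traj = is_feasible(model, grid, light, 1.5, certificate=True)
        assert ok and traj is not None
        assert traj.M.shape == (grid.n_t + 1, 1)
        assert np.all(traj.M >= -1e-9)

    def test_toy_infeasible_at_huge_alpha(self, toy_model, small_toy_scenario):
        grid, light = small_toy_scenario
        assert not is_feasible(toy_model, grid, light, 1e6)


class TestMaximizeAlpha:
    def test_matches_euler_closed_form(self, autocat):
        model, grid, light, alpha_star = autocat
        alpha, traj = maximize_alpha(model, grid, light, tol=1e-8)
        assert alpha == pytest.approx(alpha_star, rel=1e-6)
        # the trajectory is the geometric Euler recursion
        growth = traj.M[1:, 0] / traj.M[:-1, 0]
        assert np.allclose(growth, 1 + 0.25 * grid.dt[0], rtol=1e-6)

    def test_no_growth_error(self):
        """Forced maintenance that burns an irreplaceable compound admits
        no cyclic solution at all."""
        model = CFBAModel(
            name="doomed",
            compounds=[Compound("G", "dynamic", biomass_weight=1.0)],
            reactions=[Reaction("burn", {"G": -1.0})],
            maintenance_constraints=[
                MaintenanceConstraint({"burn": 1.0}, biomass_coefficient=0.01)
            ],
        )
        grid = make_grid(24, 4, 24)
        with pytest.raises(NoGrowthError):
            maximize_alpha(model, grid, binary_light(grid))

    def test_static_model_alpha_one(self):
        """Nothing grows, nothing decays: the maximal factor is exactly 1."""
        model = CFBAModel(
            name="inert",
            compounds=[Compound("E", "dynamic", biomass_weight=1.0)],
            reactions=[Reaction("noop", {"E": 0.0001}, upper_bound=0.0)],
        )
        grid = make_grid(24, 4, 24)
        alpha, _ = maximize_alpha(model, grid, binary_light(grid), tol=1e-7)
        assert alpha == pytest.approx(1.0, rel=1e-6)

    def test_scale_invariance(self, toy_model, small_toy_scenario):
        """Multiplying B0 and all flux bounds by a common factor leaves
        the growth factor unchanged."""
        grid, light = small_toy_scenario
        alpha1, _ = maximize_alpha(toy_model, grid, light)
        s = 7.3
        scaled = dataclasses.replace(
            toy_model,
            biomass_start_cap=toy_model.biomass_start_cap * s,
            reactions=[
                dataclasses.replace(
                    r,
                    lower_bound=r.lower_bound * s if np.isfinite(r.lower_bound) else r.lower_bound,
                    upper_bound=r.upper_bound * s if np.isfinite(r.upper_bound) else r.upper_bound,
                )
                for r in toy_model.reactions
            ],
        )
        alpha2, _ = maximize_alpha(scaled, grid, light)
        assert alpha2 == pytest.approx(alpha1, rel=5e-6)

    def test_deterministic_reruns(self, toy_model, small_toy_scenario):
        grid, light = small_toy_scenario
        a1, t1 = maximize_alpha(toy_model, grid, light)
        a2, t2 = maximize_alpha(toy_model, grid, light)
        assert a1 == a2
        assert np.array_equal(t1.M, t2.M) and np.array_equal(t1.v, t2.v)

    def test_invalid_tolerance(self, toy_model, small_toy_scenario):
        grid, light = small_toy_scenario
        with pytest.raises(ValueError):
            maximize_alpha(toy_model, grid, light, tol=0.0)


class TestTrajectory:
    def test_tidy_frame_layout(self, autocat):
        model, grid, light, _ = autocat
        _, traj = maximize_alpha(model, grid, light)
        df = traj.to_frame()
        assert set(df.kind) == {"amount", "flux"}
        assert len(df) == (grid.n_t + 1) * 1 + grid.n_t * 1
        assert (df[df.kind == "flux"].t_end - df[df.kind == "flux"].t_start > 0).all()


class TestVariability:
    def test_single_path_envelope_is_tight(self, autocat):
        """A one-path network has a unique solution: zero envelope width."""
        model, grid, light, _ = autocat
        alpha, traj = maximize_alpha(model, grid, light, tol=1e-9)
        env = variability(model, grid, light, alpha)
        assert env.failures == []
        width_v = np.nanmax(env.flux_max - env.flux_min)
        width_m = np.nanmax(env.comp_max - env.comp_min)
        scale = np.nanmax(env.comp_max)
        assert width_v <= 1e-6 * scale
        assert width_m <= 1e-6 * scale
        assert env.contains(traj)

    def test_subset_selection(self, autocat):
        model, grid, light, _ = autocat
        alpha, _ = maximize_alpha(model, grid, light)
        env = variability(model, grid, light, alpha, fluxes=["make_E"],
                          compounds=[], intervals=[1, 2])
        computed = ~np.isnan(env.flux_min)
        assert computed.sum() == 2
        assert np.isnan(env.comp_min).all()
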