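"""Variable-viscosity channel solver: analytic limits, two-layer oracle,
pressure-loss coefficients and their invariances."""

import numpy as np
import pytest

from cflvisc import (
    CFLDevelopment,
    ChannelGeometry,
    FlowConditions,
    FluidSpec,
    GridSpec,
    assemble_field,
    bulk_velocity_from_re,
    march_pressure_loss,
    normalized_cp,
    pressure_loss_coefficient,
    reynolds_number,
    solve_developed_profile,
    two_layer_effective_viscosity,
    wall_shear_comparison,
)
from cflvisc.flow import FlowError

H = 150e-6


def two_layer_cells(n, k_cfl, mu_cfl, mu_core):
    """Symmetric two-layer viscosity with interfaces on cell edges."""
    mu = np.full(n, mu_core)
    mu[:k_cfl] = mu_cfl
    mu[n - k_cfl:] = mu_cfl
    return mu


class TestDevelopedSolution:
    def test_plane_poiseuille_closed_forms(self):
        mu, c = 1.38e-3, 1.0
        sol = solve_developed_profile(np.full(1024, mu), c, H)
        assert sol.tau_w_bottom == pytest.approx(6 * mu * c / H, rel=1e-12)
        assert sol.tau_w_top == pytest.approx(6 * mu * c / H, rel=1e-12)
        assert sol.G == pytest.approx(12 * mu * c / H**2, rel=1e-12)
        assert sol.tau_w_bottom == pytest.approx(55.2, rel=1e-9)
        assert sol.G == pytest.approx(736_000.0, rel=1e-9)
        # parabolic velocity profile u = 6 c (h/H)(1 - h/H)
        hh = sol.h_nodes_m
        np.testing.assert_allclose(
            sol.u, 6 * c * (hh / H) * (1 - hh / H), rtol=1e-10, atol=1e-12
        )

    def test_two_layer_matches_effective_viscosity_oracle(self):
        # independent closed form: 1/mu_eff = (b/a)^3/mu_core + (1-(b/a)^3)/mu_cfl
        n, k = 1024, 137  # per-wall CFL of 137 cells, edges on the grid
        mu_cfl, mu_core, c = 1.38e-3, 1.47545e-3, 1.0
        mu = two_layer_cells(n, k, mu_cfl, mu_core)
        sol = solve_developed_profile(mu, c, H)
        a = H / 2
        b = a - k * H / n
        mu_eff = two_layer_effective_viscosity(mu_core, mu_cfl, a, b)
        assert sol.G == pytest.approx(12 * mu_eff * c / H**2, rel=1e-6)

    def test_hand_evaluated_two_layer_case(self):
        # 20 µm CFL per wall (b = 55 µm, a = 75 µm) of the 5 % blood case
        n, k = 150, 20
        mu = two_layer_cells(n, k, 1.38e-3, 1.47545e-3)
        sol = solve_developed_profile(mu, 1.0, H)
        mu_eff = sol.G * H**2 / 12.0
        assert mu_eff == pytest.approx(1.41613e-3, rel=1e-5)

    def test_symmetric_profile_symmetric_solution(self, rng):
        half = rng.uniform(1e-3, 3e-3, size=128)
        mu = np.concatenate([half, half[::-1]])
        sol = solve_developed_profile(mu, 0.8, H)
        assert sol.h0_m == pytest.approx(H / 2, rel=1e-12)
        np.testing.assert_allclose(sol.u, sol.u[::-1], rtol=1e-9, atol=1e-12)
        assert sol.tau_w_bottom == pytest.approx(sol.tau_w_top, rel=1e-12)

    def test_grid_refinement_second_order_for_smooth_viscosity(self):
        # smooth profile: cell-average representation converges ~O(dh^2)
        def mu_fun(h):
            return 1.5e-3 + 0.5e-3 * np.sin(np.pi * h / H)

        def solve_n(n):
            e = np.linspace(0, H, n + 1)
            centers = 0.5 * (e[:-1] + e[1:])
            return solve_developed_profile(mu_fun(centers), 1.0, H).G

        g_fine = solve_n(8192)
        err = [abs(solve_n(n) - g_fine) / g_fine for n in (64, 128, 256)]
        rates = np.log2(np.array(err[:-1]) / np.array(err[1:]))
        assert np.all(rates > 1.8)

    def test_invalid_inputs(self):
        with pytest.raises(FlowError):
            solve_developed_profile(np.array([1e-3, -1e-3]), 1.0, H)
        with pytest.raises(FlowError):
            solve_developed_profile(np.full(8, 1e-3), -1.0, H)


class TestConditions:
    def test_bulk_velocity_from_re(self, blood):
        c = bulk_velocity_from_re(100.0, blood, 150e-6)
        assert c == pytest.approx(0.92063, rel=1e-4)
        assert bulk_velocity_from_re(0.0, blood, 150e-6) == 0.0
        assert bulk_velocity_from_re(200.0, blood, 150e-6) == pytest.approx(2 * c)

    def test_round_trip_re(self, blood, geom):
        cond = FlowConditions(reynolds=100.0)
        re, c = cond.resolve(blood, geom)
        assert reynolds_number(c, blood, geom.H_m) == pytest.approx(re, rel=1e-12)

    def test_exactly_one_prescription(self):
        with pytest.raises(FlowError):
            FlowConditions(reynolds=100.0, bulk_velocity=1.0)
        with pytest.raises(FlowError):
            FlowConditions()

    def test_out_of_band_re_warns(self, blood, geom):
        with pytest.warns(UserWarning, match="outside"):
            FlowConditions(reynolds=1000.0).resolve(blood, geom)


class TestMarch:
    def test_uniform_field_reduces_to_poiseuille(self, baf, geom, aligned_grid):
        dev0 = CFLDevelopment(a=0.0, x0_um=1.0)
        field = assemble_field(baf, geom, dev0, grid=aligned_grid)
        cond = FlowConditions(reynolds=100.0)
        run = march_pressure_loss(field, cond, geom)
        expected = 12 * baf.mu_rheo * run.bulk_velocity * geom.L_m / geom.H_m**2
        assert run.delta_p == pytest.approx(expected, rel=1e-10)
        # cp of a developed uniform run: 24 L / (H Re)
        assert run.cp == pytest.approx(
            24 * geom.L_m / (geom.H_m * run.reynolds), rel=1e-10
        )

    def test_cfl_field_loses_less_pressure(self, baf, geom, dev, aligned_grid):
        cond = FlowConditions(reynolds=100.0)
        model = march_pressure_loss(
            assemble_field(baf, geom, dev, grid=aligned_grid), cond, geom
        )
        uniform = march_pressure_loss(
            assemble_field(baf, geom, CFLDevelopment(a=0.0), grid=aligned_grid),
            cond,
            geom,
        )
        assert model.delta_p < uniform.delta_p

    def test_gradient_decreases_as_cfl_grows(self, baf, geom, dev, aligned_grid):
        field = assemble_field(baf, geom, dev, grid=aligned_grid)
        run = march_pressure_loss(field, FlowConditions(reynolds=100.0), geom)
        assert np.all(np.diff(run.G) <= 1e-9 * run.G[0])

    def test_flow_rate_conserved_every_station(self, baf, geom, dev, aligned_grid):
        # bulk of u equals the prescribed bulk velocity at each station
        field = assemble_field(baf, geom, dev, grid=aligned_grid)
        cond = FlowConditions(reynolds=100.0)
        _, c = cond.resolve(baf, geom)
        for j in range(0, field.x_um.size, 7):
            sol = solve_developed_profile(field.mu[:, j], c, geom.H_m)
            e = sol.h_nodes_m
            bulk = np.trapezoid(sol.u, e) / geom.H_m
            # node-trapezoid on the piecewise-quadratic u is itself O(dh^2);
            # the solver's internal per-cell quadrature is exact
            assert bulk == pytest.approx(c, rel=5e-5)


class TestNormalisedCp:
    def test_single_phase_ratio_is_unity(self, baf, geom, aligned_grid):
        dev0 = CFLDevelopment(a=0.0, x0_um=1.0)
        cond = FlowConditions(reynolds=100.0)
        model = march_pressure_loss(
            assemble_field(baf, geom, dev0, grid=aligned_grid), cond, geom
        )
        carrier = baf.carrier_only()
        ref = march_pressure_loss(
            assemble_field(carrier, geom, dev0, grid=aligned_grid), cond, geom
        )
        assert normalized_cp(model, ref) == pytest.approx(1.0, abs=1e-14)

    def test_mismatched_re_rejected(self, baf, geom, aligned_grid):
        dev0 = CFLDevelopment(a=0.0, x0_um=1.0)
        field = assemble_field(baf, geom, dev0, grid=aligned_grid)
        r1 = march_pressure_loss(field, FlowConditions(reynolds=100.0), geom)
        r2 = march_pressure_loss(field, FlowConditions(reynolds=150.0), geom)
        with pytest.raises(FlowError, match="Reynolds"):
            normalized_cp(r1, r2)

    def test_blood_ratio_brackets_lower_bound(self, blood, geom, aligned_grid):
        # ratio strictly within (mu_carrier/mu_rheo, 1) for any CFL height
        lower = blood.mu_carrier / blood.mu_rheo
        cond = FlowConditions(reynolds=100.0)
        carrier_ref = march_pressure_loss(
            assemble_field(blood.carrier_only(), geom, CFLDevelopment(a=0.0),
                           grid=aligned_grid),
            cond, geom,
        )
        for h_ss in (5.0, 20.0, 45.0):
            dev = CFLDevelopment(a=2.0, x0_um=1.0, h_ss_um=h_ss)
            run = march_pressure_loss(
                assemble_field(blood, geom, dev, grid=aligned_grid), cond, geom
            )
            ratio = normalized_cp(run, carrier_ref)
            assert lower < ratio < 1.0

    def test_pressure_loss_coefficient_definition(self):
        assert pressure_loss_coefficient(0.5 * 1050 * 2.0**2, 1050, 2.0) == 1.0
        assert pressure_loss_coefficient(10.0, 1000, 1.0) == pytest.approx(
            2 * pressure_loss_coefficient(5.0, 1000, 1.0)
        )
        with pytest.raises(FlowError):
            pressure_loss_coefficient(1.0, 1000, 0.0)


class TestDimensionlessInvariances:
    @pytest.mark.parametrize("density", [1000.0, 1060.0, 1200.0])
    def test_density_independence(self, geom, aligned_grid, density):
        fluid = FluidSpec(1.38e-3, 1.45e-3, 0.05, density=density)
        dev = CFLDevelopment(a=0.5, x0_um=1.0, h_ss_um=20.0)
        cond = FlowConditions(reynolds=100.0)
        run = march_pressure_loss(
            assemble_field(fluid, geom, dev, grid=aligned_grid), cond, geom
        )
        ref = march_pressure_loss(
            assemble_field(fluid.carrier_only(), geom, CFLDevelopment(a=0.0),
                           grid=aligned_grid),
            cond, geom,
        )
        assert normalized_cp(run, ref) == pytest.approx(0.9778, abs=2e-4)

    def test_reynolds_independence_of_cp_ratio(self, blood, geom, dev, aligned_grid):
        field = assemble_field(blood, geom, dev, grid=aligned_grid)
        ref_field = assemble_field(
            blood.carrier_only(), geom, CFLDevelopment(a=0.0), grid=aligned_grid
        )
        ratios = []
        for re in (50.0, 100.0, 150.0):
            cond = FlowConditions(reynolds=re)
            run = march_pressure_loss(field, cond, geom)
            ref = march_pressure_loss(ref_field, cond, geom)
            ratios.append(normalized_cp(run, ref))
        assert np.ptp(ratios) < 1e-10


class TestWallShearComparison:
    def test_no_cfl_identical_wss(self, baf, geom, aligned_grid):
        dev0 = CFLDevelopment(a=0.0, x0_um=1.0)
        tau_s, tau_m, rel = wall_shear_comparison(
            baf, geom, dev0, FlowConditions(reynolds=100.0), grid=aligned_grid
        )
        assert tau_m == pytest.approx(tau_s, rel=1e-14)
        assert rel == pytest.approx(0.0, abs=1e-14)

    def test_carrier_equals_bulk_identical_wss(self, geom, aligned_grid):
        fluid = FluidSpec(2.85e-3, 2.85e-3, 0.0)
        dev = CFLDevelopment(a=0.5, x0_um=1.0, h_ss_um=20.0)
        tau_s, tau_m, rel = wall_shear_comparison(
            fluid, geom, dev, FlowConditions(reynolds=100.0), grid=aligned_grid
        )
        assert rel == pytest.approx(0.0, abs=1e-12)

    def test_baf_ten_micron_layer_matches_two_layer_oracle(self, baf, geom, aligned_grid):
        # per-wall 10 µm: tau_model/tau_single = mu_eff/mu_rheo ~ 0.7512,
        # numerically indistinguishable from the 169/225 Pa stress pair
        dev = CFLDevelopment(a=0.5, x0_um=1.0, h_ss_um=10.0)
        tau_s, tau_m, rel = wall_shear_comparison(
            baf, geom, dev, FlowConditions(reynolds=50.0), grid=aligned_grid
        )
        mu_core = (150 * 5.95e-3 - 20 * 2.85e-3) / 130
        mu_eff = two_layer_effective_viscosity(mu_core, 2.85e-3, 75e-6, 65e-6)
        assert tau_m / tau_s == pytest.approx(mu_eff / baf.mu_rheo, rel=1e-10)
        assert tau_m / tau_s == pytest.approx(0.7512, abs=5e-4)
        assert tau_m / tau_s == pytest.approx(169.0 / 225.0, abs=2e-3)
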