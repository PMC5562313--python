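"""Biomass bookkeeping: volume fractions, growth, uptake caps, reaction
coupling, regulation automaton and pushing."""

import numpy as np
import pytest

import dfba3d as d
from conftest import make_state


class TestVolumeFraction:
    def test_single_cell_in_ten_micron_site(self, consts):
        assert d.volume_fraction(258.0, 1000.0, consts) == pytest.approx(
            0.001)

    def test_zero_mass(self, consts):
        assert d.volume_fraction(0.0, 1000.0, consts) == 0.0

    def test_cap_mass_inversion(self, consts):
        """phi = 0.65 in a 1000 fL site corresponds to 167,700 fg."""
        m_cap = consts.phi_max * consts.rho * 1000.0
        assert m_cap == pytest.approx(167_700.0)
        assert d.volume_fraction(m_cap, 1000.0, consts) == pytest.approx(
            0.65)


class TestGrowth:
    def test_one_hour_at_mg1655_rate(self):
        assert d.grow_biomass(258.0, 0.84, 3600.0) == pytest.approx(
            258.0 * np.exp(0.84), rel=1e-12)

    def test_zero_rate_unchanged(self):
        assert d.grow_biomass(100.0, 0.0, 3600.0) == 100.0

    def test_semigroup_property(self):
        whole = d.grow_biomass(100.0, 0.5, 7200.0)
        half = d.grow_biomass(d.grow_biomass(100.0, 0.5, 3600.0), 0.5,
                              3600.0)
        assert half == pytest.approx(whole, rel=1e-14)


class TestUptakeBounds:
    def test_zero_concentration(self):
        assert d.compute_uptake_bounds(0.0, 100.0, 1000.0, 36.0, 10.0,
                                       0.015) == 0.0

    def test_saturation_limit(self):
        v = d.compute_uptake_bounds(1000.0, 1.0, 1e6, 36.0, 10.0, 0.015)
        assert v == pytest.approx(10.0, rel=1e-4)

    def test_michaelis_menten_midpoint(self):
        Km = 0.5
        v = d.compute_uptake_bounds(Km, 1.0, 1e9, 36.0, 10.0, Km)
        assert v == pytest.approx(5.0, rel=1e-6)

    def test_supply_cap_prevents_overdraw(self):
        """Large biomass in a small site is limited by what's there."""
        C, m, V, dt = 1.0, 1e6, 1000.0, 3600.0
        v = d.compute_uptake_bounds(C, m, V, dt, 10.0, 1e-6)
        assert v == pytest.approx(C * V / (m * 1.0))  # dt = 1 hr

    def test_no_cells_no_uptake(self):
        assert d.compute_uptake_bounds(5.0, 0.0, 1000.0, 36.0, 10.0,
                                       0.015) == 0.0


class TestApplyReaction:
    def test_unit_conversion_single_cell(self):
        """One cell at v = -9.5 mmol/gDCW/hr in 1000 fL: -2.451 mM/hr."""
        state = make_state((3, 3, 3), dx=10.0)
        state.C["glucose"][:] = 10.0
        state.m[d.GLU][1, 1, 1] = 258.0
        v = np.zeros((2, 3, 3, 3))
        v[d.GLU, 1, 1, 1] = -9.5
        d.apply_reaction(state, {"glucose": v}, dt=3600.0)
        assert state.C["glucose"][1, 1, 1] == pytest.approx(10.0 - 2.4510,
                                                            abs=1e-4)

    def test_zero_flux_leaves_fields(self):
        state = make_state((3, 3, 3))
        state.C["glucose"][:] = 5.0
        d.apply_reaction(state, {"glucose": np.zeros((2, 3, 3, 3))}, 36.0)
        np.testing.assert_array_equal(state.C["glucose"], 5.0)

    def test_secretion_mirrors_uptake(self):
        state = make_state((3, 3, 3))
        state.C["acetate"][:] = 5.0
        state.m[d.GLU][1, 1, 1] = 1000.0
        up = np.zeros((2, 3, 3, 3))
        up[d.GLU, 1, 1, 1] = -2.0
        down = -up
        s_up = state.copy()
        d.apply_reaction(s_up, {"acetate": up}, 3600.0)
        s_dn = state.copy()
        d.apply_reaction(s_dn, {"acetate": down}, 3600.0)
        drop = 5.0 - s_up.C["acetate"][1, 1, 1]
        rise = s_dn.C["acetate"][1, 1, 1] - 5.0
        assert drop == pytest.approx(rise, rel=1e-12)

    def test_bound_violation_is_programming_error(self):
        state = make_state((3, 3, 3))
        state.C["glucose"][:] = 0.001
        state.m[d.GLU][1, 1, 1] = 1e6
        v = np.zeros((2, 3, 3, 3))
        v[d.GLU, 1, 1, 1] = -10.0
        with pytest.raises(AssertionError):
            d.apply_reaction(state, {"glucose": v}, 3600.0)

    def test_sitewise_bookkeeping_matches_independent_resummation(self):
        """The vectorized reaction equals a site-by-site re-summation."""
        rng = np.random.default_rng(11)
        n = (4, 4, 4)
        state = make_state(n)
        state.C["glucose"] = rng.uniform(50, 100, n)
        state.m[d.GLU] = rng.uniform(0, 5000, n)
        state.m[d.ACE] = rng.uniform(0, 2000, n)
        v = rng.uniform(-5, 1, (2,) + n)
        before = state.C["glucose"].copy()
        d.apply_reaction(state, {"glucose": v}, dt=36.0)
        V = state.site_volume
        for idx in np.ndindex(n):
            dC = sum(state.m[p][idx] * v[(p,) + idx] for p in (0, 1)) \
                / V * (36.0 / 3600.0)
            assert state.C["glucose"][idx] == pytest.approx(
                before[idx] + dC, rel=1e-12)


class TestRegulation:
    def _starved_state(self):
        state = make_state((3, 3, 3))
        state.C["glucose"][:] = 0.0
        state.C["acetate"][:] = 2.0
        state.m[d.GLU][1, 1, 1] = 500.0
        return state

    def test_no_conversion_when_glucose_present(self):
        state = self._starved_state()
        state.C["glucose"][:] = 1.0
        reg = d.RegulationState.zeros(state.dims)
        params = d.RegulationParams(tau=100.0)
        for _ in range(5):
            d.update_phenotypes(state, reg, params, 50.0)
        assert reg.timer.max() == 0.0
        assert state.m[d.ACE].sum() == 0.0

    def test_conversion_exactly_at_tau(self):
        state = self._starved_state()
        reg = d.RegulationState.zeros(state.dims)
        params = d.RegulationParams(tau=100.0)
        d.update_phenotypes(state, reg, params, 50.0)
        assert state.m[d.ACE].sum() == 0.0
        d.update_phenotypes(state, reg, params, 50.0)  # timer hits tau
        assert state.m[d.ACE][1, 1, 1] == 500.0
        assert state.m[d.GLU][1, 1, 1] == 0.0

    def test_interrupted_dwell_resets(self):
        """tau - dt of starvation, a break, then tau - dt again: no
        conversion (the timer automaton restarts)."""
        state = self._starved_state()
        reg = d.RegulationState.zeros(state.dims)
        params = d.RegulationParams(tau=100.0)
        d.update_phenotypes(state, reg, params, 60.0)   # 60 < tau
        state.C["glucose"][:] = 1.0                     # break
        d.update_phenotypes(state, reg, params, 60.0)
        assert reg.timer[1, 1, 1] == 0.0
        state.C["glucose"][:] = 0.0
        d.update_phenotypes(state, reg, params, 60.0)   # 60 again
        assert state.m[d.ACE].sum() == 0.0

    def test_conversion_conserves_site_mass(self):
        state = self._starved_state()
        state.m[d.ACE][1, 1, 1] = 200.0
        total = state.total_mass().sum()
        reg = d.RegulationState.zeros(state.dims)
        d.update_phenotypes(state, reg, d.RegulationParams(tau=10.0), 20.0)
        assert state.total_mass().sum() == pytest.approx(total, rel=1e-14)


class TestPushing:
    def test_below_cap_untouched(self, consts):
        state = make_state((5, 5, 5))
        state.m[d.GLU][2, 2, 2] = 100.0
        before = state.m.copy()
        blocked = d.push_biomass(state, consts)
        np.testing.assert_array_equal(state.m, before)
        assert not blocked.any()

    def test_single_overfull_site_exports_excess_over_six(self, consts):
        state = make_state((5, 5, 5))
        cap = consts.phi_max * consts.rho * state.site_volume
        excess = 600.0
        state.m[d.GLU][2, 2, 2] = cap + excess
        d.push_biomass(state, consts)
        assert state.m[d.GLU][2, 2, 2] == pytest.approx(cap, rel=1e-12)
        for nb in ((1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1),
                   (2, 2, 3)):
            assert state.m[d.GLU][nb] == pytest.approx(excess / 6,
                                                       rel=1e-12)

    def test_mass_conserved_away_from_boundary(self, consts):
        rng = np.random.default_rng(5)
        state = make_state((9, 9, 9))
        cap = consts.phi_max * consts.rho * state.site_volume
        state.m[d.GLU][3:6, 3:6, 3:6] = rng.uniform(0.9, 1.4, (3, 3, 3)) \
            * cap
        total = state.total_mass().sum()
        d.push_biomass(state, consts)
        assert state.total_mass().sum() == pytest.approx(total, rel=1e-9)
        phi = d.volume_fraction(state.total_mass(), state.site_volume,
                                consts)
        assert phi.max() <= consts.phi_max * (1 + 1e-6)

    def test_phenotype_proportions_preserved(self, consts):
        state = make_state((5, 5, 5))
        cap = consts.phi_max * consts.rho * state.site_volume
        state.m[d.GLU][2, 2, 2] = 1.5 * cap * 0.75
        state.m[d.ACE][2, 2, 2] = 1.5 * cap * 0.25
        d.push_biomass(state, consts)
        ratio = state.m[d.ACE][1, 2, 2] / state.m[d.GLU][1, 2, 2]
        assert ratio == pytest.approx(1 / 3, rel=1e-9)

    def test_agar_neighbors_excluded(self, consts):
        """Overflow next to agar splits among the open faces only."""
        state = make_state((5, 5, 6), n_agar=2)
        cap = consts.phi_max * consts.rho * state.site_volume
        state.m[d.GLU][2, 2, 2] = cap + 500.0  # site sits on the agar
        d.push_biomass(state, consts)
        assert state.m[d.GLU][2, 2, 1] == 0.0  # nothing into the agar
        assert state.m[d.GLU][2, 2, 3] == pytest.approx(100.0, rel=1e-9)
        assert state.m[d.GLU][1, 2, 2] == pytest.approx(100.0, rel=1e-9)

    def test_boundary_mass_absorbed(self, consts):
        state = make_state((5, 5, 5))
        cap = consts.phi_max * consts.rho * state.site_volume
        state.m[d.GLU][0, 2, 2] = cap + 600.0
        d.push_biomass(state, consts)
        # one of the six faces leaves the domain: mass is removed
        assert state.total_mass().sum() == pytest.approx(
            cap + 600.0 - 100.0, rel=1e-9)
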