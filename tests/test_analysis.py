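"""Metrics: fractions, onset interpolation, colony dimensions, profiles,
convergence errors, turnover and correlations."""

import numpy as np
import pytest

import dfba3d as d
from conftest import make_state


class TestPhenotypeFractions:
    def test_all_glucose_mass(self):
        state = make_state((3, 3, 3))
        state.m[d.GLU][1, 1, 1] = 100.0
        fr = d.phenotype_fractions(state)
        assert fr.acetate_utilizer == 0.0
        assert fr.glucose_utilizer == 1.0

    def test_equal_masses(self):
        state = make_state((3, 3, 3))
        state.m[d.GLU][1, 1, 1] = 100.0
        state.m[d.ACE][1, 1, 2] = 100.0
        assert d.phenotype_fractions(state).acetate_utilizer == 0.5

    def test_three_site_fixture_hand_summed(self):
        """Masses (100, 200, 300) glucose + (60, 0, 0) acetate -> 60/660."""
        state = make_state((3, 3, 3))
        state.m[d.GLU][0, 0, 0] = 100.0
        state.m[d.GLU][1, 0, 0] = 200.0
        state.m[d.GLU][2, 0, 0] = 300.0
        state.m[d.ACE][0, 0, 0] = 60.0
        fr = d.phenotype_fractions(state)
        assert fr.acetate_utilizer == pytest.approx(60.0 / 660.0)
        assert fr.glucose_utilizer == pytest.approx(600.0 / 660.0)

    def test_empty_lattice_sentinel(self):
        fr = d.phenotype_fractions(make_state((3, 3, 3)))
        assert np.isnan(fr.acetate_utilizer)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        state = make_state((4, 4, 4))
        state.m[:] = rng.uniform(0, 100, (2, 4, 4, 4))
        fr = d.phenotype_fractions(state)
        assert fr.glucose_utilizer + fr.acetate_utilizer == pytest.approx(
            1.0)

    def test_active_consumer_share(self):
        state = make_state((3, 3, 3))
        state.m[d.ACE][0, 0, 0] = 75.0
        state.m[d.ACE][1, 0, 0] = 25.0
        uptake = np.zeros((3, 3, 3))
        uptake[0, 0, 0] = -4.0
        fr = d.phenotype_fractions(state, applied_ace_uptake=uptake)
        assert fr.active_consumer == pytest.approx(0.75)


class TestOnsetTime:
    def test_never_crossing_is_sentinel(self):
        ms = d.MetricSeries([0, 1, 2], [0.0, 0.0, 0.0])
        assert np.isnan(d.onset_time(ms))

    def test_crossing_exactly_at_sample(self):
        ms = d.MetricSeries([0, 1, 2], [0.0, 0.01, 0.4])
        assert d.onset_time(ms, 0.01) == 1.0

    def test_linear_interpolation_between_samples(self):
        ms = d.MetricSeries([10.0, 11.0], [0.005, 0.015])
        assert d.onset_time(ms, 0.01) == pytest.approx(10.5)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        v = np.cumsum(rng.uniform(0, 0.01, 50))
        ms = d.MetricSeries(np.arange(50.0), v)
        ts = [d.onset_time(ms, th) for th in (0.01, 0.05, 0.1)]
        assert ts == sorted(ts)


class TestColonyDimensions:
    def test_single_site_colony(self, consts):
        state = make_state((5, 5, 5), dx=10.0)
        state.m[d.GLU][2, 2, 2] = consts.rho * state.site_volume * 0.65
        dims = d.colony_dimensions(state, consts)
        assert dims.height == 10.0
        assert dims.width == 10.0
        assert dims.aspect == 1.0

    def test_hemisphere_has_twice_the_width(self, consts):
        """A rasterized hemisphere of radius 10 dx: width = 2 height
        within one site."""
        n = 25
        state = make_state((n, n, 14), dx=10.0)
        x = np.arange(n) - n // 2
        z = np.arange(14)
        X, Y, Z = np.meshgrid(x, x, z, indexing="ij")
        inside = X ** 2 + Y ** 2 + Z ** 2 <= 10.0 ** 2
        state.m[d.GLU][inside] = consts.rho * state.site_volume * 0.65
        dims = d.colony_dimensions(state, consts)
        assert abs(dims.width - 2 * dims.height) <= state.dx

    def test_level_above_everything_is_sentinel(self, consts):
        state = make_state((5, 5, 5))
        state.m[d.GLU][2, 2, 2] = 10.0  # phi far below any contour
        dims = d.colony_dimensions(state, consts, colony_level=0.64)
        assert np.isnan(dims.height)

    def test_acetate_feature_contour(self, consts):
        state = make_state((5, 5, 5))
        cap = consts.rho * state.site_volume
        state.m[d.GLU][1:4, 1:4, 1:3] = 0.5 * cap
        state.m[d.ACE][2, 2, 2] = 0.2 * cap
        dims = d.colony_dimensions(state, consts, colony_level=0.05,
                                   phenotype=d.ACE)
        assert dims.height == state.dx


class TestAxisProfile:
    def test_uniform_field_constant_profile(self):
        state = make_state((5, 5, 6), n_agar=3)
        state.C["glucose"][:] = 7.0
        depth, prof = d.axis_profile(state, "glucose")
        np.testing.assert_array_equal(prof, 7.0)

    def test_pregrowth_profile_steps_at_surface(self):
        state = make_state((5, 5, 6), n_agar=3)
        depth, prof = d.axis_profile(state, "glucose")
        assert (prof[depth < 0] == 138.8).all()
        assert (prof[depth > 0] == 0.0).all()
        # site centers sit half a spacing off the interface
        assert depth[2] == pytest.approx(-0.5 * state.dx)
        assert depth[3] == pytest.approx(0.5 * state.dx)

    def test_linear_field_slope_recovered(self):
        state = make_state((5, 5, 8), n_agar=4)
        z = np.arange(8, dtype=float)
        state.C["acetate"][:] = 3.0 * z[None, None, :] + 1.0
        depth, prof = d.axis_profile(state, "acetate")
        slopes = np.diff(prof) / np.diff(depth)
        np.testing.assert_allclose(slopes, 3.0 / state.dx)


def _mk_traj(times, total, glu, ace, frac):
    class _T:
        pass

    t = _T()
    t.times = np.asarray(times, dtype=float)
    t.series = {"vol_total_fl": np.asarray(total, dtype=float),
                "vol_glu_fl": np.asarray(glu, dtype=float),
                "vol_ace_fl": np.asarray(ace, dtype=float),
                "ace_fraction": np.asarray(frac, dtype=float)}
    return t


class TestConvergenceError:
    def test_identical_trajectories_zero_error(self):
        t = np.linspace(10, 30, 21)
        a = _mk_traj(t, t * 2, t, t, np.full_like(t, 0.05))
        out = d.convergence_error(a, a)
        assert out["total"] == 0.0
        assert not out["oscillation"]

    def test_constant_ten_percent_deviation(self):
        t = np.linspace(10, 30, 21)
        ref = _mk_traj(t, t * 2, t, t, np.full_like(t, 0.05))
        dev = _mk_traj(t, t * 2.2, t * 1.1, t * 1.1,
                       np.full_like(t, 0.05))
        out = d.convergence_error(dev, ref)
        assert out["total"] == pytest.approx(0.10)
        assert out["glucose"] == pytest.approx(0.10)

    def test_hand_computed_mean_deviation(self):
        t = np.array([10.0, 20.0, 30.0])
        ref = _mk_traj(t, [100.0, 200.0, 400.0], [1, 1, 1], [1, 1, 1],
                       [0, 0, 0])
        dev = _mk_traj(t, [110.0, 190.0, 500.0], [1, 1, 1], [1, 1, 1],
                       [0, 0, 0])
        out = d.convergence_error(dev, ref)
        # (0.1 + 0.05 + 0.25) / 3
        assert out["total"] == pytest.approx(0.4 / 3)

    def test_oscillation_flag_on_large_swings(self):
        t = np.linspace(10, 30, 21)
        frac = 0.05 + 0.04 * (-1.0) ** np.arange(21)
        wob = _mk_traj(t, t, t, t, frac)
        ref = _mk_traj(t, t, t, t, np.full_like(t, 0.05))
        assert d.convergence_error(wob, ref)["oscillation"]
        assert not d.convergence_error(ref, ref)["oscillation"]

    def test_disjoint_time_ranges_error(self):
        a = _mk_traj([1.0, 2.0], [1, 1], [1, 1], [1, 1], [0, 0])
        b = _mk_traj([50.0, 60.0], [1, 1], [1, 1], [1, 1], [0, 0])
        with pytest.raises(ValueError):
            d.convergence_error(a, b)


class TestAcetateTurnover:
    def test_zero_uptake(self, consts):
        state = make_state((3, 3, 3))
        state.m[d.GLU][1, 1, 1] = 100.0
        assert d.acetate_turnover(state, np.zeros((3, 3, 3)), consts) == 0.0

    def test_single_site_unit_arithmetic(self, consts):
        """258 fg at -10 mmol/gDCW/hr over 1000 fL -> 2.58 mM/hr."""
        state = make_state((3, 3, 3), dx=10.0)
        state.m[d.ACE][1, 1, 1] = 258.0
        # colony volume = total mass / rho = 1 fL; scale mass so the
        # colony volume is 1000 fL as in the worked example
        state.m[d.GLU][1, 1, 1] = consts.rho * 1000.0 - 258.0
        uptake = np.zeros((3, 3, 3))
        uptake[1, 1, 1] = -10.0
        assert d.acetate_turnover(state, uptake, consts) == pytest.approx(
            2.58)

    def test_relative_to_self_is_one(self, consts):
        state = make_state((3, 3, 3))
        state.m[d.ACE][1, 1, 1] = 500.0
        uptake = np.full((3, 3, 3), -3.0)
        absolute = d.acetate_turnover(state, uptake, consts)
        assert d.acetate_turnover(state, uptake, consts,
                                  normalize_to=absolute) == 1.0

    def test_empty_colony_sentinel(self, consts):
        assert np.isnan(d.acetate_turnover(make_state((3, 3, 3)),
                                           np.zeros((3, 3, 3)), consts))


class TestCorrelations:
    def test_perfect_positive(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, p = d.correlate_characteristics(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_negative(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, _ = d.correlate_characteristics(x, -x)
        assert r == pytest.approx(-1.0)

    def test_five_point_fixture_matches_t_transform(self):
        """r and p agree with an independent t-statistic computation."""
        from scipy.stats import t as tdist

        x = np.array([0.76, 0.96, 0.84, 0.97, 0.61])
        y = np.array([8.0, 12.5, 9.5, 9.9, 6.7])
        r, p = d.correlate_characteristics(x, y)
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        t_stat = r_hand * np.sqrt(3 / (1 - r_hand ** 2))
        p_hand = 2 * tdist.sf(abs(t_stat), df=3)
        assert r == pytest.approx(r_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-9)

    def test_zero_variance_flagged(self):
        r, p = d.correlate_characteristics([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)

    def test_packaged_strains_growth_vs_glucose_uptake(self):
        """Growth rates correlate positively with glucose uptake across
        the five strains (aerobic p < 0.05, anaerobic p < 0.02), while
        aerobic and anaerobic growth are themselves uncorrelated."""
        recs = list(d.STRAINS.values())
        mu_a = [r.mu_aero for r in recs]
        mu_n = [r.mu_anaero for r in recs]
        r_a, p_a = d.correlate_characteristics(
            mu_a, [r.v_glc_aero for r in recs])
        r_n, p_n = d.correlate_characteristics(
            mu_n, [r.v_glc_anaero for r in recs])
        assert r_a > 0 and p_a < 0.05
        assert r_n > 0 and p_n < 0.02
        _, p_x = d.correlate_characteristics(mu_a, mu_n)
        assert p_x > 0.19
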