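"""Release curves, release times, fields, and the closed-form limits."""

import math

import numpy as np
import pytest

from crfrelease import (
    DimensionlessParams,
    NoConvergenceError,
    core_concentration,
    cumulative_release,
    film_concentration,
    reaction_limit,
    reference_scenarios,
    release_time,
    scenario_by_name,
    t_max,
    theta_e_at,
    theta_e_inf,
)


class TestEquilibrium:
    @pytest.mark.parametrize("l,Vr,expected", [
        (1.0, 10.0, 1.0 / 11.0),
        (2.0, 1.0, 1.0 / 16.0),
        (1.0, 1.0, 0.5),
    ])
    def test_closed_form(self, l, Vr, expected):
        with pytest.warns(UserWarning) if l == 1.0 else _nullcontext():
            p = DimensionlessParams(Dr=1.0, Vr=Vr, l=l, Ka=1.0, Kb=1.0)
        assert theta_e_inf(p) == pytest.approx(expected)

    def test_variants_coincide_at_unit_partition(self, base_params):
        assert theta_e_inf(base_params, "literal") == pytest.approx(
            theta_e_inf(base_params, "conservation"))

    def test_variants_differ_otherwise(self):
        p = DimensionlessParams(Dr=1.0, Vr=10.0, l=1.2, Ka=2.0, Kb=0.5)
        lit = theta_e_inf(p, "literal")         # leads with Ka*Kb = 1
        con = theta_e_inf(p, "conservation")    # leads with Ka/Kb = 4
        assert lit != pytest.approx(con)
        with pytest.raises(ValueError):
            theta_e_inf(p, "bogus")


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


class TestCumulativeRelease:
    def test_long_time_release_complete(self, base_params):
        prof = cumulative_release([5.0], base_params)
        assert prof.g[-1] == pytest.approx(1.0, abs=5e-3)

    def test_starts_from_zero(self, base_params):
        prof = cumulative_release([1e-3], base_params)
        assert abs(prof.g[0]) < 1e-3

    def test_monotone_and_bounded(self, base_params):
        # within the validated window tau <= 3; beyond it the inversion
        # rule's truncation drifts upward by roughly 0.1% per tau unit
        tau = np.linspace(0.02, 3.0, 120)
        prof = cumulative_release(tau, base_params)
        assert np.all(prof.g >= -1e-3)
        assert np.all(prof.g <= 1.0 + 1e-3)
        assert np.all(np.diff(prof.g) >= -1e-3)
        assert np.all(prof.g_clipped() <= 1.0)

    def test_mode_invariant_without_reaction(self, base_params):
        tau = np.linspace(0.1, 2.0, 10)
        a = cumulative_release(tau, base_params, "integral")
        b = cumulative_release(tau, base_params, "first_order")
        np.testing.assert_allclose(a.g, b.g, rtol=1e-10)

    @pytest.mark.parametrize("bad", [[0.0, 1.0], [-0.5, 1.0], [2.0, 1.0]])
    def test_grid_validation(self, bad, base_params):
        with pytest.raises(ValueError):
            cumulative_release(bad, base_params)


class TestReleaseTime:
    def test_hits_target_fraction(self, base_params):
        t90 = release_time(0.90, base_params)
        assert theta_e_at(t90, base_params) / theta_e_inf(base_params) == \
            pytest.approx(0.90, abs=2e-3)

    def test_smaller_fraction_is_earlier(self, base_params):
        assert release_time(0.30, base_params) < release_time(0.90, base_params)

    @pytest.mark.parametrize("x", [0.0, 1.0, -0.3, 1.5])
    def test_fraction_domain(self, x, base_params):
        with pytest.raises(ValueError):
            release_time(x, base_params)

    def test_ceiling_reported(self, base_params):
        with pytest.raises(NoConvergenceError, match="0.01"):
            release_time(0.99, base_params, tau_max=0.01)

    def test_faster_film_releases_sooner(self):
        """Higher film diffusivity shortens the 99% release time."""
        taus = [release_time(
            0.99, DimensionlessParams(Dr=Dr, Vr=10.0, l=2.0, Ka=1.0, Kb=1.0))
            for Dr in (1.0, 10.0)]
        assert taus[1] < taus[0]

    def test_hydrolysis_accelerates_late_release(self):
        """A faster hydrolysis source shortens the 90% release time."""
        base = dict(Dr=1.0, Vr=10.0, l=2.0, Ka=1.0, Kb=1.0)
        t_slow = release_time(0.90, DimensionlessParams(**base, kappa=0.0))
        t_fast = release_time(0.90, DimensionlessParams(**base, kappa=0.08))
        assert t_fast < t_slow


class TestFields:
    def test_film_requires_positive_thickness(self):
        with pytest.warns(UserWarning):
            p = DimensionlessParams(Dr=1.0, Vr=10.0, l=1.0, Ka=1.0, Kb=1.0)
        with pytest.raises(ValueError):
            film_concentration([1.0], [0.5], p)

    def test_film_starts_empty(self, film_field_params):
        # interior of the film only: the eta = 1 interface value jumps
        # instantaneously on contact with the full core
        f = film_concentration(np.linspace(1.25, 2.0, 4), [1e-3],
                               film_field_params)
        assert np.all(np.abs(f.values) < 1e-2)

    def test_film_outer_value_tracks_bath(self, film_field_params):
        """Kb*theta_f(l, tau) equals theta_e(tau) after inversion."""
        p = film_field_params
        tau = np.linspace(0.1, 2.0, 8)
        f = film_concentration([p.l], tau, p)
        for j, t in enumerate(tau):
            assert p.Kb * f.values[0, j] == pytest.approx(
                theta_e_at(t, p), abs=1e-3)

    def test_film_late_time_approaches_equilibrium(self, film_field_params):
        # without the hydrolysis source the film drains to the uniform
        # equilibrium level theta_e(inf)/Kb (oracle long-time state; the
        # inversion rule's noise grows too large at tau ~ 30)
        from crfrelease import OracleGrid, solve_ibvp

        p = film_field_params.with_kappa(0.0)
        res = solve_ibvp(p, grid=OracleGrid(32, 32, 2e-3), tau_end=30.0)
        level = theta_e_inf(p) / p.Kb
        assert res.theta_f[-1] == pytest.approx(level, rel=0.01)

    def test_core_starts_full(self, base_params):
        # interior of the core: the interface value drops instantaneously
        f = core_concentration(np.linspace(0.0, 0.8, 5), [1e-4], base_params)
        assert f.values[:, 0] == pytest.approx(1.0, abs=1e-2)

    def test_core_drains_monotonically(self, base_params):
        tau = np.linspace(0.05, 2.0, 12)
        f = core_concentration([0.0, 0.5, 0.9], tau, base_params)
        assert np.all(np.diff(f.values, axis=1) <= 1e-3)

    def test_interface_partition_after_inversion(self, film_field_params):
        p = film_field_params
        tau = np.array([0.3, 0.7, 1.2])
        fm = core_concentration([1.0], tau, p)
        ff = film_concentration([1.0], tau, p)
        np.testing.assert_allclose(fm.values[0], p.Ka * ff.values[0],
                                   atol=1e-3)


class TestClosedForms:
    def test_reaction_limit_initial_value(self):
        assert reaction_limit(0.0, k=0.05, theta_r0=0.7) == 0.7

    def test_reaction_limit_no_reaction(self):
        assert reaction_limit(10.0, k=0.0, theta_r0=0.7) == 0.7

    def test_reaction_limit_growth(self):
        assert reaction_limit(10.0, k=0.05, theta_r0=1.0) == pytest.approx(
            math.exp(0.5))

    def test_t_max_identity_weight(self):
        assert t_max(k=0.1, Mn0=5000.0, M1=5000.0) == 0.0

    def test_t_max_literature_rate(self):
        assert t_max(k=0.081, Mn0=1000.0, M1=1.0) == pytest.approx(
            85.28, abs=0.01)

    def test_t_max_doubling_adds_ln2_over_k(self):
        k = 0.05
        assert t_max(k, 2000.0, 1.0) - t_max(k, 1000.0, 1.0) == \
            pytest.approx(math.log(2.0) / k)

    @pytest.mark.parametrize("kw", [
        dict(k=0.0, Mn0=10.0, M1=1.0),
        dict(k=-1.0, Mn0=10.0, M1=1.0),
        dict(k=0.1, Mn0=0.5, M1=1.0),
    ])
    def test_t_max_domain(self, kw):
        with pytest.raises(ValueError):
            t_max(**kw)


class TestScenarios:
    def test_families(self):
        fams = {s.family for s in reference_scenarios()}
        assert len(fams) >= 4

    def test_diffusion_sweep_includes_slowest_film(self):
        drs = {s.params.Dr for s in reference_scenarios()
               if s.family == "diffusion-sweep"}
        assert 0.01 in drs and drs == {0.01, 0.1, 1.0, 10.0}

    def test_film_field_rate(self):
        sc = scenario_by_name("film-field")
        assert sc.k_per_day == pytest.approx(0.05)
        assert sc.params.l == 2.0

    def test_rate_sets_sorted(self):
        for fam in ("reaction-sweep-a", "reaction-sweep-b"):
            ks = [s.k_per_day for s in reference_scenarios()
                  if s.family == fam]
            assert ks == sorted(ks) and 0.0 in ks and 0.08 in ks

    def test_names_unique(self):
        names = [s.name for s in reference_scenarios()]
        assert len(names) == len(set(names))

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            scenario_by_name("nope")
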