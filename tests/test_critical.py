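"""Critical conditions for like-charge attraction."""

import numpy as np
import pytest

from polimage import (
    CHI_CONTACT_THRESHOLD,
    MediumSpec,
    SphereSpec,
    TwoSphereSystem,
    contact_threshold_equal_size,
    critical_condition_general,
    first_level_force,
    force,
    h_factor,
    H_factor,
    phase_diagram,
    solve_rc,
    solve_rc_numeric,
    to_dimensionless,
)
from scipy.optimize import brentq


def make_system(a1, e1, q1, a2, e2, q2, R, eps_out=1.0):
    return TwoSphereSystem(
        SphereSpec(a1, e1, q1), SphereSpec(a2, e2, q2), MediumSpec(eps_out), R
    )


class TestContactThreshold:
    def test_threshold_is_18_sevenths(self):
        """h(1/2) = 7/18 exactly, so the contact threshold for the asymmetry
        parameter chi is 18/7."""
        assert contact_threshold_equal_size() == pytest.approx(18.0 / 7.0, abs=1e-14)
        assert h_factor(0.5) == pytest.approx(7.0 / 18.0, abs=1e-16)

    def test_symmetric_charges_below_threshold(self, vacuum):
        """Equal charges give chi = k1 + k2 <= 2 < 18/7: equal-sized,
        equally charged spheres can never attract."""
        for eps in (2.0, 20.0, 1e6):
            sys = make_system(1.0, eps, 3.0, 1.0, eps, 3.0, 2.5)
            p = to_dimensionless(sys)
            assert p.chi == pytest.approx(p.k1 + p.k2, rel=1e-14)
            assert p.chi < 2.0 < CHI_CONTACT_THRESHOLD

    def test_marginally_supercritical_chi_roots_near_contact(self, vacuum):
        """chi slightly above 18/7 puts the critical separation just outside
        contact (continuity of the root in chi)."""
        k = 0.999999  # conductor-grade spheres
        eps = (1.0 + k) / (1.0 - k)
        # chi = k*(q + 1/q) = 18/7 * (1 + delta)  =>  solve for q
        chi_target = CHI_CONTACT_THRESHOLD * 1.001
        q = brentq(lambda x: k * (x + 1.0 / x) - chi_target, 1.0, 10.0)
        sys = make_system(1.0, eps, 1.0, 1.0, eps, q, 2.5)
        res = solve_rc(sys)
        assert res.lca_occurs
        assert res.R_c == pytest.approx(2.0, rel=5e-2)
        assert res.t_c[0] == pytest.approx(0.5, rel=5e-2)


class TestGeneralCondition:
    def test_H_negative_on_physical_domain(self):
        t = np.linspace(1e-3, 0.999, 500)
        assert np.all(H_factor(t) < 0.0)

    def test_long_range_residual_is_coulomb_sign(self, vacuum):
        sys = make_system(1.0, 100.0, 1.0, 1.0, 100.0, 10.0, 1e5)
        assert critical_condition_general(to_dimensionless(sys)) == pytest.approx(1.0, abs=1e-10)

    def test_residual_zero_iff_first_level_force_zero(self, fig2_factory):
        """The dimensionless residual and the dimensional first-level force
        vanish at the same separation."""
        def resid(R):
            return critical_condition_general(to_dimensionless(fig2_factory(R)))

        r_force = brentq(lambda R: first_level_force(fig2_factory(R)), 2.6, 5.0, xtol=1e-13)
        r_resid = brentq(resid, 2.6, 5.0, xtol=1e-13)
        assert r_resid == pytest.approx(r_force, rel=1e-10)
        assert resid(r_force - 0.05) < 0.0 < resid(r_force + 0.05)

    def test_consistency_on_random_systems(self, rng):
        """Residual sign equals first-level-force sign for random valid
        like-charged systems (the condition is the force, nondimensionalized)."""
        medium = MediumSpec(1.0)
        for _ in range(50):
            a1, a2 = rng.uniform(0.5, 3.0, size=2)
            R = (a1 + a2) * rng.uniform(1.01, 5.0)
            sys = TwoSphereSystem(
                SphereSpec(a1, rng.uniform(1.5, 300.0), rng.uniform(0.2, 4.0)),
                SphereSpec(a2, rng.uniform(1.5, 300.0), rng.uniform(0.2, 4.0)),
                medium,
                R,
            )
            resid = critical_condition_general(to_dimensionless(sys))
            assert np.sign(resid) == np.sign(first_level_force(sys))

    def test_no_root_in_polarizable_medium(self):
        """eps_out > eps_in (k < 0): the residual exceeds 1 everywhere, so
        no critical separation exists — no LCA in a high-permittivity medium."""
        sys = make_system(1.0, 2.0, 1.0, 1.0, 5.0, 5.0, 2.5, eps_out=80.0)
        res = solve_rc(sys)
        assert not res.lca_occurs
        for R in (2.01, 3.0, 10.0, 100.0):
            assert critical_condition_general(to_dimensionless(sys.at_separation(R))) > 1.0

    def test_domain_errors(self, vacuum):
        sys = make_system(1.0, 20.0, 1.0, 1.0, 20.0, 0.0, 3.0)
        with pytest.raises(ValueError):
            critical_condition_general(to_dimensionless(sys))


class TestSolveRc:
    def test_equal_size_equal_charge_never_attracts(self):
        for eps in (5.0, 50.0, 1e8):
            res = solve_rc(make_system(1.0, eps, 2.0, 1.0, eps, 2.0, 2.1))
            assert not res.lca_occurs

    def test_fig2_system_attracts(self, fig2_factory):
        res = solve_rc(fig2_factory(3.0))
        assert res.lca_occurs
        assert res.R_c > 2.5
        assert abs(res.residual) < 1e-10
        # descending-through-zero: repulsive beyond R_c, attractive within
        assert first_level_force(fig2_factory(res.R_c + 0.01)) > 0.0
        assert first_level_force(fig2_factory(res.R_c - 0.01)) < 0.0

    def test_strong_size_asymmetry_conductors_attract(self):
        res = solve_rc(make_system(1.0, 1e8, 1.0, 8.0, 1e8, 1.0, 10.0))
        assert res.lca_occurs
        assert res.R_c >= 9.0

    def test_result_is_scale_invariant(self, fig2_factory):
        res = solve_rc(fig2_factory(3.0))
        scaled = solve_rc(
            make_system(12.5, 20.0, -1.0, 12.5, 20.0, -7.0, 30.0)
        )
        assert scaled.R_c == pytest.approx(10.0 * res.R_c, rel=1e-10)

    def test_numeric_solver_confirms_theory_ballpark(self, fig2_factory):
        """The converged-force root sits near the first-level root (the
        truncation error of the closed-form theory is a few percent at
        moderate polarizability)."""
        theory = solve_rc(fig2_factory(3.0))
        numeric = solve_rc_numeric(fig2_factory(3.0), rc_guess=theory.R_c)
        assert numeric.lca_occurs
        assert numeric.R_c == pytest.approx(theory.R_c, rel=0.05)
        # and the numeric root really is a force sign change
        assert force(fig2_factory(numeric.R_c + 0.02), method="neumann") > 0.0
        assert force(fig2_factory(numeric.R_c - 0.02), method="neumann") < 0.0

    def test_numeric_solver_reports_no_lca(self):
        sys = make_system(1.0, 50.0, 2.0, 1.0, 50.0, 2.0, 2.5)
        res = solve_rc_numeric(sys, rc_guess=2.2)
        assert not res.lca_occurs


class TestNecessaryCondition:
    def test_no_theory_root_implies_converged_repulsion(self):
        """Wherever the first-level force is everywhere repulsive, the
        converged force is repulsive too (alternating-remainder argument,
        exercised numerically on an equal-size equal-charge system)."""
        sys0 = make_system(1.0, 100.0, 2.0, 1.0, 100.0, 2.0, 2.5)
        assert not solve_rc(sys0).lca_occurs
        for R in (2.02, 2.2, 2.5, 3.5, 6.0):
            assert first_level_force(sys0.at_separation(R)) > 0.0
            assert force(sys0.at_separation(R), method="neumann") > 0.0

    def test_polarizable_medium_repels_at_all_separations(self):
        sys0 = make_system(1.0, 2.0, 1.0, 1.0, 5.0, 5.0, 2.5, eps_out=80.0)
        for R in (2.02, 2.3, 3.0, 6.0):
            assert force(sys0.at_separation(R), method="neumann") > 0.0


class TestPhaseDiagram:
    def test_equal_size_curve_starts_at_threshold(self):
        d = phase_diagram("equal_size", grid=np.linspace(1.0, 12.0, 120))
        chi, t_c = d.curves["chi"], d.curves["t_c"]
        below = chi < CHI_CONTACT_THRESHOLD
        assert np.all(np.isnan(t_c[below]))  # no LCA below 18/7
        above = chi >= CHI_CONTACT_THRESHOLD
        assert np.all(np.isfinite(t_c[above]))
        assert np.all(t_c[above] <= 0.5 + 1e-12)
        # larger asymmetry -> attraction sets in farther out (smaller t_c)
        finite = t_c[above]
        assert np.all(np.diff(finite) < 0.0)

    def test_equal_charge_region_grows_with_k(self):
        d = phase_diagram("equal_charge", k_values=(0.5, 1.0), grid=np.linspace(0.01, 0.6, 60))
        t2_half = d.curves["t2_by_k"][0.5]
        t2_one = d.curves["t2_by_k"][1.0]
        both = np.isfinite(t2_half) & np.isfinite(t2_one)
        assert both.sum() > 10
        # k = 1 needs less size asymmetry: its critical t2 lies below k = 0.5's
        assert np.all(t2_one[both] < t2_half[both])
        # k = 0.5 curve finite => k = 1 curve finite (region containment)
        assert np.all(np.isfinite(t2_one[np.isfinite(t2_half)]))

    def test_equal_charge_region_shrinks_to_point_as_k_vanishes(self):
        d = phase_diagram("equal_charge", k_values=(0.01,), grid=np.linspace(0.01, 0.99, 99))
        t2 = d.curves["t2_by_k"][0.01]
        finite = np.isfinite(t2)
        # at k = 0.01 the physical (t1 + t2 <= 1) critical curve has almost
        # vanished: attraction requires near-total size asymmetry
        if finite.any():
            t1 = d.curves["t1"][finite]
            assert np.all((t1 < 0.05) | (t2[finite] < 0.05))
            assert np.all(t1 + t2[finite] > 0.9)
        assert finite.sum() < 10

    def test_nonphysical_region_masked(self):
        d = phase_diagram("equal_charge", k_values=(1.0,), grid=np.linspace(0.01, 0.99, 99))
        t1 = d.curves["t1"]
        t2 = d.curves["t2_by_k"][1.0]
        finite = np.isfinite(t2)
        assert np.all(t1[finite] + t2[finite] <= 1.0 + 1e-9)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            phase_diagram("bogus")
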