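"""Classical Coulomb + Lennard-Jones interaction energy.

The vectorized implementation is checked against an independent naive
double-loop oracle, against analytic single-pair results, and for its
physical symmetries (A/B exchange, rigid motion, charge scaling).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from adsorbscreen.errors import DegenerateGeometryError, ParameterError
from adsorbscreen.model import Atom, ComplexGeometry, Fragment
from adsorbscreen.pairwise import (
    COULOMB_CONSTANT,
    classical_interaction,
    coulomb_energy,
    lj_energy,
)
from adsorbscreen.synthetic import FixtureSpec, brute_force_interaction, make_toy_complex


def pair(r, qa=0.0, qb=0.0, sa=1.0, sb=1.0, ea=0.0, eb=0.0):
    a = Fragment("a", (Atom("O", 1, (0.0, 0.0, 0.0), charge=qa, sigma=sa, epsilon=ea),))
    b = Fragment("b", (Atom("O", 1, (r, 0.0, 0.0), charge=qb, sigma=sb, epsilon=eb),))
    return a, b


class TestCoulomb:
    def test_zero_charges_give_zero(self):
        a, b = pair(3.0)
        assert coulomb_energy(a, b) == 0.0

    def test_unit_charges_at_k_over_100(self):
        # +1 and -1 at r = k/100 angstrom must give exactly -100 kcal/mol
        a, b = pair(COULOMB_CONSTANT / 100.0, qa=1.0, qb=-1.0)
        assert coulomb_energy(a, b) == pytest.approx(-100.0, abs=1e-12)

    def test_missing_charge_is_parameter_error(self):
        a = Fragment("a", (Atom("O", 1, (0, 0, 0)),))
        b = Fragment("b", (Atom("O", 1, (3, 0, 0), charge=1.0),))
        with pytest.raises(ParameterError):
            coulomb_energy(a, b)

    def test_clash_floor_names_the_pair(self):
        a, b = pair(0.05, qa=1.0, qb=1.0)
        with pytest.raises(DegenerateGeometryError, match="O1-O1"):
            coulomb_energy(a, b)

    def test_doubling_charges_quadruples_energy(self):
        fx = make_toy_complex(FixtureSpec(seed=3))
        geom = fx.complex_geometry
        u1 = coulomb_energy(geom.fragment_a, geom.fragment_b)
        import dataclasses

        def doubled(frag):
            return dataclasses.replace(
                frag,
                atoms=tuple(dataclasses.replace(a, charge=2 * a.charge) for a in frag),
            )

        u4 = coulomb_energy(doubled(geom.fragment_a), doubled(geom.fragment_b))
        assert u4 == pytest.approx(4.0 * u1, rel=1e-12)
        # LJ is untouched by charge scaling
        assert lj_energy(doubled(geom.fragment_a), doubled(geom.fragment_b)) == pytest.approx(
            lj_energy(geom.fragment_a, geom.fragment_b), rel=1e-12
        )


class TestLennardJones:
    def test_minimum_sits_at_sixth_root_of_two_sigma(self):
        sa, sb, ea, eb = 1.2, 1.8, 0.10, 0.25
        sig_ab, eps_ab = sa + sb, ea + eb  # plain_sum rule
        a, b = pair(2 ** (1 / 6) * sig_ab, sa=sa, sb=sb, ea=ea, eb=eb)
        assert lj_energy(a, b) == pytest.approx(-eps_ab, rel=1e-12)

    def test_golden_section_scan_recovers_the_analytic_minimum(self):
        sa, sb, ea, eb = 1.5, 1.7, 0.12, 0.08
        sig_ab, eps_ab = sa + sb, ea + eb

        def radial(r):
            a, b = pair(r, sa=sa, sb=sb, ea=ea, eb=eb)
            return lj_energy(a, b)

        res = minimize_scalar(radial, bracket=(3.0, 4.0, 8.0), method="golden")
        assert res.x == pytest.approx(2 ** (1 / 6) * sig_ab, rel=1e-6)
        assert res.fun == pytest.approx(-eps_ab, rel=1e-6)

    def test_asymptotic_decay(self):
        sa, sb, ea, eb = 1.5, 1.5, 0.2, 0.2
        a, b = pair(10 * (sa + sb), sa=sa, sb=sb, ea=ea, eb=eb)
        assert abs(lj_energy(a, b)) < 1e-4 * (ea + eb)

    def test_combining_rules_differ_when_epsilons_differ(self):
        a, b = pair(4.0, sa=1.5, sb=1.5, ea=0.3, eb=0.1)
        assert lj_energy(a, b, "plain_sum") != pytest.approx(
            lj_energy(a, b, "lorentz_berthelot")
        )

    def test_unknown_rule_rejected(self):
        a, b = pair(4.0, ea=0.1, eb=0.1)
        with pytest.raises(ValueError):
            lj_energy(a, b, combining="geometric")  # type: ignore[arg-type]


class TestClassicalInteraction:
    def test_neutral_zero_epsilon_gives_zero(self):
        a, b = pair(3.0)
        cx = ComplexGeometry.assemble("c", a, b)
        assert classical_interaction(cx).u_int == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40)
    def test_totals_match_brute_force_oracle(self, seed):
        fx = make_toy_complex(FixtureSpec(seed=seed))
        geom = fx.complex_geometry
        breakdown = classical_interaction(geom)
        oracle_elect, oracle_vdw = brute_force_interaction(
            geom.fragment_a, geom.fragment_b
        )
        assert breakdown.u_elect == pytest.approx(oracle_elect, rel=1e-10)
        assert breakdown.u_vdw == pytest.approx(oracle_vdw, rel=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_additivity_and_pair_term_sums(self, seed):
        geom = make_toy_complex(FixtureSpec(seed=seed)).complex_geometry
        breakdown = classical_interaction(geom)
        assert breakdown.u_int == pytest.approx(breakdown.u_elect + breakdown.u_vdw)
        assert breakdown.pair_terms["coulomb"].sum() == pytest.approx(
            breakdown.u_elect, rel=1e-12
        )
        assert breakdown.pair_terms["lj"].sum() == pytest.approx(
            breakdown.u_vdw, rel=1e-12
        )
        assert len(breakdown.pair_terms) == len(geom.fragment_a) * len(geom.fragment_b)

    def test_fragment_exchange_symmetry(self):
        geom = make_toy_complex(FixtureSpec(seed=11)).complex_geometry
        fwd = classical_interaction(geom)
        rev = classical_interaction(geom.swapped())
        assert rev.u_elect == pytest.approx(fwd.u_elect, rel=1e-12)
        assert rev.u_vdw == pytest.approx(fwd.u_vdw, rel=1e-12)

    def test_rigid_rotation_and_translation_invariance(self):
        import dataclasses

        geom = make_toy_complex(FixtureSpec(seed=5)).complex_geometry
        theta = 0.83
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        shift = np.array([3.1, -2.2, 7.7])

        def transform(frag):
            return dataclasses.replace(
                frag,
                atoms=tuple(
                    dataclasses.replace(
                        a, position=tuple(rot @ np.asarray(a.position) + shift)
                    )
                    for a in frag
                ),
            )

        moved = ComplexGeometry(
            geom.name, transform(geom.fragment_a), transform(geom.fragment_b)
        )
        assert classical_interaction(moved).u_int == pytest.approx(
            classical_interaction(geom).u_int, rel=1e-9
        )
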