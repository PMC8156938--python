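"""Second-order perturbation energies, cut-off, classification, H-bond detection."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adsorbscreen.errors import DegeneracyError, MissingInputError
from adsorbscreen.model import Atom, ComplexGeometry, Fragment, NBORow, parse_orbital
from adsorbscreen.nbo import (
    apply_cutoff,
    classify_interaction,
    detect_hbonds,
    e2_energy,
)
from adsorbscreen.synthetic import make_hbond_scene


def row(qi=2.0, fij=0.1, ei=-1.0, ej=-0.5, donor="LP O1", acceptor="BD* O2-H3", e2=None):
    return NBORow(
        donor=parse_orbital(donor),
        acceptor=parse_orbital(acceptor),
        occupancy_qi=qi,
        fock_fij=fij,
        e_donor=ei,
        e_acceptor=ej,
        e2=e2,
    )


class TestE2Energy:
    def test_zero_fock_element_gives_zero(self):
        assert e2_energy(row(fij=0.0)) == 0.0

    def test_direct_arithmetic(self):
        # q=2, F=0.1, gap 0.5 => -2*0.01/0.5 = -0.04 (stabilization-negative)
        assert e2_energy(row()) == pytest.approx(-0.04)

    def test_scaling_laws(self):
        base = abs(e2_energy(row()))
        assert abs(e2_energy(row(fij=0.2))) == pytest.approx(4 * base)
        assert abs(e2_energy(row(ej=0.0))) == pytest.approx(base / 2)

    def test_magnitude_invariant_under_fock_sign_flip(self):
        assert abs(e2_energy(row(fij=-0.1))) == abs(e2_energy(row(fij=0.1)))

    def test_degenerate_orbitals_rejected(self):
        with pytest.raises(DegeneracyError):
            e2_energy(row(ei=-0.7, ej=-0.7))

    def test_missing_matrix_elements_refused(self):
        bare = NBORow(donor=parse_orbital("LP O1"), acceptor=parse_orbital("BD* O2-H3"), e2=1.0)
        with pytest.raises(MissingInputError):
            e2_energy(bare)


class TestCutoff:
    def _classified(self, magnitudes):
        return [
            classify_interaction(
                NBORow(
                    donor=parse_orbital("LP O1"),
                    acceptor=parse_orbital("BD* O2-H3"),
                    e2=m,
                )
            )
            for m in magnitudes
        ]

    def test_published_cutoff_keeps_reportable_rows(self):
        result = apply_cutoff(self._classified([0.29, 0.19, 17.25]), cutoff=0.20)
        assert [c.e2_magnitude for c in result.retained] == [0.29, 17.25]
        assert [c.e2_magnitude for c in result.discarded] == [0.19]
        assert result.discarded_mass == pytest.approx(0.19)

    def test_zero_cutoff_is_identity(self):
        rows = self._classified([0.1, 0.2, 0.3])
        result = apply_cutoff(rows, cutoff=0.0)
        assert list(result.retained) == rows and not result.discarded

    @given(st.lists(st.floats(0.0, 30.0), max_size=20), st.floats(0.0, 5.0))
    @settings(max_examples=50)
    def test_retained_plus_discarded_partition_the_input(self, magnitudes, cutoff):
        rows = self._classified(magnitudes)
        result = apply_cutoff(rows, cutoff=cutoff)
        assert sorted(
            [c.e2_magnitude for c in result.retained]
            + [c.e2_magnitude for c in result.discarded]
        ) == sorted(magnitudes)


class TestClassification:
    @pytest.mark.parametrize(
        "donor, acceptor, category",
        [
            ("LP N33", "BD* N67-H68", "hydrogen_bond"),
            ("LP O33", "BD* O89-H90", "hydrogen_bond"),
            ("LP(1)O62", "BD* O92-H91", "hydrogen_bond"),  # H printed first
            ("LP O41", "BD* C48-H54", "dipolar"),  # lone pair into a C-H
            ("BD C14-H18", "BD* O89-H90", "dipolar"),  # polar acceptor, no LP donor
            ("BD C8-C9", "BD* C70-C71", "pi_pi"),
            ("BD* C11-C12", "BD* C70-C71", "pi_pi"),
            ("BD C15-C16", "LP*(1)C84", "pi_pi"),
            ("BD C48-C53", "BD* C3-H7", "sigma_pi"),
            ("BD C22-C23", "BD* C79-H82", "sigma_pi"),
            ("BD C48-C53", "RY* H7", "dispersion"),
        ],
    )
    def test_rule_table(self, donor, acceptor, category):
        nbo_row = NBORow(donor=parse_orbital(donor), acceptor=parse_orbital(acceptor), e2=1.0)
        assert classify_interaction(nbo_row).category == category

    def test_classification_total_on_every_reference_row(self, reference_nbo):
        rows = [r for group in reference_nbo.values() for r in group]
        assert len(rows) == 88
        for nbo_row in rows:
            classified = classify_interaction(nbo_row)
            assert classified.e2_magnitude >= 0.20  # published rows already cut off
            assert classified.category in (
                "hydrogen_bond",
                "dipolar",
                "pi_pi",
                "sigma_pi",
                "dispersion",
                "other",
            )

    def test_amoxicillin_chitosan_out_hydrogen_bonds_ibuprofen_chitosan(self, reference_nbo):
        def hb_mass(name):
            return sum(
                c.e2_magnitude
                for c in map(classify_interaction, reference_nbo[name])
                if c.category == "hydrogen_bond"
            )

        assert hb_mass("AMOX-CS") > hb_mass("IBU-CS")


def scene(donor_xyz, h_xyz, acceptor_xyz, acceptor_el="O"):
    a = Fragment(
        "donor",
        (Atom("O", 1, donor_xyz), Atom("H", 2, h_xyz), Atom("C", 3, (50.0, 0, 0))),
    )
    b = Fragment("acceptor", (Atom(acceptor_el, 1, acceptor_xyz), Atom("C", 2, (60.0, 0, 0))))
    return ComplexGeometry.assemble("scene", a, b)


class TestHBondDetection:
    def test_single_planted_contact_found(self):
        cx = scene((0, 0, 0), (0.96, 0, 0), (3.46, 0, 0))  # H...O = 2.5 A
        contacts = detect_hbonds(cx)
        assert len(contacts) == 1
        contact = contacts[0]
        assert (contact.donor_heavy, contact.donor_h, contact.acceptor) == (1, 2, 4)
        assert contact.distance == pytest.approx(2.5)

    def test_acceptor_beyond_cutoff_is_ignored(self):
        cx = scene((0, 0, 0), (0.96, 0, 0), (0.96 + 3.5, 0, 0))
        assert detect_hbonds(cx) == []

    def test_same_fragment_pairs_excluded(self):
        # donor and acceptor O both on fragment A, nothing detectable on B
        a = Fragment(
            "all-in-one",
            (
                Atom("O", 1, (0.0, 0, 0)),
                Atom("H", 2, (0.96, 0, 0)),
                Atom("O", 3, (3.0, 0, 0)),
            ),
        )
        b = Fragment("inert", (Atom("C", 1, (50.0, 0, 0)),))
        assert detect_hbonds(ComplexGeometry.assemble("intra", a, b)) == []

    def test_carbon_bound_hydrogen_is_not_a_donor(self):
        a = Fragment("ch", (Atom("C", 1, (0.0, 0, 0)), Atom("H", 2, (1.09, 0, 0))))
        b = Fragment("o", (Atom("O", 1, (3.0, 0, 0)),))
        assert detect_hbonds(ComplexGeometry.assemble("ch-o", a, b)) == []

    def test_optional_angle_filter(self):
        # bent arrangement: donor-H...acceptor angle = 90 degrees
        cx = scene((0, 0, 0), (0.96, 0, 0), (0.96, 2.0, 0))
        assert len(detect_hbonds(cx)) == 1
        assert detect_hbonds(cx, min_angle=120.0) == []

    def test_detection_on_both_fragment_orientations(self):
        # donor hydrogens on fragment B must be detected too
        a = Fragment("acceptor", (Atom("N", 1, (0.0, 0, 0)),))
        b = Fragment("donor", (Atom("O", 1, (3.0, 0, 0)), Atom("H", 2, (2.04, 0, 0))))
        contacts = detect_hbonds(ComplexGeometry.assemble("rev", a, b))
        assert len(contacts) == 1

    @pytest.mark.parametrize("n", [0, 1, 4])
    def test_planted_scenes_recover_exact_counts(self, n):
        cx = make_hbond_scene(n_contacts=n, cutoff=3.0, seed=42)
        assert len(detect_hbonds(cx, cutoff=3.0)) == n

    def test_raising_cutoff_never_removes_contacts(self):
        cx = make_hbond_scene(n_contacts=3, cutoff=3.0, seed=7)
        base = detect_hbonds(cx, cutoff=3.0)
        wider = detect_hbonds(cx, cutoff=4.0)
        base_keys = {(c.donor_h, c.acceptor) for c in base}
        wider_keys = {(c.donor_h, c.acceptor) for c in wider}
        assert base_keys <= wider_keys
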