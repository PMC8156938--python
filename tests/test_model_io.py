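"""Domain types, XYZ/QC-summary/parameter-table parsing, orbital grammar."""

import math

import numpy as np
import pytest

from adsorbscreen.errors import (
    ParameterError,
    ParseError,
    SchemaError,
    ValidationError,
)
from adsorbscreen.io import (
    attach_parameters,
    convert_energy,
    convert_entropy,
    parse_parameter_table,
    parse_qc_summary,
    read_qc_summary,
    read_xyz,
    write_qc_summary,
    write_xyz,
)
from adsorbscreen.model import (
    Atom,
    ComplexGeometry,
    Fragment,
    NBORow,
    QCSummary,
    parse_orbital,
)


def frag(*atoms):
    return Fragment(name="f", atoms=tuple(atoms))


class TestDomainTypes:
    def test_atom_rejects_unknown_element_and_bad_parameters(self):
        with pytest.raises(ValidationError):
            Atom("Xx", 1, (0, 0, 0))
        with pytest.raises(ValidationError):
            Atom("O", 1, (0, 0, float("nan")))
        with pytest.raises(ValidationError):
            Atom("O", 1, (0, 0, 0), sigma=-1.0)

    def test_fragment_requires_atoms_and_unique_serials(self):
        with pytest.raises(ValidationError):
            Fragment(name="empty", atoms=())
        a = Atom("O", 1, (0, 0, 0))
        with pytest.raises(ValidationError):
            Fragment(name="dup", atoms=(a, a))

    def test_complex_assembly_renumbers_bijectively(self):
        a = frag(Atom("O", 1, (0, 0, 0)), Atom("H", 2, (1, 0, 0)))
        b = frag(Atom("N", 1, (5, 0, 0)), Atom("H", 2, (6, 0, 0)), Atom("H", 3, (7, 0, 0)))
        cx = ComplexGeometry.assemble("c", a, b)
        serials = sorted(x.index for x in cx.fragment_a) + sorted(x.index for x in cx.fragment_b)
        assert serials == [1, 2, 3, 4, 5]
        assert len(cx) == len(a) + len(b)
        # direct construction with clashing serials is refused
        with pytest.raises(ValidationError):
            ComplexGeometry("bad", a, b)

    def test_qcsummary_frontier_ordering_enforced(self):
        with pytest.raises(ValidationError):
            QCSummary(species="x", homo=1.0, lumo=-1.0)
        with pytest.raises(ValidationError):
            QCSummary(species="x", temperature=0.0)


class TestXYZ:
    def test_single_oxygen(self, tmp_path):
        p = tmp_path / "o.xyz"
        p.write_text("1\n\nO 0.0 0.0 0.0\n")
        (fragment,) = read_xyz(p)
        assert fragment.elements == ["O"]
        assert fragment.atoms[0].index == 1
        assert fragment.atoms[0].position == (0.0, 0.0, 0.0)

    def test_round_trip_preserves_coordinates_to_printed_precision(self, tmp_path):
        rng = np.random.default_rng(7)
        atoms = tuple(
            Atom("C", i + 1, tuple(rng.uniform(-20, 20, 3)))
            for i in range(12)
        )
        original = Fragment(name="loop", atoms=atoms)
        path = tmp_path / "loop.xyz"
        write_xyz(original, path)
        (again,) = read_xyz(path)
        assert np.allclose(again.positions, original.positions, atol=1e-6, rtol=0)
        # a second round trip is exactly stable (printed values are fixed points)
        path2 = tmp_path / "loop2.xyz"
        write_xyz(again, path2)
        (third,) = read_xyz(path2)
        assert np.array_equal(third.positions, again.positions)

    @pytest.mark.parametrize(
        "content, message",
        [
            ("", "empty"),
            ("x\n\nO 0 0 0\n", "count"),
            ("1\n\nO 0 0 zz\n", "coordinate"),
            ("1\n\nQq 0 0 0\n", "element"),
            ("5\n\nO 0 0 0\n", "line"),
        ],
    )
    def test_malformed_files_name_the_problem(self, tmp_path, content, message):
        p = tmp_path / "bad.xyz"
        p.write_text(content)
        with pytest.raises(ParseError, match=message):
            read_xyz(p)

    def test_multi_block_file_yields_one_fragment_each(self, tmp_path):
        p = tmp_path / "two.xyz"
        p.write_text("1\nfirst\nO 0 0 0\n1\nsecond\nN 1 1 1\n")
        frags = read_xyz(p)
        assert [f.name for f in frags] == ["first", "second"]


class TestQCSummary:
    def test_reference_row_parses_to_canonical_values(self, tmp_path):
        text = (
            "species = AMOX-CS\n"
            "enthalpy = -42.53 kcal/mol\n"
            "entropy = -61.78 cal/mol/K\n"
        )
        s = parse_qc_summary(text)
        assert s.enthalpy == pytest.approx(-42.53)
        assert s.entropy == pytest.approx(-61.78)
        assert s.temperature == 298.15 and s.pressure == 1.0

    def test_entropy_unit_tag_scales_to_cal(self):
        s = parse_qc_summary(
            "species = x\nenthalpy = -1\nentropy = -0.06178 kcal/(mol.K)\n"
        )
        assert s.entropy == pytest.approx(-61.78)

    def test_energy_unit_conversions_and_idempotence(self):
        assert convert_energy(1.0, "hartree") == pytest.approx(627.5094740631)
        assert convert_energy(1.0, "eV") == pytest.approx(23.0605478, abs=1e-6)
        assert convert_energy(4.184, "kJ/mol") == pytest.approx(1.0)
        # converting an already-canonical value again is the identity
        once = convert_energy(-42.53, "kcal/mol")
        assert convert_energy(once, "kcal/mol") == once
        assert convert_entropy(convert_entropy(-61.78, None), None) == -61.78

    def test_missing_mandatory_field_is_schema_error(self):
        with pytest.raises(SchemaError, match="entropy"):
            parse_qc_summary("species = x\nenthalpy = -1\n")

    def test_bsse_absent_stays_none(self):
        s = parse_qc_summary("species = x\nenthalpy = -1\nentropy = -2\n")
        assert s.bsse is None

    def test_homo_above_lumo_rejected(self):
        with pytest.raises(ValidationError):
            parse_qc_summary(
                "species = x\nenthalpy = -1\nentropy = -2\nhomo = 5\nlumo = -5\n"
            )

    def test_write_read_round_trip(self, tmp_path):
        s = QCSummary(
            species="demo",
            electronic_energy=-123.456,
            enthalpy=-42.53,
            entropy=-61.78,
            homo=-188.77,
            lumo=30.21,
            bsse=2.5,
        )
        path = tmp_path / "demo.qc"
        write_qc_summary(s, path)
        again = read_qc_summary(path)
        assert again == s


class TestParameterTables:
    def test_element_default_populates_every_atom(self):
        table = parse_parameter_table("O -0.8 1.66 0.21\n")
        out = attach_parameters(frag(Atom("O", 1, (0, 0, 0))), table)
        atom = out.atoms[0]
        assert (atom.charge, atom.sigma, atom.epsilon) == (-0.8, 1.66, 0.21)

    def test_per_serial_override_beats_element_default(self):
        table = parse_parameter_table("O -0.8 1.66 0.21\n2 0.4 3.0 0.1\n")
        out = attach_parameters(
            frag(Atom("O", 1, (0, 0, 0)), Atom("O", 2, (2, 0, 0))), table
        )
        assert out.atoms[0].charge == -0.8
        assert out.atoms[1].charge == 0.4

    def test_unresolvable_atoms_are_listed(self):
        with pytest.raises(ParameterError, match="N1"):
            attach_parameters(frag(Atom("N", 1, (0, 0, 0))), {})


class TestOrbitalGrammar:
    @pytest.mark.parametrize(
        "text, kind, atoms, mult",
        [
            ("LP(2)O66", "LP", (("O", 66),), 2),
            ("BD* N67-H68", "BD*", (("N", 67), ("H", 68)), None),
            ("BD C 48-H 54", "BD", (("C", 48), ("H", 54)), None),
            ("LP (1)O92", "LP", (("O", 92),), 1),
            ("RY* H7", "RY*", (("H", 7),), None),
            ("LP*(1)C84", "LP*", (("C", 84),), 1),
            ("BD*C41-O42", "BD*", (("C", 41), ("O", 42)), None),
        ],
    )
    def test_printed_variants_parse(self, text, kind, atoms, mult):
        orb = parse_orbital(text)
        assert (orb.kind, orb.atoms, orb.multiplicity) == (kind, atoms, mult)

    def test_str_round_trips(self):
        for text in ("LP(2)O66", "BD* N67-H68", "RY* H7"):
            orb = parse_orbital(text)
            assert parse_orbital(str(orb)) == orb

    def test_garbage_raises_parse_error_with_raw_string(self):
        with pytest.raises(ParseError, match="XX"):
            parse_orbital("XX nonsense")

    def test_nborow_occupancy_bounds(self):
        donor, acceptor = parse_orbital("LP O1"), parse_orbital("BD* O2-H3")
        with pytest.raises(ValidationError):
            NBORow(donor=donor, acceptor=acceptor, occupancy_qi=2.5)
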