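"""Readers and writers for the plain-text formats the pipeline consumes.

Formats:

* XYZ geometries (count line, comment line, ``element x y z`` records;
  several blocks per file are allowed — one fragment each).
* QC summaries: one ``key = value [unit]`` per line, ``#`` comments;
  values are converted to canonical units on read.
* Nonbonded parameter tables: delimited columns
  ``selector charge sigma epsilon`` where the selector is an element
  symbol (default for that element) or an atom serial (per-atom override).
* NBO interaction tables: tab-separated ``donor  acceptor  ...`` rows with
  either a precomputed E(2) column or the raw matrix elements.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import ParameterError, ParseError, SchemaError
from .model import ELEMENTS, Atom, Fragment, NBORow, QCSummary, parse_orbital

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_qc_summary",
    "parse_qc_summary",
    "write_qc_summary",
    "read_parameter_table",
    "parse_parameter_table",
    "attach_parameters",
    "read_nbo_table",
    "write_nbo_table",
]

PathLike = Union[str, Path]

# Conversion factors into canonical units. Keys are lower-case unit tags with
# whitespace and unicode dots normalised away.
HARTREE_TO_KCAL = 627.5094740631
EV_TO_KCAL = 23.060547830619026

_ENERGY_FACTORS = {
    "kcal/mol": 1.0,
    "kcal": 1.0,
    "hartree": HARTREE_TO_KCAL,
    "au": HARTREE_TO_KCAL,
    "ev": EV_TO_KCAL,
    "kj/mol": 1.0 / 4.184,
    "kj": 1.0 / 4.184,
}
_ENTROPY_FACTORS = {
    "cal/(mol*k)": 1.0,
    "cal/mol/k": 1.0,
    "cal/mol*k": 1.0,
    "cal/mol": 1.0,  # the reference tables' shorthand header
    "kcal/(mol*k)": 1000.0,
    "kcal/mol/k": 1000.0,
    "j/(mol*k)": 1.0 / 4.184,
    "j/mol/k": 1.0 / 4.184,
}

_ENERGY_KEYS = {
    "electronic_energy",
    "enthalpy",
    "homo",
    "lumo",
    "scf_first",
    "scf_last",
    "e_nkvj",
    "e_kinetic",
    "bsse",
}
_MANDATORY_KEYS = ("species", "enthalpy", "entropy")


def _normalise_unit(tag: str) -> str:
    return (
        tag.strip()
        .lower()
        .replace("·", "*")
        .replace(".", "*")
        .replace(" ", "")
        .replace("k)", "k)")
    )


def convert_energy(value: float, unit: Optional[str]) -> float:
    """Convert an energy to kcal/mol. ``None`` means already canonical."""
    if unit is None:
        return value
    tag = _normalise_unit(unit)
    if tag not in _ENERGY_FACTORS:
        raise ParseError(f"unknown energy unit {unit!r}")
    return value * _ENERGY_FACTORS[tag]


def convert_entropy(value: float, unit: Optional[str]) -> float:
    """Convert an entropy to cal/(mol K)."""
    if unit is None:
        return value
    tag = _normalise_unit(unit)
    if tag not in _ENTROPY_FACTORS:
        raise ParseError(f"unknown entropy unit {unit!r}")
    return value * _ENTROPY_FACTORS[tag]


# --- XYZ ---------------------------------------------------------------------


def read_xyz(path: PathLike, name: Optional[str] = None) -> list[Fragment]:
    """Read one or more XYZ blocks into fragments.

    Atom serials are assigned 1..N in file order within each block.
    Parse failures name the offending line.
    """
    lines = Path(path).read_text().splitlines()
    fragments: list[Fragment] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():  # tolerate blank separator lines between blocks
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}, line {i + 1}: expected an atom count, got {lines[i]!r}")
        if count < 1:
            raise ParseError(f"{path}, line {i + 1}: atom count must be >= 1")
        if i + 1 + count >= n_lines + 1:
            raise ParseError(f"{path}, line {i + 1}: count {count} exceeds remaining lines")
        comment = lines[i + 1].strip() if i + 1 < n_lines else ""
        atoms = []
        for serial, j in enumerate(range(i + 2, i + 2 + count), start=1):
            if j >= n_lines:
                raise ParseError(f"{path}: truncated block starting at line {i + 1}")
            parts = lines[j].split()
            if len(parts) < 4:
                raise ParseError(f"{path}, line {j + 1}: expected 'element x y z'")
            element = parts[0]
            if element not in ELEMENTS:
                raise ParseError(f"{path}, line {j + 1}: unknown element {element!r}")
            try:
                x, y, z = (float(p) for p in parts[1:4])
            except ValueError:
                raise ParseError(f"{path}, line {j + 1}: non-numeric coordinate")
            atoms.append(Atom(element=element, index=serial, position=(x, y, z)))
        label = comment or name or Path(path).stem
        if fragments:
            label = f"{label}:{len(fragments) + 1}" if not comment else label
        fragments.append(Fragment(name=label, atoms=tuple(atoms)))
        i = i + 2 + count
    if not fragments:
        raise ParseError(f"{path}: empty XYZ file")
    return fragments


def write_xyz(fragments: Union[Fragment, Sequence[Fragment]], path: PathLike, precision: int = 6) -> None:
    """Write fragments as concatenated XYZ blocks (coordinates to ``precision`` decimals)."""
    if isinstance(fragments, Fragment):
        fragments = [fragments]
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(f"{len(frag)}\n{frag.name}\n")
            for atom in frag:
                x, y, z = atom.position
                fh.write(
                    f"{atom.element} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}\n"
                )


# --- QC summaries ------------------------------------------------------------


def parse_qc_summary(text: str, source: str = "<string>") -> QCSummary:
    """Parse a key/value QC summary from text. See module docstring for the schema."""
    fields: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{source}, line {lineno}: expected 'key = value', got {raw!r}")
        key, rhs = (s.strip() for s in line.split("=", 1))
        key = key.lower()
        if key == "species":
            fields["species"] = rhs
            continue
        parts = rhs.split()
        if not parts:
            raise ParseError(f"{source}, line {lineno}: missing value for {key!r}")
        try:
            value = float(parts[0])
        except ValueError:
            raise ParseError(f"{source}, line {lineno}: non-numeric value {parts[0]!r}")
        unit = " ".join(parts[1:]) or None
        if key in _ENERGY_KEYS:
            fields[key] = convert_energy(value, unit)
        elif key == "entropy":
            fields[key] = convert_entropy(value, unit)
        elif key in ("temperature", "pressure"):
            fields[key] = value
        else:
            raise ParseError(f"{source}, line {lineno}: unknown key {key!r}")
    missing = [k for k in _MANDATORY_KEYS if k not in fields]
    if missing:
        raise SchemaError(f"{source}: missing mandatory field(s) {missing}")
    return QCSummary(**fields)  # type: ignore[arg-type]


def read_qc_summary(path: PathLike) -> QCSummary:
    return parse_qc_summary(Path(path).read_text(), source=str(path))


def write_qc_summary(summary: QCSummary, path: PathLike) -> None:
    """Write a summary in canonical units (the reader round-trips it)."""
    with open(path, "w") as fh:
        fh.write(f"species = {summary.species}\n")
        for key in sorted(_ENERGY_KEYS):
            value = getattr(summary, key)
            if value is not None:
                fh.write(f"{key} = {value:.10g} kcal/mol\n")
        if summary.entropy is not None:
            fh.write(f"entropy = {summary.entropy:.10g} cal/mol/K\n")
        fh.write(f"temperature = {summary.temperature:.10g} K\n")
        fh.write(f"pressure = {summary.pressure:.10g} atm\n")


# --- nonbonded parameter tables ----------------------------------------------


def parse_parameter_table(text: str, source: str = "<string>") -> dict[Union[str, int], tuple[float, float, float]]:
    """Parse ``selector charge sigma epsilon`` rows (whitespace or comma delimited).

    Integer selectors are per-atom overrides; element-symbol selectors are
    per-element defaults.
    """
    table: dict[Union[str, int], tuple[float, float, float]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 4:
            raise ParseError(
                f"{source}, line {lineno}: expected 'selector charge sigma epsilon'"
            )
        selector: Union[str, int]
        if parts[0].isdigit():
            selector = int(parts[0])
        elif parts[0] in ELEMENTS:
            selector = parts[0]
        else:
            raise ParseError(f"{source}, line {lineno}: bad selector {parts[0]!r}")
        try:
            q, sigma, epsilon = (float(p) for p in parts[1:])
        except ValueError:
            raise ParseError(f"{source}, line {lineno}: non-numeric parameter")
        table[selector] = (q, sigma, epsilon)
    return table


def read_parameter_table(path: PathLike) -> dict[Union[str, int], tuple[float, float, float]]:
    return parse_parameter_table(Path(path).read_text(), source=str(path))


def attach_parameters(
    fragment: Fragment,
    table: Mapping[Union[str, int], tuple[float, float, float]],
) -> Fragment:
    """Populate charge/sigma/epsilon on every atom from a parameter map.

    Per-serial entries (integer selectors) override per-element entries.
    Raises :class:`ParameterError` naming every unresolvable atom.
    """
    atoms = []
    missing = []
    for atom in fragment:
        entry = table.get(atom.index, table.get(atom.element))
        if entry is None:
            missing.append(f"{atom.element}{atom.index}")
            continue
        q, sigma, epsilon = entry
        atoms.append(dataclasses.replace(atom, charge=q, sigma=sigma, epsilon=epsilon))
    if missing:
        raise ParameterError(
            f"fragment {fragment.name!r}: no parameters for atoms {', '.join(missing)}"
        )
    return dataclasses.replace(fragment, atoms=tuple(atoms))


# --- NBO tables --------------------------------------------------------------


def read_nbo_table(path: PathLike) -> list[NBORow]:
    """Read tab-separated NBO rows.

    Accepted layouts (after an optional header line):

    * ``donor  acceptor  e2``
    * ``donor  acceptor  qi  fij  e_donor  e_acceptor [e2]``
    """
    rows: list[NBORow] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("\t")]
        if lineno == 1 and parts and parts[0].lower() in ("donor", "donator"):
            continue  # header
        if len(parts) == 3:
            donor, acceptor, e2 = parts
            try:
                rows.append(
                    NBORow(
                        donor=parse_orbital(donor),
                        acceptor=parse_orbital(acceptor),
                        e2=float(e2),
                    )
                )
            except ValueError:
                raise ParseError(f"{path}, line {lineno}: non-numeric E(2) {e2!r}")
        elif len(parts) in (6, 7):
            donor, acceptor, *nums = parts
            try:
                values = [float(n) for n in nums]
            except ValueError:
                raise ParseError(f"{path}, line {lineno}: non-numeric matrix element")
            rows.append(
                NBORow(
                    donor=parse_orbital(donor),
                    acceptor=parse_orbital(acceptor),
                    occupancy_qi=values[0],
                    fock_fij=values[1],
                    e_donor=values[2],
                    e_acceptor=values[3],
                    e2=values[4] if len(values) == 5 else None,
                )
            )
        else:
            raise ParseError(
                f"{path}, line {lineno}: expected 3, 6 or 7 tab-separated columns, got {len(parts)}"
            )
    return rows


def write_nbo_table(rows: Iterable[NBORow], path: PathLike) -> None:
    """Write rows in a layout :func:`read_nbo_table` accepts (per-row width)."""
    with open(path, "w") as fh:
        for row in rows:
            if row.has_matrix_elements:
                cols = [
                    str(row.donor),
                    str(row.acceptor),
                    f"{row.occupancy_qi:.10g}",
                    f"{row.fock_fij:.10g}",
                    f"{row.e_donor:.10g}",
                    f"{row.e_acceptor:.10g}",
                ]
                if row.e2 is not None:
                    cols.append(f"{row.e2:.10g}")
            else:
                cols = [str(row.donor), str(row.acceptor), f"{row.e2:.10g}"]
            fh.write("\t".join(cols) + "\n")
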