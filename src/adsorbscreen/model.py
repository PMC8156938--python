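"""Domain types: atoms, fragments, complexes, QC summaries and NBO rows.

Canonical units throughout the package:

* energies            kcal/mol
* entropies           cal/(mol K)
* coordinates         angstrom, with 1-based atom serials
* partial charges     elementary charge (e)
* temperature         kelvin; pressure in atm

These match the conventions of the reference tables the package ships
(enthalpy/entropy columns in kcal/mol and cal/(mol K)), so table rows can
be compared to computed quantities without conversion.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import ParseError, ValidationError

__all__ = [
    "Atom",
    "Fragment",
    "ComplexGeometry",
    "QCSummary",
    "OrbitalDescriptor",
    "NBORow",
    "parse_orbital",
]

# Recognized element symbols (H through U covers every input this package sees).
ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U".split()
)


@dataclass(frozen=True)
class Atom:
    """One atomic site: element, 1-based serial, position, optional nonbonded parameters.

    ``charge`` is the partial charge in e; ``sigma`` (angstrom) and
    ``epsilon`` (kcal/mol) are Lennard-Jones parameters. All three are
    optional because geometries and parameter tables arrive separately.
    """

    element: str
    index: int
    position: tuple[float, float, float]
    charge: Optional[float] = None
    sigma: Optional[float] = None
    epsilon: Optional[float] = None

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValidationError(f"unknown element symbol {self.element!r}")
        if self.index < 1:
            raise ValidationError(f"atom serial must be >= 1, got {self.index}")
        if len(self.position) != 3 or not all(math.isfinite(c) for c in self.position):
            raise ValidationError(f"non-finite coordinates for atom {self.index}")
        if self.sigma is not None and self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0 (atom {self.index})")
        if self.epsilon is not None and self.epsilon < 0:
            raise ValidationError(f"epsilon must be >= 0 (atom {self.index})")

    @property
    def has_parameters(self) -> bool:
        return None not in (self.charge, self.sigma, self.epsilon)


@dataclass(frozen=True)
class Fragment:
    """An ordered, non-empty collection of atoms acting as one interaction unit.

    ``role`` distinguishes the adsorbate (``pharmaceutical``) from the
    ``absorbent`` model where the distinction matters for reporting.
    """

    name: str
    atoms: tuple[Atom, ...]
    role: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError(f"fragment {self.name!r} has no atoms")
        object.__setattr__(self, "atoms", tuple(self.atoms))
        serials = [a.index for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValidationError(f"fragment {self.name!r} has duplicate atom serials")
        if self.role not in ("pharmaceutical", "absorbent", "unspecified"):
            raise ValidationError(f"unknown fragment role {self.role!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array in angstrom, file order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def renumbered(self, offset: int) -> "Fragment":
        """Shift every atom serial by ``offset`` (used when assembling complexes)."""
        return replace(
            self,
            atoms=tuple(replace(a, index=a.index + offset) for a in self.atoms),
        )

    def translated(self, shift: Sequence[float]) -> "Fragment":
        dx, dy, dz = (float(s) for s in shift)
        return replace(
            self,
            atoms=tuple(
                replace(a, position=(a.position[0] + dx, a.position[1] + dy, a.position[2] + dz))
                for a in self.atoms
            ),
        )


@dataclass(frozen=True)
class ComplexGeometry:
    """Two fragments forming one adsorbate/absorbent complex.

    Atom serials must be globally unique across the two fragments; use
    :meth:`assemble` to renumber fragment B behind fragment A.
    """

    name: str
    fragment_a: Fragment
    fragment_b: Fragment

    def __post_init__(self) -> None:
        serials_a = {a.index for a in self.fragment_a.atoms}
        serials_b = {b.index for b in self.fragment_b.atoms}
        if serials_a & serials_b:
            raise ValidationError(
                f"complex {self.name!r}: fragments share atom serials "
                f"{sorted(serials_a & serials_b)[:5]}; use ComplexGeometry.assemble"
            )

    @classmethod
    def assemble(cls, name: str, fragment_a: Fragment, fragment_b: Fragment) -> "ComplexGeometry":
        """Build a complex, renumbering fragment B to follow fragment A.

        The renumbering is a bijection: B's serials become
        ``max(serial in A) + original serial rank``.
        """
        offset = max(a.index for a in fragment_a.atoms)
        shifted = fragment_b.renumbered(offset)
        return cls(name=name, fragment_a=fragment_a, fragment_b=shifted)

    def __len__(self) -> int:
        return len(self.fragment_a) + len(self.fragment_b)

    def swapped(self) -> "ComplexGeometry":
        """The same complex with the A/B fragment labels exchanged."""
        return ComplexGeometry(self.name, self.fragment_b, self.fragment_a)


@dataclass(frozen=True)
class QCSummary:
    """One species' quantum-chemistry summary in canonical units.

    Carries the quantities downstream operations consume: electronic energy,
    thermochemistry (H, S at stated T, P), frontier-orbital energies, SCF
    iteration endpoints and EDA inputs. Optional fields stay ``None`` when a
    summary does not provide them; operations that need them must refuse
    rather than impute (BSSE in particular is never silently zeroed).
    """

    species: str
    electronic_energy: Optional[float] = None  # kcal/mol
    enthalpy: Optional[float] = None  # kcal/mol
    entropy: Optional[float] = None  # cal/(mol K)
    homo: Optional[float] = None  # kcal/mol
    lumo: Optional[float] = None  # kcal/mol
    scf_first: Optional[float] = None  # kcal/mol
    scf_last: Optional[float] = None  # kcal/mol
    e_nkvj: Optional[float] = None  # kcal/mol
    e_kinetic: Optional[float] = None  # kcal/mol
    bsse: Optional[float] = None  # kcal/mol, complexes only
    temperature: float = 298.15  # K
    pressure: float = 1.0  # atm

    def __post_init__(self) -> None:
        if not self.species:
            raise ValidationError("QCSummary requires a species label")
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if self.homo is not None and self.lumo is not None and self.homo >= self.lumo:
            raise ValidationError(
                f"{self.species}: HOMO ({self.homo}) must lie below LUMO ({self.lumo})"
            )


# --- NBO orbital descriptors -------------------------------------------------

_ORBITAL_RE = re.compile(
    r"^(BD\*|BD|LP\*|LP|RY\*|RY|CR)"  # orbital kind, starred = non-Lewis
    r"(?:\((\d+)\))?"  # optional multiplicity index
    r"([A-Za-z0-9\-]+)$"  # atom list, e.g. N67-H68 or O66
)
_ATOM_TOKEN_RE = re.compile(r"^([A-Z][a-z]?)(\d+)$")


@dataclass(frozen=True)
class OrbitalDescriptor:
    """A natural-orbital label such as ``LP(2)O66`` or ``BD* N67-H68``.

    ``kind`` is one of BD, BD*, LP, LP*, RY, RY*, CR; ``atoms`` holds
    (element, serial) pairs in printed order.
    """

    kind: str
    atoms: tuple[tuple[str, int], ...]
    multiplicity: Optional[int] = None

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(e for e, _ in self.atoms)

    @property
    def is_antibond(self) -> bool:
        return self.kind.endswith("*")

    @property
    def is_lone_pair(self) -> bool:
        return self.kind in ("LP", "LP*")

    def involves(self, *symbols: str) -> bool:
        return any(e in symbols for e in self.elements)

    def is_bond_between(self, sym1: str, sym2: str) -> bool:
        """True for a 2-center BD/BD* orbital joining the two element symbols (either order)."""
        if self.kind not in ("BD", "BD*") or len(self.atoms) != 2:
            return False
        e = sorted(self.elements)
        return e == sorted((sym1, sym2))

    def __str__(self) -> str:  # round-trips through parse_orbital
        mult = f"({self.multiplicity})" if self.multiplicity is not None else ""
        atoms = "-".join(f"{e}{i}" for e, i in self.atoms)
        return f"{self.kind}{mult}{atoms}"


def parse_orbital(text: str) -> OrbitalDescriptor:
    """Parse an orbital descriptor string.

    The printed tables are typographically noisy ("BD C 48-H 54",
    "LP (1)O92", "BD* O63-H 64"); all interior whitespace is insignificant
    and stripped before matching.
    """
    compact = re.sub(r"\s+", "", text)
    m = _ORBITAL_RE.match(compact)
    if not m:
        raise ParseError(f"unparsable orbital descriptor {text!r}")
    kind, mult, atom_part = m.groups()
    atoms = []
    for token in atom_part.split("-"):
        am = _ATOM_TOKEN_RE.match(token)
        if not am or am.group(1) not in ELEMENTS:
            raise ParseError(f"unparsable atom token {token!r} in descriptor {text!r}")
        atoms.append((am.group(1), int(am.group(2))))
    return OrbitalDescriptor(
        kind=kind,
        atoms=tuple(atoms),
        multiplicity=int(mult) if mult else None,
    )


@dataclass(frozen=True)
class NBORow:
    """One donor->acceptor second-order perturbation entry.

    Either the matrix elements (occupancy ``occupancy_qi``, Fock element
    ``fock_fij``, orbital energies ``e_donor``/``e_acceptor``) are present so
    E(2) can be computed, or a precomputed ``e2`` (kcal/mol, printed
    magnitude) is supplied — published tables print only the latter.
    """

    donor: OrbitalDescriptor
    acceptor: OrbitalDescriptor
    occupancy_qi: Optional[float] = None  # electrons in the donor orbital
    fock_fij: Optional[float] = None  # off-diagonal Fock element
    e_donor: Optional[float] = None
    e_acceptor: Optional[float] = None
    e2: Optional[float] = None  # kcal/mol

    def __post_init__(self) -> None:
        if self.occupancy_qi is not None and not (0.0 <= self.occupancy_qi <= 2.0):
            raise ValidationError(
                f"donor occupancy must lie in [0, 2], got {self.occupancy_qi}"
            )

    @property
    def has_matrix_elements(self) -> bool:
        return None not in (self.occupancy_qi, self.fock_fij, self.e_donor, self.e_acceptor)
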