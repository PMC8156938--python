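"""Second-order perturbation (NBO) analysis: E(2), cut-off, classification,
and the geometric hydrogen-bond detector.

The stabilization from a donor orbital i delocalizing into an acceptor
orbital j is

    E(2) = - q_i F_ij^2 / (E_j - E_i)

with q_i the donor occupancy, F_ij the off-diagonal Fock element and
E_i/E_j the orbital energies. For a donor below its acceptor (E_j > E_i)
the value is negative (stabilizing); published tables print the
magnitude, and so do the reports here.

Interaction categories are assigned by a deterministic first-match rule
table constructed to reproduce the prose labels attached to the reference
interaction rows (hydrogen bond / dipolar / pi-pi / sigma-pi /
dispersion); the source describes the labels only in prose, never as an
algorithm, so the rule table is this package's own operationalization.

Hydrogen bonds are detected geometrically: an N/O-bound H on one fragment
within a distance cutoff (default 3 angstrom) of an N/O acceptor on the
other fragment. No angular criterion is applied by default (the distance
rule alone is the published criterion); an optional donor-H...acceptor
angle filter can be switched on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .errors import DegeneracyError, MissingInputError
from .model import ComplexGeometry, Fragment, NBORow, OrbitalDescriptor

__all__ = [
    "DEFAULT_E2_CUTOFF",
    "DEFAULT_HBOND_CUTOFF",
    "DEFAULT_COVALENT_MAX",
    "ClassifiedInteraction",
    "CutoffResult",
    "HBondContact",
    "e2_energy",
    "apply_cutoff",
    "classify_interaction",
    "detect_hbonds",
]

DEFAULT_E2_CUTOFF = 0.20  # kcal/mol, reporting cut-off for E(2) magnitudes
DEFAULT_HBOND_CUTOFF = 3.0  # angstrom, H...acceptor distance criterion
DEFAULT_COVALENT_MAX = 1.2  # angstrom, X-H attachment distance

CATEGORIES = ("hydrogen_bond", "dipolar", "pi_pi", "sigma_pi", "dispersion", "other")


def e2_energy(row: NBORow) -> float:
    """Signed second-order stabilization energy -q_i F_ij^2 / (E_j - E_i).

    Units follow the inputs (F, E in one consistent energy unit gives E(2)
    in that unit). Use ``abs()`` for the printed-magnitude convention.
    """
    if not row.has_matrix_elements:
        raise MissingInputError(
            f"{row.donor} -> {row.acceptor}: matrix elements (q_i, F_ij, E_i, E_j) required"
        )
    gap = row.e_acceptor - row.e_donor
    if gap == 0:
        raise DegeneracyError(
            f"{row.donor} -> {row.acceptor}: degenerate orbital energies (E_j = E_i)"
        )
    return -row.occupancy_qi * row.fock_fij**2 / gap


@dataclass(frozen=True)
class ClassifiedInteraction:
    """One NBO row with its E(2) magnitude and assigned category."""

    row: NBORow
    e2_magnitude: float
    category: str

    def __post_init__(self) -> None:
        if self.e2_magnitude < 0:
            raise ValueError("e2_magnitude must be >= 0")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_interaction(row: NBORow) -> ClassifiedInteraction:
    """Assign a category by the first matching rule.

    1. hydrogen_bond: lone-pair donor on N/O into a BD* X-H antibond, X in {N, O}
    2. dipolar: any remaining interaction touching a lone pair or a polar
       (N/O-containing) orbital
    3. pi_pi: C-C bonds / carbon LP* on both sides
    4. sigma_pi: a C-H bond on one side against a C-C bond or carbon LP* on the other
    5. dispersion: everything else
    """
    donor, acceptor = row.donor, row.acceptor
    magnitude = abs(row.e2 if row.e2 is not None else e2_energy(row))

    def _carbon_pi(orb: OrbitalDescriptor) -> bool:
        return orb.is_bond_between("C", "C") or (
            orb.is_lone_pair and orb.elements == ("C",)
        )

    def _ch_bond(orb: OrbitalDescriptor) -> bool:
        return orb.is_bond_between("C", "H")

    def _polar(orb: OrbitalDescriptor) -> bool:
        # a lone pair counts as polar only on N/O; carbon LP/LP* belongs to
        # the pi system (rule 3)
        return orb.involves("N", "O")

    if (
        donor.is_lone_pair
        and donor.involves("N", "O")
        and acceptor.kind == "BD*"
        and acceptor.involves("H")
        and (acceptor.is_bond_between("N", "H") or acceptor.is_bond_between("O", "H"))
    ):
        category = "hydrogen_bond"
    elif _polar(donor) or _polar(acceptor):
        category = "dipolar"
    elif _carbon_pi(donor) and _carbon_pi(acceptor):
        category = "pi_pi"
    elif (_ch_bond(donor) and _carbon_pi(acceptor)) or (
        _carbon_pi(donor) and _ch_bond(acceptor)
    ):
        category = "sigma_pi"
    else:
        category = "dispersion"
    return ClassifiedInteraction(row=row, e2_magnitude=magnitude, category=category)


@dataclass(frozen=True)
class CutoffResult:
    """Partition of classified rows at a reporting cut-off."""

    retained: tuple[ClassifiedInteraction, ...]
    discarded: tuple[ClassifiedInteraction, ...]
    cutoff: float

    @property
    def discarded_mass(self) -> float:
        """Total E(2) magnitude dropped below the cut-off."""
        return sum(c.e2_magnitude for c in self.discarded)


def apply_cutoff(
    rows: Iterable[ClassifiedInteraction],
    cutoff: float = DEFAULT_E2_CUTOFF,
) -> CutoffResult:
    """Retain rows with E(2) magnitude >= cutoff; the rest are reported as discarded.

    ``retained`` + ``discarded`` partition the input exactly (order preserved).
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be >= 0, got {cutoff}")
    retained, discarded = [], []
    for item in rows:
        (retained if item.e2_magnitude >= cutoff else discarded).append(item)
    return CutoffResult(retained=tuple(retained), discarded=tuple(discarded), cutoff=cutoff)


# --- geometric hydrogen-bond detection ---------------------------------------


@dataclass(frozen=True)
class HBondContact:
    """One donor-H...acceptor contact across the fragment interface."""

    donor_heavy: int  # atom serial of the N/O the H is bound to
    donor_h: int  # atom serial of the hydrogen
    acceptor: int  # atom serial of the N/O acceptor
    distance: float  # H...acceptor distance, angstrom
    angle: Optional[float] = None  # donor-H...acceptor angle, degrees


def _hydrogens_with_heavy(frag: Fragment, covalent_max: float) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """(H serial, heavy serial, H pos, heavy pos) for every N/O-bound hydrogen."""
    out = []
    heavies = [a for a in frag if a.element in ("N", "O")]
    for atom in frag:
        if atom.element != "H":
            continue
        hpos = np.asarray(atom.position)
        best = None
        for heavy in heavies:
            d = float(np.linalg.norm(hpos - np.asarray(heavy.position)))
            if d <= covalent_max and (best is None or d < best[0]):
                best = (d, heavy)
        if best is not None:
            out.append((atom.index, best[1].index, hpos, np.asarray(best[1].position)))
    return out


def detect_hbonds(
    complex_geometry: ComplexGeometry,
    cutoff: float = DEFAULT_HBOND_CUTOFF,
    covalent_max: float = DEFAULT_COVALENT_MAX,
    min_angle: Optional[float] = None,
) -> list[HBondContact]:
    """All inter-fragment (N/O)-H...(N/O) contacts with H...acceptor < cutoff.

    ``min_angle`` (degrees), when given, additionally requires the
    donor-H...acceptor angle to reach at least that value (off by default).
    Results are sorted by contact distance; an empty list is a valid outcome.
    """
    contacts: list[HBondContact] = []
    pairs = (
        (complex_geometry.fragment_a, complex_geometry.fragment_b),
        (complex_geometry.fragment_b, complex_geometry.fragment_a),
    )
    for donor_frag, acceptor_frag in pairs:
        donors = _hydrogens_with_heavy(donor_frag, covalent_max)
        acceptors = [a for a in acceptor_frag if a.element in ("N", "O")]
        for h_serial, heavy_serial, hpos, heavypos in donors:
            for acc in acceptors:
                apos = np.asarray(acc.position)
                dist = float(np.linalg.norm(hpos - apos))
                if dist >= cutoff:
                    continue
                v1 = heavypos - hpos
                v2 = apos - hpos
                denom = float(np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = (
                    math.degrees(math.acos(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)))
                    if denom > 0
                    else 180.0
                )
                if min_angle is not None and angle < min_angle:
                    continue
                contacts.append(
                    HBondContact(
                        donor_heavy=heavy_serial,
                        donor_h=h_serial,
                        acceptor=acc.index,
                        distance=dist,
                        angle=angle,
                    )
                )
    return sorted(contacts, key=lambda c: (c.distance, c.donor_h, c.acceptor))
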