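"""Synthetic fixtures: toy charged/LJ dimers, internally consistent EDA
ledgers with matching QC summaries, and planted hydrogen-bond scenes.

Every generator is a pure function of (seed, spec): identical inputs give
identical fixtures on every platform (numpy's PCG64 generator contract).
Fixtures are statistical stand-ins for quantum-chemistry outputs, not
chemistry — they exist so each pipeline identity can be tested against
known ground truth without any electronic-structure run.

Default study conditions (see the methods note for rationale): fragments
of 5 and 7 atoms drawn from {H, C, N, O}, partial charges at a 0.5 e
scale summing to an integer per fragment, LJ parameters sigma in
[2.5, 3.5] angstrom and epsilon in [0.05, 0.25] kcal/mol, an 8 angstrom
placement box and a 1.5 angstrom minimum inter-fragment separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .eda import EDARecord
from .errors import GenerationError
from .model import Atom, ComplexGeometry, Fragment, QCSummary
from .pairwise import COULOMB_CONSTANT, CombiningRule

__all__ = [
    "FixtureSpec",
    "ToyComplexFixture",
    "LedgerFixture",
    "brute_force_interaction",
    "make_toy_complex",
    "make_consistent_ledger",
    "make_hbond_scene",
    "write_toy_complex",
]

_ELEMENT_POOL = ("H", "C", "N", "O")


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the synthetic generators; (seed, spec) fixes the fixture."""

    seed: int = 0
    n_atoms_a: int = 5
    n_atoms_b: int = 7
    charge_scale: float = 0.5  # e
    box: float = 8.0  # angstrom extent per fragment
    ledger_noise: float = 0.0  # kcal/mol; 0 => identities close exactly
    min_separation: float = 1.5  # angstrom between fragments

    def __post_init__(self) -> None:
        if self.n_atoms_a < 1 or self.n_atoms_b < 1:
            raise GenerationError("fragment atom counts must be >= 1")
        if self.ledger_noise < 0:
            raise GenerationError("ledger_noise must be >= 0")


def brute_force_interaction(
    frag_a: Fragment,
    frag_b: Fragment,
    combining: CombiningRule = "plain_sum",
) -> tuple[float, float]:
    """(coulomb, lj) totals by a naive python double loop.

    Deliberately independent of the vectorized implementation so it can
    serve as its oracle.
    """
    import math

    u_elect = 0.0
    u_vdw = 0.0
    for a in frag_a:
        for b in frag_b:
            dx = a.position[0] - b.position[0]
            dy = a.position[1] - b.position[1]
            dz = a.position[2] - b.position[2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            u_elect += COULOMB_CONSTANT * a.charge * b.charge / r
            if combining == "plain_sum":
                sigma = a.sigma + b.sigma
                eps = a.epsilon + b.epsilon
            else:
                sigma = 0.5 * (a.sigma + b.sigma)
                eps = math.sqrt(a.epsilon * b.epsilon)
            sr6 = (sigma / r) ** 6
            u_vdw += 4.0 * eps * (sr6 * sr6 - sr6)
    return u_elect, u_vdw


@dataclass(frozen=True)
class ToyComplexFixture:
    """A generated dimer plus its oracle-computed interaction-energy truth."""

    complex_geometry: ComplexGeometry
    spec: FixtureSpec
    truth_u_elect: float
    truth_u_vdw: float

    @property
    def truth_u_int(self) -> float:
        return self.truth_u_elect + self.truth_u_vdw


def _random_fragment(
    rng: np.random.Generator,
    name: str,
    n_atoms: int,
    spec: FixtureSpec,
    origin: float,
) -> Fragment:
    positions = origin + rng.uniform(0.0, spec.box, size=(n_atoms, 3))
    elements = rng.choice(_ELEMENT_POOL, size=n_atoms)
    charges = rng.normal(0.0, spec.charge_scale, size=n_atoms)
    # nudge the last atom so the fragment's total charge is an integer
    total = charges.sum()
    charges[-1] += round(total) - total
    if spec.charge_scale == 0:
        charges[:] = 0.0
    sigmas = rng.uniform(2.5, 3.5, size=n_atoms)
    epsilons = rng.uniform(0.05, 0.25, size=n_atoms)
    atoms = tuple(
        Atom(
            element=str(elements[i]),
            index=i + 1,
            position=tuple(float(c) for c in positions[i]),
            charge=float(charges[i]),
            sigma=float(sigmas[i]),
            epsilon=float(epsilons[i]),
        )
        for i in range(n_atoms)
    )
    return Fragment(name=name, atoms=atoms)


def make_toy_complex(spec: FixtureSpec, combining: CombiningRule = "plain_sum") -> ToyComplexFixture:
    """A reproducible random dimer with brute-force ground-truth energies.

    Fragment B is displaced along +x until every inter-fragment distance
    clears ``spec.min_separation``; generation fails after 100 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    frag_a = _random_fragment(rng, "toy-A", spec.n_atoms_a, spec, origin=0.0)
    for attempt in range(100):
        frag_b = _random_fragment(rng, "toy-B", spec.n_atoms_b, spec, origin=0.0)
        shift = spec.box + spec.min_separation + attempt * 0.5
        frag_b = frag_b.translated((shift, 0.0, 0.0))
        diff = frag_a.positions[:, None, :] - frag_b.positions[None, :, :]
        if float(np.sqrt((diff**2).sum(axis=-1)).min()) >= spec.min_separation:
            break
    else:  # pragma: no cover - displacement grows monotonically, cannot happen
        raise GenerationError("could not place fragments clear of the clash floor")
    geometry = ComplexGeometry.assemble(f"toy-{spec.seed}", frag_a, frag_b)
    u_elect, u_vdw = brute_force_interaction(
        geometry.fragment_a, geometry.fragment_b, combining
    )
    return ToyComplexFixture(
        complex_geometry=geometry,
        spec=spec,
        truth_u_elect=u_elect,
        truth_u_vdw=u_vdw,
    )


def write_toy_complex(fixture: ToyComplexFixture, directory: Path | str) -> dict[str, Path]:
    """Emit the fixture as XYZ + per-atom parameter table files the readers accept."""
    from .io import write_xyz

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geom = fixture.complex_geometry
    paths = {}
    for tag, frag in (("a", geom.fragment_a), ("b", geom.fragment_b)):
        xyz = directory / f"{geom.name}_{tag}.xyz"
        write_xyz(frag, xyz)
        params = directory / f"{geom.name}_{tag}.params"
        with open(params, "w") as fh:
            fh.write("# selector charge sigma epsilon\n")
            for atom in frag:
                fh.write(
                    f"{atom.index} {atom.charge:.10g} {atom.sigma:.10g} {atom.epsilon:.10g}\n"
                )
        paths[f"xyz_{tag}"] = xyz
        paths[f"params_{tag}"] = params
    return paths


# --- consistent EDA ledgers --------------------------------------------------


@dataclass(frozen=True)
class LedgerFixture:
    """A ledger plus the QC summaries from which every term re-derives."""

    record: EDARecord
    complex_summary: QCSummary
    fragment_summaries: tuple[QCSummary, QCSummary]


def make_consistent_ledger(
    spec: FixtureSpec,
    targets: Optional[tuple[float, float]] = None,
) -> LedgerFixture:
    """Random EDA ledger whose identities all close exactly at noise 0.

    ``targets``, when given, pins (dE_T, dE_int); the remaining components
    are drawn around them. The emitted complex summary carries the SCF
    iteration endpoints and NKVJ/kinetic deltas so the ledger operations
    re-derive every term from raw energies. ``spec.ledger_noise`` > 0
    perturbs the stored ledger components (not the raw energies), breaking
    closure by about that many kcal/mol.
    """
    rng = np.random.default_rng(spec.seed)
    if targets is not None:
        e_t, e_int = targets
    else:
        e_int = float(rng.uniform(-40.0, -15.0))
        e_t = e_int + float(rng.uniform(0.5, 12.0))  # prep cost is positive
    e_prep = e_t - e_int
    bsse = float(rng.uniform(0.5, 3.0))
    e_elect = float(rng.uniform(-70.0, -10.0))
    e_oi = float(rng.uniform(-35.0, -5.0))
    e_pauli = e_int - e_elect - e_oi - bsse
    # raw energies the ledger operations consume
    e_frag_a = float(rng.uniform(-900.0, -400.0))
    e_frag_b = float(rng.uniform(-900.0, -400.0))
    e_complex = e_frag_a + e_frag_b + e_int
    scf_first = float(rng.uniform(-1200.0, -800.0))
    scf_last = scf_first + e_oi
    e_kinetic = float(rng.uniform(-50.0, 50.0))
    e_nkvj = e_elect + e_kinetic
    # thermochemistry consistent with a complexation at 298.15 K
    h_a = float(rng.uniform(-600.0, -200.0))
    h_b = float(rng.uniform(-600.0, -200.0))
    s_a = float(rng.uniform(80.0, 140.0))
    s_b = float(rng.uniform(80.0, 140.0))
    delta_h = float(rng.uniform(-45.0, -15.0))
    delta_s = float(rng.uniform(-80.0, -40.0))

    components = {
        "e_elect": e_elect,
        "e_oi": e_oi,
        "e_pauli": e_pauli,
        "e_int": e_int,
        "e_t": e_t,
        "e_prep": e_prep,
        "bsse": bsse,
    }
    if spec.ledger_noise > 0:
        for key in components:
            components[key] += float(rng.normal(0.0, spec.ledger_noise))
    record = EDARecord(complex_name=f"synthetic-{spec.seed}", **components)

    complex_summary = QCSummary(
        species=record.complex_name,
        electronic_energy=e_complex,
        enthalpy=h_a + h_b + delta_h,
        entropy=s_a + s_b + delta_s,
        scf_first=scf_first,
        scf_last=scf_last,
        e_nkvj=e_nkvj,
        e_kinetic=e_kinetic,
        bsse=bsse,
    )
    frag_summaries = (
        QCSummary(
            species=f"{record.complex_name}-fragment-A",
            electronic_energy=e_frag_a,
            enthalpy=h_a,
            entropy=s_a,
        ),
        QCSummary(
            species=f"{record.complex_name}-fragment-B",
            electronic_energy=e_frag_b,
            enthalpy=h_b,
            entropy=s_b,
        ),
    )
    return LedgerFixture(
        record=record,
        complex_summary=complex_summary,
        fragment_summaries=frag_summaries,
    )


# --- planted hydrogen-bond scenes --------------------------------------------

_UNIT_SPACING = 8.0  # angstrom between planted contact units
_OH_BOND = 0.96  # angstrom, donor O-H covalent distance


def make_hbond_scene(
    n_contacts: int,
    cutoff: float = 3.0,
    seed: int = 0,
    n_decoys: int = 2,
) -> ComplexGeometry:
    """A dimer with exactly ``n_contacts`` planted H...O contacts under ``cutoff``.

    Each contact unit is an O-H donor on fragment A aimed at an O acceptor
    on fragment B at a distance drawn from [1.8, cutoff - 0.2]; decoy
    acceptors sit at >= cutoff + 0.5 from every hydrogen. Units are spaced
    far enough apart that no cross-unit pair comes under the cutoff.
    """
    if n_contacts < 0:
        raise GenerationError("n_contacts must be >= 0")
    if cutoff <= 2.0:
        raise GenerationError("cutoff too tight to place contacts in [1.8, cutoff - 0.2]")
    rng = np.random.default_rng(seed)
    atoms_a: list[Atom] = []
    atoms_b: list[Atom] = []
    for i in range(n_contacts):
        x0 = i * _UNIT_SPACING
        d = float(rng.uniform(1.8, cutoff - 0.2))
        atoms_a.append(Atom("O", len(atoms_a) + 1, (x0, 0.0, 0.0)))
        atoms_a.append(Atom("H", len(atoms_a) + 1, (x0 + _OH_BOND, 0.0, 0.0)))
        atoms_b.append(Atom("O", len(atoms_b) + 1, (x0 + _OH_BOND + d, 0.0, 0.0)))
    # decoy acceptors: same lattice, but displaced past the detection shell
    for j in range(n_decoys):
        x0 = (n_contacts + j) * _UNIT_SPACING
        atoms_b.append(
            Atom("O", len(atoms_b) + 1, (x0 + _OH_BOND + cutoff + 0.5 + j, 0.0, 0.0))
        )
    # anchor carbons so neither fragment can be empty (n_contacts = 0 case)
    atoms_a.append(
        Atom("C", len(atoms_a) + 1, ((n_contacts + n_decoys + 2) * _UNIT_SPACING, 0.0, 0.0))
    )
    atoms_b.append(
        Atom("C", len(atoms_b) + 1, ((n_contacts + n_decoys + 3) * _UNIT_SPACING, 0.0, 0.0))
    )
    frag_a = Fragment(name="donors", atoms=tuple(atoms_a), role="pharmaceutical")
    frag_b = Fragment(name="acceptors", atoms=tuple(atoms_b), role="absorbent")
    return ComplexGeometry.assemble(f"hbond-scene-{seed}", frag_a, frag_b)
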