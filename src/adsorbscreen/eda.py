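"""Energy decomposition analysis (EDA) bookkeeping and closure validation.

The ledger ties together two identities:

    dE_T   = dE_int + dE_prep                       (total / preparation)
    dE_int = dE_elect + dE_oi + dE_Pauli + BSSE     (decomposition)

with the electrostatic term obtainable through two redundant routes

    dE_elect = dE_V + dE_J + dE_Nuc = dE_NKVJ - dE_K

and the orbital term from the SCF iteration endpoints of the
fragment-guess single point

    dE_oi = E_SCF,last - E_SCF,1st.

Validation runs at two tolerance tiers: a machine tier (default 1e-6
kcal/mol) for ledgers assembled from raw energies, and a looser tier
(default 0.35 kcal/mol) for published tables whose entries were rounded
to 0.01 before printing. BSSE is never imputed: without it the
decomposition identity is reported as not checkable rather than checked
against a guessed zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import InconsistencyError, MissingInputError

__all__ = [
    "EDARecord",
    "LedgerCheck",
    "LedgerReport",
    "TOL_STRICT",
    "TOL_PUBLISHED",
    "interaction_energy",
    "electrostatic_term",
    "orbital_term",
    "pauli_remainder",
    "prep_energy",
    "validate_ledger",
]

TOL_STRICT = 1e-6  # kcal/mol, self-assembled ledgers
TOL_PUBLISHED = 0.35  # kcal/mol, tables rounded to 0.01 at print time
_ROUTE_TOL = 1e-6  # kcal/mol, agreement of redundant electrostatic routes


@dataclass(frozen=True)
class EDARecord:
    """One complex's EDA ledger (kcal/mol throughout). BSSE optional."""

    complex_name: str
    e_elect: float
    e_oi: float
    e_pauli: float
    e_int: float
    e_t: float
    e_prep: float
    bsse: Optional[float] = None


def interaction_energy(e_complex: float, fragment_energies: Sequence[float]) -> float:
    """dE_int = E_complex - sum of fragment energies (fragments in their
    in-complex conformations)."""
    fragment_energies = list(fragment_energies)
    if not fragment_energies:
        raise MissingInputError("interaction_energy requires at least one fragment energy")
    return e_complex - sum(fragment_energies)


def electrostatic_term(
    e_nkvj_delta: Optional[float] = None,
    e_kinetic_delta: Optional[float] = None,
    component_sum: Optional[float] = None,
    tolerance: float = _ROUTE_TOL,
) -> float:
    """dE_elect via dE_NKVJ - dE_K and/or the dE_V + dE_J + dE_Nuc component sum.

    Either route may be supplied alone; when both are present they must
    agree within ``tolerance`` or an :class:`InconsistencyError` is raised.
    """
    nkvj_route: Optional[float] = None
    if e_nkvj_delta is not None or e_kinetic_delta is not None:
        if e_nkvj_delta is None or e_kinetic_delta is None:
            raise MissingInputError("NKVJ route needs both e_nkvj_delta and e_kinetic_delta")
        if not (math.isfinite(e_nkvj_delta) and math.isfinite(e_kinetic_delta)):
            raise MissingInputError("non-finite NKVJ-route input")
        nkvj_route = e_nkvj_delta - e_kinetic_delta
    if nkvj_route is None and component_sum is None:
        raise MissingInputError("electrostatic_term requires at least one input route")
    if nkvj_route is not None and component_sum is not None:
        if abs(nkvj_route - component_sum) > tolerance:
            raise InconsistencyError(
                f"electrostatic routes disagree: NKVJ-K gives {nkvj_route:.6f}, "
                f"V+J+Nuc gives {component_sum:.6f} (tolerance {tolerance})"
            )
    return nkvj_route if nkvj_route is not None else component_sum  # type: ignore[return-value]


@dataclass(frozen=True)
class OrbitalTerm:
    """dE_oi with a warning flag for a (suspicious) positive value."""

    value: float
    warned: bool


def orbital_term(scf_first: Optional[float], scf_last: Optional[float]) -> OrbitalTerm:
    """dE_oi = E_SCF,last - E_SCF,1st from the fragment-guess single point.

    A positive value is flagged (converged SCF should not raise the
    energy) but not rejected.
    """
    if scf_first is None or scf_last is None:
        raise MissingInputError("orbital_term requires both SCF iteration energies")
    value = scf_last - scf_first
    return OrbitalTerm(value=value, warned=value > 0)


def pauli_remainder(record: EDARecord) -> float:
    """dE_Pauli closing the decomposition: dE_int - dE_elect - dE_oi - BSSE."""
    if record.bsse is None:
        raise MissingInputError(
            f"{record.complex_name}: BSSE required to close the decomposition "
            "(never imputed)"
        )
    return record.e_int - record.e_elect - record.e_oi - record.bsse


def prep_energy(e_t: float, e_int: float) -> float:
    """dE_prep = dE_T - dE_int (monomer-distortion cost)."""
    return e_t - e_int


@dataclass(frozen=True)
class LedgerCheck:
    """One identity's residual against both tolerance tiers."""

    identity: str
    residual: Optional[float]
    checkable: bool
    passes_strict: Optional[bool]
    passes_published: Optional[bool]


@dataclass(frozen=True)
class LedgerReport:
    complex_name: str
    checks: tuple[LedgerCheck, ...]
    tol_strict: float
    tol_published: float

    @property
    def all_strict(self) -> bool:
        return all(c.passes_strict for c in self.checks if c.checkable)

    @property
    def all_published(self) -> bool:
        return all(c.passes_published for c in self.checks if c.checkable)

    def check(self, identity: str) -> LedgerCheck:
        for c in self.checks:
            if c.identity == identity:
                return c
        raise KeyError(identity)


def validate_ledger(
    record: EDARecord,
    tol_strict: float = TOL_STRICT,
    tol_published: float = TOL_PUBLISHED,
) -> LedgerReport:
    """Check both closure identities; failures are report entries, not errors.

    The decomposition identity is only checkable when BSSE is present.
    """
    checks = []
    res_total = abs(record.e_int + record.e_prep - record.e_t)
    checks.append(
        LedgerCheck(
            identity="total_vs_prep",
            residual=res_total,
            checkable=True,
            passes_strict=res_total <= tol_strict,
            passes_published=res_total <= tol_published,
        )
    )
    if record.bsse is not None:
        res_decomp = abs(
            record.e_elect + record.e_oi + record.e_pauli + record.bsse - record.e_int
        )
        checks.append(
            LedgerCheck(
                identity="decomposition",
                residual=res_decomp,
                checkable=True,
                passes_strict=res_decomp <= tol_strict,
                passes_published=res_decomp <= tol_published,
            )
        )
    else:
        checks.append(
            LedgerCheck(
                identity="decomposition",
                residual=None,
                checkable=False,
                passes_strict=None,
                passes_published=None,
            )
        )
    return LedgerReport(
        complex_name=record.complex_name,
        checks=tuple(checks),
        tol_strict=tol_strict,
        tol_published=tol_published,
    )
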