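"""Conceptual-DFT reactivity descriptors from frontier-orbital energies.

Under the Koopmans mapping IP = -E(HOMO), AE = -E(LUMO), the global
descriptors are

    mu  = -(IP + AE) / 2   (electronic chemical potential; equivalently the
                            HOMO-LUMO gap midpoint, (HOMO + LUMO)/2)
    eta =  (IP - AE) / 2   (global hardness; half the HOMO-LUMO gap)

both in kcal/mol here. The inter-fragment electron flux is computed, by
default, exactly as the source methodology writes it,

    dN = (mu_B - mu_A) / (eta_A - eta_B),

an unconventional denominator (the Parr-Pearson convention divides by
eta_A + eta_B, optionally with a factor 2). The conventional form is
available as an alternative mode but is never the default; a negative dN
is read as spontaneous electron flow from species A to species B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import DegeneracyError, ValidationError

__all__ = [
    "ReactivityDescriptors",
    "ElectronFlux",
    "descriptors_from_frontier",
    "electron_flux",
]


@dataclass(frozen=True)
class ReactivityDescriptors:
    """IP, AE, mu and eta for one species or complex (kcal/mol)."""

    species: str
    ip: float
    ae: float
    mu: float
    eta: float

    def __post_init__(self) -> None:
        if abs(self.mu + (self.ip + self.ae) / 2.0) > 1e-9:
            raise ValidationError(f"{self.species}: mu inconsistent with -(IP+AE)/2")
        if abs(self.eta - (self.ip - self.ae) / 2.0) > 1e-9:
            raise ValidationError(f"{self.species}: eta inconsistent with (IP-AE)/2")


def descriptors_from_frontier(
    homo: float,
    lumo: float,
    species: str = "",
) -> ReactivityDescriptors:
    """Descriptors from HOMO/LUMO energies (kcal/mol) via the Koopmans mapping.

    Requires HOMO < LUMO; hardness is then strictly positive.
    """
    if homo >= lumo:
        raise ValidationError(f"HOMO ({homo}) must lie below LUMO ({lumo})")
    ip = -homo
    ae = -lumo
    return ReactivityDescriptors(
        species=species,
        ip=ip,
        ae=ae,
        mu=-(ip + ae) / 2.0,
        eta=(ip - ae) / 2.0,
    )


@dataclass(frozen=True)
class ElectronFlux:
    """dN with its sign interpretation attached."""

    value: float
    mode: str
    #: 'A->B' when electrons flow from A to B, 'B->A' otherwise, 'none' at 0
    direction: str


def electron_flux(
    mu_a: float,
    mu_b: float,
    eta_a: float,
    eta_b: float,
    mode: Literal["as_published", "conventional"] = "as_published",
) -> ElectronFlux:
    """Electron flux dN between species A and B from their mu and eta.

    ``as_published`` (default): dN = (mu_B - mu_A)/(eta_A - eta_B); raises
    :class:`DegeneracyError` when eta_A = eta_B.
    ``conventional``: Parr-Pearson dN = (mu_B - mu_A)/(2 (eta_A + eta_B)).

    Negative dN means spontaneous electron flow from A to B.
    """
    if mode == "as_published":
        if eta_a == eta_b:
            raise DegeneracyError(
                "electron flux undefined for equal hardness (eta_A = eta_B) "
                "in as_published mode"
            )
        value = (mu_b - mu_a) / (eta_a - eta_b)
    elif mode == "conventional":
        if eta_a + eta_b == 0:
            raise DegeneracyError("eta_A + eta_B = 0 in conventional mode")
        value = (mu_b - mu_a) / (2.0 * (eta_a + eta_b))
    else:
        raise ValueError(f"unknown electron-flux mode {mode!r}")
    if value < 0:
        direction = "A->B"
    elif value > 0:
        direction = "B->A"
    else:
        direction = "none"
    return ElectronFlux(value=value, mode=mode, direction=direction)
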