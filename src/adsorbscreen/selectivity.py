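"""Selectivity predictor: how many molecules of pollutant A adsorb per
molecule of pollutant B on the same absorbent.

The predictor reads the Gibbs-energy quotient as a log-ratio of
equilibrium constants and reports

    ratio(A over B) = exp(dG_A / dG_B),

defined only between spontaneous adsorptions (dG_A, dG_B < 0). This
operationalization is reverse-engineered from the worked example set it
must reproduce (66:1, ~10:1, ~24:1); the printed relation
"dG_A/dG_B = Ln(Ke1/Ke2)" is dimensionally irregular as written, and
exp(dG_A/dG_B) is the unique reading consistent with all three examples.
Two formula artifacts worth knowing:

* equal affinities give ratio e (not 1);
* ratio(A,B) * ratio(B,A) = exp(x + 1/x) for x = dG_A/dG_B, generally != 1.

A pair whose rounded ratio is at most 2 is flagged "no selectivity".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .errors import DomainError
from .thermo import ComplexThermo

__all__ = [
    "NO_SELECTIVITY_MAX",
    "SelectivityResult",
    "selectivity_ratio",
    "rounded_ratio",
    "selectivity_matrix",
    "split_complex_label",
]

#: rounded ratios up to this value are flagged as showing no selectivity
NO_SELECTIVITY_MAX = 2


def selectivity_ratio(dg_a: float, dg_b: float) -> float:
    """exp(dG_A / dG_B): molecules of A per molecule of B on one absorbent.

    Both Gibbs energies must be negative (spontaneous adsorption).
    """
    if dg_a >= 0 or dg_b >= 0:
        raise DomainError(
            "selectivity defined only between spontaneous adsorptions "
            f"(got dG_A={dg_a}, dG_B={dg_b})"
        )
    return math.exp(dg_a / dg_b)


def rounded_ratio(ratio: float) -> int:
    """Round half away from zero (65.5 -> 66, 9.5 -> 10)."""
    return int(math.floor(ratio + 0.5)) if ratio >= 0 else -int(math.floor(-ratio + 0.5))


@dataclass(frozen=True)
class SelectivityResult:
    """One ordered pollutant pair on one absorbent."""

    pollutant_a: str
    pollutant_b: str
    absorbent: str
    ratio: float
    dg_a: float
    dg_b: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if abs(self.ratio - math.exp(self.dg_a / self.dg_b)) > 1e-9 * self.ratio:
            raise ValueError(
                f"{self.pollutant_a}/{self.pollutant_b} on {self.absorbent}: "
                "stored ratio inconsistent with exp(dG_A/dG_B)"
            )

    @property
    def rounded(self) -> int:
        return rounded_ratio(self.ratio)

    @property
    def no_selectivity(self) -> bool:
        return self.rounded <= NO_SELECTIVITY_MAX


def split_complex_label(label: str) -> tuple[str, str]:
    """Split 'POLLUTANT-ABSORBENT' on the first hyphen.

    'AMOX-GO-1' -> ('AMOX', 'GO-1'); 'Tetracycline-CS' -> ('Tetracycline', 'CS').
    """
    if "-" not in label:
        raise ValueError(f"cannot split complex label {label!r} into pollutant-absorbent")
    pollutant, absorbent = label.split("-", 1)
    return pollutant, absorbent


def selectivity_matrix(records: Iterable[ComplexThermo]) -> list[SelectivityResult]:
    """All ordered pollutant pairs per absorbent, from complexation records.

    Complex labels are split into (pollutant, absorbent) on the first
    hyphen; absorbents with a single pollutant contribute nothing.
    Records with non-negative dG are skipped (selectivity undefined there).
    """
    by_absorbent: dict[str, list[tuple[str, float]]] = {}
    for rec in records:
        pollutant, absorbent = split_complex_label(rec.complex_name)
        by_absorbent.setdefault(absorbent, []).append((pollutant, rec.delta_g))
    results: list[SelectivityResult] = []
    for absorbent, entries in by_absorbent.items():
        spontaneous = [(p, dg) for p, dg in entries if dg < 0]
        for p_a, dg_a in spontaneous:
            for p_b, dg_b in spontaneous:
                if p_a == p_b:
                    continue
                results.append(
                    SelectivityResult(
                        pollutant_a=p_a,
                        pollutant_b=p_b,
                        absorbent=absorbent,
                        ratio=selectivity_ratio(dg_a, dg_b),
                        dg_a=dg_a,
                        dg_b=dg_b,
                    )
                )
    return results
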