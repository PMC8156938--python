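"""Packaged reference dataset: published DFT complexation tables.

The package ships, as plain TSV fixtures, the published reference tables
for the six pharmaceutical/absorbent complexes (and nine further
tetracycline-family complexes in the thermodynamic table):

* ``complexation_thermo.tsv``   dH, dS, dG, dE_T per complex
* ``frontier_descriptors.tsv``  HOMO, LUMO, mu, eta, dN per complex
* ``eda_components.tsv``        dE_elect, dE_oi, dE_Pauli, dE_int, dE_T, dE_prep
* ``nbo_interactions.tsv``      donor, acceptor, E(2) magnitude (88 rows)

Files are stored as data, not embedded in code, so they can be audited
against the source; each load verifies a sha256 checksum. Units are the
package's canonical ones (kcal/mol; entropies cal/(mol K)).

Note the published dN row cannot be re-derived from the same table: dN
needs the per-species mu/eta of the two partners, while the table prints
complex-level descriptors only. It is carried for reference, not
recomputed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

from .eda import EDARecord
from .errors import PackagingError
from .model import NBORow, parse_orbital
from .thermo import ComplexThermo

__all__ = [
    "ReferenceTables",
    "load_reference_tables",
    "thermo_records",
    "eda_records",
    "nbo_rows",
    "COMPLEXES",
]

#: the six pharmaceutical complexes, in published adsorption-strength order
COMPLEXES = ("AMOX-CS", "AMOX-GO-1", "AMOX-GO-2", "IBU-CS", "IBU-GO-2", "IBU-GO-1")

_DATA_PACKAGE = "adsorbscreen.data"


def _read_packaged(name: str, checksums: dict[str, str]) -> pd.DataFrame:
    ref = resources.files(_DATA_PACKAGE).joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != checksums[name]:
        raise PackagingError(
            f"{name}: checksum mismatch (got {digest[:12]}..., "
            f"expected {checksums[name][:12]}...); packaged data corrupted"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")


@dataclass(frozen=True)
class ReferenceTables:
    """The four reference tables as DataFrames."""

    thermo: pd.DataFrame
    descriptors: pd.DataFrame
    eda: pd.DataFrame
    nbo: pd.DataFrame


def load_reference_tables() -> ReferenceTables:
    """Load and checksum-verify all packaged reference tables."""
    checksums = json.loads(
        resources.files(_DATA_PACKAGE).joinpath("checksums.json").read_text()
    )
    return ReferenceTables(
        thermo=_read_packaged("complexation_thermo.tsv", checksums),
        descriptors=_read_packaged("frontier_descriptors.tsv", checksums),
        eda=_read_packaged("eda_components.tsv", checksums),
        nbo=_read_packaged("nbo_interactions.tsv", checksums),
    )


def thermo_records(tables: Optional[ReferenceTables] = None) -> list[ComplexThermo]:
    """The thermodynamic table as typed records (dG closure re-validated on load)."""
    tables = tables or load_reference_tables()
    return [
        ComplexThermo(
            complex_name=row["complex"],
            delta_h=row["delta_h"],
            delta_s=row["delta_s"],
            delta_g=row["delta_g"],
            delta_e_t=row["delta_e_t"],
        )
        for _, row in tables.thermo.iterrows()
    ]


def eda_records(tables: Optional[ReferenceTables] = None) -> list[EDARecord]:
    """The EDA table as typed ledgers (no BSSE column is published)."""
    tables = tables or load_reference_tables()
    return [
        EDARecord(
            complex_name=row["complex"],
            e_elect=row["e_elect"],
            e_oi=row["e_oi"],
            e_pauli=row["e_pauli"],
            e_int=row["e_int"],
            e_t=row["e_t"],
            e_prep=row["e_prep"],
            bsse=None,
        )
        for _, row in tables.eda.iterrows()
    ]


def nbo_rows(tables: Optional[ReferenceTables] = None) -> dict[str, list[NBORow]]:
    """Published NBO rows grouped by complex, descriptors parsed."""
    tables = tables or load_reference_tables()
    grouped: dict[str, list[NBORow]] = {}
    for _, row in tables.nbo.iterrows():
        grouped.setdefault(row["complex"], []).append(
            NBORow(
                donor=parse_orbital(row["donor"]),
                acceptor=parse_orbital(row["acceptor"]),
                e2=float(row["e2"]),
            )
        )
    return grouped
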