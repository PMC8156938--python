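"""End-to-end orchestration: thermodynamics -> descriptors -> NBO -> EDA ->
selectivity -> ranking, with per-complex fail-soft error handling and a
provenance block.

The pipeline runs over a :class:`~adsorbscreen.reference.ReferenceTables`
bundle (the packaged reference dataset by default, or any bundle with the
same shape, e.g. synthetic ones). Every threshold a stage consumes lives
in :class:`RunConfig` with its documented default, and the report records
each one, so two runs with identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cdft import descriptors_from_frontier
from .eda import TOL_PUBLISHED, TOL_STRICT, validate_ledger
from .errors import AdsorbScreenError
from .nbo import (
    DEFAULT_E2_CUTOFF,
    DEFAULT_HBOND_CUTOFF,
    apply_cutoff,
    classify_interaction,
)
from .reference import ReferenceTables, eda_records, load_reference_tables, thermo_records
from .selectivity import selectivity_matrix
from .thermo import (
    DEFAULT_PHYSISORPTION_THRESHOLD,
    STANDARD_TEMPERATURE,
    classify_process,
    gibbs_energy,
    rank_complexes,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "render_report"]

logger = logging.getLogger("adsorbscreen")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline settings, with published-methodology defaults."""

    temperature: float = STANDARD_TEMPERATURE  # K
    combining_rule: str = "plain_sum"
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF  # angstrom
    nbo_cutoff: float = DEFAULT_E2_CUTOFF  # kcal/mol
    physisorption_threshold: float = DEFAULT_PHYSISORPTION_THRESHOLD  # kcal/mol
    tol_strict: float = TOL_STRICT  # kcal/mol
    tol_published: float = TOL_PUBLISHED  # kcal/mol
    ranking_key: str = "delta_g"
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("temperature", "hbond_cutoff", "physisorption_threshold"):
            if getattr(self, name) <= 0:
                raise AdsorbScreenError(f"config field {name} must be > 0")
        if self.nbo_cutoff < 0:
            raise AdsorbScreenError("config field nbo_cutoff must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise AdsorbScreenError(f"unknown config keys: {sorted(unknown)}")
        defaults = cls()
        for name in sorted(known - set(raw)):
            logger.info("config: %s defaulted to %r", name, getattr(defaults, name))
        return cls(**raw)


@dataclass(frozen=True)
class ReportBundle:
    """Per-stage tables plus run provenance."""

    thermo: pd.DataFrame  # recomputed dG, rank, physisorption verdict
    descriptors: pd.DataFrame  # recomputed mu/eta per complex
    nbo_summary: pd.DataFrame  # per complex x category E(2) aggregates
    ledger: pd.DataFrame  # per-identity closure residuals
    selectivity: pd.DataFrame  # ordered pollutant pairs per absorbent
    ranking: tuple[str, ...]
    errors: dict[str, str]
    provenance: dict[str, object]


def _thermo_stage(tables: ReferenceTables, config: RunConfig, errors: dict[str, str]):
    records = thermo_records(tables)
    eda_by_name = {r.complex_name: r for r in eda_records(tables)}
    rows = []
    for rec in records:
        row = {
            "complex": rec.complex_name,
            "delta_h": rec.delta_h,
            "delta_s": rec.delta_s,
            "delta_g": rec.delta_g,
            "delta_g_recomputed": gibbs_energy(rec.delta_h, rec.delta_s, config.temperature),
            "delta_e_t": rec.delta_e_t,
        }
        eda = eda_by_name.get(rec.complex_name)
        if eda is not None:
            verdict = classify_process(eda.e_int, config.physisorption_threshold)
            row["process"] = verdict.category
            row["process_threshold"] = verdict.threshold
        else:
            row["process"] = "not computed"
            row["process_threshold"] = config.physisorption_threshold
        rows.append(row)
    ranking = tuple(rank_complexes(records, key=config.ranking_key))  # type: ignore[arg-type]
    frame = pd.DataFrame(rows)
    frame["rank"] = frame["complex"].map({name: i + 1 for i, name in enumerate(ranking)})
    return records, frame, ranking


def _descriptor_stage(tables: ReferenceTables, errors: dict[str, str]) -> pd.DataFrame:
    rows = []
    for _, row in tables.descriptors.iterrows():
        name = row["complex"]
        try:
            desc = descriptors_from_frontier(row["homo"], row["lumo"], species=name)
            rows.append(
                {
                    "complex": name,
                    "homo": row["homo"],
                    "lumo": row["lumo"],
                    "mu": desc.mu,
                    "eta": desc.eta,
                    "ip": desc.ip,
                    "ae": desc.ae,
                }
            )
        except AdsorbScreenError as exc:
            errors[f"descriptors:{name}"] = str(exc)
    return pd.DataFrame(rows)


def _nbo_stage(tables: ReferenceTables, config: RunConfig, errors: dict[str, str]) -> pd.DataFrame:
    from .model import NBORow, parse_orbital

    rows = []
    for name, group in tables.nbo.groupby("complex", sort=False):
        try:  # fail soft per complex: one bad file must not kill the batch
            classified = [
                classify_interaction(
                    NBORow(
                        donor=parse_orbital(r["donor"]),
                        acceptor=parse_orbital(r["acceptor"]),
                        e2=float(r["e2"]),
                    )
                )
                for _, r in group.iterrows()
            ]
        except AdsorbScreenError as exc:
            errors[f"nbo:{name}"] = str(exc)
            continue
        result = apply_cutoff(classified, cutoff=config.nbo_cutoff)
        frame = pd.DataFrame(
            {
                "category": [c.category for c in result.retained],
                "e2": [c.e2_magnitude for c in result.retained],
            }
        )
        agg = frame.groupby("category")["e2"].agg(["count", "sum"]) if len(frame) else None
        for category in ("hydrogen_bond", "dipolar", "pi_pi", "sigma_pi", "dispersion", "other"):
            count = int(agg.loc[category, "count"]) if agg is not None and category in agg.index else 0
            total = float(agg.loc[category, "sum"]) if agg is not None and category in agg.index else 0.0
            rows.append(
                {
                    "complex": name,
                    "category": category,
                    "n_interactions": count,
                    "e2_sum": total,
                    "cutoff": result.cutoff,
                    "n_below_cutoff": len(result.discarded),
                }
            )
    return pd.DataFrame(rows)


def _ledger_stage(tables: ReferenceTables, config: RunConfig, errors: dict[str, str]) -> pd.DataFrame:
    rows = []
    for record in eda_records(tables):
        report = validate_ledger(record, tol_strict=config.tol_strict, tol_published=config.tol_published)
        for check in report.checks:
            rows.append(
                {
                    "complex": record.complex_name,
                    "identity": check.identity,
                    "residual": check.residual,
                    "checkable": check.checkable,
                    "passes_strict": check.passes_strict,
                    "passes_published": check.passes_published,
                }
            )
    return pd.DataFrame(rows)


def _selectivity_stage(records, errors: dict[str, str]) -> pd.DataFrame:
    try:
        results = selectivity_matrix(records)
    except AdsorbScreenError as exc:
        errors["selectivity"] = str(exc)
        return pd.DataFrame()
    return pd.DataFrame(
        [
            {
                "absorbent": r.absorbent,
                "pollutant_a": r.pollutant_a,
                "pollutant_b": r.pollutant_b,
                "dg_a": r.dg_a,
                "dg_b": r.dg_b,
                "ratio": r.ratio,
                "rounded": r.rounded,
                "no_selectivity": r.no_selectivity,
            }
            for r in results
        ]
    )


def run_pipeline(
    config: RunConfig = RunConfig(),
    tables: Optional[ReferenceTables] = None,
) -> ReportBundle:
    """Run every stage over a table bundle (packaged reference data by default).

    Stage failures are collected per complex in ``bundle.errors`` without
    aborting the remaining stages.
    """
    tables = tables or load_reference_tables()
    errors: dict[str, str] = {}
    records, thermo_frame, ranking = _thermo_stage(tables, config, errors)
    bundle = ReportBundle(
        thermo=thermo_frame,
        descriptors=_descriptor_stage(tables, errors),
        nbo_summary=_nbo_stage(tables, config, errors),
        ledger=_ledger_stage(tables, config, errors),
        selectivity=_selectivity_stage(records, errors),
        ranking=ranking,
        errors=errors,
        provenance={
            "package_version": _pkg_version,
            "config": dataclasses.asdict(config),
        },
    )
    for key, message in errors.items():
        logger.warning("stage failure %s: %s", key, message)
    return bundle


_TABLE_FILES = {
    "thermo": "thermo.tsv",
    "descriptors": "descriptors.tsv",
    "nbo_summary": "nbo_summary.tsv",
    "ledger": "ledger.tsv",
    "selectivity": "selectivity.tsv",
}


def render_report(bundle: ReportBundle, output_dir: str | Path, fmt: str = "delimited") -> list[Path]:
    """Write the bundle as TSV tables plus a human-readable summary.

    ``fmt='delimited'`` writes both; ``fmt='text'`` writes the summary only.
    Delimited tables round-trip through ``pandas.read_csv(..., sep='\\t')``.
    """
    if fmt not in ("text", "delimited"):
        raise AdsorbScreenError(f"unknown report format {fmt!r}")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "delimited":
        for attr, filename in _TABLE_FILES.items():
            frame: pd.DataFrame = getattr(bundle, attr)
            path = output_dir / filename
            if frame.empty:
                path.write_text("# not computed\n")
            else:
                frame.to_csv(path, sep="\t", index=False)
            written.append(path)
    summary = output_dir / "summary.txt"
    with open(summary, "w") as fh:
        fh.write("adsorbscreen pipeline report\n")
        fh.write("============================\n\n")
        fh.write("Provenance:\n")
        for key, value in bundle.provenance.items():
            fh.write(f"  {key}: {value}\n")
        fh.write("\nAdsorption ranking (strongest first, by "
                 f"{bundle.provenance['config']['ranking_key']}):\n")
        if bundle.ranking:
            for i, name in enumerate(bundle.ranking, 1):
                fh.write(f"  {i}. {name}\n")
        else:
            fh.write("  not computed\n")
        fh.write("\nStage errors:\n")
        if bundle.errors:
            for key, msg in bundle.errors.items():
                fh.write(f"  {key}: {msg}\n")
        else:
            fh.write("  none\n")
    written.append(summary)
    return written
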