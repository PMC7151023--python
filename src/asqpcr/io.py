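"""Tidy CSV formats and run configuration.

The Cq export dialect is one row per (sample, reaction, target)
measurement:

    sample_id,specimen,reaction,target,cq

with ``reaction`` in {wt, mut}, ``target`` in {allele, reference} and
``cq`` either a decimal number or one of the no-amplification sentinels
"Undetermined" (case-insensitive), "NA", "".  A quantifiable sample
contributes exactly four rows; the two reference rows may be omitted
when only the simple formula is wanted.  Instrument-specific exports
are expected to be pre-mapped to this schema.

Result files are CSV with ``#``-prefixed metadata comment lines
(schema version, package version, seed, config hash) so a run can be
identified after the fact.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .core import (
    UNDETERMINED,
    CqValue,
    MutantFractionResult,
    QcPolicy,
    ReactionPairRecord,
    Specimen,
    format_percent,
    is_undetermined,
    parse_cq,
)

__all__ = [
    "CqExportError",
    "read_cq_export",
    "write_cq_export",
    "write_results",
    "read_results",
    "write_lod_report",
    "RunConfig",
]

SCHEMA_VERSION = 1

_REQUIRED_COLUMNS = ("sample_id", "specimen", "reaction", "target", "cq")
_REACTIONS = ("wt", "mut")
_TARGETS = ("allele", "reference")


class CqExportError(ValueError):
    """A Cq export violated the schema; the message carries per-row
    diagnostics with file line numbers."""


def read_cq_export(path) -> list[ReactionPairRecord]:
    """Read a tidy Cq export CSV into reaction-pair records.

    Rows are grouped by sample in first-appearance order.  Duplicate
    (sample, reaction, target) rows, unknown enum values, unknown Cq
    sentinels and missing allele rows are reported as errors with the
    offending line numbers — never silently dropped.
    """
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CqExportError(f"{path}: missing required column(s) {missing}")

    errors: list[str] = []
    cells: dict[str, dict[tuple[str, str], CqValue]] = {}
    specimens: dict[str, Specimen] = {}
    order: list[str] = []

    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        sample = row["sample_id"].strip()
        if not sample:
            errors.append(f"line {line}: empty sample_id")
            continue
        reaction = row["reaction"].strip().lower()
        target = row["target"].strip().lower()
        if reaction not in _REACTIONS:
            errors.append(f"line {line}: reaction must be one of {_REACTIONS}, got {row['reaction']!r}")
            continue
        if target not in _TARGETS:
            errors.append(f"line {line}: target must be one of {_TARGETS}, got {row['target']!r}")
            continue
        try:
            specimen = Specimen(row["specimen"].strip().lower() or "other")
        except ValueError:
            errors.append(f"line {line}: unknown specimen {row['specimen']!r}")
            continue
        try:
            cq = parse_cq(row["cq"])
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
            continue

        if sample not in cells:
            cells[sample] = {}
            specimens[sample] = specimen
            order.append(sample)
        key = (reaction, target)
        if key in cells[sample]:
            errors.append(
                f"line {line}: duplicate ({sample}, {reaction}, {target}) measurement"
            )
            continue
        cells[sample][key] = cq

    records = []
    for sample in order:
        got = cells[sample]
        for reaction in _REACTIONS:
            if (reaction, "allele") not in got:
                errors.append(f"sample {sample!r}: missing ({reaction}, allele) row")
        if ("wt", "allele") in got and ("mut", "allele") in got:
            records.append(
                ReactionPairRecord(
                    sample_id=sample,
                    specimen=specimens[sample],
                    cq_wt=got[("wt", "allele")],
                    cq_mut=got[("mut", "allele")],
                    cq_rp_wt=got.get(("wt", "reference"), UNDETERMINED),
                    cq_rp_mut=got.get(("mut", "reference"), UNDETERMINED),
                )
            )

    if errors:
        raise CqExportError(f"{path}: " + "; ".join(errors))
    return records


def _cq_field(cq: CqValue) -> str:
    return "Undetermined" if is_undetermined(cq) else f"{float(cq):.4f}"


def write_cq_export(records: Sequence[ReactionPairRecord], path) -> None:
    """Write reaction-pair records in the tidy export dialect."""
    rows = []
    for r in records:
        for reaction, allele_cq, ref_cq in (
            ("wt", r.cq_wt, r.cq_rp_wt),
            ("mut", r.cq_mut, r.cq_rp_mut),
        ):
            rows.append((r.sample_id, r.specimen.value, reaction, "allele", _cq_field(allele_cq)))
            rows.append((r.sample_id, r.specimen.value, reaction, "reference", _cq_field(ref_cq)))
    df = pd.DataFrame(rows, columns=_REQUIRED_COLUMNS)
    df.to_csv(path, index=False)


def _metadata_lines(seed=None, config_hash=None) -> list[str]:
    lines = [f"# asqpcr {__version__} schema_version={SCHEMA_VERSION}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config_hash is not None:
        lines.append(f"# config_hash={config_hash}")
    return lines


_RESULT_COLUMNS = (
    "sample_id",
    "specimen",
    "formula",
    "delta_cq",
    "delta_delta_cq",
    "percent",
    "status",
    "warnings",
)


def write_results(
    results: Sequence[MutantFractionResult],
    path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write classification results with stable column order and a
    metadata comment header."""
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "specimen": r.specimen.value,
                "formula": r.formula,
                "delta_cq": "" if r.delta_cq is None else f"{r.delta_cq:.4f}",
                "delta_delta_cq": "" if r.delta_delta_cq is None else f"{r.delta_delta_cq:.4f}",
                "percent": "" if r.percent is None else format_percent(r.percent),
                "status": r.status.value,
                "warnings": " | ".join(r.warnings),
            }
        )
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    buf = _io.StringIO()
    for line in _metadata_lines(seed, config_hash):
        buf.write(line + "\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_results(path) -> pd.DataFrame:
    """Read a results CSV back (metadata comments skipped)."""
    return pd.read_csv(path, comment="#", keep_default_na=False, dtype=str)


def write_lod_report(fit, table, path, seed=None) -> None:
    """Detection-panel report: the observed counts, fitted detection
    probabilities, and the LOD with its confidence interval."""
    df = table.to_frame()
    df["fitted_probability"] = [round(p, 4) for p in fit.fitted_probabilities]
    buf = _io.StringIO()
    for line in _metadata_lines(seed):
        buf.write(line + "\n")
    buf.write(f"# lod_percent={fit.lod:.4f}\n")
    buf.write(f"# lod_ci_low={fit.lod_ci[0]:.4f} lod_ci_high={fit.lod_ci[1]:.4f}\n")
    buf.write(f"# target_probability={fit.target_probability} dose_scale={fit.dose_scale}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


@dataclass
class RunConfig:
    """Flat run configuration; an empty file reproduces the assay's
    validated defaults (cutoff 42, LOD 0.15%, LOQ 1.16%)."""

    cq_cutoff: float = 42.0
    total_cycles: float = 45.0
    lod_percent: float = 0.15
    loq_percent: float = 1.16
    rp_delta_warn: float = 1.0
    rp_max_cq: float = 30.0
    formula: str = "auto"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def policy(self) -> QcPolicy:
        return QcPolicy(
            cq_cutoff=self.cq_cutoff,
            total_cycles=self.total_cycles,
            lod_percent=self.lod_percent,
            loq_percent=self.loq_percent,
            rp_delta_warn=self.rp_delta_warn,
            rp_max_cq=self.rp_max_cq,
        )

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
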