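"""Aggregation of per-model reports into study-level summary tables.

Produces the summary artifacts a glycan-model evaluation reports: the
pass/fail proportion, per-category error percentages, a per-sugar x
per-category incidence matrix, and optional per-condition breakdowns
(modelling tool, input notation, cofolding type) driven by a condition
manifest CSV.

Accounting convention: category percentages are per *model* -- a model
counts once for a category no matter how many of its units are affected
-- with a per-unit companion count reported alongside.  Percentages are
rounded half-up to one decimal.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .detectors import ValidationReport
from .flags import CATEGORY_ORDER, ErrorCategory, ErrorFlag

__all__ = [
    "ConditionManifest",
    "SummaryTable",
    "aggregate",
    "export",
    "import_summary",
    "report_from_dict",
]

MANIFEST_COLUMNS = ["file", "tool", "notation", "cofold_type", "seed", "ligand"]
GROUPABLE_KEYS = ("tool", "notation", "cofold_type", "ligand")


def round1(x: float) -> float:
    """Round half-up to one decimal (the reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ConditionManifest:
    """Per-model condition metadata (tool, input notation, cofolding type).

    Backed by a CSV with the documented header
    ``file,tool,notation,cofold_type,seed,ligand``; model ids are matched
    against the ``file`` column (basename comparison as a fallback).
    """

    table: pd.DataFrame

    @classmethod
    def from_csv(cls, path) -> "ConditionManifest":
        df = pd.read_csv(path, dtype=str).fillna("")
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest {path} lacks columns: {missing}")
        return cls(df)

    def for_model(self, model_id: str) -> dict[str, str] | None:
        hits = self.table[self.table["file"] == model_id]
        if hits.empty:
            base = os.path.basename(model_id)
            hits = self.table[self.table["file"].map(os.path.basename) == base]
        if hits.empty:
            return None
        row = hits.iloc[0]
        return {k: str(row[k]) for k in MANIFEST_COLUMNS if k != "file"}


@dataclass
class SummaryTable:
    """Aggregated error statistics over a set of model reports."""

    total: int
    n_pass: int
    n_fail: int
    category_model_counts: dict[str, int]
    category_model_pct: dict[str, float]
    category_unit_counts: dict[str, int]
    sugar_matrix: dict[str, dict[str, int]]  # sugar -> category -> unit count
    group: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def fail_pct(self) -> float:
        return round1(100.0 * self.n_fail / self.total) if self.total else 0.0

    @property
    def pass_pct(self) -> float:
        return round1(100.0 * self.n_pass / self.total) if self.total else 0.0

    def sugar_present(self, sugar: str, category: str) -> bool:
        return self.sugar_matrix.get(sugar, {}).get(category, 0) > 0

    def to_dict(self) -> dict:
        return {
            "group": dict(sorted(self.group.items())),
            "total": self.total,
            "n_pass": self.n_pass,
            "n_fail": self.n_fail,
            "pass_pct": self.pass_pct,
            "fail_pct": self.fail_pct,
            "category_model_counts": dict(sorted(self.category_model_counts.items())),
            "category_model_pct": dict(sorted(self.category_model_pct.items())),
            "category_unit_counts": dict(sorted(self.category_unit_counts.items())),
            "sugar_matrix": {
                s: dict(sorted(v.items())) for s, v in sorted(self.sugar_matrix.items())
            },
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SummaryTable":
        return cls(
            total=int(data["total"]),
            n_pass=int(data["n_pass"]),
            n_fail=int(data["n_fail"]),
            category_model_counts={k: int(v) for k, v in data["category_model_counts"].items()},
            category_model_pct={k: float(v) for k, v in data["category_model_pct"].items()},
            category_unit_counts={k: int(v) for k, v in data["category_unit_counts"].items()},
            sugar_matrix={
                s: {c: int(n) for c, n in row.items()} for s, row in data["sugar_matrix"].items()
            },
            group=dict(data.get("group", {})),
            warnings=list(data.get("warnings", [])),
        )


def _summarize(reports: list[ValidationReport], group: dict[str, str], warnings: list[str]) -> SummaryTable:
    cats = [c.value for c in CATEGORY_ORDER]
    model_counts = {c: 0 for c in cats}
    unit_counts = {c: 0 for c in cats}
    sugar_matrix: dict[str, dict[str, int]] = {}
    n_fail = 0
    for rep in reports:
        if rep.flags:
            n_fail += 1
        seen_cats = {f.category.value for f in rep.flags}
        for c in seen_cats:
            model_counts[c] += 1
        per_unit: dict[tuple[str, str], set[str]] = {}
        for f in rep.flags:
            per_unit.setdefault((f.unit_id, f.ccd_code), set()).add(f.category.value)
        for (_, ccd), ucats in per_unit.items():
            row = sugar_matrix.setdefault(ccd, {c: 0 for c in cats})
            for c in ucats:
                unit_counts[c] += 1
                row[c] += 1
    total = len(reports)
    pct = {c: (round1(100.0 * n / total) if total else 0.0) for c, n in model_counts.items()}
    return SummaryTable(
        total=total,
        n_pass=total - n_fail,
        n_fail=n_fail,
        category_model_counts=model_counts,
        category_model_pct=pct,
        category_unit_counts=unit_counts,
        sugar_matrix=sugar_matrix,
        group=group,
        warnings=warnings,
    )


def aggregate(
    reports: list[ValidationReport],
    manifest: ConditionManifest | None = None,
    group_by: tuple[str, ...] | list[str] = (),
):
    """Aggregate reports into one summary, or one per condition group.

    Without ``group_by``, returns a single :class:`SummaryTable`.  With
    grouping keys (any of ``tool``, ``notation``, ``cofold_type``,
    ``ligand``), returns ``{group-values-tuple: SummaryTable}``; models
    absent from the manifest aggregate under ``unknown`` with a warning.
    Aggregation is independent of report order.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    group_by = tuple(group_by)
    for key in group_by:
        if key not in GROUPABLE_KEYS:
            raise ValueError(f"cannot group by {key!r}; choose from {GROUPABLE_KEYS}")
    reports = sorted(reports, key=lambda r: r.model_id)
    if not group_by:
        return _summarize(reports, {}, [])
    groups: dict[tuple[str, ...], list[ValidationReport]] = {}
    warnings: list[str] = []
    for rep in reports:
        cond = dict(rep.condition)
        if manifest is not None:
            found = manifest.for_model(rep.model_id)
            if found is not None:
                cond.update(found)
            else:
                warnings.append(f"{rep.model_id}: not in manifest; grouped as unknown")
        values = tuple(cond.get(k, "unknown") or "unknown" for k in group_by)
        groups.setdefault(values, []).append(rep)
    return {
        values: _summarize(members, dict(zip(group_by, values)), warnings)
        for values, members in sorted(groups.items())
    }


def export(summary, path_prefix, format: str = "json") -> list[str]:
    """Write a summary (or grouped summaries) to disk; returns paths.

    ``json`` writes one nested file (re-importable via
    :func:`import_summary`); ``csv`` writes a flat summary table and a
    per-sugar matrix table with stable documented headers.
    """
    fmt = format.lower()
    if isinstance(summary, dict):
        doc = {"groups": [tbl.to_dict() for tbl in summary.values()]}
        tables = list(summary.values())
    else:
        doc = summary.to_dict()
        tables = [summary]
    written: list[str] = []
    if fmt == "json":
        path = f"{path_prefix}.json"
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    elif fmt == "csv":
        cats = [c.value for c in CATEGORY_ORDER]
        rows = []
        for tbl in tables:
            base = {f"group_{k}": v for k, v in tbl.group.items()}
            base.update(
                total=tbl.total, n_pass=tbl.n_pass, n_fail=tbl.n_fail,
                pass_pct=tbl.pass_pct, fail_pct=tbl.fail_pct,
            )
            for c in cats:
                base[f"{c}_models"] = tbl.category_model_counts[c]
                base[f"{c}_pct"] = tbl.category_model_pct[c]
                base[f"{c}_units"] = tbl.category_unit_counts[c]
            rows.append(base)
        path = f"{path_prefix}_summary.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
        mrows = []
        for tbl in tables:
            for sugar, row in sorted(tbl.sugar_matrix.items()):
                entry = {f"group_{k}": v for k, v in tbl.group.items()}
                entry["sugar"] = sugar
                for c in cats:
                    entry[c] = row.get(c, 0)
                    entry[f"{c}_present"] = row.get(c, 0) > 0
                mrows.append(entry)
        mpath = f"{path_prefix}_matrix.csv"
        pd.DataFrame(mrows).to_csv(mpath, index=False)
        written.append(mpath)
    else:
        raise ValueError(f"unknown export format {format!r}; use json or csv")
    return written


def import_summary(path):
    """Inverse of :func:`export` for the JSON form."""
    with open(path) as fh:
        doc = json.load(fh)
    if "groups" in doc:
        out = {}
        for item in doc["groups"]:
            tbl = SummaryTable.from_dict(item)
            out[tuple(tbl.group.values())] = tbl
        return out
    return SummaryTable.from_dict(doc)


def report_from_dict(data: dict) -> ValidationReport:
    """Rebuild a :class:`ValidationReport` from its JSON form."""
    flags = [
        ErrorFlag(
            category=ErrorCategory(f["category"]),
            unit_id=f["unit"],
            ccd_code=f["ccd_code"],
            atoms=tuple(f["atoms"]),
            magnitude=float(f["magnitude"]),
            detail=f.get("detail", ""),
        )
        for f in data["flags"]
    ]
    return ValidationReport(
        model_id=data["model"],
        flags=flags,
        n_units=int(data["n_units"]),
        condition=dict(data.get("condition", {})),
        warnings=list(data.get("warnings", [])),
        status=data.get("status", "ok"),
    )
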