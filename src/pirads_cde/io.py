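"""Reading and writing CDE lesion reports and lesion manifests.

Two interchange formats are supported:

* ``json`` — one document with a ``reports`` list (nested per
  lesion/rater/session, values keyed by variable name) and an optional
  ``manifest`` list;
* ``csv-long`` — a long table with columns
  ``lesion_id, rater_id, session, variable, value``; manual PI-RADS category
  assignments ride along under the reserved variable names
  ``pirads_t2w/pirads_dwi/pirads_dce/pirads_overall``.

Both formats round-trip: ``read(write(x)) == x`` for valid report sets.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DuplicateRecordError, UnknownVariableError
from .schema import CdeSchema, LesionManifest, LesionReport

#: Reserved long-CSV variable names for manual PI-RADS category assignments.
CATEGORY_COLUMNS = {
    "pirads_t2w": "t2w",
    "pirads_dwi": "dwi",
    "pirads_dce": "dce",
    "pirads_overall": "overall",
}
_CATEGORY_NAMES = {v: k for k, v in CATEGORY_COLUMNS.items()}


def _canonical_reports(
    reports: Iterable[LesionReport], schema: CdeSchema | None
) -> list[LesionReport]:
    out = []
    for rep in reports:
        values = dict(rep.values)
        if schema is not None:
            unknown = [n for n in values if n not in schema]
            if unknown:
                raise UnknownVariableError(
                    f"unknown variables in report {rep.key}: {sorted(unknown)}"
                )
            # alias-map only: out-of-domain values are the validator's concern
            values = {n: schema[n].aliases.get(v, v) for n, v in values.items()}
        out.append(
            LesionReport(
                lesion_id=rep.lesion_id,
                rater_id=rep.rater_id,
                session=rep.session,
                values=values,
                categories=dict(rep.categories),
            )
        )
    return out


def _check_duplicates(reports: Sequence[LesionReport]) -> None:
    seen = set()
    for rep in reports:
        if rep.key in seen:
            raise DuplicateRecordError(f"duplicate report for {rep.key}")
        seen.add(rep.key)


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def write_reports_json(
    path: str | Path,
    reports: Sequence[LesionReport],
    manifest: Sequence[LesionManifest] | None = None,
) -> None:
    doc: dict = {
        "reports": [
            {
                "lesion_id": r.lesion_id,
                "rater_id": r.rater_id,
                "session": r.session,
                "values": dict(r.values),
                "categories": dict(r.categories),
            }
            for r in reports
        ]
    }
    if manifest is not None:
        doc["manifest"] = [
            {
                "lesion_id": m.lesion_id,
                "zone": m.zone,
                "clinically_significant": m.clinically_significant,
            }
            for m in manifest
        ]
    Path(path).write_text(json.dumps(doc, indent=1, ensure_ascii=False), encoding="utf-8")


def read_reports_json(
    path: str | Path, schema: CdeSchema | None = None
) -> tuple[list[LesionReport], list[LesionManifest] | None]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    reports = [
        LesionReport(
            lesion_id=str(e["lesion_id"]),
            rater_id=str(e["rater_id"]),
            session=int(e["session"]),
            values=dict(e.get("values", {})),
            categories=dict(e.get("categories", {})),
        )
        for e in doc.get("reports", [])
    ]
    _check_duplicates(reports)
    reports = _canonical_reports(reports, schema)
    manifest = None
    if "manifest" in doc:
        manifest = [
            LesionManifest(
                lesion_id=str(e["lesion_id"]),
                zone=str(e["zone"]),
                clinically_significant=bool(e["clinically_significant"]),
            )
            for e in doc["manifest"]
        ]
    return reports, manifest


# ---------------------------------------------------------------------------
# long CSV
# ---------------------------------------------------------------------------

def write_reports_csv(path: str | Path, reports: Sequence[LesionReport]) -> None:
    rows = []
    for r in reports:
        for var, val in r.values.items():
            rows.append((r.lesion_id, r.rater_id, r.session, var, val))
        for key, val in r.categories.items():
            rows.append((r.lesion_id, r.rater_id, r.session, _CATEGORY_NAMES[key], str(val)))
    df = pd.DataFrame(rows, columns=["lesion_id", "rater_id", "session", "variable", "value"])
    df.to_csv(path, index=False)


def read_reports_csv(
    path: str | Path, schema: CdeSchema | None = None
) -> list[LesionReport]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["lesion_id", "rater_id", "session", "variable", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise UnknownVariableError(f"long CSV is missing columns: {missing}")

    dupes = df.duplicated(subset=["lesion_id", "rater_id", "session", "variable"])
    if dupes.any():
        bad = df.loc[dupes, ["lesion_id", "rater_id", "session", "variable"]]
        raise DuplicateRecordError(
            f"duplicate (lesion, rater, session, variable) rows:\n{bad.to_string(index=False)}"
        )

    reports = []
    for (lesion, rater, session), grp in df.groupby(
        ["lesion_id", "rater_id", "session"], sort=True
    ):
        values: dict[str, str] = {}
        categories: dict[str, object] = {}
        for var, val in zip(grp["variable"], grp["value"]):
            if var in CATEGORY_COLUMNS:
                key = CATEGORY_COLUMNS[var]
                categories[key] = val if key == "dce" else int(val)
            else:
                values[var] = val
        reports.append(
            LesionReport(
                lesion_id=lesion,
                rater_id=rater,
                session=int(session),
                values=values,
                categories=categories,
            )
        )
    return _canonical_reports(reports, schema)


def read_reports(
    path: str | Path, format: str = "json", schema: CdeSchema | None = None
) -> tuple[list[LesionReport], list[LesionManifest] | None]:
    """Read a report collection in either supported format."""
    if format == "json":
        return read_reports_json(path, schema=schema)
    if format == "csv-long":
        return read_reports_csv(path, schema=schema), None
    raise ValueError(f"format must be 'json' or 'csv-long', got {format!r}")


def write_reports(
    path: str | Path,
    reports: Sequence[LesionReport],
    format: str = "json",
    manifest: Sequence[LesionManifest] | None = None,
) -> None:
    if format == "json":
        write_reports_json(path, reports, manifest=manifest)
    elif format == "csv-long":
        write_reports_csv(path, reports)
    else:
        raise ValueError(f"format must be 'json' or 'csv-long', got {format!r}")


# ---------------------------------------------------------------------------
# manifest CSV
# ---------------------------------------------------------------------------

def write_manifest_csv(path: str | Path, manifest: Sequence[LesionManifest]) -> None:
    pd.DataFrame(
        {
            "lesion_id": [m.lesion_id for m in manifest],
            "zone": [m.zone for m in manifest],
            "clinically_significant": [m.clinically_significant for m in manifest],
        }
    ).to_csv(path, index=False)


def read_manifest_csv(path: str | Path) -> list[LesionManifest]:
    df = pd.read_csv(path, dtype={"lesion_id": str, "zone": str, "clinically_significant": str})
    return [
        LesionManifest(
            lesion_id=row.lesion_id,
            zone=row.zone,
            clinically_significant=str(row.clinically_significant).strip().lower()
            in ("true", "1", "yes"),
        )
        for row in df.itertuples()
    ]
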