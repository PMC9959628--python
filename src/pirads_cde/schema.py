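"""PI-RADS v2.1 common-data-element (CDE) report schema.

A structured prostate-mpMRI report is decomposed into 34 named categorical
variables (CDEs), grouped by modality (GLOBAL, T2W, ADC, DWI, DCE), each with
a fixed value domain and, where available, an associated RadLex term.
Applicability is conditional: descriptor CDEs for a modality apply only when
that modality is present/adequate and an abnormality was reported on it.

The module also ships the two descriptor simplifications used for rule
definition: the shape lexicon collapsed to three shape types (linear, round,
irregular) and margins grouped into circumscribed vs. non-circumscribed.

Two storage states are distinguished throughout: a *missing* value (the rater
did not answer; the key is absent) and a *not-applicable* value (the schema's
applicability condition fails; stored as the sentinel ``NA``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DuplicateVariableError, SchemaParseError, UnknownValueError

#: Sentinel stored for a variable whose applicability condition fails.
NOT_APPLICABLE = "NA"

#: The three simplified shape types.
SHAPE_CATEGORIES = ("Linear", "Round", "Irregular")

#: The two simplified margin groups.
MARGIN_CATEGORIES = ("Circumscribed", "Non_Circumscribed")

# Shape-type grouping over the union of the two shape vocabularies
# (4-value report-form list and 8-value narrative lexicon).
_SHAPE_MAP = {
    "Linear": "Linear",
    "Wedge": "Linear",
    "Wedge-Shaped": "Linear",
    "Lenticular": "Round",
    "Water-Drop": "Round",
    "Tear-Shaped": "Round",
    "Round": "Round",
    "Oval": "Round",
    "Lobulated": "Irregular",
    "Irregular": "Irregular",
}

# Margin grouping; "Encapsulated" is taken as circumscribed (an encapsulated
# nodule has a visible capsule, the hallmark of a circumscribed margin).
_MARGIN_MAP = {
    "Indistinct": "Non_Circumscribed",
    "Obscured": "Non_Circumscribed",
    "Spiculated": "Non_Circumscribed",
    "Erased charcoal sign": "Non_Circumscribed",
    "Encapsulated": "Circumscribed",
    "Partly_Encapsulated": "Circumscribed",
    "Well_Defined": "Circumscribed",
}


@dataclass(frozen=True)
class Condition:
    """A single applicability condition: ``var`` must hold one of ``allowed``."""

    var: str
    allowed: tuple[str, ...]

    def holds(self, values: Mapping[str, str]) -> bool:
        return values.get(self.var) in self.allowed


@dataclass(frozen=True)
class CdeVariable:
    """One common data element: a named categorical report variable."""

    name: str
    label: str
    radlex: str | None
    group: str
    domain: tuple[str, ...]
    requires: tuple[Condition, ...] = ()
    ordinal: bool = False
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.domain:
            raise SchemaParseError(f"variable {self.name!r} has an empty value domain")
        if len(set(self.domain)) != len(self.domain):
            raise SchemaParseError(f"variable {self.name!r} has duplicate domain values")

    def canonicalize(self, value: str) -> str:
        """Map an input value (possibly an accepted alias) to its canonical form."""
        value = self.aliases.get(value, value)
        if value == NOT_APPLICABLE or value in self.domain:
            return value
        raise UnknownValueError(
            f"{value!r} is not a valid value for {self.name} (domain: {list(self.domain)})"
        )

    def applicable(self, values: Mapping[str, str]) -> bool:
        """Whether this variable applies given the other populated values."""
        return all(c.holds(values) for c in self.requires)


@dataclass(frozen=True)
class CdeSchema:
    """An ordered collection of CDE variables plus a version tag."""

    variables: tuple[CdeVariable, ...]
    version: str
    shape_dialect: str = "table1"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DuplicateVariableError(f"duplicate variable names: {sorted(dupes)}")
        known = set(names)
        for v in self.variables:
            for c in v.requires:
                if c.var not in known:
                    raise SchemaParseError(
                        f"variable {v.name!r} requires unknown variable {c.var!r}"
                    )

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def __getitem__(self, name: str) -> CdeVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def group(self, group: str) -> tuple[CdeVariable, ...]:
        return tuple(v for v in self.variables if v.group == group)

    def applicable(self, name: str, values: Mapping[str, str]) -> bool:
        """Transitive applicability: every required variable must hold the
        required value *and* itself be applicable."""
        for c in self[name].requires:
            if not c.holds(values) or not self.applicable(c.var, values):
                return False
        return True


@dataclass(frozen=True)
class LesionReport:
    """One rater's CDE assessment of one lesion in one session.

    ``values`` maps variable name -> canonical categorical value (or the
    ``NA`` sentinel).  ``categories`` optionally carries the rater's *manual*
    PI-RADS category assignments (keys ``t2w``, ``dwi``, ``dce``,
    ``overall``), which are assessments on top of the CDE vocabulary rather
    than CDEs themselves.
    """

    lesion_id: str
    rater_id: str
    session: int
    values: Mapping[str, str] = field(default_factory=dict)
    categories: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.session not in (1, 2):
            raise ValueError(f"session must be 1 or 2, got {self.session!r}")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.lesion_id, self.rater_id, self.session)


@dataclass(frozen=True)
class LesionManifest:
    """Ground-truth record for one lesion: zone and clinical significance."""

    lesion_id: str
    zone: str
    clinically_significant: bool

    ZONES = ("PZ", "TZ", "AFMS")

    def __post_init__(self) -> None:
        if self.zone not in self.ZONES:
            raise ValueError(f"zone must be one of {self.ZONES}, got {self.zone!r}")


@dataclass(frozen=True)
class Violation:
    """One validation finding: which variable, which value, which rule."""

    variable: str
    value: str | None
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.variable}={self.value!r}: {self.message}"


def _default_definition_path() -> Path:
    return Path(str(resources.files("pirads_cde").joinpath("data/cde_schema.json")))


def load_schema(
    definition: str | Path | None = None, shape_dialect: str = "table1"
) -> CdeSchema:
    """Load a CDE schema from a JSON definition file.

    Parameters
    ----------
    definition
        Path to a schema JSON document.  ``None`` loads the shipped PI-RADS
        v2.1 default (34 variables).
    shape_dialect
        Which raw shape vocabulary the ``*_shape`` variables use:
        ``"table1"`` (the 4-value report-form list) or ``"lexicon"``
        (the 8-value narrative lexicon).  The shape-type grouping is defined
        on the union of both.
    """
    path = Path(definition) if definition is not None else _default_definition_path()
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaParseError(f"cannot parse schema definition {path}: {exc}") from exc
    if not isinstance(raw, dict) or "variables" not in raw:
        raise SchemaParseError(f"schema definition {path} has no 'variables' list")

    dialects = raw.get("shape_dialects", {})
    if shape_dialect not in dialects and dialects:
        raise SchemaParseError(
            f"unknown shape dialect {shape_dialect!r}; available: {sorted(dialects)}"
        )

    variables = []
    for entry in raw["variables"]:
        if not isinstance(entry, dict) or "name" not in entry:
            raise SchemaParseError(f"malformed variable entry: {entry!r}")
        name = entry["name"]
        for key in ("label", "domain"):
            if key not in entry:
                raise SchemaParseError(f"variable {name!r} is missing {key!r}")
        domain = entry["domain"]
        if entry.get("dialect_domain") == "shape" and dialects:
            domain = dialects[shape_dialect]
        requires = tuple(
            Condition(var=c["var"], allowed=tuple(c["in"])) for c in entry.get("requires", ())
        )
        variables.append(
            CdeVariable(
                name=name,
                label=entry["label"],
                radlex=entry.get("radlex"),
                group=entry.get("group", "GLOBAL"),
                domain=tuple(domain),
                requires=requires,
                ordinal=bool(entry.get("ordinal", False)),
                aliases=dict(entry.get("aliases", {})),
            )
        )
    return CdeSchema(
        variables=tuple(variables),
        version=str(raw.get("version", "unversioned")),
        shape_dialect=shape_dialect,
    )


def validate_report(
    report: LesionReport, schema: CdeSchema, mode: str = "strict"
) -> list[Violation]:
    """Validate a lesion report against a schema.

    In ``partial`` mode only populated values are checked (domain membership
    and applicability); ``strict`` mode additionally requires every applicable
    variable to be populated.  Violations are returned as data, never raised.
    """
    if mode not in ("strict", "partial"):
        raise ValueError(f"mode must be 'strict' or 'partial', got {mode!r}")
    violations: list[Violation] = []
    values = dict(report.values)

    for name, value in values.items():
        if name not in schema:
            violations.append(
                Violation(name, value, "unknown-variable", "not defined in schema")
            )

    for var in schema:
        value = values.get(var.name)
        applicable = schema.applicable(var.name, values)
        if value is None:
            if mode == "strict" and applicable:
                violations.append(
                    Violation(var.name, None, "missing", "applicable variable not populated")
                )
            continue
        if value == NOT_APPLICABLE:
            if applicable:
                violations.append(
                    Violation(
                        var.name,
                        value,
                        "spurious-na",
                        "flagged not-applicable but applicability conditions hold",
                    )
                )
            continue
        if value not in var.domain:
            violations.append(
                Violation(
                    var.name,
                    value,
                    "domain",
                    f"not in domain {list(var.domain)}",
                )
            )
            continue
        if not applicable:
            failed = [c for c in var.requires if not c.holds(values)]
            detail = "; ".join(
                f"requires {c.var} in {list(c.allowed)} (got {values.get(c.var)!r})"
                for c in failed
            )
            violations.append(Violation(var.name, value, "applicability", detail))
    return violations


def categorize_shape(shape: str) -> str:
    """Collapse a raw shape value to one of the three shape types.

    Defined on the union of the 4-value report-form vocabulary and the
    8-value narrative shape lexicon; total and onto
    {Linear, Round, Irregular}.
    """
    try:
        return _SHAPE_MAP[shape]
    except KeyError:
        raise UnknownValueError(
            f"unknown shape {shape!r}; known: {sorted(_SHAPE_MAP)}"
        ) from None


def categorize_margin(margin: str) -> str:
    """Collapse a raw margin value to Circumscribed / Non_Circumscribed."""
    try:
        return _MARGIN_MAP[margin]
    except KeyError:
        raise UnknownValueError(
            f"unknown margin {margin!r}; known: {sorted(_MARGIN_MAP)}"
        ) from None


def shape_vocabulary() -> tuple[str, ...]:
    """The union vocabulary on which :func:`categorize_shape` is defined."""
    return tuple(_SHAPE_MAP)


def margin_vocabulary() -> tuple[str, ...]:
    """The vocabulary on which :func:`categorize_margin` is defined."""
    return tuple(_MARGIN_MAP)


def validate_reports(
    reports: Iterable[LesionReport], schema: CdeSchema, mode: str = "strict"
) -> dict[tuple[str, str, int], list[Violation]]:
    """Validate many reports; returns only the keys with violations."""
    out: dict[tuple[str, str, int], list[Violation]] = {}
    for rep in reports:
        v = validate_report(rep, schema, mode=mode)
        if v:
            out[rep.key] = v
    return out
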