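"""Declarative CDE -> PI-RADS v2.1 scoring engine.

The PI-RADS v2.1 narrative guidelines are encoded as a rule table shipped as
JSON data, so the rule content is reviewable (and replaceable) data rather
than code.  Each of the four targets (T2W score, DWI score, DCE result,
overall category) has:

* a finite *feature space* — a small vector of values derived from the CDE
  report (simplified shape/margin types, signal scales, the size bin, the
  zone group) with conditional applicability (``na_if``), and
* an ordered list of rules, each a conjunction of set-membership constraints.

The rules are required to *partition* the applicable feature space: for every
complete valid report exactly one rule fires per target.
:func:`check_rule_table` verifies this by exhaustive enumeration.

Zone handling: lesions in the anterior fibromuscular stroma (AFMS) are scored
with the TZ rule set (anterior stromal lesions are assessed under the
T2W-dominant pathway); the peripheral zone uses the DWI-dominant pathway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

from .errors import IncompleteReportError, SchemaParseError
from .schema import (
    NOT_APPLICABLE,
    LesionReport,
    categorize_margin,
    categorize_shape,
)

NA = NOT_APPLICABLE

#: Zones scored with the TZ (T2W-dominant) rule set.
_TZ_LIKE = ("TZ", "AFMS")

DCE_OUTCOMES = ("Positive", "Negative", "X")


@dataclass(frozen=True)
class Rule:
    """One scoring rule: fire ``score`` when every constraint holds."""

    score: int | str
    when: Mapping[str, tuple]

    def matches(self, features: Mapping[str, object]) -> bool:
        return all(features.get(name) in allowed for name, allowed in self.when.items())


@dataclass(frozen=True)
class TargetRules:
    """Feature space, applicability structure, and rules for one target."""

    name: str
    features: Mapping[str, tuple]
    na_if: Mapping[str, tuple]
    rules: tuple[Rule, ...]

    def enumerate_inputs(self) -> Iterator[dict[str, object]]:
        """Yield every applicable combination of feature values.

        A feature is forced to ``NA`` as soon as one of its ``na_if``
        conjunctions holds for the values already assigned (features are
        processed in declaration order, so conditions may only reference
        earlier features).
        """
        names = list(self.features)

        def rec(i: int, partial: dict) -> Iterator[dict]:
            if i == len(names):
                yield dict(partial)
                return
            name = names[i]
            if any(
                all(partial.get(var) in allowed for var, allowed in conj.items())
                for conj in self.na_if.get(name, ())
            ):
                partial[name] = NA
                yield from rec(i + 1, partial)
            else:
                for value in self.features[name]:
                    partial[name] = value
                    yield from rec(i + 1, partial)
            del partial[name]

        yield from rec(0, {})

    def firing(self, features: Mapping[str, object]) -> list[Rule]:
        return [r for r in self.rules if r.matches(features)]

    def score(self, features: Mapping[str, object]):
        fired = self.firing(features)
        if len(fired) != 1:
            raise ValueError(
                f"{self.name}: {len(fired)} rules fire for {dict(features)!r} "
                "(rule table is not a partition here)"
            )
        return fired[0].score


@dataclass(frozen=True)
class RuleTable:
    """The full PI-RADS rule set: one :class:`TargetRules` per target."""

    targets: Mapping[str, TargetRules]
    version: str

    def __getitem__(self, name: str) -> TargetRules:
        return self.targets[name]


@dataclass(frozen=True)
class PiradsScores:
    """Per-sequence PI-RADS scores and the overall assessment category."""

    t2w_score: int
    dwi_score: int
    dce_result: str
    overall: int

    def __post_init__(self) -> None:
        if not (1 <= self.t2w_score <= 5 and 1 <= self.dwi_score <= 5):
            raise ValueError("sequence scores must be in 1..5")
        if self.dce_result not in DCE_OUTCOMES:
            raise ValueError(f"dce_result must be one of {DCE_OUTCOMES}")
        if not 1 <= self.overall <= 5:
            raise ValueError("overall category must be in 1..5")

    def as_dict(self) -> dict:
        return {
            "t2w": self.t2w_score,
            "dwi": self.dwi_score,
            "dce": self.dce_result,
            "overall": self.overall,
        }


@dataclass
class RuleCheckReport:
    """Completeness/consistency findings for a rule table."""

    gaps: dict[str, list[dict]] = field(default_factory=dict)
    conflicts: dict[str, list[dict]] = field(default_factory=dict)
    n_enumerated: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not any(self.gaps.values()) and not any(self.conflicts.values())


def load_rule_table(definition: str | Path | None = None) -> RuleTable:
    """Load a rule table; ``None`` loads the shipped PI-RADS v2.1 default."""
    if definition is None:
        definition = Path(str(resources.files("pirads_cde").joinpath("data/pirads_rules.json")))
    try:
        raw = json.loads(Path(definition).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaParseError(f"cannot parse rule table {definition}: {exc}") from exc
    targets = {}
    for name, spec in raw.get("targets", {}).items():
        targets[name] = TargetRules(
            name=name,
            features={f: tuple(dom) for f, dom in spec["features"].items()},
            na_if={
                f: tuple({v: tuple(a) for v, a in conj.items()} for conj in conds)
                for f, conds in spec.get("na_if", {}).items()
            },
            rules=tuple(
                Rule(score=r["score"], when={f: tuple(v) for f, v in r["when"].items()})
                for r in spec.get("rules", ())
            ),
        )
    return RuleTable(targets=targets, version=str(raw.get("version", "unversioned")))


_DEFAULT_TABLE: RuleTable | None = None


def default_rule_table() -> RuleTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_rule_table()
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _zone_group(zone: str) -> str:
    if zone == "PZ":
        return "PZ"
    if zone in _TZ_LIKE:
        return "TZ"
    raise ValueError(f"zone must be PZ, TZ or AFMS, got {zone!r}")


def _get(values: Mapping[str, str], name: str, missing: list[str]) -> str | None:
    v = values.get(name)
    if v is None:
        missing.append(name)
    return v


def _shape_type(values: Mapping[str, str], prefix: str, missing: list[str]) -> str | None:
    """Simplified shape type: the rater's own category, else derived from raw shape."""
    cat = values.get(f"{prefix}_shape_category")
    if cat is not None and cat != NA:
        return cat
    raw = values.get(f"{prefix}_shape")
    if raw is not None and raw != NA:
        return categorize_shape(raw)
    missing.append(f"{prefix}_shape_category")
    return None


def _margin_type(values: Mapping[str, str], missing: list[str]) -> str | None:
    cat = values.get("t2w_margin_category")
    if cat is not None and cat != NA:
        return cat
    raw = values.get("t2w_margin")
    if raw is not None and raw != NA:
        return categorize_margin(raw)
    missing.append("t2w_margin_category")
    return None


def t2w_features(report: LesionReport, zone: str) -> dict[str, object]:
    v = report.values
    missing: list[str] = []
    if v.get("t2w_present_and_adequate") != "YES":
        raise IncompleteReportError(["t2w_present_and_adequate (must be YES to score T2W)"])
    feats: dict[str, object] = {"zone_group": _zone_group(zone)}
    abnormality = _get(v, "t2w_abnormality", missing)
    feats["abnormality"] = abnormality
    if abnormality == "YES":
        feats["signal_type"] = _get(v, "t2w_signal_intensity_type", missing)
        feats["signal"] = _get(v, "t2w_signal_intensity", missing)
        feats["uniformity"] = _get(v, "t2w_uniformity", missing)
        feats["focality"] = _get(v, "t2w_focality", missing)
        feats["shape_type"] = _shape_type(v, "t2w", missing)
        feats["margin_type"] = _margin_type(v, missing)
        feats["invasive"] = _get(v, "t2w_invasive", missing)
        feats["size"] = _get(v, "lesion_dim_max", missing)
    else:
        feats.update(
            dict.fromkeys(
                ("signal_type", "signal", "uniformity", "focality",
                 "shape_type", "margin_type", "invasive", "size"),
                NA,
            )
        )
    if missing:
        raise IncompleteReportError(missing)
    return feats


def dwi_features(report: LesionReport) -> dict[str, object]:
    v = report.values
    missing: list[str] = []
    for var in ("adc_present_and_adequate", "dwi_present_and_adequate"):
        if v.get(var) != "YES":
            raise IncompleteReportError([f"{var} (must be YES to score DWI)"])
    adc_abn = _get(v, "adc_abnormality", missing)
    dwi_abn = _get(v, "dwi_abnormality", missing)
    feats: dict[str, object] = {"adc_abnormality": adc_abn, "dwi_abnormality": dwi_abn}
    if adc_abn == "YES":
        feats["adc_shape_type"] = _shape_type(v, "adc", missing)
        feats["adc_signal"] = _get(v, "adc_signal_intensity", missing)
        feats["focality"] = _get(v, "adc_focality", missing)
    else:
        feats["adc_shape_type"] = feats["adc_signal"] = feats["focality"] = NA
    if dwi_abn == "YES":
        feats["dwi_shape_type"] = _shape_type(v, "dwi", missing)
        feats["dwi_signal"] = _get(v, "dwi_signal_intensity", missing)
    else:
        feats["dwi_shape_type"] = feats["dwi_signal"] = NA
    # invasive behaviour on either diffusion map counts
    inv = [v.get("adc_invasive"), v.get("dwi_invasive")]
    inv = [x for x in inv if x not in (None, NA)]
    feats["invasive"] = ("YES" if "YES" in inv else "NO") if inv else NA
    feats["size"] = _get(v, "lesion_dim_max", missing) if (adc_abn == "YES" or dwi_abn == "YES") else NA
    if feats["invasive"] == NA and (adc_abn == "YES" or dwi_abn == "YES"):
        missing.append("adc_invasive/dwi_invasive")
    if missing:
        raise IncompleteReportError(missing)
    # size only gates the 4-vs-5 split, which needs both maps abnormal
    if not (adc_abn == "YES" and dwi_abn == "YES"):
        if adc_abn == "NO" and dwi_abn == "NO":
            feats["invasive"] = NA
            feats["size"] = NA
    return feats


def dce_features(report: LesionReport) -> dict[str, object]:
    v = report.values
    missing: list[str] = []
    present = _get(v, "dce_present_and_adequate", missing)
    feats: dict[str, object] = {"present": present}
    if present == "YES":
        abn = _get(v, "dce_abnormality", missing)
        feats["abnormality"] = abn
        feats["enhancement"] = _get(v, "dce_enhancement", missing) if abn == "YES" else NA
        if feats["enhancement"] == "Positive_DCE":
            feats["corresponds"] = _get(v, "dce_corresponds_to", missing)
        else:
            feats["corresponds"] = NA
        feats["bph"] = _get(v, "dce_bph_features", missing)
    else:
        feats.update({"abnormality": NA, "enhancement": NA, "corresponds": NA, "bph": NA})
    if missing:
        raise IncompleteReportError(missing)
    return feats


# ---------------------------------------------------------------------------
# scoring operations
# ---------------------------------------------------------------------------

def score_t2w(report: LesionReport, zone: str, table: RuleTable | None = None) -> int:
    """T2W sequence score (1-5); AFMS lesions use the TZ rule set."""
    table = table or default_rule_table()
    return int(table["t2w"].score(t2w_features(report, zone)))


def score_dwi(report: LesionReport, zone: str, table: RuleTable | None = None) -> int:
    """DWI/ADC sequence score (1-5), from the joint diffusion assessment."""
    table = table or default_rule_table()
    del zone  # the default DWI rules are zone-independent
    return int(table["dwi"].score(dwi_features(report)))


def score_dce(report: LesionReport, table: RuleTable | None = None) -> str:
    """DCE result: Positive / Negative / X (unavailable)."""
    table = table or default_rule_table()
    return str(table["dce"].score(dce_features(report)))


def overall_category(
    t2w: int,
    dwi: int,
    dce: str,
    zone: str,
    size_bin: str | None = None,
    table: RuleTable | None = None,
) -> int:
    """Overall PI-RADS assessment category (1-5).

    PZ lesions follow the DWI-dominant pathway (DCE upgrades a DWI-3 lesion
    to 4); TZ/AFMS lesions follow the T2W-dominant pathway with the two DWI
    upgrade exceptions.  ``dce = "X"`` never upgrades.
    """
    table = table or default_rule_table()
    if not (1 <= int(t2w) <= 5 and 1 <= int(dwi) <= 5):
        raise ValueError(f"sequence scores must be in 1..5, got t2w={t2w}, dwi={dwi}")
    if dce not in DCE_OUTCOMES:
        raise ValueError(f"dce must be one of {DCE_OUTCOMES}, got {dce!r}")
    feats = {
        "zone_group": _zone_group(zone),
        "t2w": int(t2w),
        "dwi": int(dwi),
        "dce": dce,
        "size": size_bin if size_bin is not None else NA,
    }
    target = table["overall"]
    fired = target.firing(feats)
    if len(fired) != 1:  # retry with any size when rules do constrain size
        raise ValueError(f"overall rules are not a partition at {feats!r}")
    return int(fired[0].score)


def score_report(
    report: LesionReport, zone: str, table: RuleTable | None = None
) -> PiradsScores:
    """Compute all per-sequence scores and the overall category for one report."""
    table = table or default_rule_table()
    t2w = score_t2w(report, zone, table)
    dwi = score_dwi(report, zone, table)
    dce = score_dce(report, table)
    size = report.values.get("lesion_dim_max")
    overall = overall_category(t2w, dwi, dce, zone, size_bin=size, table=table)
    return PiradsScores(t2w_score=t2w, dwi_score=dwi, dce_result=dce, overall=overall)


def score_range(
    report: LesionReport, zone: str, target: str, table: RuleTable | None = None
) -> set:
    """Lenient mode: the set of scores compatible with the observed CDEs.

    Enumerates the applicable feature combinations that agree with every
    feature derivable from the (possibly partial) report and collects the
    scores the rule table assigns to them.  A complete report yields a
    singleton; an empty report yields the full score range.
    """
    table = table or default_rule_table()
    extract = {
        "t2w": lambda: t2w_features(report, zone),
        "dwi": lambda: dwi_features(report),
        "dce": lambda: dce_features(report),
    }
    if target not in extract:
        raise ValueError(f"target must be one of {sorted(extract)}, got {target!r}")
    try:
        observed = extract[target]()
    except IncompleteReportError:
        observed = _partial_features(report, zone, target)
    tr = table[target]
    scores = set()
    for combo in tr.enumerate_inputs():
        if all(combo[k] == v for k, v in observed.items() if v is not None):
            scores.add(tr.score(combo))
    return scores


def _partial_features(report: LesionReport, zone: str, target: str) -> dict:
    """Best-effort feature extraction with ``None`` for anything unknown."""
    v = report.values

    def opt(name):
        val = v.get(name)
        return val if val is not None else None

    if target == "t2w":
        feats = {"zone_group": _zone_group(zone), "abnormality": opt("t2w_abnormality")}
        mapping = {
            "signal_type": "t2w_signal_intensity_type",
            "signal": "t2w_signal_intensity",
            "uniformity": "t2w_uniformity",
            "focality": "t2w_focality",
            "shape_type": "t2w_shape_category",
            "margin_type": "t2w_margin_category",
            "invasive": "t2w_invasive",
            "size": "lesion_dim_max",
        }
        feats.update({f: opt(cde) for f, cde in mapping.items()})
        return {k: val for k, val in feats.items() if val is not None}
    if target == "dwi":
        mapping = {
            "adc_abnormality": "adc_abnormality",
            "dwi_abnormality": "dwi_abnormality",
            "adc_shape_type": "adc_shape_category",
            "dwi_shape_type": "dwi_shape_category",
            "adc_signal": "adc_signal_intensity",
            "dwi_signal": "dwi_signal_intensity",
            "focality": "adc_focality",
            "size": "lesion_dim_max",
        }
        feats = {f: opt(cde) for f, cde in mapping.items()}
        return {k: val for k, val in feats.items() if val is not None}
    mapping = {
        "present": "dce_present_and_adequate",
        "abnormality": "dce_abnormality",
        "enhancement": "dce_enhancement",
        "corresponds": "dce_corresponds_to",
        "bph": "dce_bph_features",
    }
    feats = {f: opt(cde) for f, cde in mapping.items()}
    return {k: val for k, val in feats.items() if val is not None}


def check_rule_table(table: RuleTable | None = None, schema=None) -> RuleCheckReport:
    """Exhaustively verify that every target's rules partition its input space.

    Enumerates the full applicable feature-combination product per target and
    records combinations with zero firing rules (gaps) or more than one
    (conflicts).
    """
    del schema  # feature domains are self-contained in the rule table
    table = table or default_rule_table()
    report = RuleCheckReport()
    for name, target in table.targets.items():
        gaps, conflicts, n = [], [], 0
        for combo in target.enumerate_inputs():
            n += 1
            fired = target.firing(combo)
            if len(fired) == 0:
                gaps.append(combo)
            elif len(fired) > 1:
                conflicts.append(combo)
        report.gaps[name] = gaps
        report.conflicts[name] = conflicts
        report.n_enumerated[name] = n
    return report
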