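"""Reader-study analyses over collections of CDE lesion reports.

Produces the standard outputs of a multi-reader multi-case agreement study:

* per-CDE inter-rater agreement tables (PA %, AC1, CI, p, band), stratified
  by session, experience group, and prostate zone;
* inter- and intra-rater agreement of the four PI-RADS category variables
  (T2W, DWI, DCE, overall);
* a Wilcoxon comparison of overall scores between experience groups on the
  clinically significant lesions;
* diagnostic accuracy of the overall category against the manifest labels at
  an ordinal threshold (category >= 3 by default).

The "overall" session stratum pools the two sessions as additional replicate
pairs by default (each rater pair contributes one result per session);
``pooling="mean"`` averages the per-session means instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .agreement import (
    AgreementResult,
    RatingMatrix,
    gwet_ac1,
    intra_rater_agreement,
    interpret_band,
    pairwise_mean_agreement,
    wilcoxon_signed_rank,
)
from .errors import DegenerateDataError, InsufficientDataError
from .schema import CdeSchema, LesionManifest, LesionReport, load_schema

GROUPS = ("experienced", "inexperienced")

#: Derived analysis features beyond the raw CDEs.
DERIVED_FEATURES = ("lesion_ge_15mm",)

#: The four category variables (stored in LesionReport.categories).
CATEGORY_FEATURES = ("pirads_t2w", "pirads_dwi", "pirads_dce", "pirads_overall")


@dataclass(frozen=True)
class StudyDesign:
    """Raters with experience groups plus the lesion manifest."""

    rater_groups: Mapping[str, str]  # rater_id -> group
    manifest: tuple[LesionManifest, ...]
    sessions: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        bad = {g for g in self.rater_groups.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown experience groups: {sorted(bad)}")
        for g in GROUPS:
            if g not in set(self.rater_groups.values()):
                raise ValueError(f"experience group {g!r} has no raters")

    @property
    def raters(self) -> tuple[str, ...]:
        return tuple(self.rater_groups)

    def group_raters(self, group: str) -> tuple[str, ...]:
        if group == "all":
            return self.raters
        return tuple(r for r, g in self.rater_groups.items() if g == group)

    def lesions(self, zone: str = "all") -> tuple[str, ...]:
        return tuple(
            m.lesion_id for m in self.manifest if zone == "all" or m.zone == zone
        )

    @property
    def zones(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(m.zone for m in self.manifest))


def _report_value(report: LesionReport, feature: str):
    if feature in CATEGORY_FEATURES:
        val = report.categories.get(feature.removeprefix("pirads_"))
        return None if val is None else str(val)
    if feature == "lesion_ge_15mm":
        size = report.values.get("lesion_dim_max")
        return None if size is None else ("YES" if size == "≥15" else "NO")
    return report.values.get(feature)


def build_rating_matrix(
    reports: Iterable[LesionReport],
    feature: str,
    session: int,
    raters: Sequence[str],
    lesions: Sequence[str],
    categories: Sequence[str] | None = None,
) -> RatingMatrix:
    """Subjects (lesions) x raters matrix for one feature and session."""
    cells: dict[str, dict[str, object]] = {les: {} for les in lesions}
    for rep in reports:
        if rep.session != session or rep.rater_id not in raters:
            continue
        if rep.lesion_id not in cells:
            continue
        cells[rep.lesion_id][rep.rater_id] = _report_value(rep, feature)
    df = pd.DataFrame(
        [[cells[les].get(r) for r in raters] for les in lesions],
        index=list(lesions),
        columns=list(raters),
    )
    if categories is not None:
        observed = {str(v) for v in df.values.ravel() if v is not None}
        categories = list(categories) + sorted(observed - set(categories))
    return RatingMatrix(df, categories=categories)


def _feature_categories(feature: str, schema: CdeSchema) -> list[str] | None:
    """Fixed category list so q does not drift with the observed data.

    Schema variables use their declared value domain (the not-applicable
    sentinel is appended as an extra category only where it occurs), so a
    feature everyone rates identically still has q >= 2 and AC1 = 1.
    """
    if feature in schema:
        return list(schema[feature].domain)
    if feature == "lesion_ge_15mm":
        return ["YES", "NO"]
    if feature == "pirads_dce":
        return ["Positive", "Negative", "X"]
    if feature in CATEGORY_FEATURES:
        return ["1", "2", "3", "4", "5"]
    return None


def analyzed_features(schema: CdeSchema | None = None) -> list[tuple[str, str]]:
    """(modality, feature) rows of the per-CDE agreement table."""
    schema = schema or load_schema()
    rows = [("GLOBAL", "lesion_ge_15mm")]
    rows += [(v.group, v.name) for v in schema]
    return rows


def _pairs_for(raters: Sequence[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(raters, 2))


def _stratum_pair_results(
    reports: Sequence[LesionReport],
    feature: str,
    sessions: Sequence[int],
    raters: Sequence[str],
    lesions: Sequence[str],
    categories: Sequence[str] | None,
) -> pd.DataFrame:
    """Per (rater pair, session) two-rater PA/AC1 results, pooled."""
    frames = []
    for session in sessions:
        matrix = build_rating_matrix(reports, feature, session, raters, lesions, categories)
        res = pairwise_mean_agreement(matrix)
        per = res.per_pair.copy()
        per["session"] = session
        frames.append(per)
    return pd.concat(frames, ignore_index=True)


def _summarize_pairs(per_pair: pd.DataFrame, pooling: str) -> dict:
    if pooling == "mean" and per_pair["session"].nunique() > 1:
        by_session = per_pair.groupby("session")[["pa", "ac1"]].mean()
        pa, ac1 = float(by_session["pa"].mean()), float(by_session["ac1"].mean())
        spread = by_session["ac1"]
    else:
        pa, ac1 = float(per_pair["pa"].mean()), float(per_pair["ac1"].mean())
        spread = per_pair["ac1"]
    m = len(spread)
    if m > 1 and spread.std(ddof=1) > 0:
        from scipy import stats as sps

        sem = float(spread.std(ddof=1)) / math.sqrt(m)
        tcrit = sps.t.ppf(0.975, df=m - 1)
        ci_low, ci_high = ac1 - tcrit * sem, min(ac1 + tcrit * sem, 1.0)
        p = 2.0 * sps.t.sf(abs(ac1) / sem, df=m - 1)
    else:
        ci_low = ci_high = ac1
        p = float("nan")
    return {
        "pa": 100.0 * pa,
        "ac1": ac1,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "p_value": min(p, 1.0) if not math.isnan(p) else p,
        "band": interpret_band(ac1),
        "n_pairs": len(per_pair),
    }


def feature_agreement_table(
    reports: Sequence[LesionReport],
    design: StudyDesign,
    session: str | int = "overall",
    group: str = "all",
    zone: str = "all",
    pooling: str = "pooled",
    schema: CdeSchema | None = None,
    features: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Inter-rater agreement per CDE for one stratum.

    One row per analyzed feature with mean pairwise PA (%), mean AC1, a 95%
    CI from the across-pair dispersion, a t-test of mean AC1 = 0, and the
    interpretation band.
    """
    schema = schema or load_schema()
    raters = design.group_raters(group)
    lesions = design.lesions(zone)
    if len(lesions) < 2:
        raise InsufficientDataError(
            f"stratum zone={zone!r} has {len(lesions)} lesion(s); need at least 2"
        )
    sessions = list(design.sessions) if session == "overall" else [int(session)]
    rows = []
    for modality, feature in features or analyzed_features(schema):
        per_pair = _stratum_pair_results(
            reports, feature, sessions, raters, lesions,
            _feature_categories(feature, schema),
        )
        row = {"modality": modality, "feature": feature}
        row.update(_summarize_pairs(per_pair, pooling))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs.update({"session": session, "group": group, "zone": zone, "pooling": pooling})
    return out


def category_agreement_table(
    reports: Sequence[LesionReport],
    design: StudyDesign,
    pooling: str = "pooled",
) -> pd.DataFrame:
    """Agreement of the four PI-RADS category variables.

    Inter-rater rows per session and overall (mean over rater pairs), and
    intra-rater rows per experience group and overall (mean over raters of
    session-1 vs session-2 agreement).
    """
    lesions = design.lesions()
    rows = []
    for feature in CATEGORY_FEATURES:
        cats = _feature_categories(feature, load_schema())
        for stratum in [1, 2, "overall"]:
            sessions = list(design.sessions) if stratum == "overall" else [stratum]
            per_pair = _stratum_pair_results(
                reports, feature, sessions, design.raters, lesions, cats
            )
            row = {"feature": feature, "analysis": "interrater", "stratum": str(stratum)}
            row.update(_summarize_pairs(per_pair, pooling))
            rows.append(row)

        m1 = build_rating_matrix(reports, feature, 1, design.raters, lesions, cats)
        m2 = build_rating_matrix(reports, feature, 2, design.raters, lesions, cats)
        per_rater = intra_rater_agreement(m1, m2)
        for stratum in ("experienced", "inexperienced", "overall"):
            raters = design.raters if stratum == "overall" else design.group_raters(stratum)
            sub = pd.DataFrame(
                {
                    "pa": [per_rater[r].pa for r in raters],
                    "ac1": [per_rater[r].ac1 for r in raters],
                    "session": 0,
                }
            )
            row = {"feature": feature, "analysis": "intrarater", "stratum": stratum}
            row.update(_summarize_pairs(sub, pooling="pooled"))
            row["n_pairs"] = len(raters)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """Between-group comparison of overall PI-RADS scores."""

    mean_experienced: float
    sd_experienced: float
    mean_inexperienced: float
    sd_inexperienced: float
    statistic: float
    p_value: float
    n_lesions: int
    no_difference: bool = False


def group_score_comparison(
    reports: Sequence[LesionReport],
    design: StudyDesign,
    significant_only: bool = True,
) -> GroupComparison:
    """Wilcoxon signed-rank comparison of group overall scores.

    Pairing unit is the lesion: each clinically significant lesion
    contributes the mean overall category of the experienced raters vs. that
    of the inexperienced raters (both sessions' ratings averaged).  Group
    means/SDs are over the individual ratings.
    """
    keep = {
        m.lesion_id
        for m in design.manifest
        if m.clinically_significant or not significant_only
    }
    if not keep:
        raise InsufficientDataError("no lesions in the requested subset")
    scores: dict[str, dict[str, list[float]]] = {g: {} for g in GROUPS}
    for rep in reports:
        if rep.lesion_id not in keep:
            continue
        overall = rep.categories.get("overall")
        if overall is None:
            continue
        group = design.rater_groups.get(rep.rater_id)
        if group is None:
            continue
        scores[group].setdefault(rep.lesion_id, []).append(float(overall))
    lesions = sorted(set(scores["experienced"]) & set(scores["inexperienced"]))
    if not lesions:
        raise InsufficientDataError("no lesion was rated by both groups")
    exp_means = [float(np.mean(scores["experienced"][l])) for l in lesions]
    inexp_means = [float(np.mean(scores["inexperienced"][l])) for l in lesions]
    exp_all = [v for l in lesions for v in scores["experienced"][l]]
    inexp_all = [v for l in lesions for v in scores["inexperienced"][l]]
    try:
        w = wilcoxon_signed_rank(exp_means, inexp_means)
        statistic, p_value, no_diff = w.statistic, w.p_value, False
    except DegenerateDataError:
        statistic, p_value, no_diff = float("nan"), 1.0, True
    return GroupComparison(
        mean_experienced=float(np.mean(exp_all)),
        sd_experienced=float(np.std(exp_all, ddof=1)) if len(exp_all) > 1 else 0.0,
        mean_inexperienced=float(np.mean(inexp_all)),
        sd_inexperienced=float(np.std(inexp_all, ddof=1)) if len(inexp_all) > 1 else 0.0,
        statistic=statistic,
        p_value=p_value,
        n_lesions=len(lesions),
        no_difference=no_diff,
    )


@dataclass(frozen=True)
class DiagnosticAccuracy:
    """Per-rater and per-group accuracy of overall category >= threshold."""

    per_rater: pd.DataFrame
    by_group: pd.DataFrame
    threshold: int
    pooled: Mapping[str, float] = field(default_factory=dict)


def _confusion_metrics(y_true: np.ndarray, y_score: np.ndarray, threshold: int) -> dict:
    y_pred = y_score >= threshold
    tp = int(np.sum(y_pred & (y_true == 1)))
    fp = int(np.sum(y_pred & (y_true == 0)))
    fn = int(np.sum(~y_pred & (y_true == 1)))
    tn = int(np.sum(~y_pred & (y_true == 0)))
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    return {"recall": recall, "precision": precision, "specificity": specificity}


def diagnostic_accuracy(
    reports: Sequence[LesionReport],
    manifest: Sequence[LesionManifest],
    threshold: int = 3,
    design: StudyDesign | None = None,
    pooled: bool = False,
) -> DiagnosticAccuracy:
    """Diagnostic accuracy of the overall category against the labels.

    Predictions are ``overall >= threshold``; recall (sensitivity),
    precision, and specificity come from the confusion counts, AUC from the
    ordinal 1-5 score via the rank (Mann-Whitney) formulation with tie
    handling.  AUC is computed per rater (sessions pooled) and averaged
    within experience group; ``pooled=True`` additionally reports metrics on
    all ratings pooled.
    """
    labels = {m.lesion_id: int(m.clinically_significant) for m in manifest}
    if len(set(labels.values())) < 2:
        raise DegenerateDataError(
            "significance labels are all one class; AUC is undefined"
        )
    by_rater: dict[str, list[tuple[int, float]]] = {}
    for rep in reports:
        overall = rep.categories.get("overall")
        if overall is None or rep.lesion_id not in labels:
            continue
        by_rater.setdefault(rep.rater_id, []).append(
            (labels[rep.lesion_id], float(overall))
        )
    if not by_rater:
        raise InsufficientDataError("no scored lesions with labels")
    rows = []
    for rater, pairs in by_rater.items():
        y_true = np.array([p[0] for p in pairs])
        y_score = np.array([p[1] for p in pairs])
        row = {"rater": rater}
        if design is not None:
            row["group"] = design.rater_groups.get(rater, "unknown")
        row["auc"] = (
            float(roc_auc_score(y_true, y_score)) if len(set(y_true)) == 2 else float("nan")
        )
        row.update(_confusion_metrics(y_true, y_score, threshold))
        row["n"] = len(pairs)
        rows.append(row)
    per_rater = pd.DataFrame(rows)
    if "group" in per_rater.columns:
        by_group = (
            per_rater.groupby("group")[["auc", "recall", "precision", "specificity"]]
            .mean()
            .reset_index()
        )
    else:
        by_group = pd.DataFrame(
            [
                {
                    "group": "all",
                    **per_rater[["auc", "recall", "precision", "specificity"]]
                    .mean()
                    .to_dict(),
                }
            ]
        )
    pooled_metrics: dict[str, float] = {}
    if pooled:
        y_true = np.array([p[0] for pairs in by_rater.values() for p in pairs])
        y_score = np.array([p[1] for pairs in by_rater.values() for p in pairs])
        pooled_metrics = {"auc": float(roc_auc_score(y_true, y_score))}
        pooled_metrics.update(_confusion_metrics(y_true, y_score, threshold))
    return DiagnosticAccuracy(
        per_rater=per_rater, by_group=by_group, threshold=threshold, pooled=pooled_metrics
    )


def design_from_study(study) -> StudyDesign:
    """Convenience: a StudyDesign from a SyntheticStudy."""
    return StudyDesign(rater_groups=dict(study.rater_groups), manifest=tuple(study.manifest))
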