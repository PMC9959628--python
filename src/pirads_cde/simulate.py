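"""Synthetic multi-reader multi-case study generator.

Emulates the reader-study composition the analysis layer targets: 32 lesions
(14 PZ = 7 clinically significant + 7 not, 11 TZ = 5 + 6, 7 AFMS = 4 + 3),
six raters in two experience groups of three, and two reading sessions, so
every analysis stage is exercisable without the (undeposited) human ratings.

Generative model
----------------
Each lesion carries a *latent profile*: a complete, schema-valid CDE truth
drawn from category prevalences conditional on zone and clinical
significance, with the implied true PI-RADS scores derived through the rule
engine.  Raters observe the truth through a per-feature confusion channel:

* session 1: a rater reports the target value with probability ``1 - eps_f``
  and otherwise confuses it, by default uniformly over the other ``q - 1``
  domain values (an ordinal-adjacent mode confuses only neighbours for
  ordinal CDEs);
* session 2: each value repeats the session-1 answer with probability
  ``rho`` and is otherwise regenerated from the session-1 mechanism.

Values are generated top-down through the applicability graph, so every
generated report validates strictly (a rater who reports no abnormality
reports the dependent descriptors as not-applicable).  Manual PI-RADS
categories are derived from the rater's noisy CDE values through the rule
engine, optionally jittered (symmetric +/-1 category noise) and, for the
inexperienced group, downgraded by one category with a configurable
probability — the minimal mechanism for the experience effect on scores.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .engine import RuleTable, default_rule_table, score_report
from .errors import ConfigError
from .schema import (
    NOT_APPLICABLE,
    CdeSchema,
    LesionManifest,
    LesionReport,
    categorize_margin,
    categorize_shape,
    load_schema,
)

NA = NOT_APPLICABLE

#: Default per-feature confusion rates (suffix-matched on variable names).
#: Image adequacy is objective (eps = 0); low-level subjective descriptors
#: (shape, margin, signal level) get high rates, detection-type CDEs low ones.
DEFAULT_EPSILON = {
    "present_and_adequate": 0.0,
    "abnormality": 0.05,
    "signal_intensity_type": 0.03,
    "signal_intensity": 0.35,
    "uniformity": 0.20,
    "focality": 0.18,
    "invasive": 0.18,
    "shape_category": 0.30,
    "shape": 0.50,
    "margin_category": 0.15,
    "margin": 0.55,
    "lesion_dim_max": 0.15,
    "lesion_location": 0.12,
    "dce_abnormality": 0.15,
    "dce_enhancement": 0.12,
    "dce_corresponds_to": 0.20,
    "dce_bph_features": 0.08,
}

_EPSILON_SUFFIX_ORDER = (
    "present_and_adequate",
    "signal_intensity_type",
    "signal_intensity",
    "shape_category",
    "margin_category",
    "abnormality",
    "uniformity",
    "focality",
    "invasive",
    "shape",
    "margin",
)


@dataclass
class GeneratorConfig:
    """Study composition and noise structure for the synthetic generator."""

    #: zone -> (clinically significant, not significant) lesion counts
    composition: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"PZ": (7, 7), "TZ": (5, 6), "AFMS": (4, 3)}
    )
    #: experience group -> number of raters
    raters: Mapping[str, int] = field(
        default_factory=lambda: {"experienced": 3, "inexperienced": 3}
    )
    sessions: int = 2
    #: per-variable confusion-rate overrides (variable name or suffix class);
    #: may also be nested per group: {"experienced": {...}, ...}
    epsilon: Mapping[str, object] = field(default_factory=dict)
    #: probability that a session-2 answer repeats the session-1 answer
    rho: float = 0.8
    #: confusion model: "uniform" over the other values, or "adjacent"
    #: (ordinal CDEs confuse only neighbouring values)
    confusion: str = "uniform"
    #: lesions whose DCE series is truly unavailable/inadequate (result X)
    n_dce_unavailable: int = 2
    #: symmetric +/-1 jitter probability on derived manual categories
    category_noise: float = 0.10
    #: probability an inexperienced rater downgrades the overall category by 1
    inexperienced_downgrade: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        for zone, pair in self.composition.items():
            if zone not in LesionManifest.ZONES:
                raise ConfigError(f"composition: unknown zone {zone!r}")
            if len(pair) != 2 or any(int(c) < 0 for c in pair):
                raise ConfigError(f"composition[{zone}]: counts must be two non-negative ints")
        if not self.raters or any(int(c) < 0 for c in self.raters.values()):
            raise ConfigError("raters: group sizes must be non-negative")
        if self.sessions != 2:
            raise ConfigError("sessions: exactly two reading sessions are supported")
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigError("rho: must be in [0, 1]")
        if self.confusion not in ("uniform", "adjacent"):
            raise ConfigError("confusion: must be 'uniform' or 'adjacent'")
        for key in ("category_noise", "inexperienced_downgrade"):
            if not 0.0 <= getattr(self, key) <= 1.0:
                raise ConfigError(f"{key}: must be in [0, 1]")
        for val in _flat_eps_values(self.epsilon):
            if not 0.0 <= float(val) <= 1.0:
                raise ConfigError("epsilon: confusion rates must be in [0, 1]")

    @property
    def n_lesions(self) -> int:
        return sum(a + b for a, b in self.composition.values())


def _flat_eps_values(eps: Mapping[str, object]):
    for v in eps.values():
        if isinstance(v, Mapping):
            yield from _flat_eps_values(v)
        else:
            yield v


@dataclass(frozen=True)
class LatentProfile:
    """Ground-truth CDE values and true PI-RADS scores for one lesion."""

    lesion_id: str
    zone: str
    clinically_significant: bool
    values: Mapping[str, str]
    true_scores: Mapping[str, object]


@dataclass(frozen=True)
class SyntheticStudy:
    """Everything :func:`generate_study` produces."""

    manifest: tuple[LesionManifest, ...]
    profiles: tuple[LatentProfile, ...]
    reports: tuple[LesionReport, ...]
    rater_groups: Mapping[str, str]  # rater_id -> experience group
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# latent-truth prevalences, conditional on (zone handled via location only,
# clinical significance)
# ---------------------------------------------------------------------------

def _prevalences(significant: bool) -> dict[str, dict[str, float]]:
    if significant:
        return {
            "lesion_dim_max": {"<5": 0.05, "≥5": 0.45, "≥15": 0.50},
            "t2w_abnormality": {"YES": 0.98, "NO": 0.02},
            "t2w_invasive": {"YES": 0.35, "NO": 0.65},
            "t2w_signal_intensity_type": {"Hypointense": 0.95, "Isointense": 0.04, "Hyperintense": 0.01},
            "t2w_signal_intensity": {"Mild": 0.03, "Moderate": 0.57, "Marked": 0.40},
            "t2w_uniformity": {"Homogeneous": 0.85, "Heterogeneous": 0.15},
            "t2w_focality": {"YES": 0.95, "NO": 0.05},
            "t2w_shape": {"Linear": 0.04, "Wedge": 0.06, "Lenticular": 0.65, "Water-Drop": 0.25},
            "t2w_margin": {
                "Indistinct": 0.25, "Obscured": 0.15, "Spiculated": 0.30,
                "Erased charcoal sign": 0.10, "Partly_Encapsulated": 0.10,
                "Encapsulated": 0.05, "Well_Defined": 0.05,
            },
            "abnormality_diffusion": {"YES": 0.98, "NO": 0.02},
            "signal_intensity_diffusion": {"Mild": 0.01, "Moderate": 0.09, "Marked": 0.90},
            "dce_abnormality": {"YES": 0.90, "NO": 0.10},
            "dce_enhancement": {"Positive_DCE": 0.90, "Negative_DCE": 0.10},
            "dce_corresponds_to": {"T2": 0.40, "DWI": 0.55, "Not_Available": 0.05},
            "dce_bph_features": {"YES": 0.10, "NO": 0.90},
        }
    return {
        "lesion_dim_max": {"<5": 0.30, "≥5": 0.60, "≥15": 0.10},
        "t2w_abnormality": {"YES": 0.80, "NO": 0.20},
        "t2w_invasive": {"YES": 0.03, "NO": 0.97},
        "t2w_signal_intensity_type": {"Hypointense": 0.60, "Isointense": 0.30, "Hyperintense": 0.10},
        "t2w_signal_intensity": {"Mild": 0.50, "Moderate": 0.40, "Marked": 0.10},
        "t2w_uniformity": {"Homogeneous": 0.50, "Heterogeneous": 0.50},
        "t2w_focality": {"YES": 0.60, "NO": 0.40},
        "t2w_shape": {"Linear": 0.30, "Wedge": 0.30, "Lenticular": 0.25, "Water-Drop": 0.15},
        "t2w_margin": {
            "Indistinct": 0.10, "Obscured": 0.10, "Spiculated": 0.03,
            "Erased charcoal sign": 0.02, "Partly_Encapsulated": 0.20,
            "Encapsulated": 0.30, "Well_Defined": 0.25,
        },
        "abnormality_diffusion": {"YES": 0.75, "NO": 0.25},
        "signal_intensity_diffusion": {"Mild": 0.50, "Moderate": 0.40, "Marked": 0.10},
        "dce_abnormality": {"YES": 0.50, "NO": 0.50},
        "dce_enhancement": {"Positive_DCE": 0.40, "Negative_DCE": 0.60},
        "dce_corresponds_to": {"T2": 0.40, "DWI": 0.40, "Not_Available": 0.20},
        "dce_bph_features": {"YES": 0.50, "NO": 0.50},
    }


def _draw(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    values = list(dist)
    probs = np.asarray([dist[v] for v in values], dtype=float)
    probs = probs / probs.sum()
    return values[int(rng.choice(len(values), p=probs))]


def _truth_dist(var: str, prev: dict, zone: str) -> dict[str, float] | None:
    """Prevalence distribution for a variable (None -> deterministic)."""
    if var == "lesion_location":
        # AFMS lesions are reported under TZ (the report-form zone CDE has
        # no AFMS value; anterior stromal lesions follow the TZ pathway)
        loc = "PZ" if zone == "PZ" else "TZ"
        return {loc: 1.0}
    if var.endswith("present_and_adequate"):
        return {"YES": 1.0}
    if var in ("adc_abnormality", "dwi_abnormality"):
        return prev["abnormality_diffusion"]
    if var in ("adc_invasive", "dwi_invasive"):
        return prev["t2w_invasive"]
    if var == "adc_signal_intensity_type":
        return {"Hypointense": 0.95, "Isointense": 0.04, "Hyperintense": 0.01}
    if var == "dwi_signal_intensity_type":
        return {"Hyperintense": 0.95, "Isointense": 0.04, "Hypointense": 0.01}
    if var in ("adc_signal_intensity", "dwi_signal_intensity"):
        return prev["signal_intensity_diffusion"]
    if var in ("adc_focality", "dwi_focality"):
        return prev["t2w_focality"]
    if var in ("adc_shape", "dwi_shape"):
        return prev["t2w_shape"]
    if var in prev:
        return prev[var]
    return None


def _latent_values(
    rng: np.random.Generator, schema: CdeSchema, zone: str, significant: bool,
    dce_available: bool,
) -> dict[str, str]:
    prev = _prevalences(significant)
    # lesion-level latents shared across modalities: a lesion has one shape
    # and one degree of diffusion restriction, seen on T2W/ADC/DWI alike
    shared_shape = _draw(rng, prev["t2w_shape"])
    shared_diffusion_si = _draw(rng, prev["signal_intensity_diffusion"])
    values: dict[str, str] = {}
    for var in schema:
        if not var.applicable(values):
            values[var.name] = NA
            continue
        if var.name == "dce_present_and_adequate" and not dce_available:
            values[var.name] = "NO"
            continue
        if var.name in ("t2w_shape", "adc_shape", "dwi_shape"):
            values[var.name] = shared_shape
            continue
        if var.name in ("adc_signal_intensity", "dwi_signal_intensity"):
            values[var.name] = shared_diffusion_si
            continue
        dist = _truth_dist(var.name, prev, zone)
        if dist is not None:
            values[var.name] = _draw(rng, dist)
        elif var.name.endswith("shape_category"):
            values[var.name] = categorize_shape(values[var.name.replace("_category", "")])
        elif var.name.endswith("margin_category"):
            values[var.name] = categorize_margin(values[var.name.replace("_category", "")])
        else:  # pragma: no cover - every schema variable is handled above
            raise ConfigError(f"no truth model for variable {var.name!r}")
    return values


# ---------------------------------------------------------------------------
# the rater confusion channel
# ---------------------------------------------------------------------------

def epsilon_for(variable: str, group: str, config: GeneratorConfig) -> float:
    """Resolve the confusion rate for a variable and experience group.

    Precedence: exact variable name (per group, then global overrides), then
    DCE-specific class, then suffix class, in ``DEFAULT_EPSILON``.
    """
    group_over = config.epsilon.get(group, {})
    sources = [group_over if isinstance(group_over, Mapping) else {}, config.epsilon]
    for src in sources:
        if variable in src and not isinstance(src[variable], Mapping):
            return float(src[variable])
    keys = [variable]
    if variable.startswith("dce_") and variable in DEFAULT_EPSILON:
        keys.append(variable)
    keys += [s for s in _EPSILON_SUFFIX_ORDER if variable.endswith(s)]
    for key in keys:
        for src in sources:
            if key in src and not isinstance(src[key], Mapping):
                return float(src[key])
        if key in DEFAULT_EPSILON:
            return float(DEFAULT_EPSILON[key])
    raise ConfigError(f"no confusion rate defined for variable {variable!r}")


def confuse(
    rng: np.random.Generator,
    target: str,
    domain: Sequence[str],
    eps: float,
    ordinal: bool = False,
    mode: str = "uniform",
) -> str:
    """One pass through the confusion channel."""
    if len(domain) < 2 or eps <= 0 or rng.random() >= eps:
        return target
    if mode == "adjacent" and ordinal:
        i = list(domain).index(target)
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < len(domain)]
        return domain[neighbours[int(rng.integers(len(neighbours)))]]
    others = [v for v in domain if v != target]
    return others[int(rng.integers(len(others)))]


def simulate_ratings(
    truth: Sequence[str],
    domain: Sequence[str],
    eps: float,
    n_raters: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Low-level helper: independent symmetric-confusion ratings of ``truth``.

    Returns an array of shape (len(truth), n_raters).  This is the channel
    whose two-rater agreement has the closed form
    ``(1 - eps)**2 + eps**2 / (q - 1)``.
    """
    out = np.empty((len(truth), n_raters), dtype=object)
    for i, t in enumerate(truth):
        for j in range(n_raters):
            out[i, j] = confuse(rng, t, domain, eps)
    return out


def expected_pairwise_pa(eps: float, q: int) -> float:
    """Expected two-rater percent agreement under symmetric confusion.

    Both raters are correct with probability (1 - eps)^2; both err to the
    same of the q - 1 alternatives with probability eps^2 / (q - 1).
    """
    if q < 2:
        raise ValueError(f"q must be >= 2, got {q}")
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"eps must be in [0, 1], got {eps}")
    return (1.0 - eps) ** 2 + eps**2 / (q - 1)


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def _rate_once(
    rng: np.random.Generator,
    schema: CdeSchema,
    truth: Mapping[str, str],
    prev: dict,
    zone: str,
    group: str,
    config: GeneratorConfig,
    previous: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Generate one complete, schema-valid rating pass.

    ``previous`` (the same rater's session-1 answers) enables the
    intra-session consistency channel: each applicable value repeats the
    previous answer with probability ``rho``.
    """
    values: dict[str, str] = {}
    for var in schema:
        if not var.applicable(values):
            values[var.name] = NA
            continue
        if previous is not None:
            prev_val = previous.get(var.name)
            if prev_val is not None and prev_val != NA and rng.random() < config.rho:
                values[var.name] = prev_val
                continue
        target = truth.get(var.name)
        if target is None or target == NA:
            dist = _truth_dist(var.name, prev, zone)
            target = _draw(rng, dist) if dist is not None else var.domain[0]
        if target not in var.domain:  # truth not representable (defensive)
            target = var.domain[0]
        values[var.name] = confuse(
            rng, target, var.domain,
            epsilon_for(var.name, group, config),
            ordinal=var.ordinal, mode=config.confusion,
        )
    return values


def _manual_categories(
    rng: np.random.Generator,
    report_values: Mapping[str, str],
    zone: str,
    group: str,
    config: GeneratorConfig,
    table: RuleTable,
) -> dict[str, object]:
    scores = score_report(
        LesionReport(lesion_id="_", rater_id="_", session=1, values=dict(report_values)),
        zone,
        table,
    ).as_dict()
    for key in ("t2w", "dwi", "overall"):
        if config.category_noise > 0 and rng.random() < config.category_noise:
            step = -1 if rng.random() < 0.5 else 1
            scores[key] = int(np.clip(scores[key] + step, 1, 5))
    if group == "inexperienced" and rng.random() < config.inexperienced_downgrade:
        scores["overall"] = max(1, scores["overall"] - 1)
    return scores


def generate_study(
    config: GeneratorConfig | None = None,
    schema: CdeSchema | None = None,
    table: RuleTable | None = None,
) -> SyntheticStudy:
    """Generate a complete synthetic reader study.

    Deterministic given ``config.seed``; every generated report validates
    strictly against the schema.
    """
    config = config if config is not None else GeneratorConfig()
    config.validate()
    schema = schema or load_schema()
    table = table or default_rule_table()
    rng = np.random.default_rng(config.seed)

    manifest: list[LesionManifest] = []
    for zone in ("PZ", "TZ", "AFMS"):
        cs, non = config.composition.get(zone, (0, 0))
        for _ in range(int(cs)):
            manifest.append(LesionManifest(f"L{len(manifest)+1:03d}", zone, True))
        for _ in range(int(non)):
            manifest.append(LesionManifest(f"L{len(manifest)+1:03d}", zone, False))

    dce_unavailable = set()
    if config.n_dce_unavailable > 0 and manifest:
        k = min(config.n_dce_unavailable, len(manifest))
        picks = rng.choice(len(manifest), size=k, replace=False)
        dce_unavailable = {manifest[int(i)].lesion_id for i in picks}

    profiles: list[LatentProfile] = []
    for lesion in manifest:
        values = _latent_values(
            rng, schema, lesion.zone, lesion.clinically_significant,
            dce_available=lesion.lesion_id not in dce_unavailable,
        )
        true_scores = score_report(
            LesionReport(lesion.lesion_id, "_truth", 1, values=values),
            lesion.zone, table,
        ).as_dict()
        profiles.append(
            LatentProfile(
                lesion_id=lesion.lesion_id,
                zone=lesion.zone,
                clinically_significant=lesion.clinically_significant,
                values=values,
                true_scores=true_scores,
            )
        )

    rater_groups: dict[str, str] = {}
    for group, count in config.raters.items():
        for i in range(int(count)):
            rater_groups[f"{group[:3]}_{i+1}"] = group

    reports: list[LesionReport] = []
    for profile in profiles:
        prev_dists = _prevalences(profile.clinically_significant)
        for rater, group in rater_groups.items():
            s1 = _rate_once(rng, schema, profile.values, prev_dists, profile.zone, group, config)
            s2 = _rate_once(
                rng, schema, profile.values, prev_dists, profile.zone, group, config,
                previous=s1,
            )
            for session, values in ((1, s1), (2, s2)):
                reports.append(
                    LesionReport(
                        lesion_id=profile.lesion_id,
                        rater_id=rater,
                        session=session,
                        values=values,
                        categories=_manual_categories(
                            rng, values, profile.zone, group, config, table
                        ),
                    )
                )

    return SyntheticStudy(
        manifest=tuple(manifest),
        profiles=tuple(profiles),
        reports=tuple(reports),
        rater_groups=rater_groups,
        config=dataclasses.replace(config),
    )
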