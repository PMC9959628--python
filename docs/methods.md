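# Methods

This note documents the models, numerical choices, and limitations behind
the package: the CDE report schema, the scoring rule table, the agreement
statistics, the synthetic reader-study generator, and the study-level
analyses.

## The CDE report schema

A structured report is a mapping from 34 named categorical variables to
values, grouped as GLOBAL (lesion size bin, zone), T2W (11 variables), ADC
(8), DWI (8) and DCE (5).  Value domains are fixed; most variables carry a
RadLex term.  Three storage states are distinguished everywhere:

* a **populated** value (in the variable's domain),
* a **missing** value (the reader did not answer; key absent),
* a **not-applicable** value (sentinel `NA`): the variable's applicability
  condition fails, e.g. all T2W descriptors when
  `t2w_abnormality = NO`, or `dce_corresponds_to` when enhancement is
  negative.

Applicability is a chain (`present_and_adequate` → `abnormality` →
descriptors) and is evaluated transitively: a descriptor whose parent is
itself inapplicable is inapplicable, whatever value the parent holds.
Strict validation requires every applicable variable to be populated and
every inapplicable one to be absent or `NA`; partial validation checks only
what is populated.  Violations are returned as data (variable, value,
rule), never raised.

Two design points:

* **Shape dialects.**  The shape vocabulary exists in two versions — a
  4-value report-form list (Linear, Wedge, Lenticular, Water-Drop) and the
  8-value narrative lexicon (round, oval, lenticular, lobulated,
  tear-shaped, wedge-shaped, linear, irregular).  The schema ships both as
  selectable dialects; the simplification map to the three shape *types*
  (linear / round / irregular) is total and surjective on the union of both
  vocabularies (wedge-shaped lesions group with linear; oval, lenticular
  and tear-drop shapes with round; lobulated with irregular).
* **Margins.**  Margin values group into circumscribed (encapsulated,
  partly-encapsulated, well-defined) and non-circumscribed (indistinct,
  obscured, spiculated, erased charcoal sign).  "Encapsulated" is assigned
  to circumscribed: a visible capsule is the defining feature of a
  circumscribed margin.
* **Zone encoding.**  The report-level zone CDE has no AFMS value, so the
  manifest carries the true zone (PZ / TZ / AFMS) as a separate field;
  anterior fibromuscular stroma lesions are reported under TZ and scored
  with the TZ rule set, the conventional pathway for anterior stromal
  lesions.
* **Spelling aliases.**  The ADC signal-intensity-type values are
  normalized to Hypointense/Isointense/Hyperintense, with the legacy
  "-intensitivity" spellings (and ASCII `>=5`/`>=15` size bins) accepted as
  input aliases.

## The scoring rule table

The PI-RADS v2.1 guidelines are encoded as data: a JSON document with one
block per target (T2W score, DWI score, DCE result, overall category).
Each block declares a small derived feature space — simplified shape and
margin types, signal scales, the size bin, the zone group, with `na_if`
applicability — and an ordered list of rules, each a conjunction of
set-membership constraints.  The rules were authored as a flattened
decision tree, so they are mutually exclusive and complete by construction;
`check_rule_table` *proves* this for any table by enumerating the full
applicable feature product (≈ 4 200 combinations for the shipped table) and
reporting gaps and conflicts.

Engine semantics worth stating explicitly:

* A reader's own `*_shape_category` / `t2w_margin_category` takes
  precedence over the category derived from their raw shape/margin value
  (the two can disagree; the category CDE is the reader's judgement).
* Score 5 on T2W and DWI requires the score-4 findings **plus** size
  ≥ 15 mm or invasive behaviour; invasiveness on either diffusion map
  counts for the DWI pathway.
* The DCE result is X exactly when `dce_present_and_adequate = NO`;
  positivity additionally requires a T2/DWI correlate and absence of BPH
  features (focal early enhancement attributable to a hyperplastic nodule
  does not count).
* Overall category: PZ is DWI-dominant (DCE upgrades DWI 3 to 4); TZ/AFMS
  is T2W-dominant with the two DWI exceptions (T2W 2 with DWI ≥ 4 → 3,
  T2W 3 with DWI 5 → 4).  An unavailable DCE (X) never upgrades.
  Verified properties (by enumeration, in the test suite): the DCE result
  moves the overall category only at (PZ, DWI = 3); raising the size bin
  never lowers any score; the overall category is monotone in the
  per-sequence scores.
* Incomplete reports are refused with the list of missing CDEs; the
  lenient `score_range` instead returns every score compatible with the
  observed values (useful while a form is being filled in).
* The interpretation of "invasiveness" is contested among readers (strict
  extraprostatic extension vs. extension into neighbouring zones/sectors);
  the engine treats `invasive = YES` as the score-5 criterion and leaves
  the semantic dispute to the reader instructions, not the code.

## Agreement statistics

For a subjects × raters categorical matrix with counts r_ik:

* **PA**: mean over subjects (with ≥ 2 ratings) of
  Σ_k r_ik(r_ik−1) / [r_i(r_i−1)] — the probability that a random pair of
  ratings of the same subject agrees.
* **AC1**: (pa − pe)/(1 − pe) with pe = Σ_k π_k(1 − π_k)/(q − 1) and
  π_k the mean share of ratings in category k.  Since pe ≤ 1/q ≤ 1/2, AC1
  is bounded below by 2·pa − 1 for q = 2 (prevalence-paradox resistance).
* **Variance**: Gwet's first-order linearization with subjects treated as
  a random sample and raters fixed; no finite-population correction.
  Confidence intervals and the AC1 = 0 test use Student's t with n − 1
  degrees of freedom; the upper CI limit is truncated at 1, and
  interpretation bands are applied to the point estimate only.
  A delete-one jackknife estimator is provided as an independent
  cross-check; the two agree in aggregate (both are unbiased against
  Monte-Carlo sampling variance) but differ per matrix by O(1/n), which at
  n ≈ 5 can reach tens of percent — a property of the estimators, not an
  implementation defect.  Under independent uniform ratings (32 subjects,
  2 raters) the AC1 = 0 test rejects at ≈ 4–5% at the nominal 5% level.
* **Missing cells**: subjects rated fewer than twice contribute to the
  propensities π_k but not to pa.  The not-applicable sentinel, when it
  occurs in a rating matrix, is an ordinary category: disagreement about
  applicability is disagreement.
* **Multi-rater summaries**: the paper-style "mean of rater pairs" computes
  two-rater PA/AC1 for every unordered pair on their co-rated subjects and
  averages; its CI comes from the across-pair dispersion (t, m − 1 df).
  Intra-rater agreement forms a two-column (session 1 vs session 2) matrix
  per rater.
* **Wilcoxon signed-rank**: zero differences dropped; for ≤ 25 non-zero
  pairs the null distribution of W+ is enumerated exactly with midranks
  for tied magnitudes (dynamic programming over doubled ranks — the exact
  method of standard libraries rejects ties); beyond that, the
  tie-corrected normal approximation.  The statistic reported is W+, the
  sum of positive ranks.

## The synthetic reader-study generator

The generator emulates a two-session, six-reader study over 32 lesions
(14 PZ = 7 significant + 7 not, 11 TZ = 5 + 6, 7 AFMS = 4 + 3) — the
composition is configurable and reproduced exactly in the output manifest.

**Latent truth.**  Each lesion draws a complete, schema-valid CDE profile
from category prevalences conditional on clinical significance, with two
lesion-level latents shared across modalities (one shape, one degree of
diffusion restriction).  Significant lesions are predominantly true
category 4–5 (they model histopathology-confirmed, conspicuous lesions);
non-significant lesions concentrate at 2–3, which keeps specificity low at
the ≥ 3 operating point, as in real PI-RADS practice.  Two lesions per
study (configurable) have a truly unavailable DCE series, so the X outcome
occurs.  True PI-RADS scores are derived from the truth through the rule
engine.

**Observation channel.**  Session 1: each applicable variable is reported
correctly with probability 1 − ε_f, else confused — uniformly over the
other q − 1 domain values by default, or over adjacent values for ordinal
CDEs in the optional `adjacent` mode.  Session 2 repeats the session-1
answer with probability ρ (default 0.8) and is otherwise regenerated.
Generation runs top-down through the applicability chain, so every report
validates strictly.  Default ε_f values encode the qualitative difficulty
ordering of the features: ~0 for image adequacy, 0.03–0.08 for
detection-type and signal-type judgements, ≈ 0.15–0.2 for focality,
invasiveness, size and zone, and 0.3–0.55 for the subjective shape, margin
and signal-level descriptors.  Under this channel two readers agree on a
feature with probability (1−ε)² + ε²/(q−1), the closed form used for
parameter-recovery checks.

**Manual categories and the experience effect.**  Each reader's manual
PI-RADS categories are derived from their own noisy CDE values through the
rule engine (the workflow coupling), then jittered by ±1 with probability
0.10, and — for inexperienced readers — downgraded one category with
probability 0.35, the minimal mechanism for the observation that less
experienced readers under-call significant lesions.

**What the generator does and does not emulate.**  It reproduces the
study's composition and the qualitative structure of its findings:
detection features agree far better than subjective descriptors; the
simplified shape/margin categories agree better than the raw values; the
three-outcome DCE variable shows higher raw agreement than the
five-category overall; the small AFMS stratum yields wider CIs; experienced
readers score significant lesions higher and separate them slightly better.
It does **not** reproduce absolute levels from human studies: because
derived categories compound the feature-level noise through conjunctive
rules, mean overall categories on significant lesions sit near 3 (human
readers, who assign categories holistically, sit near 4.5), and recall at
the ≥ 3 threshold is correspondingly lower.  Passing tests therefore
demonstrate correct mechanics and qualitative fidelity, not calibration to
any particular reader population.  Real data also contain features the
channel lacks: correlated errors between readers, lesion-specific
difficulty, and reader drift between sessions.

## Study-level analyses

* **Per-CDE tables**: one row per analyzed feature (the 34 CDEs plus the
  derived "size ≥ 15 mm" indicator), with mean pairwise PA (%), mean AC1,
  a 95% CI from the across-pair dispersion, a t-test of mean AC1 = 0, and
  the band.  Strata: session 1 / 2 / overall × all / experienced /
  inexperienced × all / PZ / TZ / AFMS.  The "overall" session stratum
  pools both sessions as additional replicate pairs (30 pair-sessions for
  six raters); `pooling="mean"` averages the per-session means instead,
  in which case the overall value lies between the session values.
* **Category tables**: the four category variables (T2W, DWI, DCE,
  overall), inter-rater per session and pooled, intra-rater per experience
  group (session 1 vs 2 per rater, averaged within group).
* **Group score comparison**: the pairing unit is the lesion — each
  clinically significant lesion contributes the mean overall category of
  each group (both sessions pooled), compared by the Wilcoxon signed-rank
  test; group means/SDs are reported over the individual ratings.  With 16
  significant lesions and the default noise, a full one-category downgrade
  is detected essentially always, a 50%-probability downgrade in about
  two-thirds of replicates (simulated detection rates: 0.99 and 0.63;
  null rate 0.025).
* **Diagnostic accuracy**: predictions are overall ≥ threshold (default 3);
  recall, precision and specificity come from the confusion counts; AUC
  uses the ordinal 1–5 score via the rank (Mann–Whitney) formulation with
  tie handling.  AUC is computed per rater (sessions pooled) and averaged
  within experience group; a pooled-ratings variant is available behind a
  flag.  Raising the threshold can only lower recall and raise
  specificity; AUC is invariant under monotone transforms of the scores.

## Problem sizes and reproducibility

All simulations are driven by a single integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical studies,
tables and JSON outputs.  The shipped test suite and the acceptance script
use 2 000 replicates for null calibration, 2 000 subjects for
parameter recovery, 40–60 study replicates for the qualitative-contrast
checks, and full enumeration (≈ 4 200 combinations) for the rule-table
audits.

## Known limitations

* The rule table encodes one defensible reading of the v2.1 narrative;
  guideline points that are disputed in the field (the DWI TZ score-2
  wording, the meaning of invasiveness) are resolved explicitly and
  documented above rather than exposed as options.
* AC1 is the only chance-corrected coefficient implemented (no weighted
  AC2, no Cohen/Fleiss kappa); ordinal category distance is ignored in
  agreement, by design.
* The generator's confusion channels are independent across readers and
  features; real reader error is correlated.
* `lesion_dim_max` is an ordinal bin, not a measurement; size-based
  criteria inherit the bin boundaries (5 mm, 15 mm).
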