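# pirads-cde

Structured PI-RADS v2.1 prostate-MRI reporting with common data elements
(CDEs), a declarative category rule engine, and chance-corrected
reader-agreement analysis.

## The problem

Prostate multiparametric MRI (mpMRI) is read with the PI-RADS v2.1 system:
each lesion receives per-sequence scores (T2-weighted imaging, diffusion/ADC,
dynamic contrast enhancement) that combine, through zone-dependent
dominant-sequence logic, into an overall assessment category 1–5.  The
narrative guidelines leave room for interpretation, and inter-reader
variability is a known weakness.  One way to study (and reduce) that
variability is to decompose the lexicon into *common data elements* — named
categorical variables with fixed value domains, most of them mapped to
RadLex terms — so that every low-level judgement a reader makes (abnormality
present? signal intensity level? margin type? ...) becomes a separately
analysable datum.

This package is for researchers running or simulating multi-reader
multi-case (MRMC) agreement studies on structured prostate reports.  It
provides:

* **`pirads_cde.schema`** — the 34-variable CDE report vocabulary (value
  domains, RadLex terms, conditional applicability), report validation, and
  the shape/margin simplifications (8/4-value shape lexicon → linear /
  round / irregular; margins → circumscribed / non-circumscribed);
* **`pirads_cde.engine`** — a CDE → PI-RADS v2.1 scoring engine whose rules
  ship as declarative JSON and are verified by exhaustive enumeration to
  fire exactly once for every complete report (plus a lenient mode giving
  the score range compatible with a partial report);
* **`pirads_cde.agreement`** — percent agreement (PA) and Gwet's
  first-order agreement coefficient AC1 with linearized variance,
  confidence intervals, a test of AC1 = 0, interpretation bands, pairwise
  and test–retest (intra-rater) forms, and a tie-aware exact Wilcoxon
  signed-rank test;
* **`pirads_cde.study`** — the study-level tables: per-CDE inter-rater
  agreement stratified by session / experience group / prostate zone,
  PI-RADS category agreement (inter and intra), between-group score
  comparison, and diagnostic accuracy (AUC, recall, precision, specificity)
  of the overall category at an ordinal threshold;
* **`pirads_cde.simulate`** — a synthetic MRMC study generator (latent
  lesion profiles, per-feature confusion channels, session-to-session
  consistency) so every analysis stage is testable end to end;
* a thin CLI, `pirads-cde`, with `validate`, `score`, `simulate`,
  `agreement` and `analyze` subcommands.

## The statistic at the core

For n subjects, raters assigning categories k = 1..q with r_ik raters
placing subject i in category k (r_i ratings on subject i):

    pa  = mean over subjects of  Σ_k r_ik (r_ik − 1) / [ r_i (r_i − 1) ]
    π_k = (1/n) Σ_i r_ik / r_i
    pe  = (1/(q−1)) Σ_k π_k (1 − π_k)
    AC1 = (pa − pe) / (1 − pe)

Because pe ≤ 1/q, AC1 resists the prevalence paradox that drives kappa
towards zero for skewed categories.  The variance is Gwet's first-order
linearization (subjects sampled, raters fixed), with Student-t confidence
intervals and a delete-one jackknife as an independent cross-check.
Agreement bands: excellent (> 0.80), good (0.61–0.80), moderate
(0.41–0.60), fair (0.21–0.40), poor (≤ 0.20).

## Worked example

```python
from pirads_cde import RatingMatrix, gwet_ac1

reader1 = ["a", "a", "a", "a", "a", "a", "b", "b", "a", "b"]
reader2 = ["a", "a", "a", "a", "a", "a", "b", "b", "b", "a"]
result = gwet_ac1(RatingMatrix.from_columns([reader1, reader2]))
```

Running `python examples/agreement_basics.py` prints:

```
percent agreement : 80.0%
chance agreement  : 0.420
AC1               : 0.6552
95% CI            : (0.082, 1.000)
p (AC1 = 0)       : 0.0294
interpretation    : good
```

Eight of ten lesions are concordant (pa = 0.8); with category propensities
0.7/0.3 the chance term is 2·0.7·0.3 = 0.42, giving
AC1 = (0.8 − 0.42)/0.58 = 0.655 — "good" agreement after chance correction.

Scoring a complete structured report (`python examples/score_a_report.py` —
a focal, homogeneous, moderately hypointense PZ lesion with marked
diffusion restriction and matching enhancement):

```
T2W score:        4
DWI score:        4
DCE result:       Positive
overall category: 4
```

The other examples generate a full synthetic six-reader study and run every
analysis table (`examples/simulate_and_analyze.py`), and audit the shipped
rule table by exhaustive enumeration (`examples/rule_table_audit.py`).

The same pipeline from the shell:

```sh
pirads-cde simulate --seed 7 --out-dir out/sim
pirads-cde validate out/sim/reports.json
pirads-cde score out/sim/reports.json --manifest out/sim/manifest.csv --out out/scores.csv
pirads-cde analyze out/sim/reports.json --manifest out/sim/manifest.csv \
    --raters out/sim/raters.csv --out-dir out/analysis
```

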