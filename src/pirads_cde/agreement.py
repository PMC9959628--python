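"""Chance-corrected reader-agreement statistics.

The central quantity is Gwet's first-order agreement coefficient AC1,

    AC1 = (pa - pe) / (1 - pe),

where ``pa`` is the observed pairwise percent agreement and the chance term
uses the category propensities ``pi_k`` (the average share of ratings falling
in category k):

    pe = (1 / (q - 1)) * sum_k pi_k * (1 - pi_k).

Unlike Cohen/Fleiss kappa, ``pe`` is bounded by 1/q, which makes AC1 robust
to the prevalence paradox: highly skewed category prevalences cannot push the
chance term towards 1.

Subjects are treated as a random sample and raters as fixed; the variance is
Gwet's first-order linearization (no finite-population correction), with
confidence intervals and the AC1 = 0 test based on Student's t with n - 1
degrees of freedom.  A delete-one jackknife estimator is provided as an
independent cross-check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, DegenerateDataError, InsufficientDataError

#: Agreement interpretation bands applied to the AC1 point estimate.
BANDS = (
    (0.80, "excellent"),   # > 0.80
    (0.60, "good"),        # > 0.60
    (0.40, "moderate"),    # > 0.40
    (0.20, "fair"),        # > 0.20
    (-math.inf, "poor"),   # <= 0.20
)


class RatingMatrix:
    """A subjects x raters table of categorical ratings for a single item.

    Cells may be missing (``None``/``NaN``); the not-applicable sentinel, if
    present, is an ordinary category (disagreement about applicability is
    disagreement).  ``categories`` fixes the category list q; by default it
    is the sorted set of observed values.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        categories: Sequence | None = None,
    ) -> None:
        self.data = data.map(lambda v: np.nan if _is_missing(v) else str(v))
        observed = sorted({v for v in self.data.values.ravel() if not _is_missing(v)})
        if categories is None:
            self.categories = tuple(observed)
        else:
            self.categories = tuple(str(c) for c in categories)
            extra = set(observed) - set(self.categories)
            if extra:
                raise ValueError(f"ratings outside the declared categories: {sorted(extra)}")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_columns(
        cls,
        columns: Sequence[Sequence],
        subjects: Sequence | None = None,
        raters: Sequence[str] | None = None,
        categories: Sequence | None = None,
    ) -> "RatingMatrix":
        """Build from per-rater columns of equal length."""
        raters = list(raters) if raters is not None else [f"R{i+1}" for i in range(len(columns))]
        n = len(columns[0])
        subjects = list(subjects) if subjects is not None else list(range(1, n + 1))
        df = pd.DataFrame({r: list(c) for r, c in zip(raters, columns)}, index=subjects)
        return cls(df, categories=categories)

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        subject_col: str = "subject",
        rater_col: str = "rater",
        value_col: str = "value",
        categories: Sequence | None = None,
    ) -> "RatingMatrix":
        wide = df.pivot(index=subject_col, columns=rater_col, values=value_col)
        return cls(wide, categories=categories)

    # -- basic properties -------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(self.data.index)

    @property
    def raters(self) -> list:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data.index)

    @property
    def q(self) -> int:
        return len(self.categories)

    def counts(self) -> np.ndarray:
        """r_ik: subjects x categories matrix of rating counts."""
        vals = self.data.to_numpy(dtype=object)
        out = np.empty((self.n_subjects, self.q))
        for j, c in enumerate(self.categories):
            out[:, j] = (vals == c).sum(axis=1)
        return out

    def select(self, raters: Sequence[str]) -> "RatingMatrix":
        return RatingMatrix(self.data[list(raters)], categories=self.categories)

    def drop_unrated(self) -> "RatingMatrix":
        """Drop subjects with fewer than one rating."""
        mask = self.counts().sum(axis=1) >= 1
        return RatingMatrix(self.data.loc[mask], categories=self.categories)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class AgreementResult:
    """Percent agreement and AC1 with uncertainty for one rating matrix."""

    pa: float
    pe: float
    ac1: float
    variance: float
    ci_low: float
    ci_high: float
    p_value: float
    n_subjects: int
    band: str

    @property
    def pa_percent(self) -> float:
        return 100.0 * self.pa

    def as_dict(self) -> dict:
        return {
            "pa": self.pa_percent,
            "ac1": self.ac1,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "band": self.band,
            "n": self.n_subjects,
        }


def _pa_from_counts(counts: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    r_i = counts.sum(axis=1)
    multi = r_i >= 2
    if not multi.any():
        raise InsufficientDataError("no subject has two or more ratings")
    s_i = (counts * (counts - 1)).sum(axis=1)
    denom = np.where(multi, r_i * (r_i - 1), 1.0)
    pa_i = np.where(multi, s_i / denom, 0.0)
    pa = pa_i[multi].mean()
    return pa, pa_i, r_i


def percent_agreement(matrix: RatingMatrix) -> float:
    """Mean over subjects of the proportion of concordant rating pairs."""
    pa, _, _ = _pa_from_counts(matrix.drop_unrated().counts())
    return float(pa)


def interpret_band(ac1_value: float) -> str:
    """Interpretation band for an AC1 point estimate.

    excellent > 0.80 >= good > 0.60 >= moderate > 0.40 >= fair > 0.20 >= poor
    (the published thresholds; 0.81 is the smallest printed 'excellent'
    value, so the open interval above 0.80 is labelled excellent).
    """
    for lo, name in BANDS:
        if ac1_value > lo:
            return name
    return "poor"


def gwet_ac1(matrix: RatingMatrix, ci_level: float = 0.95) -> AgreementResult:
    """Gwet's AC1 with linearized variance, CI, and test of AC1 = 0.

    Subjects with fewer than two ratings contribute to the category
    propensities ``pi_k`` but not to the observed agreement ``pa``.
    """
    m = matrix.drop_unrated()
    q = m.q
    if q < 2:
        raise DegenerateDataError("AC1 requires at least two categories (q >= 2)")
    counts = m.counts()
    n = counts.shape[0]
    if n < 2:
        raise InsufficientDataError("AC1 requires at least two subjects")

    pa, pa_i, r_i = _pa_from_counts(counts)
    multi = r_i >= 2
    n_multi = int(multi.sum())

    pi_k = (counts / r_i[:, None]).mean(axis=0)
    pe = float((pi_k * (1.0 - pi_k)).sum() / (q - 1))
    if pe >= 1.0:
        raise DegenerateDataError("chance agreement pe = 1; AC1 undefined")
    ac1 = (pa - pe) / (1.0 - pe)

    # first-order linearization (subjects sampled, raters fixed, f = 0)
    ac1_i = np.where(multi, (n / n_multi) * (pa_i - pe * multi) / (1.0 - pe), 0.0)
    pe_i = (counts / r_i[:, None]) @ (1.0 - pi_k) / (q - 1)
    ac1_star = ac1_i - 2.0 * (1.0 - ac1) * (pe_i - pe) / (1.0 - pe)
    variance = float(((ac1_star - ac1) ** 2).sum() / (n * (n - 1)))
    se = math.sqrt(max(variance, 0.0))

    alpha = 1.0 - ci_level
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
    ci_low = ac1 - tcrit * se
    ci_high = min(ac1 + tcrit * se, 1.0)
    if se > 0:
        p_value = 2.0 * stats.t.sf(abs(ac1) / se, df=n - 1)
    else:
        p_value = 0.0 if ac1 != 0 else 1.0

    return AgreementResult(
        pa=float(pa),
        pe=pe,
        ac1=float(ac1),
        variance=variance,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(min(p_value, 1.0)),
        n_subjects=n,
        band=interpret_band(float(ac1)),
    )


def jackknife_variance(matrix: RatingMatrix) -> float:
    """Delete-one-subject jackknife variance of AC1 (cross-check estimator)."""
    m = matrix.drop_unrated()
    n = m.n_subjects
    if n < 3:
        raise InsufficientDataError("jackknife needs at least three subjects")
    thetas = []
    for subject in m.subjects:
        sub = RatingMatrix(m.data.drop(index=subject), categories=m.categories)
        thetas.append(_ac1_point(sub))
    thetas = np.asarray(thetas)
    return float((n - 1) / n * ((thetas - thetas.mean()) ** 2).sum())


def _ac1_point(matrix: RatingMatrix) -> float:
    counts = matrix.drop_unrated().counts()
    pa, _, r_i = _pa_from_counts(counts)
    pi_k = (counts / r_i[:, None]).mean(axis=0)
    pe = (pi_k * (1.0 - pi_k)).sum() / (matrix.q - 1)
    return float((pa - pe) / (1.0 - pe))


@dataclass(frozen=True)
class PairwiseMeanResult:
    """Across-pair mean agreement (the paper-style 'mean of rater pairs')."""

    mean_pa: float
    mean_ac1: float
    ci_low: float
    ci_high: float
    per_pair: pd.DataFrame
    excluded_pairs: tuple

    @property
    def n_pairs(self) -> int:
        return len(self.per_pair)


def pairwise_mean_agreement(
    matrix: RatingMatrix,
    pairs: Iterable[tuple[str, str]] | None = None,
    ci_level: float = 0.95,
) -> PairwiseMeanResult:
    """Two-rater PA and AC1 per rater pair, averaged across pairs.

    ``pairs`` defaults to all unordered rater pairs (C(m, 2)).  Each pair is
    evaluated on the subjects both raters rated; pairs with no co-rated
    subjects are excluded with a warning entry.  The CI of the mean AC1 comes
    from the across-pair dispersion (t distribution, m - 1 df).
    """
    if pairs is None:
        pairs = list(itertools.combinations(matrix.raters, 2))
    else:
        pairs = [tuple(p) for p in pairs]
    rows, excluded = [], []
    for a, b in pairs:
        sub = matrix.select([a, b])
        counts = sub.counts()
        co_rated = (counts.sum(axis=1) >= 2).sum()
        if co_rated == 0:
            excluded.append((a, b))
            continue
        res = gwet_ac1(sub, ci_level=ci_level)
        rows.append(
            {"rater_a": a, "rater_b": b, "pa": res.pa, "ac1": res.ac1, "n": res.n_subjects}
        )
    if not rows:
        raise InsufficientDataError("every rater pair lacks co-rated subjects")
    per_pair = pd.DataFrame(rows)
    mean_pa = float(per_pair["pa"].mean())
    mean_ac1 = float(per_pair["ac1"].mean())
    m = len(per_pair)
    if m > 1:
        sem = float(per_pair["ac1"].std(ddof=1)) / math.sqrt(m)
        tcrit = stats.t.ppf(1.0 - (1.0 - ci_level) / 2.0, df=m - 1)
        ci = (mean_ac1 - tcrit * sem, min(mean_ac1 + tcrit * sem, 1.0))
    else:
        ci = (-math.inf, math.inf) if m == 1 else (math.nan, math.nan)
    return PairwiseMeanResult(
        mean_pa=mean_pa,
        mean_ac1=mean_ac1,
        ci_low=ci[0],
        ci_high=ci[1],
        per_pair=per_pair,
        excluded_pairs=tuple(excluded),
    )


def intra_rater_agreement(
    session1: RatingMatrix, session2: RatingMatrix, ci_level: float = 0.95
) -> dict[str, AgreementResult]:
    """Test-retest agreement per rater between two sessions.

    For each rater a two-column matrix (session 1 vs. session 2) is formed on
    the shared subjects and PA/AC1 computed.  Both matrices must cover the
    same subjects and raters.
    """
    subj_diff = set(session1.subjects) ^ set(session2.subjects)
    rater_diff = set(session1.raters) ^ set(session2.raters)
    if subj_diff or rater_diff:
        raise AlignmentError(
            f"session matrices differ (subjects: {sorted(subj_diff)}, "
            f"raters: {sorted(rater_diff)})"
        )
    categories = tuple(sorted(set(session1.categories) | set(session2.categories)))
    out = {}
    for rater in session1.raters:
        df = pd.DataFrame(
            {
                "session1": session1.data[rater],
                "session2": session2.data.loc[session1.subjects, rater],
            },
            index=session1.subjects,
        )
        out[rater] = gwet_ac1(RatingMatrix(df, categories=categories), ci_level=ci_level)
    return out


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float       # W+: sum of ranks of positive differences
    p_value: float
    n: int                 # non-zero differences used
    method: str            # "exact" or "normal"
    z: float | None = None


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  With at most ``exact_limit`` non-zero
    pairs the null distribution of W+ is enumerated exactly (midranks for
    tied magnitudes, handled by dynamic programming over doubled ranks);
    otherwise the tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_limit:
        # exact: enumerate the 2^n sign assignments via DP over doubled ranks
        doubled = np.rint(2 * ranks).astype(int)
        total = int(doubled.sum())
        pmf = np.zeros(total + 1)
        pmf[0] = 1.0
        for r in doubled:
            shifted = np.zeros_like(pmf)
            shifted[r:] = pmf[: total + 1 - r]
            pmf = 0.5 * (pmf + shifted)
        w2 = int(round(2 * w_plus))
        cdf = pmf[: w2 + 1].sum()
        sf = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(cdf, sf))
        return WilcoxonResult(statistic=w_plus, p_value=float(p), n=n, method="exact")

    mu = ranks.sum() / 2.0
    sigma2 = float((ranks**2).sum()) / 4.0  # midranks absorb the tie correction
    z = (w_plus - mu) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return WilcoxonResult(statistic=w_plus, p_value=float(min(p, 1.0)), n=n, method="normal", z=z)
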