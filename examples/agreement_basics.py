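"""Percent agreement and Gwet's AC1 on a small two-reader matrix.

Ten lesions rated by two readers into two categories; eight concordant.
AC1 corrects the observed agreement for chance using the category
propensities, which keeps the coefficient meaningful under skewed
prevalence (where Cohen's kappa collapses).
"""

from pirads_cde import RatingMatrix, gwet_ac1, interpret_band

reader1 = ["a", "a", "a", "a", "a", "a", "b", "b", "a", "b"]
reader2 = ["a", "a", "a", "a", "a", "a", "b", "b", "b", "a"]

matrix = RatingMatrix.from_columns([reader1, reader2], raters=["reader1", "reader2"])
result = gwet_ac1(matrix)

print(f"percent agreement : {result.pa_percent:.1f}%")
print(f"chance agreement  : {result.pe:.3f}")
print(f"AC1               : {result.ac1:.4f}")
print(f"95% CI            : ({result.ci_low:.3f}, {result.ci_high:.3f})")
print(f"p (AC1 = 0)       : {result.p_value:.4f}")
print(f"interpretation    : {interpret_band(result.ac1)}")
# pa = 0.8 and pe = 2 * 0.7 * 0.3 = 0.42, so AC1 = (0.8 - 0.42)/0.58 = 0.655:
# "good" agreement after chance correction.
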