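"""Trial-flow arithmetic and the 2x2 test battery on published count tables.

These are the categorical comparisons a two-arm trial reports at baseline:
completion/dropout by arm (Fisher exact) and demographic 2x2 tables
(Pearson chi-square without continuity correction, or Fisher when counts
are small).
"""

from vftrial import chi_square_2x2, fisher_exact_2x2, flow_summary, format_p

flow = flow_summary(randomized=(41, 38), dropped=(1, 3))
print(f"randomized {flow['randomized']}, completed {flow['completed']}")
print(f"completion: {flow['completion_pct']}%")
print(f"dropout comparison (Fisher exact): "
      f"p = {flow['dropout_test']['p_formatted']}")

side = chi_square_2x2([[22, 18], [20, 15]])   # defect side by arm
sex = chi_square_2x2([[26, 14], [18, 17]])    # sex by arm
stroke = fisher_exact_2x2([[3, 37], [2, 33]]) # stroke type by arm
print(f"\ndefect side by arm:  chi2 = {side.statistic:.3f}, "
      f"p = {format_p(side.p_value)}")
print(f"sex by arm:          chi2 = {sex.statistic:.3f}, "
      f"p = {format_p(sex.p_value)}")
print(f"stroke type by arm:  Fisher p = {format_p(stroke.p_value)}")
print("\nAll null, as expected for baseline characteristics of a randomized "
      "cohort.")
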