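"""Method agreement on the packaged nine-cup reference table.

Loads the nine (CT, gravimetric) mass-loss pairs measured at two million
cycles on the hip simulator, and runs the full agreement analysis:
regression of CT on gravimetric, Bland-Altman bias and 95% limits of
agreement, Shapiro-Wilk normality of the differences, and per-specimen
percentage differences.
"""

import cupwear as cw

pairs = cw.load_table2_pairs()
report = cw.analyze_pairs(pairs)
print(report.summary())
print()
print("An R^2 near 1 says the two methods rank and scale wear the same way;")
print("the bias is how much the CT route under-reads on average (mg), and")
print("the limits of agreement bracket ~95% of expected disagreements.")
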