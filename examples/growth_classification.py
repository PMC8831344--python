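"""Calling growth on a pair of surveillance scans.

The conventional rule calls growth only above a 25% volume increase; the
measurement-variability floor for small nodules scanned under identical
parameters supports a 15% rule.  A nodule growing 20% between scans is
classified differently under the two rules — exactly the band where closer
surveillance is argued for.
"""

from nodulevar import classify_growth, fractional_growth_from_vdt, vdt_from_fractional_growth

v_prev, v_curr = 100.0, 120.0
change = (v_curr - v_prev) / v_prev * 100
print(f"nodule: {v_prev:.0f} -> {v_curr:.0f} mm^3 (+{change:.0f}%) over one quarter")
for threshold in (25.0, 15.0):
    call = classify_growth(v_prev, v_curr, threshold_pct=threshold)
    print(f"  {threshold:.0f}% rule: {call.value}")

vdt = vdt_from_fractional_growth(change / 100, 92.0)
print(f"if sustained, this is a volume doubling time of {vdt:.0f} days "
      f"({fractional_growth_from_vdt(vdt, 365.0):.0%} per year-equivalent interval)"
      " - well inside the range considered suspicious for malignancy.")
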