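"""Population Achieved Sensitivity and the break-even adoption ratio.

PAS = s_c * c * p_c * d_c / (c*p_c + (1-c)*p_nc) measures true cases found at
population scale.  Comparing two systems at shared access eliminates the
access fraction: the ratio is the adoption multiple at which a cheaper,
slightly less sensitive system identifies the same number of true cases.
"""

from drdtrial import PASInputs, pas_break_even_ratio, pas_ratio_interval, risk_annotation

predicate = PASInputs(s_c=0.872)  # desktop-camera system, pivotal-trial sensitivity
improved = PASInputs(s_c=0.815)  # handheld-camera system, this trial

ratio = pas_break_even_ratio(predicate, improved)
lo, hi = pas_ratio_interval((0.872, (0.818, 0.912)), (0.815, (0.769, 0.861)), seed=0)
print(f"break-even adoption ratio: {ratio:.2f}x  (95% MC interval {lo:.2f}-{hi:.2f})")
# If the handheld system is adopted at least 1.07x as widely as the desktop
# system, more people with true disease are identified despite its lower
# sensitivity.

risk = risk_annotation("detected")
print(
    f"a 'disease present' output carries {100 * risk.risk_pdr_3y:.1f}% 3-year risk of "
    f"proliferative retinopathy (ICD-10 {risk.icd10_category})"
)
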