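"""Person-time progression statistics from the observed cohort totals.

The surveillance cohort's printed event/exposure totals (25 progressions
over 3872 person-years for non-dysplastic Barrett's, 7/699 for LGD at the
index endoscopy, 14/642 for LGD arising during surveillance) are turned
into incidence rates per 100 person-years with exact Poisson CIs and
incidence rate ratios with exact conditional CIs.
"""

from besurv import fixture_table4, rates_table, render_report

counts = fixture_table4()
report = render_report(rates_table(counts))
print(report.to_string(index=False))
print()
print(
    "Each row: events/person-years as a rate per 100 person-years with its\n"
    "exact 95% CI, and the rate ratio against the non-dysplastic group.\n"
    "LGD found during surveillance progresses ~3.4x faster than\n"
    "non-dysplastic Barrett's; the pooled cohort rate is 0.9 per 100\n"
    "person-years."
)
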