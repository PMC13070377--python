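"""Generate a synthetic surveillance cohort and re-estimate its rates.

The generator draws per-patient exponential progression times at the
group hazards and truncated-gamma censoring matched to the observed
follow-up distribution, so the statistics module can be exercised
end-to-end without any real patient data.
"""

from besurv import (
    SyntheticCohortSpec,
    cohort_summary,
    generate_cohort,
    rates_table,
    render_report,
)

spec = SyntheticCohortSpec(seed=42)
cohort = generate_cohort(spec)
print(cohort.head().to_string(index=False))
print(f"\n{len(cohort)} patients, {cohort['person_years'].sum():.0f} person-years, "
      f"{cohort['event'].sum()} progressions\n")

report = render_report(rates_table(cohort_summary(cohort)))
print(report.to_string(index=False))
print(
    "\nWith the default spec the estimated group rates scatter around the\n"
    "generating hazards (0.65, 1.0, 2.2 per 100 person-years) within the\n"
    "sampling noise of a 914-patient cohort."
)
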