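"""Run the Markov cohort model for all four LGD management strategies.

The cohort starts in LGD (52% diagnosed at the index endoscopy, 48%
during surveillance) and is propagated through 70 half-year cycles with
costs and QALYs discounted at 5% a year. Note the shipped costs and
utilities are documented placeholders, so the currency amounts describe
this configuration, not any published analysis.
"""

from besurv import compare_to_baseline, default_spec, evaluate_strategies

spec = default_spec()
results = evaluate_strategies(spec)
table = compare_to_baseline(results, "surveillance_all_LGD", spec.wtp)
print(table.round(3).to_string(index=False))
print(
    "\nEach row: discounted cost (AUD) and QALYs per patient over 35 years,\n"
    "lifetime EAC incidence, and the ICER against surveillance-only.\n"
    "Ablating LGD found during surveillance buys QALYs at an ICER below\n"
    "the AU$50,000/QALY willingness-to-pay; ablating index LGD does not."
)
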