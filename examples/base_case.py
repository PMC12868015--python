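"""Base case: run both treatment arms of the low-risk scenario and compare.

Prints each arm's total discounted cost and QALYs over the 5-year horizon
and the incremental comparison at WTP $100,000/QALY.  "Dominant" means
cryoablation is both cheaper and more effective, so the preference does not
depend on the willingness-to-pay.
"""

from cryocea import compare, low_risk_scenario, run_cohort

scenario = low_risk_scenario()
bca = run_cohort(scenario, "bca")
bcs = run_cohort(scenario, "bcs")
cr = compare(bca, bcs, scenario.econ.wtp)

print(f"scenario: {scenario.name} (WTP ${scenario.econ.wtp:,.0f}/QALY)")
print(f"  cryoablation: cost ${bca.total_cost:>10,.0f}   QALYs {bca.total_qaly:.3f}")
print(f"  surgery:      cost ${bcs.total_cost:>10,.0f}   QALYs {bcs.total_qaly:.3f}")
print(f"  incremental (BCA-BCS): ${cr.delta_cost:,.0f}, {cr.delta_qaly:+.3f} QALY")
print(f"  ICER flag: {cr.icer_flag};  preferred: {cr.preferred}")
print(f"  NMB: BCA ${cr.nmb_bca:,.0f} vs BCS ${cr.nmb_bcs:,.0f}")
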