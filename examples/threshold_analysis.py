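"""Break-even (threshold) analysis on the low-risk scenario.

For each parameter, bisection finds the value at which the two strategies'
net monetary benefits are equal — the point where the preferred strategy
flips.  Values below/above each threshold (depending on the parameter's
direction) keep cryoablation preferred.
"""

from cryocea import find_threshold, low_risk_scenario, nmb_difference

scenario = low_risk_scenario()
print(f"base NMB difference (BCA - BCS): ${nmb_difference(scenario):,.0f}")

searches = [
    ("bca.procedure_cost", (0.0, 60_000.0), "$ {v:,.0f}"),
    ("bca.routine_cost_increment", (0.0, 10_000.0), "$ {v:,.0f}/yr extra"),
    ("bca.p_mortality_annual", (0.0, 0.10), "{p:.2f}%/yr"),
    ("bca.p_local_annual", (0.0, 0.98), "{p:.1f}%/yr"),
    ("bca.p_distant_annual", (0.0, 0.10), "{p:.2f}%/yr"),
]
for path, bracket, fmt in searches:
    tr = find_threshold(scenario, path, bracket)
    shown = fmt.format(v=tr.value or 0.0, p=100 * (tr.value or 0.0))
    print(f"  {path:<28s} flips at {shown}  ({tr.status})")

# the procedure-cost threshold has an exact closed form: NMB_bca falls with
# slope -1 in a one-time cost, so the crossing is base cost + base NMB diff
closed = scenario.bca.procedure_cost.base_value + nmb_difference(scenario)
print(f"  closed-form procedure-cost check: ${closed:,.0f}")
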