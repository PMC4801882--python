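"""Global sensitivity of subset totals to the kinetic rates.

Draws Latin hypercube samples over each group's published CI ranges (source
and capacity held fixed), simulates each group's protocol, and summarizes
which rates drive each subset's total cell number, by forward stepwise
regression (with partial correlations) and by PRCC.
"""
import bcellkin as bk

sample = bk.build_sensitivity_sample(bk.default_sensitivity_ranges(), n=300, seed=0)
print(f"sample: {len(sample.inputs)} simulated mice ({sample.n_failed} failed draws)")

for outcome in ("immature", "transitional", "mature_recirculating", "splenic_mature"):
    report = bk.stepwise_regression_sensitivity(sample, outcome)
    print(f"\n=== {outcome} totals: R = {report.r:.2f}, R^2 = {report.r2:.2f} ===")
    for name, pr in report.included:
        print(f"  {name:12s} partial R = {pr:+.2f}")
    coeffs = bk.prcc(sample, outcome)
    top = coeffs.abs().sort_values(ascending=False).head(3)
    print("  strongest PRCCs:", ", ".join(f"{k} {coeffs[k]:+.2f}" for k in top.index))

print(
    "\nA positive partial R means raising that rate raises the subset total "
    "with all\nother inputs held fixed; e.g. immature death (mu_i) carries a "
    "negative sign for\nthe immature and downstream pools."
)
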