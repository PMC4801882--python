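"""Fit a synthetic cohort and compare recovered rates with the truth.

Generates per-mouse labeled fractions at the published control best fit
(8 mice per time point, Gaussian scatter sd 0.03), then runs the Latin
hypercube maximum-likelihood fit over CI-widened ranges with a steady-state
totals filter. N is kept small here so the example runs in seconds; the
full analysis uses 10,000 candidates.
"""
import bcellkin as bk
from bcellkin.synthetic import totals_ranges_dict

truth = bk.table1_parameters("control")
design = bk.default_designs()["control"]
cohort = bk.generate_cohort(
    bk.CohortSpec(params={"control": truth}, designs={"control": design}, seed=42)
)
print(f"synthetic cohort: {len(cohort)} measurements")

ranges = bk.ParameterRanges.from_ci(bk.table1_ci("control"))
total_ranges = totals_ranges_dict(bk.generate_totals_ranges(truth))
fit = bk.fit_mle(
    cohort, ranges, n=2000, seed=42, design=design, total_ranges=total_ranges
)
print(
    f"{fit.n_passing}/{fit.n_candidates} candidates passed the totals filter; "
    f"best lnL = {fit.log_likelihood:.2f}"
)
print(f"{'rate':12s} {'truth':>8s} {'recovered':>10s}")
for name in fit.sampled_names:
    print(f"{name:12s} {getattr(truth, name):8.4f} {getattr(fit.params, name):10.4f}")
print(
    "\nWell-identified rates (e.g. the immature exit rates) land near the "
    "truth;\nweakly identified ones scatter across their sampled range — the "
    "profile\nlikelihood (example 03) quantifies that uncertainty."
)
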