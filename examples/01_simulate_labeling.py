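"""Simulate continuous-labeling kinetics for control and depleted mice.

Builds the full parameter set for each group (published best-fit rates plus
a run-time calibration of the source S and carrying capacity K), runs the
group's protocol — straight from steady state for controls; steady state,
depletion and 34 days of recovery for depleted mice — and prints the
labeled fraction of each measured subset on days 2, 4 and 7.
"""
import bcellkin as bk

designs = bk.default_designs()
for group in ("control", "depleted"):
    params = bk.table1_parameters(group)
    traj = bk.simulate_experiment(params, designs[group])
    table = bk.labeled_fraction_table(traj)
    print(f"\n=== {group} mice: labeled fraction by day and subset ===")
    print(table.pivot(index="day", columns="subset", values="fraction").round(3))

print(
    "\nEach entry is the model's L/(U+L) for that subset at that day of "
    "labeling.\nDepleted mice label much faster in the mature pools because "
    "their (emptied,\nrecovering) downstream compartments turn over quickly."
)
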