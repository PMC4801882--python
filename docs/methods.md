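# Methods

## Population model

The model tracks five B-cell compartments — bone-marrow pro-/pre-B
(`pro_pre`), immature (`immature`) and mature recirculating
(`mature_recirculating`), and splenic transitional (`transitional`) and
mature (`splenic_mature`) — as cell counts evolving per 6-hour time unit
(4 units per day; all day-valued inputs are converted at that factor).
Pro-/pre-B cells are the only dividing population. Their proliferation term
is γ·B_oe·(1 − (B_oe + B_Mrec)/K): the number of cells able to divide times
the maximal rate times a logistic brake driven by the joint occupancy of
the pro-/pre-B and mature-recirculating BM niches. This term is the model's
homeostatic feedback: removing mature recirculating cells frees capacity
and accelerates production. The carrying capacity K also implicitly absorbs
competition by unmodeled niche occupants (e.g. plasma cells).

Assumptions worth stating explicitly: transitional and mature cells do not
divide; the upstream source S (cells/6 h) is constant, i.e. stem-cell input
is not itself under feedback; compartments are well mixed with exponential
waiting times, so the mean residence time of a compartment is the
reciprocal of its summed death and exit rates; the immature→pro-/pre-B
reflux δ_r is retained as a parameter but defaults to 0, consistent with
the published residence-time arithmetic.

## Labeling bookkeeping

Each compartment splits into unlabeled (U) and labeled (L) pools. Division
during continuous label administration converts: the unlabeled pro-/pre-B
pool loses γλ·UB_oe to division (λ the logistic factor evaluated on
totals) and the labeled pool gains γλ·(2·UB_oe + LB_oe) — two labeled
daughters per unlabeled divider, one net new cell per labeled divider.
This form is chosen so that the U and L equations sum exactly to the
totals-only model; variants that multiply the total pool by 2 create mass
from nothing and are rejected by the package's conservation tests. Label is
assumed non-toxic (identical death rates for U and L — defensible for a
7-day experiment) and the source enters the unlabeled pool only. A
consequence of the unlabeled source is that the pro-/pre-B labeled fraction
saturates strictly below 1, at 2γλ/(δ_oe + γλ) when δ_r = 0 — about 0.46
at the control best fit with the default calibration.

## Simulation protocols

Control: integrate from the all-zero state to steady state, then label for
28 units (7 days) starting fully unlabeled. Depleted: reach steady state
with the (depleted) rate set under evaluation, apply the depletion
operator, integrate 136 units (34 days) of recovery, then label. The
depletion operator multiplies each compartment by a survival fraction;
the default (pro-/pre-B 1.0, immature 0.5, mature recirculating,
transitional and splenic mature 0.0) mirrors the anti-CD20 phenotype: the
target antigen is absent from pro-/pre-B cells, carried by roughly half the
immature pool, and present on all peripheral IgM+ subsets. The transitional
survival of 0 is a design choice — the antigen is expressed on peripheral
IgM+ cells, but the exact depletion depth of splenic transitional cells is
not established; it is configurable in `data/defaults.yaml`.

## Calibrating the unprinted constants

Published best-fit tables report the kinetic rates but not S, K, or the
steady-state totals. Given the rates, the four downstream balance equations
fix every compartment ratio, so the steady state has exactly one degree of
freedom. The calibration (`calibrate_source_and_capacity`) therefore takes
one anchor — the splenic mature total, default 2×10^7 cells, a standard
order of magnitude for an adult mouse spleen — plus a target logistic
occupancy λ (default 0.5, the midpoint of the feedback's dynamic range) and
solves

    K = (B_oe + B_Mrec) / (1 − λ),
    S = δ_oe·B_oe − γ·λ·B_oe − δ_r·B_i.

Any user-supplied target totals are first replaced by the nearest
balance-consistent point (anchored at their splenic mature entry), since
mutually inconsistent totals cannot all sit on a steady state. At the
control best fit this yields B_oe ≈ 6.0×10^5, B_i ≈ 3.4×10^5, B_Mrec ≈
7.0×10^5, B_t ≈ 3.4×10^6, S ≈ 2.1×10^5 cells/6 h and K ≈ 2.6×10^6 cells,
which places the spleen→BM inflow (ϕ_s·B_Mspl = 6.0×10^5 cells/6 h) and the
direct immature→BM-mature flow (6.4×10^4 cells/6 h) inside the ranges the
original analysis reports for those flows. Calibration is re-done per
candidate rate set during fitting, so every candidate's steady state passes
through the same anchor. Because the rates alone pin the compartment
ratios, the mass-conserving labeling model at the published control rates
bounds the day-7 BM mature recirculating labeled fraction near 10% (the
label inflow into that pool is ~90% splenic, and the large splenic pool
labels slowly through its ε_spl-limited turnover); the depleted protocol,
by contrast, reproduces the fast (~58% by day 7) labeling of the mature
BM pool.

## Numerics

Integration uses LSODA (stiff-capable, adaptive) with rtol 1e-8 and atol
1e-3 cells. `find_steady_state` integrates from zero in 500-unit windows
until max |dB/dt|/(B+1) < 1e-8 per 6 h, failing explicitly beyond 4000
units. The steady state also has a closed form (the balance ratios plus one
quadratic for B_oe); it equals the integration limit (round-trip tested)
and is used wherever thousands of candidates must be screened. Negative
solver excursions are clipped at 0. Labeled fractions are reported on a
0.25-unit output grid; an empty compartment reports a missing value, never
0/0. Likelihood ties break toward the earliest candidate in sampling order,
making fits reproducible bit-for-bit given a seed.

## Estimation

The observation model is independent Gaussian noise on per-mouse labeled
fractions. The likelihood family is a package choice: fractions are means
over thousands of cells, and a Gaussian keeps the objective smooth; the
per-subset standard deviation is profiled in closed form (the maximizing sd
is the per-subset RMS residual) unless fixed by the user. Candidates are
drawn by Latin hypercube sampling — each parameter's range divided into N
equal-width strata, each stratum sampled exactly once — over the published
per-group 95% CIs widened by ±50% of their width (floored at 0), with
δ_r ∈ [0, 0.1]; the original search ranges are unpublished, so these are
declared defaults, not inferences. Candidates whose steady-state totals
fall outside plausibility ranges are discarded before likelihood
evaluation; the synthetic workflow derives those ranges from the true
parameter set's steady state (±50%). The fit is the likelihood argmax over
surviving candidates. A known limitation: an argmax over ~10^4 stratified
draws in a 12-dimensional rate space pins only the strongly identified
directions; weakly identified rates scatter widely within their sampled
ranges, so point estimates for them should be read together with their
profile intervals.

Profile-likelihood CIs step one parameter over a 41-point grid (log-spaced
when the range spans more than a decade), re-optimize the others by two
rounds of Latin-hypercube refinement (500 draws each, boxes centered on the
running conditional optimum at 50% then 20% of the full range, warm-started
from the neighboring grid point), and keep grid values with G² = 2[lnL_max −
lnL(θ0)] ≤ 3.84 (χ²(1), α = 0.05). Intervals touching a sampling bound are
flagged censored. Because the nuisance search is stochastic and finite,
under-optimization can only shrink the interval; the bundled examples and
tests use reduced grid/draw counts and should be read accordingly.

## Sensitivity analysis

Inputs are the per-group kinetic rates sampled over their published CI
ranges plus a mouse-type indicator (0 control, 1 depleted; no interaction
terms); outcomes are subset totals at each protocol's measurement epoch —
steady state for control rows, 34 days post-depletion for depleted rows
(which have not re-equilibrated). S, K and δ_r are held fixed at the
control calibration across all draws: re-calibrating S and K per draw would
pin the anchored totals by construction and cancel exactly the rate
responses the analysis measures, and a shared K is consistent with the
finding that the capacity does not differ between mouse types. Stepwise
regression adds inputs in order of R² improvement with a default stopping
threshold of ΔR² = 0.01 (no published value exists); partial correlations
are computed residual-on-residual among the included inputs. PRCC
rank-transforms all columns (average ranks on ties) and partials each input
against all others; it is invariant under strictly monotone
reparameterizations. Only the sign structure and rough ordering of the
coefficients are meaningful — their magnitudes depend on the (unpublished)
sampling ranges.

## Synthetic cohorts

The generator emulates the study design: two groups, continuous labeling
sampled at days 2, 4 and 7, eight mice per time point, four measured
subsets, cross-sectional mice (terminal harvests, fresh IDs per day). Each
observation is the simulated true fraction plus Gaussian noise (default sd
0.03, matching the inference model and typical per-mouse scatter in such
designs) clipped to [0, 1]; clipping is logged when it exceeds 1% of rows,
and near-boundary cells (e.g. early splenic time points) are the ones it
biases. The generator does not emulate raw cytometry events, gating error,
label-intensity dilution, or between-mouse kinetic heterogeneity — passing
recovery tests on these cohorts therefore validates the estimation
machinery under the assumed observation model, not robustness to instrument
artifacts.

## Problem sizes used in the test suite

Unit and property tests run at small sizes (tens to hundreds of draws,
short horizons). The recovery check fits 10,000 LHS candidates per group;
the sensitivity sign check uses 1,000 draws per group across five seeds;
the law-of-large-numbers check uses 10,000 synthetic mice per time point.
Full-size profile runs (41 × 2 × 500 evaluations per parameter) are
exposed through the API defaults but exercised in reduced form in tests and
examples.
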