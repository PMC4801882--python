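# bcellkin

Compartmental modeling of B-cell development and continuous-labeling (BrdU)
kinetics in mouse bone marrow and spleen, with Latin-hypercube
maximum-likelihood fitting, profile-likelihood confidence intervals, and
global sensitivity analysis.

## The problem

In adult mice the peripheral B-cell pool stays constant despite continuous
production of new B cells in the bone marrow (BM). Whether BM B
lymphopoiesis is autonomous or regulated by feedback from mature peripheral
B cells can be probed by selectively depleting mature B cells and comparing
BrdU labeling kinetics between depleted and control animals: continuous
BrdU administration marks every cell that divides (and its progeny), so the
rise of the labeled fraction in each developmental subset encodes that
subset's production, death and flow rates. Extracting those rates requires
a mechanistic model — labeling curves alone are easily misread.

`bcellkin` implements that analysis as a reusable library: a deterministic
five-compartment population model, its ten-equation labeled/unlabeled
extension, the simulation protocols for control and depleted mice, a
screening-style maximum-likelihood estimator, profile-likelihood confidence
intervals, regression/PRCC sensitivity analysis, and a synthetic-cohort
generator so the whole pipeline is testable without animal data.

## The model

Five compartments: BM pro-/pre-B cells (B_oe, the only proliferating pool),
BM immature (B_i) and mature recirculating (B_Mrec) cells, and splenic
transitional (B_t) and mature (B_Mspl) cells. With all rates per 6-h unit:

    dB_oe/dt   = S + γ·B_oe·(1 − (B_oe + B_Mrec)/K) − δ_oe·B_oe + δ_r·B_i
    dB_i/dt    = δ_oe·B_oe − (μ_i + δ_i_t + δ_r + δ_i_re)·B_i
    dB_Mrec/dt = δ_i_re·B_i + ϕ_s·B_Mspl − (μ_re + ϕ_BM)·B_Mrec
    dB_t/dt    = δ_i_t·B_i − (μ_t + δ_t)·B_t
    dB_Mspl/dt = δ_t·B_t + ϕ_BM·B_Mrec − (ϕ_s + ε_spl)·B_Mspl

Proliferation is throttled logistically by the joint occupancy of the
pro-/pre-B and mature-recirculating niches relative to a carrying capacity
K — the homeostatic feedback under study. For labeling, each compartment
splits into unlabeled (U) and labeled (L) pools; an unlabeled pro-/pre-B
cell that divides moves both daughters to the labeled pool (a factor-2
gain), all other flows act identically on both pools, and the upstream
source S is never labeled. Fitting maximizes a Gaussian likelihood of
per-mouse labeled fractions over Latin-hypercube-sampled candidate rate
sets, pre-screened by requiring plausible steady-state subset totals;
confidence intervals come from the profile likelihood with the χ²(1)
cutoff G² ≤ 3.84.

## Worked example

```python
import bcellkin as bk

params = bk.table1_parameters("depleted")      # published rates + calibrated S, K
design = bk.default_designs()["depleted"]      # deplete, recover 34 d, label 7 d
traj = bk.simulate_experiment(params, design)
print(bk.labeled_fraction_table(traj).pivot(
    index="day", columns="subset", values="fraction").round(3))
```

prints

```
subset  immature  mature_recirculating  splenic_mature  transitional
day
2.0        0.814                 0.413           0.058         0.222
4.0        0.862                 0.506           0.166         0.477
7.0        0.864                 0.577           0.306         0.686
```

— the fraction of each subset that is BrdU-labeled after 2, 4 and 7 days of
continuous labeling in depleted mice. The mature recirculating pool reaches
~58% labeled by day 7 (against ~9% in the control simulation, run with
`group="control"`): after depletion the mature pools are refilled almost
entirely by newly produced, labeled cells, which is the signature of
demand-driven B-cell production. The `examples/` directory has one short
script per capability (simulation, fitting, profiling, sensitivity), and a
thin CLI (`bcellkin simulate|fit|profile|sensitivity|synth ...`) wraps the
same calls for shell use.

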