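# Profile-likelihood 95% confidence intervals for control-mouse rates.
gamma: [0.20, 0.35]
delta_oe: [0.32, 0.55]
mu_i: [0.02, 0.2]
delta_i_t: [0.50, 0.75]
delta_i_re: [0.10, 0.22]
mu_re: [0.000, 0.048]
phi_BM: [0.6, 10.0]
mu_t: [0.02, 0.05]
delta_t: [0.014, 0.04]
phi_s: [0.015, 0.030]
eps_spl: [0.008, 0.009]
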