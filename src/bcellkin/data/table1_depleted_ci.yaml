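# Profile-likelihood 95% confidence intervals for depleted-mouse rates.
gamma: [0.30, 0.4]
delta_oe: [0.20, 0.48]
mu_i: [0.2, 0.75]
delta_i_t: [0.05, 0.50]
delta_i_re: [0.10, 0.20]
mu_re: [0.005, 0.060]
phi_BM: [0.7, 10.0]
mu_t: [0.04, 0.06]
delta_t: [0.005, 0.04]
phi_s: [0.014, 0.024]
eps_spl: [0.014, 0.022]
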