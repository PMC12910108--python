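# Wild-type polymerase with Ku pre-loaded on the DNA end.
condition_label: pol_lambda_ku
k_bind: 0.03
bound_fraction: 0.71
tau_dwell: 2.7
t_incorporation: 2.4
n_nucleotides: 4
e_start: 0.6
delta_e_per_nt: 0.1
frame_interval: 0.2
movie_length: 180.0
photon_budget: 500.0
leakage: 0.1
direct_excitation: 0.05
gamma: 1.2
bleach_tau_donor: 200.0
bleach_tau_acceptor: 100.0
background: 10.0
n_molecules: 500
seed: 0
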