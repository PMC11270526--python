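# Example simulation configuration (pass via `sabrekin simulate --config`).
# Unknown keys are rejected.  For `sabrekin fit-sexsy --config`, use only
# the subset {ratio_r, C0_mM, S0_mM, K, R_free, fit_r_free, min_d_mix}.
#
# The benchmark study grid this emulates:
#   substrates:   Py (S0 40 mM), 4AP (80 mM), NAM (80 mM); C0 = 4 mM each
#   temperatures: 280, 283, 288, 293, 298 K
#   measured free/equatorial ratios (Py): 7.46, 8.61, 9.72, 15.82, 11.04
#   (4AP): 21.86, 20.83, 22.48, 23.85, 24.33
#   (NAM): 23.48, 24.25, 24.92, 26.37, 27.22
#
# The block below is the Py / 280 K condition.

substrate: Py
T: 280.0
C0_mM: 4.0
S0_mM: 40.0
ratio_r: 7.46
k_d: 1.9          # 1/s, dissociation rate used for simulation
R_bound: 0.5      # 1/s, relaxation of complex-bound protons
R_free: 0.125     # 1/s, free-substrate relaxation (from T1 without catalyst)
noise_sd: 0.10    # relative Gaussian integral noise
n_d_mix: 24       # log-spaced mixing times on [0.02, 12] s
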