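"""Steady-state speciation of a SABRE sample.

Given loaded concentrations and the association equilibrium constant, the
mass balances fix how much substrate is free, singly bound (transient
CsS), or in the active complex CsS2 — and hence the free/equatorial
integral ratio r seen in a 1D spectrum.
"""

import sabrekin as sk

# 4 mM IrIMes precatalyst + 40 mM pyridine; K chosen to reproduce the
# measured free/equatorial ratio of 7.46 at 280 K
K = sk.equilibrium_constant_from_ratio(C0=0.004, S0=0.040, ratio_r=7.46)
sp = sk.steady_state_concentrations(
    sk.ChemicalSystem(C0=0.004, S0=0.040, K=K, T=280.0, substrate="Py")
)

print(f"K                = {K:.1f} 1/M")
print(f"[S] free         = {sp.S_free * 1e3:.2f} mM")
print(f"[CsS] transient  = {sp.CsS * 1e3:.2f} mM")
print(f"[CsS2] active    = {sp.CsS2 * 1e3:.2f} mM")
print(f"ratio fS/eS      = {sp.ratio_r:.2f}")
# The ratio equals [S]/(2 [CsS2]): two equivalent equatorial ligands per
# active complex carry the bound-pool signal.
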