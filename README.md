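# sabrekin

Substrate-exchange kinetics for SABRE nuclear-spin hyperpolarization.

SABRE (Signal Amplification By Reversible Exchange) boosts NMR signals of
analytes — pyridine, 4-aminopyridine, nicotinamide and many other
N-heterocycles — by transferring parahydrogen spin order through a
transient [Ir(H)₂(IMes)(S)₃]Cl complex. The efficiency of the transfer is
governed by how fast the equatorial substrate ligands dissociate
(monomolecular rate constant k_d), so quantifying k_d, and its activation
enthalpy ΔH‡ and entropy ΔS‡, is central to optimizing SABRE catalysts.
`sabrekin` is a toolkit for extracting those quantities from exchange-NMR
observables.

It provides, as a Python library with a thin CLI:

* **Speciation** — steady-state pool concentrations of free substrate,
  transient CsS and active CsS2 from mass balance and the association
  constant K, and the free/equatorial ratio r = [S]/(2[CsS2]) matched to
  1D integrals.
* **Bloch–McConnell exchange models** — longitudinal-magnetization
  generators for three topologies (three-pool CsS2 ↔ CsS + S; reduced
  two-pool CsS2 ↔ S2 with the k_d/2 magnetization-exchange rate; one-site
  C0S ↔ S for bidentate ligands), exact matrix-exponential propagation,
  and the biexponential eigenvalue analysis
  `M(t) = M0 + A e^{-kt} + B e^{-Rt}`.
* **Rate estimation** — direct SEXSY model fits (bound pool inverted,
  R_free fixed from T₁), joint biexponential fits with eigenvalue
  inversion, single- and two-spectrum EXSY estimators, all with
  linearized or delta-method uncertainties.
* **Thermodynamics** — Eyring regression of ln(k_d/T) on 1/T for
  ΔH‡/ΔS‡, and inverse-variance combination of independent estimates.
* **Synthetic data** — seeded generators for SEXSY series, EXSY
  quartets and Eyring-consistent temperature series, so the whole chain
  is testable without raw spectrometer data.

See `docs/methods.md` for the model assumptions and numerical choices.

## Worked example

Fit a synthetic SEXSY experiment (pyridine-like conditions: 4 mM
catalyst, 40 mM substrate, measured ratio 7.46, k_d = 1.9 s⁻¹, 5%
integral noise) with the three-pool and the reduced model:

```python
import numpy as np
import sabrekin as sk

K = sk.equilibrium_constant_from_ratio(0.004, 0.040, 7.46)
sp = sk.steady_state_concentrations(
    sk.ChemicalSystem(C0=0.004, S0=0.040, K=K, T=280.0, substrate="Py"))
spec = sk.ExchangeModelSpec("A", sk.RateConstants(k_d=1.9),
                            R_bound=0.5, R_free=0.125, speciation=sp)
ds = sk.simulate_sexsy(sk.SimulationConfig(
    spec=spec, d_mix=np.geomspace(0.02, 12, 40), noise_sd=0.05, seed=11))
for model in ("A", "B"):
    fit = sk.fit_sexsy(ds, model)
    print(model, fit.estimates["k_d"], fit.stderr["k_d"])
```

prints (`examples/sexsy_fit.py`):

```
model A: k_d = 2.29 +/- 0.74 1/s, R_bound = 0.44 1/s
model B: k_d = 2.19 +/- 0.72 1/s, R_bound = 0.60 1/s
```

both consistent with the generating k_d = 1.9 s⁻¹ within one standard
error (5% noise on integrals whose baseline is the large free-pool
magnetization is a hard regime). Activation analysis of the bundled
reference rates (`examples/eyring_analysis.py`):

```
NAM 280 K combined: k_d = 1.37 +/- 0.05 1/s (published mean 1.38 +/- 0.04)

substrate   dH (kJ/mol)      dS (J/(mol K))
Py          100.7 +/-  6.4    120.5 +/-  22.1
4AP          73.0 +/-  5.7     17.8 +/-  19.8
NAM          74.0 +/-  4.7     22.5 +/-  16.3
```

Positive ΔS‡ is the signature of dissociative (Sₙ1) ligand exchange.
Each script in `examples/` demonstrates one capability end to end;
`examples/full_pipeline.py` chains temperature-series simulation,
per-temperature fits and the Eyring refit.

## Command line

```sh
sabrekin simulate --model B --seed 7 --config examples/pipeline.yaml --out kin.csv
sabrekin fit-sexsy kin.csv --model B --ratio 7.46 --r-free 0.125 --out fit.json
sabrekin fit-biexp kin.csv --out biexp.json
sabrekin eyring rates.csv --out eyring.json
sabrekin combine estimates.csv --out combined.json
```

Tables are plain CSV/TSV (`d_mix_s, pool, integral, sigma`; temperatures
always Kelvin); reports are deterministic JSON with a full input echo.

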