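"""Published reference measurements for the standard IrIMes SABRE catalyst.

Dissociation rate constants of [Ir(H)2(IMes)(S)3]Cl in methanol-d4 for the
three benchmark substrates pyridine (Py, 40 mM), 4-aminopyridine (4AP,
80 mM) and nicotinamide (NAM, 80 mM) at 4 mM precatalyst, measured at five
temperatures by four routes: the three-pool model-A fit of SEXSY kinetics,
the single-spectrum EXSY estimator, the two-pool model-B fit of SEXSY
kinetics, and the biexponential (eigenvalue) analysis of SEXSY with its
back-calculated ``k_d``.  ``ratio`` is the measured free/equatorial
integral ratio, ``k``/``R`` the fast/slow biexponential rates, and
``kd_mean`` the inverse-variance combination of the four estimates.

These values serve as realistic inputs for simulations and examples and as
cross-checks for the analysis chain; they are not recomputed by this
package from raw spectra.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["reference_rates", "SUBSTRATES", "SAMPLE_COMPOSITION"]

SUBSTRATES = ("Py", "4AP", "NAM")

#: loaded concentrations (M): precatalyst C0 and substrate S0 per substrate
SAMPLE_COMPOSITION = {
    "Py": {"C0": 0.004, "S0": 0.040},
    "4AP": {"C0": 0.004, "S0": 0.080},
    "NAM": {"C0": 0.004, "S0": 0.080},
}

_COLUMNS = (
    "substrate T_K ratio "
    "kd_A_sexsy kd_A_sexsy_err kd_exsy kd_exsy_err kd_B_sexsy kd_B_sexsy_err "
    "k_biexp k_biexp_err R_biexp R_biexp_err kd_from_k kd_from_k_err "
    "kd_mean kd_mean_err"
).split()

_ROWS = [
    ("Py", 280, 7.46, 1.9, 0.1, 1.1, 0.1, 1.7, 0.1, 1.55, 0.06, 0.15, 0.02, 2.44, 0.10, 1.81, 0.04),
    ("Py", 283, 8.61, 3.4, 0.1, 1.7, 0.2, 3.0, 0.1, 2.57, 0.20, 0.10, 0.06, 4.17, 0.33, 3.01, 0.08),
    ("Py", 288, 9.72, 7.6, 0.2, 3.6, 0.5, 6.4, 0.3, 4.64, 0.22, 0.08, 0.03, 7.69, 0.37, 6.99, 0.15),
    ("Py", 293, 15.82, 14.9, 0.9, 6.0, 0.8, 10.5, 0.8, 7.95, 0.56, 0.18, 0.06, 14.12, 0.99, 10.92, 0.43),
    ("Py", 298, 11.04, 37.4, 3.9, 25.3, 2.9, 30.2, 3.0, 17.05, 0.96, 0.13, 0.02, 28.88, 1.62, 29.31, 1.21),
    ("4AP", 280, 21.86, 0.80, 0.04, 0.7, 0.1, 0.90, 0.04, 0.82, 0.01, 0.08, 0.005, 1.51, 0.03, 1.13, 0.02),
    ("4AP", 283, 20.83, 1.4, 0.1, 1.0, 0.1, 1.7, 0.1, 1.09, 0.03, 0.09, 0.005, 1.99, 0.05, 1.68, 0.04),
    ("4AP", 288, 22.48, 3.6, 0.1, 1.7, 0.2, 3.6, 0.1, 2.00, 0.09, 0.09, 0.005, 3.68, 0.16, 3.38, 0.07),
    ("4AP", 293, 23.85, 5.5, 0.6, 3.5, 0.4, 8.2, 2.8, 2.90, 0.45, 0.10, 0.019, 5.36, 0.82, 4.36, 0.30),
    ("4AP", 298, 24.33, 7.3, 0.8, 8.0, 0.9, 20.1, 10.5, 5.63, 0.46, 0.07, 0.005, 10.41, 0.85, 8.65, 0.48),
    ("NAM", 280, 23.48, 1.5, 0.1, 0.6, 0.1, 1.3, 0.1, 1.20, 0.06, 0.16, 0.015, 2.22, 0.11, 1.38, 0.04),
    ("NAM", 283, 24.25, 2.1, 0.1, 0.95, 0.11, 2.1, 0.1, 1.62, 0.09, 0.15, 0.013, 2.99, 0.16, 1.93, 0.05),
    ("NAM", 288, 24.92, 3.5, 0.2, 2.4, 0.3, 5.8, 0.6, 1.73, 0.09, 0.16, 0.008, 3.20, 0.16, 3.29, 0.10),
    ("NAM", 293, 26.37, 6.3, 0.4, 5.7, 0.6, 9.9, 0.8, 4.06, 0.33, 0.11, 0.011, 7.55, 0.62, 6.84, 0.29),
    ("NAM", 298, 27.22, 8.0, 0.8, 12.5, 1.3, 24.8, 9.8, 5.13, 0.68, 0.099, 0.008, 9.55, 1.27, 9.24, 0.58),
]


def reference_rates() -> pd.DataFrame:
    """The reference rate table as a tidy DataFrame (one row per substrate/T)."""
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    df["T_K"] = df["T_K"].astype(float)
    return df


def rate_series(substrate: str, column: str = "kd_mean"):
    """A :class:`~sabrekin.thermo.RateSeries` for one substrate and estimate."""
    from .thermo import RateSeries

    df = reference_rates()
    sub = df[df["substrate"] == substrate].sort_values("T_K")
    if sub.empty:
        raise KeyError(f"unknown substrate {substrate!r}; choose from {SUBSTRATES}")
    err_col = column + "_err"
    return RateSeries(
        T=sub["T_K"].to_numpy(),
        k_d=sub[column].to_numpy(dtype=float),
        sigma=sub[err_col].to_numpy(dtype=float) if err_col in sub else None,
        labels={"substrate": substrate, "estimate": column},
    )
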