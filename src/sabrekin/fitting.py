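"""Rate-constant estimation from SEXSY kinetics and EXSY integral quartets.

Three estimation routes are provided, mirroring common practice:

* :func:`fit_biexponential` — model-free joint biexponential fit of the
  bound (e) and free (f) pool recovery curves sharing two decay rates
  (``k_eff`` fast, ``R_eff`` slow), each pool with its own amplitudes and
  offset.
* :func:`fit_sexsy` — direct fit of the Bloch-McConnell solution of model
  A, B or C to the mixing-time curves, with the bound pool initially
  inverted and everything else unpolarized (the SEXSY preparation), the
  free-pool relaxation rate fixed from an independent T1 measurement, and
  the concentration ratio used as a restraint on the back rate.
* :func:`exsy_rate_estimate` / :func:`exsy_two_spectrum_estimate` —
  closed-form estimators from a single 2D EXSY spectrum (equal-relaxation
  assumption) or from a pair of spectra at ``d_mix`` and ``d_mix = 0``
  (reference normalization that removes the relaxation difference).

Uncertainties come from the Jacobian linearization of the weighted
least-squares problem (:func:`standard_errors`) or, for the EXSY
estimators, from first-order (delta-method) propagation of an assumed
relative integral precision (:func:`exsy_error`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .chem import RateConstants, equilibrium_constant_from_ratio, \
    steady_state_concentrations, ChemicalSystem
from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    SaturationError,
)
from .models import (
    ExchangeModelSpec,
    build_generator,
    propagate_grid,
)

__all__ = [
    "KineticsDataset",
    "ExsyIntegrals",
    "FitResult",
    "fit_biexponential",
    "fit_sexsy",
    "exsy_rate_estimate",
    "exsy_two_spectrum_estimate",
    "exsy_error",
    "standard_errors",
]

#: dataset pool labels accepted for the bound-equatorial and free pools
_BOUND_ALIASES = ("e", "CsS2")
_FREE_ALIASES = ("f", "S")


@dataclass
class KineticsDataset:
    """Mixing-time series of per-pool net-magnetization integrals.

    ``integrals`` has shape ``(n_pools, n_times)`` following ``pools``;
    ``sigma`` (same shape) holds per-point uncertainties or is None.
    ``meta`` carries the experimental context consumed by the fitters:
    ``substrate``, ``T`` (K), ``ratio_r``, ``C0``/``S0`` (M), ``R_free``
    (1/s, from an independent T1 measurement of the catalyst-free sample).
    """

    d_mix: np.ndarray
    pools: tuple
    integrals: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.d_mix = np.asarray(self.d_mix, dtype=float)
        self.integrals = np.atleast_2d(np.asarray(self.integrals, dtype=float))
        self.pools = tuple(self.pools)
        if self.sigma is not None:
            self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
            if self.sigma.shape != self.integrals.shape:
                raise DomainError("sigma and integrals shapes differ")
        if self.integrals.shape != (len(self.pools), self.d_mix.size):
            raise DomainError(
                f"integrals shape {self.integrals.shape} does not match "
                f"{len(self.pools)} pools x {self.d_mix.size} mixing times"
            )
        if np.any(self.d_mix < 0):
            raise DomainError("mixing times must be non-negative")
        if np.any(np.diff(self.d_mix) <= 0):
            raise DomainError("mixing times must be strictly increasing")
        if not np.all(np.isfinite(self.integrals)):
            raise DomainError("integrals must be finite")

    def pool(self, label: str) -> np.ndarray:
        return self.integrals[self.pools.index(label)]

    def to_frame(self):
        """Long-format table: columns d_mix_s, pool, integral, sigma."""
        import pandas as pd

        rows = []
        for j, p in enumerate(self.pools):
            for i, t in enumerate(self.d_mix):
                rows.append(
                    {
                        "d_mix_s": t,
                        "pool": p,
                        "integral": self.integrals[j, i],
                        "sigma": (
                            self.sigma[j, i] if self.sigma is not None else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df, meta=None):
        pools = tuple(dict.fromkeys(df["pool"]))
        t = np.sort(np.unique(df["d_mix_s"].to_numpy(dtype=float)))
        integrals = np.empty((len(pools), t.size))
        sigma = np.empty_like(integrals)
        have_sigma = "sigma" in df.columns and df["sigma"].notna().all()
        for j, p in enumerate(pools):
            sub = df[df["pool"] == p].sort_values("d_mix_s")
            if sub.shape[0] != t.size or not np.allclose(
                sub["d_mix_s"].to_numpy(dtype=float), t
            ):
                raise DomainError(f"pool {p!r} does not cover the full d_mix grid")
            integrals[j] = sub["integral"].to_numpy(dtype=float)
            if have_sigma:
                sigma[j] = sub["sigma"].to_numpy(dtype=float)
        return cls(
            d_mix=t,
            pools=pools,
            integrals=integrals,
            sigma=sigma if have_sigma else None,
            meta=dict(meta or {}),
        )


@dataclass
class ExsyIntegrals:
    """Diagonal/cross peak integrals of one 2D EXSY spectrum.

    ``I_ee`` and ``I_ff`` are the bound- and free-pool diagonal integrals,
    ``I_cross`` the average of the two cross-peak integrals, all at mixing
    time ``d_mix`` (s).  ``precision`` is the assumed relative intensity
    precision used for error propagation (noise plus peak-overlap errors).
    """

    I_ee: float
    I_ff: float
    I_cross: float
    d_mix: float
    precision: float = 0.10

    def __post_init__(self):
        if self.d_mix < 0:
            raise DomainError(f"d_mix must be non-negative, got {self.d_mix}")
        if not (0 <= self.precision < 1):
            raise DomainError(f"precision must be in [0, 1), got {self.precision}")
        for name in ("I_ee", "I_ff", "I_cross"):
            if not np.isfinite(getattr(self, name)):
                raise DomainError(f"{name} must be finite")


@dataclass
class FitResult:
    """Point estimates with linearized uncertainties for one fit."""

    estimates: dict
    stderr: dict
    covariance: np.ndarray
    param_names: tuple
    residuals: np.ndarray
    model_id: str
    converged: bool
    ndata: int
    cost: float
    jacobian: np.ndarray | None = None
    warnings: list = field(default_factory=list)
    fixed: dict = field(default_factory=dict)

    @property
    def nfree(self) -> int:
        return len(self.param_names)

    def to_dict(self):
        return {
            "model_id": self.model_id,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "stderr": {k: float(v) for k, v in self.stderr.items()},
            "covariance": np.asarray(self.covariance).tolist(),
            "param_names": list(self.param_names),
            "fixed": {k: float(v) for k, v in self.fixed.items()},
            "converged": bool(self.converged),
            "ndata": int(self.ndata),
            "cost": float(self.cost),
            "warnings": list(self.warnings),
        }


def standard_errors(fit: FitResult) -> dict:
    """Standard errors from the weighted Jacobian at the optimum.

    ``stderr = sqrt(diag( s^2 (J^T J)^{-1} ))`` with the residual variance
    ``s^2 = chi^2 / (N - p)`` (J already carries the weights).  Parameters
    whose Jacobian column is numerically null are flagged unidentifiable
    and get infinite standard error.
    """
    J = fit.jacobian
    if J is None:
        raise ConfigurationError("fit result carries no Jacobian")
    ndata, p = J.shape
    dof = max(ndata - p, 1)
    chi2 = float(np.sum(fit.residuals**2))
    s2 = chi2 / dof
    col_norms = np.linalg.norm(J, axis=0)
    bad = col_norms < 1e-8 * max(col_norms.max(), 1e-300)
    JtJ = J.T @ J
    cov = s2 * np.linalg.pinv(JtJ, rcond=1e-12)
    cov = 0.5 * (cov + cov.T)
    err = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    err[bad] = np.inf
    for i, name in enumerate(fit.param_names):
        if bad[i] and f"parameter {name!r} unidentifiable" not in fit.warnings:
            fit.warnings.append(f"parameter {name!r} unidentifiable")
    fit.covariance = cov
    fit.stderr = dict(zip(fit.param_names, err))
    return fit.stderr


def _weights(ds: KineticsDataset, mask) -> np.ndarray:
    if ds.sigma is not None:
        w = 1.0 / ds.sigma[:, mask]
        if not np.all(np.isfinite(w)):
            raise DomainError("sigma contains zeros or non-finite values")
        return w
    return np.ones_like(ds.integrals[:, mask])


def _run_least_squares(resid, starts, bounds, param_names, model_id, ndata):
    best = None
    for p0 in starts:
        try:
            sol = least_squares(resid, p0, bounds=bounds, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ConfigurationError("all optimizer starts failed")
    fit = FitResult(
        estimates=dict(zip(param_names, best.x)),
        stderr={},
        covariance=np.empty((0, 0)),
        param_names=tuple(param_names),
        residuals=best.fun,
        model_id=model_id,
        converged=bool(best.success),
        ndata=ndata,
        cost=float(best.cost),
        jacobian=best.jac,
    )
    standard_errors(fit)
    if not best.success:
        fit.warnings.append("optimizer did not report convergence; "
                            "estimates are best-so-far")
    return fit


def _find_pool(ds: KineticsDataset, aliases):
    for a in aliases:
        if a in ds.pools:
            return a
    return None


def fit_biexponential(ds: KineticsDataset, min_d_mix: float = 0.0) -> FitResult:
    """Joint biexponential fit of all observed pools with shared rates.

    Each pool is modeled as ``off + a exp(-k t) + b exp(-R t)`` with the
    two decay rates shared across pools and ``k_eff >= R_eff`` enforced by
    sorting (amplitude labels swap accordingly).  Requires at least six
    distinct mixing times.
    """
    mask = ds.d_mix >= min_d_mix
    t = ds.d_mix[mask]
    if t.size < 6:
        raise InsufficientDataError(
            f"need >= 6 mixing times for a biexponential fit, got {t.size}"
        )
    data = ds.integrals[:, mask]
    w = _weights(ds, mask)
    npool = len(ds.pools)

    def unpack(p):
        k, R = p[0], p[1]
        rest = p[2:].reshape(npool, 3)
        return k, R, rest  # rest rows: (a, b, off)

    def model(p):
        k, R, rest = unpack(p)
        ek = np.exp(-k * t)[None, :]
        eR = np.exp(-R * t)[None, :]
        return rest[:, 0:1] * ek + rest[:, 1:2] * eR + rest[:, 2:3]

    def resid(p):
        return ((model(p) - data) * w).ravel()

    t_scale = max(np.median(t[t > 0]) if np.any(t > 0) else 1.0, 1e-9)
    starts = []
    for k0 in (0.3 / t_scale, 3.0 / t_scale, 30.0 / t_scale):
        R0 = min(0.3 / t[-1] if t[-1] > 0 else 0.1, 0.5 * k0)
        # linear solve for amplitudes/offsets at the candidate rates
        A = np.column_stack([np.exp(-k0 * t), np.exp(-R0 * t), np.ones_like(t)])
        rest0 = np.linalg.lstsq(A, data.T, rcond=None)[0].T
        starts.append(np.concatenate([[k0, R0], rest0.ravel()]))
    lb = np.concatenate([[0.0, 0.0], np.full(3 * npool, -np.inf)])
    ub = np.full(2 + 3 * npool, np.inf)
    names = ["k_eff", "R_eff"]
    for p in ds.pools:
        names += [f"amp_k_{p}", f"amp_R_{p}", f"offset_{p}"]
    fit = _run_least_squares(resid, starts, (lb, ub), names, "biexp", data.size)
    # enforce k_eff >= R_eff by relabeling
    if fit.estimates["k_eff"] < fit.estimates["R_eff"]:
        swap = {}
        for name, v in fit.estimates.items():
            if name == "k_eff":
                swap["k_eff"] = fit.estimates["R_eff"]
            elif name == "R_eff":
                swap["R_eff"] = fit.estimates["k_eff"]
            elif name.startswith("amp_k_"):
                swap[name] = fit.estimates["amp_R_" + name[6:]]
            elif name.startswith("amp_R_"):
                swap[name] = fit.estimates["amp_k_" + name[6:]]
            else:
                swap[name] = v
        err = dict(fit.stderr)
        fit.estimates.update(swap)
        fit.stderr["k_eff"], fit.stderr["R_eff"] = err["R_eff"], err["k_eff"]
        for p in ds.pools:
            fit.stderr[f"amp_k_{p}"], fit.stderr[f"amp_R_{p}"] = (
                err[f"amp_R_{p}"],
                err[f"amp_k_{p}"],
            )
    # a rate whose amplitudes all vanish is not constrained by the data
    span = max(np.ptp(data), 1e-300)
    for tag, rate in (("amp_k_", "k_eff"), ("amp_R_", "R_eff")):
        amp_max = max(abs(fit.estimates[tag + p]) for p in ds.pools)
        if amp_max < 1e-3 * span:
            fit.warnings.append(
                f"parameter {rate!r} unidentifiable (vanishing amplitude)"
            )
            fit.stderr[rate] = np.inf
    return fit


def _resolve_meta(ds, key, override):
    if override is not None:
        return override
    return ds.meta.get(key)


def fit_sexsy(
    ds: KineticsDataset,
    model_id: str,
    *,
    ratio_r: float | None = None,
    C0: float | None = None,
    S0: float | None = None,
    K: float | None = None,
    R_free: float | None = None,
    fit_r_free: bool = False,
    min_d_mix: float = 0.0,
) -> FitResult:
    """Weighted least-squares fit of the exchange-model solution to SEXSY data.

    The initial condition is the SEXSY preparation (bound pool at
    ``-M0_e``, every other pool unpolarized).  The concentration ratio (or,
    for model A, the full speciation derived from ``C0``, ``S0`` and ``K``)
    restrains the back rate, leaving ``k_d``, ``R_bound`` and an overall
    intensity scale as the fit variables; ``R_free`` is fixed from the
    supplied T1-derived value unless ``fit_r_free`` is set.
    """
    ratio_r = _resolve_meta(ds, "ratio_r", ratio_r)
    C0 = _resolve_meta(ds, "C0", C0)
    S0 = _resolve_meta(ds, "S0", S0)
    R_free_val = _resolve_meta(ds, "R_free", R_free)
    if R_free_val is None:
        raise ConfigurationError(
            "R_free must be supplied (from an independent T1 measurement) "
            "or present in the dataset meta"
        )
    if model_id == "A":
        if C0 is None or S0 is None:
            raise ConfigurationError("model A needs C0 and S0")
        if K is None:
            if ratio_r is None:
                raise ConfigurationError("model A needs K or a measured ratio_r")
            K = equilibrium_constant_from_ratio(C0, S0, ratio_r)
        speciation = steady_state_concentrations(
            ChemicalSystem(C0=C0, S0=S0, K=K)
        )
        ratio_eff = speciation.ratio_r
    elif model_id in ("B", "C"):
        if ratio_r is None:
            raise ConfigurationError(f"model {model_id} needs ratio_r")
        speciation = None
        ratio_eff = ratio_r
    else:
        raise ConfigurationError(f"unknown model_id {model_id!r}")

    bound = _find_pool(ds, _BOUND_ALIASES)
    free = _find_pool(ds, _FREE_ALIASES)
    observed = [p for p in (bound, free) if p is not None]
    if not observed:
        raise ConfigurationError(
            f"dataset pools {ds.pools} contain neither a bound ({_BOUND_ALIASES}) "
            f"nor a free ({_FREE_ALIASES}) pool"
        )
    if model_id == "A":
        pool_row = {"CsS2": 0, "CsS": 1, "S": 2}
        rows = [pool_row["CsS2"] if p == bound else pool_row["S"] for p in observed]
    else:
        rows = [0 if p == bound else 1 for p in observed]

    mask = ds.d_mix >= min_d_mix
    t = ds.d_mix[mask]
    data = np.stack([ds.pool(p)[mask] for p in observed])
    w = (
        np.stack([ds.sigma[ds.pools.index(p)][mask] for p in observed]) ** -1
        if ds.sigma is not None
        else np.ones_like(data)
    )

    param_names = ["k_d", "R_bound", "scale"]
    if fit_r_free:
        param_names.append("R_free")

    def build(p):
        k_d = p[0]
        spec = ExchangeModelSpec(
            model_id=model_id,
            rates=RateConstants(k_d=k_d),
            R_bound=max(p[1], 1e-12),
            R_free=max(p[3] if fit_r_free else R_free_val, 1e-12),
            speciation=speciation,
            ratio_r=None if model_id == "A" else ratio_eff,
        )
        return build_generator(spec)

    def model(p):
        gen = build(p)
        curves = propagate_grid(gen, gen.sexsy_initial_state(), t)
        return p[2] * curves[rows]

    def resid(p):
        return ((model(p) - data) * w).ravel()

    # overall scale: bound pool starts at -scale*M0_e
    gen0 = build([1.0, 0.3, 1.0] + ([R_free_val] if fit_r_free else []))
    m0e = gen0.M0[0]
    if bound is not None and t[0] < 0.2 * t[-1]:
        scale0 = abs(data[observed.index(bound)][0]) / m0e
    else:
        scale0 = np.abs(data).max() / max(gen0.M0.max(), 1e-300)
    scale0 = max(scale0, 1e-12)
    t_scale = max(np.median(t[t > 0]) if np.any(t > 0) else 1.0, 1e-9)
    starts = []
    for k0 in (0.3 / t_scale, 3.0 / t_scale, 30.0 / t_scale):
        p0 = [k0, 0.3 / t_scale, scale0]
        if fit_r_free:
            p0.append(R_free_val)
        starts.append(np.array(p0))
    lb = np.zeros(len(param_names))
    ub = np.full(len(param_names), np.inf)
    fit = _run_least_squares(resid, starts, (lb, ub), param_names, model_id, data.size)
    fit.fixed = {"ratio_r": ratio_eff}
    if not fit_r_free:
        fit.fixed["R_free"] = R_free_val
    if model_id == "A":
        fit.fixed["K"] = K
    return fit


def _exsy_check(x: ExsyIntegrals, ratio_r: float):
    if x.d_mix <= 0:
        raise DomainError("EXSY estimation needs d_mix > 0")
    if ratio_r <= 0:
        raise DomainError(f"ratio_r must be positive, got {ratio_r}")
    if x.I_ee <= 0 or x.I_ff <= 0:
        raise DomainError("diagonal integrals must be positive")


def _kd_factor(model_id: str) -> float:
    if model_id == "B":
        return 2.0
    if model_id == "C":
        return 1.0
    raise ConfigurationError("EXSY estimators apply to two-pool models B and C")


def exsy_rate_estimate(
    x: ExsyIntegrals, ratio_r: float, model_id: str = "B"
) -> RateConstants:
    """Single-spectrum EXSY estimator under the equal-relaxation assumption.

    When both pools relax at the same rate, the uniform decay cancels from
    integral ratios and the surviving exchange eigenmode ``q =
    exp(-k_ex (1 + 1/r) d_mix)`` is recovered in closed form:

        q  = (I_ee - I_cross / r) / (I_ee + I_cross)
        q' = (I_ff - r I_cross) / (I_ff + I_cross)

    (the two forms coincide on exact equal-relaxation data).  ``k_d`` is
    computed from ``q`` (bound-pool diagonal) and ``k_a'`` from ``q'``.
    With unequal relaxation the estimate acquires a mixing-time-dependent
    bias; prefer :func:`exsy_two_spectrum_estimate` in that case.
    """
    _exsy_check(x, ratio_r)
    factor = _kd_factor(model_id)
    r = ratio_r
    if x.I_cross == 0:
        return RateConstants(k_d=0.0, k_a_prime=0.0)
    q = (x.I_ee - x.I_cross / r) / (x.I_ee + x.I_cross)
    if q <= 0:
        raise SaturationError(
            "cross/diagonal ratio outside the invertible range "
            f"(q={q:.3g} <= 0); use a shorter mixing time"
        )
    kappa = -np.log(q) / x.d_mix
    k_ex = kappa * r / (1.0 + r)
    qf = (x.I_ff - r * x.I_cross) / (x.I_ff + x.I_cross)
    if qf > 0:
        k_a_prime = (-np.log(qf) / x.d_mix) / (1.0 + r)
    else:
        k_a_prime = k_ex / r
    return RateConstants(k_d=factor * k_ex, k_a_prime=k_a_prime)


def exsy_two_spectrum_estimate(
    x: ExsyIntegrals,
    x0: ExsyIntegrals,
    ratio_r: float,
    model_id: str = "B",
) -> RateConstants:
    """Reference-normalized EXSY estimator from spectra at ``d_mix`` and 0.

    The ``d_mix = 0`` spectrum measures the thermal pool magnetizations, so
    the normalized integral matrix ``B`` (diagonals divided by their
    reference, cross peak by the geometric mean of the references) is the
    detailed-balance symmetrization of the full propagator.  Its matrix
    logarithm returns the exchange rate exactly, independent of the two
    pools' spin-lattice relaxation rates:

        k_ex = sqrt(r) [log B]_{ef} / d_mix.
    """
    _exsy_check(x, ratio_r)
    if x0.d_mix != 0:
        raise DomainError("reference spectrum must have d_mix = 0")
    if x0.I_ee <= 0 or x0.I_ff <= 0:
        raise DomainError("reference diagonal integrals must be positive")
    factor = _kd_factor(model_id)
    r = ratio_r
    if x.I_cross == 0:
        return RateConstants(k_d=0.0, k_a_prime=0.0)
    B = np.array(
        [
            [x.I_ee / x0.I_ee, x.I_cross / np.sqrt(x0.I_ee * x0.I_ff)],
            [x.I_cross / np.sqrt(x0.I_ee * x0.I_ff), x.I_ff / x0.I_ff],
        ]
    )
    evals, Q = np.linalg.eigh(B)
    if np.any(evals <= 0):
        raise SaturationError(
            "normalized integral matrix is not positive definite; "
            "mixing time too long (or integrals too noisy)"
        )
    logB = Q @ np.diag(np.log(evals)) @ Q.T
    k_ex = np.sqrt(r) * logB[0, 1] / x.d_mix
    if k_ex < 0:
        raise SaturationError(
            f"negative exchange rate {k_ex:.3g} from matrix log; "
            "integrals outside the valid range"
        )
    return RateConstants(k_d=factor * k_ex, k_a_prime=k_ex / r)


def exsy_error(
    x: ExsyIntegrals,
    ratio_r: float,
    model_id: str = "B",
    estimator=exsy_rate_estimate,
) -> float:
    """Delta-method standard error of an EXSY ``k_d`` estimate.

    Propagates independent relative intensity variances
    ``sigma_I = precision * |I|`` through the estimator to first order
    using central numerical derivatives.
    """
    if x.precision == 0:
        return 0.0

    def kd_of(I):
        return estimator(
            ExsyIntegrals(I[0], I[1], I[2], x.d_mix, x.precision),
            ratio_r,
            model_id,
        ).k_d

    I = np.array([x.I_ee, x.I_ff, x.I_cross], dtype=float)
    sig = x.precision * np.abs(I)
    var = 0.0
    for i in range(3):
        h = 1e-6 * max(abs(I[i]), 1e-12)
        up, dn = I.copy(), I.copy()
        up[i] += h
        dn[i] -= h
        g = (kd_of(up) - kd_of(dn)) / (2 * h)
        var += (g * sig[i]) ** 2
    return float(np.sqrt(var))
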