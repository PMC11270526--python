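"""Longitudinal-magnetization evolution generators for the exchange models.

Three models of substrate exchange on the SABRE catalyst are supported, in
decreasing order of mechanistic detail:

``A`` (``CsS2 <-> CsS + S``)
    Three pools (CsS2, CsS, S).  One of the two equatorial ligands leaves at
    a time.  The CsS2 *pool magnetization* (sum over its two equivalent
    ligands) is lost at total rate ``k_d`` and is routed half to the CsS
    pool and half to the free pool — the ``k_d/2`` production rule that
    follows from bookkeeping two spins per complex.  Re-association enters
    as pseudo-first-order rates frozen at the steady-state concentrations:
    ``k_a [S]`` restores CsS magnetization and ``k_a [CsS]`` restores free
    magnetization.

``B`` (``CsS2 <-> S2``)
    Two pools (e = equatorial-bound, f = free).  Both equatorial ligands
    leave simultaneously, so the magnetization exchange rate is ``k_d/2``;
    the back rate ``(k_d/2) * M0_e/M0_f = (k_d/2)/r`` follows from detailed
    balance, ``r`` being the free/equatorial ratio.

``C`` (``C0S <-> S``)
    Two pools, a single exchangeable ligand (e.g. a bidentate substrate like
    pyruvate): forward rate ``k_d``, back rate ``k_d/r``.

In every model longitudinal relaxation is a positive diagonal (``R_bound``
on bound pools — the transient CsS is assigned the same rate as CsS2 — and
``R_free`` on the free pool), and cross-relaxation between pools is
neglected.  The Bloch-McConnell equation then reads

    dM/dt = -L (M - M0),        L = -E + diag(R),

with the exchange part ``E`` conserving total magnetization (zero column
sums) and annihilating the thermal vector ``M0`` (detailed balance), so the
exact solution over a mixing time is

    M(d_mix) = M0 + expm(-L d_mix) (M(0) - M0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .chem import RateConstants, Speciation, association_from_equilibrium
from .errors import ConfigurationError, DomainError

__all__ = [
    "ExchangeModelSpec",
    "MagnetizationState",
    "Generator",
    "BiexpParams",
    "build_generator",
    "propagate",
    "propagate_grid",
    "eigen_rates",
    "two_pool_eigenvalues",
    "rates_from_eigen",
]

POOLS_A = ("CsS2", "CsS", "S")
POOLS_2 = ("e", "f")


@dataclass(frozen=True)
class ExchangeModelSpec:
    """Complete parameterization of one exchange model.

    ``speciation`` is required for model A (it fixes the pseudo-first-order
    back rates and the thermal pool sizes); models B/C only need the
    free/equatorial ratio ``ratio_r``.  ``P0`` is the thermal polarization
    setting the overall magnetization scale (arbitrary units).
    """

    model_id: str
    rates: RateConstants
    R_bound: float
    R_free: float
    speciation: Speciation | None = None
    ratio_r: float | None = None
    P0: float = 1.0

    def __post_init__(self):
        if self.model_id not in ("A", "B", "C"):
            raise ConfigurationError(f"unknown model_id {self.model_id!r}")
        if not (self.R_bound > 0 and self.R_free > 0):
            raise DomainError(
                f"relaxation rates must be positive, got R_bound={self.R_bound}, "
                f"R_free={self.R_free}"
            )
        if self.model_id == "A":
            if self.speciation is None:
                raise ConfigurationError("model A requires a full Speciation")
        else:
            r = self.effective_ratio
            if r is None or not r > 0:
                raise ConfigurationError(
                    f"model {self.model_id} requires ratio_r > 0, got {r}"
                )

    @property
    def effective_ratio(self) -> float | None:
        if self.ratio_r is not None:
            return self.ratio_r
        if self.speciation is not None:
            return self.speciation.ratio_r
        return None


@dataclass
class MagnetizationState:
    """Per-pool longitudinal magnetization and its thermal value."""

    pools: tuple
    M: np.ndarray
    M0: np.ndarray

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        self.M0 = np.asarray(self.M0, dtype=float)
        if not (len(self.pools) == self.M.size == self.M0.size):
            raise ConfigurationError("pools, M and M0 must have equal length")
        if np.any(self.M0 < 0):
            raise DomainError("thermal magnetizations M0 must be non-negative")

    def as_dict(self):
        return dict(zip(self.pools, self.M))


@dataclass
class Generator:
    """Evolution operator ``L`` with its exchange/relaxation split."""

    pools: tuple
    L: np.ndarray
    exchange_part: np.ndarray  # E, with dM/dt = E M - R (M - M0)
    relaxation_part: np.ndarray  # diagonal matrix of relaxation rates
    M0: np.ndarray
    model_id: str
    rates: RateConstants

    def equilibrium_state(self) -> MagnetizationState:
        return MagnetizationState(self.pools, self.M0.copy(), self.M0.copy())

    def sexsy_initial_state(self) -> MagnetizationState:
        """Bound pool inverted, all other pools unpolarized.

        Mimics the SEXSY preparation: the selective pulse plus phase cycling
        leaves only the equatorial-bound resonance encoded (inverted).
        """
        M = np.zeros_like(self.M0)
        M[0] = -self.M0[0]
        return MagnetizationState(self.pools, M, self.M0.copy())

    def to_dict(self):
        return {
            "model_id": self.model_id,
            "pools": list(self.pools),
            "L": self.L.tolist(),
            "exchange_part": self.exchange_part.tolist(),
            "relaxation_part": np.diag(self.relaxation_part).tolist(),
            "M0": self.M0.tolist(),
            "k_d": self.rates.k_d,
        }


@dataclass(frozen=True)
class BiexpParams:
    """Decay rates of the biexponential solution ``M0 + A e^{-kt} + B e^{-Rt}``."""

    k_eff: float
    R_eff: float
    amplitudes: dict | None = None
    offsets: dict | None = None
    extra_rates: tuple = ()

    def __post_init__(self):
        if not (self.k_eff >= self.R_eff >= 0 or np.isclose(self.R_eff, 0, atol=1e-12)):
            raise DomainError(
                f"require k_eff >= R_eff >= 0, got {self.k_eff}, {self.R_eff}"
            )


def build_generator(spec: ExchangeModelSpec) -> Generator:
    """Assemble the Bloch-McConnell operator for ``spec``.

    Model A derives ``k_a`` from the equilibrium constant of the speciation's
    chemical system when not given explicitly, which guarantees detailed
    balance (``E @ M0 = 0``) at the steady-state concentrations.
    """
    k_d = spec.rates.k_d
    if spec.model_id == "A":
        sp = spec.speciation
        k_a = spec.rates.k_a
        if k_a is None:
            if sp.system is None or not np.isfinite(sp.system.K):
                raise ConfigurationError(
                    "model A needs k_a, or a speciation carrying a finite-K system"
                )
            k_a = association_from_equilibrium(k_d, sp.system.K)
        s, ci, x = sp.S_free, sp.CsS, sp.CsS2
        E = np.array(
            [
                [-k_d, k_a * s, k_a * ci],
                [k_d / 2.0, -k_a * s, 0.0],
                [k_d / 2.0, 0.0, -k_a * ci],
            ]
        )
        R = np.diag([spec.R_bound, spec.R_bound, spec.R_free])
        M0 = spec.P0 * np.array([2.0 * x, ci, s])
        pools = POOLS_A
        rates = RateConstants(k_d=k_d, k_a=k_a)
    else:
        r = spec.effective_ratio
        k_ex = k_d / 2.0 if spec.model_id == "B" else k_d
        E = np.array([[-k_ex, k_ex / r], [k_ex, -k_ex / r]])
        R = np.diag([spec.R_bound, spec.R_free])
        M0 = spec.P0 * np.array([1.0, r])
        pools = POOLS_2
        rates = RateConstants(k_d=k_d, k_a_prime=k_ex / r)
    L = -E + R
    return Generator(
        pools=pools,
        L=L,
        exchange_part=E,
        relaxation_part=R,
        M0=M0,
        model_id=spec.model_id,
        rates=rates,
    )


def propagate(gen: Generator, state: MagnetizationState, d_mix: float) -> MagnetizationState:
    """Evolve ``state`` for a mixing time ``d_mix`` (exact matrix exponential)."""
    if d_mix < 0:
        raise DomainError(f"d_mix must be non-negative, got {d_mix}")
    dM = state.M - gen.M0
    M = gen.M0 + expm(-gen.L * d_mix) @ dM
    return MagnetizationState(gen.pools, M, gen.M0.copy())


def propagate_grid(gen: Generator, state: MagnetizationState, times) -> np.ndarray:
    """Evolve over a time grid; returns array of shape (n_pools, n_times).

    Uses one eigendecomposition of ``L`` for the whole grid; falls back to
    per-point matrix exponentials if ``L`` is (numerically) defective.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise DomainError("mixing times must be non-negative")
    dM = state.M - gen.M0
    lam, V = np.linalg.eig(gen.L)
    try:
        c = np.linalg.solve(V, dM)
        if np.linalg.cond(V) > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        out = gen.M0[:, None] + np.real(
            V @ (c[:, None] * np.exp(-lam[:, None] * times[None, :]))
        )
    except np.linalg.LinAlgError:
        out = np.column_stack(
            [gen.M0 + expm(-gen.L * t) @ dM for t in times]
        )
    return out


def two_pool_eigenvalues(k_ex: float, ratio_r: float, R_e: float, R_f: float):
    """Closed-form decay rates of the two-pool operator.

    For ``L = [[k_ex + R_e, -k_ex/r], [-k_ex, k_ex/r + R_f]]``:

        2 lambda_± = k_ex (1 + 1/r) + R_e + R_f
                     ± sqrt( (k_ex (1 - 1/r) + R_e - R_f)^2 + 4 k_ex^2 / r )

    Returns ``(k_eff, R_eff)`` = (fast, slow).
    """
    tr = k_ex * (1.0 + 1.0 / ratio_r) + R_e + R_f
    disc = np.sqrt(
        (k_ex * (1.0 - 1.0 / ratio_r) + R_e - R_f) ** 2
        + 4.0 * k_ex**2 / ratio_r
    )
    return (tr + disc) / 2.0, (tr - disc) / 2.0


def eigen_rates(gen: Generator, state: MagnetizationState | None = None) -> BiexpParams:
    """Decay rates (and optionally amplitudes) of the biexponential solution.

    For two-pool generators the two eigenvalues of ``L`` are returned as
    (``k_eff``, ``R_eff``) = (fast, slow).  For model A the three rates are
    computed and the two *slowest* are labeled; the fastest is reported in
    ``extra_rates``.  If ``state`` is given, per-pool mode amplitudes for
    ``M(t) = M0 + sum_i a_i v_i e^{-lambda_i t}`` are attached.
    """
    lam, V = np.linalg.eig(gen.L)
    order = np.argsort(lam.real)
    lam = lam[order].real
    V = V[:, order].real
    amplitudes = offsets = None
    if state is not None:
        c = np.linalg.solve(V, state.M - gen.M0)
        amp = V * c[None, :]  # amp[p, i]: contribution of mode i to pool p
        amplitudes = {p: tuple(amp[j]) for j, p in enumerate(gen.pools)}
        offsets = dict(zip(gen.pools, gen.M0))
    if len(lam) == 2:
        R_eff, k_eff = lam
        extra = ()
    else:
        R_eff, k_eff = lam[0], lam[1]
        extra = tuple(lam[2:])
    return BiexpParams(
        k_eff=float(k_eff),
        R_eff=float(max(R_eff, 0.0)),
        amplitudes=amplitudes,
        offsets=offsets,
        extra_rates=extra,
    )


def rates_from_eigen(
    k_eff: float,
    R_eff: float,
    ratio_r: float,
    model_id: str,
    R_free: float | None = None,
) -> RateConstants:
    """Recover ``k_d`` (and ``k_a'``) from measured biexponential rates.

    Inverts the two-pool closed form.  With the independently measured free
    relaxation rate ``R_free`` supplied, the eigenvalue sum/product equations
    are solved exactly for the magnetization exchange rate ``k_ex``.  The
    resulting quadratic has two algebraic branches; the larger root is the
    physical one whenever exchange dominates the relaxation asymmetry
    (``k_ex (1 + 1/r) > R_bound - R_free``), which holds throughout the
    SABRE regime this inversion is meant for.  Without ``R_free`` the
    common simplification ``R_e = R_f = R_eff`` is used, giving

        k_ex = r (k_eff - R_eff) / (1 + r),

    which in the fast-exchange limit ``R_eff -> 0`` partitions ``k_eff`` by
    the pool ratio, ``k_ex = k_eff r/(1+r)``.  ``k_d = 2 k_ex`` for model B
    and ``k_d = k_ex`` for model C.
    """
    if model_id not in ("B", "C"):
        raise ConfigurationError(
            "eigenvalue inversion is defined for the two-pool models B and C"
        )
    if ratio_r <= 0:
        raise DomainError(f"ratio_r must be positive, got {ratio_r}")
    if not (k_eff > R_eff >= 0):
        raise DomainError(
            f"require k_eff > R_eff >= 0, got k_eff={k_eff}, R_eff={R_eff}"
        )
    r = ratio_r
    if R_free is None:
        k_ex = r * (k_eff - R_eff) / (1.0 + r)
    else:
        S, P = k_eff + R_eff, k_eff * R_eff
        b = r * (S - 2.0 * R_free) / (r + 1.0)
        c = r**2 * (R_free * (S - R_free) - P) / (r + 1.0)
        disc = b * b + 4.0 * c
        if -1e-9 * max(b * b, 1.0) < disc < 0:  # numerical grazing of the boundary
            disc = 0.0
        if disc < 0:
            warnings.warn(
                "eigenvalue inversion outside the invertible region "
                f"(discriminant {disc:.3g} < 0); falling back to the "
                "equal-relaxation simplification",
                stacklevel=2,
            )
            k_ex = r * (k_eff - R_eff) / (1.0 + r)
        else:
            k_ex = (b + np.sqrt(disc)) / 2.0
            R_e = S - R_free - k_ex * (1.0 + 1.0 / r)
            if k_ex <= 0 or R_e < -1e-9:
                warnings.warn(
                    f"eigenvalue inversion gave k_ex={k_ex:.4g}, "
                    f"R_bound={R_e:.4g}; estimate is outside the physical "
                    "region and should be treated as diagnostic only",
                    stacklevel=2,
                )
    factor = 2.0 if model_id == "B" else 1.0
    return RateConstants(k_d=factor * max(k_ex, 0.0), k_a_prime=max(k_ex, 0.0) / r)
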