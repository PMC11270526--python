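"""Chemical system and steady-state speciation of the SABRE catalyst pools.

The active SABRE complex ``CsS2`` = [Ir(H)2(IMes)(S)3]Cl carries two
exchangeable *equatorial* substrate ligands (the third, axial, substrate is
treated as sequestered in the catalyst core ``Cs`` and does not exchange on
the relevant timescale).  Dissociative (SN1) exchange proceeds through the
transient ``CsS`` complex:

    CsS2  -->(k_d)  CsS + S        CsS + S  -->(k_a)  CsS2

with association equilibrium constant ``K = k_a / k_d`` (units 1/M), so that
detailed balance reads ``k_d [CsS2] = k_a [CsS] [S]``.

Mass balance (all concentrations molar):

    catalyst:      [CsS] + [CsS2] = C0
    exchangeable:  S0 - C0 = [S] + [CsS] + 2 [CsS2]

i.e. one substrate equivalent per catalyst is locked in the axial position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .errors import DomainError, InfeasibleSystemError, UndefinedRatioError

__all__ = [
    "RateConstants",
    "ChemicalSystem",
    "Speciation",
    "steady_state_concentrations",
    "pool_ratio",
    "association_from_equilibrium",
    "equilibrium_constant_from_ratio",
]


@dataclass(frozen=True)
class RateConstants:
    """Exchange rate constants.

    Parameters
    ----------
    k_d:
        Monomolecular dissociation rate constant (1/s).  ``1/k_d`` is the
        lifetime of the active complex; ``2/k_d`` the lifetime of a single
        Ir-S contact.
    k_a:
        Bimolecular association rate constant (1/(M s)); ``k_a = K * k_d``.
    k_a_prime:
        Effective (pseudo-first-order) re-association rate of the reduced
        two-pool models, in 1/s.
    """

    k_d: float = 0.0
    k_a: float | None = None
    k_a_prime: float | None = None

    def __post_init__(self):
        if self.k_d < 0:
            raise DomainError(f"k_d must be non-negative, got {self.k_d}")
        for name in ("k_a", "k_a_prime"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class ChemicalSystem:
    """Initial composition and association equilibrium of a SABRE sample.

    ``C0``/``S0`` are the loaded precatalyst and substrate concentrations (M),
    ``K`` the association constant (1/M, ``math.inf`` allowed), ``T`` the
    temperature (K).
    """

    C0: float
    S0: float
    K: float
    T: float = 298.0
    substrate: str = ""

    def __post_init__(self):
        if not self.C0 > 0:
            raise DomainError(f"C0 must be positive, got {self.C0}")
        if not self.S0 > 0:
            raise DomainError(f"S0 must be positive, got {self.S0}")
        if self.K < 0 or math.isnan(self.K):
            raise DomainError(f"K must be non-negative, got {self.K}")
        if not self.T > 0:
            raise DomainError(f"T must be positive (Kelvin), got {self.T}")


@dataclass(frozen=True)
class Speciation:
    """Steady-state concentrations of the three substrate pools (M)."""

    S_free: float
    CsS: float
    CsS2: float
    system: ChemicalSystem | None = field(default=None, compare=False)

    @property
    def ratio_r(self) -> float:
        """Free-to-equatorial intensity ratio [fS]/[eS] = [S]/(2 [CsS2])."""
        return pool_ratio(self)


def steady_state_concentrations(system: ChemicalSystem) -> Speciation:
    """Solve equilibrium + mass balance for the unique non-negative root.

    Reduces the system to one scalar equation in the free-substrate
    concentration ``s``: with ``[CsS] = C0/(1+K s)`` and
    ``[CsS2] = C0 K s/(1+K s)`` from the catalyst balance and equilibrium,
    the exchangeable balance becomes

        g(s) = s + C0 (1 + 2 K s)/(1 + K s) - (S0 - C0) = 0,

    which is strictly increasing in ``s`` and is solved by a bracketed
    root-finder on ``[0, S0 - 2 C0]``.

    Raises
    ------
    InfeasibleSystemError
        If the substrate cannot cover the axial + first-equatorial demand
        (``S0 <= 2 C0``), or full saturation is impossible at ``K = inf``
        (``S0 < 3 C0``).
    """
    C0, S0, K = system.C0, system.S0, system.K
    if S0 <= 2 * C0:
        raise InfeasibleSystemError(
            "exchangeable substrate balance violated: need S0 > 2*C0 "
            f"(axial + first equatorial demand), got S0={S0} M, C0={C0} M"
        )
    if math.isinf(K):
        s = S0 - 3 * C0
        if s < 0:
            raise InfeasibleSystemError(
                "catalyst saturation (K=inf) needs S0 >= 3*C0, got "
                f"S0={S0} M, C0={C0} M"
            )
        return Speciation(S_free=s, CsS=0.0, CsS2=C0, system=system)
    if K == 0.0:
        return Speciation(S_free=S0 - 2 * C0, CsS=C0, CsS2=0.0, system=system)

    target = S0 - C0

    def g(s):
        return s + C0 * (1.0 + 2.0 * K * s) / (1.0 + K * s) - target

    lo, hi = 0.0, S0 - 2 * C0
    s = brentq(g, lo, hi, xtol=1e-18, rtol=8.9e-16, maxiter=200)
    CsS = C0 / (1.0 + K * s)
    CsS2 = C0 * K * s / (1.0 + K * s)
    return Speciation(S_free=s, CsS=CsS, CsS2=CsS2, system=system)


def pool_ratio(spec: Speciation) -> float:
    """Free-to-equatorial ratio ``r = [S] / (2 [CsS2])``.

    This is the quantity matched against the measured fS/eS integral ratio
    from a standard 1D spectrum (two equivalent equatorial ligands per
    complex, hence the factor 2).
    """
    if spec.CsS2 <= 0:
        raise UndefinedRatioError(
            "pool ratio undefined: no CsS2 complex present (CsS2 = "
            f"{spec.CsS2} M)"
        )
    return spec.S_free / (2.0 * spec.CsS2)


def association_from_equilibrium(k_d: float, K: float) -> float:
    """Bimolecular association constant ``k_a = K * k_d`` (1/(M s))."""
    if k_d < 0:
        raise DomainError(f"k_d must be non-negative, got {k_d}")
    if K < 0:
        raise DomainError(f"K must be non-negative, got {K}")
    return K * k_d


def equilibrium_constant_from_ratio(C0: float, S0: float, ratio_r: float) -> float:
    """Invert the speciation for ``K`` given a measured fS/eS ratio.

    Closed form: the balances give ``[CsS2] = (S0 - 2 C0)/(1 + 2 r)``,
    ``[S] = 2 r [CsS2]`` and ``[CsS] = C0 - [CsS2]``, whence
    ``K = [CsS2]/([CsS][S])``.
    """
    if ratio_r <= 0:
        raise DomainError(f"ratio_r must be positive, got {ratio_r}")
    if S0 <= 2 * C0:
        raise InfeasibleSystemError(
            f"need S0 > 2*C0 for a feasible speciation, got S0={S0}, C0={C0}"
        )
    x = (S0 - 2 * C0) / (1.0 + 2.0 * ratio_r)  # [CsS2]
    if x >= C0:
        raise InfeasibleSystemError(
            f"measured ratio {ratio_r} implies [CsS2]={x} M >= C0={C0} M; "
            "ratio inconsistent with concentrations"
        )
    s = 2.0 * ratio_r * x
    CsS = C0 - x
    return x / (CsS * s)
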