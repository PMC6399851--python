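"""Emax dose-response function and growth/decay regime classification.

The inhibitory Emax (Hill) model maps a payload concentration ``conc`` to
a response

    E(conc) = E0 * (1 - Emax * conc**g / (IC50**g + conc**g))

with baseline ``E0`` at zero payload, maximum fractional killing effect
``Emax``, half-maximal concentration ``IC50`` and Hill coefficient ``g``.
Coupled to the tumor growth inhibition equation dT/dt = c*E*F*T - lam*T,
the sign of ``c*E(conc) - lam`` decides whether the tumor grows or
decays, and the equilibrium intracellular payload ``C0/(1+k)`` makes that
sign a function of the efflux-to-influx ratio ``k``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np
from scipy.optimize import brentq

from .payload_kinetics import PayloadParameters

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class DoseResponseParameters:
    """Parameters of the inhibitory Emax model.

    ``e0`` carries nM response units so that the product ``c * E`` in the
    growth equation is a per-day rate (``c`` is per nM per day);
    ``emax`` is a dimensionless fraction in (0, 1].
    """

    e0: float = 120.0
    emax: float = 0.6931
    ic50: float = 300.0
    gamma_hill: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.e0) and self.e0 > 0):
            raise ValueError(f"e0 must be positive, got {self.e0}")
        if not (np.isfinite(self.emax) and 0 < self.emax <= 1):
            raise ValueError(f"emax must lie in (0, 1], got {self.emax}")
        if not (np.isfinite(self.ic50) and self.ic50 > 0):
            raise ValueError(f"ic50 must be positive, got {self.ic50}")
        if not (np.isfinite(self.gamma_hill) and self.gamma_hill > 0):
            raise ValueError(f"gamma_hill must be positive, got {self.gamma_hill}")

    @property
    def floor(self) -> float:
        """Response in the saturating high-concentration limit."""
        return self.e0 * (1.0 - self.emax)


def emax_inhibition(conc: ArrayLike, params: DoseResponseParameters) -> ArrayLike:
    """Evaluate the Emax response at payload concentration ``conc`` (nM).

    Strictly decreasing in ``conc``, from ``E0`` at zero payload to
    ``E0*(1-Emax)`` in the saturating limit; ``E(IC50) = E0*(1-Emax/2)``
    for any Hill coefficient.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("payload concentration must be >= 0")
    g = params.gamma_hill
    with np.errstate(over="ignore"):
        cg = np.power(c, g)
        frac = np.where(np.isinf(cg), 1.0, cg / (params.ic50**g + cg))
    e = params.e0 * (1.0 - params.emax * frac)
    return float(e) if np.isscalar(conc) or np.ndim(conc) == 0 else e


class Regime(str, enum.Enum):
    """Net tumor behaviour at a fixed payload concentration."""

    GROWING = "growing"
    DECAYING = "decaying"
    CRITICAL = "critical"


class NetGrowth(NamedTuple):
    rate: float  #: c*E(conc) - lam, per day
    regime: Regime


def net_growth_rate(
    conc: float,
    dr: DoseResponseParameters,
    c: float,
    lam: float,
    tol: float = 1e-9,
) -> NetGrowth:
    """Signed exponential net growth rate ``c*E(conc) - lam`` (per day).

    Labels the regime ``growing`` when the rate exceeds ``tol``,
    ``decaying`` below ``-tol`` and ``critical`` in between.  ``tol`` is a
    numerical dead-band for the knife-edge case, not a biological
    threshold.
    """
    rate = c * emax_inhibition(conc, dr) - lam
    if rate > tol:
        regime = Regime.GROWING
    elif rate < -tol:
        regime = Regime.DECAYING
    else:
        regime = Regime.CRITICAL
    return NetGrowth(float(rate), regime)


def critical_efflux_ratio(
    dr: DoseResponseParameters,
    payload_template: PayloadParameters,
    c: float,
    lam: float,
    bracket: tuple[float, float] = (1e-6, 1e6),
    xtol: float = 1e-10,
) -> float:
    """Efflux-to-influx ratio at which the equilibrium regime flips.

    At equilibrium the total intracellular payload is ``C0/(1+k)``, a
    strictly decreasing function of ``k``; hence ``c*E(C0/(1+k)) - lam``
    is strictly increasing in ``k`` and crosses zero at most once.  The
    returned root separates a decaying regime (below) from a growing one
    (above).  Raises ``ValueError`` with the endpoint regimes if no sign
    change exists on ``bracket``.
    """

    c0 = payload_template.c0

    def objective(k: float) -> float:
        return c * emax_inhibition(c0 / (1.0 + k), dr) - lam

    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError(f"bracket must satisfy 0 < lo < hi, got {bracket}")
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        lab = lambda f: net_growth_rate(0.0, dr, 0.0, -f).regime.value  # noqa: E731
        raise ValueError(
            "no critical efflux ratio in "
            f"[{lo:g}, {hi:g}]: regime is {lab(f_lo)} at k={lo:g} "
            f"and {lab(f_hi)} at k={hi:g}; no finite root "
            "(for lam >= c*E0 the boundary lies at k -> infinity)"
        )
    return float(brentq(objective, lo, hi, xtol=xtol))
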