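"""Payload exchange between Ag+ cells, Ag- cells and extracellular space.

After an antibody-drug conjugate (ADC) is internalised and its linker
cleaved, the cytotoxic payload (e.g. MMAE) accumulates in antigen-positive
(Ag+) tumor cells.  A membrane-permeable payload leaks into the
extracellular space and re-enters both Ag+ and antigen-negative (Ag-)
cells, which is the physical basis of the bystander-killing effect.  With
``beta`` the Ag+ fraction of the tumor, the concentrations obey the closed
linear system

.. math::

    \\dot C_{int,p} &= \\beta\\, k_{in} C_{ext,p} - k_{out} C_{int,p} \\\\
    \\dot C_{int,n} &= (1-\\beta)\\, k_{in} C_{ext,p} - k_{out} C_{int,n} \\\\
    \\dot C_{ext,p} &= -k_{in} C_{ext,p} + k_{out} (C_{int,p} + C_{int,n})

from the single-administration initial state ``(C0, 0, 0)``.  The system
conserves total payload, is independent of ``beta`` in the sum
``C_int_p + C_int_n``, and relaxes to an equilibrium set by the
efflux-to-influx ratio ``k = k_out / k_in``.  Because the system is linear
it has a closed-form solution, used as ground truth for the numerical
integrator.

All rates are per day; concentrations are nM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidStateError
from .trajectory import Trajectory

MINUTES_PER_DAY = 1440.0

#: Literature cell-line influx/efflux rates for auristatin payloads,
#: per minute.  Simulations use the day-scale convention k_in = 1/day
#: with k = k_out/k_in configurable; these constants are provided for
#: reference only.
K_IN_LITERATURE_PER_MIN = 8.46e-2
K_OUT_LITERATURE_PER_MIN = 4.122e-2


def convert_rate_minutes_to_days(rate: float) -> float:
    """Convert a first-order rate from per-minute to per-day units."""
    if not np.isfinite(rate):
        raise ValueError("rate must be finite")
    return rate * MINUTES_PER_DAY


@dataclass(frozen=True)
class PayloadParameters:
    """Rates and initial condition of the payload-exchange system.

    Attributes
    ----------
    k_in
        Influx rate from extracellular space into cells (1/day), > 0.
    k_out
        Efflux rate out of cells (1/day), >= 0.  ``k_out = 0`` encodes an
        impermeable payload, i.e. the bystander-off case.
    beta
        Fraction of tumor cells that are Ag+, in (0, 1].  ``beta = 0`` is
        rejected: the initial intracellular payload concentration is
        defined per Ag+ cell and has no meaning without Ag+ cells.
    c0
        Initial payload concentration in Ag+ cells (nM), >= 0.
    """

    k_in: float = 1.0
    k_out: float = 2.0
    beta: float = 0.7
    c0: float = 200.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k_in) and self.k_in > 0):
            raise ValueError(f"k_in must be positive and finite, got {self.k_in}")
        if not (np.isfinite(self.k_out) and self.k_out >= 0):
            raise ValueError(f"k_out must be >= 0 and finite, got {self.k_out}")
        if not (np.isfinite(self.beta) and 0 < self.beta <= 1):
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")
        if not (np.isfinite(self.c0) and self.c0 >= 0):
            raise ValueError(f"c0 must be >= 0 and finite, got {self.c0}")

    @property
    def k(self) -> float:
        """Efflux-to-influx ratio ``k_out / k_in`` (dimensionless)."""
        return self.k_out / self.k_in

    def with_bystander_off(self) -> "PayloadParameters":
        """Return a copy with ``k_out = 0`` (payload trapped in Ag+ cells)."""
        return replace(self, k_out=0.0)


@dataclass(frozen=True)
class PayloadState:
    """Payload concentrations (nM) in the three compartments."""

    c_int_p: float  #: payload in Ag+ cells
    c_int_n: float  #: payload in Ag- cells
    c_ext_p: float  #: payload in the extracellular space

    @property
    def total_intracellular(self) -> float:
        return self.c_int_p + self.c_int_n

    @property
    def total(self) -> float:
        return self.c_int_p + self.c_int_n + self.c_ext_p

    def as_array(self) -> np.ndarray:
        return np.array([self.c_int_p, self.c_int_n, self.c_ext_p], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PayloadState":
        return cls(float(arr[0]), float(arr[1]), float(arr[2]))


def initial_payload_state(params: PayloadParameters) -> PayloadState:
    """Single administration into Ag+ cells: ``(C0, 0, 0)``."""
    return PayloadState(params.c0, 0.0, 0.0)


def payload_rhs(state: PayloadState, params: PayloadParameters) -> PayloadState:
    """Time derivative of the payload system (nM/day).

    The three components sum to exactly zero: the system is closed (no
    extracellular clearance), so total payload is conserved.
    """
    arr = state.as_array()
    if not np.all(np.isfinite(arr)):
        raise InvalidStateError(f"payload state has non-finite components: {arr}")
    cp, cn, ce = arr
    influx = params.k_in * ce
    d_cp = params.beta * influx - params.k_out * cp
    d_cn = (1.0 - params.beta) * influx - params.k_out * cn
    d_ce = -influx + params.k_out * (cp + cn)
    return PayloadState(d_cp, d_cn, d_ce)


def rate_matrix(params: PayloadParameters) -> np.ndarray:
    """The 3x3 generator A with d/dt (Cp, Cn, Ce) = A (Cp, Cn, Ce)."""
    ki, ko, b = params.k_in, params.k_out, params.beta
    return np.array(
        [
            [-ko, 0.0, b * ki],
            [0.0, -ko, (1.0 - b) * ki],
            [ko, ko, -ki],
        ]
    )


def _closed_form_arrays(
    params: PayloadParameters, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised exact solution from the initial state (C0, 0, 0).

    Derivation: the sum S = Cp + Cn and Ce form a beta-free 2-D system
    with eigenvalues 0 and -(k_in + k_out); the differences
    Cp - beta*S and Cn - (1-beta)*S each decay at rate k_out.
    """
    t = np.asarray(t, dtype=float)
    ki, ko, b, c0 = params.k_in, params.k_out, params.beta, params.c0
    k = ko / ki
    s = c0 / (1.0 + k) * (1.0 + k * np.exp(-(ki + ko) * t))
    leak = c0 * np.exp(-ko * t)
    cp = b * s + (1.0 - b) * leak
    cn = (1.0 - b) * (s - leak)
    ce = c0 - s
    return cp, cn, ce


def payload_closed_form(params: PayloadParameters, t: float) -> PayloadState:
    """Exact solution of the payload system at time ``t`` (days).

    Exact (to floating precision) solution of the linear system from the
    initial state ``(C0, 0, 0)``; conservation holds exactly by
    construction (``C_ext`` is computed as the conserved remainder).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    cp, cn, ce = _closed_form_arrays(params, np.asarray(t, dtype=float))
    return PayloadState(float(cp), float(cn), float(ce))


def payload_equilibrium(params: PayloadParameters) -> PayloadState:
    """Stationary state of the exchange system for ``k_out > 0``.

    The total payload partitions as ``C0/(1+k)`` intracellular (split
    ``beta : 1-beta`` between Ag+ and Ag- cells) and ``C0*k/(1+k)``
    extracellular, with ``k = k_out/k_in``.
    """
    if params.k_out == 0:
        raise ValueError(
            "k_out = 0 has no non-trivial equilibrium: the initial state "
            "(C0, 0, 0) is already stationary (bystander-off case)"
        )
    k = params.k
    intra = params.c0 / (1.0 + k)
    return PayloadState(
        params.beta * intra, (1.0 - params.beta) * intra, params.c0 * k / (1.0 + k)
    )


def simulate_payload(
    params: PayloadParameters,
    time_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    **solver_options: Any,
) -> Trajectory:
    """Integrate the payload system numerically on ``time_grid``.

    The grid must start at 0 (administration time) and be strictly
    increasing.  Output series: ``C_int_p``, ``C_int_n``, ``C_ext_p`` and
    ``total_intracellular``.  Small negative undershoots within the solver
    absolute tolerance are clamped to zero; larger ones raise
    :class:`IntegrationError`.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time_grid must be 1-D with at least two points")
    if t[0] != 0.0:
        raise ValueError("time_grid must start at t = 0")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time_grid must be strictly increasing")

    y0 = initial_payload_state(params).as_array()

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return payload_rhs(PayloadState.from_array(y), params).as_array()

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        y0,
        t_eval=t,
        rtol=rtol,
        atol=atol,
        method=method,
        **solver_options,
    )
    if not sol.success:
        raise IntegrationError(
            f"payload integration failed: {sol.message}",
            diagnostics={"nfev": sol.nfev, "status": sol.status},
        )
    y = sol.y
    if np.any(y < -atol):
        raise IntegrationError(
            f"negative concentration beyond tolerance: min={y.min():.3e}",
            diagnostics={"atol": atol},
        )
    y = np.where(y < 0.0, 0.0, y)
    return Trajectory(
        time=t,
        series={
            "C_int_p": y[0],
            "C_int_n": y[1],
            "C_ext_p": y[2],
            "total_intracellular": y[0] + y[1],
        },
        metadata={
            "model": "payload",
            "k_in": params.k_in,
            "k_out": params.k_out,
            "beta": params.beta,
            "c0": params.c0,
            "solver": {"method": method, "rtol": rtol, "atol": atol},
            "nfev": int(sol.nfev),
        },
    )


def total_intracellular(traj: Trajectory) -> np.ndarray:
    """Pointwise ``C_int_p + C_int_n`` series of a payload trajectory.

    For fixed ``(k_in, k_out, C0)`` this series is independent of
    ``beta``: summing the two intracellular equations eliminates the
    beta-weighted partition of the influx.
    """
    return traj["C_int_p"] + traj["C_int_n"]
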