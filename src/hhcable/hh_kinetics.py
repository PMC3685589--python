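"""Hodgkin-Huxley channel kinetics for the squid giant axon membrane.

This module holds the voltage-dependent rate constants of the classic
squid-axon sodium and potassium channels, their steady states and time
constants, the Q10 temperature coefficient applied to all gating rates,
Nernst equilibrium potentials, and the instantaneous ionic current
densities.  Everything here is a pure function of its arguments; the
cable integrator in :mod:`hhcable.cable_model` consumes these.

Unit conventions: voltages in mV, time in ms, rates in 1/ms, specific
conductances in S/cm2, current densities in mA/cm2, concentrations in mM,
temperatures in degrees Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "ActiveParams",
    "GatingState",
    "rate_constants",
    "steady_state",
    "q10_factor",
    "nernst",
    "channel_currents",
]

# Gas constant (J/(mol K)) and Faraday constant (C/mol) as used in the
# Nernst potential; monovalent ions, so z = 1 throughout.
_R = 8.314
_F = 96485.3


@dataclass(frozen=True)
class ActiveParams:
    """Active membrane properties of the squid giant axon.

    Parameters
    ----------
    GNa, GK
        Maximum specific sodium / potassium conductances (S/cm2).
    Na_ext, Na_int, K_ext, K_int
        Extra-/intracellular ionic concentrations (mM).  The classic
        squid values are the defaults; the equilibrium potentials ENa
        and EK are derived from these via :func:`nernst`.
    Q10
        Ratio by which all six gating rates scale per 10 degC rise.
    T0
        Reference temperature (degC) at which the rate formulas hold;
        6.3 degC is the internal temperature of the squid giant axon.
    """

    GNa: float = 0.12
    GK: float = 0.036
    Na_ext: float = 440.0
    Na_int: float = 50.0
    K_ext: float = 20.0
    K_int: float = 400.0
    Q10: float = 3.0
    T0: float = 6.3

    def __post_init__(self) -> None:
        if self.GNa < 0 or self.GK < 0:
            raise InvalidInputError("conductances GNa, GK must be >= 0")
        for name in ("Na_ext", "Na_int", "K_ext", "K_int"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"concentration {name} must be > 0")
        if self.Q10 <= 0:
            raise InvalidInputError("Q10 must be > 0")


@dataclass
class GatingState:
    """Gating variables m (Na activation), h (Na inactivation recovery),
    n (K activation); arrays with one entry per compartment, each in [0, 1]."""

    m: np.ndarray
    h: np.ndarray
    n: np.ndarray

    def copy(self) -> "GatingState":
        return GatingState(self.m.copy(), self.h.copy(), self.n.copy())


def _vtrap(x, y):
    """Numerically stable x / (1 - exp(-x/y)).

    The expression has a removable singularity at x = 0 with limit y;
    writing the denominator via expm1 keeps full precision arbitrarily
    close to the singular point, and the exact zero is patched to the
    analytic limit.
    """
    x = np.asarray(x, dtype=float)
    u = x / y
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(u == 0.0, y, x / (-np.expm1(-u)))
    return out


def _check_voltage(V) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise InvalidInputError("membrane potential must be finite")
    return V


def rate_constants(V):
    """Six HH gating rate constants at membrane potential ``V`` (mV).

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)`` in
    1/ms, at the reference temperature (apply :func:`q10_factor` for
    other temperatures).  Voltages follow the modern convention
    (rest near -65 mV, extracellular potential zero).
    """
    V = _check_voltage(V)
    alpha_m = 0.1 * _vtrap(V + 40.0, 10.0)
    beta_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    alpha_n = 0.01 * _vtrap(V + 55.0, 10.0)
    beta_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def steady_state(V):
    """Steady-state gating values and time constants at ``V`` (mV).

    Returns ``(m_inf, h_inf, n_inf, tau_m, tau_h, tau_n)`` where
    x_inf = alpha/(alpha+beta) and tau_x = 1/(alpha+beta) (ms, at the
    reference temperature).
    """
    am, bm, ah, bh, an, bn = rate_constants(V)
    tau_m = 1.0 / (am + bm)
    tau_h = 1.0 / (ah + bh)
    tau_n = 1.0 / (an + bn)
    return am * tau_m, ah * tau_h, an * tau_n, tau_m, tau_h, tau_n


def q10_factor(T: float, T0: float = 6.3, Q10: float = 3.0) -> float:
    """Temperature coefficient k = Q10**((T - T0)/10).

    All six gating rates are multiplied by k before integration, so the
    kinetics speed up uniformly with temperature.
    """
    if Q10 <= 0:
        raise InvalidInputError("Q10 must be > 0")
    return float(Q10 ** ((T - T0) / 10.0))


def nernst(C_ext: float, C_int: float, T: float) -> float:
    """Nernst equilibrium potential (mV) for a monovalent cation.

    E = 1000 * R * (273.15 + T) / F * ln(C_ext / C_int), with R the gas
    constant, F the Faraday constant and T in degC.  Antisymmetric under
    swapping the two concentrations.
    """
    if C_ext <= 0 or C_int <= 0:
        raise InvalidInputError("concentrations must be > 0")
    return 1000.0 * _R * (273.15 + T) / _F * np.log(C_ext / C_int)


def channel_currents(V, g: GatingState, p: ActiveParams, GL: float,
                     EL: float, ENa: float, EK: float):
    """Instantaneous ionic current densities (mA/cm2) at potential ``V``.

    INa = GNa * m^3 h * (V - ENa), IK = GK * n^4 * (V - EK),
    Ileak = GL * (V - EL).  Outward current is positive; each component
    vanishes exactly when V sits at its equilibrium potential.
    """
    V = np.asarray(V, dtype=float)
    INa = p.GNa * g.m ** 3 * g.h * (V - ENa)
    IK = p.GK * g.n ** 4 * (V - EK)
    Ileak = GL * (V - EL)
    return INa, IK, Ileak
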