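"""Compartmental cable model of a cylindrical unmyelinated axon.

The axon is split into ``nseg`` equal cylindrical compartments.  Each
compartment carries the HH membrane (Na, K, leak) and is coupled to its
neighbours through the axoplasmic resistance; the ends are sealed (zero
axial flux).  The membrane equation per compartment is

    Cm dV/dt = -(INa + IK + Ileak) + axial coupling + Iinj/area

integrated with a Crank-Nicolson (theta = 1/2) tridiagonal solve for the
voltage vector and an exact-exponential update of the gating variables
with the voltage frozen over the step (staggered in the usual way: the
gating state is advanced first with the pre-step voltage, then the
voltage step uses the fresh gating).  A first-order fully implicit
scheme (theta = 1) is selectable; both are unconditionally stable.

Units: lengths um (converted to cm internally), voltages mV, time ms,
specific conductances S/cm2, Cm uF/cm2, Ra Ohm*cm, injected current nA,
current densities mA/cm2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.linalg import solve_banded

from .errors import InvalidInputError, NumericalError
from .hh_kinetics import (ActiveParams, GatingState, channel_currents,
                          nernst, q10_factor, rate_constants, steady_state)
from .recording_analysis import SimulationResult
from .stimulus import StimulusTrain, current_at

__all__ = [
    "resting_leak_potential",
    "STIM_POSITION",
    "RECORD_POSITION",
    "AxonGeometry",
    "PassiveParams",
    "SimControl",
    "CableState",
    "Cable",
    "build_compartments",
    "CableModel",
    "initialize",
    "simulate",
]

# Fixed electrode locations (normalized position along the axon): the
# stimulating electrode sits near the left end, the measuring point at
# the middle, so propagated spikes are observed away from the stimulus
# artifact.
STIM_POSITION = 0.1
RECORD_POSITION = 0.5


@dataclass(frozen=True)
class AxonGeometry:
    """Cylinder dimensions and spatial discretization.

    ``nseg`` odd places a compartment center exactly at the middle of
    the axon, where the measuring point is.
    """

    L: float = 10000.0     # um
    diam: float = 500.0    # um
    nseg: int = 101

    def __post_init__(self) -> None:
        if self.L <= 0 or self.diam <= 0:
            raise InvalidInputError("L and diam must be > 0")
        if int(self.nseg) < 1 or self.nseg != int(self.nseg):
            raise InvalidInputError("nseg must be an integer >= 1")


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane and axoplasm properties.

    ``EL = None`` (the default) means the leak equilibrium potential is
    calculated automatically at model construction so that the initial
    potential Vinit is a genuine resting point of the membrane: the leak
    current then exactly balances the steady-state Na and K currents at
    Vinit.  This is necessary because the Nernst-derived ENa and EK vary
    with temperature and concentrations, and no single fixed EL keeps
    the membrane quiescent across those settings.  A numeric EL (e.g.
    the classic -54.3 mV) is honored verbatim.
    """

    GL: float = 0.0003          # S/cm2
    Cm: float = 1.0             # uF/cm2
    Ra: float = 35.4            # Ohm*cm
    EL: float | None = None     # mV; None -> balance at Vinit

    def __post_init__(self) -> None:
        if self.GL <= 0 or self.Cm <= 0 or self.Ra <= 0:
            raise InvalidInputError("GL, Cm and Ra must be > 0")


@dataclass(frozen=True)
class SimControl:
    """Integration control: step, total time, temperature, initial Vm."""

    dt: float = 0.025    # ms
    ts: float = 60.0     # ms
    T: float = 6.3       # degC
    Vinit: float = -65.0  # mV

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidInputError("dt must be > 0")
        if self.ts < self.dt:
            raise InvalidInputError("ts must be >= dt")


@dataclass
class CableState:
    """Per-compartment voltages and gating variables at time ``t``."""

    V: np.ndarray
    gating: GatingState
    t: float = 0.0

    def copy(self) -> "CableState":
        return CableState(self.V.copy(), self.gating.copy(), self.t)


class Cable(NamedTuple):
    """Discretized cable: per-compartment membrane area and the axial
    conductance between adjacent compartment centers."""

    dx_um: float
    area_cm2: np.ndarray       # nseg entries
    g_axial_S: np.ndarray      # nseg - 1 entries
    centers: np.ndarray        # normalized positions of compartment centers


def build_compartments(geom: AxonGeometry, pp: PassiveParams) -> Cable:
    """Split the cylinder into nseg compartments.

    Each compartment has membrane area pi*diam*dx (their sum is the full
    cylinder area pi*diam*L); adjacent compartment centers are connected
    by the axial conductance (pi*diam^2/4)/(Ra*dx) with lengths in cm.
    """
    nseg = int(geom.nseg)
    dx_um = geom.L / nseg
    area_cm2 = np.full(nseg, np.pi * geom.diam * dx_um * 1e-8)
    dx_cm = dx_um * 1e-4
    diam_cm = geom.diam * 1e-4
    g_ax = (np.pi * diam_cm ** 2 / 4.0) / (pp.Ra * dx_cm)
    g_axial_S = np.full(max(nseg - 1, 0), g_ax)
    centers = (np.arange(nseg) + 0.5) / nseg
    return Cable(dx_um, area_cm2, g_axial_S, centers)


def resting_leak_potential(ap: ActiveParams, GL: float, Vrest: float,
                           ENa: float, EK: float) -> float:
    """Leak reversal EL that makes ``Vrest`` a resting point.

    With gating at its steady state for Vrest, the leak current is set
    to cancel the steady-state Na and K currents:
    EL = Vrest + (INa + IK)/GL.
    """
    m_inf, h_inf, n_inf, *_ = steady_state(float(Vrest))
    INa = ap.GNa * m_inf ** 3 * h_inf * (Vrest - ENa)
    IK = ap.GK * n_inf ** 4 * (Vrest - EK)
    return float(Vrest + (INa + IK) / GL)


def compartment_index(position: float, nseg: int) -> int:
    """Index of the compartment containing normalized ``position``."""
    if not 0.0 <= position <= 1.0:
        raise InvalidInputError("position must lie in [0, 1]")
    return min(int(position * nseg), nseg - 1)


class CableModel:
    """Bound model: geometry + membrane parameters + integration setup.

    Precomputes the discretized cable, the temperature coefficient k and
    the Nernst potentials, and exposes :meth:`initialize`, :meth:`step`
    and :meth:`simulate`.
    """

    def __init__(self, geom: AxonGeometry = AxonGeometry(),
                 pp: PassiveParams = PassiveParams(),
                 ap: ActiveParams = ActiveParams(),
                 ctl: SimControl = SimControl(),
                 method: str = "cn"):
        if method not in ("cn", "implicit"):
            raise InvalidInputError("method must be 'cn' or 'implicit'")
        self.geom, self.pp, self.ap, self.ctl = geom, pp, ap, ctl
        self.method = method
        self.theta = 0.5 if method == "cn" else 1.0
        self.cable = build_compartments(geom, pp)
        self.k = q10_factor(ctl.T, ap.T0, ap.Q10)
        self.ENa = nernst(ap.Na_ext, ap.Na_int, ctl.T)
        self.EK = nernst(ap.K_ext, ap.K_int, ctl.T)
        if pp.EL is not None:
            self.EL = float(pp.EL)
        else:
            self.EL = resting_leak_potential(ap, pp.GL, ctl.Vinit,
                                             self.ENa, self.EK)
        # 1e3 converts mA/cm2 over uF/cm2 into mV/ms
        self._c = 1e3 / pp.Cm

    # ------------------------------------------------------------------
    def initialize(self) -> CableState:
        """All compartments at Vinit, gating at its steady state there."""
        nseg = int(self.geom.nseg)
        V = np.full(nseg, float(self.ctl.Vinit))
        m_inf, h_inf, n_inf, *_ = steady_state(V)
        return CableState(V, GatingState(m_inf.copy(), h_inf.copy(),
                                         n_inf.copy()), 0.0)

    # ------------------------------------------------------------------
    def _advance_gating(self, state: CableState, dt: float) -> None:
        """Exact exponential gating update with voltage frozen at the
        start of the step; all rates carry the Q10 factor k."""
        am, bm, ah, bh, an, bn = rate_constants(state.V)
        g = state.gating
        for x, a, b in ((g.m, am, bm), (g.h, ah, bh), (g.n, an, bn)):
            tot = self.k * (a + b)
            x_inf = a / (a + b)
            x += (x_inf - x) * -np.expm1(-dt * tot)

    def step(self, state: CableState, inj_nA: np.ndarray,
             dt: float) -> CableState:
        """Advance the state by one time step of length ``dt`` (ms).

        ``inj_nA`` is the per-compartment injected current (nA).
        Mutates and returns ``state``.  Raises :class:`NumericalError`
        naming the first offending compartment if the update produces a
        non-finite voltage.
        """
        if dt <= 0:
            raise InvalidInputError("dt must be > 0")
        if not np.all(np.isfinite(state.V)):
            bad = int(np.flatnonzero(~np.isfinite(state.V))[0])
            raise NumericalError(
                f"non-finite Vm in compartment {bad} at t = {state.t:g} ms")

        self._advance_gating(state, dt)
        g = state.gating

        gNa = self.ap.GNa * g.m ** 3 * g.h
        gK = self.ap.GK * g.n ** 4
        G = gNa + gK + self.pp.GL                       # S/cm2
        E = gNa * self.ENa + gK * self.EK + self.pp.GL * self.EL

        c = self._c
        a = self.cable.area_cm2
        gax = self.cable.g_axial_S
        nseg = a.size

        # tridiagonal Jacobian J (1/ms) of dV/dt = J V + b
        diag = -c * G
        lower = np.zeros(nseg)
        upper = np.zeros(nseg)
        if nseg > 1:
            w = c * gax / a[:-1]          # uniform areas: symmetric coupling
            upper[:-1] = w
            lower[1:] = w
            diag[:-1] -= w
            diag[1:] -= w
        b = c * E + c * 1e-6 * np.asarray(inj_nA) / a

        th = self.theta
        V = state.V
        rhs = V + (1.0 - th) * dt * (diag * V + b) + th * dt * b
        if nseg > 1:
            axial = np.zeros(nseg)
            axial[:-1] += upper[:-1] * V[1:]
            axial[1:] += lower[1:] * V[:-1]
            rhs += (1.0 - th) * dt * axial
            ab = np.zeros((3, nseg))
            ab[0, 1:] = -th * dt * upper[:-1]
            ab[1] = 1.0 - th * dt * diag
            ab[2, :-1] = -th * dt * lower[1:]
            V_new = solve_banded((1, 1), ab, rhs)
        else:
            V_new = rhs / (1.0 - th * dt * diag)

        if not np.all(np.isfinite(V_new)):
            bad = int(np.flatnonzero(~np.isfinite(V_new))[0])
            raise NumericalError(
                f"integration diverged in compartment {bad} "
                f"at t = {state.t + dt:g} ms")

        state.V = V_new
        state.t += dt
        return state

    # ------------------------------------------------------------------
    def simulate(self, stim: StimulusTrain = StimulusTrain(),
                 record_position: float = RECORD_POSITION,
                 stim_position: float = STIM_POSITION,
                 extra_record_positions: Sequence[float] = ()
                 ) -> SimulationResult:
        """Run the full protocol and record traces at the measuring point.

        The injected current enters entirely into the single compartment
        containing ``stim_position``; the stimulus is sampled at the
        midpoint of each step.  Trace length is floor(ts/dt) + 1.
        """
        ctl = self.ctl
        nseg = int(self.geom.nseg)
        nsteps = int(np.floor(ctl.ts / ctl.dt + 1e-9))
        time = np.arange(nsteps + 1) * ctl.dt

        i_rec = compartment_index(record_position, nseg)
        i_stim = compartment_index(stim_position, nseg)
        i_extra = {p: compartment_index(p, nseg)
                   for p in extra_record_positions}

        state = self.initialize()
        vm = np.empty(nsteps + 1)
        m = np.empty(nsteps + 1)
        h = np.empty(nsteps + 1)
        n = np.empty(nsteps + 1)
        extra = {p: np.empty(nsteps + 1) for p in i_extra}

        def record(idx: int) -> None:
            vm[idx] = state.V[i_rec]
            m[idx] = state.gating.m[i_rec]
            h[idx] = state.gating.h[i_rec]
            n[idx] = state.gating.n[i_rec]
            for p, j in i_extra.items():
                extra[p][idx] = state.V[j]

        record(0)
        inj = np.zeros(nseg)
        for istep in range(nsteps):
            t_mid = (istep + 0.5) * ctl.dt
            inj[i_stim] = current_at(t_mid, stim)
            self.step(state, inj, ctl.dt)
            record(istep + 1)

        gate = GatingState(m, h, n)
        ina, ik, ileak = channel_currents(vm, gate, self.ap, self.pp.GL,
                                          self.EL, self.ENa, self.EK)
        icap = 1e-3 * self.pp.Cm * np.gradient(vm, ctl.dt)
        im = ina + ik + ileak + icap

        metadata = {
            "geometry": {"L": self.geom.L, "diam": self.geom.diam,
                         "nseg": nseg},
            "passive": {"GL": self.pp.GL, "Cm": self.pp.Cm,
                        "Ra": self.pp.Ra, "EL": self.EL},
            "active": {"GNa": self.ap.GNa, "GK": self.ap.GK,
                       "Na_ext": self.ap.Na_ext, "Na_int": self.ap.Na_int,
                       "K_ext": self.ap.K_ext, "K_int": self.ap.K_int,
                       "Q10": self.ap.Q10, "T0": self.ap.T0},
            "general": {"dt": ctl.dt, "ts": ctl.ts, "T": ctl.T,
                        "Vinitial": ctl.Vinit},
            "stimulus": {"NoStim": stim.NoStim, "Amp": stim.Amp,
                         "Dur": stim.Dur, "Delay": stim.Delay,
                         "tintp": stim.tintp},
            "electrodes": {"stim_position": stim_position,
                           "record_position": record_position},
            "method": self.method,
        }
        return SimulationResult(time=time, vm=vm, ina=ina, ik=ik,
                                ileak=ileak, icap=icap, im=im,
                                m=m, h=h, n=n,
                                record_position=record_position,
                                extra_vm=extra, metadata=metadata)


# Thin functional wrappers -------------------------------------------------

def initialize(geom: AxonGeometry, pp: PassiveParams, ap: ActiveParams,
               ctl: SimControl) -> CableState:
    """Initial state: uniform Vinit, gating at steady state."""
    return CableModel(geom, pp, ap, ctl).initialize()


def simulate(geom: AxonGeometry = AxonGeometry(),
             pp: PassiveParams = PassiveParams(),
             ap: ActiveParams = ActiveParams(),
             ctl: SimControl = SimControl(),
             stim: StimulusTrain = StimulusTrain(),
             **kwargs) -> SimulationResult:
    """One-call simulation with explicit parameter bundles."""
    return CableModel(geom, pp, ap, ctl).simulate(stim, **kwargs)
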