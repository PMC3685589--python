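"""Closed-form derived electrophysiological and geometric quantities.

These are the passive cable constants, the heuristic propagation
velocity, the cylinder area/volume, the Nernst equilibrium potentials
and the stimulus frequency that accompany every run.  Each formula
operates on plain numbers in the panel units (lengths um, GL S/cm2,
Cm uF/cm2, Ra Ohm*cm) and carries its unit-conversion prefactor
explicitly, so the displayed values are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError
from .hh_kinetics import ActiveParams, nernst, q10_factor
from .stimulus import StimulusTrain, stimulus_frequency

__all__ = [
    "DerivedParams",
    "membrane_resistance",
    "time_constant",
    "space_constant",
    "predicted_velocity",
    "membrane_area",
    "axon_volume",
    "compute_derived",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise InvalidInputError(f"{name} must be > 0, got {value!r}")


def membrane_resistance(GL: float) -> float:
    """Specific membrane resistance Rm = 1/GL (Ohm*cm2), GL in S/cm2."""
    _require_positive(GL=GL)
    return 1.0 / GL


def time_constant(Cm: float, GL: float) -> float:
    """Membrane time constant Tau = 1e-3 * Cm/GL (ms), Cm in uF/cm2."""
    _require_positive(Cm=Cm, GL=GL)
    return 1e-3 * Cm / GL


def space_constant(diam: float, Ra: float, GL: float) -> float:
    """Passive space constant Lambda = 1e-2 * sqrt(diam/(4 Ra GL)) (cm).

    ``diam`` in um, ``Ra`` in Ohm*cm, ``GL`` in S/cm2.
    """
    _require_positive(diam=diam, Ra=Ra, GL=GL)
    return 1e-2 * math.sqrt(diam / (4.0 * Ra * GL))


def predicted_velocity(Lambda: float, Tau: float) -> float:
    """Heuristic propagation velocity v = 10 * Lambda/Tau (m/s).

    This is the passive-cable estimate lambda/tau; the empirically
    measured conduction velocity lives in
    :func:`hhcable.recording_analysis.measured_velocity` and the two are
    reported side by side, neither correcting the other.
    """
    _require_positive(Lambda=Lambda, Tau=Tau)
    return 10.0 * Lambda / Tau


def membrane_area(diam: float, L: float) -> float:
    """Lateral membrane area of the cylinder, Ac = pi*diam*L (um2)."""
    _require_positive(diam=diam, L=L)
    return math.pi * diam * L


def axon_volume(diam: float, L: float) -> float:
    """Axoplasmic volume of the cylinder, Vc = pi*diam^2*L/4 (um3)."""
    _require_positive(diam=diam, L=L)
    return math.pi * diam ** 2 * L / 4.0


@dataclass(frozen=True)
class DerivedParams:
    """Bundle of all automatically computed quantities for one run.

    ``fe`` is ``None`` when the stimulus train is empty (no frequency
    is defined for zero pulses).
    """

    Rm: float        # Ohm*cm2
    Tau: float       # ms
    Lambda: float    # cm
    v: float         # m/s (predicted, passive heuristic)
    Ac: float        # um2
    Vc: float        # um3
    ENa: float       # mV
    EK: float        # mV
    k: float         # dimensionless temperature coefficient
    fe: float | None  # Hz

    def as_dict(self) -> dict:
        return {
            "Rm_Ohmcm2": self.Rm,
            "Tau_ms": self.Tau,
            "Lambda_cm": self.Lambda,
            "v_m_per_s": self.v,
            "Ac_um2": self.Ac,
            "Vc_um3": self.Vc,
            "ENa_mV": self.ENa,
            "EK_mV": self.EK,
            "k": self.k,
            "fe_Hz": self.fe,
        }


def compute_derived(geom, pp, ap: ActiveParams, ctl,
                    stim: StimulusTrain | None = None) -> DerivedParams:
    """Assemble every derived quantity for a configuration.

    ``geom``, ``pp`` and ``ctl`` are the AxonGeometry, PassiveParams and
    SimControl of :mod:`hhcable.cable_model` (imported lazily here to
    keep this module free of the integrator).
    """
    Tau = time_constant(pp.Cm, pp.GL)
    Lambda = space_constant(geom.diam, pp.Ra, pp.GL)
    fe = None
    if stim is not None and stim.NoStim >= 1:
        fe = stimulus_frequency(stim.NoStim, stim.Dur, stim.tintp)
    return DerivedParams(
        Rm=membrane_resistance(pp.GL),
        Tau=Tau,
        Lambda=Lambda,
        v=predicted_velocity(Lambda, Tau),
        Ac=membrane_area(geom.diam, geom.L),
        Vc=axon_volume(geom.diam, geom.L),
        ENa=nernst(ap.Na_ext, ap.Na_int, ctl.T),
        EK=nernst(ap.K_ext, ap.K_int, ctl.T),
        k=q10_factor(ctl.T, ap.T0, ap.Q10),
        fe=fe,
    )
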