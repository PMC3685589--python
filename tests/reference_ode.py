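"""Independent high-accuracy reference for the space-clamped membrane.

Integrates the four-variable (V, m, h, n) point-membrane system with
scipy's stiff Radau solver at tight tolerances, splitting the time axis
at the stimulus discontinuities so the adaptive solver cannot step over
a pulse.  Used as the oracle for the single-compartment cable runs; it
shares only the rate-constant formulas with the implementation under
test, not the integrator.
"""

import numpy as np
from scipy.integrate import solve_ivp

from hhcable.hh_kinetics import rate_constants, steady_state
from hhcable.stimulus import current_at


def reference_voltage(model, stim, t_eval):
    """Reference Vm(t) for a single-compartment CableModel + stimulus."""
    area = model.cable.area_cm2[0]
    ap, pp = model.ap, model.pp
    ENa, EK, EL, k = model.ENa, model.EK, model.EL, model.k

    def rhs_for(inj_nA):
        dens = inj_nA * 1e-6 / area

        def rhs(t, y):
            V, m, h, n = y
            am, bm, ah, bh, an, bn = rate_constants(V)
            INa = ap.GNa * m ** 3 * h * (V - ENa)
            IK = ap.GK * n ** 4 * (V - EK)
            IL = pp.GL * (V - EL)
            return [1e3 / pp.Cm * (-(INa + IK + IL) + dens),
                    k * (am * (1 - m) - bm * m),
                    k * (ah * (1 - h) - bh * h),
                    k * (an * (1 - n) - bn * n)]
        return rhs

    # breakpoints at every pulse edge
    edges = [0.0]
    for i in range(stim.NoStim):
        start = stim.Delay + i * (stim.Dur + stim.tintp)
        edges += [start, start + stim.Dur]
    t_end = float(t_eval[-1])
    edges = sorted({e for e in edges if e < t_end} | {t_end})

    m0, h0, n0, *_ = steady_state(float(model.ctl.Vinit))
    y = [float(model.ctl.Vinit), float(m0), float(h0), float(n0)]
    V_parts, t_parts = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        inj = current_at((a + b) / 2.0, stim)
        sol = solve_ivp(rhs_for(inj), [a, b], y, method="Radau",
                        rtol=1e-10, atol=1e-12, dense_output=True)
        mask = (t_eval >= a) & (t_eval < b)
        V_parts.append(sol.sol(t_eval[mask])[0])
        t_parts.append(t_eval[mask])
        y = sol.y[:, -1]
    if np.isclose(t_eval[-1], t_end):
        V_parts.append(np.array([y[0]]))
        t_parts.append(np.array([t_end]))
    V = np.concatenate(V_parts)
    assert np.allclose(np.concatenate(t_parts), t_eval)
    return V
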