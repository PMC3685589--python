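"""Post-processing of simulated voltage traces.

Spike detection by upward threshold crossing with a debounce interval,
spike counting at the fixed measuring point, full width at half maximum
of individual spikes, and the empirically measured conduction velocity
from two recording sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "SimulationResult",
    "DEFAULT_SPIKE_THRESHOLD",
    "DEFAULT_MIN_SEPARATION",
    "detect_spikes",
    "count_propagated_aps",
    "spike_half_width",
    "measured_velocity",
]

# HH action potentials overshoot 0 mV robustly, and inter-spike
# intervals at squid temperatures far exceed 1 ms.
DEFAULT_SPIKE_THRESHOLD = 0.0   # mV
DEFAULT_MIN_SEPARATION = 1.0    # ms


@dataclass
class SimulationResult:
    """Time-aligned traces recorded at the measuring point.

    All traces share the length of ``time`` (uniform spacing ``dt``).
    ``extra_vm`` maps additional normalized recording positions to their
    Vm traces (used for velocity measurement); ``metadata`` carries the
    full configuration and the derived parameters of the run.
    """

    time: np.ndarray        # ms
    vm: np.ndarray          # mV at the measuring point
    ina: np.ndarray         # mA/cm2
    ik: np.ndarray          # mA/cm2
    ileak: np.ndarray       # mA/cm2
    icap: np.ndarray        # mA/cm2 (capacitive, Cm * dV/dt)
    im: np.ndarray          # mA/cm2 (total = ionic + capacitive)
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    record_position: float = 0.5
    extra_vm: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def m3(self) -> np.ndarray:
        return self.m ** 3

    @property
    def m3h(self) -> np.ndarray:
        return self.m ** 3 * self.h

    @property
    def n4(self) -> np.ndarray:
        return self.n ** 4


def detect_spikes(time, vm, threshold: float = DEFAULT_SPIKE_THRESHOLD,
                  min_separation: float = DEFAULT_MIN_SEPARATION) -> np.ndarray:
    """Times (ms) of upward crossings of ``threshold`` in ``vm``.

    A crossing is counted at the first sample at or above threshold;
    crossings closer than ``min_separation`` to the previously accepted
    one are discarded (debouncing).  Returns a strictly increasing array.
    """
    time = np.asarray(time, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if vm.size == 0:
        raise InvalidInputError("empty trace")
    above = vm >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    spikes: list[float] = []
    for i in crossings:
        t = time[i]
        if not spikes or t - spikes[-1] >= min_separation:
            spikes.append(t)
    return np.asarray(spikes)


def count_propagated_aps(result: SimulationResult,
                         threshold: float = DEFAULT_SPIKE_THRESHOLD,
                         min_separation: float = DEFAULT_MIN_SEPARATION) -> int:
    """Number of action potentials arriving at the measuring point."""
    return int(detect_spikes(result.time, result.vm, threshold,
                             min_separation).size)


def _peak_index_for_spike(time, vm, spike_times, spike_index,
                          threshold) -> int:
    """Sample index of the maximum of the indexed spike."""
    start = int(np.searchsorted(time, spike_times[spike_index]))
    if spike_index + 1 < len(spike_times):
        stop = int(np.searchsorted(time, spike_times[spike_index + 1]))
    else:
        stop = len(time)
    return start + int(np.argmax(vm[start:stop]))


def spike_half_width(result: SimulationResult, spike_index: int = 0,
                     threshold: float = DEFAULT_SPIKE_THRESHOLD,
                     min_separation: float = DEFAULT_MIN_SEPARATION) -> float:
    """Full width at half maximum (ms) of the indexed spike.

    Height is measured from the resting baseline (Vm at the first sample
    of the run) to the spike peak; the two half-height crossing times
    are located by linear interpolation between adjacent samples.
    """
    time, vm = result.time, result.vm
    spikes = detect_spikes(time, vm, threshold, min_separation)
    if spike_index >= spikes.size:
        raise InvalidInputError(
            f"spike {spike_index} requested but only {spikes.size} detected")
    baseline = float(vm[0])
    ipk = _peak_index_for_spike(time, vm, spikes, spike_index, threshold)
    half = baseline + 0.5 * (vm[ipk] - baseline)

    # walk left from the peak to the last sample below half-height
    i = ipk
    while i > 0 and vm[i - 1] >= half:
        i -= 1
    if i == 0:
        raise InvalidInputError("spike has no rising half-height crossing")
    t_rise = np.interp(half, [vm[i - 1], vm[i]], [time[i - 1], time[i]])

    j = ipk
    while j < len(vm) - 1 and vm[j + 1] >= half:
        j += 1
    if j == len(vm) - 1:
        raise InvalidInputError("spike has no falling half-height crossing")
    # vm decreasing across [j, j+1]; interpolate on the reversed pair
    t_fall = np.interp(half, [vm[j + 1], vm[j]], [time[j + 1], time[j]])
    return float(t_fall - t_rise)


def _interpolated_peak_time(time, vm, threshold, min_separation) -> float:
    """First-spike peak time refined by parabolic interpolation.

    Fitting a parabola through the three samples around the discrete
    maximum makes the estimate robust to the sampling step dt.
    """
    spikes = detect_spikes(time, vm, threshold, min_separation)
    if spikes.size == 0:
        raise InvalidInputError("no spike in trace")
    ipk = _peak_index_for_spike(time, vm, spikes, 0, threshold)
    if ipk == 0 or ipk == len(vm) - 1:
        return float(time[ipk])
    y0, y1, y2 = vm[ipk - 1], vm[ipk], vm[ipk + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(time[ipk])
    shift = 0.5 * (y0 - y2) / denom
    dt = time[1] - time[0]
    return float(time[ipk] + shift * dt)


def measured_velocity(result: SimulationResult, x1: float, x2: float,
                      threshold: float = DEFAULT_SPIKE_THRESHOLD,
                      min_separation: float = DEFAULT_MIN_SEPARATION) -> float:
    """Empirical conduction velocity (m/s) between two recording sites.

    ``x1`` and ``x2`` are normalized positions along the axon whose Vm
    traces are available in the result (the measuring point itself or
    entries of ``extra_vm``).  Velocity is the site separation divided
    by the difference of the first-spike peak times.
    """
    L_um = result.metadata.get("geometry", {}).get("L")
    if L_um is None:
        raise InvalidInputError("result metadata lacks geometry.L")

    def trace_at(x: float) -> np.ndarray:
        if np.isclose(x, result.record_position):
            return result.vm
        for pos, tr in result.extra_vm.items():
            if np.isclose(x, pos):
                return np.asarray(tr)
        raise InvalidInputError(f"no recorded trace at position {x}")

    t1 = _interpolated_peak_time(result.time, trace_at(x1), threshold,
                                 min_separation)
    t2 = _interpolated_peak_time(result.time, trace_at(x2), threshold,
                                 min_separation)
    if t2 == t1:
        raise InvalidInputError("identical peak times; velocity undefined")
    dx_m = (x2 - x1) * L_um * 1e-6
    dt_s = (t2 - t1) * 1e-3
    return float(dx_m / dt_s)


def analysis_summary(result: SimulationResult) -> dict:
    """Spike count, spike times and first-spike FWHM for a run."""
    spikes = detect_spikes(result.time, result.vm)
    summary = {
        "spike_count": int(spikes.size),
        "spike_times_ms": [float(t) for t in spikes],
    }
    if spikes.size:
        summary["fwhm_ms"] = spike_half_width(result, 0)
    return summary
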