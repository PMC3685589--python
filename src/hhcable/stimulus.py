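"""Current-clamp pulse-train stimuli and the stimulus-frequency formula.

A stimulus is a train of ``NoStim`` ideal square current pulses of
amplitude ``Amp`` (nA) and duration ``Dur`` (ms), the first starting at
``Delay`` (ms), with a gap of ``tintp`` (ms) between the end of one
pulse and the start of the next (so the pulse period is Dur + tintp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["StimulusTrain", "current_at", "stimulus_frequency"]


@dataclass(frozen=True)
class StimulusTrain:
    """Square current-pulse train for current-clamp stimulation.

    ``Amp`` is signed: positive depolarizes, negative hyperpolarizes.
    """

    NoStim: int = 1
    Amp: float = 12000.0
    Dur: float = 0.2
    Delay: float = 1.0
    tintp: float = 13.0

    def __post_init__(self) -> None:
        if self.NoStim < 0:
            raise InvalidInputError("NoStim must be >= 0")
        if self.NoStim > 0 and self.Dur <= 0:
            raise InvalidInputError("Dur must be > 0 when NoStim > 0")
        if self.Delay < 0:
            raise InvalidInputError("Delay must be >= 0")
        if self.NoStim > 1 and self.tintp < 0:
            raise InvalidInputError("tintp must be >= 0 when NoStim > 1")


def current_at(t, s: StimulusTrain):
    """Injected current (nA) at time ``t`` (ms); vectorized over ``t``.

    Pulse i occupies the half-open interval
    [Delay + i*(Dur + tintp), Delay + i*(Dur + tintp) + Dur) so a sample
    falling exactly on a pulse edge is counted once.
    """
    t = np.asarray(t, dtype=float)
    if s.NoStim == 0:
        out = np.zeros_like(t)
        return out if out.ndim else float(out)
    period = s.Dur + s.tintp
    rel = t - s.Delay
    idx = np.floor_divide(rel, period) if period > 0 else np.zeros_like(rel)
    phase = rel - idx * period if period > 0 else rel
    inside = (rel >= 0) & (idx < s.NoStim) & (phase < s.Dur)
    out = np.where(inside, s.Amp, 0.0)
    return out if out.ndim else float(out)


def stimulus_frequency(NoStim: int, Dur: float, tintp: float) -> float:
    """Stimulus frequency fe (Hz) of a pulse train.

    fe = 1e3 * NoStim / (NoStim*Dur + (NoStim-1)*tintp): the number of
    pulses divided by the total span of the train from the onset of the
    first pulse to the offset of the last, converted from ms to s.
    """
    if NoStim < 1:
        raise InvalidInputError("NoStim must be >= 1 to define a frequency")
    return 1e3 * NoStim / (NoStim * Dur + (NoStim - 1) * tintp)
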