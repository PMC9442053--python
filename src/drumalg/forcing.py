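"""Time-dependent culture forcing: light, dilution, inflow nitrate, pulses.

Internal time unit is hours.  Dilution rates are accepted in 1/d at the
public constructors (the unit culture experiments are reported in) and stored
in 1/h; light intensity is in umol photons m-2 s-1; nitrate in mol/L.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["PiecewiseConstant", "day_night_light", "ForcingProtocol"]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class PiecewiseConstant:
    """Right-continuous piecewise-constant function of time (hours).

    ``values[i]`` applies on ``[breaks[i-1], breaks[i])`` with ``breaks``
    strictly increasing interior breakpoints (len(values) == len(breaks) + 1).
    """

    values: tuple[float, ...]
    breaks: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.values) != len(self.breaks) + 1:
            raise ValueError("need exactly one more value than breakpoints")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    def __call__(self, t: float) -> float:
        return self.values[bisect_right(self.breaks, t)]

    @classmethod
    def constant(cls, value: float) -> "PiecewiseConstant":
        return cls((value,))


def day_night_light(
    i_max: float, photoperiod_h: float = 12.0, dawn_h: float = 0.0
) -> Callable[[float], float]:
    """Half-sinusoid day/night light profile.

    I(t) = i_max * sin(pi * s / photoperiod) while 0 <= s < photoperiod with
    s the time since the last dawn, and 0 at night.  This reconstructs the
    light monitoring of indoor day/night cultures where intensity ramps up to
    its noon maximum and back down over the photoperiod.
    """

    def light(t: float) -> float:
        s = (t - dawn_h) % HOURS_PER_DAY
        if s >= photoperiod_h:
            return 0.0
        return i_max * float(np.sin(np.pi * s / photoperiod_h))

    return light


@dataclass
class ForcingProtocol:
    """Forcing of one culture run.

    Attributes
    ----------
    light
        Light intensity I(t) (umol m-2 s-1), t in hours.
    dilution
        Piecewise-constant dilution rate D(t), stored in 1/h.
    inflow_substrate
        Piecewise-constant inflow nitrate concentration S_in(t), mol/L.
    pulses
        Instantaneous concentration additions ``(time_h, species, mol/L)``
        with strictly increasing times; applied as state jumps.
    light_breaks_per_day
        Times (hours since midnight-dawn) where the light profile has a
        discontinuous derivative; used as integration breakpoints.
    """

    light: Callable[[float], float]
    dilution: PiecewiseConstant
    inflow_substrate: PiecewiseConstant
    pulses: list[tuple[float, str, float]] = field(default_factory=list)
    light_breaks_per_day: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        times = [p[0] for p in self.pulses]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("pulse times must be strictly increasing")
        for _, _, amount in self.pulses:
            if amount < 0:
                raise ValueError("pulse additions must be non-negative")

    # -- constructors ---------------------------------------------------------

    @classmethod
    def chemostat(
        cls, dilution_per_day: float, s_in: float, light_intensity: float
    ) -> "ForcingProtocol":
        """Constant-light chemostat at fixed dilution rate (1/d) and inflow."""
        return cls(
            light=lambda t: light_intensity,
            dilution=PiecewiseConstant.constant(dilution_per_day / HOURS_PER_DAY),
            inflow_substrate=PiecewiseConstant.constant(s_in),
        )

    @classmethod
    def day_night_starvation(
        cls,
        i_max: float = 1500.0,
        photoperiod_h: float = 12.0,
        d_replete_per_day: float = 0.25,
        d_starved_per_day: float = 0.1,
        s_in_replete: float = 2.0e-3,
        starvation_start_day: float = 1.0,
        pulse_day: float = 5.5,
        pulse_mgN_per_L: float = 2.7,
    ) -> "ForcingProtocol":
        """Day/night nitrogen-starvation protocol.

        12h:12h light peaking at ``i_max``; nitrate removed from the inflow at
        ``starvation_start_day`` (dilution lowered to avoid washout while
        growth is hindered) and restored at ``pulse_day`` together with an
        instantaneous nitrate pulse of ``pulse_mgN_per_L``.
        """
        t_starve = starvation_start_day * HOURS_PER_DAY
        t_pulse = pulse_day * HOURS_PER_DAY
        pulse_molN = pulse_mgN_per_L * 1e-3 / 14.0
        return cls(
            light=day_night_light(i_max, photoperiod_h),
            dilution=PiecewiseConstant(
                (d_replete_per_day / HOURS_PER_DAY,
                 d_starved_per_day / HOURS_PER_DAY,
                 d_replete_per_day / HOURS_PER_DAY),
                (t_starve, t_pulse),
            ),
            inflow_substrate=PiecewiseConstant(
                (s_in_replete, 0.0, s_in_replete), (t_starve, t_pulse)
            ),
            pulses=[(t_pulse, "NO3", pulse_molN)],
            light_breaks_per_day=(0.0, photoperiod_h),
        )

    # -- integration support --------------------------------------------------

    def breakpoints(self, t0: float, t1: float) -> list[float]:
        """Sorted interior event times in (t0, t1): light kinks, D/S_in steps, pulses."""
        pts: set[float] = set()
        for b in self.dilution.breaks:
            pts.add(b)
        for b in self.inflow_substrate.breaks:
            pts.add(b)
        for t, _, _ in self.pulses:
            pts.add(t)
        if self.light_breaks_per_day:
            day0 = int(np.floor(t0 / HOURS_PER_DAY)) - 1
            day1 = int(np.ceil(t1 / HOURS_PER_DAY)) + 1
            for d in range(day0, day1 + 1):
                for h in self.light_breaks_per_day:
                    pts.add(d * HOURS_PER_DAY + h)
        return sorted(p for p in pts if t0 < p < t1)

    def pulses_in(self, t0: float, t1: float) -> list[tuple[float, str, float]]:
        return [p for p in self.pulses if t0 < p[0] <= t1]
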