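"""Retort schedules: program notation and wall-temperature profiles.

Canning retort programs are written ``"a-b-...-c/T1-...-Tk"``: durations in
minutes (come-up, one or more holds, cooling), hold set-points in degC.
``"10-86-24/121"`` is a 10 min come-up to 121 degC, an 86 min hold, and a
24 min cool; ``"10-65-48-14/118-110"`` stacks two holds (65 min at 118 degC
then 48 min at 110 degC).  The wall boundary condition is piecewise linear:
linear come-up from the initial product temperature, constant holds (with a
short smoothing ramp between stacked holds), and a linear cool-down to the
cooling-water temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Phase", "RetortSchedule", "TabulatedRetortSchedule",
           "parse_schedule", "retort_temperature"]

C_TO_K = 273.15


class ScheduleParseError(ValueError):
    pass


@dataclass(frozen=True)
class Phase:
    kind: str          # "come_up" | "hold" | "cool"
    duration: float    # s
    target: float      # K reached at the end of the phase


@dataclass(frozen=True)
class RetortSchedule:
    """A parsed multi-phase retort program (all temperatures kelvin)."""

    phases: tuple[Phase, ...]
    come_up_start_temperature: float = 341.15
    cooling_water_temperature: float = 298.15
    hold_transition_s: float = 1.0  # smoothing of hold-to-hold steps
    notation: str = ""

    def __post_init__(self):
        kinds = [p.kind for p in self.phases]
        if len(kinds) < 3 or kinds[0] != "come_up" or kinds[-1] != "cool" \
                or any(k != "hold" for k in kinds[1:-1]):
            raise ValueError(
                "schedule must be come_up, >= 1 hold, cool; got " + "-".join(kinds)
            )
        if any(p.duration <= 0 for p in self.phases):
            raise ValueError("phase durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration for p in self.phases))

    @property
    def phase_starts(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([p.duration for p in self.phases])])

    @property
    def max_hold_temperature(self) -> float:
        return max(p.target for p in self.phases if p.kind == "hold")

    def format(self) -> str:
        """Reproduce the program notation this schedule was parsed from."""
        mins = [p.duration / 60.0 for p in self.phases]
        temps = [p.target - C_TO_K for p in self.phases if p.kind == "hold"]
        fmt = lambda x: f"{x:g}"
        return "-".join(fmt(m) for m in mins) + "/" + "-".join(fmt(t) for t in temps)


def parse_schedule(
    notation: str,
    come_up_start: float = 341.15,
    cooling_water: float = 298.15,
) -> RetortSchedule:
    """Parse ``"d1-d2-...-dn/T1-...-T(n-2)"`` (minutes / degC) into a schedule.

    The first duration is the come-up, the last the cool-down; each middle
    duration is a hold at the corresponding set-point.  Temperatures are
    converted to kelvin; the number of set-points must be exactly n - 2.
    """
    if "/" not in notation:
        raise ScheduleParseError(
            f"{notation!r}: expected 'durations/temperatures' with a '/'"
        )
    dur_part, temp_part = notation.split("/", 1)
    try:
        durations = [float(x) for x in dur_part.split("-")]
        temps_c = [float(x) for x in temp_part.split("-")]
    except ValueError as exc:
        raise ScheduleParseError(f"{notation!r}: non-numeric field ({exc})") from None
    n = len(durations)
    if n < 3:
        raise ScheduleParseError(
            f"{notation!r}: need at least come-up, hold and cool durations (got {n})"
        )
    if len(temps_c) != n - 2:
        raise ScheduleParseError(
            f"{notation!r}: {n} durations require {n - 2} hold temperatures, "
            f"got {len(temps_c)} (after '/')"
        )
    for pos, d in enumerate(durations):
        if d <= 0:
            raise ScheduleParseError(
                f"{notation!r}: duration #{pos + 1} must be positive, got {d:g}"
            )
    temps_k = [t + C_TO_K for t in temps_c]
    for pos, t in enumerate(temps_k):
        if t <= cooling_water:
            raise ScheduleParseError(
                f"{notation!r}: hold temperature #{pos + 1} ({temps_c[pos]:g} degC) "
                f"is not above the cooling water ({cooling_water - C_TO_K:g} degC)"
            )
    phases = [Phase("come_up", durations[0] * 60.0, temps_k[0])]
    for d, t in zip(durations[1:-1], temps_k):
        phases.append(Phase("hold", d * 60.0, t))
    phases.append(Phase("cool", durations[-1] * 60.0, cooling_water))
    return RetortSchedule(
        phases=tuple(phases),
        come_up_start_temperature=come_up_start,
        cooling_water_temperature=cooling_water,
        notation=notation,
    )


@dataclass(frozen=True)
class TabulatedRetortSchedule:
    """A measured retort log: wall temperature tabulated against time.

    Used to replay a recorded process in place of the program notation;
    linear interpolation between samples, held at the last value after the
    log ends.
    """

    times: np.ndarray         # s, strictly increasing from 0
    temperatures: np.ndarray  # K

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        T = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", T)
        if t.ndim != 1 or t.shape != T.shape or t.size < 2:
            raise ValueError("need matching 1-D times/temperatures, >= 2 rows")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and increase strictly")

    @classmethod
    def from_csv(cls, path) -> "TabulatedRetortSchedule":
        from .export import read_probe_csv
        t, T = read_probe_csv(path)
        return cls(times=t, temperatures=T)

    @property
    def total_duration(self) -> float:
        return float(self.times[-1])

    @property
    def cooling_water_temperature(self) -> float:
        return float(self.temperatures[-1])

    @property
    def max_hold_temperature(self) -> float:
        return float(self.temperatures.max())


def retort_temperature(schedule, t) -> float | np.ndarray:
    """Wall (retort) temperature at time ``t`` seconds, kelvin.

    Continuous everywhere: linear ramps for come-up and cooling, constant
    holds, and hold-to-hold steps smoothed linearly over
    ``schedule.hold_transition_s``.  Past the schedule end it returns the
    cooling-water temperature.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if isinstance(schedule, TabulatedRetortSchedule):
        out = np.interp(t_arr, schedule.times, schedule.temperatures)
        return float(out) if np.ndim(t) == 0 else out
    starts = schedule.phase_starts
    out = np.full(t_arr.shape, schedule.cooling_water_temperature)
    prev_target = schedule.come_up_start_temperature
    for phase, t0, t1 in zip(schedule.phases, starts[:-1], starts[1:]):
        sel = (t_arr >= t0) & (t_arr < t1)
        if phase.kind in ("come_up", "cool"):
            frac = (t_arr - t0) / phase.duration
            out = np.where(sel, prev_target + frac * (phase.target - prev_target), out)
        else:  # hold: constant, with a short entry ramp if the set-point changed
            tau = min(schedule.hold_transition_s, phase.duration)
            if prev_target != phase.target and tau > 0:
                frac = np.clip((t_arr - t0) / tau, 0.0, 1.0)
                val = prev_target + frac * (phase.target - prev_target)
            else:
                val = np.full(t_arr.shape, phase.target)
            out = np.where(sel, val, out)
        prev_target = phase.target
    return float(out) if np.ndim(t) == 0 else out
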