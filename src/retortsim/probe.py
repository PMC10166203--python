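"""Thermal-penetration probe emulation and model-vs-measurement scoring.

A physical heat-penetration test threads a thermocouple through the lid to
the predicted cold point and records temperature through the whole retort
cycle.  The synthetic generator here stands in for that test: it applies a
first-order sensor lag and Gaussian measurement noise to a "true"
time-temperature series (typically one produced by the solver), so the
validation loop — simulate, measure, compare, integrate lethality by the
general method — can be exercised without hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lethality import LethalityConfig, lethal_rate

__all__ = ["ProbeSeries", "NoiseModel", "synthesize_probe",
           "general_method_F", "compare"]


@dataclass(frozen=True)
class ProbeSeries:
    """A time-temperature record at a fixed (r, z) position."""

    position: tuple[float, float]  # (r, z) m
    times: np.ndarray              # s, strictly increasing, starting at 0
    temperatures: np.ndarray       # K
    provenance: str = "simulated"  # simulated | synthetic | external

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        T = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", T)
        if t.shape != T.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and temperatures must be equal-length 1-D")
        if t[0] != 0.0:
            raise ValueError("probe series must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(T)):
            raise ValueError("temperatures must be finite")


@dataclass(frozen=True)
class NoiseModel:
    """First-order sensor lag plus Gaussian read-out noise.

    ``sigma`` defaults to 0.25 K, consistent with a +/-0.5 K initial-fill
    tolerance window read as ~2 sigma; ``tau`` is the probe time constant.
    """

    sigma: float = 0.25  # K
    tau: float = 5.0     # s
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.tau < 0:
            raise ValueError("sigma and tau must be non-negative")


def synthesize_probe(truth: ProbeSeries, noise: NoiseModel) -> ProbeSeries:
    """Pass a true series through the sensor model.

    The lag is integrated exactly per interval (piecewise-constant input
    would be crude for ramps, so the truth is treated as linear within each
    interval and the ODE dT_m/dt = (T - T_m)/tau solved in closed form),
    then i.i.d. N(0, sigma^2) noise is added with the model's seed.
    """
    t, T = truth.times, truth.temperatures
    meas = np.empty_like(T)
    meas[0] = T[0]
    if noise.tau == 0.0:
        meas[:] = T
    else:
        for i in range(1, t.size):
            dt = t[i] - t[i - 1]
            a = np.exp(-dt / noise.tau)
            # linear-in-interval input: exact response of a first-order lag
            slope = (T[i] - T[i - 1]) / dt
            meas[i] = (T[i] - slope * noise.tau
                       + (meas[i - 1] - T[i - 1] + slope * noise.tau) * a)
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        meas = meas + rng.normal(0.0, noise.sigma, size=meas.shape)
    return ProbeSeries(position=truth.position, times=t.copy(),
                       temperatures=meas, provenance="synthetic")


def general_method_F(series: ProbeSeries,
                     config: LethalityConfig = LethalityConfig()) -> float:
    """Classical (general-method) process lethality from a probe record.

    Trapezoidal integration of the lethal rate 10^((T-RT)/Z) over the whole
    series; returns minutes at the reference temperature.
    """
    if series.times.size < 2:
        raise ValueError("need at least two samples to integrate")
    rate = lethal_rate(series.temperatures, config)
    return float(np.trapezoid(rate, series.times) / 60.0)


def compare(predicted: ProbeSeries, measured: ProbeSeries,
            config: LethalityConfig = LethalityConfig()) -> dict:
    """Score a predicted curve against a measured one.

    The measured series is resampled onto the predicted time grid by linear
    interpolation; only the overlapping time range enters the RMSE and the
    maximum absolute deviation.  Both series also get a general-method F.
    """
    t_lo = max(predicted.times[0], measured.times[0])
    t_hi = min(predicted.times[-1], measured.times[-1])
    if t_hi <= t_lo:
        raise ValueError("series do not overlap in time")
    sel = (predicted.times >= t_lo) & (predicted.times <= t_hi)
    tp = predicted.times[sel]
    Tp = predicted.temperatures[sel]
    Tm = np.interp(tp, measured.times, measured.temperatures)
    resid = Tp - Tm
    return {
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
        "max_abs_dev": float(np.abs(resid).max()),
        "F_pred": general_method_F(predicted, config),
        "F_meas": general_method_F(measured, config),
        "n_overlap": int(sel.sum()),
    }
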