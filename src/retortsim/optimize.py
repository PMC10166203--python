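"""Schedule evaluation, comparison and exhaustive search.

A retort schedule is judged on two criteria pulling in opposite
directions: the cold point must accumulate at least the commercial-
sterility target F (safety), while the volume driven past the overheat
threshold (F > 25 min by default, the browning proxy) should be as small
as possible (quality).  Lower, longer processes narrow the F spread across
the can; the search here automates that trade-off over a candidate grid of
hold temperatures and times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .geometry import AxiMesh
from .lethality import LethalityConfig
from .schedule import RetortSchedule, parse_schedule
from .solver import SimulationResult, SolverConfig, simulate

logger = logging.getLogger(__name__)

__all__ = ["QualityReport", "ComparisonReport", "evaluate_schedule",
           "compare_schedules", "grid_search"]


@dataclass(frozen=True)
class QualityReport:
    """Lethality / quality summary of one simulated schedule."""

    schedule: RetortSchedule
    F_min: float            # min
    F_max: float            # min
    cold_point: tuple[float, float]  # (r, z) m
    oz_fraction: float      # puree-volume fraction with F > threshold
    total_process_time: float  # s
    meets_target: bool
    target_F: float         # min
    mesh: AxiMesh = None

    def summary(self) -> dict:
        return {
            "schedule": self.schedule.format(),
            "F_min": self.F_min,
            "F_max": self.F_max,
            "cold_point_r_m": self.cold_point[0],
            "cold_point_z_m": self.cold_point[1],
            "oz_fraction": self.oz_fraction,
            "total_process_time_s": self.total_process_time,
            "meets_target": self.meets_target,
            "target_F_min": self.target_F,
        }


@dataclass(frozen=True)
class ComparisonReport:
    """Baseline-vs-candidate schedule comparison."""

    baseline: QualityReport
    candidate: QualityReport
    oz_reduction_percent: float
    F_min_difference: float  # candidate - baseline, min
    time_penalty: float      # candidate - baseline, s
    equivalent_lethality: bool  # |dF_min| <= 10 % of baseline F_min

    def summary(self) -> dict:
        return {
            "baseline": self.baseline.summary(),
            "candidate": self.candidate.summary(),
            "oz_reduction_percent": self.oz_reduction_percent,
            "F_min_difference_min": self.F_min_difference,
            "time_penalty_s": self.time_penalty,
            "equivalent_lethality": self.equivalent_lethality,
        }


def report_from_result(result: SimulationResult,
                       leth_config: LethalityConfig) -> QualityReport:
    """Assemble a QualityReport from a finished simulation."""
    leth = result.lethality
    r, z = leth.cold_point
    return QualityReport(
        schedule=result.realized_schedule,
        F_min=leth.F_min,
        F_max=leth.F_max,
        cold_point=(r, z),
        oz_fraction=leth.oz_fraction,
        total_process_time=result.realized_schedule.total_duration,
        meets_target=leth.F_min >= leth_config.target_F,
        target_F=leth_config.target_F,
        mesh=result.config.mesh,
    )


def evaluate_schedule(
    schedule: RetortSchedule,
    solver_config: SolverConfig,
    leth_config: LethalityConfig | None = None,
) -> QualityReport:
    """Simulate the whole process under ``schedule`` and score it."""
    leth_config = leth_config or LethalityConfig()
    result = simulate(solver_config, schedule, probes=[],
                      lethality_config=leth_config)
    return report_from_result(result, leth_config)


def compare_schedules(baseline: QualityReport,
                      candidate: QualityReport) -> ComparisonReport:
    """Compare two reports produced on the same geometry and mesh."""
    if baseline.mesh is not None and candidate.mesh is not None:
        gb, gc = baseline.mesh.geometry, candidate.mesh.geometry
        if gb != gc:
            raise ValueError("reports come from different can geometries")
    if baseline.oz_fraction > 0:
        reduction = 100.0 * (1.0 - candidate.oz_fraction / baseline.oz_fraction)
    else:
        reduction = 0.0 if candidate.oz_fraction == 0 else -float("inf")
    dF = candidate.F_min - baseline.F_min
    equivalent = abs(dF) <= 0.10 * baseline.F_min if baseline.F_min > 0 else dF == 0
    return ComparisonReport(
        baseline=baseline,
        candidate=candidate,
        oz_reduction_percent=reduction,
        F_min_difference=dF,
        time_penalty=candidate.total_process_time - baseline.total_process_time,
        equivalent_lethality=equivalent,
    )


def grid_search(
    hold_temps: list[float],
    hold_times: list[float],
    stages: int,
    constraint: LethalityConfig,
    solver_config: SolverConfig,
    come_up_min: float = 10.0,
    cool_min: float = 20.0,
    extra_candidates: list[str] | None = None,
    budget: int = 64,
) -> list[QualityReport]:
    """Exhaustive search over single- or two-stage hold programs.

    Candidates are all combinations of hold temperatures (degC) and hold
    times (min): one hold for ``stages == 1``; for ``stages == 2`` every
    ordered pair with a strictly decreasing temperature sequence (the
    second stage finishes lower, the pattern that narrows the F spread).
    ``extra_candidates`` adds literal schedule strings to the pool.
    Feasible candidates (cold-point F >= target) are ranked by overheated
    fraction, then total process time; ties keep input order (stable sort).
    """
    if stages not in (1, 2):
        raise ValueError("stages must be 1 or 2")
    if not hold_temps or not hold_times:
        raise ValueError("hold_temps and hold_times must be non-empty")
    notations: list[str] = []
    if stages == 1:
        for T in hold_temps:
            for m in hold_times:
                notations.append(f"{come_up_min:g}-{m:g}-{cool_min:g}/{T:g}")
    else:
        for T1 in hold_temps:
            for T2 in hold_temps:
                if T2 >= T1:
                    continue
                for m1 in hold_times:
                    for m2 in hold_times:
                        notations.append(
                            f"{come_up_min:g}-{m1:g}-{m2:g}-{cool_min:g}/{T1:g}-{T2:g}"
                        )
    notations.extend(extra_candidates or [])
    if len(notations) > budget:
        raise ValueError(
            f"{len(notations)} candidates exceed the search budget of {budget}"
        )
    reports = []
    for notation in notations:
        schedule = parse_schedule(
            notation,
            come_up_start=solver_config.initial_temperature,
        )
        reports.append(evaluate_schedule(schedule, solver_config, constraint))
    feasible = [rep for rep in reports if rep.meets_target]
    if not feasible:
        logger.warning("no candidate meets the target F of %.2f min "
                       "(%d evaluated)", constraint.target_F, len(reports))
        return []
    # stable sort preserves input order on exact ties
    return sorted(feasible,
                  key=lambda rep: (rep.oz_fraction, rep.total_process_time))
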