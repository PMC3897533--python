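"""Factorial scenario design, runners, log response ratios and flux budgets.

The experiment families mirror the study design: a subsidy gradient
(terrestrial prey flux at 0–200% of the field rate, reference benthic
assemblage), an armoring gradient (0–100% of initial invertebrate
biomass armored, reference subsidies), and a 2×2 predator
presence/absence factorial crossed with each.  Scenario outcomes are
compared with log response ratios LRR = ln(X_E / X_C) of day-90 pool
biomasses, and emergence-vs-consumption flux budgets summarize how much
benthic production leaves the stream as winged adults versus entering
predators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import Trajectory, simulate
from .params import (
    ALGAE_0,
    ARMORED_FRACTION_REF,
    INVERTEBRATE_TOTAL_0,
    SALAMANDER_0,
    TROUT_0,
    FoodWebState,
    ModelParams,
    default_initial_detritus,
)

__all__ = [
    "Scenario",
    "Run",
    "SUBSIDY_GRID",
    "ARMORING_GRID",
    "PREDATOR_COMBOS",
    "build_scenarios",
    "initial_state_for",
    "run_scenario",
    "run_scenarios",
    "log_response_ratio",
    "predator_effect_lrr",
    "flux_budget",
    "FluxBudget",
    "summarize",
    "UndefinedLRRError",
    "UndefinedRatioError",
    "MissingScenarioError",
]

SUBSIDY_GRID: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
ARMORING_GRID: tuple[float, ...] = (0.0, 0.2, 0.4, ARMORED_FRACTION_REF, 0.8, 1.0)
#: (trout_present, salamander_present)
PREDATOR_COMBOS: tuple[tuple[bool, bool], ...] = (
    (False, False), (True, False), (False, True), (True, True))


class UndefinedLRRError(ValueError):
    """LRR requested for a non-positive biomass."""


class UndefinedRatioError(ZeroDivisionError):
    """Flux ratio requested with zero denominator."""


class MissingScenarioError(KeyError):
    """A presence/absence contrast is missing one member."""


def _predator_tag(trout: bool, salamander: bool) -> str:
    return {(False, False): "none", (True, False): "T",
            (False, True): "S", (True, True): "TS"}[(trout, salamander)]


@dataclass(frozen=True)
class Scenario:
    """One cell of the factorial design."""

    subsidy_multiplier: float = 1.0
    armored_fraction: float = ARMORED_FRACTION_REF
    trout_present: bool = True
    salamander_present: bool = True
    days: int = 90
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.subsidy_multiplier < 0:
            raise ValueError("subsidy_multiplier must be >= 0")
        if not 0.0 <= self.armored_fraction <= 1.0:
            raise ValueError("armored_fraction must lie in [0, 1]")
        if self.days < 1:
            raise ValueError("days must be >= 1")

    @property
    def scenario_id(self) -> str:
        return (f"sub{round(100 * self.subsidy_multiplier)}"
                f"_arm{round(1000 * self.armored_fraction) / 10:g}"
                f"_{_predator_tag(self.trout_present, self.salamander_present)}")


REFERENCE_SCENARIO = Scenario(is_control=True)


def build_scenarios(
    subsidy_grid: Sequence[float] | None = None,
    armoring_grid: Sequence[float] | None = None,
    predator_combos: Sequence[tuple[bool, bool]] | None = None,
    days: int = 90,
) -> list[Scenario]:
    """Build the full factorial scenario set.

    The subsidy gradient runs at the reference assemblage; the armoring
    gradient runs at reference subsidies; each is crossed with every
    predator combination.  The reference cell (100% subsidy, reference
    armoring, both predators) appears exactly once, flagged as control.
    ``armored_fraction`` partitions both functional groups identically,
    conserving the total initial invertebrate biomass.
    """
    subsidy_grid = tuple(SUBSIDY_GRID if subsidy_grid is None else subsidy_grid)
    armoring_grid = tuple(ARMORING_GRID if armoring_grid is None else armoring_grid)
    combos = tuple(PREDATOR_COMBOS if predator_combos is None else predator_combos)
    if not subsidy_grid or not armoring_grid or not combos:
        raise ValueError("scenario grids must be non-empty")
    out: dict[str, Scenario] = {}

    def add(sc: Scenario) -> None:
        out.setdefault(sc.scenario_id, sc)

    for mult in subsidy_grid:
        for trout, sal in combos:
            add(Scenario(subsidy_multiplier=mult, trout_present=trout,
                         salamander_present=sal, days=days,
                         is_control=(mult == 1.0 and trout and sal)))
    for frac in armoring_grid:
        for trout, sal in combos:
            add(Scenario(armored_fraction=frac, trout_present=trout,
                         salamander_present=sal, days=days,
                         is_control=(frac == ARMORED_FRACTION_REF and trout and sal)))
    return list(out.values())


def initial_state_for(
    scenario: Scenario,
    params: ModelParams,
    D_0: float | None = None,
    total_invertebrates: float = INVERTEBRATE_TOTAL_0,
    algae_0: float = ALGAE_0,
    trout_0: float = TROUT_0,
    salamander_0: float = SALAMANDER_0,
) -> FoodWebState:
    """Starting pools for a scenario.

    The total benthic standing stock is conserved across
    ``armored_fraction`` values; within each vulnerability class the
    algivore/detritivore split is 50/50.  An absent predator starts (and
    stays) at zero biomass.  ``D_0`` defaults to the input/consumption
    balance point.
    """
    f = scenario.armored_fraction
    G0 = f * total_invertebrates
    H0 = total_invertebrates - G0
    detritivores = 0.5 * (H0 + G0)
    if D_0 is None:
        D_0 = default_initial_detritus(params, detritivores)
    return FoodWebState(
        A=algae_0, D=D_0,
        H_alg=0.5 * H0, H_det=0.5 * H0,
        G_alg=0.5 * G0, G_det=0.5 * G0,
        T=trout_0 if scenario.trout_present else 0.0,
        S=salamander_0 if scenario.salamander_present else 0.0,
    )


@dataclass
class Run:
    """A completed scenario simulation."""

    scenario: Scenario
    trajectory: Trajectory


def run_scenario(
    scenario: Scenario,
    params: ModelParams,
    D_0: float | None = None,
    **state_kwargs,
) -> Run:
    """Simulate one scenario: scale X by the subsidy multiplier and run."""
    p = params.replace(X=params.X * scenario.subsidy_multiplier)
    state0 = initial_state_for(scenario, params, D_0=D_0, **state_kwargs)
    traj = simulate(state0, p, days=scenario.days,
                    trout_present=scenario.trout_present,
                    salamander_present=scenario.salamander_present,
                    scenario_id=scenario.scenario_id)
    return Run(scenario=scenario, trajectory=traj)


def run_scenarios(
    scenarios: Iterable[Scenario],
    params: ModelParams,
    D_0: float | None = None,
    **state_kwargs,
) -> dict[str, Run]:
    """Run every scenario; returns {scenario_id: Run}."""
    return {sc.scenario_id: run_scenario(sc, params, D_0=D_0, **state_kwargs)
            for sc in scenarios}


def log_response_ratio(x_experiment: float, x_control: float) -> float:
    """LRR = ln(x_experiment / x_control); both inputs must be > 0."""
    if x_experiment <= 0 or x_control <= 0:
        raise UndefinedLRRError(
            f"LRR undefined for non-positive biomass "
            f"({x_experiment!r}, {x_control!r})")
    return math.log(x_experiment / x_control)


_RESPONSES = ("A", "D", "H", "G", "T", "S")


def _response_value(run: Run, variable: str) -> float:
    if variable == "mean_emergence":
        return run.trajectory.mean_emergence()
    return float(run.trajectory.final[variable])


def predator_effect_lrr(
    runs: Mapping[str, Run] | Iterable[Run],
    predator: str,
    response_variable: str,
) -> pd.DataFrame:
    """Predator presence-vs-absence LRRs at matched subsidy/armoring.

    ``predator`` is one of ``"trout"`` (trout-only vs no-predator),
    ``"salamander"`` (salamander-only vs no-predator) or ``"both"``.
    One row per (subsidy_multiplier, armored_fraction) for which both
    pair members exist; a missing member raises
    :class:`MissingScenarioError` naming it.
    """
    flags = {"trout": (True, False), "salamander": (False, True),
             "both": (True, True)}
    try:
        pres = flags[predator]
    except KeyError:
        raise ValueError(f"unknown predator {predator!r}") from None
    if not isinstance(runs, Mapping):
        runs = {r.scenario.scenario_id: r for r in runs}
    by_key = {(r.scenario.subsidy_multiplier, r.scenario.armored_fraction,
               r.scenario.trout_present, r.scenario.salamander_present): r
              for r in runs.values()}
    rows = []
    seen = set()
    for (mult, frac, trout, sal), run in by_key.items():
        if (trout, sal) != pres or (mult, frac) in seen:
            continue
        seen.add((mult, frac))
        ctrl_key = (mult, frac, False, False)
        if ctrl_key not in by_key:
            raise MissingScenarioError(
                f"no-predator control missing for subsidy={mult}, "
                f"armored_fraction={frac}")
        ctrl = by_key[ctrl_key]
        rows.append({
            "response_variable": response_variable,
            "predator": predator,
            "subsidy_multiplier": mult,
            "armored_fraction": frac,
            "experiment_scenario_id": run.scenario.scenario_id,
            "control_scenario_id": ctrl.scenario.scenario_id,
            "lrr": log_response_ratio(_response_value(run, response_variable),
                                      _response_value(ctrl, response_variable)),
        })
    if not rows:
        raise MissingScenarioError(
            f"no {predator}-presence scenarios found in runs")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FluxBudget:
    """Cumulative emergence vs predator consumption of aquatic prey."""

    cumulative_emergence: float
    cumulative_consumption: float
    emergence_pct_of_consumption: float


def flux_budget(trajectory: Trajectory) -> FluxBudget:
    """Sum the run's emergence and aquatic-prey predation ledgers.

    Consumption counts trout aquatic intake plus salamander vulnerable
    and armored intakes; terrestrial intakes are excluded (they are
    subsidy, not benthic production).  The ratio is reported as
    100·emergence/consumption, i.e. "emergence is N% of consumption".
    """
    lg = trajectory.ledger
    emergence = float(lg["emergence_flux"].sum())
    consumption = float(lg["trout_aquatic_intake"].sum()
                        + lg["salamander_vulnerable_intake"].sum()
                        + lg["salamander_armored_intake"].sum())
    if consumption <= 0:
        raise UndefinedRatioError(
            "flux ratio undefined: cumulative predator consumption is zero")
    return FluxBudget(emergence, consumption, 100.0 * emergence / consumption)


def _lrr_or_nan(xe: float, xc: float) -> float:
    try:
        return log_response_ratio(xe, xc)
    except UndefinedLRRError:
        return float("nan")


def summarize(runs: Mapping[str, Run] | Iterable[Run]) -> pd.DataFrame:
    """Tidy per-scenario results table.

    One row per scenario: day-90 pool biomasses, mean daily emergence,
    cumulative flux budget, and LRRs of each response against two
    baselines — the declared control scenario (``lrr_vs_ref_*``) and,
    for subsidy-family members, the matched 0%-subsidy run
    (``lrr_vs_zero_*``).  Percent-change columns are 100·(e^LRR − 1).
    """
    if not isinstance(runs, Mapping):
        runs = {r.scenario.scenario_id: r for r in runs}
    control = next((r for r in runs.values() if r.scenario.is_control), None)
    by_key = {(r.scenario.subsidy_multiplier, r.scenario.armored_fraction,
               r.scenario.trout_present, r.scenario.salamander_present): r
              for r in runs.values()}
    responses = _RESPONSES + ("mean_emergence",)
    rows = []
    for sid, run in runs.items():
        sc = run.scenario
        final = run.trajectory.final
        row: dict = {"scenario_id": sid,
                     "subsidy_multiplier": sc.subsidy_multiplier,
                     "armored_fraction": sc.armored_fraction,
                     "trout_present": sc.trout_present,
                     "salamander_present": sc.salamander_present,
                     "is_control": sc.is_control}
        for v in ("A", "D", "H_alg", "H_det", "G_alg", "G_det", "T", "S",
                  "H", "G"):
            row[f"day{sc.days}_{v}"] = float(final[v])
        row["mean_emergence"] = run.trajectory.mean_emergence()
        try:
            budget = flux_budget(run.trajectory)
            row["cumulative_emergence"] = budget.cumulative_emergence
            row["cumulative_consumption"] = budget.cumulative_consumption
            row["emergence_pct_of_consumption"] = (
                budget.emergence_pct_of_consumption)
        except UndefinedRatioError:
            row["cumulative_emergence"] = float(
                run.trajectory.ledger["emergence_flux"].sum())
            row["cumulative_consumption"] = 0.0
            row["emergence_pct_of_consumption"] = float("nan")
        zero_key = (0.0, sc.armored_fraction, sc.trout_present,
                    sc.salamander_present)
        zero = by_key.get(zero_key)
        for v in responses:
            x = _response_value(run, v)
            if control is not None:
                lrr = _lrr_or_nan(x, _response_value(control, v))
                row[f"lrr_vs_ref_{v}"] = lrr
                row[f"pct_change_vs_ref_{v}"] = 100.0 * (math.exp(lrr) - 1.0) \
                    if lrr == lrr else float("nan")
            if zero is not None:
                lrr0 = _lrr_or_nan(x, _response_value(zero, v))
                row[f"lrr_vs_zero_{v}"] = lrr0
                row[f"pct_change_vs_zero_{v}"] = 100.0 * (math.exp(lrr0) - 1.0) \
                    if lrr0 == lrr0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
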