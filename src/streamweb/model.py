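"""Daily discrete-time update rules for the eight-pool stream food web.

The web couples two basal pools (algae fed by light through a canopy
gap, detritus fed by a constant terrestrial litter flux I), four
primary-consumer pools (vulnerable and armored algivores and
detritivores), and two predators (trout and salamanders) that share a
type III functional response on vulnerable prey.  Terrestrial prey
arrive as a donor-controlled flux X that trout exploit first; the
leftover (X − c_t·T) is available to salamanders.  Armored prey are
invulnerable to trout and only marginally (≤ armored_cap of daily
demand) vulnerable to salamanders.  Emergence exports e_h·(H+G) per day
to the riparian forest.

The update is synchronous: every gain and loss is evaluated from the
current day's state and applied at once.  When the summed losses of a
pool would overdraw it, all losses of that pool are rescaled
proportionally so the pool lands exactly at zero, and the rescaled
(realized) flows are what the predators grow on and what the ledger
records — biomass is conserved between the prey ledger and the state.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .params import (
    POOLS,
    FoodWebState,
    InvalidParameterError,
    ModelParams,
)

__all__ = [
    "type3_fraction",
    "algae_step",
    "detritus_step",
    "predation_on_vulnerable",
    "predation_on_armored",
    "emergence_flux",
    "step",
    "simulate",
    "Trajectory",
    "SimulationDivergedError",
    "LEDGER_COLUMNS",
]


class SimulationDivergedError(ArithmeticError):
    """A pool became non-finite during a simulation."""

    def __init__(self, day: int, pool: str):
        super().__init__(f"simulation diverged on day {day} in pool {pool}")
        self.day = day
        self.pool = pool


LEDGER_COLUMNS = (
    "emergence_flux",
    "trout_aquatic_intake",
    "trout_terrestrial_intake",
    "salamander_vulnerable_intake",
    "salamander_armored_intake",
    "salamander_terrestrial_intake",
    "algal_growth",
    "algal_grazing",
    "detritus_input",
    "detritus_consumption",
)


def type3_fraction(B: float, alpha: float) -> float:
    """Holling type III exploited fraction B² / (α² + B²).

    Sigmoid in prey biomass ``B``: vanishes quadratically at low
    density (a low-density refuge) and saturates toward 1 at high
    density.  ``alpha`` is the half-saturation biomass.
    """
    if alpha is None or alpha <= 0:
        raise InvalidParameterError(f"alpha must be > 0, got {alpha!r}")
    if B < 0:
        raise InvalidParameterError(f"prey biomass must be >= 0, got {B!r}")
    return B * B / (alpha * alpha + B * B)


def algae_step(state: FoodWebState, params: ModelParams) -> tuple[float, float]:
    """One day of algal gain and grazing demand (no background loss).

    gain = b_a·(1−L)·A — light input through the canopy gap, scaled by
    standing algal biomass; loss = c_alg·(H_alg+G_alg)·A — grazing by
    both vulnerable and armored algivores.
    """
    gain = params.b_a * (1.0 - params.L) * state.A
    loss = params.c_alg * (state.H_alg + state.G_alg) * state.A
    return gain, loss


def detritus_step(state: FoodWebState, params: ModelParams) -> tuple[float, float]:
    """One day of detrital input (constant I) and consumption demand."""
    consumption = params.c_det * (state.H_det + state.G_det) * state.D
    return params.I, consumption


def predation_on_vulnerable(
    state: FoodWebState,
    params: ModelParams,
    trout_present: bool = True,
    salamander_present: bool = True,
) -> dict[str, float]:
    """Per-(group × predator) predation demand on vulnerable prey.

    Each predator's demand c·P·f₃(H) is apportioned to H_alg and H_det
    by their share of the total vulnerable pool H.
    """
    H = state.H
    zero = {"trout_H_alg": 0.0, "trout_H_det": 0.0,
            "salamander_H_alg": 0.0, "salamander_H_det": 0.0}
    if H <= 0:
        return zero
    phi = type3_fraction(H, params.alpha)
    T = state.T if trout_present else 0.0
    S = state.S if salamander_present else 0.0
    trout_total = params.c_t * T * phi
    sal_total = params.c_s * S * phi
    w_alg = state.H_alg / H
    w_det = state.H_det / H
    return {
        "trout_H_alg": trout_total * w_alg,
        "trout_H_det": trout_total * w_det,
        "salamander_H_alg": sal_total * w_alg,
        "salamander_H_det": sal_total * w_det,
    }


def predation_on_armored(
    state: FoodWebState,
    params: ModelParams,
    salamander_present: bool = True,
) -> dict[str, float]:
    """Salamander predation demand on armored prey; trout take none.

    The type III response applies, limited to ``armored_cap`` (6.5%) of
    the salamander's daily consumption rate, reflecting the small
    armored share of salamander diets.  With the default
    ``armored_response="scaled"`` the limit scales the functional
    response itself (armored prey are taken at 6.5% of the rate an
    equally abundant vulnerable pool would be); with ``"cap"`` the raw
    type III demand is truncated at armored_cap·c_s·S.
    """
    G = state.G
    zero = {"salamander_G_alg": 0.0, "salamander_G_det": 0.0}
    if G <= 0 or not salamander_present or state.S <= 0:
        return zero
    S = state.S
    psi = type3_fraction(G, params.alpha)
    if params.armored_response == "scaled":
        demand = params.armored_cap * params.c_s * S * psi
    else:
        demand = min(params.armored_cap * params.c_s * S,
                     params.c_s * S * psi)
    return {
        "salamander_G_alg": demand * state.G_alg / G,
        "salamander_G_det": demand * state.G_det / G,
    }


def emergence_flux(state: FoodWebState, params: ModelParams) -> float:
    """Daily aerial-adult emergence e_h·(H+G), g·m⁻²·day⁻¹."""
    return params.e_h * (state.H + state.G)


def _clamped(pool: float, growth: float, losses: list[float]) -> tuple[float, list[float], float]:
    """Apply losses to pool+growth; rescale proportionally if overdrawn.

    Returns (new_pool, realized_losses, scale).  When the clamp binds
    the pool lands exactly at 0 and every loss is scaled by the same
    factor, preserving the relative loss composition.
    """
    total = sum(losses)
    avail = pool + growth
    if total <= avail or total <= 0.0:
        return avail - total, losses, 1.0
    scale = avail / total
    return 0.0, [x * scale for x in losses], scale


def step(
    state: FoodWebState,
    params: ModelParams,
    trout_present: bool = True,
    salamander_present: bool = True,
    day: int = 0,
) -> tuple[FoodWebState, dict[str, float]]:
    """Advance the food web one day; return the new state and ledger row.

    All flows are evaluated from ``state`` (synchronous update).  An
    absent predator contributes zero intake and zero growth throughout.
    The donor-controlled inputs X and I are unaffected by any pool.
    """
    params.require_calibrated()
    p = params
    T_eff = state.T if trout_present else 0.0
    S_eff = state.S if salamander_present else 0.0

    # --- basal pools -------------------------------------------------
    a_gain, a_graze = algae_step(state, p)
    A_new, (a_graze_real,), a_scale = _clamped(state.A, a_gain, [a_graze])

    d_in, d_cons = detritus_step(state, p)
    D_new, (d_cons_real,), d_scale = _clamped(state.D, d_in, [d_cons])

    # --- primary consumers ------------------------------------------
    vuln = predation_on_vulnerable(state, p, trout_present, salamander_present)
    arm = predation_on_armored(state, p, salamander_present)
    m_h = p.m_h

    # realized resource intake per group scales with the basal clamp so
    # consumer growth never exceeds what the resource actually supplied
    def consumer_update(pool: float, b_g: float, c_g: float, resource: float,
                        r_scale: float, predation: list[float]):
        growth = b_g * c_g * pool * resource * r_scale
        losses = predation + [p.e_h * pool, m_h * pool]
        new, real, _ = _clamped(pool, growth, losses)
        return new, real

    H_alg_new, real_Halg = consumer_update(
        state.H_alg, p.b_alg, p.c_alg, state.A, a_scale,
        [vuln["trout_H_alg"], vuln["salamander_H_alg"]])
    H_det_new, real_Hdet = consumer_update(
        state.H_det, p.b_det, p.c_det, state.D, d_scale,
        [vuln["trout_H_det"], vuln["salamander_H_det"]])
    G_alg_new, real_Galg = consumer_update(
        state.G_alg, p.b_alg, p.c_alg, state.A, a_scale,
        [arm["salamander_G_alg"]])
    G_det_new, real_Gdet = consumer_update(
        state.G_det, p.b_det, p.c_det, state.D, d_scale,
        [arm["salamander_G_det"]])

    trout_aquatic = real_Halg[0] + real_Hdet[0]
    sal_vulnerable = real_Halg[1] + real_Hdet[1]
    sal_armored = real_Galg[0] + real_Gdet[0]
    emergence = real_Halg[-2] + real_Hdet[-2] + real_Galg[-2] + real_Gdet[-2]

    # --- predators (donor-controlled terrestrial stream) -------------
    trout_terrestrial = min(p.c_t * T_eff, p.X)
    sal_terrestrial = min(p.c_s * S_eff, max(0.0, p.X - p.c_t * T_eff))
    T_new = state.T + p.b_t * (trout_aquatic + trout_terrestrial)
    S_new = state.S + p.b_s * (sal_vulnerable + sal_armored + sal_terrestrial)

    values = (A_new, D_new, H_alg_new, H_det_new,
              G_alg_new, G_det_new, T_new, S_new)
    for name, v in zip(POOLS, values):
        if not (v == v and abs(v) != float("inf")):  # NaN / inf check
            raise SimulationDivergedError(day, name)

    ledger = {
        "emergence_flux": emergence,
        "trout_aquatic_intake": trout_aquatic,
        "trout_terrestrial_intake": trout_terrestrial,
        "salamander_vulnerable_intake": sal_vulnerable,
        "salamander_armored_intake": sal_armored,
        "salamander_terrestrial_intake": sal_terrestrial,
        "algal_growth": a_gain,
        "algal_grazing": a_graze_real,
        "detritus_input": d_in,
        "detritus_consumption": d_cons_real,
    }
    return FoodWebState.from_tuple(values), ledger


@dataclass
class Trajectory:
    """States (day 0..days) and daily flux ledger (day 1..days) of one run."""

    states: pd.DataFrame
    ledger: pd.DataFrame
    scenario_id: str | None = None

    @property
    def days(self) -> int:
        return int(self.states.index[-1])

    @property
    def final(self) -> pd.Series:
        """Day-``days`` pool biomasses, with derived totals H and G."""
        s = self.states.iloc[-1].copy()
        s["H"] = s["H_alg"] + s["H_det"]
        s["G"] = s["G_alg"] + s["G_det"]
        return s

    def mean_emergence(self) -> float:
        """Mean daily emergence flux over the run, g·m⁻²·day⁻¹."""
        return float(self.ledger["emergence_flux"].mean())

    def to_tidy(self, scenario_id: str | None = None) -> pd.DataFrame:
        """Long-format table: one row per (day, variable, value)."""
        sid = scenario_id or self.scenario_id or ""
        st = self.states.reset_index().melt(
            id_vars="day", var_name="variable", value_name="value")
        lg = self.ledger.reset_index().melt(
            id_vars="day", var_name="variable", value_name="value")
        out = pd.concat([st, lg], ignore_index=True)
        out["scenario_id"] = sid
        return out[["day", "variable", "value", "scenario_id"]]


def simulate(
    initial_state: FoodWebState,
    params: ModelParams,
    days: int = 90,
    trout_present: bool = True,
    salamander_present: bool = True,
    scenario_id: str | None = None,
) -> Trajectory:
    """Run the daily update for ``days`` steps (deterministic).

    Returns a :class:`Trajectory` with days+1 states and ``days``
    ledger rows.  Identical inputs give bit-identical output.
    """
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    params.require_calibrated()
    states = [initial_state.as_tuple()]
    rows = []
    s = initial_state
    for d in range(1, days + 1):
        s, row = step(s, params, trout_present, salamander_present, day=d)
        states.append(s.as_tuple())
        rows.append(row)
    sdf = pd.DataFrame(states, columns=POOLS)
    sdf.index.name = "day"
    ldf = pd.DataFrame(rows, columns=LEDGER_COLUMNS,
                       index=range(1, days + 1))
    ldf.index.name = "day"
    return Trajectory(states=sdf, ledger=ldf, scenario_id=scenario_id)


def _final_state_fast(
    initial: tuple[float, ...],
    params: ModelParams,
    days: int,
    trout_present: bool = True,
    salamander_present: bool = True,
) -> tuple[float, ...]:
    """Final pool tuple without DataFrame assembly (calibration path)."""
    s = FoodWebState.from_tuple(initial)
    for d in range(1, days + 1):
        s, _ = step(s, params, trout_present, salamander_present, day=d)
    return s.as_tuple()
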