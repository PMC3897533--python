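"""Parameter and state containers for the stream food-web model.

All biomasses are ash-free dry mass in g·m⁻²; all rates are daily
(g·g⁻¹·day⁻¹ or day⁻¹).  The model tracks eight pools: algae (A),
detritus (D), vulnerable algivores/detritivores (H_alg, H_det), armored
algivores/detritivores (G_alg, G_det), trout (T) and salamanders (S).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


class InvalidParameterError(ValueError):
    """A model parameter violates its admissible range."""


class UncalibratedParameterError(ValueError):
    """A simulation was requested before alpha / m_h were set."""


class InvalidStateError(ValueError):
    """A biomass pool is negative or non-finite."""


# Reference (field-derived) starting conditions.
ALGAE_0 = 1.59                       # g·m⁻², tile AFDM
INVERTEBRATE_TOTAL_0 = 0.23          # g·m⁻², H + G standing stock
ARMORED_FRACTION_REF = 0.13 / 0.23   # armored share of the benthic standing stock
TROUT_0 = 5.12                       # g·m⁻², depletion-survey estimate
SALAMANDER_0 = 13.42                 # g·m⁻², depletion-survey estimate

#: fields that must lie in [0, 1]
_UNIT_FIELDS = ("b_a", "L", "b_alg", "b_det", "b_t", "b_s", "armored_cap")


@dataclass(frozen=True)
class ModelParams:
    """Rates and efficiencies of the daily food-web update.

    ``alpha`` (half-saturation biomass of the type III functional
    response, shared by both predators) and ``m_h`` (background
    invertebrate mortality) have no field-measured value and default to
    ``None``; they must be set — normally by
    :func:`streamweb.calibration.calibrate_free_parameters` — before a
    simulation can run.
    """

    b_a: float = 0.15          # light-to-algae conversion efficiency
    L: float = 0.90            # canopy cover fraction
    c_alg: float = 0.2         # algivore consumption rate, g·g⁻¹·day⁻¹
    c_det: float = 0.35        # detritivore consumption rate, g·g⁻¹·day⁻¹
    b_alg: float = 0.195       # algivore growth efficiency
    b_det: float = 0.065       # detritivore growth efficiency
    e_h: float = 0.039         # emergence coefficient, day⁻¹
    m_h: float | None = None   # background invertebrate mortality, day⁻¹ (calibrated)
    c_t: float = 0.075         # trout consumption rate, g·g⁻¹·day⁻¹
    c_s: float = 0.02236       # salamander consumption rate, g·g⁻¹·day⁻¹
    b_t: float = 0.10          # trout growth efficiency
    b_s: float = 0.10          # salamander growth efficiency
    alpha: float | None = None  # type III half-saturation biomass, g·m⁻² (calibrated)
    armored_cap: float = 0.065  # armored share cap of salamander daily consumption
    I: float = 1.7             # detritus input flux, g·m⁻²·day⁻¹
    X: float = 0.261           # terrestrial prey input flux, g·m⁻²·day⁻¹
    #: how the armored_cap limits salamander intake of armored prey:
    #: "scaled" multiplies the type III response by armored_cap (armored
    #: prey are consumed at 6.5% of the rate an equally abundant
    #: vulnerable pool would be); "cap" takes the raw type III demand
    #: truncated at armored_cap·c_s·S.
    armored_response: str = "scaled"

    def __post_init__(self) -> None:
        if self.armored_response not in ("scaled", "cap"):
            raise InvalidParameterError(
                f"armored_response must be 'scaled' or 'cap', "
                f"got {self.armored_response!r}")
        for f in dataclasses.fields(self):
            if f.name == "armored_response":
                continue
            v = getattr(self, f.name)
            if v is None:
                if f.name in ("alpha", "m_h"):
                    continue
                raise InvalidParameterError(f"{f.name} may not be None")
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(
                    f"{f.name} must be finite and >= 0, got {v!r}")
            if f.name in _UNIT_FIELDS and v > 1:
                raise InvalidParameterError(
                    f"{f.name} must lie in [0, 1], got {v!r}")
        if self.alpha is not None and self.alpha <= 0:
            raise InvalidParameterError(f"alpha must be > 0, got {self.alpha!r}")

    def require_calibrated(self) -> None:
        if self.alpha is None or self.m_h is None:
            missing = [n for n in ("alpha", "m_h") if getattr(self, n) is None]
            raise UncalibratedParameterError(
                "simulation requires calibrated parameters; unset: "
                + ", ".join(missing))

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: canonical pool order used throughout trajectories and tidy output
POOLS = ("A", "D", "H_alg", "H_det", "G_alg", "G_det", "T", "S")


@dataclass(frozen=True)
class FoodWebState:
    """Biomass of the eight pools at one daily time step (g·m⁻²)."""

    A: float
    D: float
    H_alg: float
    H_det: float
    G_alg: float
    G_det: float
    T: float
    S: float

    def __post_init__(self) -> None:
        for name in POOLS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidStateError(
                    f"pool {name} must be finite and >= 0, got {v!r}")

    @property
    def H(self) -> float:
        """Total vulnerable invertebrate biomass."""
        return self.H_alg + self.H_det

    @property
    def G(self) -> float:
        """Total armored invertebrate biomass."""
        return self.G_alg + self.G_det

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in POOLS)

    @classmethod
    def from_tuple(cls, values) -> "FoodWebState":
        return cls(**dict(zip(POOLS, values)))

    def replace(self, **changes: float) -> "FoodWebState":
        return dataclasses.replace(self, **changes)


def default_initial_detritus(params: ModelParams,
                             detritivore_biomass: float) -> float:
    """Input/consumption balance point I / (c_det · detritivores).

    Used as the starting detrital standing stock when no calibrated
    value is available; with the reference benthic stock (0.115 g·m⁻²
    of detritivores) this is ≈ 42 g·m⁻².
    """
    if detritivore_biomass <= 0:
        raise InvalidParameterError(
            "balance-point detritus requires detritivore biomass > 0")
    return params.I / (params.c_det * detritivore_biomass)
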