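"""Poisson dilution-to-extinction planning.

When an inoculum is diluted so that cells land in wells as a Poisson
process with mean lambda cells per well, the fraction of wells showing
growth is g = 1 - e^-lambda, and a growing well is monoclonal (founded by
exactly one cell) with probability

    P(N = 1 | N >= 1) = lambda e^-lambda / (1 - e^-lambda) = lambda (1-g) / g.

At ~35% growth roughly 80% of growing wells are monoclonal, which is why
plates in the 20-60% growth window are kept for isolate picking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Growth-fraction window from observed plate tallies: plates above the
#: high bound have too many occupied wells ("TM"), below the low bound too
#: few ("TF").
ACCEPT_LOW = 0.20
ACCEPT_HIGH = 0.60
IDEAL_GROWTH = 0.35

#: Alternative, slightly tighter plate-pick preset used when selecting
#: individual plates rather than dilutions.
PLATE_PICK_LOW = 0.18
PLATE_PICK_HIGH = 0.55

TOO_MANY = "too_many"
TOO_FEW = "too_few"

DEFAULT_INITIAL = 2000
DEFAULT_FACTOR = 3
DEFAULT_N_STEPS = 6


@dataclass(frozen=True)
class DilutionObservation:
    """One plate tally: dilution factor (e.g. 54000 for 54,000x) and the
    fraction of its 96 wells that grew, or a too_many/too_few marker.
    """

    dilution_factor: int
    growth_fraction: float | str

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        g = self.growth_fraction
        if isinstance(g, str):
            if g not in (TOO_MANY, TOO_FEW):
                raise ValueError(f"unknown growth marker {g!r}")
        elif not 0.0 <= g <= 1.0:
            raise ValueError(f"growth_fraction {g} outside [0, 1]")

    @property
    def is_numeric(self) -> bool:
        return not isinstance(self.growth_fraction, str)


@dataclass(frozen=True)
class DilutionPlan:
    series: tuple[int, ...]
    accept_window: tuple[float, float] = (ACCEPT_LOW, ACCEPT_HIGH)
    ideal: float = IDEAL_GROWTH

    def __post_init__(self) -> None:
        if list(self.series) != sorted(set(self.series)):
            raise ValueError("series must be strictly increasing")
        low, high = self.accept_window
        if not low < self.ideal < high:
            raise ValueError("need accept_low < ideal < accept_high")


def make_series(
    initial: int = DEFAULT_INITIAL,
    factor: int = DEFAULT_FACTOR,
    n_steps: int = DEFAULT_N_STEPS,
) -> list[int]:
    """Geometric dilution series [initial * factor**k for k in 0..n_steps-1];
    the defaults give the threefold 2000x .. 486,000x series.
    """
    if initial < 1 or factor <= 1 or n_steps < 1:
        raise ValueError("need initial >= 1, factor > 1, n_steps >= 1")
    return [initial * factor**k for k in range(n_steps)]


def lambda_from_growth(g: float) -> float:
    """Mean cells per well from the growing-well fraction: -ln(1 - g)."""
    if not 0.0 <= g < 1.0:
        raise ValueError(f"growth fraction must be in [0, 1): {g}")
    return -math.log1p(-g)


def p_monoclonal_given_growth(g: float) -> float:
    """Probability a *growing* well was founded by exactly one cell."""
    if not 0.0 < g < 1.0:
        raise ValueError(f"growth fraction must be in (0, 1): {g}")
    lam = lambda_from_growth(g)
    return lam * (1.0 - g) / g


def select_dilutions(
    observations,
    accept_low: float = ACCEPT_LOW,
    accept_high: float = ACCEPT_HIGH,
    ideal: float = IDEAL_GROWTH,
) -> list[DilutionObservation]:
    """Keep numeric observations inside the acceptance window, ordered by
    closeness of growth to the ideal (ties: higher dilution first).

    Empty output means every plate was too dense or too sparse; extend the
    series and re-culture.
    """
    acceptable = [
        o
        for o in observations
        if o.is_numeric and accept_low <= o.growth_fraction <= accept_high
    ]
    # round the distance so float representation jitter cannot break ties
    acceptable.sort(
        key=lambda o: (round(abs(o.growth_fraction - ideal), 12), -o.dilution_factor)
    )
    return acceptable
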