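"""Age-structured biological sub-model on the planning-unit grid.

State is abundance-at-age N (shape (A+1, n_pu)) together with
weight-at-age W_a (kg) and selectivity-at-age Sel_a.  Monthly processes:

* Beverton-Holt recruitment on the density scale in the spawning month,
  with multiplicative lognormal process error;
* exponential survival under fishing mortality (scaled by selectivity)
  plus natural mortality;
* habitat-driven dispersal: a fraction omega * m_i of each PU's fish
  emigrates and splits evenly among its rook neighbours (mass conserving);
* seasonal migration at the domain scale: a spawner influx before May
  recruitment and an all-ages outflux in November;
* annual age advancement into a plus group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import GridDomain
from .habitat import MovementField

__all__ = [
    "PopulationState",
    "BioParams",
    "recruit",
    "apply_mortality",
    "move",
    "seasonal_influx",
    "seasonal_outflux",
    "advance_age",
    "spawning_biomass",
]


@dataclass
class PopulationState:
    """Abundance-at-age by planning unit, with age-schedule vectors.

    ``N[a, k]`` is the number of fish of age ``a`` in the PU at domain
    position ``k``.  ``A = N.shape[0] - 1`` is the plus group.
    """

    N: np.ndarray          # (A+1, n_pu) individuals
    W: np.ndarray          # (A+1,) kg
    Sel: np.ndarray        # (A+1,) in [0, 1]
    maturity_age: int = 1

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.Sel = np.asarray(self.Sel, dtype=float)
        if self.N.ndim != 2:
            raise ValueError("N must be 2-D (ages x PUs)")
        n_age = self.N.shape[0]
        if self.W.shape != (n_age,) or self.Sel.shape != (n_age,):
            raise ValueError("W and Sel must have one entry per age class")
        if (self.N < 0).any():
            raise ValueError("negative abundance")
        if (self.W <= 0).any():
            raise ValueError("weight-at-age must be > 0")
        if ((self.Sel < 0) | (self.Sel > 1)).any():
            raise ValueError("selectivity must lie in [0, 1]")
        if not 0 <= self.maturity_age <= self.plus_age:
            raise ValueError(
                f"maturity_age {self.maturity_age} outside 0..{self.plus_age}"
            )

    @property
    def plus_age(self) -> int:
        return self.N.shape[0] - 1

    @property
    def n_pu(self) -> int:
        return self.N.shape[1]

    def biomass(self) -> np.ndarray:
        """Per-PU biomass (kg)."""
        return self.W @ self.N

    def copy(self) -> "PopulationState":
        return replace(self, N=self.N.copy())


@dataclass
class BioParams:
    """Biological parameters.

    ``alpha``/``beta`` are the Beverton-Holt parameters on the *density*
    scale (recruit density from spawner density, kg/km²), matching a
    spawner-recruit relationship estimated on per-area values.  Seasonal
    rates are fractions of the resident stock.  ``M_annual`` maps year to
    annual natural mortality; monthly survival uses M/12.
    """

    alpha: float = 0.14
    beta: float = 6.674e-5
    M_annual: dict[int, float] = field(default_factory=dict)
    influx_rate: float = 0.6133
    outflux_rate: float = 0.5351
    spawning_month: int = 5
    outflux_month: int = 11
    recruitment_error_sd: float = 0.2
    movement_error_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta < 0:
            raise ValueError("alpha must be > 0 and beta >= 0")
        for name in ("influx_rate", "outflux_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.recruitment_error_sd < 0 or self.movement_error_sd < 0:
            raise ValueError("error sd must be >= 0")


def recruit(
    state: PopulationState,
    domain: GridDomain,
    params: BioParams,
    epsilon: float | np.ndarray = 0.0,
) -> PopulationState:
    """Add Beverton-Holt recruits to age 0, PU by PU.

    Spawning biomass is converted to density S = SSB_i / area_i (kg/km²),
    recruit density is R = alpha*S / (1 + beta*S) * exp(epsilon), and the
    result is rescaled to counts by the PU area.  ``epsilon`` may be a
    scalar (one shared annual draw) or a per-PU vector.
    """
    ssb = spawning_biomass(state, state.maturity_age)
    if (ssb < 0).any():
        raise ValueError("negative spawning biomass")
    s_density = ssb / domain.areas
    r_density = params.alpha * s_density / (1.0 + params.beta * s_density)
    recruits = r_density * np.exp(epsilon) * domain.areas
    out = state.copy()
    out.N[0] += recruits
    return out


def apply_mortality(
    state: PopulationState,
    F_full: np.ndarray | float,
    M_monthly: float,
) -> PopulationState:
    """One month of exponential decay: N -> N * exp(-(F_i*Sel_a + M)).

    ``F_full`` is the per-PU fishing mortality at full selectivity for the
    month (month⁻¹); ``M_monthly`` the monthly natural mortality.
    """
    F_full = np.asarray(F_full, dtype=float)
    if (F_full < 0).any() or M_monthly < 0:
        raise ValueError("mortality rates must be >= 0")
    Z = state.Sel[:, None] * F_full[None, :] + M_monthly
    out = state.copy()
    out.N = state.N * np.exp(-Z)
    return out


def move(
    state: PopulationState,
    fieldm: MovementField,
    omega: float,
    domain: GridDomain,
    month: int,
    rate_noise: np.ndarray | None = None,
) -> PopulationState:
    """Redistribute fish along rook adjacency; conserves each age total.

    Emigrants from PU j are ``omega * m_j * preN_j`` and split evenly
    among j's neighbours.  ``rate_noise`` optionally multiplies m
    (lognormal process error); the product is clamped to [0, 1] so the
    emigrating fraction stays a probability.  PUs without neighbours keep
    their fish.
    """
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    m = fieldm.month_rates(month).copy()
    if rate_noise is not None:
        m = np.clip(m * rate_noise, 0.0, 1.0)
    # isolated PUs cannot emigrate (nowhere to go)
    m[domain.neighbor_counts() == 0] = 0.0
    frac = omega * m  # emigrating fraction per PU, in [0, 1]
    T = domain.movement_matrix()
    out = state.copy()
    emig = state.N * frac[None, :]
    out.N = state.N - emig + emig @ T.T
    return out


def seasonal_influx(
    state: PopulationState,
    rate: float,
    weights: np.ndarray,
) -> PopulationState:
    """Spawning migration into the domain before recruitment.

    The mature stock (ages >= maturity_age) grows by ``rate`` of its
    current total; the immigrants are distributed across PUs by
    ``weights`` (summing to 1) and across mature ages by the stock's
    current age composition.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"influx rate must lie in [0, 1], got {rate}")
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be >= 0 and sum to 1")
    out = state.copy()
    mat = slice(state.maturity_age, None)
    totals_by_age = state.N[mat].sum(axis=1)  # mature total per age
    grand = totals_by_age.sum()
    if rate == 0.0 or grand == 0.0:
        return out
    age_comp = totals_by_age / grand
    added = rate * grand * age_comp[:, None] * weights[None, :]
    out.N[mat] += added
    return out


def seasonal_outflux(state: PopulationState, rate: float) -> PopulationState:
    """Wintering migration out of the domain: every cell scaled by 1-rate."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"outflux rate must lie in [0, 1], got {rate}")
    out = state.copy()
    out.N *= 1.0 - rate
    return out


def advance_age(state: PopulationState) -> PopulationState:
    """Year-boundary ageing: a -> a+1, plus group accumulates, age 0 empties."""
    out = state.copy()
    A = state.plus_age
    out.N[A] = state.N[A] + state.N[A - 1] if A >= 1 else state.N[A]
    for a in range(A - 1, 0, -1):
        out.N[a] = state.N[a - 1]
    if A >= 1:
        out.N[0] = 0.0
    return out


def spawning_biomass(state: PopulationState, maturity_age: int | None = None) -> np.ndarray:
    """Per-PU spawning stock biomass (kg): sum over mature ages of N*W."""
    if maturity_age is None:
        maturity_age = state.maturity_age
    if not 0 <= maturity_age <= state.plus_age:
        raise ValueError(
            f"maturity_age {maturity_age} outside 0..{state.plus_age}"
        )
    return state.W[maturity_age:] @ state.N[maturity_age:]
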