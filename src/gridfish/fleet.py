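"""Fleet sub-model: Baranov catch, CPUE, effort allocation, compensation.

Fishing effort is expressed directly as fishing mortality at full
selectivity (catchability 1).  A fixed annual total F_T is split across
open months and then across open planning units in proportion to
(CPUE * openness)^v, the ideal-free-style gravity rule: larger v means
fishers concentrate more sharply on high-CPUE ground.  When seasonal or
spatial closures remove fishing opportunities, the total effort is
compensated upward so overall pressure is redistributed, not removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import PopulationState

__all__ = [
    "FleetParams",
    "FleetState",
    "catch_baranov",
    "cpue",
    "allocate_effort",
    "compensate_effort",
]


@dataclass
class FleetParams:
    """Fleet parameters: pre-management annual F, aggregation exponent v,
    and the lognormal sd of the aggregation (fisher-knowledge) error."""

    F_base: float = 0.72
    v: float = 1.0
    aggregation_error_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.F_base < 0:
            raise ValueError("F_base must be >= 0")
        if self.v < 0:
            raise ValueError("v must be >= 0")
        if self.aggregation_error_sd < 0:
            raise ValueError("aggregation_error_sd must be >= 0")


@dataclass
class FleetState:
    """Per-PU fleet variables for one time step."""

    F: np.ndarray      # per-PU fishing mortality at full selectivity (month⁻¹)
    C: np.ndarray      # per-PU catch (kg)
    CPUE: np.ndarray   # per-PU catch per unit effort
    F_T: float         # compensated annual total effort
    x: np.ndarray      # per-PU openness 0/1

    @classmethod
    def idle(cls, n_pu: int) -> "FleetState":
        z = np.zeros(n_pu)
        return cls(F=z.copy(), C=z.copy(), CPUE=z.copy(), F_T=0.0, x=np.ones(n_pu))


def catch_baranov(
    state: PopulationState,
    F_full: np.ndarray | float,
    M_monthly: float,
) -> np.ndarray:
    """Per-PU monthly catch in kg from the Baranov catch equation.

    C_i = sum_a [F_i Sel_a / (F_i Sel_a + M)] (1 - e^{-(F_i Sel_a + M)}) N_{a,i} W_a,
    with the 0/0 case (no mortality at all) defined as 0.
    """
    F_full = np.atleast_1d(np.asarray(F_full, dtype=float))
    if (F_full < 0).any() or M_monthly < 0:
        raise ValueError("mortality rates must be >= 0")
    Fa = state.Sel[:, None] * F_full[None, :]          # (A+1, n_pu)
    Z = Fa + M_monthly
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(Z > 0, Fa / np.where(Z > 0, Z, 1.0), 0.0)
    dead = (1.0 - np.exp(-Z)) * state.N
    return np.einsum("a,ap->p", state.W, frac * dead)


def cpue(C: np.ndarray | float, F: np.ndarray | float) -> np.ndarray:
    """Catch per unit effort C/F, defined as 0 where F = 0 (unfished PU)."""
    C = np.asarray(C, dtype=float)
    F = np.asarray(F, dtype=float)
    if (C < 0).any() or (F < 0).any():
        raise ValueError("C and F must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(F > 0, C / np.where(F > 0, F, 1.0), 0.0)


def allocate_effort(
    CPUE: np.ndarray,
    x: np.ndarray,
    v: float,
    F_T: float,
) -> np.ndarray:
    """Split total effort F_T over PUs with weights (CPUE_i * x_i)^v.

    Closed PUs (x = 0) always receive 0, including at v = 0.  If every
    open PU has zero weight (first step, or all-zero CPUE), effort spreads
    uniformly over the open PUs.  The allocation sums to F_T exactly.
    """
    CPUE = np.asarray(CPUE, dtype=float)
    x = np.asarray(x, dtype=float)
    if v < 0:
        raise ValueError("v must be >= 0")
    open_mask = x > 0
    if not open_mask.any():
        raise ValueError("no open PU: cannot allocate effort")
    w = np.zeros_like(CPUE)
    w[open_mask] = (CPUE[open_mask] * x[open_mask]) ** v
    total = w.sum()
    if total == 0.0:
        w[open_mask] = 1.0
        total = w.sum()
    return F_T * w / total


def compensate_effort(
    F_base: float,
    n_c: int,
    n_o: int,
    PU_c: int,
    PU_o: int,
) -> float:
    """Compensated total effort under seasonal and spatial closure.

    F_T = F_base * (1 + n_c/n_o) * (1 + PU_c/PU_o): the effort displaced
    by closed months and closed PUs is reallocated to what stays open so
    total annual pressure is unchanged by management.
    """
    if F_base < 0 or n_c < 0 or PU_c < 0:
        raise ValueError("effort and closure counts must be >= 0")
    if n_o <= 0 or PU_o <= 0:
        raise ValueError("fishery fully closed: n_o and PU_o must be > 0")
    return F_base * (1.0 + n_c / n_o) * (1.0 + PU_c / PU_o)
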