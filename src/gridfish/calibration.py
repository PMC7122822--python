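"""Calibration of the movement coefficient omega and aggregation factor v.

Observed and simulated September biomass surfaces are compared per year
after delta-distribution standardization: z-scoring of log biomass over
the positive entries (zero-biomass PUs carry no information about the
log-scale spatial pattern and are dropped pairwise).  The objective is
the sum of squared differences of the standardized surfaces over all
observation years; it is minimised by an iterated zooming grid search —
a derivative-free, reproducible stand-in for generic least squares that
needs no gradients of the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine as eng
from . import fleet as fl
from . import population as pop
from .grid import GridDomain
from .habitat import MovementField

__all__ = [
    "ObservationSet",
    "CalibrationResult",
    "delta_standardize",
    "objective",
    "calibrate",
]


class DegenerateInputError(ValueError):
    """Input cannot be standardized (fewer than 2 positive values, or sd 0)."""


@dataclass
class ObservationSet:
    """Observed per-PU biomass (kg) by survey year, sampled in one month."""

    biomass: dict[int, dict[int, float]]  # year -> {pu_id: kg}
    month: int = 9

    def years(self) -> list[int]:
        return sorted(self.biomass)

    def vector(self, year: int, domain: GridDomain) -> np.ndarray:
        obs = self.biomass[year]
        return np.array([obs.get(int(pid), 0.0) for pid in domain.ids])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (year, pid, b)
            for year, obs in sorted(self.biomass.items())
            for pid, b in sorted(obs.items())
        ]
        return pd.DataFrame(rows, columns=["year", "pu_id", "biomass"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, month: int = 9) -> "ObservationSet":
        table: dict[int, dict[int, float]] = {}
        for rec in df.itertuples():
            table.setdefault(int(rec.year), {})[int(rec.pu_id)] = float(rec.biomass)
        return cls(biomass=table, month=month)


@dataclass
class CalibrationResult:
    omega_hat: float
    v_hat: float
    ssq: float
    trace: pd.DataFrame = field(repr=False)


def delta_standardize(biomass: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score log biomass over positive entries.

    Returns ``(z, positive_mask)`` where ``z`` has one entry per positive
    input in order.  Fewer than two positive values or zero variance of
    the logs is a degenerate input.
    """
    biomass = np.asarray(biomass, dtype=float)
    if (biomass < 0).any():
        raise ValueError("biomass must be >= 0")
    mask = biomass > 0
    if mask.sum() < 2:
        raise DegenerateInputError("need >= 2 positive biomass values")
    logs = np.log(biomass[mask])
    sd = logs.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("log-biomass has zero variance")
    return (logs - logs.mean()) / sd, mask


def objective(
    omega: float,
    v: float,
    observations: ObservationSet,
    domain: GridDomain,
    fieldm: MovementField,
    scenario: eng.Scenario,
    initial: pop.PopulationState,
    bio: pop.BioParams,
    fleet_params: fl.FleetParams,
) -> float:
    """Hindcast sum of squared standardized-biomass differences.

    Runs the deterministic engine at (omega, v), standardizes observed
    and simulated surfaces per observation year, and accumulates squared
    differences over PUs positive in both (pairwise deletion).
    """
    fp = fl.FleetParams(
        F_base=fleet_params.F_base, v=v,
        aggregation_error_sd=fleet_params.aggregation_error_sd,
    )
    traj = eng.run(initial, domain, fieldm, scenario, bio, fp, omega, rng=None)
    ssq = 0.0
    for year in observations.years():
        sim = traj.biomass[traj.at(year, observations.month)]
        obs = observations.vector(year, domain)
        both = (sim > 0) & (obs > 0)
        if both.sum() < 2:
            continue
        z_sim, _ = delta_standardize(np.where(both, sim, 0.0))
        z_obs, _ = delta_standardize(np.where(both, obs, 0.0))
        ssq += float(((z_sim - z_obs) ** 2).sum())
    return ssq


def calibrate(
    observations: ObservationSet,
    domain: GridDomain,
    fieldm: MovementField,
    scenario: eng.Scenario,
    initial: pop.PopulationState,
    bio: pop.BioParams,
    fleet_params: fl.FleetParams,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 3.0)),
    grid_sizes: tuple[int, int] = (9, 9),
    n_refinements: int = 3,
) -> CalibrationResult:
    """Iterated zooming grid search over (omega, v).

    A coarse grid over the bounds is evaluated, then ``n_refinements``
    grids each zoomed to one coarse cell around the incumbent.  Ties are
    broken toward smaller omega, then smaller v; a flat objective over a
    whole grid triggers a warning.
    """
    (om_lo, om_hi), (v_lo, v_hi) = bounds
    if om_lo > om_hi or v_lo > v_hi:
        raise ValueError("invalid bounds")
    if min(grid_sizes) < 2 and (om_lo < om_hi or v_lo < v_hi):
        raise ValueError("grid_sizes must be >= 2")

    rows = []

    def evaluate(om_grid, v_grid, stage):
        best = None
        vals = {}
        for om in om_grid:
            for v in v_grid:
                s = objective(
                    om, v, observations, domain, fieldm, scenario,
                    initial, bio, fleet_params,
                )
                vals[(om, v)] = s
                rows.append((stage, om, v, s))
                key = (s, om, v)
                if best is None or key < best:
                    best = key
        if len(set(vals.values())) == 1 and len(vals) > 1:
            warnings.warn(
                "flat calibration objective: parameters not identifiable",
                stacklevel=3,
            )
        return best

    om_grid = np.linspace(om_lo, om_hi, max(grid_sizes[0], 1))
    v_grid = np.linspace(v_lo, v_hi, max(grid_sizes[1], 1))
    best = evaluate(om_grid, v_grid, stage=0)

    for r in range(1, n_refinements + 1):
        _, om_c, v_c = best
        om_step = (om_grid[-1] - om_grid[0]) / max(len(om_grid) - 1, 1)
        v_step = (v_grid[-1] - v_grid[0]) / max(len(v_grid) - 1, 1)
        om_grid = np.linspace(
            max(om_lo, om_c - om_step), min(om_hi, om_c + om_step), grid_sizes[0]
        )
        v_grid = np.linspace(
            max(v_lo, v_c - v_step), min(v_hi, v_c + v_step), grid_sizes[1]
        )
        cand = evaluate(om_grid, v_grid, stage=r)
        if cand < best:
            best = cand

    ssq, om_hat, v_hat = best
    trace = pd.DataFrame(rows, columns=["stage", "omega", "v", "ssq"])
    return CalibrationResult(
        omega_hat=float(om_hat), v_hat=float(v_hat), ssq=float(ssq), trace=trace
    )
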