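"""Monthly time-stepping engine coupling the biological and fleet sub-models.

Each simulated month applies, in order:

1. (spawning month only) spawner influx, then Beverton-Holt recruitment;
2. catch (Baranov) and survival under F*Sel + M/12;
3. habitat-driven dispersal between adjacent planning units;
4. (outflux month only) wintering emigration of all ages;
5. (January only) age advancement into the plus group;
6. effort reallocation for the next month from this month's CPUE.

Total annual effort is fixed per year by the compensation rule, split
equally across that year's open months, and spread over open PUs by the
CPUE-gravity rule.  Stochastic mode perturbs recruitment (one lognormal
draw per year), per-PU movement rates, and the aggregation exponent v,
each with the configured lognormal errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fleet as fl
from . import population as pop
from .grid import ClosureSchedule, GridDomain
from .habitat import MovementField

__all__ = ["Scenario", "Trajectory", "EnsembleSummary", "step", "run", "run_ensemble", "indicators"]

QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


@dataclass
class Scenario:
    """A multi-year management scenario: closures, reserves, and rates."""

    years: list[int]
    closed_months: dict[int, frozenset[int]]
    reserve_pus: dict[int, frozenset[int]]
    M_annual: dict[int, float]
    F_annual: dict[int, float]
    label: str = "scenario"

    def __post_init__(self) -> None:
        for year in self.years:
            for table, name in (
                (self.closed_months, "closed_months"),
                (self.reserve_pus, "reserve_pus"),
                (self.M_annual, "M_annual"),
                (self.F_annual, "F_annual"),
            ):
                if year not in table:
                    raise ValueError(f"scenario gap: {name} missing year {year}")
        self.closed_months = {y: frozenset(v) for y, v in self.closed_months.items()}
        self.reserve_pus = {y: frozenset(v) for y, v in self.reserve_pus.items()}

    def schedule(self) -> ClosureSchedule:
        return ClosureSchedule(
            closed_months=dict(self.closed_months),
            reserve_pus=dict(self.reserve_pus),
        )

    def validate_domain(self, domain: GridDomain) -> None:
        known = set(int(i) for i in domain.ids)
        for year, pus in self.reserve_pus.items():
            bad = sorted(set(pus) - known)
            if bad:
                raise ValueError(f"reserve PU(s) not in domain for {year}: {bad}")


@dataclass
class Trajectory:
    """Recorded monthly states: step 0 is the initial condition (month 0)."""

    domain: GridDomain
    years: np.ndarray        # (n_steps,)
    months: np.ndarray       # (n_steps,) 0 for the initial snapshot
    biomass: np.ndarray      # (n_steps, n_pu) kg
    ssb: np.ndarray          # (n_steps, n_pu) kg
    catch: np.ndarray        # (n_steps, n_pu) kg
    F: np.ndarray            # (n_steps, n_pu) month⁻¹
    cpue: np.ndarray         # (n_steps, n_pu)
    N: np.ndarray            # (n_steps, A+1, n_pu)

    @property
    def n_steps(self) -> int:
        return len(self.years)

    def total(self, name: str) -> np.ndarray:
        return getattr(self, name).sum(axis=1)

    def at(self, year: int, month: int) -> int:
        """Index of the recorded step for (year, month)."""
        hits = np.flatnonzero((self.years == year) & (self.months == month))
        if len(hits) != 1:
            raise KeyError(f"no unique step for year={year}, month={month}")
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: year, month, pu_id, variable, value."""
        frames = []
        ids = self.domain.ids
        for name in ("biomass", "ssb", "catch", "F", "cpue"):
            arr = getattr(self, name)
            df = pd.DataFrame(arr, columns=ids)
            df["year"] = self.years
            df["month"] = self.months
            long = df.melt(
                id_vars=["year", "month"], var_name="pu_id", value_name="value"
            )
            long["variable"] = name
            frames.append(long)
        out = pd.concat(frames, ignore_index=True)
        return out[["year", "month", "pu_id", "variable", "value"]]


@dataclass
class EnsembleSummary:
    """Per-series replicate matrices and their cross-replicate quantiles."""

    years: np.ndarray
    months: np.ndarray
    series: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (reps, steps)

    def quantiles(self, name: str) -> pd.DataFrame:
        mat = self.series[name]
        qs = np.quantile(mat, QUANTILES, axis=0)
        df = pd.DataFrame(
            qs.T, columns=[f"q{100 * q:g}" for q in QUANTILES]
        )
        df.insert(0, "month", self.months)
        df.insert(0, "year", self.years)
        return df


@dataclass
class _StepNoise:
    """Multiplicative process errors for one month (all 1.0 when deterministic)."""

    movement: np.ndarray | None = None  # per-PU lognormal factor on m
    v_factor: float = 1.0               # lognormal factor on the aggregation v


def step(
    state: pop.PopulationState,
    fleet_state: fl.FleetState,
    year: int,
    month: int,
    domain: GridDomain,
    fieldm: MovementField,
    scenario: Scenario,
    bio: pop.BioParams,
    fleet_params: fl.FleetParams,
    omega: float,
    epsilon: float = 0.0,
    noise: _StepNoise | None = None,
) -> tuple[pop.PopulationState, fl.FleetState]:
    """Advance one month.  ``fleet_state.F`` must already hold this month's
    allocation; the returned fleet state carries next month's allocation."""
    noise = noise or _StepNoise()
    schedule = scenario.schedule()
    M_monthly = scenario.M_annual[year] / 12.0

    if month == bio.spawning_month:
        w = fieldm.hsi_month(month)
        w = w / w.sum() if w.sum() > 0 else np.full(domain.n_pu, 1.0 / domain.n_pu)
        state = pop.seasonal_influx(state, bio.influx_rate, w)
        state = pop.recruit(state, domain, bio, epsilon)

    F_vec = fleet_state.F
    C = fl.catch_baranov(state, F_vec, M_monthly)
    state = pop.apply_mortality(state, F_vec, M_monthly)
    state = pop.move(state, fieldm, omega, domain, month, rate_noise=noise.movement)

    if month == bio.outflux_month:
        state = pop.seasonal_outflux(state, bio.outflux_rate)
    if month == 1:
        state = pop.advance_age(state)

    cpue_vec = fl.cpue(C, F_vec)

    # allocate next month's effort (wraps into the next scenario year)
    ny, nm = (year, month + 1) if month < 12 else (year + 1, 1)
    if ny in scenario.M_annual:
        next_F = _monthly_allocation(
            cpue_vec, schedule, domain, scenario, fleet_params, ny, nm,
            v_factor=noise.v_factor,
        )
        F_T = _annual_total(scenario, domain, fleet_params, ny)
    else:
        next_F = np.zeros(domain.n_pu)
        F_T = 0.0
    open_next = (
        schedule.open_mask(domain, ny, nm).astype(float)
        if ny in scenario.M_annual
        else np.zeros(domain.n_pu)
    )
    new_fleet = fl.FleetState(F=next_F, C=C, CPUE=cpue_vec, F_T=F_T, x=open_next)
    return state, new_fleet


def _annual_total(scenario, domain, fleet_params, year: int) -> float:
    if scenario.F_annual[year] == 0.0:
        return 0.0
    n_c = len(scenario.closed_months[year])
    pu_c = len(scenario.reserve_pus[year])
    return fl.compensate_effort(
        scenario.F_annual[year], n_c, 12 - n_c, pu_c, domain.n_pu - pu_c
    )


def _monthly_allocation(
    cpue_vec, schedule, domain, scenario, fleet_params, year, month, v_factor=1.0
) -> np.ndarray:
    """Per-PU F for (year, month): zero in closed months, else the annual
    compensated total divided by the open-month count and spread by CPUE."""
    if month in scenario.closed_months[year]:
        return np.zeros(domain.n_pu)
    n_o = 12 - len(scenario.closed_months[year])
    F_T_month = _annual_total(scenario, domain, fleet_params, year) / n_o
    if F_T_month == 0.0:
        return np.zeros(domain.n_pu)
    open_mask = schedule.open_mask(domain, year, month)
    if not open_mask.any():
        raise ValueError(
            f"no open planning unit in {year}-{month:02d} but effort is positive"
        )
    v_eff = fleet_params.v * v_factor
    return fl.allocate_effort(cpue_vec, open_mask.astype(float), v_eff, F_T_month)


def run(
    initial: pop.PopulationState,
    domain: GridDomain,
    fieldm: MovementField,
    scenario: Scenario,
    bio: pop.BioParams,
    fleet_params: fl.FleetParams,
    omega: float,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate the scenario's years month by month.

    Deterministic when ``rng`` is None (all process errors off); otherwise
    lognormal errors are drawn for recruitment (one per year), movement
    (per PU per month) and fleet aggregation (per month).
    """
    scenario.validate_domain(domain)
    for year in scenario.years:
        if year not in scenario.M_annual:
            raise ValueError(f"scenario gap at year {year}")

    state = initial.copy()
    n_pu = domain.n_pu
    n_steps = 1 + 12 * len(scenario.years)
    A1 = state.N.shape[0]
    rec = {
        "years": np.zeros(n_steps, dtype=int),
        "months": np.zeros(n_steps, dtype=int),
        "biomass": np.zeros((n_steps, n_pu)),
        "ssb": np.zeros((n_steps, n_pu)),
        "catch": np.zeros((n_steps, n_pu)),
        "F": np.zeros((n_steps, n_pu)),
        "cpue": np.zeros((n_steps, n_pu)),
        "N": np.zeros((n_steps, A1, n_pu)),
    }

    def snap(k, year, month, state, C, F_vec, cpue_vec):
        rec["years"][k] = year
        rec["months"][k] = month
        rec["biomass"][k] = state.biomass()
        rec["ssb"][k] = pop.spawning_biomass(state)
        rec["catch"][k] = C
        rec["F"][k] = F_vec
        rec["cpue"][k] = cpue_vec
        rec["N"][k] = state.N

    zeros = np.zeros(n_pu)
    snap(0, scenario.years[0] if scenario.years else 0, 0, state, zeros, zeros, zeros)
    if not scenario.years:
        return Trajectory(domain=domain, **{k2: v for k2, v in rec.items()})

    schedule = scenario.schedule()
    first_year = scenario.years[0]
    fleet_state = fl.FleetState(
        F=_monthly_allocation(zeros, schedule, domain, scenario, fleet_params,
                              first_year, 1),
        C=zeros.copy(),
        CPUE=zeros.copy(),
        F_T=_annual_total(scenario, domain, fleet_params, first_year),
        x=schedule.open_mask(domain, first_year, 1).astype(float),
    )

    k = 1
    for year in scenario.years:
        epsilon = (
            float(rng.normal(0.0, bio.recruitment_error_sd))
            if rng is not None and bio.recruitment_error_sd > 0
            else 0.0
        )
        for month in range(1, 13):
            noise = _StepNoise()
            if rng is not None:
                if bio.movement_error_sd > 0:
                    noise.movement = np.exp(
                        rng.normal(0.0, bio.movement_error_sd, size=n_pu)
                    )
                if fleet_params.aggregation_error_sd > 0:
                    noise.v_factor = float(
                        np.exp(rng.normal(0.0, fleet_params.aggregation_error_sd))
                    )
            F_this = fleet_state.F
            state, fleet_state = step(
                state, fleet_state, year, month, domain, fieldm, scenario,
                bio, fleet_params, omega, epsilon=epsilon, noise=noise,
            )
            snap(k, year, month, state, fleet_state.C, F_this, fleet_state.CPUE)
            k += 1

    return Trajectory(domain=domain, **{k2: v for k2, v in rec.items()})


def run_ensemble(
    initial: pop.PopulationState,
    domain: GridDomain,
    fieldm: MovementField,
    scenario: Scenario,
    bio: pop.BioParams,
    fleet_params: fl.FleetParams,
    omega: float,
    n_reps: int,
    seed: int,
) -> EnsembleSummary:
    """Run ``n_reps`` stochastic replicates and summarise key series.

    Replicate generators are spawned deterministically from ``seed``.
    Collected series (one row per replicate, one column per time step):
    total_biomass, total_catch, total_ssb, reserve_biomass.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    names = ("total_biomass", "total_catch", "total_ssb", "reserve_biomass")
    mats: dict[str, list[np.ndarray]] = {n: [] for n in names}
    years = months = None
    for ss in streams:
        traj = run(
            initial, domain, fieldm, scenario, bio, fleet_params, omega,
            rng=np.random.default_rng(ss),
        )
        ind = indicators(traj, scenario)
        years, months = traj.years, traj.months
        for n in names:
            mats[n].append(ind[n].to_numpy())
    return EnsembleSummary(
        years=years,
        months=months,
        series={n: np.vstack(v) for n, v in mats.items()},
    )


def indicators(traj: Trajectory, scenario: Scenario) -> pd.DataFrame:
    """Per-step biological and fishery indicators.

    Columns: total biomass/catch/SSB (kg), biomass inside the reserve of
    the step's year, and per-age fish density (individuals per km²)
    inside the reserve.
    """
    domain = traj.domain
    n_age = traj.N.shape[1]
    out = {
        "year": traj.years,
        "month": traj.months,
        "total_biomass": traj.total("biomass"),
        "total_catch": traj.total("catch"),
        "total_ssb": traj.total("ssb"),
    }
    reserve_biomass = np.zeros(traj.n_steps)
    density = np.zeros((traj.n_steps, n_age))
    for k in range(traj.n_steps):
        year = int(traj.years[k])
        reserve = scenario.reserve_pus.get(year, frozenset())
        idx = [domain.index_of(p) for p in sorted(reserve)]
        if idx:
            reserve_biomass[k] = traj.biomass[k, idx].sum()
            area = domain.areas[idx].sum()
            density[k] = traj.N[k][:, idx].sum(axis=1) / area
    out["reserve_biomass"] = reserve_biomass
    for a in range(n_age):
        out[f"reserve_density_age{a}"] = density[:, a]
    return pd.DataFrame(out)
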