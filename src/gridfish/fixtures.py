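"""Synthetic study systems: grids, HSI fields, stocks, reserves, surveys.

Everything the simulator, calibrator and economics layer consume can be
generated here from a seed, emulating the structure of a coastal
trawl-fishery study system: a regular planning-unit lattice, spatially
smooth seasonal habitat suitability, an initial stock distributed along
habitat quality, no-take reserve masks, and noisy September "survey"
biomass surfaces produced by the model itself for calibration tests.

The default conditions mirror the reference study system: 9 km² planning
units, a 2011–2017 management schedule with a June–August seasonal
closure (May–August in the final year), per-year natural and fishing
mortality, a Beverton-Holt spawner-recruit relationship on the density
scale, May spawner influx (61.33%) and November wintering outflux
(53.51%), and lognormal LN(0, 0.2) process errors.  Weight-at-age is a
synthetic stand-in (an increasing power curve), since no published
schedule accompanies the other parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import engine as eng
from . import fleet as fl
from . import population as pop
from .calibration import ObservationSet
from .grid import GridDomain, build_regular_grid
from .habitat import HSISeries, MovementField, build_movement_field

__all__ = [
    "FixtureSpec",
    "make_hsi_field",
    "make_initial_distribution",
    "make_reserve",
    "make_observations",
    "make_fixture_set",
    "default_weight_at_age",
    "study_schedule",
    "default_scenario",
    "scaled_reserve_counts",
]

# Reference-system management schedule: per-year seasonal closure months
# and annual natural/fishing mortality (yr⁻¹).
STUDY_YEARS = (2011, 2012, 2013, 2014, 2015, 2016, 2017)
STUDY_CLOSED_MONTHS = {y: frozenset({6, 7, 8}) for y in STUDY_YEARS[:-1]}
STUDY_CLOSED_MONTHS[2017] = frozenset({5, 6, 7, 8})
STUDY_M = {2011: 0.52, 2012: 0.49, 2013: 0.45, 2014: 0.52,
           2015: 0.37, 2016: 0.48, 2017: 0.48}
STUDY_F = {2011: 0.72, 2012: 0.89, 2013: 1.06, 2014: 0.65,
           2015: 0.41, 2016: 0.52, 2017: 0.74}
# Reserve sizes in the reference system: PUs out of 4815 per year, and the
# prioritization-tool alternative (60 PUs).
STUDY_RESERVE_COUNTS = {2011: 158, 2012: 158, 2013: 158, 2014: 167,
                        2015: 167, 2016: 167, 2017: 209}
STUDY_N_PU = 4815
MARXAN_RESERVE_COUNT = 60


@dataclass
class FixtureSpec:
    """Parameters of a synthetic study system."""

    n_rows: int = 10
    n_cols: int = 10
    cell_area: float = 9.0               # km², as in the reference system
    hsi_mean_range: tuple[float, float] = (0.05, 0.95)
    hsi_amp_range: tuple[float, float] = (0.05, 0.30)
    initial_biomass: float = 1.0e6       # kg over the whole domain
    n_ages: int = 6                      # ages 0..5, 5 = plus group
    age_composition: tuple[float, ...] | None = None  # default exp(-0.5a), normed
    maturity_age: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.hsi_mean_range, self.hsi_amp_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("HSI ranges must satisfy 0 <= lo <= hi <= 1")
        if self.age_composition is None:
            c = np.exp(-0.5 * np.arange(self.n_ages))
            self.age_composition = tuple(c / c.sum())
        comp = np.asarray(self.age_composition)
        if len(comp) != self.n_ages or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("age_composition must have n_ages entries summing to 1")

    def domain(self) -> GridDomain:
        return build_regular_grid(self.n_rows, self.n_cols, self.cell_area)


def default_weight_at_age(n_ages: int = 6) -> np.ndarray:
    """Synthetic increasing weight-at-age (kg): 0.01 * (a+1)^1.5.

    A stand-in schedule for a small demersal fish; no published
    weight-at-age accompanies the other reference parameters.
    """
    a = np.arange(n_ages)
    return 0.01 * (a + 1) ** 1.5


def _smooth_field(rng: np.random.Generator, n_rows: int, n_cols: int) -> np.ndarray:
    """Spatially smooth random surface in [0, 1] from low-frequency cosines."""
    r = np.arange(n_rows)[:, None] / max(n_rows, 2)
    c = np.arange(n_cols)[None, :] / max(n_cols, 2)
    surf = np.zeros((n_rows, n_cols))
    for _ in range(3):
        fr, fc = rng.uniform(0.5, 1.5, size=2)
        pr, pc = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(0.5, 1.0)
        surf += amp * np.cos(2 * np.pi * fr * r + pr) * np.cos(2 * np.pi * fc * c + pc)
    lo, hi = surf.min(), surf.max()
    if hi - lo < 1e-12:
        return np.full((n_rows, n_cols), 0.5)
    return (surf - lo) / (hi - lo)


def make_hsi_field(spec: FixtureSpec) -> dict[int, HSISeries]:
    """Per-PU monthly HSI series from spatially smooth sinusoid parameters.

    Means, amplitudes and phases vary smoothly in space; monthly values
    are exact sinusoid evaluations (ranges are chosen so no clipping
    occurs), so a seasonal-sinusoid fit recovers the generating
    parameters to numerical precision.
    """
    rng = np.random.default_rng(spec.seed)
    mean_s = _smooth_field(rng, spec.n_rows, spec.n_cols)
    amp_s = _smooth_field(rng, spec.n_rows, spec.n_cols)
    phase_s = _smooth_field(rng, spec.n_rows, spec.n_cols)
    m_lo, m_hi = spec.hsi_mean_range
    a_lo, a_hi = spec.hsi_amp_range
    out: dict[int, HSISeries] = {}
    months = np.arange(1, 13)
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            pid = r * spec.n_cols + c + 1
            mean = m_lo + (m_hi - m_lo) * mean_s[r, c]
            amp = a_lo + (a_hi - a_lo) * amp_s[r, c]
            amp = min(amp, mean, 1.0 - mean)  # keep values strictly in [0, 1]
            phase = 2 * np.pi * phase_s[r, c]
            vals = mean + amp * np.sin(2 * np.pi * months / 12.0 + phase)
            out[pid] = HSISeries(pu_id=pid, values=dict(zip(months.tolist(), vals)))
    return out


def hsi_to_frame(hsi: dict[int, HSISeries]):
    """HSI field as a tidy table ``pu_id, month, hsi``."""
    import pandas as pd

    rows = [
        (pid, m, v)
        for pid, s in sorted(hsi.items())
        for m, v in sorted(s.values.items())
    ]
    return pd.DataFrame(rows, columns=["pu_id", "month", "hsi"])


def hsi_from_frame(df) -> dict[int, HSISeries]:
    out: dict[int, HSISeries] = {}
    for pid, grp in df.groupby("pu_id"):
        out[int(pid)] = HSISeries(
            pu_id=int(pid),
            values={int(m): float(v) for m, v in zip(grp["month"], grp["hsi"])},
        )
    return out


def make_initial_distribution(
    spec: FixtureSpec,
    domain: GridDomain,
    hsi: dict[int, HSISeries],
) -> pop.PopulationState:
    """Initial stock: biomass along January HSI, split into ages.

    Per-PU biomass is proportional to the month-1 HSI; each PU's biomass
    is divided among ages by the spec's composition vector and converted
    to numbers with the synthetic weight-at-age.
    """
    w_jan = np.array([hsi[pid].values[1] for pid in domain.ids])
    if w_jan.sum() <= 0:
        w_jan = np.ones(domain.n_pu)
    b_pu = spec.initial_biomass * w_jan / w_jan.sum()
    comp = np.asarray(spec.age_composition)
    W = default_weight_at_age(spec.n_ages)
    N = (b_pu[None, :] * comp[:, None]) / W[:, None]
    return pop.PopulationState(
        N=N, W=W, Sel=np.ones(spec.n_ages), maturity_age=spec.maturity_age
    )


def make_reserve(
    domain: GridDomain,
    fraction: float,
    strategy: str = "block",
    hsi: dict[int, HSISeries] | None = None,
) -> set[int]:
    """Select ceil(fraction * n_pu) PUs as a no-take reserve.

    ``block``: a contiguous run of ids in row-major order (coastal-strip
    analogue); ``top-hsi``: the PUs with the highest annual-mean HSI.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    k = math.ceil(fraction * domain.n_pu)
    if k == 0:
        return set()
    ids = [int(i) for i in domain.ids]
    if strategy == "block":
        return set(ids[:k])
    if strategy == "top-hsi":
        if hsi is None:
            raise ValueError("top-hsi strategy needs an HSI field")
        score = {pid: float(np.mean(list(hsi[pid].values.values()))) for pid in ids}
        ranked = sorted(ids, key=lambda p: (-score[p], p))
        return set(ranked[:k])
    raise ValueError(f"unknown reserve strategy: {strategy!r}")


def scaled_reserve_counts(n_pu: int) -> dict[int, int]:
    """Reference-system reserve sizes rescaled to an ``n_pu`` domain."""
    return {
        y: max(1, round(c * n_pu / STUDY_N_PU))
        for y, c in STUDY_RESERVE_COUNTS.items()
    }


def study_schedule() -> tuple[dict[int, frozenset[int]], dict[int, float], dict[int, float]]:
    """Closed months and annual M/F of the 2011–2017 reference schedule."""
    return dict(STUDY_CLOSED_MONTHS), dict(STUDY_M), dict(STUDY_F)


def default_scenario(
    domain: GridDomain,
    reserve_pus: dict[int, set[int]] | set[int] | None = None,
    label: str = "hindcast",
) -> eng.Scenario:
    """The 2011–2017 reference scenario on ``domain``.

    ``reserve_pus`` may be a per-year mapping, one set applied to every
    year, or None for reserves grown per the reference schedule (block
    reserves scaled to the domain size).
    """
    closed, M, F = study_schedule()
    if reserve_pus is None:
        counts = scaled_reserve_counts(domain.n_pu)
        ids = [int(i) for i in domain.ids]
        reserve_pus = {y: set(ids[: counts[y]]) for y in STUDY_YEARS}
    elif isinstance(reserve_pus, (set, frozenset)):
        reserve_pus = {y: set(reserve_pus) for y in STUDY_YEARS}
    return eng.Scenario(
        years=list(STUDY_YEARS),
        closed_months=closed,
        reserve_pus={y: frozenset(v) for y, v in reserve_pus.items()},
        M_annual=M,
        F_annual=F,
        label=label,
    )


def make_observations(
    true_omega: float,
    true_v: float,
    domain: GridDomain,
    fieldm: MovementField,
    scenario: eng.Scenario,
    initial: pop.PopulationState,
    bio: pop.BioParams,
    fleet_params: fl.FleetParams,
    noise_sd: float = 0.2,
    seed: int = 0,
    obs_month: int = 9,
    obs_years: list[int] | None = None,
) -> ObservationSet:
    """Synthetic survey surfaces for calibration experiments.

    Runs the deterministic engine at the true (omega, v), extracts the
    per-PU biomass in ``obs_month`` of each observation year (default:
    all scenario years after the first two, mimicking a survey gap), and
    applies multiplicative lognormal LN(0, noise_sd) observation error.
    """
    fp = fl.FleetParams(
        F_base=fleet_params.F_base, v=true_v,
        aggregation_error_sd=fleet_params.aggregation_error_sd,
    )
    traj = eng.run(initial, domain, fieldm, scenario, bio, fp, true_omega, rng=None)
    if obs_years is None:
        obs_years = list(scenario.years[2:])
    rng = np.random.default_rng(seed)
    table: dict[int, dict[int, float]] = {}
    for year in obs_years:
        sim = traj.biomass[traj.at(year, obs_month)]
        noise = np.exp(rng.normal(0.0, noise_sd, size=domain.n_pu)) if noise_sd > 0 else 1.0
        vals = sim * noise
        table[year] = {int(pid): float(v) for pid, v in zip(domain.ids, vals)}
    return ObservationSet(biomass=table, month=obs_month)


def make_fixture_set(
    spec: FixtureSpec,
    lag: float = 1.0,
    reserve_pus: dict[int, set[int]] | set[int] | None = None,
):
    """Build the full synthetic system: (domain, hsi, field, initial, scenario, bio)."""
    domain = spec.domain()
    hsi = make_hsi_field(spec)
    fieldm = build_movement_field(domain, hsi, lag=lag)
    initial = make_initial_distribution(spec, domain, hsi)
    scenario = default_scenario(domain, reserve_pus=reserve_pus)
    bio = pop.BioParams(M_annual=dict(STUDY_M))
    return domain, hsi, fieldm, initial, scenario, bio
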