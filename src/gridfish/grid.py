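"""Planning-unit grids, adjacency, closure schedules, and Marxan-style I/O.

The simulation domain is a collection of planning units (PUs) — the grid
cells a conservation planner selects reserves from.  Fish move between
rook-adjacent (edge-sharing) PUs, so the domain carries a symmetric
adjacency structure.  Regular lattices are built directly; irregular
coastal domains can be loaded from a PU table with explicit adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlanningUnit",
    "GridDomain",
    "ClosureSchedule",
    "build_regular_grid",
    "read_pu_table",
    "write_pu_table",
    "read_solution_mask",
    "write_solution_mask",
]


class GridFormatError(ValueError):
    """A PU table or solution file violates the expected format."""


@dataclass(frozen=True)
class PlanningUnit:
    """One planning unit: a grid cell with an id, location, and area (km²)."""

    id: int
    row: int
    col: int
    centroid_x: float
    centroid_y: float
    area: float

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError(f"PU id must be positive, got {self.id}")
        if self.area <= 0:
            raise ValueError(f"PU area must be > 0, got {self.area}")


@dataclass
class GridDomain:
    """A set of planning units with rook adjacency.

    ``units`` is ordered; internal arrays are indexed in this order.
    ``adjacency`` maps PU id -> sorted list of neighbour ids and is
    symmetric by construction.
    """

    units: list[PlanningUnit]
    adjacency: dict[int, list[int]]
    n_rows: int | None = None
    n_cols: int | None = None
    _index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [u.id for u in self.units]
        if len(set(ids)) != len(ids):
            raise GridFormatError("duplicate PU ids in domain")
        self._index = {pid: k for k, pid in enumerate(ids)}
        for i, nbrs in self.adjacency.items():
            for j in nbrs:
                if i not in self.adjacency.get(j, []):
                    raise ValueError(f"adjacency not symmetric: {i} -> {j}")

    @property
    def n_pu(self) -> int:
        return len(self.units)

    @property
    def ids(self) -> np.ndarray:
        return np.array([u.id for u in self.units], dtype=int)

    @property
    def areas(self) -> np.ndarray:
        return np.array([u.area for u in self.units], dtype=float)

    def index_of(self, pu_id: int) -> int:
        """Position of ``pu_id`` in the domain's internal ordering."""
        try:
            return self._index[pu_id]
        except KeyError:
            raise KeyError(f"unknown PU id {pu_id}") from None

    def neighbors(self, pu_id: int) -> list[int]:
        """Rook neighbours of ``pu_id``, ascending by id."""
        if pu_id not in self._index:
            raise KeyError(f"unknown PU id {pu_id}")
        return list(self.adjacency.get(pu_id, []))

    def neighbor_counts(self) -> np.ndarray:
        return np.array([len(self.adjacency.get(u.id, [])) for u in self.units])

    def movement_matrix(self) -> np.ndarray:
        """Dense redistribution matrix T with T[i, j] = 1/n_j for j's
        neighbours i, 0 elsewhere.  ``T @ emigrants`` yields per-PU
        immigration when each PU's emigrants split evenly among its
        neighbours; columns of T sum to 1 (or 0 for isolated PUs)."""
        n = self.n_pu
        T = np.zeros((n, n))
        for j, unit in enumerate(self.units):
            nbrs = self.adjacency.get(unit.id, [])
            if nbrs:
                w = 1.0 / len(nbrs)
                for pid in nbrs:
                    T[self._index[pid], j] = w
        return T


def build_regular_grid(n_rows: int, n_cols: int, cell_area: float) -> GridDomain:
    """Build a regular ``n_rows`` x ``n_cols`` lattice of square PUs.

    Ids run 1..n_rows*n_cols in row-major order; adjacency is rook
    (4-neighbour).  Centroids are placed on a unit lattice scaled by the
    cell side length sqrt(cell_area).
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if cell_area <= 0:
        raise ValueError("cell_area must be > 0")
    side = float(np.sqrt(cell_area))
    units = []
    for r in range(n_rows):
        for c in range(n_cols):
            pid = r * n_cols + c + 1
            units.append(
                PlanningUnit(
                    id=pid,
                    row=r,
                    col=c,
                    centroid_x=(c + 0.5) * side,
                    centroid_y=(r + 0.5) * side,
                    area=cell_area,
                )
            )
    adjacency = _lattice_adjacency(n_rows, n_cols)
    return GridDomain(units=units, adjacency=adjacency, n_rows=n_rows, n_cols=n_cols)


def _lattice_adjacency(n_rows: int, n_cols: int) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            pid = r * n_cols + c + 1
            nbrs = []
            if r > 0:
                nbrs.append(pid - n_cols)
            if c > 0:
                nbrs.append(pid - 1)
            if c < n_cols - 1:
                nbrs.append(pid + 1)
            if r < n_rows - 1:
                nbrs.append(pid + n_cols)
            adj[pid] = sorted(nbrs)
    return adj


def read_pu_table(path, adjacency: dict[int, list[int]] | None = None) -> GridDomain:
    """Read a planning-unit table (CSV ``id,x,y,area[,row,col]``).

    When ``row``/``col`` columns are present, or the coordinates lie on a
    regular lattice, rook adjacency is inferred; otherwise an explicit
    ``adjacency`` mapping must be supplied.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise GridFormatError(f"empty PU table: {path}")
    required = {"id", "x", "y", "area"}
    missing = required - set(df.columns)
    if missing:
        raise GridFormatError(f"PU table missing column(s): {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise GridFormatError(f"duplicate PU id(s): {dups}")

    if {"row", "col"}.issubset(df.columns):
        rows = df["row"].to_numpy(dtype=int)
        cols = df["col"].to_numpy(dtype=int)
    else:
        rows, cols = _infer_lattice(df["x"].to_numpy(), df["y"].to_numpy())
        if rows is None:
            if adjacency is None:
                raise GridFormatError(
                    "PU coordinates are not on a regular lattice; "
                    "supply adjacency explicitly"
                )
            cols = rows = np.zeros(len(df), dtype=int)

    units = [
        PlanningUnit(
            id=int(rec.id),
            row=int(r),
            col=int(c),
            centroid_x=float(rec.x),
            centroid_y=float(rec.y),
            area=float(rec.area),
        )
        for rec, r, c in zip(df.itertuples(), rows, cols)
    ]
    if adjacency is None:
        adjacency = _adjacency_from_rowcol(units)
    n_rows = int(max(u.row for u in units)) + 1
    n_cols = int(max(u.col for u in units)) + 1
    return GridDomain(units=units, adjacency=adjacency, n_rows=n_rows, n_cols=n_cols)


def _infer_lattice(x: np.ndarray, y: np.ndarray):
    """Map coordinates to (row, col) indices if they form a regular lattice."""
    ux, uy = np.unique(x), np.unique(y)
    if len(ux) * len(uy) < len(x):
        return None, None
    col = np.searchsorted(ux, x)
    row = np.searchsorted(uy, y)
    # lattice must place every PU on a distinct (row, col)
    if len({(r, c) for r, c in zip(row, col)}) != len(x):
        return None, None
    for u in (ux, uy):
        if len(u) > 2:
            steps = np.diff(u)
            if not np.allclose(steps, steps[0], rtol=1e-6):
                return None, None
    return row, col


def _adjacency_from_rowcol(units: list[PlanningUnit]) -> dict[int, list[int]]:
    by_pos = {(u.row, u.col): u.id for u in units}
    adj: dict[int, list[int]] = {}
    for u in units:
        nbrs = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            pid = by_pos.get((u.row + dr, u.col + dc))
            if pid is not None:
                nbrs.append(pid)
        adj[u.id] = sorted(nbrs)
    return adj


def write_pu_table(domain: GridDomain, path) -> None:
    """Write the domain as a PU table readable by :func:`read_pu_table`."""
    pd.DataFrame(
        {
            "id": [u.id for u in domain.units],
            "x": [u.centroid_x for u in domain.units],
            "y": [u.centroid_y for u in domain.units],
            "area": [u.area for u in domain.units],
            "row": [u.row for u in domain.units],
            "col": [u.col for u in domain.units],
        }
    ).to_csv(path, index=False)


def read_solution_mask(path, domain: GridDomain) -> set[int]:
    """Read a Marxan-style best-solution file: columns (PU id, 0/1).

    Returns the set of PU ids selected as reserve (value 1).  Ids absent
    from the file are treated as unselected; ids outside the domain are a
    consistency error.  Accepts comma- or whitespace-delimited text, with
    or without a header row.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return set()
    if df.shape[1] < 2:
        raise GridFormatError("solution file must have two columns: pu id, 0/1")
    df = df.iloc[:, :2]
    df.columns = ["pu", "sol"]
    # tolerate a header row of names
    first = df.iloc[0]
    if not str(first["pu"]).lstrip("-").isdigit():
        df = df.iloc[1:]
    pu = pd.to_numeric(df["pu"], errors="raise").astype(int)
    sol = pd.to_numeric(df["sol"], errors="raise")
    if not sol.isin([0, 1]).all():
        bad = sorted(sol[~sol.isin([0, 1])].unique())
        raise GridFormatError(f"solution values must be 0/1, got {bad}")
    known = set(domain._index)
    outside = sorted(set(pu) - known)
    if outside:
        raise GridFormatError(f"solution file lists PU id(s) not in domain: {outside}")
    return set(pu[sol == 1].astype(int))


def write_solution_mask(reserve: set[int], domain: GridDomain, path) -> None:
    """Write a two-column Marxan-style solution file covering every PU."""
    pd.DataFrame(
        {
            "planning_unit": domain.ids,
            "solution": [1 if pid in reserve else 0 for pid in domain.ids],
        }
    ).to_csv(path, index=False)


@dataclass
class ClosureSchedule:
    """Per-year seasonal closures and no-take reserve sets.

    ``closed_months[year]`` holds month indices 1-12 during which the
    whole fishery is closed; ``reserve_pus[year]`` holds PU ids closed to
    fishing all year.  A PU is open in (year, month) iff the month is not
    closed and the PU is not in that year's reserve.
    """

    closed_months: dict[int, frozenset[int]]
    reserve_pus: dict[int, frozenset[int]]

    def __post_init__(self) -> None:
        for year, months in self.closed_months.items():
            self.closed_months[year] = frozenset(int(m) for m in months)
            if not self.closed_months[year] <= frozenset(range(1, 13)):
                raise ValueError(f"closed months for {year} outside 1-12: {months}")
        for year, pus in self.reserve_pus.items():
            self.reserve_pus[year] = frozenset(int(p) for p in pus)

    def years(self) -> list[int]:
        return sorted(set(self.closed_months) | set(self.reserve_pus))

    def openness(self, pu_id: int, year: int, month: int) -> int:
        """1 if (pu, year, month) is open to fishing, else 0."""
        if year not in self.closed_months and year not in self.reserve_pus:
            raise KeyError(f"year {year} not in schedule")
        if month in self.closed_months.get(year, frozenset()):
            return 0
        if pu_id in self.reserve_pus.get(year, frozenset()):
            return 0
        return 1

    def open_mask(self, domain: GridDomain, year: int, month: int) -> np.ndarray:
        """Boolean openness vector over the domain ordering."""
        if year not in self.closed_months and year not in self.reserve_pus:
            raise KeyError(f"year {year} not in schedule")
        if month in self.closed_months.get(year, frozenset()):
            return np.zeros(domain.n_pu, dtype=bool)
        reserve = self.reserve_pus.get(year, frozenset())
        return np.array([pid not in reserve for pid in domain.ids])
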