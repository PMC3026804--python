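"""Build bipartite incidence matrices and unipartite projections from visitation records.

The input is a flat table of visitation survey rows (one row per plant x
pollinator-species combination within a population, plus optional zero-visit
census rows that carry observation effort for unvisited plants).  Plants are
filtered on censusing effort and visitation before any network is built; the
retained plants define the rows of a binary plants x pollinator-species
incidence matrix, whose one-mode projections (plant side and pollinator side)
are multigraphs where edge multiplicity counts shared partners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VISITATION_COLUMNS",
    "CENSUS_SENTINEL",
    "FilterReport",
    "IncidenceMatrix",
    "ProjectionGraph",
    "validate_visitation",
    "filter_plants",
    "build_incidence",
    "project_plants",
    "project_pollinators",
]

#: Required columns of a visitation table, in canonical order.
VISITATION_COLUMNS = (
    "population_id",
    "plant_id",
    "pollinator_species",
    "functional_group",
    "visits",
    "minutes_observed",
    "open_flowers",
)

#: Pseudo-species used for zero-visit census rows (effort bookkeeping only).
CENSUS_SENTINEL = "__census__"


class NoPlantsSurviveFilterError(ValueError):
    """Raised when the effort/visitation filter removes every plant."""


def validate_visitation(table: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and basic invariants of a visitation table.

    Returns the table with canonical column order.  Raises ``ValueError``
    listing the expected header on missing columns, or on negative visits /
    non-positive observation minutes.
    """
    missing = [c for c in VISITATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"visitation table missing columns {missing}; "
            f"expected header: {list(VISITATION_COLUMNS)}"
        )
    tab = table.loc[:, list(VISITATION_COLUMNS)].copy()
    if (tab["visits"] < 0).any():
        raise ValueError("visitation table contains negative visit counts")
    if (tab["minutes_observed"] <= 0).any():
        raise ValueError("minutes_observed must be positive for every row")
    if (tab["open_flowers"] < 0).any():
        raise ValueError("open_flowers must be nonnegative")
    return tab


@dataclass
class FilterReport:
    """Bookkeeping for the effort/visitation plant filter."""

    n_plants_in: int
    n_plants_kept: int
    n_dropped_minutes: int
    n_dropped_no_visits: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_plants_kept}/{self.n_plants_in} plants kept "
            f"({self.n_dropped_minutes} dropped for insufficient minutes, "
            f"{self.n_dropped_no_visits} for zero visits)"
        )


def filter_plants(
    visits: pd.DataFrame,
    min_minutes: float = 15.0,
    return_report: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, FilterReport]:
    """Keep plants censused strictly more than ``min_minutes`` with >= 1 visit.

    Both conditions are evaluated per plant (within each population) on the
    aggregated table: total visits summed across rows, observation minutes
    taken as the per-plant effort (constant across a plant's rows).  Plants at
    exactly ``min_minutes`` are dropped (strict inequality).  Idempotent.
    """
    tab = validate_visitation(visits)
    key = ["population_id", "plant_id"]
    per_plant = tab.groupby(key, sort=False).agg(
        total_visits=("visits", "sum"),
        minutes=("minutes_observed", "max"),
    )
    enough_minutes = per_plant["minutes"] > min_minutes
    visited = per_plant["total_visits"] >= 1
    keep = enough_minutes & visited
    report = FilterReport(
        n_plants_in=len(per_plant),
        n_plants_kept=int(keep.sum()),
        n_dropped_minutes=int((~enough_minutes).sum()),
        n_dropped_no_visits=int((~visited).sum()),
    )
    if report.n_plants_kept == 0:
        raise NoPlantsSurviveFilterError(
            f"no plants survive filter (min_minutes={min_minutes}): {report}"
        )
    kept_index = per_plant.index[keep]
    mask = pd.MultiIndex.from_frame(tab[key]).isin(kept_index)
    out = tab.loc[mask].reset_index(drop=True)
    if return_report:
        return out, report
    return out


@dataclass
class IncidenceMatrix:
    """Binary plants x pollinator-species matrix with visit counts alongside.

    ``presence[i, k] == 1`` iff ``counts[i, k] >= 1``.  Row and column
    orderings are stable (lexicographically sorted identifiers).
    """

    plants: list
    pollinators: list
    presence: np.ndarray
    counts: np.ndarray
    functional_groups: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.presence.shape

    def validate(self) -> None:
        if self.presence.shape != self.counts.shape:
            raise ValueError("presence/counts shape mismatch")
        if not np.array_equal(self.presence, (self.counts >= 1).astype(int)):
            raise ValueError("presence must be the indicator of counts >= 1")
        if (self.presence.sum(axis=1) == 0).any():
            raise ValueError("incidence matrix has an all-zero plant row")


def build_incidence(visits: pd.DataFrame) -> IncidenceMatrix:
    """Aggregate a (filtered) visitation table into an incidence matrix.

    Zero-visit census rows are ignored; ``counts[i, k]`` is the summed number
    of visits of species ``k`` to plant ``i``.
    """
    tab = validate_visitation(visits)
    tab = tab[(tab["visits"] >= 1) & (tab["pollinator_species"] != CENSUS_SENTINEL)]
    if tab.empty:
        raise ValueError("no visit rows to build an incidence matrix from")
    plants = sorted(tab["plant_id"].unique())
    pollinators = sorted(tab["pollinator_species"].unique())
    p_index = {p: i for i, p in enumerate(plants)}
    s_index = {s: k for k, s in enumerate(pollinators)}
    counts = np.zeros((len(plants), len(pollinators)), dtype=np.int64)
    for plant, species, v in zip(
        tab["plant_id"], tab["pollinator_species"], tab["visits"]
    ):
        counts[p_index[plant], s_index[species]] += int(v)
    groups = (
        tab.drop_duplicates("pollinator_species")
        .set_index("pollinator_species")["functional_group"]
        .to_dict()
    )
    inc = IncidenceMatrix(
        plants=plants,
        pollinators=pollinators,
        presence=(counts >= 1).astype(int),
        counts=counts,
        functional_groups=groups,
    )
    inc.validate()
    return inc


@dataclass
class ProjectionGraph:
    """Unipartite projection: nodes from one mode, multi-edges = shared partners.

    ``multiplicity`` is a symmetric n x n integer matrix with zero diagonal;
    an (unordered) pair is an edge iff its multiplicity is >= 1.  The simple
    reduction is the 0/1 support of ``multiplicity``.
    """

    nodes: list
    multiplicity: np.ndarray
    node_groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.multiplicity)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("multiplicity must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("multiplicity must be symmetric")
        if np.diagonal(m).any():
            raise ValueError("self-loops are not allowed")
        self.multiplicity = m

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def adjacency(self) -> np.ndarray:
        """Simple-graph 0/1 adjacency (support of the multiplicity matrix)."""
        return (self.multiplicity >= 1).astype(int)

    @property
    def L(self) -> int:
        """Number of edges of the simple reduction."""
        return int(self.adjacency.sum()) // 2

    def simple_edges(self) -> list[tuple]:
        iu, ju = np.nonzero(np.triu(self.multiplicity, k=1))
        return [(self.nodes[i], self.nodes[j]) for i, j in zip(iu, ju)]


def _project(presence: np.ndarray) -> np.ndarray:
    shared = presence @ presence.T
    np.fill_diagonal(shared, 0)
    return shared


def project_plants(inc: IncidenceMatrix) -> ProjectionGraph:
    """Plant-plant projection: multiplicity = number of shared pollinator species."""
    return ProjectionGraph(
        nodes=list(inc.plants),
        multiplicity=_project(np.asarray(inc.presence, dtype=np.int64)),
    )


def project_pollinators(inc: IncidenceMatrix) -> ProjectionGraph:
    """Pollinator-pollinator projection: multiplicity = number of shared plants."""
    return ProjectionGraph(
        nodes=list(inc.pollinators),
        multiplicity=_project(np.asarray(inc.presence, dtype=np.int64).T),
        node_groups=dict(inc.functional_groups),
    )
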