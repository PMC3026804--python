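"""Synthetic visitation surveys, spatial layouts, and a downstream fitness chain.

Generates multi-population pollinator visitation data with heterogeneous
species abundances, functional-group-specific foraging behaviour, and a
multiplicative per-plant fitness chain (seed-ovule ratio -> fruits -> seeds ->
germination -> survival -> juveniles) whose expectation can be coupled to a
latent per-plant connectivity score.  All randomness flows through explicit
seeds; identical seeds give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .construction import (
    CENSUS_SENTINEL,
    VISITATION_COLUMNS,
    build_incidence,
    filter_plants,
    project_plants,
)

__all__ = [
    "FUNCTIONAL_GROUPS",
    "FORAGING_MODES",
    "PollinatorPool",
    "SimulatedPopulation",
    "FitnessChainParams",
    "SyntheticStudy",
    "simulate_pool",
    "simulate_population",
    "simulate_visitation",
    "simulate_performance",
    "simulate_study",
]

FUNCTIONAL_GROUPS = (
    "large_bee",
    "small_bee",
    "wasp",
    "beefly",
    "hoverfly",
    "beetle",
    "butterfly",
    "other",
)

FORAGING_MODES = ("indiscriminate", "distance_limited", "within_plant")

#: Fixed foraging modes for groups with well-characterized behaviour.
_GROUP_MODE = {
    "beefly": "indiscriminate",
    "hoverfly": "distance_limited",
    "beetle": "within_plant",
}

#: Default mode mixture for the remaining groups.
DEFAULT_MODE_PROBS = {
    "indiscriminate": 0.4,
    "distance_limited": 0.4,
    "within_plant": 0.2,
}


@dataclass
class PollinatorPool:
    """A local pollinator species pool with abundances and foraging modes."""

    species_id: list
    functional_group: list
    relative_abundance: np.ndarray
    foraging_mode: list

    def __post_init__(self) -> None:
        ab = np.asarray(self.relative_abundance, dtype=float)
        if (ab < 0).any():
            raise ValueError("relative abundances must be nonnegative")
        if abs(ab.sum() - 1.0) > 1e-12:
            raise ValueError("relative abundances must sum to 1")
        bad = set(self.functional_group) - set(FUNCTIONAL_GROUPS)
        if bad:
            raise ValueError(f"unknown functional groups: {sorted(bad)}")
        bad_modes = set(self.foraging_mode) - set(FORAGING_MODES)
        if bad_modes:
            raise ValueError(f"unknown foraging modes: {sorted(bad_modes)}")
        self.relative_abundance = ab

    @property
    def n_species(self) -> int:
        return len(self.species_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": self.species_id,
                "functional_group": self.functional_group,
                "relative_abundance": self.relative_abundance,
                "foraging_mode": self.foraging_mode,
            }
        )


@dataclass
class SimulatedPopulation:
    """Plant spatial layout and floral display of one population."""

    population_id: str
    plant_coords: np.ndarray  # n x 2, metres
    flowers_per_plant: np.ndarray  # n positive ints
    population_coord: tuple  # km scale

    def __post_init__(self) -> None:
        coords = np.asarray(self.plant_coords, dtype=float)
        flowers = np.asarray(self.flowers_per_plant, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
            raise ValueError("plant_coords must be n x 2 with n >= 2")
        if not np.isfinite(coords).all():
            raise ValueError("plant coordinates must be finite")
        if (flowers < 1).any():
            raise ValueError("flowers_per_plant must be >= 1")
        if flowers.shape[0] != coords.shape[0]:
            raise ValueError("flowers_per_plant must align with plant_coords")
        self.plant_coords = coords
        self.flowers_per_plant = flowers

    @property
    def n_plants(self) -> int:
        return self.plant_coords.shape[0]

    @property
    def plant_ids(self) -> list:
        return [f"{self.population_id}_p{i:03d}" for i in range(self.n_plants)]


@dataclass
class FitnessChainParams:
    """Parameters of the multiplicative fitness chain."""

    so_ratio_mean: float = 0.6
    fruits_per_plant_mean: float = 20.0
    germination_prob: float = 0.5
    survival_prob: float = 0.5
    architecture_effect: float = 0.0
    noise_sd: float = 0.3
    spatial_autocorr_range: float = 20.0
    seeds_planted: int = 10
    ovules_per_fruit: int = 20

    def validate(self) -> None:
        for name in ("so_ratio_mean", "germination_prob", "survival_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.fruits_per_plant_mean <= 0:
            raise ValueError("fruits_per_plant_mean must be positive")
        if self.spatial_autocorr_range <= 0:
            raise ValueError("spatial_autocorr_range must be positive")
        if self.seeds_planted < 1 or self.ovules_per_fruit < 1:
            raise ValueError("seeds_planted and ovules_per_fruit must be >= 1")


def simulate_pool(
    n_species: int,
    abundance_shape: float = 1.5,
    group_weights=None,
    seed: int | np.random.Generator | None = None,
    default_mode_probs: dict | None = None,
) -> PollinatorPool:
    """Draw a pollinator pool with heavy-tailed (lognormal) abundances.

    ``group_weights`` is a length-8 probability vector over the functional
    groups (uniform by default).  Foraging modes are fixed per group for
    beeflies (indiscriminate), hoverflies (distance-limited) and beetles
    (within-plant); other groups draw from ``default_mode_probs``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if abundance_shape <= 0:
        raise ValueError("abundance_shape must be positive")
    if group_weights is None:
        weights = np.full(len(FUNCTIONAL_GROUPS), 1.0 / len(FUNCTIONAL_GROUPS))
    else:
        weights = np.asarray(group_weights, dtype=float)
        if weights.shape != (len(FUNCTIONAL_GROUPS),):
            raise ValueError("group_weights must have 8 entries")
        if (weights < 0).any() or weights.sum() <= 0:
            raise ValueError("group_weights are not normalizable")
        weights = weights / weights.sum()
    mode_probs = dict(DEFAULT_MODE_PROBS if default_mode_probs is None else default_mode_probs)
    mp = np.array([mode_probs.get(m, 0.0) for m in FORAGING_MODES], dtype=float)
    if mp.sum() <= 0:
        raise ValueError("default_mode_probs are not normalizable")
    mp = mp / mp.sum()

    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=abundance_shape, size=n_species)
    abundance = raw / raw.sum()
    groups = list(rng.choice(FUNCTIONAL_GROUPS, size=n_species, p=weights))
    modes = [
        _GROUP_MODE.get(g, FORAGING_MODES[rng.choice(len(FORAGING_MODES), p=mp)])
        for g in groups
    ]
    species = [f"sp{i:03d}" for i in range(n_species)]
    return PollinatorPool(
        species_id=species,
        functional_group=groups,
        relative_abundance=abundance,
        foraging_mode=modes,
    )


def simulate_population(
    population_id: str,
    n_plants: int,
    extent: float = 30.0,
    flowers_mean: float = 25.0,
    population_coord=(0.0, 0.0),
    seed: int | np.random.Generator | None = None,
) -> SimulatedPopulation:
    """Scatter plants uniformly in an ``extent x extent`` plot (metres)."""
    if n_plants < 2:
        raise ValueError("a population needs at least 2 plants")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, extent, size=(n_plants, 2))
    flowers = 1 + rng.poisson(max(flowers_mean - 1, 0.0), size=n_plants)
    return SimulatedPopulation(
        population_id=population_id,
        plant_coords=coords,
        flowers_per_plant=flowers,
        population_coord=tuple(population_coord),
    )


def _choose(rng: np.random.Generator, probs: np.ndarray) -> int:
    """Index draw from unnormalized nonnegative weights."""
    total = probs.sum()
    return int(rng.choice(probs.size, p=probs / total))


def simulate_visitation(
    pool: PollinatorPool,
    pop: SimulatedPopulation,
    surveys: int = 5,
    minutes_per_plant: float = 5.0,
    base_rate: float = 0.02,
    distance_range: float = 5.0,
    within_subset_mean: float = 2.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate visit counts per plant x pollinator species over repeated surveys.

    Each species produces a Poisson number of visit events per survey at a
    rate proportional to its relative abundance, the number of plants and the
    per-plant census minutes.  Events are placed on plants according to the
    species' foraging mode:

    * ``indiscriminate`` - every event chooses a plant with probability
      proportional to its floral display;
    * ``distance_limited`` - a sequential walk where each subsequent plant is
      weighted by display times ``exp(-d / distance_range)`` from the current
      plant;
    * ``within_plant`` - events are confined to a small random plant subset.

    The output has one row per visited (plant, species) pair plus one
    zero-visit census row per plant carrying observation effort; every row's
    ``minutes_observed`` is the plant's total censused minutes
    (``surveys * minutes_per_plant``).
    """
    if pool.n_species < 1 or pop.n_plants < 2:
        raise ValueError("pool and population must be non-empty")
    if surveys < 1:
        raise ValueError("surveys must be >= 1")
    if minutes_per_plant <= 0:
        raise ValueError("minutes_per_plant must be positive")
    rng = np.random.default_rng(seed)
    n = pop.n_plants
    flowers = pop.flowers_per_plant.astype(float)
    d = np.sqrt(
        ((pop.plant_coords[:, None, :] - pop.plant_coords[None, :, :]) ** 2).sum(axis=2)
    )
    kernel = np.exp(-d / distance_range) * flowers[None, :]

    counts = np.zeros((n, pool.n_species), dtype=np.int64)
    for _ in range(surveys):
        for k in range(pool.n_species):
            lam = base_rate * pool.relative_abundance[k] * n * minutes_per_plant
            n_events = rng.poisson(lam)
            if n_events == 0:
                continue
            mode = pool.foraging_mode[k]
            if mode == "indiscriminate":
                plants = rng.choice(n, size=n_events, p=flowers / flowers.sum())
                np.add.at(counts[:, k], plants, 1)
            elif mode == "distance_limited":
                current = _choose(rng, flowers)
                counts[current, k] += 1
                for _ev in range(n_events - 1):
                    current = _choose(rng, kernel[current])
                    counts[current, k] += 1
            else:  # within_plant
                m = min(n, 1 + rng.poisson(max(within_subset_mean - 1.0, 0.0)))
                subset = rng.choice(
                    n, size=m, replace=False, p=flowers / flowers.sum()
                )
                sub_flowers = flowers[subset]
                plants = subset[
                    rng.choice(m, size=n_events, p=sub_flowers / sub_flowers.sum())
                ]
                np.add.at(counts[:, k], plants, 1)

    minutes = float(surveys * minutes_per_plant)
    plant_ids = pop.plant_ids
    group_of = dict(zip(pool.species_id, pool.functional_group))
    rows = []
    for i in range(n):
        visited = np.nonzero(counts[i])[0]
        for k in visited:
            rows.append(
                (
                    pop.population_id,
                    plant_ids[i],
                    pool.species_id[k],
                    group_of[pool.species_id[k]],
                    int(counts[i, k]),
                    minutes,
                    int(pop.flowers_per_plant[i]),
                )
            )
        # census row: carries effort even for unvisited plants
        rows.append(
            (
                pop.population_id,
                plant_ids[i],
                CENSUS_SENTINEL,
                "other",
                0,
                minutes,
                int(pop.flowers_per_plant[i]),
            )
        )
    return pd.DataFrame(rows, columns=list(VISITATION_COLUMNS))


def simulate_performance(
    latent_connectivity,
    params: FitnessChainParams,
    seed: int | np.random.Generator | None = None,
    coords=None,
    log_shift=0.0,
) -> pd.DataFrame:
    """Run the fitness chain for one set of plants.

    Per plant: seeds per fruit are binomial over ovules at the seed-ovule
    ratio; fruit number is Poisson with its log-mean shifted by
    ``architecture_effect * latent_connectivity`` plus noise (spatially
    autocorrelated over ``coords`` if given, else iid) plus any external
    ``log_shift``; lifetime seeds multiply fruits by seeds per fruit; 10 seeds
    (configurable) are planted per plant, germinate and survive binomially;
    juveniles scale the per-seed recruitment rate back to lifetime seeds.
    """
    latent = np.asarray(latent_connectivity, dtype=float)
    if latent.ndim != 1:
        raise ValueError("latent_connectivity must be a 1-D vector")
    if np.isnan(latent).any():
        raise ValueError("latent_connectivity contains NaN")
    params.validate()
    rng = np.random.default_rng(seed)
    n = latent.size

    if coords is not None:
        pts = np.asarray(coords, dtype=float)
        dmat = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        cov = params.noise_sd**2 * np.exp(-dmat / params.spatial_autocorr_range)
        cov += 1e-10 * np.eye(n)
        noise = rng.multivariate_normal(np.zeros(n), cov, method="cholesky")
    else:
        noise = rng.normal(0.0, params.noise_sd, size=n)

    log_mult = params.architecture_effect * latent + noise + np.asarray(log_shift)
    seeds_per_fruit = rng.binomial(params.ovules_per_fruit, params.so_ratio_mean, size=n)
    fruits = rng.poisson(params.fruits_per_plant_mean * np.exp(log_mult))
    seeds = fruits * seeds_per_fruit
    planted = np.minimum(seeds, params.seeds_planted)
    germinants = rng.binomial(planted, params.germination_prob)
    survivors = rng.binomial(germinants, params.survival_prob)
    with np.errstate(divide="ignore", invalid="ignore"):
        recruit_rate = np.where(planted > 0, survivors / np.maximum(planted, 1), 0.0)
    juveniles = seeds * recruit_rate
    return pd.DataFrame(
        {
            "latent_connectivity": latent,
            "seeds_per_fruit": seeds_per_fruit,
            "fruits": fruits,
            "seeds": seeds,
            "planted": planted,
            "germinants": germinants,
            "survivors": survivors,
            "juveniles": juveniles,
        }
    )


@dataclass
class SyntheticStudy:
    """Full multi-population synthetic study: visits, plants, populations."""

    visits: pd.DataFrame
    plants: pd.DataFrame
    populations: pd.DataFrame
    pools: dict = field(default_factory=dict)


def simulate_study(
    n_pops: int = 8,
    n_plants_range: tuple = (47, 90),
    n_species_range: tuple = (30, 41),
    abundance_shape: float = 1.2,
    surveys: int = 5,
    minutes_per_plant: float = 5.0,
    base_rate_range: tuple = (0.02, 0.08),
    fitness: FitnessChainParams | None = None,
    min_minutes: float = 15.0,
    extent_km: float = 100.0,
    seed: int | None = None,
) -> SyntheticStudy:
    """Generate an end-to-end study: surveys, spatial layout, fitness chain.

    Populations differ in species richness, abundance structure, functional
    composition and overall visitation rate, so realized network metrics vary
    across populations.  The per-plant latent connectivity fed to the fitness
    chain is the plant's realized normalized degree in its population's
    plant-plant projection (zero for plants dropped by the effort filter),
    making the architecture-performance coupling operate through the realized
    networks.  A population-level spatially autocorrelated shift (exponential
    covariance over population coordinates) enters the fitness chain's
    log-mean.
    """
    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    if n_pops < 3:
        import warnings

        warnings.warn(
            "fewer than 3 populations: downstream spatial models will not be "
            "identifiable",
            stacklevel=2,
        )
    fitness = fitness or FitnessChainParams()
    fitness.validate()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    pop_seeds = ss.spawn(n_pops)

    pop_ids = [f"pop{i+1:02d}" for i in range(n_pops)]
    pop_coords = rng.uniform(0.0, extent_km, size=(n_pops, 2))
    # population-level spatially autocorrelated fitness shift
    dk = np.sqrt(((pop_coords[:, None, :] - pop_coords[None, :, :]) ** 2).sum(axis=2))
    cov = fitness.noise_sd**2 * np.exp(-dk / fitness.spatial_autocorr_range)
    cov += 1e-10 * np.eye(n_pops)
    pop_shift = rng.multivariate_normal(np.zeros(n_pops), cov, method="cholesky")

    visit_frames, plant_frames, pools = [], [], {}
    pop_records = []
    for p, (pid, child) in enumerate(zip(pop_ids, pop_seeds)):
        crng = np.random.default_rng(child)
        n_plants = int(crng.integers(n_plants_range[0], n_plants_range[1] + 1))
        n_species = int(crng.integers(n_species_range[0], n_species_range[1] + 1))
        group_weights = crng.dirichlet(np.full(len(FUNCTIONAL_GROUPS), 2.0))
        base_rate = float(crng.uniform(*base_rate_range))
        pool = simulate_pool(
            n_species,
            abundance_shape=abundance_shape,
            group_weights=group_weights,
            seed=crng,
        )
        pop = simulate_population(
            pid,
            n_plants,
            population_coord=tuple(pop_coords[p]),
            seed=crng,
        )
        visits = simulate_visitation(
            pool,
            pop,
            surveys=surveys,
            minutes_per_plant=minutes_per_plant,
            base_rate=base_rate,
            seed=crng,
        )

        # realized latent connectivity: normalized degree in the projection
        latent = np.zeros(n_plants)
        try:
            filtered = filter_plants(visits, min_minutes=min_minutes)
            inc = build_incidence(filtered)
            g = project_plants(inc)
            if g.n >= 2:
                norm_deg = g.adjacency.sum(axis=1) / (g.n - 1)
                index = {pl: i for i, pl in enumerate(pop.plant_ids)}
                for node, nd in zip(g.nodes, norm_deg):
                    latent[index[node]] = nd
        except ValueError:
            pass  # no plants survive: all latent scores stay zero

        perf = simulate_performance(
            latent, fitness, seed=crng, log_shift=pop_shift[p]
        )
        perf.insert(0, "plant_id", pop.plant_ids)
        perf.insert(0, "population_id", pid)
        perf["x_m"] = pop.plant_coords[:, 0]
        perf["y_m"] = pop.plant_coords[:, 1]
        perf["flowers"] = pop.flowers_per_plant

        visit_frames.append(visits)
        plant_frames.append(perf)
        pools[pid] = pool
        pop_records.append(
            {
                "population_id": pid,
                "x_km": pop_coords[p, 0],
                "y_km": pop_coords[p, 1],
                "n_plants": n_plants,
                "n_species_pool": n_species,
                "base_rate": base_rate,
            }
        )

    return SyntheticStudy(
        visits=pd.concat(visit_frames, ignore_index=True),
        plants=pd.concat(plant_frames, ignore_index=True),
        populations=pd.DataFrame(pop_records),
        pools=pools,
    )
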