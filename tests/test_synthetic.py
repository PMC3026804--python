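import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pollnet.construction import (
    CENSUS_SENTINEL,
    build_incidence,
    filter_plants,
    project_plants,
)
from pollnet.synthetic import (
    FORAGING_MODES,
    FUNCTIONAL_GROUPS,
    FitnessChainParams,
    simulate_performance,
    simulate_pool,
    simulate_population,
    simulate_study,
    simulate_visitation,
)


class TestSimulatePool:
    def test_single_species_abundance_one(self):
        pool = simulate_pool(1, seed=0)
        assert pool.relative_abundance[0] == pytest.approx(1.0)

    def test_invariants_32_species(self):
        pool = simulate_pool(32, seed=1)
        assert pool.relative_abundance.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pool.relative_abundance >= 0).all()
        assert set(pool.functional_group) <= set(FUNCTIONAL_GROUPS)
        assert set(pool.foraging_mode) <= set(FORAGING_MODES)

    def test_seed_reproducibility_bit_identical(self):
        a = simulate_pool(30, abundance_shape=1.5, seed=7)
        b = simulate_pool(30, abundance_shape=1.5, seed=7)
        np.testing.assert_array_equal(a.relative_abundance, b.relative_abundance)
        assert a.functional_group == b.functional_group
        assert a.foraging_mode == b.foraging_mode

    def test_fixed_group_modes(self):
        pool = simulate_pool(200, seed=3)
        for sp, grp, mode in zip(
            pool.species_id, pool.functional_group, pool.foraging_mode
        ):
            if grp == "beefly":
                assert mode == "indiscriminate"
            elif grp == "hoverfly":
                assert mode == "distance_limited"
            elif grp == "beetle":
                assert mode == "within_plant"

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="normalizable|8 entries"):
            simulate_pool(5, group_weights=np.zeros(8), seed=0)
        with pytest.raises(ValueError):
            simulate_pool(5, group_weights=np.ones(3), seed=0)

    def test_nonpositive_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_pool(0, seed=0)


class TestSimulateVisitation:
    def test_high_rate_indiscriminate_visits_both_plants(self):
        pool = simulate_pool(1, group_weights=np.eye(8)[3], seed=0)  # beefly
        assert pool.foraging_mode == ["indiscriminate"]
        pop = simulate_population("pop01", 2, seed=0)
        v = simulate_visitation(pool, pop, surveys=1, minutes_per_plant=500.0,
                                base_rate=1.0, seed=0)
        visited = set(v[v.visits >= 1]["plant_id"])
        assert visited == set(pop.plant_ids)

    def test_zero_rate_gives_no_visit_rows(self):
        pool = simulate_pool(3, seed=0)
        pop = simulate_population("pop01", 4, seed=0)
        v = simulate_visitation(pool, pop, base_rate=0.0, seed=0)
        assert (v["visits"] == 0).all()
        assert (v["pollinator_species"] == CENSUS_SENTINEL).all()

    def test_effort_bookkeeping(self):
        pool = simulate_pool(5, seed=1)
        pop = simulate_population("pop01", 7, seed=1)
        surveys, minutes = 4, 5.0
        v = simulate_visitation(pool, pop, surveys=surveys,
                                minutes_per_plant=minutes, seed=1)
        per_plant = v.groupby("plant_id")["minutes_observed"].first()
        assert len(per_plant) == 7
        assert per_plant.sum() == pytest.approx(surveys * 7 * minutes)

    def test_determinism(self):
        pool = simulate_pool(6, seed=2)
        pop = simulate_population("pop01", 10, seed=2)
        a = simulate_visitation(pool, pop, seed=5)
        b = simulate_visitation(pool, pop, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_incidence_fill_near_target(self):
        # base_rate tuned so mean per-plant richness ~ 4 of 32 species
        pool = simulate_pool(32, abundance_shape=1.0, seed=5)
        pop = simulate_population("pop01", 60, seed=5)
        target_fill = 4 / 32
        fills = []
        for rep in range(20):
            v = simulate_visitation(pool, pop, base_rate=0.21, seed=100 + rep)
            real = v[v.visits >= 1]
            rich = (
                real.groupby("plant_id")["pollinator_species"]
                .nunique()
                .reindex(pop.plant_ids)
                .fillna(0)
            )
            fills.append(rich.mean() / pool.n_species)
        assert np.mean(fills) == pytest.approx(target_fill, rel=0.2)

    def test_empty_population_rejected(self):
        pool = simulate_pool(3, seed=0)
        with pytest.raises(ValueError):
            simulate_population("x", 1, seed=0)


class TestSimulatePerformance:
    def test_zero_germination_zero_juveniles(self):
        params = FitnessChainParams(germination_prob=0.0)
        out = simulate_performance(np.linspace(0, 1, 50), params, seed=0)
        assert (out["juveniles"] == 0).all()

    def test_null_coupling_uncorrelated(self):
        params = FitnessChainParams(architecture_effect=0.0)
        rng = np.random.default_rng(0)
        latent = rng.normal(size=1000)
        out = simulate_performance(latent, params, seed=1)
        r = stats.spearmanr(latent, out["juveniles"]).statistic
        assert abs(r) < 0.1

    def test_positive_coupling_recovered(self):
        # rank correlation positive in >= 95% of 100 seeds
        params = FitnessChainParams(architecture_effect=0.5, noise_sd=0.1)
        hits = 0
        rng = np.random.default_rng(42)
        for s in range(100):
            latent = rng.normal(size=200)
            out = simulate_performance(latent, params, seed=1000 + s)
            r = stats.spearmanr(latent, out["juveniles"]).statistic
            hits += r > 0
        assert hits >= 95

    def test_nan_latent_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            simulate_performance(np.array([0.0, np.nan]), FitnessChainParams(),
                                 seed=0)

    def test_negative_latent_allowed(self):
        out = simulate_performance(np.array([-1.0, -2.0, 0.5]),
                                   FitnessChainParams(), seed=0)
        assert len(out) == 3

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FitnessChainParams(germination_prob=1.5).validate()
        with pytest.raises(ValueError):
            FitnessChainParams(noise_sd=0.0).validate()

    def test_components_consistent(self):
        out = simulate_performance(np.zeros(100), FitnessChainParams(), seed=3)
        np.testing.assert_array_equal(out["seeds"],
                                      out["fruits"] * out["seeds_per_fruit"])
        assert (out["germinants"] <= out["planted"]).all()
        assert (out["survivors"] <= out["germinants"]).all()

    def test_coupling_monotonicity_paired(self):
        # increasing the architecture effect increases mean juveniles
        rng = np.random.default_rng(9)
        latent = rng.uniform(0.2, 1.0, size=1000)
        lo = simulate_performance(latent,
                                  FitnessChainParams(architecture_effect=0.3),
                                  seed=77)
        hi = simulate_performance(latent,
                                  FitnessChainParams(architecture_effect=0.9),
                                  seed=77)
        assert hi["juveniles"].mean() > lo["juveniles"].mean()

    def test_spatial_noise_path(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, size=(30, 2))
        out = simulate_performance(np.zeros(30), FitnessChainParams(), seed=2,
                                   coords=coords)
        assert len(out) == 30


class TestForagingContrast:
    def test_indiscriminate_exceeds_within_plant_degree(self):
        # identical rates; compare mean plant degree in the projection
        wins = 0
        for s in range(50):
            deg = {}
            for mode_probs, label in (
                ({"indiscriminate": 1.0}, "ind"),
                ({"within_plant": 1.0}, "wp"),
            ):
                pool = simulate_pool(
                    8,
                    abundance_shape=0.5,
                    group_weights=np.eye(8)[7],  # 'other': configurable mode
                    default_mode_probs=mode_probs,
                    seed=s,
                )
                pop = simulate_population("pop01", 20, seed=s)
                v = simulate_visitation(pool, pop, base_rate=0.3, seed=s)
                try:
                    inc = build_incidence(filter_plants(v, min_minutes=0.0))
                    g = project_plants(inc)
                    deg[label] = g.adjacency.sum() / g.n
                except ValueError:
                    deg[label] = 0.0
            wins += deg["ind"] > deg["wp"]
        assert wins >= 40


class TestSimulateStudy:
    def test_dimensions_in_configured_ranges(self):
        study = simulate_study(n_pops=8, seed=11)
        pops = study.populations
        assert len(pops) == 8
        assert pops["n_plants"].between(47, 90).all()
        assert pops["n_species_pool"].between(30, 41).all()

    def test_same_seed_byte_identical(self, tmp_path):
        a = simulate_study(n_pops=4, n_plants_range=(10, 15),
                           n_species_range=(5, 8), seed=21)
        b = simulate_study(n_pops=4, n_plants_range=(10, 15),
                           n_species_range=(5, 8), seed=21)
        for x, y in ((a.visits, b.visits), (a.plants, b.plants),
                     (a.populations, b.populations)):
            fa, fb = tmp_path / "a.csv", tmp_path / "b.csv"
            x.to_csv(fa, index=False)
            y.to_csv(fb, index=False)
            assert fa.read_bytes() == fb.read_bytes()

    def test_metric_variation_across_populations(self):
        study = simulate_study(n_pops=6, n_plants_range=(20, 30),
                               n_species_range=(8, 12), seed=13)
        conns = []
        for pid, sub in study.visits.groupby("population_id"):
            inc = build_incidence(filter_plants(sub))
            g = project_plants(inc)
            conns.append(g.adjacency.sum() / (g.n * (g.n - 1)))
        assert np.std(conns) > 0.0

    def test_few_populations_warns(self):
        with pytest.warns(UserWarning, match="spatial"):
            simulate_study(n_pops=2, n_plants_range=(5, 8),
                           n_species_range=(3, 5), seed=1)

    def test_plants_table_carries_fitness_chain(self):
        study = simulate_study(n_pops=3, n_plants_range=(8, 10),
                               n_species_range=(4, 6), seed=2)
        for col in ("latent_connectivity", "fruits", "seeds", "germinants",
                    "survivors", "juveniles"):
            assert col in study.plants.columns
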