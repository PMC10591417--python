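"""Lattice dynamics: initialization, hazards, reproduction, generations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import senesim as ss
from senesim.environment import TargetPhenotype
from senesim.genome import Genome, LocusLayout
from senesim.lattice import (
    Individual,
    advance,
    candidate_parents,
    death_probability,
    derive_seeds,
    diffusion_step,
    elementary_update,
    fill_empty_site,
    initialize,
    moore_neighbors,
    run,
    run_generation,
)
from senesim.params import SimParams


def _stab_target(phi):
    return TargetPhenotype(np.asarray(phi, dtype=np.uint8), "stabilizing", 1)


class TestSimParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(delta0=1.5),
            dict(delta0=0.0),
            dict(p_f=-0.01),
            dict(p_a=1.2),
            dict(p_rec=2.0),
            dict(b=1.0),
            dict(N=4, n=2),
            dict(reproduction="parthenogenetic"),
            dict(selection="disruptive"),
            dict(L_f=0),
            dict(T=0),
            dict(D=-1.0),
            dict(fixed_alpha=0.05),  # conflicts with default p_a > 0
            dict(fixed_alpha=0.013, p_a=0.0),  # not a multiple of 0.01
            dict(fixed_alpha=0.05, p_a=0.0, evolvable_baseline=True),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**kwargs)

    def test_table_defaults(self):
        p = SimParams()
        assert (p.N, p.L_f, p.L_a) == (200, 50, 50)
        assert (p.delta0, p.b, p.n, p.T) == (0.05, 1.2, 1, 10)
        assert (p.p_rec, p.p_f, p.p_a, p.D) == (1.0, 0.01, 0.01, 0.0)


class TestInitialize:
    def test_full_occupancy_non_aging_start(self, rng):
        params = SimParams(N=50, generations=0)
        lat, target = initialize(params, rng)
        assert lat.occupancy == 1.0
        assert lat.sum_a.sum() == 0  # senescence alleles all 0 -> alpha = 0
        ages = lat.age.ravel()
        assert ages.min() >= 0 and ages.max() <= 19
        # floor of U(0, 1/delta0) has mean ~9.5 for delta0 = 0.05
        assert abs(ages.mean() - 9.5) < 0.5
        # fecundity alleles are fair coins
        fpos = lat.layout.fecundity_positions
        freq = lat.genomes[:, :, fpos].mean()
        assert abs(freq - 0.5) < 0.01

    def test_fixed_alpha_presets_alleles(self, rng):
        params = SimParams(N=10, p_a=0.0, fixed_alpha=0.07, generations=0)
        lat, _ = initialize(params, rng)
        assert np.all(lat.sum_a == 7)

    def test_monomorphic_fertility_matches_target(self, rng):
        params = SimParams(
            N=10, selection="stabilizing", monomorphic_fertility=True, generations=0
        )
        lat, target = initialize(params, rng)
        assert np.all(lat.match == params.L_f)


class TestDeathProbability:
    def test_non_ager_keeps_baseline_at_any_age(self, tiny_layout):
        g = Genome(np.zeros(4, dtype=np.uint8), tiny_layout)
        for age in (0, 5, 1000):
            assert death_probability(Individual(g, age), 0.05) == pytest.approx(0.05)

    def test_hazard_ramp_and_cap(self):
        # alpha = 0.1 (10 ON alleles), delta0 = 0.05: tau_max = floor(0.95/0.1) = 9
        layout = LocusLayout(np.array([0] + [1] * 10, dtype=np.int8))
        alleles = np.array([0] + [1] * 10, dtype=np.uint8)
        g = Genome(alleles, layout)
        assert death_probability(Individual(g, 0), 0.05) == pytest.approx(0.05)
        assert death_probability(Individual(g, 9), 0.05) == pytest.approx(0.95)
        assert death_probability(Individual(g, 10), 0.05) == 1.0

    def test_max_alpha_gives_tau_max_one(self):
        # alpha = 0.5: tau_max = floor(0.95/0.5) = 1
        layout = LocusLayout(np.array([0] + [1] * 50, dtype=np.int8))
        g = Genome(np.array([0] + [1] * 50, dtype=np.uint8), layout)
        assert death_probability(Individual(g, 1), 0.05) == pytest.approx(0.55)
        assert death_probability(Individual(g, 2), 0.05) == 1.0


class TestNeighborhoods:
    def test_moore_counts(self):
        assert len(moore_neighbors((5, 5), 1, 20)) == 8
        assert len(moore_neighbors((5, 5), 2, 20)) == 24

    def test_torus_wraparound(self):
        neigh = moore_neighbors((0, 0), 1, 200)
        assert (199, 199) in neigh
        assert len(set(neigh)) == 8

    def test_candidate_parents_normal_mode(self, tiny_layout, lattice_builder):
        occupants = {
            (1, 1): ([0, 0, 0, 0], 3),
            (1, 2): ([1, 1, 1, 1], 5),
            (3, 3): ([0, 1, 0, 1], 2),
        }
        lat = lattice_builder(5, tiny_layout, occupants)
        params = SimParams(N=5, generations=0)
        cands = candidate_parents(lat, (2, 2), params, np.random.default_rng(0))
        assert set(cands) == {(1, 1), (1, 2), (3, 3)}
        assert candidate_parents(lat, (4, 0), params, np.random.default_rng(0)) == []

    def test_candidate_parents_config_field_samples_lattice_wide(
        self, tiny_layout, lattice_builder
    ):
        # fully occupied 20x20 lattice: config-field candidates are 8 distinct
        # sites, regularly beyond the focal Moore neighborhood
        occupants = {
            (x, y): ([0, 0, 0, 0], 0) for x in range(20) for y in range(20)
        }
        lat = lattice_builder(20, tiny_layout, occupants)
        params = SimParams(N=20, config_field=True, generations=0)
        far = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            cands = candidate_parents(lat, (0, 0), params, rng)
            assert len(cands) == len(set(cands)) == 8
            assert (0, 0) not in cands
            cheb = [
                max(min(abs(x - 0), 20 - abs(x - 0)), min(abs(y - 0), 20 - abs(y - 0)))
                for x, y in cands
            ]
            far += sum(d > 1 for d in cheb)
        assert far > 100  # overwhelmingly non-local


class TestFillEmptySite:
    def test_parent_choice_proportional_to_raw_fecundity(
        self, tiny_layout, lattice_builder
    ):
        # two candidates with match counts 2 and 0 at b = 1.2: the fitter
        # parent is chosen with probability 1.44 / 2.44
        target = _stab_target([0, 0])
        occupants = {
            (1, 1): ([0, 0, 0, 0], 1),  # fecundity (0,0) matches -> s=2
            (3, 3): ([1, 0, 1, 0], 1),  # fecundity (1,1) -> s=0
        }
        params = SimParams(
            N=5, L_f=2, L_a=2, reproduction="asexual", p_f=0.0, p_a=0.0, generations=0
        )
        rng = np.random.default_rng(99)
        lat = lattice_builder(5, tiny_layout, occupants, target)
        wins = 0
        n = 5000
        for _ in range(n):
            newborn = fill_empty_site(lat, (2, 2), target, params, rng)
            assert newborn is not None and newborn.age == 0
            if newborn.genome.alleles.sum() == 0:
                wins += 1
            lat.clear_site((2, 2))
        expected = 1.44 / 2.44
        assert abs(wins / n - expected) < 4 * np.sqrt(expected * (1 - expected) / n)

    def test_sexual_needs_two_candidates(self, tiny_layout, lattice_builder):
        target = _stab_target([0, 0])
        lat = lattice_builder(5, tiny_layout, {(1, 1): ([0, 0, 0, 0], 1)}, target)
        params = SimParams(N=5, L_f=2, L_a=2, generations=0)
        out = fill_empty_site(lat, (2, 2), target, params, np.random.default_rng(0))
        assert out is None
        assert not lat.is_occupied((2, 2))

    def test_asexual_without_mutation_clones_parent(self, tiny_layout, lattice_builder):
        target = _stab_target([0, 0])
        alleles = [1, 0, 1, 1]
        lat = lattice_builder(5, tiny_layout, {(1, 1): (alleles, 4, 1)}, target)
        params = SimParams(
            N=5, L_f=2, L_a=2, reproduction="asexual", p_f=0.0, p_a=0.0, generations=0
        )
        newborn = fill_empty_site(lat, (2, 2), target, params, np.random.default_rng(0))
        assert list(newborn.genome.alleles) == alleles
        assert newborn.age == 0
        assert lat.tag[2, 2] == 1  # lineage tag inherited from the parent

    def test_occupied_site_rejected(self, tiny_layout, lattice_builder):
        target = _stab_target([0, 0])
        lat = lattice_builder(5, tiny_layout, {(2, 2): ([0, 0, 0, 0], 0)}, target)
        params = SimParams(N=5, L_f=2, L_a=2, generations=0)
        with pytest.raises(ValueError):
            fill_empty_site(lat, (2, 2), target, params, np.random.default_rng(0))


class TestDiffusion:
    def test_d_zero_never_swaps(self, tiny_layout, lattice_builder):
        lat = lattice_builder(4, tiny_layout, {(0, 0): ([1, 1, 1, 1], 7)})
        before = lat.copy()
        rng = np.random.default_rng(5)
        for _ in range(100):
            assert not diffusion_step(lat, 0.0, rng)
        assert np.array_equal(before.occupied, lat.occupied)
        assert np.array_equal(before.age, lat.age)

    def test_d_one_swaps_and_conserves_contents(self, tiny_layout, lattice_builder):
        lat = lattice_builder(
            4, tiny_layout, {(0, 0): ([1, 1, 1, 1], 7), (2, 2): ([0, 1, 0, 1], 3)}
        )
        rng = np.random.default_rng(5)
        for _ in range(50):
            assert diffusion_step(lat, 1.0, rng)
        assert lat.population == 2
        ages = sorted(lat.age[lat.occupied == 1])
        assert ages == [3, 7]

    def test_kernel_swap_counts_calibrate_to_2D_moves_per_site(self, rng):
        # D = 0.5 -> 2 * 0.5 = 1 lattice step per site per generation;
        # D = 1 and D = 2 perform exactly 1 and 2 swaps per elementary update
        params = SimParams(N=16, generations=40, D=0.5, seed=11)
        result = run(params)
        nn = 16 * 16
        moves_per_site = 2.0 * result.metrics["swaps"].mean() / nn
        assert abs(moves_per_site - 1.0) < 0.05
        for D, exact in ((1.0, nn), (2.0, 2 * nn)):
            res = run(SimParams(N=16, generations=5, D=D, seed=12))
            assert (res.metrics["swaps"] == exact).all()


class TestElementaryUpdateAndGeneration:
    def test_update_changes_at_most_one_site(self, rng):
        params = SimParams(N=6, generations=0, seed=4)
        lat, target = initialize(params, rng)
        for _ in range(300):
            before = lat.occupied.copy()
            elementary_update(lat, target, params, rng)
            assert int(np.abs(lat.occupied.astype(int) - before.astype(int)).sum()) <= 1

    def test_python_generation_increments_survivor_ages(self, rng):
        params = SimParams(N=5, generations=0, p_f=0.0, p_a=0.0, seed=4)
        lat, target = initialize(params, rng)
        before_age = lat.age.copy()
        before_occ = lat.occupied.copy()
        run_generation(lat, target, params, 1, rng)
        survivors = (before_occ == 1) & (lat.occupied == 1) & (lat.age > 0)
        # survivors never drawn for death kept their age + 1; newborns reset
        assert lat.population <= 25
        assert np.all(lat.age[lat.occupied == 1] >= 1)
        assert np.all(lat.age[survivors] <= before_age[survivors] + 1)

    def test_kernel_single_occupant_survival_matches_closed_form(self, tiny_layout):
        # a lone occupant on 3x3 (sexual: no births possible) with alpha = 0
        # survives one generation with probability (1 - delta0/9)^9
        delta0 = 0.3
        params = SimParams(
            N=3, L_f=2, L_a=2, delta0=delta0, generations=0, seed=0
        )
        target = _stab_target([0, 0])
        survived = 0
        n = 2000
        from senesim.lattice import Lattice

        for s in range(n):
            lat = Lattice.empty(3, tiny_layout)
            lat.occupied[1, 1] = 1
            lat.refresh_caches(target)
            metrics, _ = advance(lat, target, params, 1, t0=0, kernel_seed=1000 + s)
            survived += int(lat.population)
        expected = (1 - delta0 / 9) ** 9
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(survived / n - expected) < 4 * se


class TestRunContract:
    def test_same_seed_bit_identical_metrics(self):
        params = SimParams(N=8, generations=30, seed=42)
        a = run(params).metrics
        b = run(params).metrics
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = run(SimParams(N=8, generations=30, seed=1)).metrics
        b = run(SimParams(N=8, generations=30, seed=2)).metrics
        assert not a["mean_age"].equals(b["mean_age"])

    def test_population_bounded_and_occupancy_high(self):
        res = run(SimParams(N=16, generations=50, seed=3))
        assert (res.metrics["occupancy"] <= 1.0).all()
        assert res.metrics["occupancy"].iloc[-1] > 0.99

    def test_aging_cannot_arise_without_senescence_mutation(self):
        # p_a = 0 with the all-zero senescence start: alpha stays 0 forever
        res = run(SimParams(N=12, generations=60, p_a=0.0, seed=6))
        assert (res.metrics["mean_alpha"] == 0.0).all()

    def test_kernel_crossover_point_uniform(self, tiny_layout):
        # center site of a 3x3 ring of complementary parents (equal weights):
        # offspring ones-count from a mixed pair is uniform on {1, 2, 3}
        from senesim.lattice import Lattice

        target = _stab_target([0, 1])  # both genome types match s = 1
        params = SimParams(
            N=3, L_f=2, L_a=2, delta0=1e-6, p_f=0.0, p_a=0.0, generations=0
        )
        counts = np.zeros(5, dtype=int)
        for s in range(4000):
            lat = Lattice.empty(3, tiny_layout)
            lat.occupied[:] = 1
            lat.occupied[1, 1] = 0
            ring = [(x, y) for x in range(3) for y in range(3) if (x, y) != (1, 1)]
            for i, site in enumerate(ring):
                lat.genomes[site] = 0 if i % 2 == 0 else 1
            lat.refresh_caches(target)
            advance(lat, target, params, 1, t0=0, kernel_seed=50_000 + s)
            if lat.occupied[1, 1]:
                counts[int(lat.genomes[1, 1].sum())] += 1
                assert lat.age[1, 1] == 1  # newborn censused after age update
        # mixed pairs can never produce 0 or 4 ones (one gene from each side)
        mixed = counts[1:4]
        assert mixed.sum() > 1000
        _, p = stats.chisquare(mixed)
        assert p > 1e-3
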