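import itertools

import numpy as np
import pytest

from epinet.modularity import (
    ModulePartition, all_participation_coefficients, barber_modularity,
    optimize_modules, participation_coefficient,
)
from epinet.synthetic_networks import GeneratorConfig, gen_modular, planted_modules

from conftest import barber_q_oracle, random_count_matrix


def two_block_matrix():
    w = np.zeros((4, 4))
    w[:2, :2] = 1.0
    w[2:, 2:] = 1.0
    return w


def partitions_match(planted_r, planted_c, found_r, found_c) -> bool:
    """Planted and found partitions identical up to module relabelling."""
    mapping = {}
    for a, b in zip([*planted_r, *planted_c], [*found_r, *found_c]):
        if mapping.setdefault(a, b) != b:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestBarberModularity:
    def test_single_module_is_zero(self, rng):
        w = random_count_matrix(rng, (5, 6), high=4)
        part = ModulePartition((0,) * 5, (0,) * 6)
        assert barber_modularity(w, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_block_diagonal_is_half(self):
        part = ModulePartition((0, 0, 1, 1), (0, 0, 1, 1))
        assert barber_modularity(two_block_matrix(), part) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_cell_by_cell_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = random_count_matrix(rng, (6, 6), high=5)
        rm = rng.integers(0, 3, size=6)
        cm = rng.integers(0, 3, size=6)
        rm[0], cm[0] = 0, 1  # make ids 0..2 present
        rm[1], cm[1] = 2, 2
        part = ModulePartition(tuple(int(x) for x in rm), tuple(int(x) for x in cm))
        assert barber_modularity(w, part) == pytest.approx(
            barber_q_oracle(w, rm, cm), abs=1e-12)

    def test_partition_must_cover_matrix(self):
        with pytest.raises(ValueError, match="cover"):
            barber_modularity(np.ones((3, 3)), ModulePartition((0, 1), (0, 1, 1)))


class TestOptimizeModules:
    def test_two_block_recovery_matches_exhaustive_search(self):
        w = two_block_matrix()
        best_q = -np.inf
        for rm in itertools.product(range(4), repeat=4):
            for cm in itertools.product(range(4), repeat=4):
                q = barber_q_oracle(w, rm, cm)
                best_q = max(best_q, q)
        res = optimize_modules(w, n_restarts=10, seed=0)
        assert best_q == pytest.approx(0.5)
        assert res.Q == pytest.approx(best_q)
        assert partitions_match((0, 0, 1, 1), (0, 0, 1, 1),
                                res.partition.row_modules,
                                res.partition.col_modules)

    def test_reported_q_equals_recomputation_from_partition(self, rng):
        w = random_count_matrix(rng, (6, 7), high=4)
        res = optimize_modules(w, n_restarts=3, seed=11)
        assert res.Q == barber_modularity(w, res.partition)
        assert res.Q >= -1e-12  # never worse than the single-module split

    def test_deterministic_given_seed(self, rng):
        w = random_count_matrix(rng, (6, 6), high=4)
        a = optimize_modules(w, n_restarts=3, seed=7)
        b = optimize_modules(w, n_restarts=3, seed=7)
        assert a.Q == b.Q and a.partition == b.partition

    @pytest.mark.parametrize("n_modules", [2, 3])
    def test_planted_partition_recovery_rate(self, n_modules):
        hits = 0
        n_runs = 40
        for s in range(n_runs):
            cfg = GeneratorConfig(
                n_rows=6, n_cols=6, total_interactions=300, regime="modular",
                n_modules=n_modules, within_between_ratio=8.0, seed=s)
            net = gen_modular(cfg)
            res = optimize_modules(net, n_restarts=5, seed=s)
            rm, cm = planted_modules(cfg)
            hits += partitions_match(rm, cm, res.partition.row_modules,
                                     res.partition.col_modules)
        assert hits >= int(0.95 * n_runs) - 1

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            optimize_modules(np.ones((1, 5)))


class TestParticipationCoefficient:
    @pytest.mark.parametrize("strengths,modules,expected", [
        ([4, 0, 0, 0], [0, 1, 2, 3], 0.0),          # all within one module
        ([2, 2, 0, 0], [0, 1, 2, 3], 0.5),          # even 2-way split
        ([1, 1, 1, 1], [0, 1, 2, 3], 0.75),         # even 4-way split
    ])
    def test_canonical_splits(self, strengths, modules, expected):
        w = np.vstack([strengths, np.ones(4)])
        part = ModulePartition((0, 0), tuple(modules))
        role = participation_coefficient(w, part, 0, "row")
        assert role.c_value == pytest.approx(expected)

    def test_zero_strength_species_rejected(self):
        part = ModulePartition((0, 0), (0, 1))
        with pytest.raises(ValueError, match="no interactions"):
            participation_coefficient(np.array([[0, 0], [1, 2]]), part, 0, "row")

    def test_mean_c_tracks_between_module_mixing(self):
        # stronger between-module weight -> higher among-module connectivity
        ladder = []
        for ratio in (10.0, 3.0, 1.0):
            cs = []
            for s in range(10):
                cfg = GeneratorConfig(
                    n_rows=6, n_cols=6, total_interactions=400,
                    regime="modular", n_modules=3,
                    within_between_ratio=ratio, seed=100 + s)
                net = gen_modular(cfg)
                rm, cm = planted_modules(cfg)
                part = ModulePartition(tuple(int(x) for x in rm),
                                       tuple(int(x) for x in cm))
                cs.extend(r.c_value
                          for r in all_participation_coefficients(net, part))
            ladder.append(np.mean(cs))
        assert ladder[0] < ladder[1] < ladder[2]

    def test_strong_modules_give_low_mean_c(self):
        # with 3 planted modules the per-cell within:between ratio R gives
        # expected c ~= 1 - (R/(R+2))^2 - 2/(R+2)^2; R = 30 puts it near 0.12
        means = []
        for s in range(10):
            cfg = GeneratorConfig(
                n_rows=6, n_cols=6, total_interactions=400, regime="modular",
                n_modules=3, within_between_ratio=30.0, seed=s)
            net = gen_modular(cfg)
            res = optimize_modules(net, n_restarts=3, seed=s)
            roles = all_participation_coefficients(net, res.partition)
            means.append(np.mean([r.c_value for r in roles]))
        assert np.mean(means) < 0.2
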