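"""Monte-Carlo percolation simulator: topology, traversal, sweeps, power laws."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import oracle_cluster, sample_discrete_power_law
from seqspace.simulate import (
    SpaceConfig,
    attempts_until_connected,
    cluster_from_start,
    cluster_size_distribution,
    connect_to_target,
    decode,
    encode,
    fit_power_law_tau,
    functional,
    functional_index,
    large_cluster_fraction,
    neighbor_indices,
    neighbors,
    sweep_transition,
    uniform_deviates,
)


class TestConfig:
    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            SpaceConfig(L=1, A=7, p_fs=0.1, seed=0)
        with pytest.raises(ValueError):
            SpaceConfig(L=5, A=1, p_fs=0.1, seed=0)
        with pytest.raises(ValueError):
            SpaceConfig(L=5, A=4, p_fs=1.5, seed=0)
        with pytest.raises(ValueError):
            SpaceConfig(L=5, A=7, p_fs=0.1, seed=0, A_t=7)

    def test_odd_restricted_degree_on_odd_alphabet_rejected(self):
        with pytest.raises(ValueError):
            SpaceConfig(L=5, A=7, p_fs=0.1, seed=0, A_t=3)

    def test_encode_decode_roundtrip(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 7, (100, 10))
        assert np.array_equal(decode(encode(codes, 7), 10, 7), codes)


class TestNeighbors:
    def test_full_rule_count(self):
        cfg = SpaceConfig(L=10, A=7, p_fs=0.1, seed=0)
        assert neighbors(cfg, [0] * 10).shape == (60, 10)

    def test_restricted_rule_count(self):
        cfg = SpaceConfig(L=10, A=7, p_fs=0.1, seed=0, A_t=2)
        assert neighbors(cfg, [3] * 10).shape == (20, 10)

    @pytest.mark.parametrize("A_t", [None, 2, 4])
    def test_symmetry(self, A_t):
        cfg = SpaceConfig(L=6, A=7, p_fs=0.1, seed=0, A_t=A_t)
        rng = np.random.default_rng(1)
        for _ in range(100):
            seq = rng.integers(0, 7, 6)
            nbrs = neighbors(cfg, seq)
            pick = nbrs[rng.integers(0, len(nbrs))]
            assert any((neighbors(cfg, pick) == seq).all(axis=1))

    def test_exact_degree_everywhere(self):
        """Substitution space has no boundaries: degree is L*A_t for all."""
        cfg = SpaceConfig(L=4, A=5, p_fs=0.1, seed=0, A_t=2)
        idx = np.arange(cfg.size)
        nbrs = neighbor_indices(cfg, idx)
        assert nbrs.shape == (cfg.size, 8)
        # each row contains distinct sequences, none equal to itself
        for i in (0, 17, 311, cfg.size - 1):
            row = nbrs[i]
            assert len(set(row.tolist())) == 8
            assert i not in row


class TestFunctional:
    def test_p_zero_and_one(self):
        cfg0 = SpaceConfig(L=4, A=4, p_fs=0.0, seed=3)
        cfg1 = SpaceConfig(L=4, A=4, p_fs=1.0, seed=3)
        assert not functional(cfg0, [1, 2, 3, 0])
        assert functional(cfg1, [1, 2, 3, 0])
        # forced start is functional even at p_fs = 0
        assert functional(cfg0, [0, 0, 0, 0])

    def test_deterministic_given_seed(self):
        cfg = SpaceConfig(L=10, A=7, p_fs=0.02, seed=11)
        idx = np.random.default_rng(0).integers(0, cfg.size, 1000)
        a = functional_index(cfg, idx)
        b = functional_index(replace(cfg, seed=11), idx)
        assert np.array_equal(a, b)
        c = functional_index(replace(cfg, seed=12), idx)
        assert not np.array_equal(a, c)

    def test_empirical_fraction_matches_p_fs(self):
        cfg = SpaceConfig(
            L=10, A=7, p_fs=0.02, seed=5, force_start_functional=False
        )
        idx = np.random.default_rng(2).integers(0, cfg.size, 100_000)
        frac = functional_index(cfg, idx).mean()
        tol = 4 * np.sqrt(0.02 * 0.98 / 100_000)
        assert abs(frac - 0.02) < tol

    def test_deviates_are_uniform(self):
        cfg = SpaceConfig(L=10, A=7, p_fs=0.5, seed=9)
        u = uniform_deviates(cfg, np.arange(50_000))
        # coarse uniformity: decile occupancy within 5 sigma
        counts, _ = np.histogram(u, bins=10, range=(0, 1))
        assert np.all(np.abs(counts - 5000) < 5 * np.sqrt(5000 * 0.9))


class TestClusterSearch:
    def test_isolated_start(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=0.0, seed=0)
        out = cluster_from_start(cfg)
        assert out.size == 1 and not out.capped and not out.is_large

    def test_cap_truncates_and_flags(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=1.0, seed=0)
        out = cluster_from_start(cfg, cap=10)
        assert out.size == 10 and out.capped and out.is_large

    def test_full_space_cluster(self):
        cfg = SpaceConfig(L=3, A=3, p_fs=1.0, seed=0)
        out = cluster_from_start(cfg, cap=None)
        assert out.size == 27

    @pytest.mark.parametrize(
        "L, A, n_seeds", [(3, 3, 40), (4, 4, 30), (5, 4, 20), (4, 10, 10)]
    )
    def test_oracle_equivalence(self, L, A, n_seeds):
        """BFS cluster equals networkx connected component, exhaustively."""
        rng = np.random.default_rng(L * 100 + A)
        for _ in range(n_seeds):
            seed = int(rng.integers(0, 2**31))
            p = float(rng.uniform(0.05, 0.9))
            cfg = SpaceConfig(L=L, A=A, p_fs=p, seed=seed)
            comp = oracle_cluster(cfg)
            out = cluster_from_start(cfg, cap=None)
            assert out.size == len(comp)

    def test_determinism_across_runs(self):
        cfg = SpaceConfig(L=10, A=7, p_fs=0.019, seed=1234)
        a = cluster_from_start(cfg)
        b = cluster_from_start(cfg)
        assert a == b

    def test_monotone_coupling_exact(self):
        """Shared uniforms: the functional set only grows with P_fs."""
        base = SpaceConfig(L=5, A=5, p_fs=0.1, seed=21)
        idx = np.arange(base.size)
        lo = functional_index(base, idx)
        hi = functional_index(replace(base, p_fs=0.35), idx)
        assert np.all(hi[lo])  # lo set is a subset of hi set
        # hence per-seed cluster size is non-decreasing
        s_lo = cluster_from_start(base, cap=None).size
        s_hi = cluster_from_start(replace(base, p_fs=0.35), cap=None).size
        assert s_hi >= s_lo


class TestConnectivity:
    def test_tolerance_covering_whole_space(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=0.0, seed=0)
        assert connect_to_target(cfg, tol=4)

    def test_fully_functional_space_connects(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=1.0, seed=0)
        assert connect_to_target(cfg, tol=0)

    def test_oracle_equivalence_small_space(self):
        """Path existence agrees with the explicit-graph oracle."""
        import networkx as nx

        from conftest import explicit_graph

        rng = np.random.default_rng(33)
        for _ in range(40):
            cfg = SpaceConfig(
                L=3, A=3, p_fs=float(rng.uniform(0.2, 0.8)),
                seed=int(rng.integers(0, 2**31)),
            )
            graph, func = explicit_graph(cfg)
            got = connect_to_target(cfg, tol=1)
            target_codes = decode(np.array([cfg.target_index]), 3, 3)[0]
            in_ball = [
                i
                for i in graph.nodes
                if (decode(np.array([i]), 3, 3)[0] != target_codes).sum() <= 1
            ]
            expected = func[cfg.start_index] and any(
                nx.has_path(graph, cfg.start_index, j) for j in in_ball
            )
            assert got == bool(expected)

    def test_attempts_immediate_at_full_occupancy(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=1.0, seed=0)
        out = attempts_until_connected(cfg, tol=0)
        assert out.attempts == 1 and out.success

    def test_attempts_exhausts_at_zero_occupancy(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=0.0, seed=0)
        out = attempts_until_connected(cfg, tol=0, max_attempts=50)
        assert out.attempts == 50 and not out.success


class TestSweep:
    def test_unsorted_grid_rejected(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=0.1, seed=0)
        with pytest.raises(ValueError):
            sweep_transition(cfg, [0.2, 0.1], reps=10)

    def test_all_zero_grid_has_no_transition(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=0.0, seed=0)
        res = sweep_transition(cfg, [0.0, 0.0], reps=10, cap=50)
        assert res.critical_p_fs is None
        assert res.large_fraction == (0.0, 0.0)

    def test_fraction_and_size_monotone_in_p_fs(self):
        """Monotone coupling forces per-seed monotone statistics."""
        cfg = SpaceConfig(L=5, A=5, p_fs=0.1, seed=4)
        res = sweep_transition(
            cfg, [0.05, 0.15, 0.25, 0.35], reps=25, cap=500
        )
        assert list(res.large_fraction) == sorted(res.large_fraction)
        assert list(res.mean_size) == sorted(res.mean_size)


class TestSizeDistribution:
    def test_zero_occupancy_gives_singletons(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=0.0, seed=0)
        sizes, capped = cluster_size_distribution(cfg, reps=10, cap=100)
        assert np.all(sizes == 1) and not capped.any()

    def test_zero_reps_rejected(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=0.0, seed=0)
        with pytest.raises(ValueError):
            cluster_size_distribution(cfg, reps=0)

    def test_matches_oracle_per_seed(self):
        base = SpaceConfig(L=3, A=3, p_fs=0.55, seed=99)
        sizes, capped = cluster_size_distribution(base, reps=15, cap=10_000)
        from seqspace.simulate import _spawned_seed

        for r in range(15):
            cfg = replace(base, seed=_spawned_seed(base.seed, r))
            assert sizes[r] == len(oracle_cluster(cfg))
        assert not capped.any()


class TestPowerLawFit:
    @pytest.mark.parametrize("tau, band", [(2.0, (1.9, 2.1)), (3.0, (2.85, 3.15))])
    def test_recovery_from_synthetic_samples(self, tau, band):
        rng = np.random.default_rng(17)
        sizes = sample_discrete_power_law(tau, 10_000, s_min=5, rng=rng)
        fit = fit_power_law_tau(sizes, s_min=5)
        assert band[0] <= fit.tau <= band[1]

    def test_identical_sizes_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law_tau([7] * 100, s_min=1)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law_tau([5, 6, 7], s_min=1)


class TestLargeClusterFraction:
    def test_zero_occupancy(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=0.0, seed=0)
        assert large_cluster_fraction(cfg, reps=5, cap=10) == 0.0

    def test_full_occupancy_space_beyond_cap(self):
        cfg = SpaceConfig(L=4, A=4, p_fs=1.0, seed=0)
        assert large_cluster_fraction(cfg, reps=5, cap=100) == 1.0
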