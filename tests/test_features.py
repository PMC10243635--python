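"""Cheeger mixing index, entry/exit probabilities, heterogeneity, ranking."""

import numpy as np
import pytest

from diffwalk import (
    CommunityPartition,
    cheeger_index,
    entry_probability,
    exit_probability,
    heterogeneity,
    make_time_grid,
    mean_cheeger,
    rank_communities,
    scan_steps,
    spectral_decomposition,
    transition_matrix,
)
from diffwalk.features import TimeGrid, community_features, entry_exit_profiles


def part_of(labels, k):
    return CommunityPartition(labels=np.asarray(labels), k=k, t_embed=0)


class TestCheeger:
    def test_p4_halves(self, p4):
        p = part_of([0, 0, 1, 1], 2)
        assert cheeger_index(p4, p, 0) == pytest.approx(1 / 3)
        assert mean_cheeger(p4, p) == pytest.approx(1 / 3)

    def test_p4_singleton(self, p4):
        p = part_of([0, 1, 1, 1], 2)
        assert cheeger_index(p4, p, 0) == pytest.approx(1.0)

    def test_k4_halves(self, k4):
        p = part_of([0, 0, 1, 1], 2)
        assert cheeger_index(k4, p, 0) == pytest.approx(2 / 3)
        assert mean_cheeger(k4, p) == pytest.approx(2 / 3)

    def test_mean_is_mean_of_members(self, random_graph_factory):
        g = random_graph_factory(30, 4.0, seed=3)
        labels = np.arange(30) % 3
        p = part_of(labels, 3)
        vals = [cheeger_index(g, p, c) for c in range(3)]
        assert mean_cheeger(g, p) == pytest.approx(np.mean(vals))

    def test_whole_graph_community_errors(self, p4):
        with pytest.raises(ValueError):
            cheeger_index(p4, part_of([0, 0, 0, 0], 1), 0)
        with pytest.raises(ValueError, match="2 communities"):
            mean_cheeger(p4, part_of([0, 0, 0, 0], 1))


class TestEntryExit:
    def test_k4_singleton_one_step(self, k4):
        m = spectral_decomposition(k4, 4)
        p = part_of([0, 1, 1, 1], 2)
        assert entry_probability(m, p, 0, 1) == pytest.approx(1 / 3, abs=1e-10)
        assert exit_probability(m, p, 0, 1) == pytest.approx(1 / 3, abs=1e-10)

    def test_lollipop_stationary_limits(self, lollipop):
        m = spectral_decomposition(lollipop, 4)
        p = part_of([1, 1, 1, 0], 2)  # community 0 = pendant node 3
        assert entry_probability(m, p, 0, 10**6) == pytest.approx(1 / 8, abs=1e-9)
        assert exit_probability(m, p, 0, 10**6) == pytest.approx(7 / 24, abs=1e-9)

    def test_dense_oracle(self, random_graph_factory):
        g = random_graph_factory(50, 4.0, seed=4)
        m = spectral_decomposition(g, 50)
        labels = np.arange(50) % 4
        p = part_of(labels, 4)
        t_pow = np.linalg.matrix_power(transition_matrix(g).T.toarray(), 6)
        for c in range(4):
            in_c = labels == c
            direct_in = t_pow[np.ix_(~in_c, in_c)].sum() / (in_c.sum() * (~in_c).sum())
            direct_out = t_pow[np.ix_(in_c, ~in_c)].sum() / (in_c.sum() * (~in_c).sum())
            assert entry_probability(m, p, c, 6) == pytest.approx(direct_in, abs=1e-8)
            assert exit_probability(m, p, c, 6) == pytest.approx(direct_out, abs=1e-8)

    def test_regular_graph_symmetry(self, k4):
        # on a d-regular graph psi_k phi_k products are symmetric in the pair
        m = spectral_decomposition(k4, 4)
        p = part_of([0, 0, 1, 1], 2)
        for t in (0, 1, 2, 9):
            for c in (0, 1):
                assert entry_probability(m, p, c, t) == pytest.approx(
                    exit_probability(m, p, c, t), abs=1e-12
                )

    def test_whole_graph_community_errors(self, k4):
        m = spectral_decomposition(k4, 4)
        with pytest.raises(ValueError):
            entry_exit_profiles(m, part_of([0, 0, 0, 0], 1), [1])


class TestHeterogeneity:
    def test_symmetric_split_has_zero_sd(self, k4):
        m = spectral_decomposition(k4, 4)
        p = part_of([0, 0, 1, 1], 2)
        grid = TimeGrid(steps=(1, 2, 5), tau_index=0)
        het = heterogeneity(m, p, grid)
        assert het.max_sd_pin == pytest.approx(0.0, abs=1e-12)
        assert het.max_sd_pout == pytest.approx(0.0, abs=1e-12)

    def test_singleton_grid_max_is_that_sd(self, lollipop):
        m = spectral_decomposition(lollipop, 4)
        p = part_of([0, 0, 1, 1], 2)
        grid = TimeGrid(steps=(3,), tau_index=0)
        het = heterogeneity(m, p, grid)
        assert het.max_sd_pin == pytest.approx(het.sd_pin[0])
        p_in, _ = entry_exit_profiles(m, p, [3])
        assert het.sd_pin[0] == pytest.approx(p_in[:, 0].std(ddof=0))


class TestTimeGrid:
    def test_includes_tau_sorted_unique(self):
        grid = make_time_grid(137.4)
        steps = np.array(grid.steps)
        assert 137 in steps
        assert np.all(np.diff(steps) > 0)
        assert steps[0] >= 1 and steps[-1] <= 2 * 137 + 1
        assert grid.steps[grid.tau_index] == 137

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            TimeGrid(steps=(), tau_index=0)
        with pytest.raises(ValueError):
            TimeGrid(steps=(3, 2), tau_index=0)
        with pytest.raises(ValueError):
            TimeGrid(steps=(0, 2), tau_index=0)


class TestRanking:
    def test_lowest_and_highest(self):
        vals = [0.1, 0.5, 0.3]
        assert rank_communities(vals, 1, "lowest").tolist() == [0]
        assert rank_communities(vals, 3, "lowest").tolist() == [0, 2, 1]
        assert rank_communities(vals, 2, "highest").tolist() == [1, 2]

    def test_percentage_mode(self):
        ids, pct = rank_communities([1.0, 2.0, 3.0], 3, "lowest", as_percentage=True)
        assert np.allclose(pct, [50.0, 100.0, 150.0])

    def test_m_too_large_errors(self):
        with pytest.raises(ValueError):
            rank_communities([1.0, 2.0], 3)


class TestScanSteps:
    @pytest.mark.parametrize(
        "residence,speed,edge_length,expected",
        [(720, 13, 10, 935), (720, 10, 10, 720), (0.77, 13, 10, 1)],
    )
    def test_worked_examples(self, residence, speed, edge_length, expected):
        assert scan_steps(residence, speed, edge_length) == expected

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            scan_steps(0, 13, 10)
        with pytest.raises(ValueError):
            scan_steps(720, -1, 10)


class TestFeatureTable:
    def test_columns_and_consistency(self, lollipop):
        m = spectral_decomposition(lollipop, 4)
        p = part_of([0, 0, 1, 1], 2)
        grid = TimeGrid(steps=(1, 4), tau_index=0)
        df = community_features(lollipop, m, p, grid)
        assert list(df.columns) == [
            "community_id", "n_c", "mean_degree", "cheeger",
            "p_in@1", "p_in@4", "p_out@1", "p_out@4",
        ]
        assert df["n_c"].sum() == 4
        assert df.loc[0, "cheeger"] == pytest.approx(cheeger_index(lollipop, p, 0))
        assert df.loc[1, "p_in@4"] == pytest.approx(entry_probability(m, p, 1, 4))
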