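import numpy as np
import pandas as pd
import pytest

from toxicoclust import (
    ClusterAssignment,
    SimulationConfig,
    build_grid,
    generate_fcge,
    logistic_transform,
    rank_and_relabel,
    reorder_matrix,
)


def _assign(labels, codes, axis="gene"):
    codes = np.asarray(codes)
    return ClusterAssignment(list(labels), codes, int(codes.max()), axis)


@pytest.fixture
def random_grid(rng):
    x = pd.DataFrame(
        rng.uniform(size=(8, 6)),
        index=[f"g{i}" for i in range(8)],
        columns=[f"d{j}" for j in range(6)],
    )
    gc = _assign(x.index, [1, 1, 2, 2, 2, 3, 3, 3])
    dcc = _assign(x.columns, [1, 1, 1, 2, 2, 3], "dc")
    return x, build_grid(x, gc, dcc)


class TestBuildGrid:
    def test_constant_matrix_blocks(self):
        x = pd.DataFrame(0.7, index=["a", "b"], columns=["u", "v"])
        grid = build_grid(x, _assign(x.index, [1, 2]), _assign(x.columns, [1, 2], "dc"))
        assert np.allclose(grid.table["mean"], 0.7)
        assert grid.n_blocks == 4

    def test_singleton_clusters_reproduce_cells(self):
        x = pd.DataFrame(
            [[1.0, 0.0], [0.0, 0.0]], index=["a", "b"], columns=["u", "v"]
        )
        grid = build_grid(x, _assign(x.index, [1, 2]), _assign(x.columns, [1, 2], "dc"))
        assert sorted(grid.table["mean"]) == [0.0, 0.0, 0.0, 1.0]
        assert set(grid.table["n_cells"]) == {1}

    def test_label_mismatch_rejected(self, random_grid):
        x, _ = random_grid
        bad = _assign([f"other{i}" for i in range(8)], [1] * 4 + [2] * 4)
        with pytest.raises(ValueError, match="cover the matrix labels"):
            build_grid(x, bad, _assign(x.columns, [1, 1, 1, 2, 2, 2], "dc"))

    def test_block_mean_conservation(self, random_grid):
        """Weighted block means reconstitute the global sum exactly."""
        x, grid = random_grid
        total = (grid.table["mean"] * grid.table["n_cells"]).sum()
        assert total == pytest.approx(x.to_numpy().sum(), abs=1e-9)


class TestRankAndRelabel:
    def test_greedy_forces_descending_diagonal(self):
        x = pd.DataFrame(
            [[0.9, 0.5], [0.5, 0.8]], index=["a", "b"], columns=["u", "v"]
        )
        grid = rank_and_relabel(
            build_grid(x, _assign(x.index, [1, 2]), _assign(x.columns, [1, 2], "dc"))
        )
        assert grid.block(1, 1)["mean"] == pytest.approx(0.9)
        assert grid.block(2, 2)["mean"] == pytest.approx(0.8)
        assert grid.block(1, 1)["rank"] == 1

    def test_maps_are_permutations(self, random_grid):
        _, grid = random_grid
        ranked = rank_and_relabel(grid)
        assert sorted(ranked.gene_map.values()) == list(range(1, 4))
        assert sorted(ranked.dc_map.values()) == list(range(1, 4))

    def test_mean_multiset_unchanged(self, random_grid):
        _, grid = random_grid
        ranked = rank_and_relabel(grid)
        assert sorted(ranked.table["mean"]) == pytest.approx(sorted(grid.table["mean"]))

    def test_diagonal_monotone(self, random_grid):
        _, grid = random_grid
        m = rank_and_relabel(grid).mean_matrix()
        diag = np.diag(m)
        assert np.all(np.diff(diag) <= 1e-12)

    def test_idempotent(self, random_grid):
        _, grid = random_grid
        once = rank_and_relabel(grid)
        twice = rank_and_relabel(once)
        pd.testing.assert_frame_equal(once.table, twice.table)
        assert np.array_equal(once.gene_assign.codes, twice.gene_assign.codes)

    def test_rectangular_grid_appends_leftover_axis(self, rng):
        x = pd.DataFrame(
            rng.uniform(size=(6, 4)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"d{j}" for j in range(4)],
        )
        gc = _assign(x.index, [1, 1, 2, 2, 3, 3])
        dcc = _assign(x.columns, [1, 1, 2, 2], "dc")
        ranked = rank_and_relabel(build_grid(x, gc, dcc))
        assert sorted(ranked.gene_map.values()) == [1, 2, 3]
        assert sorted(ranked.dc_map.values()) == [1, 2]


class TestReorderMatrix:
    def test_round_trip_permutation(self, random_grid):
        x, grid = random_grid
        ranked = rank_and_relabel(grid)
        out = reorder_matrix(x, ranked)
        restored = out.matrix.iloc[np.argsort(out.row_perm), :].iloc[
            :, np.argsort(out.col_perm)
        ]
        pd.testing.assert_frame_equal(restored, x)

    def test_boundaries_partition_axes(self, random_grid):
        x, grid = random_grid
        out = reorder_matrix(x, rank_and_relabel(grid))
        assert out.row_boundaries[-1] == x.shape[0]
        assert out.col_boundaries[-1] == x.shape[1]

    def test_unranked_grid_rejected(self, random_grid):
        x, grid = random_grid
        with pytest.raises(ValueError, match="ranked"):
            reorder_matrix(x, grid)

    def test_shuffled_simulation_recovers_block_structure(self, rng):
        """Reordering a shuffled noise-free matrix restores generator blocks."""
        f, truth = generate_fcge(SimulationConfig(noise_variance=0.0), rng)
        x = logistic_transform(f)
        perm_r = rng.permutation(len(x.index))
        perm_c = rng.permutation(len(x.columns))
        shuffled = x.iloc[perm_r, :].iloc[:, perm_c]
        gc = _assign(
            shuffled.index,
            pd.Series(truth.gene_clusters.codes, index=truth.gene_clusters.labels)[
                shuffled.index
            ],
        )
        dcc = _assign(
            shuffled.columns,
            pd.Series(truth.dc_clusters.codes, index=truth.dc_clusters.labels)[
                shuffled.columns
            ],
            "dc",
        )
        ranked = rank_and_relabel(build_grid(shuffled, gc, dcc))
        out = reorder_matrix(shuffled, ranked)
        vals = out.matrix.to_numpy()
        # within each reordered block every value is constant (noise-free)
        r0 = 0
        for r1 in out.row_boundaries:
            c0 = 0
            for c1 in out.col_boundaries:
                block = vals[r0:r1, c0:c1]
                assert np.allclose(block, block[0, 0])
                c0 = c1
            r0 = r1
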