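import numpy as np
import pandas as pd
import pytest

from multiomesim import (SimulationConfig, builtin_tree,
                         cci_correlation_analysis, example_lr_database,
                         place_new_cell, run_simulation,
                         sample_cci_ground_truth, synthetic_benchmark_grn)
from multiomesim.spatial import SpatialState, _OFFSETS


def _rng(seed=0):
    return np.random.default_rng(seed)


@pytest.fixture(scope="module")
def cci_output():
    cfg = SimulationConfig(n_cell=150, n_gene=120, seed=3, cci_on=True,
                           sigma_cif=0.1)
    grn = synthetic_benchmark_grn(100, 8, 100)
    lr = example_lr_database(120, grn)
    return run_simulation(cfg, tree=builtin_tree("phyla3"), grn=grn,
                          lr_database=lr)


class TestPlacement:
    def test_forced_adjacency_at_pn_one(self):
        state = SpatialState(side=10, n_nbs=4)
        place_new_cell(state, "A", 1.0, _rng(1))
        place_new_cell(state, "A", 1.0, _rng(2))
        (x0, y0), (x1, y1) = state.coords
        assert abs(x0 - x1) + abs(y0 - y1) == 1

    def test_neighbor_slots_are_reciprocal(self):
        state = SpatialState(side=6, n_nbs=4)
        for i in range(12):
            place_new_cell(state, "A", 1.0, _rng(i))
        for c, nbrs in enumerate(state.neighbors):
            for slot, j in nbrs.items():
                assert c in state.neighbors[j].values()

    def test_full_grid_errors(self):
        state = SpatialState(side=2, n_nbs=4)
        for i in range(4):
            place_new_cell(state, "A", 0.5, _rng(i))
        with pytest.raises(RuntimeError):
            place_new_cell(state, "A", 0.5, _rng(9))

    def test_same_type_clustering_stronger_at_high_pn(self):
        def same_type_adjacency(p_n, seed):
            rng = _rng(seed)
            state = SpatialState(side=25, n_nbs=4)
            types = ["A", "B", "C", "D"] * 75
            for t in types:
                place_new_cell(state, t, p_n, rng)
            same = total = 0
            for c, pos in enumerate(state.coords):
                for dx, dy in _OFFSETS:
                    j = state.grid.get((pos[0] + dx, pos[1] + dy))
                    if j is not None:
                        total += 1
                        same += state.types[c] == state.types[j]
            return same / total

        high = np.mean([same_type_adjacency(1.0, s) for s in (1, 2)])
        low = np.mean([same_type_adjacency(0.5, s) for s in (1, 2)])
        assert high > low


class TestCciGroundTruth:
    def _db(self, m=10):
        return pd.DataFrame({"ligand": range(100, 100 + m),
                             "receptor": range(m),
                             "effect": np.ones(m)})

    def test_subset_sizes_in_range(self):
        gt = sample_cci_ground_truth(self._db(), ["A", "B", "C"], _rng(4),
                                     per_pair_count_range=(3, 6))
        assert set(gt) == {("A", "B"), ("A", "C"), ("B", "C")}
        for rows in gt.values():
            assert 3 <= len(rows) <= 6
            assert len(set(rows.tolist())) == len(rows)

    def test_single_row_database(self):
        gt = sample_cci_ground_truth(self._db(1), ["A", "B"], _rng(5),
                                     per_pair_count_range=(1, 1))
        assert gt[("A", "B")].tolist() == [0]

    def test_range_exceeding_database_errors(self):
        with pytest.raises(ValueError):
            sample_cci_ground_truth(self._db(2), ["A", "B"], _rng(6),
                                    per_pair_count_range=(3, 6))

    def test_same_type_pairs_excluded_by_default(self):
        gt = sample_cci_ground_truth(self._db(), ["A", "B"], _rng(7))
        assert ("A", "A") not in gt and ("B", "B") not in gt


class TestSpatialSimulation:
    def test_locations_on_grid_and_unique(self, cci_output):
        loc = cci_output.locations
        assert len(loc) == 150
        assert not loc.duplicated(subset=["x", "y"]).any()

    def test_pair_ground_truth_subset_of_type_level(self, cci_output):
        type_rows = set(map(tuple, cci_output.ctype_cci[
            ["type_a", "type_b", "ligand", "receptor"]].to_numpy()))
        types = dict(zip(range(len(cci_output.locations)),
                         cci_output.locations["type_label"]))
        for _, r in cci_output.pair_cci.iterrows():
            a, b = sorted([types[r["cell_i"]], types[r["cell_j"]]])
            assert (a, b, r["ligand"], r["receptor"]) in type_rows

    def test_cci_pairs_are_grid_neighbors(self, cci_output):
        coords = {i: (x, y) for i, (x, y) in enumerate(
            zip(cci_output.locations["x"], cci_output.locations["y"]))}
        for _, r in cci_output.pair_cci.iterrows():
            (xi, yi), (xj, yj) = coords[r["cell_i"]], coords[r["cell_j"]]
            assert abs(xi - xj) + abs(yi - yj) == 1

    def test_neighbor_count_capped(self, cci_output):
        pair_counts = cci_output.pair_cci.groupby("cell_i")["cell_j"] \
            .nunique()
        assert pair_counts.max() <= 4

    def test_development_stages_span_tree(self, cci_output):
        pt = cci_output.pseudotime
        depth = builtin_tree("phyla3").max_depth
        assert pt.min() < 0.2 * depth
        assert pt.max() > 0.8 * depth

    def test_determinism(self):
        cfg = SimulationConfig(n_cell=60, n_gene=60, seed=5, cci_on=True)
        grn = synthetic_benchmark_grn(50, 5, 40)
        lr = example_lr_database(60, grn)
        a = run_simulation(cfg, tree=builtin_tree("phyla3"), grn=grn,
                           lr_database=lr)
        b = run_simulation(cfg, tree=builtin_tree("phyla3"), grn=grn,
                           lr_database=lr)
        assert np.array_equal(a.counts_true, b.counts_true)
        assert a.locations.equals(b.locations)
        assert a.pair_cci.equals(b.pair_cci)

    def test_requires_lr_database(self):
        cfg = SimulationConfig(n_cell=20, n_gene=20, seed=1, cci_on=True)
        with pytest.raises(ValueError):
            run_simulation(cfg, tree=builtin_tree("phyla3"))


class TestCciCorrelation:
    def test_groups_returned(self, cci_output):
        res = cci_correlation_analysis(cci_output)
        assert set(res) == {"neighbor_cci", "neighbor_no_cci",
                            "non_neighbor"}

    def test_shuffled_labels_break_coupling(self, cci_output):
        rng = _rng(8)
        vals = []
        for _ in range(4):
            shuffled = cci_output.counts_true[
                rng.permutation(len(cci_output.counts_true))]
            res = cci_correlation_analysis(cci_output, counts=shuffled)
            vals.append(res["neighbor_cci"])
        assert abs(np.mean(vals)) < 0.05

    def test_cci_neighbors_exceed_non_neighbors(self, cci_output):
        res = cci_correlation_analysis(cci_output)
        assert res["neighbor_cci"] > res["non_neighbor"]
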