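import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiomesim import (GrnSpec, build_diff_giv_with_grn,
                         build_effect_matrix, build_giv,
                         evolve_cell_specific_grn, sample_sparse_gaussian,
                         update_tf_cif)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSparseGaussian:
    def test_all_zero_at_p1(self):
        assert np.all(sample_sparse_gaussian(20, 20, 1.0, 0, 1,
                                             _rng()) == 0)

    def test_constant_at_p0_sd0(self):
        m = sample_sparse_gaussian(20, 20, 0.0, 3.5, 0.0, _rng())
        assert np.all(m == 3.5)

    def test_zero_fraction_binomial_ci(self):
        m = sample_sparse_gaussian(100, 100, 0.5, 0, 1, _rng(1))
        # 3-sigma binomial CI at n = 1e4: 0.5 +- 0.015
        assert abs(np.mean(m == 0) - 0.5) < 0.015

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            sample_sparse_gaussian(2, 2, 0.5, 0, -1, _rng())

    @settings(max_examples=20, deadline=None)
    @given(p0=st.floats(0, 1), seed=st.integers(0, 1000))
    def test_zero_probability_bounds(self, p0, seed):
        m = sample_sparse_gaussian(30, 30, p0, 1.0, 0.5, _rng(seed))
        zf = np.mean(m == 0)
        assert 0 <= zf <= 1
        if p0 == 0:
            assert zf == 0


class TestEffectMatrix:
    def test_empty_grn(self):
        assert build_effect_matrix(None, 5).shape == (5, 0)

    def test_single_edge_placement(self):
        grn = GrnSpec([(0, 5, 2.0)])
        eff = build_effect_matrix(grn, 10)
        assert eff[5, 0] == 2.0
        assert np.count_nonzero(eff) == 1

    def test_nonzero_count_equals_edge_count(self, grn100):
        eff = build_effect_matrix(grn100, 100)
        assert np.count_nonzero(eff) == len(grn100.edges)

    def test_out_of_range_gene_rejected(self):
        with pytest.raises(ValueError):
            build_effect_matrix(GrnSpec([(0, 50, 1.0)]), 10)

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError):
            GrnSpec([(0, 1, 1.0), (0, 1, 2.0)])


class TestTfCif:
    def test_equal_expression_gives_half(self):
        assert np.allclose(update_tf_cif(np.array([3.0, 3.0, 3.0])), 0.5)

    def test_hand_computed_two_tf_case(self):
        out = update_tf_cif(np.array([4.0, 0.0]))
        assert out == pytest.approx([2 / 3, 0.0])

    def test_silent_tf_is_zero(self):
        out = update_tf_cif(np.array([0.0, 5.0, 2.0]))
        assert out[0] == 0.0

    def test_all_silent_defined_as_zero(self):
        assert np.all(update_tf_cif(np.zeros(4)) == 0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1e4), min_size=1, max_size=8))
    def test_values_in_unit_interval(self, xs):
        out = update_tf_cif(np.array(xs))
        assert np.all((out >= 0) & (out < 1))


class TestDiffGivWithGrn:
    def test_identity_effect_copies_tf_column(self):
        grn = GrnSpec([(0, 1, 1.0)])
        eff = build_effect_matrix(grn, 3)
        giv = build_diff_giv_with_grn(eff, grn, 6, 3, _rng(1), p0=0.5)
        assert np.array_equal(giv[:, 1], giv[:, 0])
        assert np.count_nonzero(giv[:, 0]) == 2

    def test_two_regulators_weighted_sum(self):
        grn = GrnSpec([(0, 2, 2.0), (1, 2, 3.0)])
        eff = build_effect_matrix(grn, 4)
        giv = build_diff_giv_with_grn(eff, grn, 8, 4, _rng(2), p0=0.5)
        assert np.allclose(giv[:, 2], 2 * giv[:, 0] + 3 * giv[:, 1])

    def test_dual_tf_target_with_zero_effect(self):
        # gene 1 is both a TF and the (zero-effect) target of TF 0:
        # the product part vanishes, leaving half its own TF column
        grn = GrnSpec([(0, 1, 0.0), (1, 2, 1.0)])
        eff = build_effect_matrix(grn, 4)
        giv = build_diff_giv_with_grn(eff, grn, 6, 4, _rng(3), p0=0.5)
        own = np.zeros(6)
        own[np.nonzero(giv[:, 1])] = 1.0
        assert np.count_nonzero(giv[:, 1]) == 2
        assert set(np.unique(giv[:, 1])) == {0.0, 0.5}

    def test_requires_two_diff_dims(self):
        grn = GrnSpec([(0, 1, 1.0)])
        eff = build_effect_matrix(grn, 2)
        with pytest.raises(ValueError):
            build_diff_giv_with_grn(eff, grn, 1, 2, _rng())

    def test_coregulated_targets_more_similar(self, grn100):
        """Targets sharing a TF have more similar diff-GIV columns than
        unrelated gene pairs (drives gene-module structure)."""
        eff = build_effect_matrix(grn100, 100)
        giv = build_diff_giv_with_grn(eff, grn100, 25, 100, _rng(4))

        def cos(a, b):
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            return a @ b / (na * nb) if na > 0 and nb > 0 else 0.0

        targets_of = {}
        for tf, t, _ in grn100.edges:
            targets_of.setdefault(tf, []).append(t)
        shared, rng = [], _rng(5)
        for tf, ts in targets_of.items():
            for i in range(len(ts)):
                for j in range(i + 1, len(ts)):
                    shared.append(cos(giv[:, ts[i]], giv[:, ts[j]]))
        grn_genes = set(grn100.tf_set) | set(grn100.targets)
        free = [g for g in range(100) if g not in grn_genes]
        unrelated = [cos(giv[:, rng.choice(free)], giv[:, rng.choice(free)])
                     for _ in range(300)]
        assert np.mean(shared) > np.mean(unrelated)


class TestGivAssembly:
    def test_tf_lig_blocks_zero_for_kon_koff(self, grn100):
        for param in ("kon", "koff"):
            giv = build_giv(param, grn100, 100, 30, 20, 8, 0.7, 0.0, 1.0,
                            _rng(6))
            tf_block = giv.matrix[50:50 + giv.n_tf]
            lig_block = giv.matrix[50 + giv.n_tf:]
            assert np.all(tf_block == 0) and np.all(lig_block == 0)

    def test_s_tf_block_is_effect_matrix(self, grn100):
        giv = build_giv("s", grn100, 100, 30, 20, 0, 0.7, 0.0, 1.0,
                        _rng(6))
        eff = build_effect_matrix(grn100, 100)
        assert np.array_equal(giv.matrix[50:50 + giv.n_tf], eff.T)

    def test_segment_widths_match_cif_layout(self, grn100):
        giv = build_giv("s", grn100, 100, 30, 20, 12, 0.7, 0.0, 1.0,
                        _rng(6))
        assert giv.width == 30 + 20 + grn100.n_tf + 12


class TestCellSpecificGrn:
    def test_zero_rate_keeps_grn(self, grn100):
        seq = evolve_cell_specific_grn(grn100, 5, 0.0, _rng())
        assert all(g.edges == grn100.edges for g in seq)

    def test_rate_one_deletes_single_edge(self):
        grn = GrnSpec([(0, 1, 1.0)])
        seq = evolve_cell_specific_grn(grn, 4, 1.0, _rng(1), n_gene=5)
        # the original edge is gone in cell 2 with certainty (later cells
        # may regrow the pair as a fresh random edge)
        assert seq[0].edges == grn.edges
        assert (0, 1) not in {(tf, t) for tf, t, _ in seq[1].edges}

    def test_edge_count_follows_birth_death_chain(self):
        """Mean edge count over replicates matches an independent
        simulation of the birth-death recursion."""
        grn = GrnSpec([(i % 3, 3 + i, 1.0) for i in range(10)])
        rate, steps, reps = 0.15, 12, 300
        means = np.zeros(steps)
        for r in range(reps):
            seq = evolve_cell_specific_grn(grn, steps, rate,
                                           _rng(1000 + r), n_gene=30)
            means += [len(g.edges) for g in seq]
        means /= reps
        # oracle: n_{t+1} = n_t (1 - rate) + rate (one Bernoulli birth)
        expect = [10.0]
        for _ in range(steps - 1):
            expect.append(expect[-1] * (1 - rate) + rate)
        assert np.allclose(means, expect, atol=0.35)
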