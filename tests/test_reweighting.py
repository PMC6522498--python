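"""Simplex-constrained weight fitting and ensemble summaries."""

import itertools

import numpy as np
import pytest

from polyq_ens import (
    ShiftMatrix,
    ShiftTable,
    build_chain,
    compare_variants,
    ensemble_summary,
    fit_weights,
    pool_matrix,
    supported_observables,
)
from polyq_ens.ensemble_reweighting import EnsembleSummary, WeightVector

HELIX = (-57.0, -47.0)
EXTENDED = (-135.0, 135.0)
PPII = (-75.0, 145.0)


def _table_from_vector(sequence, observables, values):
    shifts = {
        (idx, nuc): float(v) for (idx, _aa, nuc), v in zip(observables, values)
    }
    return ShiftTable(sequence=sequence, shifts=shifts)


def _random_matrix(rng, k, j, seq=None):
    seq = seq or "A" * (j // 5 + 5)
    obs = [(i + 1, "A", "CA") for i in range(j)]
    seq = "A" * j
    return ShiftMatrix(observables=obs, values=52.5 + rng.normal(0, 1, (k, j))), seq


def _grid_objective(matrix, y, w):
    resid = w @ matrix - y
    return float(resid @ resid)


class TestFitWeights:
    def test_single_conformer_gets_weight_one(self, rc):
        conf = build_chain("AQRA", [PPII] * 4)
        obs = supported_observables("AQRA", rc)
        matrix = pool_matrix([conf], obs, rc)
        exp = _table_from_vector("AQRA", obs, matrix.values[0] + 0.3)
        wv = fit_weights(matrix, exp)
        assert wv.w == pytest.approx([1.0])

    def test_two_conformer_mixture_recovered_and_matches_grid(self, rng):
        matrix, seq = _random_matrix(rng, 2, 30)
        y = 0.7 * matrix.values[0] + 0.3 * matrix.values[1]
        exp = _table_from_vector(seq, matrix.observables, y)
        wv = fit_weights(matrix, exp)
        assert wv.w == pytest.approx([0.7, 0.3], abs=1e-6)
        # 1-D grid search oracle over the simplex
        grid = np.arange(0.0, 1.0 + 1e-12, 1e-4)
        objectives = [
            _grid_objective(matrix.values, y, np.array([a, 1 - a])) for a in grid
        ]
        best = grid[int(np.argmin(objectives))]
        assert wv.w[0] == pytest.approx(best, abs=2e-4)

    def test_vertex_solution_recovered(self, rng):
        matrix, seq = _random_matrix(rng, 3, 30)
        exp = _table_from_vector(seq, matrix.observables, matrix.values[1])
        wv = fit_weights(matrix, exp)
        assert wv.w[1] >= 0.999
        # exhaustive 3-simplex grid at step 1e-2
        best_obj = min(
            _grid_objective(matrix.values, matrix.values[1],
                            np.array([a, b, 1 - a - b]))
            for a in np.arange(0, 1.0 + 1e-12, 0.01)
            for b in np.arange(0, 1.0 - a + 1e-12, 0.01)
        )
        assert wv.objective <= best_obj + 1e-6

    def test_grid_search_equivalence_small_pools(self, rng):
        """Fitted objective never worse than a grid search for K <= 3."""
        step = 0.02
        for trial in range(20):
            k = int(rng.integers(2, 4))
            matrix, seq = _random_matrix(rng, k, 15)
            w_true = rng.dirichlet(np.ones(k))
            y = w_true @ matrix.values + rng.normal(0, 0.05, 15)
            exp = _table_from_vector(seq, matrix.observables, y)
            wv = fit_weights(matrix, exp)
            if k == 2:
                candidates = (np.array([a, 1 - a])
                              for a in np.arange(0, 1 + 1e-12, step))
            else:
                candidates = (
                    np.array([a, b, 1 - a - b])
                    for a in np.arange(0, 1 + 1e-12, step)
                    for b in np.arange(0, 1 - a + 1e-12, step)
                )
            best = min(_grid_objective(matrix.values, y, c) for c in candidates)
            assert wv.objective <= best + 1e-6

    def test_simplex_feasibility_on_random_problems(self, rng):
        for _ in range(10):
            k = int(rng.integers(2, 8))
            matrix, seq = _random_matrix(rng, k, 20)
            y = rng.dirichlet(np.ones(k)) @ matrix.values + rng.normal(0, 0.2, 20)
            wv = fit_weights(matrix, _table_from_vector(seq, matrix.observables, y))
            assert wv.w.min() >= -1e-10
            assert abs(wv.w.sum() - 1.0) <= 1e-8
            uniform = np.full(k, 1 / k)
            assert wv.objective <= _grid_objective(
                matrix.values, y, uniform
            ) + 1e-9

    def test_sparse_weight_recovery_well_conditioned(self, rng):
        k = 8
        matrix, seq = _random_matrix(rng, k, 3 * k)
        w_true = np.zeros(k)
        w_true[[1, 4, 6]] = (0.5, 0.3, 0.2)
        y = w_true @ matrix.values
        wv = fit_weights(matrix, _table_from_vector(seq, matrix.observables, y))
        assert np.abs(wv.w - w_true).max() <= 0.02
        y_noisy = y + rng.normal(0, 0.1, len(y))
        wv_noisy = fit_weights(
            matrix, _table_from_vector(seq, matrix.observables, y_noisy)
        )
        assert np.abs(wv_noisy.w - w_true).max() <= 0.10

    def test_l2_never_increases_weight_norm(self, rng):
        matrix, seq = _random_matrix(rng, 5, 8)  # underdetermined
        y = rng.dirichlet(np.ones(5)) @ matrix.values
        exp = _table_from_vector(seq, matrix.observables, y)
        base = fit_weights(matrix, exp, l2=0.0)
        reg = fit_weights(matrix, exp, l2=1.0)
        assert np.sum(reg.w**2) <= np.sum(base.w**2) + 1e-8

    def test_duplicate_rows_flagged_rank_deficient(self, rng):
        matrix, seq = _random_matrix(rng, 2, 10)
        matrix.values[1] = matrix.values[0]
        exp = _table_from_vector(seq, matrix.observables, matrix.values[0])
        wv = fit_weights(matrix, exp)
        assert wv.rank_deficient

    def test_no_overlapping_observables_is_error(self, rng):
        matrix, seq = _random_matrix(rng, 2, 5)
        exp = ShiftTable(sequence=seq, shifts={(1, "CB"): 19.0})
        with pytest.raises(ValueError):
            fit_weights(matrix, exp)


class TestEnsembleSummary:
    def test_uniform_weights_over_h_and_c_pool(self):
        seq = "A" * 8
        pool = [build_chain(seq, [HELIX] * 8), build_chain(seq, [PPII] * 8)]
        wv = WeightVector(w=np.array([0.5, 0.5]), objective=0.0)
        summary = ensemble_summary(pool, wv)
        assert summary.p_h[2:6] == pytest.approx([0.5] * 4)
        assert summary.p_c[2:6] == pytest.approx([0.5] * 4)
        assert summary.effective_size == pytest.approx(2.0)

    def test_one_hot_weights_reproduce_single_conformer(self):
        seq = "A" * 8
        pool = [build_chain(seq, [HELIX] * 8), build_chain(seq, [EXTENDED] * 8)]
        wv = WeightVector(w=np.array([1.0, 0.0]), objective=0.0)
        summary = ensemble_summary(pool, wv)
        expected_h = np.array([c == "H" for c in pool[0].ss], dtype=float)
        assert summary.p_h == pytest.approx(expected_h)

    def test_probabilities_match_direct_count_oracle(self, rng):
        seq = "AQRAQRAQ"
        dihedral_sets = [[HELIX] * 8, [EXTENDED] * 8, [PPII] * 8,
                         [HELIX] * 4 + [PPII] * 4, [PPII] * 4 + [EXTENDED] * 4]
        pool = [build_chain(seq, d) for d in dihedral_sets]
        w = rng.dirichlet(np.ones(5))
        wv = WeightVector(w=w, objective=0.0)
        summary = ensemble_summary(pool, wv)
        for i in range(8):
            for state, arr in (("H", summary.p_h), ("E", summary.p_e),
                               ("C", summary.p_c)):
                expected = sum(
                    wk for wk, conf in zip(w, pool) if conf.ss[i] == state
                )
                assert arr[i] == pytest.approx(expected)

    def test_pool_weight_length_mismatch_rejected(self):
        pool = [build_chain("AAAA", [HELIX] * 4)]
        wv = WeightVector(w=np.array([0.5, 0.5]), objective=0.0)
        with pytest.raises(ValueError):
            ensemble_summary(pool, wv)


def _summary(p_h, seq=None):
    n = len(p_h)
    seq = seq or "Q" * n
    p_h = np.asarray(p_h, dtype=float)
    return EnsembleSummary(
        sequence=seq, p_h=p_h, p_e=np.zeros(n), p_c=1.0 - p_h,
        effective_size=1.0,
    )


class TestCompareVariants:
    def test_identical_summaries_give_zero(self):
        a = _summary([0.4] * 6)
        delta, mean = compare_variants(a, a, (1, 6))
        assert np.allclose(delta, 0.0) and mean == 0.0

    def test_region_mean_difference(self):
        a = _summary([0.4] * 6)
        b = _summary([0.6] * 6)
        _delta, mean = compare_variants(a, b, (2, 5))
        assert mean == pytest.approx(0.2)

    def test_insertions_aligned_by_frame_labels(self):
        a = _summary([0.1, 0.2, 0.3])
        b = _summary([0.1, 0.2, 0.5, 0.3], seq="QQQQ")
        delta, _ = compare_variants(
            a, b, (1, 3),
            a_frame=[1, 2, 3], b_frame=[1, 2, 2.01, 3],
        )
        assert delta == pytest.approx([0.0, 0.0, 0.0])

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_variants(_summary([0.4] * 3), _summary([0.4] * 5), (1, 3))
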