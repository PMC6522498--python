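"""Synthetic scenarios: sequences, pools, shifts and HDX series."""

import numpy as np
import pytest

from polyq_ens import (
    classify_hdx,
    compare_hdx,
    fit_weights,
    make_scenario,
    pool_helix_frequency,
    pool_matrix,
    sample_pool,
    supported_observables,
    synth_experimental_shifts,
    synth_hdx,
)
from polyq_ens.synthetic_data import (
    ARR2_REGION,
    POLYQ_END_10Q,
    POLYQ_START,
    Scenario,
)


def _longest_q_run(sequence):
    best = run = 0
    for ch in sequence:
        run = run + 1 if ch == "Q" else 0
        best = max(best, run)
    return best


class TestMakeScenario:
    @pytest.mark.parametrize(
        "preset,q_len",
        [("normal_10Q", 10), ("expanded_22Q", 22), ("expanded_33Q", 33),
         ("helix_broken", 33)],
    )
    def test_polyq_run_length(self, preset, q_len):
        scenario = make_scenario(preset, seed=0)
        assert _longest_q_run(scenario.sequence) == q_len

    def test_normal_preset_propensity_structure(self):
        sc = make_scenario("normal_10Q", seed=0)
        arr2 = (sc.labels >= ARR2_REGION[0]) & (sc.labels <= ARR2_REGION[1])
        polyq = (sc.labels >= POLYQ_START) & (sc.labels <= POLYQ_END_10Q)
        assert (sc.helix_propensity[arr2] >= 0.6).all()
        assert (sc.helix_propensity[polyq] <= 0.2).all()

    def test_expanded_preset_boost_decays_from_arr(self):
        sc = make_scenario("expanded_22Q", seed=0)
        tract = np.flatnonzero(
            (sc.labels >= POLYQ_START) & (sc.labels < 40)
        )
        p = sc.helix_propensity[tract]
        assert p[0] >= 0.5
        assert (np.diff(p) <= 1e-12).all()
        assert p[-1] <= 0.2

    def test_helix_broken_preset_has_flat_arr2(self):
        sc = make_scenario("helix_broken", seed=0)
        arr2 = (sc.labels >= ARR2_REGION[0]) & (sc.labels <= ARR2_REGION[1])
        assert (sc.helix_propensity[arr2] <= 0.1).all()

    def test_deterministic_per_seed(self):
        a = make_scenario("expanded_22Q", seed=5)
        b = make_scenario("expanded_22Q", seed=5)
        assert a.sequence == b.sequence
        assert (a.labels == b.labels).all()
        assert (a.helix_propensity == b.helix_propensity).all()
        assert (a.truth_weights(10) == b.truth_weights(10)).all()

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            make_scenario("expanded_99Q", seed=0)

    def test_sequence_length_10q_frame(self):
        sc = make_scenario("normal_10Q", seed=0)
        assert len(sc.sequence) == 62
        assert sc.sequence[28] == "R"  # Arg29
        assert (sc.labels == np.arange(1, 63)).all()

    def test_invalid_propensity_rejected(self):
        with pytest.raises(ValueError):
            Scenario(
                preset="x", sequence="AA", labels=[1, 2],
                helix_propensity=[0.5, 1.5], polyq_len=0,
            )


class TestSamplePool:
    def test_zero_propensity_gives_all_coil(self):
        sc = make_scenario("normal_10Q", seed=1)
        sc.helix_propensity[:] = 0.0
        pool = sample_pool(sc, k=5)
        assert all(set(conf.ss) == {"C"} or "H" not in conf.ss for conf in pool)

    def test_unit_propensity_gives_interior_all_helix(self):
        sc = make_scenario("normal_10Q", seed=1)
        sc.helix_propensity[:] = 1.0
        pool = sample_pool(sc, k=5)
        for conf in pool:
            assert set(conf.ss[1:-1]) == {"H"}

    def test_pool_is_seed_reproducible(self):
        sc = make_scenario("normal_10Q", seed=9, pool_size=3)
        a, b = sample_pool(sc), sample_pool(sc)
        for conf_a, conf_b in zip(a, b):
            assert (conf_a.coords == conf_b.coords).all()

    def test_arr2_helix_frequency_matches_propensity(self):
        """Monte-Carlo frequency over a large pool tracks the generator."""
        sc = make_scenario("normal_10Q", seed=3, pool_size=500)
        freq = pool_helix_frequency(sample_pool(sc))
        arr2 = (sc.labels >= ARR2_REGION[0]) & (sc.labels <= ARR2_REGION[1])
        assert freq[arr2].mean() == pytest.approx(0.70, abs=0.05)

    def test_minimum_helix_run_length(self):
        sc = make_scenario("expanded_22Q", seed=2, pool_size=20)
        for conf in sample_pool(sc):
            runs = [len(r) for r in conf.ss.split("C") if "H" in r]
            # interior H runs come from >= 4-residue masks, possibly
            # truncated to >= 3 only by the coil termini
            assert all(r >= 3 for r in runs)


class TestSynthShifts:
    def test_one_hot_noiseless_equals_single_prediction(self, rc):
        from polyq_ens import predict_shifts

        sc = make_scenario("normal_10Q", seed=4, pool_size=3)
        pool = sample_pool(sc)
        w = np.array([0.0, 1.0, 0.0])
        exp = synth_experimental_shifts(pool, w, 0.0, sc.seed, rc=rc)
        predicted = predict_shifts(pool[1], rc)
        for key, value in exp.shifts.items():
            assert value == pytest.approx(predicted.shifts[key])

    def test_uniform_two_conformer_mean(self, rc):
        from polyq_ens import predict_shifts

        sc = make_scenario("normal_10Q", seed=4, pool_size=2)
        pool = sample_pool(sc)
        exp = synth_experimental_shifts(pool, [0.5, 0.5], 0.0, sc.seed, rc=rc)
        p0 = predict_shifts(pool[0], rc)
        p1 = predict_shifts(pool[1], rc)
        for key, value in exp.shifts.items():
            assert value == pytest.approx((p0.shifts[key] + p1.shifts[key]) / 2)

    def test_noisy_table_reproducible_and_recoverable(self, rc):
        sc = make_scenario("normal_10Q", seed=6, pool_size=10)
        pool = sample_pool(sc)
        rng = np.random.default_rng(0)
        w_true = np.zeros(10)
        w_true[[0, 3, 7]] = (0.5, 0.3, 0.2)
        a = synth_experimental_shifts(pool, w_true, 0.1, sc.seed, rc=rc)
        b = synth_experimental_shifts(pool, w_true, 0.1, sc.seed, rc=rc)
        assert a == b
        matrix = pool_matrix(
            pool, supported_observables(sc.sequence, rc), rc
        )
        wv = fit_weights(matrix, a)
        assert np.abs(wv.w - w_true).max() <= 0.10

    def test_weights_must_lie_on_simplex(self, rc):
        sc = make_scenario("normal_10Q", seed=4, pool_size=2)
        pool = sample_pool(sc)
        with pytest.raises(ValueError):
            synth_experimental_shifts(pool, [0.7, 0.7], 0.0, 1, rc=rc)


class TestSynthHdx:
    def test_helix_broken_has_no_slow_arr2(self):
        sc = make_scenario("helix_broken", seed=8)
        hdx_map = classify_hdx(synth_hdx(sc), polyq_region=sc.polyq_region)
        arr2 = (sc.labels >= ARR2_REGION[0]) & (sc.labels <= ARR2_REGION[1])
        assert not (hdx_map.slow_mask() & arr2).any()

    def test_expansion_adds_slow_polyq_amides(self):
        normal = make_scenario("normal_10Q", seed=8)
        expanded = make_scenario("expanded_33Q", seed=8)
        map_n = classify_hdx(synth_hdx(normal), polyq_region=(30, 39))
        map_e = classify_hdx(synth_hdx(expanded), polyq_region=(30, 39))
        _n, _e, diff = compare_hdx(map_n, map_e, (30, 39))
        assert diff > 0

    def test_series_is_seed_reproducible(self):
        sc = make_scenario("normal_10Q", seed=13)
        a, b = synth_hdx(sc), synth_hdx(sc)
        assert (a.intensities == b.intensities).all()
        assert (a.control == b.control).all()

    def test_slow_residues_follow_propensity(self):
        sc = make_scenario("expanded_22Q", seed=3)
        series = synth_hdx(sc)
        t15 = series.intensities[0] / np.where(series.control > 0,
                                               series.control, 1.0)
        protected = sc.helix_propensity >= 0.5
        amide = np.array([aa != "P" for aa in sc.sequence])
        assert (t15[protected & amide] >= 0.4).all()
        assert (t15[~protected & amide] <= 0.1).all()
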