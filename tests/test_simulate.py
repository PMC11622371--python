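import numpy as np
import pytest

from specdiff import (
    FAST_MECHANISM,
    MechanismParams,
    SimulationConfig,
    apply_mechanism,
    chain_deltas,
    make_dataset,
    make_initial_spectra,
    mechanism_delta,
    plsda_permutation_pvalue,
    run_benchmark,
    sample_mechanism,
)
from specdiff.preprocess import preprocess
from specdiff.simulate import SLOW_MECHANISM, _dataset_rngs


class TestSampleMechanism:
    def test_same_seed_is_deterministic(self):
        a = sample_mechanism(100, FAST_MECHANISM, 42)
        b = sample_mechanism(100, FAST_MECHANISM, 42)
        np.testing.assert_array_equal(a.selected, b.selected)
        np.testing.assert_array_equal(a.rate, b.rate)
        np.testing.assert_array_equal(a.factor, b.factor)

    def test_exactly_half_the_peaks_selected(self):
        spec = sample_mechanism(1000, FAST_MECHANISM, 0)
        assert spec.selected.size == 500
        assert np.unique(spec.selected).size == 500
        spec = sample_mechanism(993, FAST_MECHANISM, 0)
        assert spec.selected.size == 496

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sample_mechanism(1, FAST_MECHANISM, 0)

    def test_direction_is_a_fair_coin(self):
        # 2000 mechanisms x 50 selected peaks; binomial 3-sigma band
        rng = np.random.default_rng(7)
        ups = sum(
            int((sample_mechanism(100, FAST_MECHANISM, rng).direction > 0).sum())
            for _ in range(2000)
        )
        assert abs(ups / (2000 * 50) - 0.5) < 0.03

    def test_factors_only_for_increasing_peaks(self):
        spec = sample_mechanism(200, FAST_MECHANISM, 3)
        inc = spec.direction > 0
        assert np.all(np.isfinite(spec.factor[inc]))
        assert np.all(np.isnan(spec.factor[~inc]))
        assert np.all(spec.factor[inc] >= FAST_MECHANISM.f_lo)
        assert np.all(spec.factor[inc] <= FAST_MECHANISM.f_hi)


class TestApplyMechanism:
    def test_time_zero_is_identity(self):
        X = np.random.default_rng(0).uniform(10, 100, size=(3, 20))
        spec = sample_mechanism(20, FAST_MECHANISM, 1)
        np.testing.assert_array_equal(apply_mechanism(X, spec, 0.0), X)

    def test_decreasing_peak_follows_exponential_decay(self):
        spec = sample_mechanism(2, MechanismParams(1.0, 0.0), 0)
        # force a single decreasing peak with rate 1 at column 0
        spec = type(spec)(selected=np.array([0]), direction=np.array([-1]),
                          rate=np.array([1.0]), factor=np.array([np.nan]),
                          params=spec.params)
        X = np.array([[100.0, 50.0]])
        out = apply_mechanism(X, spec, 0.1)
        assert out[0, 0] == pytest.approx(100 * np.exp(-0.1))  # ~90.48
        assert out[0, 1] == 50.0  # unselected peak untouched

    def test_decrease_is_monotone_to_zero(self):
        spec = type(sample_mechanism(2, FAST_MECHANISM, 0))(
            selected=np.array([0]), direction=np.array([-1]),
            rate=np.array([2.0]), factor=np.array([np.nan]),
            params=FAST_MECHANISM)
        X = np.array([[100.0, 1.0]])
        values = [apply_mechanism(X, spec, t)[0, 0]
                  for t in (0.0, 0.5, 1.0, 5.0, 50.0)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(0.0, abs=1e-30)

    def test_increase_saturates_at_update_factor(self):
        spec = type(sample_mechanism(2, FAST_MECHANISM, 0))(
            selected=np.array([1]), direction=np.array([1]),
            rate=np.array([1.0]), factor=np.array([3.0]),
            params=FAST_MECHANISM)
        X = np.array([[10.0, 100.0]])
        out = apply_mechanism(X, spec, 1e3)
        assert out[0, 1] == pytest.approx(100.0 * 4.0)

    def test_negative_time_rejected(self):
        spec = sample_mechanism(5, FAST_MECHANISM, 0)
        with pytest.raises(ValueError, match="nonnegative"):
            apply_mechanism(np.ones((1, 5)), spec, -0.1)


class TestMechanismDelta:
    def test_zero_time_gives_zero_vector(self):
        spec = sample_mechanism(10, FAST_MECHANISM, 0)
        delta = mechanism_delta(np.ones((3, 10)) * 50, spec, 0.0)
        np.testing.assert_array_equal(delta, np.zeros(10))

    def test_unselected_peaks_have_exactly_zero_entries(self):
        spec = sample_mechanism(10, FAST_MECHANISM, 0)
        delta = mechanism_delta(np.ones((3, 10)) * 50, spec, 1.0)
        unselected = np.setdiff1d(np.arange(10), spec.selected)
        np.testing.assert_array_equal(delta[unselected], 0.0)

    def test_single_peak_decrease_value(self):
        spec = type(sample_mechanism(2, FAST_MECHANISM, 0))(
            selected=np.array([0]), direction=np.array([-1]),
            rate=np.array([1.0]), factor=np.array([np.nan]),
            params=FAST_MECHANISM)
        delta = mechanism_delta(np.array([[100.0, 5.0]]), spec, 1.0)
        assert delta[0] == pytest.approx(100 * (np.exp(-1) - 1))  # ~ -63.21

    def test_chain_deltas_sum_to_total_change(self, rng):
        init = make_initial_spectra(50, rng=rng)
        m1 = sample_mechanism(init.peaks, FAST_MECHANISM, 1)
        m2 = sample_mechanism(init.peaks, SLOW_MECHANISM, 2)
        d1, d2 = chain_deltas(init, [m1, m2], 0.7)
        X = apply_mechanism(apply_mechanism(init.intensities, m1, 0.7),
                            m2, 0.7)
        np.testing.assert_allclose(d1 + d2,
                                   (X - init.intensities).mean(axis=0),
                                   rtol=1e-10)


class TestMakeDataset:
    def test_row_count_and_labels(self, rng):
        init = make_initial_spectra(30, n_spectra=3, rng=rng)
        spec = sample_mechanism(init.peaks, FAST_MECHANISM, 5)
        ds = make_dataset(init, [spec], 1.0, rng, n_replicate_spectra=3)
        assert ds.n_spectra == 6
        assert ds.labels.count("initial") == 3
        assert ds.labels.count("artificial") == 3

    def test_bit_identical_under_same_master_seed(self):
        def build():
            rngs = _dataset_rngs(99, 0, 3)
            init = make_initial_spectra(40, rng=rngs[0])
            spec = sample_mechanism(init.peaks, FAST_MECHANISM, rngs[1])
            return make_dataset(init, [spec], 0.5, rngs[2])

        a, b = build(), build()
        np.testing.assert_array_equal(a.intensities, b.intensities)
        np.testing.assert_array_equal(a.peaks.center_mz, b.peaks.center_mz)

    def test_no_change_dataset_is_not_separable(self):
        """At t=0 the artificial class is a Poisson re-draw of the initial
        mean, so PLS-DA separation should not beat the permutation null."""
        rngs = _dataset_rngs(11, 0, 4)
        init = make_initial_spectra(200, rng=rngs[0])
        spec = sample_mechanism(init.peaks, FAST_MECHANISM, rngs[1])
        ds = make_dataset(init, [spec], 0.0, rngs[2])
        centered, state = preprocess(ds)
        p = plsda_permutation_pvalue(centered, ds.labels, state,
                                     n_permutations=100, rng=rngs[3])
        assert p > 0.05


class TestBenchmark:
    def test_well_separated_classes_recover_the_mechanism(self):
        cfg = SimulationConfig(t_values=(1.0,), n_datasets=1,
                               n_peaks=300, master_seed=4)
        res = run_benchmark(cfg)
        assert res.mean_similarity("pca", 1.0) > 0.95
        assert res.mean_similarity("plsda", 1.0) > 0.95
        assert res.n_failed == 0

    def test_benchmark_is_reproducible_from_master_seed(self):
        cfg = SimulationConfig(t_values=(0.5,), n_datasets=3,
                               n_peaks=100, master_seed=21)
        a, b = run_benchmark(cfg), run_benchmark(cfg)
        np.testing.assert_array_equal(a.similarities[("plsda", 0.5)],
                                      b.similarities[("plsda", 0.5)])

    def test_plsda_discriminating_component_is_first(self):
        """The between-within criterion should pick PLS component 1 in
        nearly every dataset."""
        from specdiff import fit_plsda

        firsts = 0
        n = 40
        for i in range(n):
            rngs = _dataset_rngs(17, i, 3)
            init = make_initial_spectra(150, rng=rngs[0])
            spec = sample_mechanism(init.peaks, FAST_MECHANISM, rngs[1])
            ds = make_dataset(init, [spec], 0.1, rngs[2])
            centered, state = preprocess(ds)
            model = fit_plsda(centered, ds.labels, state)
            firsts += model.selected == 0
        assert firsts / n >= 0.95

    def test_two_mechanism_config_requires_fast_then_slow(self):
        with pytest.raises(ValueError, match="faster"):
            SimulationConfig(mechanisms=(SLOW_MECHANISM, FAST_MECHANISM))
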