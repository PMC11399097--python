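import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trwaxs.geometry import QGrid
from trwaxs.kinetics import SequentialModel, concentration_profiles
from trwaxs.reduction import (
    DEFAULT_CORRELATION_THRESHOLD,
    DifferenceSeries,
    TrainCorrelationFilter,
    compute_difference,
    filter_trains,
    merge_concentrations,
    normalize_profile,
)
from trwaxs.synthetic import GeneratorConfig, TrainSeries, inject_instability, simulate_train_series


class TestFilterTrains:
    def test_identical_trains_all_kept_with_unit_correlation(self, qgrid):
        base = np.linspace(10.0, 1.0, len(qgrid))
        profiles = np.tile(base, (10, 4, 1))
        series = TrainSeries(profiles, np.arange(10) % 2 == 0, np.arange(4.0), qgrid)
        kept, report = filter_trains(series)
        assert kept.n_trains == 10
        assert np.allclose(report["per_train_correlation"], 1.0)

    def test_two_injected_instabilities_dropped(self, noisy_series):
        """10 trains with 2 injected instabilities: exactly 8 survive."""
        _, big = noisy_series
        small = TrainSeries(
            big.profiles[:10].copy(), big.light_flag[:10].copy(), big.time_us, big.q,
            truth=dict(big.truth),
        )
        out = inject_instability(small, [3, 6])
        kept, report = filter_trains(out)
        assert kept.n_trains == 8
        assert set(report["dropped_ids"]) == {3, 6}

    def test_default_threshold_value(self):
        assert TrainCorrelationFilter().threshold == DEFAULT_CORRELATION_THRESHOLD == 0.99995

    def test_clean_run_fully_retained(self):
        cfg = GeneratorConfig(n_train_pairs=10, pulses_per_train=16, seed=2)
        _, report = filter_trains(simulate_train_series(cfg))
        assert report["n_trains_dropped"] == 0

    def test_corrupt_fraction_drives_retention(self):
        """With 30 percent corrupted trains about 70 percent survive."""
        cfg = GeneratorConfig(n_train_pairs=20, pulses_per_train=16, corrupt_fraction=0.3, seed=6)
        series = simulate_train_series(cfg)
        kept, report = filter_trains(series)
        n_corrupt = len(series.truth["corrupted_ids"])
        assert report["n_trains_dropped"] == n_corrupt
        assert kept.n_trains == series.n_trains - n_corrupt
        assert kept.n_trains / series.n_trains == pytest.approx(0.7, abs=0.05)

    def test_all_dropped_is_error(self, qgrid):
        # constant profiles have undefined (NaN) correlation, which counts as
        # failing the threshold: every train is dropped and that is an error
        profiles = np.ones((4, 3, len(qgrid)))
        series = TrainSeries(profiles, np.arange(4) % 2 == 0, np.arange(3.0), qgrid)
        with pytest.raises(ValueError, match="every train"):
            filter_trains(series)


class TestNormalizeProfile:
    def test_window_sum_is_one(self, qgrid):
        rng = np.random.default_rng(1)
        out = normalize_profile(rng.random(len(qgrid)) + 0.1, qgrid, 0.08, 1.5)
        assert out[qgrid.window(0.08, 1.5)].sum() == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(1e-3, 1e6))
    def test_scale_invariance(self, scale):
        q = QGrid.linear(0.08, 1.5, 50)
        base = np.linspace(5.0, 1.0, 50)
        assert np.allclose(
            normalize_profile(scale * base, q), normalize_profile(base, q), rtol=1e-12
        )

    def test_display_window_supported(self, qgrid):
        out = normalize_profile(np.ones(len(qgrid)), qgrid, 1.4, 1.6)
        assert out[qgrid.window(1.4, 1.6)].sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_window_sum_rejected(self, qgrid):
        with pytest.raises(ValueError):
            normalize_profile(np.zeros(len(qgrid)), qgrid)


class TestComputeDifference:
    def test_identical_classes_give_zero(self, qgrid):
        base = np.tile(np.linspace(3.0, 1.0, len(qgrid)), (6, 4, 1))
        series = TrainSeries(base, np.arange(6) % 2 == 0, np.arange(4.0), qgrid)
        ds = compute_difference(series)
        assert np.allclose(ds.delta_S, 0.0)

    def test_noiseless_equals_kinetic_forward_model(self, noiseless_series):
        cfg, series = noiseless_series
        ds = compute_difference(series)
        conc = concentration_profiles(SequentialModel(cfg.n_states, cfg.rates), series.time_us)
        expected = cfg.yield_c * (conc @ series.truth["basis_spectra"]).T
        assert np.allclose(ds.delta_S, expected, atol=1e-9 * np.abs(expected).max(), rtol=0)

    def test_label_swap_antisymmetry(self, noiseless_series):
        _, series = noiseless_series
        swapped = TrainSeries(
            series.profiles, ~series.light_flag, series.time_us, series.q
        )
        a = compute_difference(series).delta_S
        b = compute_difference(swapped).delta_S
        assert np.allclose(a, -b)

    def test_adjacent_pairing_beats_shuffled_under_drift(self):
        """Slowly drifting train gain favours adjacent-pair subtraction."""
        cfg = GeneratorConfig(
            n_train_pairs=100, pulses_per_train=4, yield_c=0.0,
            photons_per_pulse_scale=1e12, jitter_sd=5e-3, seed=14,
        )
        series = simulate_train_series(cfg)
        rng = np.random.default_rng(0)
        var_adj = compute_difference(series, pairing="adjacent").delta_S.var()
        var_shuf = compute_difference(series, pairing="shuffled", rng=rng).delta_S.var()
        assert var_adj <= var_shuf

    def test_noise_floor_scales_with_retained_pairs(self):
        """dS noise floor follows 1/sqrt(train pairs) over a 4x range."""
        sds = []
        for n_pairs in (6, 24):
            cfg = GeneratorConfig(
                n_train_pairs=n_pairs, pulses_per_train=12, yield_c=0.0,
                jitter_sd=0.0, seed=77,
            )
            series = simulate_train_series(cfg)
            ds = compute_difference(series)
            relative = ds.delta_S / series.truth["dark_profile"][:, None]
            sds.append(relative.std())
        assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.15)

    def test_missing_class_is_error(self, qgrid):
        profiles = np.ones((3, 2, len(qgrid)))
        series = TrainSeries(profiles, np.ones(3, bool), np.arange(2.0), qgrid)
        with pytest.raises(ValueError):
            compute_difference(series)


class TestMergeConcentrations:
    def _ds(self, qgrid, mat, n_frames):
        return DifferenceSeries(
            q=qgrid, time_us=np.arange(float(mat.shape[1])), delta_S=mat, n_light_frames=n_frames
        )

    def test_identity_merge(self, qgrid):
        rng = np.random.default_rng(2)
        mat = rng.standard_normal((len(qgrid), 5))
        merged = merge_concentrations(self._ds(qgrid, mat, 10), self._ds(qgrid, mat.copy(), 10))
        assert np.allclose(merged.delta_S, mat)
        assert merged.provenance["merge"]["scale_a"] == pytest.approx(1.0)
        assert merged.provenance["merge"]["offset_b"] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_scale_and_offset(self, qgrid):
        rng = np.random.default_rng(3)
        high = rng.standard_normal((len(qgrid), 5))
        a0, b0 = 2.5, 0.3
        low = (high - b0) / a0
        merged = merge_concentrations(self._ds(qgrid, high, 10), self._ds(qgrid, low, 10))
        assert merged.provenance["merge"]["scale_a"] == pytest.approx(a0, abs=1e-9)
        assert merged.provenance["merge"]["offset_b"] == pytest.approx(b0, abs=1e-9)
        assert np.allclose(merged.delta_S, high, atol=1e-9)

    def test_weighted_average_three_to_one(self, qgrid):
        rng = np.random.default_rng(4)
        a_mat = rng.standard_normal((len(qgrid), 4))
        b_mat = rng.standard_normal((len(qgrid), 4))
        merged = merge_concentrations(self._ds(qgrid, a_mat, 30), self._ds(qgrid, b_mat, 10))
        fit = merged.provenance["merge"]
        aligned = fit["scale_a"] * b_mat + fit["offset_b"]
        assert np.allclose(merged.delta_S, (3 * a_mat + aligned) / 4)

    def test_grid_mismatch_rejected(self, qgrid):
        other = QGrid.linear(0.1, 1.4, len(qgrid))
        a = self._ds(qgrid, np.ones((len(qgrid), 3)), 5)
        b = DifferenceSeries(
            q=other, time_us=np.arange(3.0), delta_S=np.ones((len(other), 3)), n_light_frames=5
        )
        with pytest.raises(ValueError):
            merge_concentrations(a, b)
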