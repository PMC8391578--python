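"""Epoching, band energies, time-domain statistics, table assembly."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from eegcv.bands import DEFAULT_BANDS
from eegcv.features import (
    Epoch,
    FeatureTable,
    band_energy,
    build_feature_table,
    extract_epochs,
    segment_feature_table,
    time_domain_features,
)
from eegcv.preprocess import CleanSegment, butterworth_bandpass


def make_segment(duration_s, fs=250.0, n_ch=1, seed=0, offset=0.0):
    rng = np.random.default_rng(seed)
    return CleanSegment("S1", "CN", fs, [f"ch{i}" for i in range(n_ch)],
                        rng.standard_normal((n_ch, int(round(duration_s * fs)))),
                        start_offset_s=offset)


class TestExtractEpochs:
    @pytest.mark.parametrize("duration,epoch,stride,expected", [
        (60.0, 5.0, 2.5, 23),   # floor((60-5)/2.5) + 1
        (5.0, 5.0, 2.5, 1),     # exact fit
        (4.9, 5.0, 2.5, 0),     # too short
        (60.0, 2.0, 1.0, 59),
        (60.0, 10.0, 5.0, 11),
    ])
    def test_epoch_count(self, duration, epoch, stride, expected):
        assert len(extract_epochs(make_segment(duration), epoch, stride)) == expected

    def test_consecutive_epochs_share_overlap_samples(self):
        seg = make_segment(20.0)
        epochs = extract_epochs(seg, 5.0, 2.5)
        overlap = int(2.5 * seg.fs_hz)
        for a, b in zip(epochs, epochs[1:]):
            np.testing.assert_array_equal(a.samples[:, overlap:], b.samples[:, :overlap])
            assert b.start_time_s - a.start_time_s == pytest.approx(2.5)

    def test_epochs_inherit_segment_offset(self):
        epochs = extract_epochs(make_segment(10.0, offset=50.0), 5.0, 2.5)
        assert epochs[0].start_time_s == pytest.approx(50.0)

    def test_invalid_stride_rejected(self):
        with pytest.raises(ValueError):
            extract_epochs(make_segment(10.0), 5.0, 6.0)  # stride > duration


class TestBandEnergy:
    def test_zero_signal_has_zero_energy_everywhere(self):
        x = np.zeros(1250)
        for band in DEFAULT_BANDS:
            assert band_energy(x, band, 250.0) == 0.0

    @pytest.mark.parametrize("freq,band_name", [
        (2.0, "delta"), (6.0, "theta"), (10.0, "alpha"), (18.0, "beta"), (35.0, "gamma"),
    ])
    def test_sinusoid_energy_lands_in_its_band(self, freq, band_name):
        """A unit tone concentrates >=95% of summed band energy in its band,
        cross-checked against the FFT/Parseval location of the tone."""
        fs = 250.0
        t = np.arange(1250) / fs
        x = np.sin(2 * np.pi * freq * t)
        # FFT oracle: the tone's spectral peak sits inside the claimed band
        freqs = np.fft.rfftfreq(len(x), 1 / fs)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        band = next(b for b in DEFAULT_BANDS if b.name == band_name)
        assert band.low_hz <= peak < band.high_hz
        # Parseval oracle: total energy is sum of squares
        energies = {b.name: float(band_energy(x, b, fs)) for b in DEFAULT_BANDS}
        assert energies[band_name] >= 0.95 * sum(energies.values())
        # band energy tracks the tone's total energy (small filtfilt edge slack)
        assert energies[band_name] <= 1.05 * np.sum(x * x)

    def test_delta_is_argmax_for_slow_tone(self):
        fs = 250.0
        x = np.sin(2 * np.pi * 2.0 * np.arange(1250) / fs)
        energies = {b.name: float(band_energy(x, b, fs)) for b in DEFAULT_BANDS}
        assert max(energies, key=energies.get) == "delta"

    def test_band_energies_partition_broadband_signal(self):
        """After 0.5-48 Hz conditioning, the five band energies sum to the
        broadband energy within 15% (the filters approximately tile the band)."""
        seg = butterworth_bandpass(make_segment(60.0, seed=4))
        total = float(np.sum(seg.samples**2))
        banded = sum(float(band_energy(seg.samples[0], b, seg.fs_hz)) for b in DEFAULT_BANDS)
        assert abs(banded - total) / total < 0.15


class TestTimeDomainFeatures:
    def test_constant_signal(self):
        mean, var, iqr = time_domain_features(np.full(100, 3.7))
        assert (mean, var, iqr) == (3.7, 0.0, 0.0)

    def test_hand_computed_population_variance(self):
        mean, var, _ = time_domain_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert mean == 2.5
        assert var == 1.25  # divisor N, not N-1

    @settings(max_examples=50, deadline=None)
    @given(arrays(np.float64, st.integers(2, 50),
                  elements=st.floats(-1e6, 1e6, allow_nan=False)))
    def test_translation_invariance(self, x):
        m0, v0, i0 = time_domain_features(x)
        m1, v1, i1 = time_domain_features(x + 10.0)
        assert m1 == pytest.approx(m0 + 10.0, abs=1e-6)
        assert v1 == pytest.approx(v0, rel=1e-6, abs=1e-4)
        assert i1 == pytest.approx(i0, rel=1e-6, abs=1e-6)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            time_domain_features(np.array([1.0]))


class TestFeatureTable:
    def test_17_channels_give_137_columns(self, tiny_table):
        assert tiny_table.data.shape[1] == 137
        assert tiny_table.data.columns[-1] == "class"
        assert len(tiny_table.feature_columns) == 136
        assert "subject_id" not in tiny_table.data.columns

    def test_single_channel_single_epoch(self):
        epochs = extract_epochs(make_segment(5.0), 5.0, 2.5)
        table = build_feature_table(epochs)
        assert table.data.shape == (1, 9)

    def test_no_epochs_gives_header_only_table(self):
        table = build_feature_table([])
        assert len(table) == 0
        assert list(table.data.columns) == ["class"]

    def test_column_order_is_channel_major(self):
        table = segment_feature_table([make_segment(10.0, n_ch=2)], 5.0, 2.5)
        assert list(table.data.columns[:9]) == [
            "ch0_energy_delta", "ch0_energy_theta", "ch0_energy_alpha",
            "ch0_energy_beta", "ch0_energy_gamma",
            "ch0_mean", "ch0_variance", "ch0_iqr", "ch1_energy_delta"]

    def test_mixed_channel_schemas_rejected(self):
        e1 = extract_epochs(make_segment(5.0, n_ch=1), 5.0, 2.5)
        e2 = extract_epochs(make_segment(5.0, n_ch=2), 5.0, 2.5)
        with pytest.raises(ValueError, match="schema"):
            build_feature_table(e1 + e2)

    def test_csv_round_trip(self, tiny_table, tmp_path):
        f, g = tmp_path / "feat.csv", tmp_path / "groups.csv"
        tiny_table.write_csv(f, g)
        back = FeatureTable.read_csv(f, g)
        pd.testing.assert_frame_equal(
            back.data, tiny_table.data, check_exact=False, rtol=1e-12)
        assert (back.subject_ids == tiny_table.subject_ids).all()

    def test_segment_table_matches_epoch_grid(self):
        seg = make_segment(60.0, n_ch=2)
        table = segment_feature_table([seg], 5.0, 2.5)
        assert len(table) == 23  # same grid as extract_epochs
        assert (table.subject_ids == "S1").all()
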