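import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadsync import (
    FeatureSequence,
    SpectrogramConfig,
    append_deltas,
    mel_spectrogram,
    read_feature_table,
    standardize_per_recording,
    write_feature_table,
)
from dyadsync.features_io import (
    DEEP_SPECTRUM,
    EmbeddingBackend,
    FeatureTableError,
    InsufficientDataError,
    mel_band_center_frequencies,
)


class TestReadFeatureTable:
    def test_reads_plain_csv_in_row_order(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("1,2\n3,4\n5,6\n")
        seq = read_feature_table(p)
        assert (seq.n_frames, seq.n_dims) == (3, 2)
        np.testing.assert_array_equal(seq.values[0], [1.0, 2.0])

    def test_header_row_becomes_dim_names(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("f0,loudness\n1,2\n3,4\n")
        seq = read_feature_table(p)
        assert seq.dim_names == ["f0", "loudness"]
        assert seq.n_dims == 2

    def test_tab_delimited(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("1\t2\n3\t4\n")
        assert read_feature_table(p).n_frames == 2

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("1,2\n3,4,5\n")
        with pytest.raises(FeatureTableError, match="ragged"):
            read_feature_table(p)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("1,2\n3,oops\n")
        with pytest.raises(FeatureTableError, match=r"row 1, column 1"):
            read_feature_table(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("")
        with pytest.raises(InsufficientDataError):
            read_feature_table(p)

    def test_arff_data_section_with_attribute_names(self, tmp_path):
        p = tmp_path / "f.arff"
        p.write_text(
            "@relation smile\n"
            "@attribute name string\n"
            "@attribute pcm_loudness numeric\n"
            "@attribute mfcc1 numeric\n"
            "@data\n"
            "'x',0.5,1.5\n"
            "'x',0.6,1.6\n"
        )
        seq = read_feature_table(p)
        assert seq.dim_names == ["pcm_loudness", "mfcc1"]
        np.testing.assert_allclose(seq.values, [[0.5, 1.5], [0.6, 1.6]])

    def test_write_read_round_trip(self, tmp_path, toy_sequence):
        p = tmp_path / "rt.csv"
        write_feature_table(toy_sequence, p, fmt="%.17g")
        back = read_feature_table(p)
        np.testing.assert_array_equal(back.values, toy_sequence.values)


class TestStandardize:
    def test_population_sigma_hand_case(self):
        seq = FeatureSequence(values=np.array([[1.0], [2.0], [3.0]]))
        out = standardize_per_recording(seq)
        np.testing.assert_allclose(out.values[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_column_maps_to_zeros(self):
        seq = FeatureSequence(values=np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        out = standardize_per_recording(seq)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)
        assert abs(out.values[:, 1].mean()) < 1e-12

    def test_idempotent(self, toy_sequence):
        once = standardize_per_recording(toy_sequence)
        twice = standardize_per_recording(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_single_frame_rejected(self):
        seq = FeatureSequence(values=np.array([[1.0, 2.0]]))
        with pytest.raises(InsufficientDataError):
            standardize_per_recording(seq)

    def test_deep_spectrum_features_refuse_standardization(self):
        seq = FeatureSequence(
            values=np.random.default_rng(0).normal(size=(5, 8)),
            feature_set_name=DEEP_SPECTRUM,
        )
        with pytest.raises(ValueError, match="deep_spectrum"):
            standardize_per_recording(seq)


class TestAppendDeltas:
    def test_first_difference_with_zero_start(self):
        seq = FeatureSequence(values=np.array([[1.0], [3.0], [6.0]]))
        out = append_deltas(seq)
        np.testing.assert_array_equal(out.values, [[1, 0], [3, 2], [6, 3]])

    def test_constant_column_gives_zero_deltas(self):
        seq = FeatureSequence(values=np.full((4, 2), 7.0))
        out = append_deltas(seq)
        np.testing.assert_array_equal(out.values[:, 2:], 0.0)

    def test_doubles_dimensionality_65_to_130(self, rng):
        seq = FeatureSequence(values=rng.normal(size=(20, 65)))
        assert append_deltas(seq).n_dims == 130

    @given(n=st.integers(2, 30), d=st.integers(1, 8))
    @settings(max_examples=25, deadline=None)
    def test_dropping_delta_columns_recovers_input(self, n, d):
        vals = np.random.default_rng(n * 100 + d).normal(size=(n, d))
        out = append_deltas(FeatureSequence(values=vals))
        np.testing.assert_array_equal(out.values[:, :d], vals)


class TestMelSpectrogram:
    SR = 16000

    def test_window_count_formula(self):
        spec = mel_spectrogram(np.zeros(self.SR), self.SR, SpectrogramConfig())
        assert spec.shape == (51, 128)  # floor((1.0-0.5)/0.01)+1

    def test_silence_hits_log_floor_uniformly(self):
        spec = mel_spectrogram(np.zeros(self.SR), self.SR, SpectrogramConfig())
        assert np.allclose(spec, spec[0, 0])
        assert spec[0, 0] == pytest.approx(-10.0)  # log10 floor

    def test_pure_tone_maximizes_its_center_band(self):
        cfg = SpectrogramConfig()
        centers = mel_band_center_frequencies(cfg.n_mel_bands, self.SR)
        band = 60
        t = np.arange(self.SR) / self.SR
        spec = mel_spectrogram(np.sin(2 * np.pi * centers[band] * t), self.SR, cfg)
        assert (spec.argmax(axis=1) == band).all()

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(InsufficientDataError):
            mel_spectrogram(np.zeros(100), self.SR, SpectrogramConfig())

    @given(n_extra=st.integers(0, 4000))
    @settings(max_examples=20, deadline=None)
    def test_shape_is_pure_function_of_length_and_config(self, n_extra):
        cfg = SpectrogramConfig(window_seconds=0.1, hop_seconds=0.02, n_mel_bands=16)
        n = int(0.1 * self.SR) + n_extra
        spec = mel_spectrogram(np.random.default_rng(n).normal(size=n), self.SR, cfg)
        win, hop = int(0.1 * self.SR), int(0.02 * self.SR)
        assert spec.shape == ((n - win) // hop + 1, 16)

    def test_literal_overlap_mode(self):
        # hop = window - overlap for a literal 10 ms overlap reading
        cfg = SpectrogramConfig(window_seconds=0.5, hop_seconds=0.49)
        spec = mel_spectrogram(np.zeros(self.SR), self.SR, cfg)
        assert spec.shape[0] == (self.SR - 8000) // 7840 + 1


class TestEmbeddingBackend:
    def test_output_dim_contract_enforced(self):
        backend = EmbeddingBackend(embed=lambda s: s.ravel()[:3], output_dim=4)
        with pytest.raises(ValueError, match="shape"):
            backend(np.zeros((2, 4)))

    def test_deterministic_backend_passes_through(self):
        backend = EmbeddingBackend(embed=lambda s: s.mean(axis=0), output_dim=4)
        spec = np.arange(8.0).reshape(2, 4)
        np.testing.assert_array_equal(backend(spec), backend(spec))
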