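"""Wavelet band features, ROI averaging and feature-table assembly."""

import numpy as np
import pandas as pd
import pytest
import pywt

from erpmkl.features import (BandMap, FeatureTable, MissingValenceError,
                             STATISTICS, STATISTICS_5, average_erp,
                             band_statistics, build_feature_table,
                             collapse_valences, dwt_band_decompose,
                             resample_to_analysis_fs, roi_average)
from erpmkl.layout import ROILayout
from erpmkl.synth import BANDS


def _sine_freq(y, fs):
    """Dominant-frequency oracle via the FFT peak."""
    spec = np.abs(np.fft.rfft(y))
    return np.fft.rfftfreq(y.size, 1 / fs)[np.argmax(spec[1:]) + 1]


class TestAverageErp:
    def test_identical_epochs(self, tiny_cohort):
        rec = tiny_cohort[0].copy()
        rec.data[:] = rec.data[0]
        assert np.allclose(average_erp(rec, "neutral"), rec.data[0])

    def test_two_epoch_mean(self, tiny_cohort):
        rec = tiny_cohort[0].copy()
        mask = rec.valences == "positive"
        rec.data[mask] = 0.0
        rec.data[np.flatnonzero(mask)[0]] = 2.0
        erp = average_erp(rec, "positive")
        assert np.allclose(erp, 2.0 / mask.sum())

    def test_missing_valence_raises(self, tiny_cohort):
        rec = tiny_cohort[0]
        sub = rec.copy()
        keep = sub.valences != "negative"
        sub.data = sub.data[keep]
        sub.events = sub.events[keep].reset_index(drop=True)
        with pytest.raises(MissingValenceError):
            average_erp(sub, "negative")

    def test_noise_averaging_reduces_residual(self, rng):
        # ERP residual RMS after averaging n epochs ~ sd/sqrt(n)
        from erpmkl.synth import SynthConfig, make_event_schedule, synth_subject
        config = SynthConfig(n_pos=1, n_neg=1, fs=125.0, noise_sd=5.0,
                             subject_jitter_sd=0.0, artifact_rate=0.0, seed=0)
        sched = make_event_schedule(4, 20, (250, 300), seed=2)
        rec = synth_subject(config, -1, sched, subject_seed=9)
        from erpmkl.synth import valence_template
        template = valence_template(config, "neutral", -1)
        n = (rec.valences == "neutral").sum()
        resid = average_erp(rec, "neutral") - template
        expected = 5.0 / np.sqrt(n)
        assert resid.std() == pytest.approx(expected, rel=0.3)


class TestResample:
    def test_identity(self, rng):
        x = rng.standard_normal((2, 100))
        assert np.array_equal(resample_to_analysis_fs(x, 125.0, 125.0), x)

    def test_length_scaling(self):
        out = resample_to_analysis_fs(np.zeros((3, 1000)), 1000.0, 125.0)
        assert out.shape == (3, 125)

    def test_frequency_preserved(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        y = resample_to_analysis_fs(x[None], 1000.0, 125.0)[0]
        assert _sine_freq(y, 125.0) == pytest.approx(10.0, rel=0.01)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_to_analysis_fs(np.zeros((1, 10)), 125.0, 250.0)


class TestDwtBands:
    def test_zero_signal_zero_coefficients(self):
        bands = dwt_band_decompose(np.zeros(125))
        assert set(bands) == set(BANDS)
        assert all(np.allclose(v, 0) for v in bands.values())

    def test_slow_sinusoid_energy_in_delta(self):
        t = np.arange(250) / 125.0
        bands = dwt_band_decompose(np.sin(2 * np.pi * 2 * t))
        energies = {b: np.sum(v**2) for b, v in bands.items()}
        assert energies["delta"] / sum(energies.values()) >= 0.8

    @pytest.mark.parametrize("freq,band", [(2, "delta"), (6, "theta"),
                                           (12, "alpha"), (24, "beta"),
                                           (45, "gamma")])
    def test_band_center_targeting(self, freq, band):
        t = np.arange(250) / 125.0
        bands = dwt_band_decompose(np.sin(2 * np.pi * freq * t))
        energies = {b: np.sum(v**2) for b, v in bands.items()}
        assert max(energies, key=energies.get) == band

    def test_reconstruction_round_trip(self, rng):
        x = rng.standard_normal(125)
        bands = dwt_band_decompose(x)
        coeffs = [bands[b] for b in BANDS]  # [A4, D4, D3, D2, D1]
        r = pywt.waverec(coeffs, "sym8", mode="symmetric")[: x.size]
        assert np.abs(r - x).max() / np.abs(x).max() <= 1e-8

    def test_energy_partition_orthogonal_mode(self, rng):
        x = rng.standard_normal(256)
        bands = dwt_band_decompose(x, mode="periodization")
        total = sum(np.sum(v**2) for v in bands.values())
        assert total == pytest.approx(np.sum(x**2), rel=1e-10)

    def test_too_short_signal_reports_minimum(self):
        with pytest.raises(ValueError, match="minimum length"):
            dwt_band_decompose(np.zeros(32), mode="periodization")


class TestBandStatistics:
    def test_hand_computed_example(self):
        out = band_statistics(np.array([1.0, 2.0, 3.0, 4.0]))
        expect = dict(zip(STATISTICS, out))
        assert expect["max"] == 4 and expect["min"] == 1
        assert expect["mean"] == 2.5 and expect["median"] == 2.5
        assert expect["variance"] == pytest.approx(1.25)  # population
        assert expect["std"] == pytest.approx(np.sqrt(1.25))

    def test_constant_vector(self):
        out = dict(zip(STATISTICS, band_statistics(np.full(6, 3.0))))
        assert out["variance"] == 0 and out["std"] == 0
        assert out["skewness"] == 0 and out["kurtosis"] == 0

    def test_symmetric_vector_zero_skew(self):
        out = dict(zip(STATISTICS, band_statistics(np.array([-2.0, -1.0, 1.0, 2.0]))))
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_moments(self, rng):
        from scipy import stats as sps
        c = rng.standard_normal(50)
        out = dict(zip(STATISTICS, band_statistics(c)))
        assert out["skewness"] == pytest.approx(sps.skew(c, bias=True))
        assert out["kurtosis"] == pytest.approx(sps.kurtosis(c, fisher=False, bias=True))

    def test_too_few_coefficients_rejected(self):
        with pytest.raises(ValueError):
            band_statistics(np.ones(3))


class TestRoiAverage:
    def test_uniform_roi(self):
        layout = ROILayout(rois={1: ("a", "b"), 2: ("c",)}, labels={})
        arr = np.ones((3, 2, 4))
        out = roi_average(arr, ("a", "b", "c"), layout)
        assert out.shape == (2, 2, 4)
        assert np.allclose(out, 1.0)

    def test_two_channel_mean(self):
        layout = ROILayout(rois={1: ("a", "b")}, labels={})
        arr = np.array([[[1.0]], [[3.0]]])
        assert roi_average(arr, ("a", "b"), layout)[0, 0, 0] == 2.0

    def test_matches_brute_force_groupby(self, rng):
        layout = ROILayout()
        names = tuple(layout.channels)
        arr = rng.standard_normal((64, 5, 8))
        out = roi_average(arr, names, layout)
        for k, roi in enumerate(layout.roi_ids):
            rows = [names.index(ch) for ch in layout.rois[roi]]
            assert np.allclose(out[k], arr[rows].mean(axis=0))

    def test_unmapped_channel_rejected(self):
        layout = ROILayout(rois={1: ("a", "zz")}, labels={})
        with pytest.raises(ValueError, match="zz"):
            roi_average(np.ones((1, 2, 2)), ("a",), layout)


class TestFeatureTable:
    def test_source_counts_and_widths(self, planted_table):
        per_valence = planted_table.sources_for_valence("positive")
        assert len(per_valence) == 40  # 8 ROIs x 5 bands
        assert planted_table.source_block(per_valence[0]).shape[1] == 8
        assert planted_table.df.shape[1] == 3 * 40 * 8

    def test_five_statistic_preset_gives_200_per_valence(self, tiny_cohort):
        table = build_feature_table(tiny_cohort, statistic_set=STATISTICS_5)
        per_valence = [c for c in table.df.columns if c[0] == "positive"]
        assert len(per_valence) == 200  # 8 x 5 x 5

    def test_collapsed_width_24(self, planted_table):
        collapsed = collapse_valences(planted_table)
        assert len(collapsed.source_ids) == 40
        assert collapsed.source_block(collapsed.source_ids[0]).shape[1] == 24

    def test_collapsed_width_with_five_stats(self, tiny_cohort):
        table = build_feature_table(tiny_cohort, statistic_set=STATISTICS_5)
        collapsed = collapse_valences(table)
        assert collapsed.source_block(collapsed.source_ids[0]).shape[1] == 15

    def test_collapse_preserves_values(self, planted_table):
        collapsed = collapse_valences(planted_table)
        src = ("negative", 3, "alpha")
        block = planted_table.source_block(src)
        cblock = collapsed.source_block((3, "alpha"))
        assert np.allclose(cblock[:, :8], block)  # negative comes first

    def test_single_valence_collapse_rejected(self, tiny_cohort):
        table = build_feature_table(tiny_cohort, valences=("positive",))
        with pytest.raises(ValueError):
            collapse_valences(table)

    def test_single_valence_table_shape(self, tiny_cohort):
        table = build_feature_table(tiny_cohort[:1], valences=("neutral",))
        assert table.df.shape == (1, 40 * 8)
        assert len(table.source_ids) == 40

    def test_tsv_round_trip(self, tiny_cohort, tmp_path):
        table = build_feature_table(tiny_cohort)
        path = tmp_path / "features.tsv"
        table.to_tsv(path)
        back = FeatureTable.from_tsv(path)
        assert np.allclose(back.df.to_numpy(), table.df.to_numpy())
        assert list(back.groups) == list(table.groups)
        assert back.source_ids == table.source_ids

    def test_inconsistent_channels_rejected(self, tiny_cohort):
        bad = tiny_cohort[0].copy()
        names = list(bad.channel_names)
        names[0] = "XX"
        bad.channel_names = tuple(names)
        with pytest.raises(ValueError, match="inconsistent"):
            build_feature_table([tiny_cohort[1], bad])


class TestBandMap:
    def test_default_edges_close_to_stated_bands(self):
        BandMap()  # validates internally

    def test_wrong_rate_rejected(self):
        with pytest.raises(ValueError):
            BandMap(analysis_fs=1000.0)
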