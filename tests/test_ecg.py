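"""ECG preprocessing: resampling, R-peak detection, QRS windows, grouping."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofusion import ecg
from biofusion.synthetic import generate_ecg_record, generate_phenotypes


@pytest.fixture(scope="module")
def phenotype():
    ph = generate_phenotypes(1, 1.0, seed=7)[0]
    ph.ecg["rr_s"] = 0.8  # exactly 75 bpm
    return ph


@pytest.fixture(scope="module")
def clean_record(phenotype):
    return generate_ecg_record(phenotype, seed=3, noise_sd=0.0, rr_jitter_sd=0.0)


class TestResample:
    def test_exact_decimation_length(self):
        rec = ecg.EcgRecord(np.sin(np.arange(10_000) * 0.01), 1000.0)
        out = ecg.resample_record(rec, 500.0)
        assert out.sampling_rate == 500.0
        assert len(out.samples) == 5_000

    def test_identity_when_already_at_rate(self, rng):
        rec = ecg.EcgRecord(rng.normal(size=2_000), 500.0, "s1")
        out = ecg.resample_record(rec, 500.0)
        assert out is not rec
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_sinusoid_matches_closed_form(self):
        t = np.arange(10_000) / 1000.0
        rec = ecg.EcgRecord(np.sin(2 * np.pi * 5.0 * t), 1000.0)
        out = ecg.resample_record(rec, 500.0)
        t2 = np.arange(len(out.samples)) / 500.0
        assert np.max(np.abs(out.samples - np.sin(2 * np.pi * 5.0 * t2))) < 1e-3

    def test_duration_preserved_for_noninteger_ratio(self, rng):
        rec = ecg.EcgRecord(rng.normal(size=3_000), 360.0)
        out = ecg.resample_record(rec, 500.0)
        assert abs(out.duration_s - rec.duration_s) <= 1.0 / 500.0

    def test_empty_signal_rejected(self):
        rec = ecg.EcgRecord(np.array([]), 1000.0)
        with pytest.raises(ValueError):
            ecg.resample_record(rec, 500.0)


class TestDetectRPeaks:
    def test_known_positions_recovered(self, clean_record):
        truth = np.array(clean_record.meta["r_peaks"])
        found = ecg.detect_r_peaks(clean_record)
        assert len(found) == len(truth)
        assert np.max(np.abs(found - truth)) <= 2

    def test_25_beats_in_20s_at_75bpm(self, clean_record):
        assert len(ecg.detect_r_peaks(clean_record)) == 25

    def test_all_zero_signal_gives_empty(self):
        rec = ecg.EcgRecord(np.zeros(10_000), 500.0)
        assert len(ecg.detect_r_peaks(rec)) == 0

    def test_indices_strictly_increasing_with_refractory(self, phenotype):
        rec = generate_ecg_record(phenotype, seed=11)
        peaks = ecg.detect_r_peaks(rec)
        diffs = np.diff(peaks)
        assert np.all(diffs > 0)
        assert np.all(diffs >= int(ecg.REFRACTORY_S * rec.sampling_rate))

    def test_recall_and_precision_on_noisy_records(self):
        phs = generate_phenotypes(5, 0.5, seed=21)
        tp = fp = fn = 0
        for i, ph in enumerate(phs):
            rec = generate_ecg_record(ph, seed=100 + i)
            truth = np.array(rec.meta["r_peaks"])
            found = ecg.detect_r_peaks(rec)
            matched = set()
            for f in found:
                d = np.abs(truth - f)
                j = int(np.argmin(d))
                if d[j] <= 10 and j not in matched:
                    matched.add(j)
                    tp += 1
                else:
                    fp += 1
            fn += len(truth) - len(matched)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95


class TestMinmaxNormalize:
    def test_simple_case(self):
        np.testing.assert_allclose(ecg.minmax_normalize([0, 5, 10]), [0, 0.5, 1])

    def test_constant_maps_to_zeros(self):
        np.testing.assert_array_equal(ecg.minmax_normalize([2, 2, 2]), np.zeros(3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecg.minmax_normalize(np.array([]))

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_range_and_order_preserved(self, seed):
        v = np.random.default_rng(seed).normal(size=300)
        out = ecg.minmax_normalize(v)
        assert out.min() == 0.0 and out.max() == 1.0
        np.testing.assert_array_equal(np.argsort(out, kind="stable"),
                                      np.argsort(v, kind="stable"))


class TestExtractQrs:
    def test_window_length_300(self, clean_record):
        q = ecg.extract_qrs(clean_record, clean_record.meta["r_peaks"][3])
        assert q.values.shape == (300,)
        assert q.values.min() == 0.0 and q.values.max() == 1.0

    def test_boundary_peak_skipped(self, clean_record):
        assert ecg.extract_qrs(clean_record, 10) is None
        assert ecg.extract_qrs(clean_record, len(clean_record.samples) - 10) is None

    def test_ramp_matches_two_pass_oracle(self):
        n = 2_000
        rec = ecg.EcgRecord(np.arange(n, dtype=float), 500.0)
        peak = 1_000
        q = ecg.extract_qrs(rec, peak)
        window = rec.samples[peak - 150 : peak + 150]
        lo, hi = min(window), max(window)  # independent two-pass min/max
        np.testing.assert_allclose(q.values, (window - lo) / (hi - lo))


class TestGroupComplexes:
    @staticmethod
    def _complexes(n, rng):
        return [ecg.QrsComplex(ecg.minmax_normalize(rng.normal(size=300)), 200 * i)
                for i in range(n)]

    @pytest.mark.parametrize("n,expected", [(15, 5), (2, 0), (7, 2)])
    def test_floor_rule(self, n, expected, rng):
        seqs = ecg.group_complexes(self._complexes(n, rng))
        assert len(seqs) == expected

    def test_consecutive_temporal_order(self, rng):
        cx = self._complexes(7, rng)
        seqs = ecg.group_complexes(cx)
        np.testing.assert_array_equal(seqs[0].complexes[0], cx[0].values)
        np.testing.assert_array_equal(seqs[1].complexes[2], cx[5].values)

    def test_too_few_logs_warning(self, rng, caplog):
        with caplog.at_level(logging.WARNING, logger="biofusion.ecg"):
            out = ecg.group_complexes(self._complexes(2, rng))
        assert out == []
        assert any("complexes" in r.message for r in caplog.records)

    def test_random_mode_is_seeded(self, rng):
        cx = self._complexes(10, rng)
        a = ecg.group_complexes(cx, mode="random", n_sequences=4,
                                rng=np.random.default_rng(5))
        b = ecg.group_complexes(cx, mode="random", n_sequences=4,
                                rng=np.random.default_rng(5))
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.complexes, s2.complexes)


class TestPipeline:
    def test_generator_records_yield_at_least_15_complexes(self):
        for i, ph in enumerate(generate_phenotypes(3, 0.5, seed=31)):
            rec = generate_ecg_record(ph, seed=50 + i)
            seqs = ecg.record_to_sequences(rec)
            assert len(seqs) >= 5  # >= 15 complexes grouped in threes
            for s in seqs:
                assert s.complexes.shape == (3, 300)
                assert s.complexes.min() >= 0.0 and s.complexes.max() <= 1.0

    def test_pipeline_deterministic(self, clean_record):
        a = ecg.record_to_sequences(clean_record)
        b = ecg.record_to_sequences(clean_record)
        assert len(a) == len(b)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.complexes, s2.complexes)


class TestIO:
    def test_record_roundtrip(self, tmp_path, clean_record):
        path = tmp_path / "rec.txt"
        ecg.write_record_txt(clean_record, path)
        back = ecg.read_record_txt(path)
        assert back.sampling_rate == clean_record.sampling_rate
        np.testing.assert_allclose(back.samples, clean_record.samples, atol=1e-6)
        assert back.meta["gender"] == clean_record.meta["gender"]

    def test_sequence_roundtrip(self, tmp_path, clean_record):
        seqs = ecg.record_to_sequences(clean_record)
        path = tmp_path / "seqs"
        ecg.write_sequences(seqs, path)
        back = ecg.read_sequences(path)
        assert len(back) == len(seqs)
        np.testing.assert_array_equal(back[0].complexes, seqs[0].complexes)
        assert back[0].subject_id == seqs[0].subject_id
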