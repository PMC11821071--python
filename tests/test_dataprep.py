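"""Record I/O, resampling, segmentation, noise splits, RMN corruption."""

import numpy as np
import pytest

from fgdae.dataprep import (
    COMBINATION_FLAGS,
    NoiseRecipe,
    NoiseSplit,
    PairSet,
    SEGMENT_LENGTH,
    SignalSegment,
    TEST_RECORD_IDS,
    build_benchmark,
    corrupt_segment,
    load_record,
    make_noise_splits,
    resample_signal,
    sample_rmn_recipe,
    segment_signal,
    write_wfdb_record,
)


class TestRecordIO:
    def test_csv_roundtrip(self, tmp_path, rng):
        p = tmp_path / "ecg.csv"
        data = rng.standard_normal((100, 2))
        p.write_text(
            "# fs=360\nch0,ch1\n"
            + "\n".join(",".join(f"{v:.8f}" for v in row) for row in data)
        )
        sig, fs = load_record(p)
        assert fs == 360 and sig.shape == (100, 2)
        assert np.abs(sig - data).max() < 1e-7

    def test_wfdb_format16_roundtrip(self, tmp_path, rng):
        sig = rng.standard_normal((1500, 2)) * 0.8
        write_wfdb_record(tmp_path / "rec", sig, fs=250, gain=1000)
        back, fs = load_record(tmp_path / "rec.hea")
        assert fs == 250 and back.shape == sig.shape
        assert np.abs(back - sig).max() <= 0.5 / 1000 + 1e-12  # quantization bound

    def test_wfdb_format212_reader(self, tmp_path, rng):
        """Hand-pack 12-bit samples and check the reader recovers them."""
        digital = rng.integers(-2048, 2048, size=(200, 2)).astype(np.int32)
        flat = digital.reshape(-1)
        raw = bytearray()
        for i in range(0, len(flat), 2):
            a, b = int(flat[i]) & 0xFFF, int(flat[i + 1]) & 0xFFF
            raw += bytes([a & 0xFF, ((b >> 4) & 0xF0) | ((a >> 8) & 0x0F), b & 0xFF])
        (tmp_path / "r212.dat").write_bytes(bytes(raw))
        (tmp_path / "r212.hea").write_text(
            "r212 2 360 200\nr212.dat 212 200(0)/mV 12 0 0 0 0 ch0\n"
            "r212.dat 212 200(0)/mV 12 0 0 0 0 ch1\n"
        )
        sig, fs = load_record(tmp_path / "r212.hea")
        assert fs == 360
        assert np.array_equal(np.round(sig * 200).astype(int), digital)

    def test_missing_dat_raises(self, tmp_path):
        (tmp_path / "ghost.hea").write_text("ghost 1 360 10\nghost.dat 16 200(0)/mV 16 0 0 0 0 x\n")
        with pytest.raises(FileNotFoundError):
            load_record(tmp_path / "ghost.hea")

    def test_malformed_header_raises(self, tmp_path):
        (tmp_path / "bad.hea").write_text("bad\n")
        with pytest.raises(ValueError):
            load_record(tmp_path / "bad.hea")


class TestResample:
    def test_identity_when_rates_match(self, rng):
        x = rng.standard_normal(1000)
        assert np.array_equal(resample_signal(x, 360, 360), x)

    def test_qtdb_length_scaling(self):
        # 15 min at 250 Hz -> 360 Hz
        assert len(resample_signal(np.zeros(225_000), 250, 360)) == 324_000

    def test_sine_against_analytic_oracle(self):
        fs_in, fs_out, f0 = 250.0, 360.0, 1.0
        t_in = np.arange(int(20 * fs_in)) / fs_in
        y = resample_signal(np.sin(2 * np.pi * f0 * t_in), fs_in, fs_out)
        t_out = np.arange(len(y)) / fs_out
        ref = np.sin(2 * np.pi * f0 * t_out)
        interior = slice(500, -500)
        rms = np.sqrt(np.mean((y[interior] - ref[interior]) ** 2))
        assert rms < 1e-3


class TestSegmentation:
    @pytest.mark.parametrize("n,expected", [(511, 0), (512, 1), (1024, 3), (324_000, 1264)])
    def test_window_counts(self, n, expected, rng):
        segs = segment_signal(rng.standard_normal(n) + 1.0)
        assert len(segs) == expected

    def test_grid_and_zero_mean(self, rng):
        segs = segment_signal(rng.standard_normal(2000) + 3.0)
        for s in segs:
            assert s.start_index % 256 == 0
            assert len(s.samples) == SEGMENT_LENGTH
            assert abs(s.samples.mean()) < 1e-9

    def test_no_amplitude_normalization(self):
        x = np.zeros(512)
        x[100] = 7.0
        seg = segment_signal(x)[0]
        assert seg.samples.max() == pytest.approx(7.0 - 7.0 / 512)


class TestNoiseSplits:
    def _noise(self, rng):
        return {t: rng.standard_normal((1000, 2)) for t in ("bw", "ma", "em")}

    def test_nv1_and_nv2_assignments(self, rng):
        n = self._noise(rng)
        tr1, te1 = make_noise_splits(n["bw"], n["ma"], n["em"], "nv1")
        assert np.array_equal(tr1.series["bw"], n["bw"][:500, 0])  # channel 1_a
        assert np.array_equal(te1.series["bw"], n["bw"][500:, 1])  # channel 2_b
        tr2, te2 = make_noise_splits(n["bw"], n["ma"], n["em"], "nv2")
        assert np.array_equal(tr2.series["ma"], n["ma"][:500, 1])  # channel 2_a
        assert np.array_equal(te2.series["ma"], n["ma"][500:, 0])  # channel 1_b

    def test_train_test_sources_disjoint(self, rng):
        n = self._noise(rng)
        for v in ("nv1", "nv2"):
            tr, te = make_noise_splits(n["bw"], n["ma"], n["em"], v)
            for t in ("bw", "ma", "em"):
                # different channel AND different half: no shared values
                assert not np.intersect1d(tr.series[t], te.series[t]).size

    def test_single_channel_noise_rejected(self, rng):
        with pytest.raises(ValueError):
            make_noise_splits(rng.standard_normal((100, 1)),
                              rng.standard_normal((100, 2)),
                              rng.standard_normal((100, 2)))


@pytest.fixture()
def split(rng):
    return NoiseSplit("nv1", "train", {t: rng.standard_normal(3000) for t in ("bw", "ma", "em")})


class TestRecipeSampling:
    def test_deterministic_under_seed(self, split):
        def draw():
            r = np.random.default_rng(99)
            return [sample_rmn_recipe(r, split) for _ in range(20)]

        a, b = draw(), draw()
        assert all(
            r1.combination == r2.combination and r1.scale_a == r2.scale_a
            and r1.noise_offsets == r2.noise_offsets
            for r1, r2 in zip(a, b)
        )

    def test_combination_frequencies_uniform(self, split):
        from scipy.stats import chisquare

        r = np.random.default_rng(5)
        n = 80_000
        counts = np.bincount(
            [sample_rmn_recipe(r, split).combination for _ in range(n)], minlength=9
        )[1:]
        # goodness of fit against the uniform 1/8 law over all 8 bins
        assert chisquare(counts).pvalue > 1e-3
        se = np.sqrt(n * (1 / 8) * (7 / 8))
        assert np.abs(counts - n / 8).max() < 4 * se

    def test_scales_within_range_and_offsets_valid(self, split):
        r = np.random.default_rng(6)
        for _ in range(500):
            rec = sample_rmn_recipe(r, split)
            assert 0.2 <= rec.scale_a <= 2.0
            for t, off in rec.noise_offsets.items():
                assert 0 <= off <= len(split.series[t]) - SEGMENT_LENGTH


class TestCorruption:
    def _segment(self, rng):
        x = rng.standard_normal(SEGMENT_LENGTH)
        return SignalSegment(x - x.mean())

    def test_clean_combination_is_bit_identical(self, split, rng):
        seg = self._segment(rng)
        rec = NoiseRecipe(combination=1, scale_a=1.0)
        assert np.array_equal(corrupt_segment(seg, split, rec).samples, seg.samples)

    def test_noise_peak_matches_scale_exactly(self, split, rng):
        r = np.random.default_rng(7)
        for _ in range(50):
            seg = self._segment(rng)
            rec = sample_rmn_recipe(r, split)
            if rec.combination == 1:
                continue
            noisy = corrupt_segment(seg, split, rec)
            ratio = np.max(np.abs(noisy.samples - seg.samples)) / np.max(np.abs(seg.samples))
            assert ratio == pytest.approx(rec.scale_a, abs=1e-9)

    def test_corruption_is_purely_additive(self, split, rng):
        """noisy - clean reconstructs the scaled noise slice sum exactly."""
        seg = self._segment(rng)
        rec = NoiseRecipe(combination=4, scale_a=1.3, noise_offsets={"bw": 10, "ma": 700})
        noisy = corrupt_segment(seg, split, rec)
        combined = split.series["bw"][10:522] + split.series["ma"][700:1212]
        scale = 1.3 * np.max(np.abs(seg.samples)) / np.max(np.abs(combined))
        assert np.abs((noisy.samples - seg.samples) - combined * scale).max() < 1e-12

    def test_zero_amplitude_clean_rejected(self, split):
        seg = SignalSegment(np.zeros(SEGMENT_LENGTH))
        rec = NoiseRecipe(combination=2, scale_a=1.0, noise_offsets={"bw": 0})
        with pytest.raises(ValueError):
            corrupt_segment(seg, split, rec)


class TestBuildBenchmark:
    def _records(self, rng, names, n=2048, fs=250.0):
        return {
            name: (np.cumsum(rng.standard_normal((n, 2)), axis=0) * 0.01 + 0.5, fs)
            for name in names
        }

    def test_split_and_determinism(self, rng):
        records = self._records(rng, ["sel123", "train01", "train02"])
        noise = {t: rng.standard_normal((8000, 2)) for t in ("bw", "ma", "em")}
        tr1, te1 = build_benchmark(records, noise, "nv1", seed=3)
        tr2, te2 = build_benchmark(records, noise, "nv1", seed=3)
        assert np.array_equal(tr1.noisy, tr2.noisy) and np.array_equal(te1.noisy, te2.noisy)
        # sel123 is a canonical test subject; the other two records train
        n_seg_per_channel = (int(2048 * 360 / 250) - 512) // 256 + 1
        assert len(te1) == 2 * n_seg_per_channel
        assert len(tr1) == 4 * n_seg_per_channel

    def test_canonical_test_ids_count(self):
        assert len(TEST_RECORD_IDS) == 14

    def test_unknown_custom_test_id_rejected(self, rng):
        records = self._records(rng, ["a"])
        noise = {t: rng.standard_normal((4000, 2)) for t in ("bw", "ma", "em")}
        with pytest.raises(ValueError):
            build_benchmark(records, noise, test_ids=["nonexistent"])

    def test_pairset_roundtrip(self, tmp_path, tiny_benchmark):
        tr, _ = tiny_benchmark
        tr.save(tmp_path / "pairs.npz")
        back = PairSet.load(tmp_path / "pairs.npz")
        assert np.array_equal(back.noisy, tr.noisy)
        assert np.array_equal(back.clean, tr.clean)
        assert [r.combination for r in back.recipes] == [r.combination for r in tr.recipes]


def test_combination_table_flags():
    assert COMBINATION_FLAGS[1] == (False, False, False)
    assert COMBINATION_FLAGS[4] == (True, True, False)
    assert COMBINATION_FLAGS[8] == (True, True, True)
    assert len(COMBINATION_FLAGS) == 8
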