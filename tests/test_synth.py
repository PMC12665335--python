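"""Generator contracts: reproducibility, dominance ratio, coupling limits."""

import numpy as np
import pytest

from costructure import ingest
from costructure.dtw import FEATURE_COLUMNS, build_distance_table
from costructure.kinematics import kinetic_energy
from costructure.synth import SynthConfig, generate_dataset, synthesize_audio, write_dataset


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"coupling": 1.2}, "λ|coupling"),
            ({"coupling": -0.1}, "λ|coupling"),
            ({"duration_range_s": (1.0, 3.0)}, "duration"),
            ({"duration_range_s": (3.0, 2.0)}, "duration"),
            ({"sonic_rate_hz": 0.0}, "rate"),
            ({"sonic_noise_sd": -1.0}, "noise"),
            ({"hand_dominance_ratio": 1.0}, "dominance"),
            ({"warp_strength": -0.5}, "warp"),
        ],
    )
    def test_invalid_config_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            SynthConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SynthConfig(n_performers=2, motifs_per_performer=4, seed=42)
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        assert d1.motif_table == d2.motif_table
        assert d1.class_labels == d2.class_labels
        for m in d1.sonic:
            assert np.array_equal(d1.sonic[m].f0, d2.sonic[m].f0)
            assert np.array_equal(d1.kinematic[m].hand_pos, d2.kinematic[m].hand_pos)

    def test_different_seed_differs(self):
        d1 = generate_dataset(SynthConfig(n_performers=1, motifs_per_performer=3, seed=1))
        d2 = generate_dataset(SynthConfig(n_performers=1, motifs_per_performer=3, seed=2))
        m1, m2 = d1.motif_table[0].motif_id, d2.motif_table[0].motif_id
        assert not np.array_equal(d1.sonic[m1].f0[:50], d2.sonic[m2].f0[:50])


class TestStructure:
    def test_every_motif_has_all_series_and_label(self, coupled_dataset):
        ds = coupled_dataset
        for rec in ds.motif_table:
            assert rec.motif_id in ds.class_labels
            sf, kf = ds.sonic[rec.motif_id], ds.kinematic[rec.motif_id]
            for feat in FEATURE_COLUMNS:
                arr = getattr(sf, feat, None)
                if arr is None:
                    arr = getattr(kf, feat)
                assert len(arr) > 0
            assert kf.in_left_hand_space

    def test_durations_respect_floor(self, coupled_dataset):
        for rec in coupled_dataset.motif_table:
            assert rec.duration_s >= 1.5

    def test_class_labels_within_range(self, coupled_dataset):
        labels = set(coupled_dataset.class_labels.values())
        assert labels <= set(range(coupled_dataset.config.n_classes))


class TestHandDominance:
    def test_noise_free_ratio_within_ten_percent(self):
        cfg = SynthConfig(
            n_performers=2, motifs_per_performer=6, kinematic_noise_sd=0.0,
            hand_dominance_ratio=3.0, seed=5,
        )
        ds = generate_dataset(cfg)
        ratios = np.array([ds.kinematic[m].energy_ratio for m in ds.kinematic])
        assert np.all(np.abs(ratios - 3.0) / 3.0 < 0.10)

    def test_dominant_hand_selected_consistently(self):
        cfg = SynthConfig(n_performers=3, motifs_per_performer=5, kinematic_noise_sd=0.0, seed=8)
        ds = generate_dataset(cfg)
        # with noise-free generation the selected hand is the energetic one
        for m, kf in ds.kinematic.items():
            assert kf.energy_ratio > 1.0


class TestCouplingLimits:
    def test_degenerate_limit_within_class_distances_vanish(self):
        """λ=1, no noise, no warp, fixed duration: same class ⇒ identical motifs."""
        cfg = SynthConfig(
            n_performers=1, motifs_per_performer=12, n_classes=2, coupling=1.0,
            sonic_noise_sd=0.0, kinematic_noise_sd=0.0, warp_strength=0.0,
            duration_range_s=(2.0, 2.0), seed=3,
        )
        ds = generate_dataset(cfg)
        table = build_distance_table(ds.sonic, ds.kinematic, ds.motif_frame())
        lab = ds.class_labels
        same = np.array([lab[i] == lab[j] for i, j in zip(table.motif_i, table.motif_j)])
        assert same.any() and (~same).any()
        for feat in FEATURE_COLUMNS:
            d = table[feat].to_numpy()
            assert np.all(d[same] < 1e-9)
            assert d[~same].min() > 0

    def test_degenerate_limit_value_channels_with_variable_duration(self):
        """With variable durations the value channels still collapse within class.

        Derivative channels do not: traversing the same prototype faster
        scales per-frame derivatives, which time warping cannot absorb.
        """
        cfg = SynthConfig(
            n_performers=1, motifs_per_performer=12, n_classes=2, coupling=1.0,
            sonic_noise_sd=0.0, kinematic_noise_sd=0.0, warp_strength=0.0, seed=3,
        )
        ds = generate_dataset(cfg)
        table = build_distance_table(ds.sonic, ds.kinematic, ds.motif_frame())
        lab = ds.class_labels
        same = np.array([lab[i] == lab[j] for i, j in zip(table.motif_i, table.motif_j)])
        for feat in ("f0", "loudness", "spectral_centroid", "hand_pos", "head_pos"):
            d = table[feat].to_numpy()
            assert d[same].mean() < 0.1 * d[~same].mean()

    def test_uncoupled_value_cells_near_zero(self):
        """λ=0: gesture carries no melodic-class information in value channels."""
        from scipy.stats import spearmanr

        cfg = SynthConfig(n_performers=3, motifs_per_performer=10, coupling=0.0, seed=7)
        ds = generate_dataset(cfg)
        table = build_distance_table(ds.sonic, ds.kinematic, ds.motif_frame())
        for sf in ("f0", "loudness", "spectral_centroid"):
            for kf in ("hand_pos", "head_pos"):
                rho = spearmanr(table[sf], table[kf]).statistic
                assert abs(rho) < 0.12, (sf, kf, rho)


class TestAudioSynth:
    def test_constant_contour_roundtrip(self):
        from costructure.sonic import estimate_f0

        n = 200
        wav = synthesize_audio(np.full(n, 440.0), np.full(n, 0.9), 48000, 100.0)
        f0, voiced = estimate_f0(wav, 48000, 100.0)
        assert np.nanmedian(f0[voiced]) == pytest.approx(440.0, rel=0.01)

    def test_unvoiced_gap_rendered_silent(self):
        contour = np.full(100, 300.0)
        contour[40:60] = np.nan
        wav = synthesize_audio(contour, np.full(100, 1.0), 8000, 100.0)
        gap = wav[int(0.45 * 8000): int(0.55 * 8000)]
        assert np.abs(gap).max() < 0.05

    def test_phase_continuity(self):
        contour = np.linspace(200, 400, 100)
        wav = synthesize_audio(contour, np.full(100, 1.0), 8000, 100.0, n_harmonics=1)
        assert np.abs(np.diff(wav)).max() < 2 * np.pi * 400 / 8000 * 1.2

    def test_empty_contour_errors(self):
        with pytest.raises(ValueError, match="empty"):
            synthesize_audio(np.array([]), np.array([]), 8000)

    def test_envelope_bounds_enforced(self):
        with pytest.raises(ValueError, match="envelope"):
            synthesize_audio(np.full(10, 100.0), np.full(10, 1.5), 8000)


class TestDiskRoundTrip:
    def test_written_layout_is_ingestible(self, tmp_path):
        cfg = SynthConfig(n_performers=2, motifs_per_performer=3, seed=9)
        ds = generate_dataset(cfg)
        write_dataset(ds, tmp_path)
        records = ingest.read_motif_table(tmp_path / "motif_table.csv")
        assert len(records) == 6
        perf = records[0].performance_id
        frames = ingest.read_kinematics(tmp_path / f"{perf}_kin.csv")
        assert set(frames) == set(ingest.SEGMENTS)
        t, f0 = ingest.read_feature_series(tmp_path / f"{perf}_f0.csv", "f0")
        sliced = ingest.slice_motif(f0, cfg.sonic_rate_hz, records[0])
        assert np.all(np.isfinite(sliced))
        assert len(sliced) == len(ds.sonic[records[0].motif_id].f0)
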