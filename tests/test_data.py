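import numpy as np
import pytest

from mstnn.data import (
    ConcatenationSpec,
    OcclusionSpec,
    SyntheticActionSpec,
    VideoSequence,
    append_black_frames,
    apply_occlusion,
    concatenate_actions,
    generate_synthetic_action,
    load_dataset,
    loso_splits,
    make_action_dataset,
    make_concatenated_dataset,
    make_order_discrimination_dataset,
    normalize_frames,
    occlusion_mask,
    read_sequence,
    write_manifest,
    write_sequence,
)


class TestVideoSequence:
    def test_rejects_out_of_range_intensities(self):
        with pytest.raises(ValueError):
            VideoSequence(np.full((2, 4, 4), 1.5), 0, "s0")

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            VideoSequence(np.zeros((0, 4, 4)), 0, "s0")


class TestIO:
    def test_roundtrip_through_png(self, tmp_path, rng):
        frames = (rng.random((8, 12, 10)) > 0.5).astype(float)
        seq = VideoSequence(frames, 2, "s3", "synthetic", name="seq_a")
        write_sequence(seq, tmp_path / "seq_a")
        loaded = read_sequence(tmp_path / "seq_a", 2, "s3")
        assert loaded.T == 8
        assert np.allclose(loaded.frames, frames)  # binary survives 8-bit exactly

    def test_full_intensity_maps_to_one(self, tmp_path):
        seq = VideoSequence(np.ones((1, 4, 4)), 0, "s0")
        write_sequence(seq, tmp_path / "w")
        assert read_sequence(tmp_path / "w", 0, "s0").frames.max() == 1.0

    def test_empty_directory_rejected(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FileNotFoundError):
            read_sequence(tmp_path / "empty", 0, "s0")

    def test_manifest_roundtrip(self, tmp_path):
        ds = make_action_dataset(n_subjects=2, length=5, seed=0)
        manifest = write_manifest(ds, tmp_path / "data")
        loaded = load_dataset(manifest)
        assert len(loaded) == len(ds)
        assert [s.label for s in loaded] == [s.label for s in ds]
        assert [s.subject for s in loaded] == [s.subject for s in ds]


class TestNormalize:
    def test_constant_frame_stays_constant(self):
        seq = VideoSequence(np.full((2, 10, 12), 0.4), 0, "s0")
        out = normalize_frames(seq)
        assert out.shape == (48, 54)
        assert np.allclose(out.frames, 0.4, atol=1e-9)

    def test_identity_when_already_target_size(self, rng):
        seq = VideoSequence(rng.random((2, 48, 54)), 0, "s0")
        out = normalize_frames(seq)
        assert np.allclose(out.frames, seq.frames)

    def test_downsampling_preserves_mean_intensity(self):
        """A 96x108 checkerboard halved in size keeps its mean within 1%
        (cross-checked against the exact box-filter average 0.5)."""
        r, c = np.mgrid[0:96, 0:108]
        board = (((r // 4) + (c // 4)) % 2).astype(float)
        seq = VideoSequence(np.tile(board, (2, 1, 1)), 0, "s0")
        out = normalize_frames(seq, 48, 54)
        assert abs(out.frames.mean() - 0.5) < 0.01

    def test_degenerate_target_rejected(self, rng):
        seq = VideoSequence(rng.random((1, 8, 8)), 0, "s0")
        with pytest.raises(ValueError):
            normalize_frames(seq, 1, 54)


class TestBlackFrames:
    def test_lengths_add(self, rng):
        seq = VideoSequence(rng.random((84, 6, 7)), 0, "s0")
        out = append_black_frames(seq, 15)
        assert out.T == 99
        assert np.all(out.frames[-15:] == 0.0)

    def test_zero_delay_rejected(self, rng):
        seq = VideoSequence(rng.random((4, 6, 7)), 0, "s0")
        with pytest.raises(ValueError):
            append_black_frames(seq, 0)


class TestOcclusion:
    def test_zero_width_is_identity(self, rng):
        seq = VideoSequence(rng.random((5, 8, 20)), 0, "s0")
        out = apply_occlusion(seq, OcclusionSpec(bar_width=0))
        assert np.array_equal(out.frames, seq.frames)

    def test_half_of_each_period_masked(self):
        occ = OcclusionSpec(bar_width=5, gap=5)
        mask = occlusion_mask(50, 0, occ)
        # 50 columns = 5 full periods of 10; exactly half masked
        assert mask.sum() == 25

    def test_mask_moves_two_pixels_left_per_frame(self):
        occ = OcclusionSpec(bar_width=10, gap=5, speed=2)
        m0 = occlusion_mask(54, 3, occ)
        m1 = occlusion_mask(54, 4, occ)
        assert np.array_equal(m1, np.roll(m0, -2))

    def test_bar_flush_with_right_edge_at_start(self):
        occ = OcclusionSpec(bar_width=7, gap=5)
        mask = occlusion_mask(54, 0, occ)
        assert mask[-1]  # rightmost column covered
        assert mask[-7:].all() and not mask[-8]

    def test_idempotent_and_commutes_with_black_frames(self, rng):
        seq = VideoSequence((rng.random((6, 8, 20)) > 0.5).astype(float), 0, "s0")
        occ = OcclusionSpec(bar_width=5, gap=5)
        once = apply_occlusion(seq, occ)
        twice = apply_occlusion(once, occ)
        assert np.array_equal(once.frames, twice.frames)
        a = append_black_frames(apply_occlusion(seq, occ), 3)
        b = apply_occlusion(append_black_frames(seq, 3), occ)
        assert np.array_equal(a.frames, b.frames)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            OcclusionSpec(bar_width=-1)
        with pytest.raises(ValueError):
            OcclusionSpec(bar_width=5, gap=0)


class TestConcatenation:
    @pytest.fixture
    def base(self):
        return make_action_dataset(n_subjects=2, length=42, seed=1)

    def test_total_length_and_black_tail(self, base):
        spec = ConcatenationSpec()
        out = concatenate_actions(base[0], base[1], spec)
        assert out.T == 42 + 42 + 15 == 99
        assert np.all(out.frames[-15:] == 0.0)

    def test_ordered_pairs_get_distinct_labels(self, base):
        spec = ConcatenationSpec()
        ab = concatenate_actions(base[0], base[1], spec)
        ba = concatenate_actions(base[1], base[0], spec)
        assert ab.label != ba.label
        assert ab.label == base[0].label * 3 + base[1].label

    def test_dataset_counts(self):
        base = make_action_dataset(n_subjects=9, length=42, seed=0)
        derived = make_concatenated_dataset(base)
        assert len(derived) == 81  # 3 x 3 ordered pairs x 9 subjects
        assert all(s.T == 99 for s in derived)
        assert len({s.label for s in derived}) == 9

    def test_subject_mismatch_rejected(self, base):
        a = [s for s in base if s.subject == "s00"][0]
        b = [s for s in base if s.subject == "s01"][0]
        with pytest.raises(ValueError, match="subject"):
            concatenate_actions(a, b, ConcatenationSpec())

    def test_short_source_rejected(self, base):
        short = VideoSequence(base[0].frames[:10], 0, base[0].subject)
        with pytest.raises(ValueError):
            concatenate_actions(short, base[1], ConcatenationSpec())


class TestSyntheticGenerator:
    def test_same_seed_bit_identical(self):
        spec = SyntheticActionSpec(archetype="bounce", length=10, seed=42)
        a = generate_synthetic_action(spec)
        b = generate_synthetic_action(spec)
        assert np.array_equal(a.frames, b.frames)

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_action(SyntheticActionSpec(archetype="cartwheel"))

    def test_reversed_pair_shares_frame_multiset(self):
        """The order-discrimination classes are exact time reversals, so
        their per-frame pixel histograms match frame for frame."""
        common = dict(length=12, seed=3, phase=0.7, noise_rate=0.02)
        fwd = generate_synthetic_action(SyntheticActionSpec(archetype="grow", **common))
        rev = generate_synthetic_action(SyntheticActionSpec(archetype="shrink", **common))
        assert np.array_equal(rev.frames, fwd.frames[::-1])

    def test_archetypes_differ_spatiotemporally(self):
        specs = {
            a: generate_synthetic_action(SyntheticActionSpec(archetype=a, length=16, noise_rate=0.0))
            for a in ("bounce", "one_arm_wave", "two_arm_wave")
        }
        for a in specs.values():
            for b in specs.values():
                if a is not b:
                    assert not np.array_equal(a.frames, b.frames)

    def test_counting_and_metadata(self):
        ds = make_action_dataset(n_subjects=9, n_trials=1, length=6, seed=0)
        assert len(ds) == 27  # 3 archetypes x 9 subjects
        assert {s.label for s in ds} == {0, 1, 2}
        assert len({s.subject for s in ds}) == 9

    def test_order_task_is_invisible_to_per_frame_classifier(self):
        """A classifier that sees single frames (temporal information
        destroyed) stays near chance on the order-discrimination pair,
        because every frame occurs with both labels."""
        from sklearn.linear_model import LogisticRegression

        ds = make_order_discrimination_dataset(n_per_class=20, length=10, seed=0)
        X = np.concatenate([s.frames.reshape(s.T, -1) for s in ds])
        y = np.concatenate([np.full(s.T, s.label) for s in ds])
        acc = LogisticRegression(max_iter=500).fit(X, y).score(X, y)
        assert acc <= 0.5 + 0.10


class TestLosoSplits:
    def test_folds_partition_without_subject_overlap(self):
        ds = make_action_dataset(n_subjects=9, length=4, seed=0)
        folds = loso_splits(ds)
        assert len(folds) == 9
        test_names = []
        for train, test in folds:
            assert len(train) + len(test) == len(ds)
            assert {s.subject for s in train} & {s.subject for s in test} == set()
            assert len({s.subject for s in train}) == 8
            test_names += [s.name for s in test]
        assert sorted(test_names) == sorted(s.name for s in ds)

    def test_single_subject_rejected(self):
        ds = make_action_dataset(n_subjects=1, length=4, seed=0)
        with pytest.raises(ValueError):
            loso_splits(ds)
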