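"""Temporal mixup and temporal copy-paste behaviour."""

import numpy as np
import pytest

from plantgrow.augmentation import (
    MixupLambda,
    PlacementError,
    compose_plant,
    extract_leaf_tracks,
    filter_leaf_tracks,
    generate_augmented_dataset,
    tmixup_frames,
    tmixup_window,
)
from plantgrow.core_types import (
    InstanceMask,
    PlantRecord,
    RGBFrame,
    SoftMask,
    mask_to_onehot,
)
from plantgrow.dataset_io import make_windows
from plantgrow.synthetic_plants import generate_background

from conftest import make_disjoint_leaf_record


def _rand_pair(rng, size=8, c=4):
    rgb = RGBFrame(rng.random((size, size, 3)).astype(np.float32))
    labels = rng.integers(0, c, (size, size))
    soft = mask_to_onehot(InstanceMask(labels, n_classes=c))
    return rgb, soft


class TestTMixupFrames:
    def test_lambda_one_returns_first_frame(self, rng):
        a, b = _rand_pair(rng), _rand_pair(rng)
        out_rgb, out_soft = tmixup_frames(a, b, 1.0)
        np.testing.assert_allclose(out_rgb.pixels, a[0].pixels, atol=1e-7)
        np.testing.assert_allclose(out_soft.probs, a[1].probs, atol=1e-7)

    def test_lambda_zero_returns_second_frame(self, rng):
        a, b = _rand_pair(rng), _rand_pair(rng)
        out_rgb, _ = tmixup_frames(a, b, 0.0)
        np.testing.assert_allclose(out_rgb.pixels, b[0].pixels, atol=1e-7)

    def test_midpoint_arithmetic(self):
        a = (RGBFrame(np.full((2, 2, 3), 0.2)), SoftMask(np.eye(2, dtype=np.float32)[np.zeros((2, 2), int)]))
        b = (RGBFrame(np.full((2, 2, 3), 0.6)), SoftMask(np.eye(2, dtype=np.float32)[np.ones((2, 2), int)]))
        out_rgb, out_soft = tmixup_frames(a, b, 0.5)
        np.testing.assert_allclose(out_rgb.pixels, 0.4, atol=1e-7)
        np.testing.assert_allclose(out_soft.probs, 0.5, atol=1e-7)

    def test_matches_per_pixel_loop_oracle(self, rng):
        a, b = _rand_pair(rng, size=4), _rand_pair(rng, size=4)
        lam = 0.3
        out_rgb, out_soft = tmixup_frames(a, b, lam)
        for i in range(4):
            for j in range(4):
                for ch in range(3):
                    exp = lam * a[0].pixels[i, j, ch] + (1 - lam) * b[0].pixels[i, j, ch]
                    assert out_rgb.pixels[i, j, ch] == pytest.approx(exp, abs=1e-6)
                for c in range(4):
                    exp = lam * a[1].probs[i, j, c] + (1 - lam) * b[1].probs[i, j, c]
                    assert out_soft.probs[i, j, c] == pytest.approx(exp, abs=1e-6)

    def test_output_bounded_by_sources_and_sums_to_one(self, rng):
        a, b = _rand_pair(rng), _rand_pair(rng)
        out_rgb, out_soft = tmixup_frames(a, b, 0.37)
        lo = np.minimum(a[0].pixels, b[0].pixels) - 1e-6
        hi = np.maximum(a[0].pixels, b[0].pixels) + 1e-6
        assert np.all(out_rgb.pixels >= lo) and np.all(out_rgb.pixels <= hi)
        np.testing.assert_allclose(out_soft.probs.sum(axis=2), 1.0, atol=1e-5)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            MixupLambda(1.5)

    def test_shape_mismatch_rejected(self, rng):
        a = _rand_pair(rng, size=8)
        b = _rand_pair(rng, size=4)
        with pytest.raises(ValueError, match="match"):
            tmixup_frames(a, b, 0.5)


class TestTMixupWindow:
    def test_lambda_one_is_identity(self, small_record):
        w = make_windows(small_record, 3, 1)[0]
        mixed = tmixup_window(w, lam=1.0)
        for (rgb, soft), (orig_rgb, orig_mask) in zip(
            mixed.inputs + mixed.targets, w.inputs + w.targets
        ):
            np.testing.assert_allclose(rgb.pixels, orig_rgb.pixels, atol=1e-6)
            np.testing.assert_allclose(
                soft.probs, mask_to_onehot(orig_mask).probs, atol=1e-6
            )

    def test_lambda_zero_is_one_frame_shift(self, small_record):
        w = make_windows(small_record, 3, 1)[0]
        mixed = tmixup_window(w, lam=0.0)
        shifted = small_record.frames[w.start + 1 : w.start + 5]
        for (rgb, _), (orig_rgb, _) in zip(mixed.inputs + mixed.targets, shifted):
            np.testing.assert_allclose(rgb.pixels, orig_rgb.pixels, atol=1e-6)

    def test_every_frame_equals_per_frame_oracle(self, small_record):
        w = make_windows(small_record, 3, 1)[1]
        lam = 0.5
        mixed = tmixup_window(w, lam=lam)
        for offset, (rgb, soft) in enumerate(mixed.inputs + mixed.targets):
            t = w.start + offset
            rgb_t, m_t = small_record.frames[t]
            rgb_n, m_n = small_record.frames[t + 1]
            exp_rgb, exp_soft = tmixup_frames(
                (rgb_t, mask_to_onehot(m_t)), (rgb_n, mask_to_onehot(m_n)), lam
            )
            np.testing.assert_allclose(rgb.pixels, exp_rgb.pixels, atol=1e-6)
            np.testing.assert_allclose(soft.probs, exp_soft.probs, atol=1e-6)

    def test_window_at_record_end_is_skipped(self, small_record, caplog):
        last = make_windows(small_record, 3, 1)[-1]
        assert last.start + 4 == small_record.n_frames
        import logging

        with caplog.at_level(logging.INFO, logger="plantgrow.augmentation"):
            assert tmixup_window(last, lam=0.5) is None
        assert any("skipped" in m for m in caplog.messages)


class TestLeafTracks:
    def test_track_areas_match_per_label_pixel_counts(self, disjoint_record):
        tracks = extract_leaf_tracks(disjoint_record)
        assert len(tracks) == 2
        for track in tracks:
            for entry in track.entries:
                count = int(np.sum(disjoint_record.frames[entry.frame][1].labels == track.label))
                assert entry.area == count

    def test_no_leaves_gives_empty_list(self):
        frame = (RGBFrame(np.zeros((8, 8, 3))), InstanceMask(np.zeros((8, 8), dtype=int)))
        rec = PlantRecord("empty", "v", [frame] * 3)
        assert extract_leaf_tracks(rec) == []

    def test_tracks_contiguous_from_emergence(self, disjoint_record):
        tracks = {t.label: t for t in extract_leaf_tracks(disjoint_record)}
        assert tracks[1].first_frame == 0 and len(tracks[1]) == 5
        assert tracks[2].first_frame == 1 and len(tracks[2]) == 4
        for t in tracks.values():
            assert [e.frame for e in t.entries] == list(
                range(t.first_frame, disjoint_record.n_frames)
            )

    def test_mask_patches_padded_off_border(self, disjoint_record):
        for track in extract_leaf_tracks(disjoint_record):
            for e in track.entries:
                assert not e.mask[0, :].any() and not e.mask[-1, :].any()
                assert not e.mask[:, 0].any() and not e.mask[:, -1].any()


def _record_with_split_leaf(size=24):
    """Leaf 1 gets cut into two components by leaf 2 in the last frame."""
    frames = []
    for t in range(3):
        rgb = np.full((size, size, 3), 0.3, dtype=np.float32)
        mask = np.zeros((size, size), dtype=np.int64)
        mask[8:16, 4:20] = 1  # horizontal bar
        if t == 2:
            mask[4:20, 10:14] = 2  # vertical bar on top splits leaf 1
        frames.append((RGBFrame(rgb), InstanceMask(mask, n_classes=9)))
    return PlantRecord("split", "v", frames)


class TestFilter:
    def test_split_leaf_track_removed(self):
        tracks = extract_leaf_tracks(_record_with_split_leaf())
        kept = filter_leaf_tracks(tracks, occlusion_threshold=0.0)
        assert {t.label for t in tracks} == {1, 2}
        assert {t.label for t in kept} == {2}

    def test_disjoint_tracks_all_kept(self, disjoint_record):
        tracks = extract_leaf_tracks(disjoint_record)
        assert len(filter_leaf_tracks(tracks)) == 2

    def test_degenerate_config_is_identity(self):
        tracks = extract_leaf_tracks(_record_with_split_leaf())
        kept = filter_leaf_tracks(tracks, occlusion_threshold=0.0, require_connected=False)
        assert len(kept) == len(tracks)

    def test_occluded_leaf_removed_by_area_rule(self):
        # leaf 1 loses half its area to leaf 2 (still one component)
        size = 24
        frames = []
        for t in range(3):
            rgb = np.full((size, size, 3), 0.3, dtype=np.float32)
            mask = np.zeros((size, size), dtype=np.int64)
            mask[8:16, 4:20] = 1
            if t == 2:
                mask[8:16, 4:11] = 2  # covers ~half of leaf 1 from one side
            frames.append((RGBFrame(rgb), InstanceMask(mask, n_classes=9)))
        rec = PlantRecord("occl", "v", frames)
        tracks = extract_leaf_tracks(rec)
        kept = filter_leaf_tracks(tracks, occlusion_threshold=0.9)
        assert {t.label for t in kept} == {2}
        kept_loose = filter_leaf_tracks(tracks, occlusion_threshold=0.3)
        assert {t.label for t in kept_loose} == {1, 2}

    def test_border_touching_leaf_removed(self):
        size = 16
        frames = []
        rgb = np.full((size, size, 3), 0.3, dtype=np.float32)
        mask = np.zeros((size, size), dtype=np.int64)
        mask[0:5, 4:9] = 1  # touches the top border
        frames.append((RGBFrame(rgb), InstanceMask(mask, n_classes=9)))
        rec = PlantRecord("border", "v", frames)
        assert filter_leaf_tracks(extract_leaf_tracks(rec)) == []

    def test_raising_threshold_never_keeps_more_tracks(self, medium_record):
        tracks = extract_leaf_tracks(medium_record)
        counts = [
            len(filter_leaf_tracks(tracks, occlusion_threshold=thr))
            for thr in (0.0, 0.5, 0.9, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCompose:
    @pytest.fixture()
    def clean_tracks(self, disjoint_record):
        return filter_leaf_tracks(extract_leaf_tracks(disjoint_record))

    @pytest.fixture()
    def background(self):
        return generate_background(48, seed=4)

    def test_area_round_trip_without_transform(self, clean_tracks, background):
        track = clean_tracks[0]
        rec = compose_plant(
            background, [track], rng_seed=0, emergence_frames=[0],
            rotation_range=(0.0, 0.0), scale_range=(1.0, 1.0),
        )
        for t, (_, mask) in enumerate(rec.frames):
            idx = min(t, len(track.entries) - 1)
            assert int(np.sum(mask.labels == 1)) == track.entries[idx].area

    def test_compose_then_extract_recovers_areas(self, clean_tracks, background):
        rec = compose_plant(
            background, clean_tracks, placements=[(12, 12), (34, 34)],
            rng_seed=1, emergence_frames=[0, 1],
            rotation_range=(0.0, 0.0), scale_range=(1.0, 1.0),
        )
        back = extract_leaf_tracks(rec)
        assert len(back) == 2
        for j, track in enumerate(back):
            src = clean_tracks[j]
            for e in track.entries:
                src_idx = min(e.frame - track.first_frame, len(src.entries) - 1)
                assert e.area == src.entries[src_idx].area

    def test_painters_rule_at_overlaps(self, clean_tracks, background):
        rec = compose_plant(
            background, clean_tracks, placements=[(24, 24), (26, 26)],
            rng_seed=2, emergence_frames=[0, 0],
            rotation_range=(0.0, 0.0), scale_range=(1.0, 1.0),
        )
        # the later-pasted track (label 2) wins wherever both leaves project
        last_mask = rec.frames[-1][1].labels
        t2 = clean_tracks[1].entries[-1]
        ph, pw = t2.mask.shape
        r0, c0 = 26 - ph // 2, 26 - pw // 2
        region = np.zeros_like(last_mask, dtype=bool)
        region[r0 : r0 + ph, c0 : c0 + pw] = t2.mask
        assert np.all(last_mask[region] == 2)

    def test_determinism_given_seed(self, clean_tracks, background):
        a = compose_plant(background, clean_tracks, rng_seed=7)
        b = compose_plant(background, clean_tracks, rng_seed=7)
        for (ra, ma), (rb, mb) in zip(a.frames, b.frames):
            np.testing.assert_array_equal(ra.pixels, rb.pixels)
            np.testing.assert_array_equal(ma.labels, mb.labels)

    def test_shared_background_across_frames(self, clean_tracks, background):
        rec = compose_plant(background, clean_tracks, rng_seed=3)
        bg_everywhere = np.ones(rec.frames[0][1].labels.shape, dtype=bool)
        for _, mask in rec.frames:
            bg_everywhere &= mask.labels == 0
        for rgb, _ in rec.frames:
            np.testing.assert_array_equal(
                rgb.pixels[bg_everywhere], background.pixels[bg_everywhere]
            )

    def test_too_many_tracks_rejected(self, clean_tracks, background):
        with pytest.raises(ValueError, match="tracks"):
            compose_plant(background, clean_tracks * 5, rng_seed=0)

    def test_out_of_image_placement_rejected(self, clean_tracks, background):
        with pytest.raises(PlacementError):
            compose_plant(
                background, clean_tracks[:1], placements=[(1, 1)], rng_seed=0,
                emergence_frames=[0], rotation_range=(0.0, 0.0), scale_range=(1.0, 1.0),
            )

    def test_unfiltered_track_with_gap_rejected(self, background):
        tracks = extract_leaf_tracks(_record_with_split_leaf())
        bad = [t for t in tracks if t.label == 1]
        # leaf 1 has a split (still nonzero) — force a vanished entry instead
        bad[0].entries[1].mask = None
        bad[0].entries[1].rgb = None
        with pytest.raises(ValueError, match="filter"):
            compose_plant(background, bad, rng_seed=0)


class TestGenerateAugmented:
    def test_records_pass_invariants_and_are_deterministic(self, medium_record):
        bgs = [generate_background(64, seed=s) for s in range(2)]
        a = generate_augmented_dataset([medium_record], bgs, n_new_plants=3, rng_seed=5)
        b = generate_augmented_dataset([medium_record], bgs, n_new_plants=3, rng_seed=5)
        assert len(a) == 3
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.frames[0][0].pixels, rb.frames[0][0].pixels)
            # PlantRecord construction already validated emergence order
            assert ra.n_frames == rb.n_frames

    def test_empty_inputs_rejected(self, medium_record):
        with pytest.raises(ValueError):
            generate_augmented_dataset([], [generate_background(64)], n_new_plants=1)
        with pytest.raises(ValueError):
            generate_augmented_dataset([medium_record], [], n_new_plants=1)

    def test_all_tracks_filtered_out_raises(self):
        # single leaf touching the border: nothing survives filtering
        size = 16
        rgb = np.full((size, size, 3), 0.3, dtype=np.float32)
        mask = np.zeros((size, size), dtype=np.int64)
        mask[0:5, 4:9] = 1
        rec = PlantRecord("border", "v", [(RGBFrame(rgb), InstanceMask(mask, n_classes=9))])
        with pytest.raises(ValueError, match="filter"):
            generate_augmented_dataset([rec], [generate_background(16, seed=0)], n_new_plants=1)
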