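"""Registration, feature detection, NCC tracking, and the well-tracked gate."""

import numpy as np
import pytest

from dermakin import (
    FeatureTrack,
    ImageVolume,
    collagen_mask,
    detect_features,
    forward_backward_gate,
    generate_macro_scene,
    register_translation,
    track_features,
    track_increment,
    track_macro_markers,
)


@pytest.fixture(scope="module")
def textured_volume():
    rng = np.random.default_rng(0)
    from scipy.ndimage import gaussian_filter

    data = gaussian_filter(rng.random((64, 64, 48)), 1.2)
    data -= data.min()
    return ImageVolume(data, (1.0, 1.0, 1.0))


class TestRegistration:
    def test_self_registration_is_zero(self, textured_volume):
        assert np.allclose(register_translation(textured_volume, textured_volume), 0.0)

    def test_circular_shift_recovered(self, textured_volume):
        moving = textured_volume.with_data(
            np.roll(textured_volume.data, (5, -3, 2), axis=(0, 1, 2))
        )
        assert np.array_equal(register_translation(textured_volume, moving), [5, -3, 2])

    def test_random_integer_shift_sweep(self, textured_volume):
        rng = np.random.default_rng(4)
        for _ in range(10):
            s = rng.integers(-8, 9, size=3)
            moving = textured_volume.with_data(
                np.roll(textured_volume.data, s, axis=(0, 1, 2))
            )
            assert np.array_equal(register_translation(textured_volume, moving), s)

    def test_all_zero_volume_rejected(self, textured_volume):
        zero = ImageVolume(np.zeros((64, 64, 48)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            register_translation(textured_volume, zero)


class TestDetectFeatures:
    def test_uniform_volume_yields_nothing(self):
        vol = ImageVolume(np.ones((64, 64, 48)), (1.0, 1.0, 1.0))
        assert len(detect_features(vol)) == 0

    def test_deterministic_ordering(self, textured_volume):
        a = detect_features(textured_volume, n_max=20, min_spacing=5)
        b = detect_features(textured_volume, n_max=20, min_spacing=5)
        assert np.array_equal(a, b)

    def test_min_spacing_respected(self, textured_volume):
        feats = detect_features(textured_volume, n_max=30, min_spacing=6)
        assert len(feats) > 1
        d = np.linalg.norm(feats[:, None] - feats[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 6

    def test_features_cluster_at_fiber_crossings(self):
        # pairs of short fiber segments intersecting at known interior points;
        # corner responses should land on the true corner structures of the
        # scene — the planned crossings and the segment terminations
        shape = (128, 128, 64)
        vs = np.array([1.144, 1.144, 1.0])
        rng = np.random.default_rng(77)
        ext = np.array(shape) * vs
        margin = np.array([24, 24, 16]) * vs
        pts = []
        while len(pts) < 30:
            p = margin + rng.random(3) * (ext - 2 * margin)
            if not pts or min(np.linalg.norm(p - q) for q in pts) > 16:
                pts.append(p)
        pts = np.array(pts)
        ax = [np.arange(n) * s for n, s in zip(shape, vs)]
        grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
        vol = np.zeros(shape)
        ends = []
        for p in pts:
            for _ in range(2):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                d = grid - p
                t = d @ v
                d2 = (d * d).sum(-1) - t * t
                fall = np.exp(-np.maximum(np.abs(t) - 15.0, 0) ** 2 / 72.0)
                vol += 100 * np.exp(-d2 / (2 * 1.25**2)) * fall
                ends += [p + 15 * v, p - 15 * v]
        ends = np.array(ends)
        volume = ImageVolume(vol, tuple(vs))
        feats = detect_features(volume, collagen_mask(volume).data, n_max=40, min_spacing=8)
        assert len(feats) >= 20
        fp = feats * vs
        d_cross = np.linalg.norm(fp[:, None] - pts[None], axis=-1).min(axis=1) / vs.mean()
        d_corner = np.minimum(
            d_cross,
            np.linalg.norm(fp[:, None] - ends[None], axis=-1).min(axis=1) / vs.mean(),
        )
        assert (d_corner < 4).sum() >= 0.9 * len(feats)  # features sit on corners
        # and a healthy share of the planned crossings attract a feature
        hit = np.linalg.norm(pts[:, None] - fp[None], axis=-1).min(axis=1) / vs.mean()
        assert (hit < 3).sum() >= 10


class TestTrackIncrement:
    def test_translation_recovered(self, textured_volume):
        shifted = textured_volume.with_data(
            np.roll(textured_volume.data, (3, 2, 1), axis=(0, 1, 2))
        )
        new, peak = track_increment((30, 30, 24), textured_volume, shifted,
                                    patch=(12, 12, 5), search=(12, 12, 8))
        assert np.allclose(new, [33, 32, 25], atol=0.05)
        assert peak == pytest.approx(1.0, abs=1e-6)

    def test_affine_intensity_invariance(self, textured_volume):
        target = textured_volume.with_data(2.0 * textured_volume.data + 7.0)
        new, peak = track_increment((30, 30, 24), textured_volume, target,
                                    patch=(12, 12, 5), search=(12, 12, 8))
        assert np.allclose(new, [30, 30, 24], atol=1e-6)
        assert peak == pytest.approx(1.0, abs=1e-6)

    def test_flat_patch_untrackable(self, textured_volume):
        flat = textured_volume.with_data(np.ones_like(textured_volume.data))
        with pytest.raises(ValueError, match="flat"):
            track_increment((30, 30, 24), flat, textured_volume,
                            patch=(12, 12, 5), search=(12, 12, 8))


class TestForwardBackwardGate:
    def test_identity_sequence_all_pass_with_zero_error(self, textured_volume):
        feats = detect_features(textured_volume, n_max=10, min_spacing=5,
                                patch=(12, 12, 5), search=(10, 10, 8))
        tracks = track_features([textured_volume] * 3, feats,
                                patch=(12, 12, 5), search=(10, 10, 8))
        good = forward_backward_gate(tracks)
        assert len(good) == len(tracks) == len(feats) > 0
        for t in good:
            assert np.allclose(t.incremental_errors, 0.0, atol=1e-9)
            assert t.overall_error < 1e-9

    def test_boundary_semantics_strict(self):
        def make(inc, overall):
            return FeatureTrack(
                id=0, ref_position=np.zeros(3), positions=np.zeros((3, 3)),
                correlations=np.ones(2), incremental_errors=np.array(inc),
                overall_error=overall,
            )
        at_limit = make([10.0, 0.0], 0.5)
        under = make([9.99, 0.0], 0.5)
        big_overall = make([0.0, 0.0], 1.0)
        passing = make([9.0, 9.0], 0.99)
        gated = forward_backward_gate([at_limit, under, big_overall, passing])
        assert at_limit.well_tracked is False  # incremental error == 10 fails (<)
        assert big_overall.well_tracked is False  # overall error == 1 fails (<)
        assert under.well_tracked and passing.well_tracked
        assert gated == [under, passing]

    def test_gate_is_idempotent(self):
        t = FeatureTrack(
            id=0, ref_position=np.zeros(3), positions=np.zeros((2, 3)),
            correlations=np.ones(1), incremental_errors=np.array([0.1]),
            overall_error=0.2,
        )
        once = forward_backward_gate([t])
        twice = forward_backward_gate(once)
        assert twice == once


SQUARE_MM = np.array([[2.0, 2.0], [2.0, 6.0], [6.0, 2.0], [6.0, 6.0]])


class TestMacroMarkers:
    def test_stationary_scene_zero_displacement(self):
        frames, truth = generate_macro_scene(SQUARE_MM, [np.eye(2)] * 4, seed=0)
        tracks = track_macro_markers(frames, initial_positions=truth[0])
        for t, p0 in zip(tracks, truth[0]):
            assert np.allclose(t.positions - p0, 0.0, atol=1e-9)
            assert not t.lost.any()

    def test_known_deformation_recovered_subpixel(self):
        F = np.diag([1.1, 0.9])
        frames, truth = generate_macro_scene(SQUARE_MM, [np.eye(2), F], seed=0)
        tracks = track_macro_markers(frames, template_radius=12, search_radius=30,
                                     initial_positions=truth[0])
        rec = np.array([t.positions[1] for t in tracks])
        assert np.max(np.linalg.norm(rec - truth[1], axis=1)) < 0.25

    def test_reversed_sequence_reverses_trajectories(self):
        F = np.diag([1.08, 0.94])
        frames, truth = generate_macro_scene(SQUARE_MM, [np.eye(2), F], seed=0)
        fwd = track_macro_markers(frames, template_radius=12, search_radius=30,
                                  initial_positions=truth[0])
        rev = track_macro_markers(frames[::-1], template_radius=12, search_radius=30,
                                  initial_positions=np.array([t.positions[1] for t in fwd]))
        for f, r in zip(fwd, rev):
            assert np.allclose(r.positions[::-1], f.positions, atol=0.1)

    def test_too_few_markers_rejected(self):
        frames, truth = generate_macro_scene(SQUARE_MM, [np.eye(2)], seed=0)
        with pytest.raises(ValueError, match=">= 4"):
            track_macro_markers(frames, initial_positions=truth[0][:3])
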