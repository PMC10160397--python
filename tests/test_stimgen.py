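"""Stimulus generators: geometry, noise calibration, frame I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dflgmd import (LuminanceSequence, StimulusSpec, add_gaussian_noise,
                    gen_looming, gen_receding, gen_translating, load_frames,
                    save_frames)


def object_area(frame, bg=1.0):
    """Total coverage of the (dark) object, from the luminance deficit."""
    return float((bg - frame).sum())


class TestLooming:
    def spec(self, **kw):
        base = dict(kind="looming", grid=(32, 32), n_frames=20,
                    start_size=4, fill_frame=15)
        base.update(kw)
        return StimulusSpec(**base)

    def test_frames_constant_after_fill(self):
        seq = gen_looming(self.spec())
        for t in range(15, 20):
            np.testing.assert_array_equal(seq.frames[t - 1], seq.frames[14])

    def test_area_nondecreasing(self):
        seq = gen_looming(self.spec())
        areas = [object_area(f) for f in seq.frames]
        assert np.all(np.diff(areas) >= -1e-9)

    def test_dark_object_fills_field(self):
        seq = gen_looming(self.spec())
        assert seq.frames[0].mean() > seq.frames[14].mean()
        np.testing.assert_allclose(seq.frames[14], 0.0, atol=1e-12)

    def test_fill_frame_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            self.spec(fill_frame=25)


class TestReceding:
    def test_time_reverse_of_looming(self):
        loom = StimulusSpec(kind="looming", grid=(32, 32), n_frames=20,
                            start_size=4, fill_frame=15)
        rec = StimulusSpec(kind="receding", grid=(32, 32), n_frames=20,
                           start_size=4, fill_frame=15)
        np.testing.assert_array_equal(gen_receding(rec).frames,
                                      gen_looming(loom).frames[::-1])

    def test_area_nonincreasing(self):
        rec = StimulusSpec(kind="receding", grid=(32, 32), n_frames=20,
                           start_size=4, fill_frame=20)
        areas = [object_area(f) for f in gen_receding(rec).frames]
        assert np.all(np.diff(areas) <= 1e-9)
        assert areas[-1] >= 0.0


class TestTranslating:
    def test_centroid_moves_one_px_per_frame(self):
        spec = StimulusSpec(kind="translate", grid=(32, 32), n_frames=10,
                            direction=0.0, speed=1.0, size=5)
        seq = gen_translating(spec)
        cols = np.arange(32)
        cents = []
        for f in seq.frames:
            mass = 1.0 - f
            cents.append((mass.sum(axis=0) * cols).sum() / mass.sum())
        np.testing.assert_allclose(np.diff(cents), 1.0, atol=1e-9)

    def test_opposite_direction_is_mirror_image(self):
        kw = dict(kind="translate", grid=(32, 32), n_frames=10, speed=1.0, size=5)
        right = gen_translating(StimulusSpec(direction=0.0, **kw))
        left = gen_translating(StimulusSpec(direction=np.pi, **kw))
        np.testing.assert_allclose(left.frames, right.frames[:, :, ::-1], atol=1e-12)

    def test_object_mass_constant_while_inside(self):
        spec = StimulusSpec(kind="translate", grid=(32, 32), n_frames=10,
                            direction=np.pi / 4, speed=0.5, size=5)
        areas = [object_area(f) for f in gen_translating(spec).frames]
        np.testing.assert_allclose(areas, areas[0], rtol=1e-9)

    def test_bar_shape_axis_aligned_only(self):
        with pytest.raises(ValueError):
            gen_translating(StimulusSpec(kind="translate", grid=(32, 32),
                                         n_frames=10, direction=np.pi / 4,
                                         speed=1.0, shape="bar", size=3))

    def test_non_canonical_direction_rejected(self):
        with pytest.raises(ValueError):
            gen_translating(StimulusSpec(kind="translate", grid=(32, 32),
                                         n_frames=10, direction=0.1, speed=1.0))

    def test_absurd_speed_rejected(self):
        with pytest.raises(ValueError):
            gen_translating(StimulusSpec(kind="translate", grid=(16, 16),
                                         n_frames=10, direction=0.0,
                                         speed=40.0, size=3))


class TestNoise:
    def make(self):
        spec = StimulusSpec(kind="translate", grid=(64, 64), n_frames=30,
                            direction=0.0, speed=0.5, size=9,
                            object_luminance=0.3, background_luminance=0.7)
        return gen_translating(spec)

    def test_same_seed_bit_identical(self):
        seq = self.make()
        a = add_gaussian_noise(seq, 10.0, seed=42)
        b = add_gaussian_noise(seq, 10.0, seed=42)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_infinite_snr_is_identity(self):
        seq = self.make()
        out = add_gaussian_noise(seq, np.inf, seed=0)
        np.testing.assert_array_equal(out.frames, seq.frames)

    def test_nan_snr_rejected(self):
        with pytest.raises(ValueError):
            add_gaussian_noise(self.make(), np.nan, seed=0)

    @pytest.mark.parametrize("snr_db", [5.0, 30.0])
    def test_empirical_snr_matches_request(self, snr_db):
        """Realized SNR (mid-gray stimulus, no clipping) within 0.1 dB."""
        seq = self.make()
        noisy = add_gaussian_noise(seq, snr_db, seed=3)
        noise = noisy.frames - seq.frames
        assert not np.any(noisy.frames <= 0.0) and not np.any(noisy.frames >= 1.0)
        p_sig = np.mean((seq.frames - seq.frames.mean(axis=0)) ** 2)
        realized = 10.0 * np.log10(p_sig / np.mean(noise ** 2))
        assert abs(realized - snr_db) < 0.1


class TestFrameIO:
    def test_roundtrip_within_quantization(self, tmp_path):
        spec = StimulusSpec(kind="translate", grid=(16, 16), n_frames=5,
                            direction=0.0, speed=0.5, size=5)
        seq = gen_translating(spec)
        save_frames(seq, tmp_path / "frames", spec=spec)
        assert (tmp_path / "frames" / "stimulus.json").exists()
        back = load_frames(tmp_path / "frames")
        assert np.abs(back.frames - seq.frames).max() <= 1.0 / 255.0 + 1e-12

    def test_zeros_roundtrip_exact(self, tmp_path):
        seq = LuminanceSequence(np.zeros((3, 4, 4)))
        back = load_frames(save_frames(seq, tmp_path / "z"))
        np.testing.assert_array_equal(back.frames, 0.0)

    def test_zero_padded_ordering(self, tmp_path):
        import imageio.v3 as iio
        d = tmp_path / "f"
        d.mkdir()
        for name, val in [("frame_002.png", 20), ("frame_010.png", 100),
                          ("frame_001.png", 10)]:
            iio.imwrite(d / name, np.full((4, 4), val, dtype=np.uint8))
        seq = load_frames(d)
        means = seq.frames.mean(axis=(1, 2)) * 255.0
        np.testing.assert_allclose(means, [10, 20, 100], atol=0.5)

    def test_mixed_sizes_rejected(self, tmp_path):
        import imageio.v3 as iio
        d = tmp_path / "f"
        d.mkdir()
        iio.imwrite(d / "frame_001.png", np.zeros((4, 4), dtype=np.uint8))
        iio.imwrite(d / "frame_002.png", np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            load_frames(d)

    def test_empty_directory_rejected(self, tmp_path):
        d = tmp_path / "empty"
        d.mkdir()
        with pytest.raises(FileNotFoundError):
            load_frames(d)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(kind=st.sampled_from(["looming", "receding", "translate"]),
       n_frames=st.integers(3, 25),
       k=st.integers(0, 7),
       speed=st.floats(0.25, 2.0))
def test_generators_stay_in_unit_range(kind, n_frames, k, speed):
    """Every generated stimulus is a valid luminance stack in [0, 1], T >= 3."""
    spec = StimulusSpec(kind=kind, grid=(24, 24), n_frames=n_frames,
                        start_size=3, fill_frame=max(1, n_frames - 1),
                        direction=k * np.pi / 4, speed=speed, size=5)
    gen = {"looming": gen_looming, "receding": gen_receding,
           "translate": gen_translating}[kind]
    seq = gen(spec)
    assert seq.frames.shape[0] == n_frames >= 3
    assert seq.frames.min() >= 0.0 and seq.frames.max() <= 1.0
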