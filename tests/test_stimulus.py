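"""Stimulus construction: scrambling, matching, sampling, geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peritex import (
    GrayImage,
    StimulusSpec,
    compose_stimulus,
    histogram_match,
    iterative_fas_hist_match,
    phase_scramble,
    sample_patch,
)
from peritex.stimulus import fourier_amplitude, stimulus_geometry


@pytest.fixture(scope="module")
def src():
    return GrayImage(np.random.default_rng(0).random((512, 512)))


class TestPhaseScramble:
    def test_fas_preserved_exactly(self, src):
        scr = phase_scramble(src, 5)
        a, b = fourier_amplitude(src), fourier_amplitude(scr)
        assert np.max(np.abs(a - b)) <= 1e-10 * np.max(a)

    def test_sinusoid_stays_sinusoid(self):
        xx = np.arange(64)[None, :]
        img = GrayImage(0.5 + 0.2 * np.sin(2 * np.pi * xx * 4 / 64) * np.ones((64, 1)))
        scr = phase_scramble(img, 9)
        # identical amplitude at the grating frequency, zero elsewhere
        assert np.allclose(fourier_amplitude(img), fourier_amplitude(scr), atol=1e-8)
        assert scr.pixels.std() == pytest.approx(img.pixels.std(), rel=1e-10)

    def test_scrambling_destroys_skewness(self):
        """A skewed structured texture loses its pixel skewness under
        scrambling (Monte-Carlo bound over seeds)."""
        from scipy.stats import skew

        from peritex import ProceduralTextureParams, generate_texture

        tex = generate_texture(ProceduralTextureParams(size_px=512, rng_seed=2))
        assert skew(tex.pixels.ravel()) > 0.5
        for seed in range(3):
            scr = phase_scramble(tex, seed)
            assert abs(skew(scr.pixels.ravel())) < 0.1

    def test_deterministic(self, src):
        assert np.array_equal(
            phase_scramble(src, 3).pixels, phase_scramble(src, 3).pixels
        )


class TestHistogramMatch:
    def test_idempotent_on_own_values(self, src):
        out = histogram_match(src, np.sort(src.pixels.ravel()))
        assert np.allclose(out.pixels, src.pixels)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_output_multiset_equals_reference(self, seed):
        r = np.random.default_rng(seed)
        img = GrayImage(r.random((32, 32)))
        ref = r.random(32 * 32)
        out = histogram_match(img, ref)
        assert np.allclose(np.sort(out.pixels.ravel()), np.sort(ref))

    def test_comatched_pair_shares_sorted_values(self, src):
        other = phase_scramble(src, 1)
        avg = (np.sort(src.pixels.ravel()) + np.sort(other.pixels.ravel())) / 2
        a = histogram_match(src, avg)
        b = histogram_match(other, avg)
        assert np.allclose(np.sort(a.pixels.ravel()), np.sort(b.pixels.ravel()))

    def test_length_mismatch_raises(self, src):
        with pytest.raises(ValueError, match="length"):
            histogram_match(src, np.zeros(10))


class TestIterativeMatch:
    def test_fixed_point(self, src):
        res = iterative_fas_hist_match(src, src, src.pixels.ravel(), n_iter=5)
        assert np.allclose(res.image.pixels, src.pixels, atol=1e-8)
        assert res.fas_error < 1e-10

    def test_noise_to_grating_regression_bound(self):
        """White noise forced to a pure grating's FAS and a uniform
        histogram: the loop settles near 15% relative FAS error (frozen
        regression bound for this adversarial target)."""
        xx = np.arange(128)[None, :]
        grating = GrayImage(0.5 + 0.3 * np.sin(2 * np.pi * xx * 8 / 128) * np.ones((128, 1)))
        noise = GrayImage(np.random.default_rng(4).random((128, 128)))
        res = iterative_fas_hist_match(noise, grating, np.linspace(0, 1, 128 * 128))
        assert res.hist_error < 1e-12  # ends on the histogram step
        assert res.fas_error < 0.2

    def test_default_iterations(self):
        import inspect

        sig = inspect.signature(iterative_fas_hist_match)
        assert sig.parameters["n_iter"].default == 30


class TestSamplePatch:
    def test_full_size_crop_without_rotation_is_identity(self, src):
        # seed chosen so the rotation draw is 0
        for seed in range(50):
            if np.random.default_rng(seed).integers(4) == 0:
                break
        out = sample_patch(src, src.shape, seed)
        assert np.array_equal(out.pixels, src.pixels)

    def test_deterministic(self, src):
        a = sample_patch(src, (64, 64), 123)
        b = sample_patch(src, (64, 64), 123)
        assert np.array_equal(a.pixels, b.pixels)

    def test_rotations_uniform(self, src):
        counts = np.zeros(4)
        for seed in range(1000):
            counts[np.random.default_rng(seed).integers(4)] += 1
        assert np.all(np.abs(counts / 1000 - 0.25) < 0.05)

    def test_oversize_patch_raises(self, src):
        with pytest.raises(ValueError, match="larger"):
            sample_patch(src, (600, 600), 0)


class TestComposeStimulus:
    def test_gap_geometry_in_pixels(self):
        """0.5 deg gap at 30 px/deg: ring inner radius exceeds the rendered
        target radius by 15 px, in both gap modes."""
        for mode in ("shrink_target", "enlarge_surround"):
            spec = StimulusSpec(gap_deg=0.5, gap_mode=mode, canvas_px=384)
            geom = stimulus_geometry(spec, 30.0)
            assert geom["r_inner"] - geom["r_target"] == pytest.approx(15.0)

    def test_ring_width_equals_target_diameter(self):
        spec = StimulusSpec(gap_deg=0.0, surround_width_factor=1.0, canvas_px=384)
        geom = stimulus_geometry(spec, 30.0)
        assert geom["r_outer"] - geom["r_inner"] == pytest.approx(3.7 * 30)

    def test_no_surround_shows_background_outside_target(self, src):
        spec = StimulusSpec(surround_kind="none", canvas_px=384)
        img, masks = compose_stimulus(spec, src, src, 0.25, 7, return_masks=True)
        outside = masks["target_alpha"] == 0
        assert np.all(img.pixels[outside] == 0.25)

    def test_gap_zero_modes_identical(self, src):
        for shape in ("disk", "split"):
            a = compose_stimulus(
                StimulusSpec(target_shape=shape, gap_deg=0, gap_mode="shrink_target",
                             canvas_px=384), src, src, 0.5, 11)
            b = compose_stimulus(
                StimulusSpec(target_shape=shape, gap_deg=0, gap_mode="enlarge_surround",
                             canvas_px=384), src, src, 0.5, 11)
            assert np.array_equal(a.pixels, b.pixels)

    def test_masks_disjoint_and_gap_shows_background(self, src):
        spec = StimulusSpec(gap_deg=0.5, canvas_px=384)
        img, masks = compose_stimulus(spec, src, src, 0.5, 3, return_masks=True)
        a_t, a_s = masks["target_alpha"], masks["surround_alpha"]
        assert not np.any((a_t == 1) & (a_s > 0))
        assert not np.any((a_s == 1) & (a_t > 0))
        # an annulus strictly inside the gap shows pure background
        n = img.shape[0]
        yy, xx = np.ogrid[:n, :n]
        r = np.hypot(yy - n // 2, xx - n // 2)
        geom = masks["geometry"]
        in_gap = (r > geom["r_target"] + spec.edge_gradient_px) & (
            r < geom["r_inner"] - spec.edge_gradient_px
        )
        assert np.all(img.pixels[in_gap] == 0.5)

    def test_half_rings_partition_the_ring(self, src):
        full = compose_stimulus(
            StimulusSpec(surround_kind="ring", gap_deg=0.5, canvas_px=384),
            src, src, 0.5, 3, return_masks=True)[1]["surround_alpha"]
        inward = compose_stimulus(
            StimulusSpec(surround_kind="half_ring_inward", gap_deg=0.5, canvas_px=384),
            src, src, 0.5, 3, return_masks=True)[1]["surround_alpha"]
        outward = compose_stimulus(
            StimulusSpec(surround_kind="half_ring_outward", gap_deg=0.5, canvas_px=384),
            src, src, 0.5, 3, return_masks=True)[1]["surround_alpha"]
        n = full.shape[0]
        assert inward[:, : n // 2 - 8].sum() > 0 and inward[:, n // 2 + 8 :].sum() == 0
        assert outward[:, n // 2 + 8 :].sum() > 0 and outward[:, : n // 2 - 8].sum() == 0
        # away from the cut the two halves reproduce the full ring support
        support = (full > 0).sum()
        assert 0.4 < (inward > 0).sum() / support < 0.6

    def test_split_target_area_close_to_disk(self, src):
        disk = compose_stimulus(
            StimulusSpec(target_shape="disk", gap_deg=0, canvas_px=384),
            src, src, 0.5, 3, return_masks=True)[1]["target_alpha"]
        split = compose_stimulus(
            StimulusSpec(target_shape="split", gap_deg=0.5, canvas_px=384),
            src, src, 0.5, 3, return_masks=True)[1]["target_alpha"]
        assert (split > 0).sum() == pytest.approx((disk > 0).sum(), rel=0.15)

    def test_bad_geometry_raises(self, src):
        spec = StimulusSpec(target_diameter_deg=0.5, gap_deg=1.0,
                            gap_mode="shrink_target", canvas_px=384)
        with pytest.raises(ValueError, match="geometry"):
            compose_stimulus(spec, src, src, 0.5, 0)


def test_spec_json_roundtrip(tmp_path):
    spec = StimulusSpec(target_shape="split", gap_deg=0.35, canvas_px=256)
    path = tmp_path / "spec.json"
    spec.to_json(path)
    assert StimulusSpec.from_json(path) == spec
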