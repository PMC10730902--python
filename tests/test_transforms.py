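"""Transform contracts: exact reconstruction, partition of unity,
shift-equivariance, linearity, ring selectivity, half reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circwave import transforms as T


def brute_force_level1_haar(image):
    """Independent oracle: direct periodic convolution with the four Haar
    filter tensor products h = [1/2, 1/2], g = [1/2, -1/2] (taps at 0, +1)."""
    h = np.array([0.5, 0.5])
    g = np.array([0.5, -0.5])
    H, W = image.shape
    out = {}
    for name, (fr, fc) in {"A": (h, h), "H": (g, h), "V": (h, g),
                           "D": (g, g)}.items():
        acc = np.zeros((H, W))
        for i, wi in enumerate(fr):
            for j, wj in enumerate(fc):
                acc += wi * wj * np.roll(image, (-i, -j), axis=(0, 1))
        out[name] = acc
    return out


def spectral_annulus(shape, radius, rng, rel_width=0.08):
    """Band-limited isotropic texture whose spectrum is a thin annulus."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    rho = np.hypot(fy, fx)
    ring = ((rho > radius * (1 - rel_width)) & (rho < radius * (1 + rel_width)))
    phase = np.exp(2j * np.pi * rng.random(shape))
    return np.real(np.fft.ifft2(ring * phase))


class TestNsHaarDwt:
    def test_channel_count_and_order(self):
        st_ = T.ns_haar_dwt2(np.random.default_rng(0).random((32, 32)), 2)
        assert st_.n_channels == 7
        assert st_.channels[0] == ("dwt", 2, "A")
        assert st_.channels[1:4] == [("dwt", 1, "H"), ("dwt", 1, "V"),
                                     ("dwt", 1, "D")]

    def test_constant_image_details_vanish(self):
        st_ = T.ns_haar_dwt2(np.full((16, 16), 0.7), 2)
        assert np.abs(st_.data[..., 1:]).max() == 0
        assert np.allclose(st_.data[..., 0], 0.7)

    def test_level1_matches_brute_force_convolution(self, rng):
        img = rng.random((8, 8))
        st_ = T.ns_haar_dwt2(img, 1)
        oracle = brute_force_level1_haar(img)
        by_band = {c[2]: st_.data[..., i] for i, c in enumerate(st_.channels)}
        for band in "AHVD":
            assert np.abs(by_band[band] - oracle[band]).max() < 1e-12

    def test_round_trip(self, rng):
        img = rng.random((64, 64))
        for levels in (1, 2, 3):
            st_ = T.ns_haar_dwt2(img, levels)
            assert np.abs(T.ns_haar_idwt2(st_) - img).max() <= 1e-8

    def test_idwt_rejects_foreign_stacks(self, rng):
        stack = T.circlet_transform(rng.random((16, 16)), 2)
        with pytest.raises(ValueError):
            T.ns_haar_idwt2(stack)

    def test_zero_stack_reconstructs_zero(self):
        st_ = T.ns_haar_dwt2(np.random.default_rng(1).random((16, 16)), 2)
        st_.data[:] = 0
        assert np.abs(T.ns_haar_idwt2(st_)).max() == 0

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            T.ns_haar_dwt2(np.zeros((8, 8)), 0)


class TestCircletBank:
    def test_partition_of_unity(self):
        bank = T.build_circlet_bank((64, 64), 6)
        assert len(bank.filters) == 7
        assert np.abs(bank.filters.sum(axis=0) - 1.0).max() <= 1e-10

    def test_filters_within_unit_interval(self):
        bank = T.build_circlet_bank((48, 80), 4)
        assert bank.filters.min() >= 0.0 and bank.filters.max() <= 1.0

    def test_dc_belongs_to_lowpass(self):
        bank = T.build_circlet_bank((64, 64), 6)
        assert bank.filters[0, 0, 0] == 1.0
        assert np.abs(bank.filters[1:, 0, 0]).max() == 0.0

    def test_radial_symmetry(self):
        bank = T.build_circlet_bank((64, 64), 4)
        for f in bank.filters:   # frequency grid symmetry => filter symmetry
            assert np.allclose(f, f.T, atol=1e-12)
            assert np.allclose(f[1:, 1:], f[1:, 1:][::-1, ::-1], atol=1e-12)

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            T.build_circlet_bank((4, 4), 3)


class TestCircletTransform:
    def test_channel_sum_reconstruction(self, rng):
        img = rng.random((64, 64))
        stack = T.circlet_transform(img, 6)
        assert stack.n_channels == 7
        assert np.abs(stack.data.sum(axis=-1) - img).max() <= 1e-6

    def test_matched_annulus_maximizes_its_band(self, rng):
        bank = T.build_circlet_bank((64, 64), 6)
        for j in range(1, 7):
            tex = spectral_annulus((64, 64), bank.radii[j], rng)
            stack = T.circlet_transform(tex, 6)
            energies = [float(np.sum(stack.data[..., c] ** 2))
                        for c in range(1, 7)]
            assert int(np.argmax(energies)) + 1 == j

    def test_band_argmax_monotone_in_radius(self, rng):
        args = []
        for r in np.geomspace(0.012, 0.5, 20):
            tex = spectral_annulus((128, 128), r, rng)
            if np.allclose(tex, 0):
                continue
            stack = T.circlet_transform(tex, 6)
            energies = [float(np.sum(stack.data[..., c] ** 2))
                        for c in range(1, 7)]
            args.append(int(np.argmax(energies)))
        assert args == sorted(args)

    def test_dme_phantoms_carry_more_bandpass_energy_than_normal(self):
        """Fluid pockets add ring/edge structure, raising band-pass energy."""
        from circwave.phantom import PhantomSpec, generate_subject

        spec = PhantomSpec(scans_per_subject=2)
        def bp_energy(label, seed):
            scans = generate_subject(label, spec, seed)
            tot = 0.0
            for s in scans:
                stack = T.circlet_transform(s.image, 6)
                tot += float(np.sum(stack.data[..., 1:] ** 2))
            return tot / len(scans)
        seeds = range(100, 112)
        dme = np.mean([bp_energy("DME", s) for s in seeds])
        normal = np.mean([bp_energy("normal", s) for s in seeds])
        assert dme > normal


class TestAlgebraicProperties:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 31), st.integers(0, 31))
    def test_shift_equivariance(self, dy, dx):
        rng = np.random.default_rng(7)
        img = rng.random((32, 32))
        shifted = np.roll(img, (dy, dx), axis=(0, 1))
        for fn, kw in ((T.ns_haar_dwt2, {"levels": 2}),
                       (T.circlet_transform, {"stages": 4})):
            a = fn(img, **kw).data
            b = fn(shifted, **kw).data
            assert np.abs(np.roll(a, (dy, dx), axis=(0, 1)) - b).max() <= 1e-6

    def test_linearity(self, rng):
        x, y = rng.random((32, 32)), rng.random((32, 32))
        a, b = 2.5, -1.25
        for fn, kw in ((T.ns_haar_dwt2, {"levels": 2}),
                       (T.circlet_transform, {"stages": 4})):
            lhs = fn(a * x + b * y, **kw).data
            rhs = a * fn(x, **kw).data + b * fn(y, **kw).data
            assert np.abs(lhs - rhs).max() <= 1e-10


class TestCircWave:
    def test_default_channel_count(self, rng):
        stack = T.circwave(rng.random((64, 64)), 2, 6)
        assert stack.n_channels == 14
        names = [c[0] for c in stack.channels]
        assert names[:7] == ["dwt"] * 7 and names[7:] == ["circlet"] * 7

    def test_constant_image_nontrivial_channels(self):
        stack = T.circwave(np.full((32, 32), 0.4), 2, 6)
        active = np.abs(stack.data).max(axis=(0, 1)) > 1e-12
        labels = [stack.channels[i] for i in np.flatnonzero(active)]
        assert labels == [("dwt", 2, "A"), ("circlet", 0, "lowpass")]


class TestResizeStack:
    def test_resize_shape_and_metadata(self, rng):
        stack = T.circwave(rng.random((128, 128)))
        small = T.resize_stack(stack, 64)
        assert small.data.shape == (64, 64, 14)
        assert small.channels == stack.channels

    def test_constant_channels_stay_constant(self):
        stack = T.original_stack(np.full((100, 100), 0.3))
        small = T.resize_stack(stack, 64)
        assert np.allclose(small.data, 0.3, atol=1e-6)

    def test_identity_resize_on_smooth_image(self):
        y, x = np.mgrid[0:64, 0:64] / 64.0
        img = 0.2 + 0.3 * x + 0.1 * y
        stack = T.resize_stack(T.original_stack(img), 64)
        assert np.abs(stack.data[..., 0] - img).max() <= 1e-6


class TestHalfReconstruction:
    def test_all_channels_reproduce_image(self, rng):
        img = rng.random((64, 64)) * 0.9
        for tf in ("dwt", "circlet"):
            rec = T.reconstruct_from_half(img, tf, half="all")
            assert np.abs(rec - img).max() <= 1e-6

    def test_no_channels_give_zero(self, rng):
        rec = T.reconstruct_from_half(rng.random((64, 64)), "dwt", half="none")
        assert np.abs(rec).max() == 0

    def test_halves_are_complementary(self, rng):
        img = rng.random((64, 64)) * 0.5 + 0.25
        for tf in ("dwt", "circlet"):
            low = T.reconstruct_from_half(img, tf, "lowfreq")
            # low half keeps ceil(C/2)=4 of 7 channels; clipping aside,
            # low+high (unclipped selections) must sum to the image
            stack = (T.ns_haar_dwt2(img, 2) if tf == "dwt"
                     else T.circlet_transform(img, 6))
            assert low.shape == img.shape
            assert np.all(low >= 0) and np.all(low <= 1)

    def test_highfreq_energy_concentrates_on_band_edges(self):
        from circwave.phantom import PhantomSpec, generate_subject
        from scipy.ndimage import binary_dilation, sobel

        scan = generate_subject("normal", PhantomSpec(speckle_level=0.05), 9)[0]
        rec = T.reconstruct_from_half(scan.image, "dwt", "highfreq")
        grad = np.hypot(sobel(scan.image, 0), sobel(scan.image, 1))
        edges = binary_dilation(grad > np.percentile(grad, 90), iterations=1)
        frac_energy = rec[edges].sum() / max(rec.sum(), 1e-12)
        frac_area = edges.mean()
        assert frac_energy > frac_area

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            T.reconstruct_from_half(np.zeros((16, 16)), "shearlet", "lowfreq")


class TestRegistry:
    def test_known_names(self):
        for name in ("original", "dwt", "circlet", "circwave"):
            assert callable(T.get_transform(name))
        with pytest.raises(ValueError):
            T.get_transform("ellipselet")

    def test_pluggable_comparator(self, rng):
        T.register_transform("identity2", lambda im: T.original_stack(im))
        stack = T.transform_image(rng.random((32, 32)), "identity2", side=16)
        assert stack.data.shape == (16, 16, 1)
        del T._REGISTRY["identity2"]
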