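"""Dilated convolution against an explicit-loop oracle; pyramid pooling laws."""

import numpy as np
import pytest

from cmmnet.building_blocks import (
    DilatedConvSpec,
    PPMSpec,
    PyramidPooling,
    dilated_convolve,
    ppm_forward,
    receptive_field_side,
)


def loop_dilated_convolution_2d(f, w, r):
    """Independent oracle: direct double-loop evaluation of the dilated
    convolution sum out[x] = sum_k f[k] * w[r*(x-k)] with a centered kernel."""
    h, wd, cin = f.shape
    k = w.shape[0]
    c = k // 2
    cout = w.shape[3]
    out = np.zeros((h, wd, cout))
    for y in range(h):
        for x in range(wd):
            for i in range(k):
                for j in range(k):
                    sy, sx = y - r * (i - c), x - r * (j - c)
                    if 0 <= sy < h and 0 <= sx < wd:
                        out[y, x] += f[sy, sx] @ w[i, j]
    return out


class TestDilatedConvolve:
    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_matches_loop_oracle_on_random_inputs(self, r, rng):
        f = rng.normal(size=(7, 9, 2))
        w = rng.normal(size=(3, 3, 2, 4))
        spec = DilatedConvSpec(2, 4, dilation_rate=r, activation="none")
        got = dilated_convolve(f, spec, w)
        np.testing.assert_allclose(got, loop_dilated_convolution_2d(f, w, r),
                                   atol=1e-6)

    def test_rate_one_reduces_to_standard_convolution(self, rng):
        from scipy import ndimage
        f = rng.normal(size=(8, 8, 1))
        w = rng.normal(size=(3, 3, 1, 1))
        spec = DilatedConvSpec(1, 1, dilation_rate=1, activation="none")
        got = dilated_convolve(f, spec, w)[..., 0]
        ref = ndimage.convolve(f[..., 0], w[..., 0, 0], mode="constant")
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_1d_impulse_spreads_kernel_with_dilation_gaps(self):
        f = np.zeros(11)
        f[5] = 1.0
        w = np.array([1.0, 2.0, 3.0])
        spec = DilatedConvSpec(1, 1, dilation_rate=3, activation="none")
        out = dilated_convolve(f, spec, w)
        expect = np.zeros(11)
        expect[5 - 3], expect[5], expect[5 + 3] = 1.0, 2.0, 3.0
        np.testing.assert_array_equal(out, expect)

    def test_zero_input_gives_zero_output(self):
        spec = DilatedConvSpec(3, 2, dilation_rate=2, activation="none")
        out = dilated_convolve(np.zeros((6, 6, 3)), spec, np.ones((3, 3, 3, 2)))
        assert not out.any()

    def test_channel_mismatch_raises(self, rng):
        spec = DilatedConvSpec(3, 2)
        with pytest.raises(ValueError, match="channels"):
            dilated_convolve(rng.normal(size=(6, 6, 2)), spec,
                             np.ones((3, 3, 3, 2)))

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            DilatedConvSpec(1, 1, dilation_rate=0)


class TestReceptiveField:
    @pytest.mark.parametrize("r,side", [(1, 3), (2, 7), (3, 15)])
    def test_known_values(self, r, side):
        assert receptive_field_side(r) == side

    def test_strictly_increasing_and_odd(self):
        sides = [receptive_field_side(r) for r in range(1, 8)]
        assert all(b > a for a, b in zip(sides, sides[1:]))
        assert all(s % 2 == 1 for s in sides)

    def test_rejects_invalid_rate(self):
        with pytest.raises(ValueError):
            receptive_field_side(0)


class TestPyramidPoolingFunctional:
    def test_channel_reduction_law(self):
        # N=4 levels reduce the context dimension to C/N per level and the
        # concatenated output doubles the channels
        spec = PPMSpec(in_channels=256, pooled_sizes=[64, 21, 4, 1])
        assert spec.bottleneck_channels_per_level == 64
        assert spec.out_channels == 512

    def test_output_shape_and_channels(self, rng):
        f = rng.normal(size=(16, 16, 8))
        spec = PPMSpec(in_channels=8, pooled_sizes=[8, 4, 2, 1],
                       bottleneck_channels_per_level=3)
        out = ppm_forward(f, spec)
        assert out.shape == (16, 16, 8 + 4 * 3)

    def test_constant_input_preserved_before_projection(self, rng):
        f = np.full((12, 12, 5), 3.25)
        spec = PPMSpec(in_channels=5, pooled_sizes=[6, 3, 2, 1],
                       bottleneck_channels_per_level=5)
        # identity 1x1 kernels: each branch must return the constant itself
        kernels = [np.eye(5)] * 4
        out, branches = ppm_forward(f, spec, kernels=kernels,
                                    return_branches=True)
        for b in branches:
            np.testing.assert_allclose(b, f, atol=1e-12)

    def test_degenerate_single_level_identity_path(self, rng):
        f = rng.normal(size=(9, 9, 3))
        spec = PPMSpec(in_channels=3, pooled_sizes=[9, 3, 2, 1],
                       bottleneck_channels_per_level=3)
        out, branches = ppm_forward(f, spec, kernels=[np.eye(3)] * 4,
                                    return_branches=True)
        # pooled size == input side with identity kernel reproduces the input
        np.testing.assert_allclose(branches[0], f, atol=1e-10)

    def test_size_one_level_is_global_average(self, rng):
        f = rng.normal(size=(10, 14, 4))
        spec = PPMSpec(in_channels=4, pooled_sizes=[5, 3, 2, 1],
                       bottleneck_channels_per_level=4)
        _, branches = ppm_forward(f, spec, kernels=[np.eye(4)] * 4,
                                  return_branches=True)
        np.testing.assert_allclose(branches[-1][0, 0],
                                   f.mean(axis=(0, 1)), atol=1e-12)
        assert np.ptp(branches[-1], axis=(0, 1)).max() < 1e-12

    def test_oversized_pooled_size_rejected(self, rng):
        spec = PPMSpec(in_channels=2, pooled_sizes=[32, 4, 2, 1])
        with pytest.raises(ValueError, match="exceeds"):
            ppm_forward(rng.normal(size=(8, 8, 2)), spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="decreasing"):
            PPMSpec(in_channels=8, pooled_sizes=[4, 8, 2, 1])
        with pytest.raises(ValueError, match="smallest"):
            PPMSpec(in_channels=8, pooled_sizes=[8, 4, 2])


class TestPyramidPoolingModule:
    @pytest.mark.parametrize("c,b,n", [(8, 2, 4), (6, 3, 3), (16, 4, 4)])
    def test_out_channel_law_over_config_grid(self, c, b, n, rng):
        sizes = [2 ** (n - 1 - i) for i in range(n)]
        ppm = PyramidPooling(c, b, sizes)
        x = rng.normal(size=(1, c, 8, 8))
        out = ppm(__import__("cmmnet.nn", fromlist=["Tensor"]).Tensor(x))
        assert out.data.shape == (1, c + n * b, 8, 8)
        assert ppm.out_channels == c + n * b
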