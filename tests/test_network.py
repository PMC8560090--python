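"""Network architecture: frontend, dilated/separable convolutions,
normalization, shapes, receptive field, checkpointing."""

import numpy as np
import pytest

from songseg import build_network, init_stft_kernels, load_preset, receptive_field, upsample_repeat
from songseg.config import ClassDef, NetworkConfig
from songseg.nn import Conv1D, SeparableConv1D, STFTFrontend
from songseg.nn.layers import LOG_FLOOR, _same_pad
from songseg.nn.model import ResidualBlock


class TestSTFTKernels:
    def test_dc_bin_cos_ones_sin_zeros(self):
        cos, sin, _ = init_stft_kernels(T=16, pairs=3)
        np.testing.assert_allclose(cos[:, 0], 1.0)
        np.testing.assert_allclose(sin[:, 0], 0.0, atol=1e-15)

    def test_T4_bin1_closed_form(self):
        cos, sin, _ = init_stft_kernels(T=4, pairs=3)
        np.testing.assert_allclose(cos[:, 1], [1, 0, -1, 0], atol=1e-15)
        np.testing.assert_allclose(sin[:, 1], [0, -1, 0, 1], atol=1e-15)

    def test_default_mouse_shapes(self):
        cos, sin, freqs = init_stft_kernels(T=64, pairs=33, rate=300_000.0)
        assert cos.shape == sin.shape == (64, 33)
        assert freqs[1] == pytest.approx(300_000.0 / 64)

    def test_too_many_pairs_rejected(self):
        with pytest.raises(ValueError):
            init_stft_kernels(T=8, pairs=6)
        with pytest.raises(ValueError):
            init_stft_kernels(T=1, pairs=1)


class TestFrontendForward:
    def test_pure_tone_maximizes_matching_filter(self, rng):
        """At initialization the frontend is a rectangular-window DFT: a pure
        sinusoid at a filter's frequency wins the time-averaged response."""
        T, s, pairs, rate = 64, 16, 33, 16_000.0
        fr = STFTFrontend(T, pairs, s, rate=rate)
        bin_idx = 7
        t = np.arange(int(rate)) / rate
        x = np.sin(2 * np.pi * fr.frequencies[bin_idx] * t)[None, :, None]
        y = fr.forward(x)
        assert np.argmax(y.mean(axis=1)[0]) == bin_idx

    def test_matches_fft_log_magnitude(self, rng):
        T, s, pairs = 64, 16, 33
        fr = STFTFrontend(T, pairs, s)
        x = rng.standard_normal((1, 512, 1))
        y = fr.forward(x)
        xp = np.pad(x[0, :, 0], (0, T - s))
        for i in range(512 // s):
            spec = np.fft.rfft(xp[i * s : i * s + T])[:pairs]
            expected = np.log10(np.maximum(np.abs(spec), LOG_FLOOR))
            np.testing.assert_allclose(y[0, i], expected, atol=1e-10)

    def test_stride_16_downsamples_8192_to_512(self, rng):
        fr = STFTFrontend(64, 33, 16)
        y = fr.forward(rng.standard_normal((1, 8192, 1)))
        assert y.shape == (1, 512, 33)

    def test_zero_input_hits_log_floor(self):
        fr = STFTFrontend(64, 33, 16)
        y = fr.forward(np.zeros((1, 256, 1)))
        np.testing.assert_allclose(y, np.log10(LOG_FLOOR))


class TestDilatedConv:
    @pytest.mark.parametrize("dilation", [1, 2, 4])
    def test_matches_direct_summation_oracle(self, rng, dilation):
        """y_i(t) = sum_{tau,gamma} k(tau,gamma) x(t + a*tau - pad, gamma),
        verified against a naive per-sample summation."""
        k, c_in, c_out, n = 5, 3, 2, 40
        conv = Conv1D(c_in, c_out, k, dilation, rng=rng)
        x = rng.standard_normal((1, n, c_in))
        y = conv.forward(x)
        left, right = _same_pad(k, dilation)
        xp = np.pad(x[0], ((left, right), (0, 0)))
        for t in range(n):
            for o in range(c_out):
                ref = conv.b.v[o] + sum(
                    conv.W.v[tau, g, o] * xp[t + tau * dilation, g]
                    for tau in range(k) for g in range(c_in)
                )
                assert y[0, t, o] == pytest.approx(ref, abs=1e-12)

    def test_impulse_response_follows_dilation_pattern(self, rng):
        conv = Conv1D(1, 1, 3, dilation=4, rng=0)
        conv.b.v[...] = 0.0
        n = 32
        x = np.zeros((1, n, 1))
        x[0, 16, 0] = 1.0
        y = conv.forward(x)
        assert np.count_nonzero(y[0, :, 0]) == 3
        taps = np.flatnonzero(y[0, :, 0])
        assert np.all(np.diff(taps) == 4)

    def test_dilation_below_one_rejected(self):
        with pytest.raises(ValueError):
            Conv1D(1, 1, 3, dilation=0)


class TestSeparableConv:
    def test_single_channel_equals_full(self, rng):
        """With one input channel the separable factorization spans the same
        function family; with matched kernels the outputs are identical."""
        k, n = 5, 30
        sep = SeparableConv1D(1, 4, k, dilation=2, rng=rng)
        full = Conv1D(1, 4, k, dilation=2, rng=rng)
        full.W.v[:, 0, :] = sep.Wt.v[:, None] * sep.Wc.v[0][None, :]
        full.b.v[...] = sep.b.v
        x = rng.standard_normal((1, n, 1))
        np.testing.assert_allclose(sep.forward(x), full.forward(x), atol=1e-12)

    def test_parameter_count_tau_plus_N_gamma(self):
        sep = SeparableConv1D(9, 32, 32, rng=0)
        n_weights = sum(p.v.size for p in sep.params() if p is not sep.b)
        assert n_weights == 32 + 32 * 9  # tau + N x gamma

    def test_one_hot_channel_mix_selects_filtered_channel(self, rng):
        sep = SeparableConv1D(3, 3, 4, rng=rng)
        sep.Wc.v[...] = np.eye(3)
        sep.b.v[...] = 0.0
        x = rng.standard_normal((1, 20, 3))
        y = sep.forward(x)
        for j in range(3):
            solo = SeparableConv1D(1, 1, 4, rng=0)
            solo.Wt.v[...] = sep.Wt.v
            solo.Wc.v[...] = [[1.0]]
            solo.b.v[...] = 0.0
            np.testing.assert_allclose(y[0, :, j], solo.forward(x[:, :, j:j + 1])[0, :, 0],
                                       atol=1e-12)


class TestResidualBlock:
    def test_zero_input_zero_output(self):
        blk = ResidualBlock(4, 4, 3, 1, separable=False, rng=0)
        x = np.zeros((1, 16, 4))
        o, z = blk.forward(x)
        np.testing.assert_array_equal(o, 0.0)
        np.testing.assert_array_equal(z, 0.0)

    def test_normalization_scale(self, rng):
        """A channel whose rectified output peaks at 4 is scaled by
        1/(4 + 1e-5)."""
        from songseg.nn import MaxAbsNorm

        norm = MaxAbsNorm(1)
        x = np.array([[[1.0], [-4.0], [2.0]]])
        y = norm.forward(x, train=True)
        np.testing.assert_allclose(y, x / (4.0 + 1e-5))


class TestBuildNetwork:
    def test_fly_single_structure(self):
        cfg = load_preset("fly_single")
        net = build_network(cfg, rng=0)
        assert len(net.blocks) == 15
        assert net.blocks[-1].conv.dilation == 16
        dil = [b.conv.dilation for b in net.blocks[:5]]
        assert dil == [1, 2, 4, 8, 16]
        assert net.frontend is None

    def test_softmax_rows_sum_to_one(self, tiny_config, rng):
        net = build_network(tiny_config, rng=1)
        p = net.forward(rng.standard_normal((2, 256, 1)))
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(p >= 0) and np.all(p <= 1)

    @pytest.mark.parametrize("preset", ["fly_single", "mouse"])
    def test_output_length_equals_input_length(self, preset, rng):
        cfg = load_preset(preset)
        net = build_network(cfg, rng=0)
        n = cfg.chunk_samples
        p = net.forward(rng.standard_normal((1, n, cfg.channels)))
        assert p.shape == (1, n, cfg.n_classes)

    def test_translation_covariance_interior(self, tiny_frontend_config, rng):
        """Shifting the input by one frontend stride shifts interior outputs."""
        cfg = tiny_frontend_config
        net = build_network(cfg, rng=2)
        s = cfg.stft_stride_s
        x = rng.standard_normal((1, 4096, 1))
        shifted = np.roll(x, s, axis=1)
        p = net.forward(x)
        q = net.forward(shifted)
        margin = 1024  # > half receptive field in samples
        np.testing.assert_allclose(
            p[0, margin : -margin - s], q[0, margin + s : -margin], atol=1e-9
        )

    def test_checkpoint_roundtrip_identical_forward(self, tmp_path, tiny_config, rng):
        net = build_network(tiny_config, rng=3)
        x = rng.standard_normal((1, 512, 1))
        net.forward(x, train=True)  # move running norm stats off their init
        before = net.forward(x)
        net.save(tmp_path / "ckpt")
        from songseg.nn import Network

        back = Network.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(back.forward(x), before)


class TestUpsampleRepeat:
    def test_identity_and_repetition(self):
        y = np.array([[[0.2], [0.8]]])
        np.testing.assert_array_equal(upsample_repeat(y, 1), y)
        np.testing.assert_array_equal(
            upsample_repeat(y, 2)[0, :, 0], [0.2, 0.2, 0.8, 0.8]
        )

    def test_mouse_preset_restores_length(self, rng):
        y = rng.random((1, 512, 2))
        assert upsample_repeat(y, 16).shape == (1, 8192, 2)


class TestReceptiveField:
    def test_kernel2_single_stack(self):
        cfg = NetworkConfig(rate=1000, chunk_samples=64, kernel_size=2, kernel_count=4,
                            tcn_blocks=1, classes=[ClassDef("a", "event")])
        assert receptive_field(cfg) == 1 + 31

    def test_kernel1_contributes_nothing(self):
        cfg = NetworkConfig(rate=1000, chunk_samples=64, kernel_size=1, kernel_count=4,
                            tcn_blocks=3, classes=[ClassDef("a", "event")])
        assert receptive_field(cfg) == 1

    def test_linear_in_stacks(self):
        def rf(stacks):
            cfg = NetworkConfig(rate=1000, chunk_samples=64, kernel_size=4,
                                kernel_count=4, tcn_blocks=stacks,
                                classes=[ClassDef("a", "event")])
            return receptive_field(cfg)

        assert rf(2) - 1 == 2 * (rf(1) - 1)
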