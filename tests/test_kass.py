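"""KASS block: RSWAF basis, FasterKAN layer, selective scan, residuals."""

import numpy as np
import pytest

from angioseg import autodiff as ad
from angioseg.autodiff import Tensor
from angioseg.kass import (FasterKANLayer, KASSBlock, KassConfig,
                           LocalAttention, RswafGrid, SS2D, rswaf_basis)
from conftest import numeric_grad


class TestRswaf:
    def test_unity_at_centers(self):
        grid = RswafGrid()
        phi = rswaf_basis(grid.centers, grid)
        assert np.allclose(np.diagonal(phi), 1.0, atol=1e-12)

    def test_vanishes_far_from_centers(self):
        grid = RswafGrid()
        far = grid.centers + 20 * grid.denominator
        phi = rswaf_basis(far, grid)
        assert np.all(np.diagonal(phi) < 1e-6)

    def test_half_height_point(self):
        grid = RswafGrid()
        h = grid.centers[0] + grid.denominator * np.arctanh(1 / np.sqrt(2))
        phi = rswaf_basis(np.array(h), grid)
        assert abs(phi[0] - 0.5) < 1e-9

    def test_values_in_unit_interval(self, rng):
        grid = RswafGrid()
        phi = rswaf_basis(rng.standard_normal(100) * 5, grid)
        # analytically positive; tanh saturation can round to exactly 0
        assert phi.min() >= 0.0 and phi.max() <= 1.0
        near = rswaf_basis(rng.uniform(-4, 4, 100), grid)
        assert near.min() > 0.0

    def test_invalid_denominator_rejected(self):
        with pytest.raises(ValueError):
            RswafGrid(denominator=0.0)


class TestFasterKAN:
    def test_shape_preserved(self, rng):
        layer = FasterKANLayer(4, rng)
        x = Tensor(rng.standard_normal((1, 3, 3, 4)).astype(np.float32))
        assert layer(x).shape == x.shape

    def test_zero_combination_weights_give_zero_output(self, rng):
        layer = FasterKANLayer(4, rng, zero_init=True)
        x = Tensor(rng.standard_normal((1, 2, 2, 4)).astype(np.float32))
        assert np.all(layer(x).data == 0)

    def test_finite_difference_gradients(self, rng):
        layer = FasterKANLayer(4, rng)
        # float64 copies for a tight finite-difference check
        layer.proj.weight.data = layer.proj.weight.data.astype(np.float64)
        layer.proj.bias.data = layer.proj.bias.data.astype(np.float64)
        x = Tensor(rng.standard_normal((1, 2, 2, 4)), requires_grad=True)
        out = layer(x)
        (out * out).sum().backward()

        def f():
            return float((layer(Tensor(x.data)).data ** 2).sum())

        for t in (x, layer.proj.weight):
            ng = numeric_grad(f, t.data)
            assert np.abs(t.grad - ng).max() < 1e-4


class TestSS2D:
    def test_shape_preserved(self, rng):
        ss = SS2D(4, rng, state_dim=4)
        x = Tensor(rng.standard_normal((2, 6, 5, 4)).astype(np.float32))
        assert ss(x).shape == x.shape

    def test_zero_input_gives_zero_output(self, rng):
        ss = SS2D(4, rng, state_dim=4)
        y = ss(Tensor(np.zeros((1, 4, 4, 4), dtype=np.float32))).data
        assert np.all(y == 0)

    def test_matches_sequential_loop_oracle(self, rng):
        ss = SS2D(4, rng, state_dim=16)
        x = rng.standard_normal((1, 8, 8, 4)).astype(np.float32)
        with ad.no_grad():
            fast = ss(Tensor(x)).data
        slow = ss.scan_reference(x)
        assert np.abs(fast - slow).max() < 1e-5

    def test_invalid_state_dim_rejected(self, rng):
        with pytest.raises(ValueError):
            SS2D(4, rng, state_dim=0)


class TestLocalAttention:
    def test_shape_and_contraction(self, rng):
        la = LocalAttention(4, rng)
        x = rng.standard_normal((2, 5, 5, 4)).astype(np.float32)
        y = la(Tensor(x)).data
        assert y.shape == x.shape
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)

    def test_constant_input_gives_constant_gate_interior(self, rng):
        la = LocalAttention(3, rng)
        x = np.full((1, 9, 9, 3), 1.7, dtype=np.float32)
        y = la(Tensor(x)).data
        inner = y[0, 2:-2, 2:-2]
        assert np.allclose(inner, inner[0, 0], atol=1e-6)


class TestKASSBlock:
    def test_shape_preserved_and_vsass_tail(self, rng):
        block = KASSBlock(8, rng, downsample=True)
        x = Tensor(rng.standard_normal((1, 6, 10, 8)).astype(np.float32))
        f_kass, f_vsass = block(x, close_stage=True)
        assert f_kass.shape == x.shape
        assert f_vsass.shape == (1, 3, 5, 16)

    def test_residual_identity_with_zero_output_projections(self, rng):
        block = KASSBlock(8, rng)
        block.zero_output_init()
        x = Tensor(rng.standard_normal((1, 4, 4, 8)).astype(np.float32))
        y = block(x)
        assert np.array_equal(y.data, x.data)

    def test_every_parameter_receives_gradient(self, rng):
        for tail in ("cam_ln", "linear"):
            block = KASSBlock(8, rng, KassConfig(branch1_tail=tail))
            x = Tensor(rng.standard_normal((2, 4, 4, 8)).astype(np.float32),
                       requires_grad=True)
            out = block(x)
            (out * out).sum().backward()
            for name, p in block.named_parameters():
                assert p.grad is not None and np.any(p.grad), (tail, name)
            assert np.any(x.grad)

    def test_evaluation_mode_determinism(self, rng):
        block = KASSBlock(4, rng).eval()
        x = Tensor(rng.standard_normal((1, 4, 6, 4)).astype(np.float32))
        with ad.no_grad():
            y1 = block(x).data
            y2 = block(x).data
        assert np.array_equal(y1, y2)

    def test_vanilla_variant_runs_without_kan_and_local_attention(self, rng):
        cfg = KassConfig(use_ffn=False, use_local_attention=False)
        block = KASSBlock(4, rng, cfg)
        x = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32))
        assert block(x).shape == x.shape
        names = [n for n, _ in block.named_parameters()]
        assert not any("ffn" in n or "local_attn" in n for n in names)

    def test_invalid_tail_rejected(self, rng):
        with pytest.raises(ValueError):
            KASSBlock(4, rng, KassConfig(branch1_tail="bogus"))
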