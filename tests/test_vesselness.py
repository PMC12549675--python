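"""Frangi vesselness: closed-form examples, invariants, oracle equivalence."""

import numpy as np
import pytest

from angioseg import vesselness as vs
from oracles import frangi_oracle


class TestGaussianSmooth:
    def test_constant_image_is_preserved(self):
        img = np.full((32, 32), 7.3)
        out = vs.gaussian_smooth(img, 1.5)
        assert np.allclose(out, 7.3)

    def test_impulse_response_matches_discrete_kernel(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = vs.gaussian_smooth(img, 1.0)
        # discretised, renormalised 2-D Gaussian evaluated at the center
        xx, yy = np.meshgrid(np.arange(33) - 16.0, np.arange(33) - 16.0)
        kernel = np.exp(-(xx ** 2 + yy ** 2) / 2.0)
        kernel /= kernel.sum()
        assert abs(out[16, 16] - kernel[16, 16]) < 1e-3
        assert abs(out[16, 16] - 1 / (2 * np.pi)) < 5e-3

    def test_smoothing_contracts_variance(self, rng):
        img = rng.standard_normal((64, 64))
        out = vs.gaussian_smooth(img, 2.0)
        assert out.var() < img.var()

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            vs.gaussian_smooth(np.zeros((8, 8)), 0.0)


class TestHessianField:
    def test_constant_image_has_zero_hessian(self):
        f = vs.hessian_field(np.full((16, 16), 3.0), 1.0)
        for comp in (f.ixx, f.ixy, f.iyy):
            assert np.allclose(comp, 0.0, atol=1e-10)

    def test_separable_quadratic_second_derivative(self):
        # I(x, y) = x² → ∂²I/∂x² = 2, times σ² normalisation
        n, sigma = 64, 1.0
        x = np.arange(n, dtype=float)
        img = np.tile(x ** 2, (n, 1))
        f = vs.hessian_field(img, sigma)
        interior = (slice(16, -16), slice(16, -16))
        assert np.allclose(f.ixx[interior], 2.0 * sigma ** 2, rtol=1e-3)
        assert np.allclose(f.iyy[interior], 0.0, atol=1e-6)
        assert np.allclose(f.ixy[interior], 0.0, atol=1e-6)

    def test_rotation_by_90_swaps_components(self, rng):
        img = vs.gaussian_smooth(rng.standard_normal((32, 32)), 1.0)
        f = vs.hessian_field(img, 1.2)
        fr = vs.hessian_field(np.rot90(img), 1.2)
        assert np.allclose(fr.ixx, np.rot90(f.iyy), atol=1e-8)
        assert np.allclose(fr.iyy, np.rot90(f.ixx), atol=1e-8)
        assert np.allclose(fr.ixy, -np.rot90(f.ixy), atol=1e-8)

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError):
            vs.hessian_field(np.zeros((4, 4, 4)), 1.0)


class TestEigvals:
    def test_diagonal_matrix(self):
        f = vs.HessianField(ixx=np.array([[3.0]]), ixy=np.array([[0.0]]),
                            iyy=np.array([[1.0]]), sigma=1.0)
        e = vs.eigvals_2x2(f)
        assert e.lam1[0, 0] == 1.0 and e.lam2[0, 0] == 3.0

    def test_antidiagonal_tie_takes_algebraically_larger(self):
        f = vs.HessianField(ixx=np.array([[0.0]]), ixy=np.array([[1.0]]),
                            iyy=np.array([[0.0]]), sigma=1.0)
        e = vs.eigvals_2x2(f)
        assert e.lam2[0, 0] == 1.0 and e.lam1[0, 0] == -1.0

    def test_matches_general_eigensolver(self, rng):
        ixx = rng.standard_normal((16, 16))
        ixy = rng.standard_normal((16, 16))
        iyy = rng.standard_normal((16, 16))
        e = vs.eigvals_2x2(vs.HessianField(ixx, ixy, iyy, 1.0))
        hmat = np.stack([np.stack([ixx, ixy], -1),
                         np.stack([ixy, iyy], -1)], -2)
        vals = np.linalg.eigvalsh(hmat)
        got = np.sort(np.stack([e.lam1, e.lam2], -1), axis=-1)
        assert np.abs(got - vals).max() < 1e-10

    def test_trace_and_determinant_conserved(self, rng):
        ixx = rng.standard_normal((32, 32))
        ixy = rng.standard_normal((32, 32))
        iyy = rng.standard_normal((32, 32))
        e = vs.eigvals_2x2(vs.HessianField(ixx, ixy, iyy, 1.0))
        assert np.abs(e.lam1 + e.lam2 - (ixx + iyy)).max() < 1e-8
        assert np.abs(e.lam1 * e.lam2 - (ixx * iyy - ixy ** 2)).max() < 1e-8


class TestFrangiResponse:
    def test_flat_region_is_zero(self):
        e = vs.EigenPair(lam1=np.zeros((2, 2)), lam2=np.zeros((2, 2)))
        assert np.all(vs.frangi_response(e) == 0.0)

    def test_positive_lam2_branch_suppressed(self):
        e = vs.EigenPair(lam1=np.array([0.0]), lam2=np.array([10.0]))
        assert vs.frangi_response(e)[0] == 0.0

    def test_closed_form_spot_value(self):
        e = vs.EigenPair(lam1=np.array([0.0]), lam2=np.array([-10.0]))
        got = vs.frangi_response(e, beta=0.5, c=15.0)[0]
        expected = 1.0 * (1.0 - np.exp(-100.0 / (2.0 * 15.0 ** 2)))
        assert abs(got - expected) < 1e-12

    def test_invalid_parameters_rejected(self):
        e = vs.EigenPair(lam1=np.zeros(1), lam2=np.zeros(1))
        with pytest.raises(ValueError):
            vs.frangi_response(e, beta=0.0)
        with pytest.raises(ValueError):
            vs.frangi_response(e, c=-1.0)


class TestMultiscale:
    def test_single_scale_equals_pipeline_composition(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        vm = vs.multiscale_vesselness(img, sigmas=[1.5])
        direct = vs.frangi_response(
            vs.eigvals_2x2(vs.hessian_field(-img, 1.5)))
        assert np.allclose(vm.response, direct)

    def test_adding_scale_never_decreases_response(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        r2 = vs.multiscale_vesselness(img, sigmas=[1.0, 2.0]).response
        r3 = vs.multiscale_vesselness(img, sigmas=[1.0, 2.0, 4.0]).response
        assert np.all(r3 >= r2 - 1e-12)

    def test_response_in_unit_interval_and_sigma_of_max_valid(self, rng):
        img = rng.uniform(0, 255, (48, 48))
        vm = vs.multiscale_vesselness(img)
        assert vm.response.min() >= 0.0 and vm.response.max() <= 1.0
        assert np.all(np.isin(vm.sigma_of_max, vs.default_sigmas()))

    def test_empty_sigma_list_rejected(self):
        with pytest.raises(ValueError):
            vs.multiscale_vesselness(np.zeros((16, 16)), sigmas=[])

    def test_oracle_equivalence_on_random_images(self, rng):
        sigmas = vs.default_sigmas()
        for _ in range(5):
            img = rng.uniform(0, 255, (32, 32))
            mine = vs.multiscale_vesselness(img, sigmas=sigmas).response
            ref = frangi_oracle(img, sigmas, beta=0.5, c=15.0)
            assert np.abs(mine - ref).max() < 1e-6

    def test_rotation_covariance(self, rng):
        # covariance holds to rounding: the separable filters are applied
        # axis 0 then axis 1, so rotation permutes summation order only
        img = rng.uniform(0, 255, (32, 32))
        a = vs.multiscale_vesselness(np.rot90(img)).response
        b = np.rot90(vs.multiscale_vesselness(img).response)
        assert np.abs(a - b).max() < 1e-12

    def test_contrast_monotonicity_on_tube(self):
        from angioseg.phantoms import tube_phantom
        means = []
        for contrast in (40.0, 80.0):
            img, center = tube_phantom(5, frame_size=96, contrast_depth=contrast,
                                       noise_sigma=0.0, blur_sigma=0.6)
            vm = vs.multiscale_vesselness(img, sigmas=[0.5, 1, 2, 4])
            rows = np.arange(10, 86)
            cols = np.round(center[rows]).astype(int)
            means.append(vm.response[rows, cols].mean())
        assert means[1] >= means[0]

    def test_centerline_localisation_on_tube_phantoms(self):
        from angioseg.phantoms import tube_phantom
        hits = tot = 0
        for seed in range(3):
            img, center = tube_phantom(seed, frame_size=128, half_width=2.0)
            vm = vs.multiscale_vesselness(img, sigmas=[0.5, 1, 2, 4])
            for row in range(8, 120):
                peak = np.argmax(vm.response[row])
                tot += 1
                hits += abs(peak - center[row]) <= 1.0
        assert hits / tot >= 0.95
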