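import numpy as np
import pytest

from smpci import (
    DetectorImage,
    PixelFields,
    compute_pixel_fields,
    cosine_mask,
    dpc_to_refraction,
    flat_correct,
    flat_field_image,
    make_cylinder_phantom,
    make_gaussian_phantom,
    mask_coefficients,
    retrieve_pb_dpc,
    single_mask_image_closed_form,
)
from smpci import MATERIALS
from smpci.mask_model import MaskCoefficients


def forward(fields, co, g, parity=0):
    sample = single_mask_image_closed_form(fields, co, parity=parity, geometry=g)
    flat = flat_field_image(co, g)
    return flat_correct(sample, flat, parity=parity)


def kernel_truth(truth: np.ndarray, pair) -> np.ndarray:
    """Ground truth averaged with the estimator's documented column kernel."""
    if pair.pairing == "disjoint":
        n = 2 * len(pair.x)
        return 0.5 * (truth[..., 0:n:2] + truth[..., 1:n:2])
    w = np.array(pair.meta["kernel"])
    out = np.apply_along_axis(lambda r: np.convolve(r, w, mode="same"), -1, truth)
    return out


class TestFlatCorrect:
    def test_sample_equal_flat_gives_unity(self, small_geometry):
        g = small_geometry
        co = mask_coefficients(cosine_mask(g.p))
        flat = flat_field_image(co, g)
        corr = flat_correct(flat, flat)
        np.testing.assert_allclose(corr.values, 1.0)

    def test_half_intensity_gives_half(self, small_geometry):
        g = small_geometry
        co = mask_coefficients(cosine_mask(g.p))
        flat = flat_field_image(co, g)
        half = DetectorImage(0.5 * flat.values, p=g.p)
        np.testing.assert_allclose(flat_correct(half, flat).values, 0.5)

    def test_recovers_dimensionless_model_exactly(self, small_geometry):
        """sample/flat = Tn(1-Ln) + s_n (alpha/we) Tn Dn, by construction."""
        g = small_geometry
        co = mask_coefficients(cosine_mask(g.p))
        obj = make_gaussian_phantom(20.0, 0.1, 8 * g.p, g)
        f = compute_pixel_fields(obj, g)
        corr = forward(f, co, g)
        from smpci.forward_tie import parity_signs
        signs = parity_signs(g.nx)
        expected = f.Tn * (1 - f.Ln) + signs * (co.alpha / co.we) * f.Tn * f.Dn
        np.testing.assert_allclose(corr.values, expected, rtol=1e-12)

    def test_masks_dead_flat_pixels(self, small_geometry):
        g = small_geometry
        co = mask_coefficients(cosine_mask(g.p))
        flat = flat_field_image(co, g)
        flat.values[1, 3] = 0.0
        corr = flat_correct(flat_field_image(co, g), flat)
        assert not corr.valid[1, 3]
        assert np.isnan(corr.values[1, 3])

    def test_rejects_shape_mismatch(self, small_geometry):
        g = small_geometry
        co = mask_coefficients(cosine_mask(g.p))
        flat = flat_field_image(co, g)
        other = DetectorImage(np.ones((g.ny, g.nx + 2)), p=g.p)
        with pytest.raises(ValueError):
            flat_correct(other, flat)


class TestRetrieve:
    def test_constant_image_gives_flat_pb_and_zero_dpc(self, small_geometry):
        g = small_geometry
        co = mask_coefficients(cosine_mask(g.p))
        from smpci.retrieval import CorrectedImage
        corr = CorrectedImage(np.full((g.ny, g.nx), 0.8))
        for pairing in ("disjoint", "sliding"):
            pair = retrieve_pb_dpc(corr, co, pairing=pairing, geometry=g)
            np.testing.assert_allclose(pair.pb, 0.8, rtol=1e-12)
            np.testing.assert_allclose(pair.dpc, 0.0, atol=1e-18)

    def test_single_pair_substitution(self, small_geometry):
        """(1+d, 1-d) on (even, odd) columns retrieves dpc = +(we/alpha)d."""
        g = small_geometry
        co = mask_coefficients(cosine_mask(g.p))
        d = 0.01
        vals = np.tile(np.where(np.arange(g.nx) % 2 == 0, 1 + d, 1 - d), (g.ny, 1))
        from smpci.retrieval import CorrectedImage
        pair = retrieve_pb_dpc(CorrectedImage(vals), co, pairing="disjoint", geometry=g)
        np.testing.assert_allclose(pair.pb, 1.0, rtol=1e-12)
        np.testing.assert_allclose(pair.dpc, co.we / co.alpha * d, rtol=1e-12)

    def test_exact_recovery_for_pairwise_constant_fields(self, small_geometry):
        """If Tn, Dn are constant in each pair and Ln=0 the formulas are
        exact, so retrieval returns the ground truth to machine precision."""
        g = small_geometry
        co = mask_coefficients(cosine_mask(g.p))
        rng = np.random.default_rng(7)
        npair = g.nx // 2
        T_pair = rng.uniform(0.6, 1.0, (g.ny, npair))
        D_pair = rng.uniform(-2e-6, 2e-6, (g.ny, npair))
        T = np.repeat(T_pair, 2, axis=1)
        D = np.repeat(D_pair, 2, axis=1)
        f = PixelFields(T, np.zeros_like(T), D)
        pair = retrieve_pb_dpc(forward(f, co, g), co, pairing="disjoint", geometry=g)
        np.testing.assert_allclose(pair.pb, T_pair, rtol=1e-12)
        np.testing.assert_allclose(pair.dpc, D_pair, rtol=1e-10, atol=1e-20)

    def test_round_trip_recovers_displacement_on_smooth_phantom(self, bench_geometry):
        g = bench_geometry
        co = mask_coefficients(cosine_mask(g.p))
        obj = make_gaussian_phantom(50.0, 0.05, 10 * g.p, g)
        f = compute_pixel_fields(obj, g)
        corr = forward(f, co, g)
        pair = retrieve_pb_dpc(corr, co, pairing="sliding", geometry=g,
                               pb_gradient_correction=True)
        Dk = kernel_truth(f.Dn, pair)
        interior = (slice(None), slice(2, -2))
        scale = np.abs(Dk).max()
        assert np.max(np.abs(pair.dpc[interior] - Dk[interior])) / scale < 0.01
        Ak = kernel_truth(f.Tn * (1 - f.Ln), pair)
        assert np.max(
            np.abs(pair.pb[interior] - Ak[interior]) / Ak[interior]
        ) < 0.005

    def test_attenuation_only_null(self, bench_geometry):
        """phi=0: uniform attenuation gives exactly zero dpc; a smooth
        attenuation gradient leaks only at the documented crosstalk level."""
        g = bench_geometry
        co = mask_coefficients(cosine_mask(g.p))
        uniform = PixelFields(
            np.full((g.ny, g.nx), 0.8),
            np.zeros((g.ny, g.nx)),
            np.zeros((g.ny, g.nx)),
        )
        pair = retrieve_pb_dpc(forward(uniform, co, g), co, pairing="sliding",
                               geometry=g, pb_gradient_correction=True)
        assert np.nanmax(np.abs(pair.dpc)) < 1e-10
        # smooth gradient: disjoint-pair crosstalk ~ (we/2 alpha) p |d lnT/dx|
        obj = make_gaussian_phantom(0.0, 0.2, 10 * g.p, g)
        f = compute_pixel_fields(obj, g)
        dis = retrieve_pb_dpc(forward(f, co, g), co, pairing="disjoint", geometry=g)
        bound = (co.we / (2 * co.alpha)) * g.p * 0.2 * np.exp(-0.5) / (10 * g.p) * 2
        assert 0 < np.nanmax(np.abs(dis.dpc)) < bound
        # the balanced estimator suppresses it by >10x
        sld = retrieve_pb_dpc(forward(f, co, g), co, pairing="sliding", geometry=g,
                              pb_gradient_correction=True)
        assert np.nanmax(np.abs(sld.dpc)) < np.nanmax(np.abs(dis.dpc)) / 10

    def test_cylinder_dpc_antisymmetric_pb_symmetric(self, bench_geometry):
        g = bench_geometry
        co = mask_coefficients(cosine_mask(g.p))
        obj = make_cylinder_phantom(1.5e-3, MATERIALS["pmma"], g)
        f = compute_pixel_fields(obj, g)
        pair = retrieve_pb_dpc(forward(f, co, g), co, pairing="sliding", geometry=g)
        d, b = pair.dpc[0], pair.pb[0]
        scale = np.nanmax(np.abs(d))
        np.testing.assert_allclose(d[1:-1], -d[::-1][1:-1], atol=1e-10 * scale)
        np.testing.assert_allclose(b[1:-1], b[::-1][1:-1], rtol=1e-10)

    def test_bias_shrinks_quadratically_with_pixel_size(self):
        """Halving p cuts the sliding-mode retrieval error ~4x (same object)."""
        errs = []
        from smpci import Geometry
        for p, nx in ((55e-6, 64), (27.5e-6, 128)):
            g = Geometry(z=0.6, p=p, nx=nx, ny=4, energy=20.0, s=16)
            co = mask_coefficients(cosine_mask(g.p))
            obj = make_gaussian_phantom(50.0, 0.05, 55e-5, g)  # fixed physical scale
            f = compute_pixel_fields(obj, g)
            pair = retrieve_pb_dpc(forward(f, co, g), co, pairing="sliding",
                                   geometry=g)
            Dk = kernel_truth(f.Dn, pair)
            interior = (slice(None), slice(2, -2))
            errs.append(
                np.max(np.abs(pair.dpc[interior] - Dk[interior])) / np.abs(Dk).max()
            )
        assert errs[0] / errs[1] > 3.0

    def test_rejects_zero_contrast_for_dpc(self, small_geometry):
        g = small_geometry
        from smpci.retrieval import CorrectedImage
        corr = CorrectedImage(np.ones((g.ny, g.nx)))
        with pytest.raises(ValueError):
            retrieve_pb_dpc(corr, MaskCoefficients(we=g.p, alpha=0.0), geometry=g)

    def test_parity_flag_flips_dpc_sign(self, small_geometry):
        g = small_geometry
        co = mask_coefficients(cosine_mask(g.p))
        obj = make_gaussian_phantom(50.0, 0.0, 8 * g.p, g)
        f = compute_pixel_fields(obj, g)
        corr0 = forward(f, co, g, parity=0)
        pair0 = retrieve_pb_dpc(corr0, co, pairing="disjoint", geometry=g)
        from smpci.retrieval import CorrectedImage
        corr_wrong = CorrectedImage(corr0.values, parity=1)
        pair1 = retrieve_pb_dpc(corr_wrong, co, pairing="disjoint", geometry=g)
        np.testing.assert_allclose(pair1.dpc, -pair0.dpc, rtol=1e-12)


class TestRefraction:
    def test_zero_maps_to_zero(self, small_geometry):
        g = small_geometry
        co = mask_coefficients(cosine_mask(g.p))
        from smpci.retrieval import CorrectedImage
        pair = retrieve_pb_dpc(CorrectedImage(np.ones((g.ny, g.nx))), co, geometry=g)
        np.testing.assert_array_equal(dpc_to_refraction(pair, g), 0.0)

    def test_micron_displacement_at_60cm(self, small_geometry):
        g = small_geometry
        co = mask_coefficients(cosine_mask(g.p))
        from smpci.retrieval import CorrectedImage, RetrievedPair
        pair = RetrievedPair(
            pb=np.ones((1, 4)), dpc=np.full((1, 4), 1e-6),
            x=np.arange(4.0), pairing="disjoint",
        )
        np.testing.assert_allclose(
            dpc_to_refraction(pair, g), 1e-6 / 0.6, rtol=1e-12
        )

    def test_angle_invariant_under_distance_change(self):
        """Doubling z doubles Dn but leaves the recovered angle fixed."""
        from smpci import Geometry
        angles = []
        for z in (0.6, 1.2):
            g = Geometry(z=z, p=55e-6, nx=64, ny=4, energy=20.0, s=16)
            co = mask_coefficients(cosine_mask(g.p))
            obj = make_gaussian_phantom(50.0, 0.0, 8 * g.p, g)
            f = compute_pixel_fields(obj, g)
            pair = retrieve_pb_dpc(forward(f, co, g), co, pairing="sliding",
                                   geometry=g, pb_gradient_correction=True)
            angles.append(dpc_to_refraction(pair, g)[0])
        # equality holds to the level of the retrieval bias, which is not
        # strictly z-independent
        scale = np.nanmax(np.abs(angles[0]))
        np.testing.assert_allclose(angles[0], angles[1], rtol=5e-3, atol=1e-3 * scale)
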