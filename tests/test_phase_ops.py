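"""Laplacian unwrapping, reliability masking, echo combination, T2* fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsmpipe import (
    DegenerateMaskError,
    ParameterError,
    PhaseImage,
    combine_echoes,
    echo_weights,
    fit_t2star,
    laplacian_unwrap,
    phase_reliability,
    refine_mask,
)
from qsmpipe.core import wrap_phase


def _quadratic_ramp(shape=(48, 48, 32), span=6 * np.pi):
    x, y, z = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape], indexing="ij")
    phi = span / 2 * (x**2 + 0.5 * y**2 + 0.3 * z)
    return phi


class TestLaplacianUnwrap:
    def test_recovers_multi_wrap_ramp(self):
        phi = _quadratic_ramp()
        mask = np.ones(phi.shape, bool)
        out = laplacian_unwrap(wrap_phase(phi), mask)
        ref = phi - phi.mean()
        inner = np.zeros_like(mask)
        inner[3:-3, 3:-3, 3:-3] = True
        rms = np.sqrt(np.mean((out.values[inner] - ref[inner]) ** 2))
        assert rms < 0.1

    def test_constant_phase_maps_to_zero(self):
        out = laplacian_unwrap(np.full((16, 16, 16), 0.5), np.ones((16, 16, 16), bool))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_invariant_to_2pi_shift(self):
        phi = _quadratic_ramp((32, 32, 16))
        mask = np.ones(phi.shape, bool)
        a = laplacian_unwrap(wrap_phase(phi), mask).values
        b = laplacian_unwrap(wrap_phase(phi + 2 * np.pi), mask).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_unwrapped_input_warns_and_passes_through(self):
        img = PhaseImage(values=np.zeros((8, 8, 8)), wrapped=False)
        with pytest.warns(UserWarning):
            laplacian_unwrap(img, np.ones((8, 8, 8), bool))


class TestPhaseReliability:
    def test_constant_phase_fully_reliable(self):
        rel = phase_reliability(np.exp(1j * np.full((6, 6, 6), 0.3)))
        np.testing.assert_allclose(rel.values, 1.0)

    def test_opposed_neighbors_zero_reliability(self):
        # voxel at pi, all neighbours at 0 -> neighbour gradient pi
        phase = np.zeros((7, 7, 7))
        phase[3, 3, 3] = np.pi
        rel = phase_reliability(np.exp(1j * phase))
        assert rel.values[3, 3, 3] == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_half_reliability(self):
        # +-pi/4 checkerboard: every neighbour differs by pi/2 -> 1 - 1/2
        idx = np.indices((4, 4, 4)).sum(axis=0) % 2
        phase = np.where(idx, np.pi / 4, -np.pi / 4)
        rel = phase_reliability(np.exp(1j * phase))
        np.testing.assert_allclose(rel.values, 0.5, atol=1e-12)


class TestRefineMask:
    def test_fully_reliable_keeps_mask(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        ones = np.ones(mask.shape)
        np.testing.assert_array_equal(refine_mask(mask, ones, ones), mask)

    def test_first_echo_threshold_is_070(self):
        mask = np.ones((4, 4, 4), bool)
        r1 = np.ones(mask.shape)
        r1[1, 2, 3] = 0.69
        out = refine_mask(mask, r1, np.ones(mask.shape))
        assert not out[1, 2, 3] and out.sum() == mask.sum() - 1

    def test_second_echo_061_survives(self):
        mask = np.ones((4, 4, 4), bool)
        out = refine_mask(mask, np.ones(mask.shape), np.full(mask.shape, 0.61))
        np.testing.assert_array_equal(out, mask)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        mask = np.ones((8, 8, 8), bool)
        r1, r2 = rng.uniform(0.5, 1, mask.shape), rng.uniform(0.5, 1, mask.shape)
        lo = refine_mask(mask, r1, r2, 0.6, 0.55)
        hi = refine_mask(mask, r1, r2, 0.8, 0.7)
        assert not np.any(hi & ~lo)

    def test_empty_result_raises(self):
        mask = np.ones((4, 4, 4), bool)
        with pytest.raises(DegenerateMaskError):
            refine_mask(mask, np.zeros(mask.shape), np.ones(mask.shape))


class TestEchoCombination:
    def test_printed_weights(self):
        w = echo_weights((9.4, 20.0), 40.0)
        assert w[0] == pytest.approx(0.3798, abs=2e-4)
        assert w[1] == pytest.approx(0.6202, abs=2e-4)
        assert w.sum() == pytest.approx(1.0)

    def test_infinite_t2star_limit_weights_by_te(self):
        w = echo_weights((9.4, 20.0), 1e12)
        np.testing.assert_allclose(w, [9.4 / 29.4, 20.0 / 29.4], atol=1e-9)

    def test_identical_echoes_pass_through(self):
        phi = np.random.default_rng(1).normal(size=(8, 8, 8))
        out = combine_echoes(phi, phi)
        np.testing.assert_allclose(out.values, phi)

    def test_effective_te_recorded(self):
        out = combine_echoes(np.zeros((8, 8, 8)), np.zeros((8, 8, 8)))
        w = echo_weights((9.4, 20.0), 40.0)
        assert out.effective_te_ms == pytest.approx(w[0] * 9.4 + w[1] * 20.0)

    def test_te_order_enforced(self):
        z = np.zeros((8, 8, 8))
        with pytest.raises(ParameterError):
            combine_echoes(z, z, te_ms=(20.0, 9.4))

    @given(
        te1=st.floats(1.0, 15.0),
        dte=st.floats(0.5, 30.0),
        t2s=st.floats(5.0, 200.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_weights_positive_and_normalized(self, te1, dte, t2s):
        w = echo_weights((te1, te1 + dte), t2s)
        assert np.all(w > 0)
        assert w.sum() == pytest.approx(1.0)


class TestT2StarFit:
    def test_exact_inverse_of_construction(self):
        m1 = np.full((6, 6, 6), 100.0)
        m2 = m1 * np.exp(-10.6 / 40.0)
        t2s = fit_t2star(m1, m2, (9.4, 20.0))
        np.testing.assert_allclose(t2s.values, 40.0, atol=1e-10)

    def test_non_decaying_signal_invalid(self):
        m = np.full((4, 4, 4), 10.0)
        t2s = fit_t2star(m, m, (9.4, 20.0))
        assert not t2s.valid_mask.any()
        assert np.isnan(t2s.values).all()

    def test_phantom_roi_t2star_recovered(self):
        from qsmpipe import PhantomSpec, ROISpec, forward_field, make_phantom, synthesize_multicoil

        spec = PhantomSpec(
            grid_shape=(32, 32, 24),
            rois=(ROISpec("r", "ellipsoid", (16, 16, 12), (5, 5, 3), 50.0, 60.0),),
            noise_sd=0.0, n_coils=1, seed=0,
        )
        ph = make_phantom(spec)
        mc = synthesize_multicoil(ph, forward_field(ph), uniform_coils=True)
        t2s = fit_t2star(np.abs(mc.data[0, 0]), np.abs(mc.data[0, 1]), (9.4, 20.0))
        roi = ph.labels == 1
        assert np.median(t2s.values[roi]) == pytest.approx(60.0, abs=0.1)
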