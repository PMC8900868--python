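"""Unit and property tests for the phase-symmetry COR estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter1d

from tomocor import (
    ProjectionImage,
    ReflectionPair,
    Sinogram,
    arcsine_theta_sum,
    find_center_phase_symmetry,
    make_reflection_pair,
    normalize_background_edges,
    phase_at_fmin,
    phase_to_shift,
    point_sinogram,
    reflection_sum,
    shepp_logan_3d,
    theta_sum,
)
from tomocor.exceptions import DegenerateInputError, InvalidInputError

from conftest import pair_symmetry_center


class TestThetaSum:
    def test_linearity_and_identity(self):
        zero = Sinogram(np.zeros((4, 8)), np.arange(4.0))
        assert np.array_equal(theta_sum(zero).profile, np.zeros(8))
        row = np.array([[1.0, 2.0, 3.0, 4.0]])
        single = Sinogram(row, np.array([0.0]))
        assert np.array_equal(theta_sum(single).profile, row[0])
        assert theta_sum(single).n_projections_summed == 1

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            theta_sum(Sinogram(np.empty((0, 8)), np.empty(0)))

    def test_point_object_matches_arcsine_density(self):
        # 3600-angle orbit of a blurred point: theta-sum should match the
        # closed-form arcsine density convolved with the same blur.
        angles = np.arange(3600) * 0.1
        sino = point_sinogram(40.0, 127.5, angles, blur_sigma=2.0, n_t=256)
        profile = theta_sum(sino).profile
        profile = profile / profile.sum()
        oracle = arcsine_theta_sum(40.0, 127.5, np.arange(256.0))
        oracle = gaussian_filter1d(oracle, 2.0, mode="constant")
        oracle = oracle / oracle.sum()
        assert np.abs(profile - oracle).sum() < 0.02


class TestReflectionSum:
    def test_elementwise_sum_and_k_index(self):
        p = ProjectionImage(np.array([[1.0, 2.0, 3.0, 2.0]]))
        pair = ReflectionPair(p, p)
        profile, k = reflection_sum(pair, collapse="rows_collapsed")
        assert np.array_equal(profile, [2.0, 4.0, 6.0, 4.0])
        assert k == 1

    def test_flattened_layout(self):
        data = np.arange(8.0).reshape(2, 4)
        pair = ReflectionPair(ProjectionImage(data), ProjectionImage(data))
        flat, k = reflection_sum(pair, collapse="flattened")
        assert flat.shape == (8,)
        assert k == 2
        assert np.array_equal(flat, 2 * data.ravel())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            ReflectionPair(
                ProjectionImage(np.zeros((1, 4))), ProjectionImage(np.zeros((1, 5)))
            )

    def test_analytic_pair_is_even_about_axis(self, shepp_pair_factory):
        # Half-integer offset: the symmetry center 2c = 255 + 2*7.5 lands on
        # the lattice, so evenness is exact sample-for-sample.
        pair = shepp_pair_factory(7.5, theta_prime_deg=30.0)
        profile, _ = reflection_sum(pair, collapse="rows_collapsed")
        # mirror about c = 127.5 + 7.5: S[i] == S[270 - i] for valid i
        idx = np.arange(15, 256)
        asym = np.abs(profile[idx] - profile[270 - idx]).max()
        assert asym < 1e-9 * profile.max()


class TestPhaseAtFmin:
    def test_centered_even_signal_has_zero_phase(self):
        t = np.arange(256)
        sig = np.exp(-((t - 127.5) ** 2) / 50.0)
        phi, r, i = phase_at_fmin(sig, 1)
        assert abs(phi) < 1e-9

    def test_polarity_invariance(self):
        t = np.arange(64)
        sig = np.cos(2 * np.pi * (t - 30.0) / 64) + 0.2
        phi_pos, *_ = phase_at_fmin(sig, 1)
        phi_neg, *_ = phase_at_fmin(-sig, 1)
        assert phi_pos == pytest.approx(phi_neg, abs=1e-12)

    def test_shift_theorem_on_cyclic_shift(self):
        # A 3-sample cyclic shift of a centered Gaussian should move the
        # bin-1 phase by 2*pi*3/256 (DFT shift theorem).
        t = np.arange(256)
        sig = np.exp(-((t - 127.5) ** 2) / 50.0)
        phi, *_ = phase_at_fmin(np.roll(sig, 3), 1)
        assert abs(phi) == pytest.approx(2 * np.pi * 3 / 256, rel=1e-6)
        # cross-check against a direct DFT summation
        direct = np.exp(-2j * np.pi * t / 256) @ np.roll(sig, 3)
        direct *= np.exp(2j * np.pi * (255 / 2) / 256)
        assert phi == pytest.approx(np.arctan(direct.imag / direct.real), abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            phase_at_fmin(np.ones(32), 1)
        with pytest.raises(InvalidInputError):
            phase_at_fmin(np.arange(4.0), 2)


class TestPhaseToShift:
    def test_linearity(self):
        assert phase_to_shift(0.0, 1, 256) == 0.0
        assert abs(phase_to_shift(2 * np.pi * 2 / 256, 1, 256)) == pytest.approx(2.0)
        # doubling k at fixed phase halves the shift
        assert phase_to_shift(0.1, 2, 512) == pytest.approx(
            phase_to_shift(0.1, 1, 256)
        )

    def test_preconditions(self):
        with pytest.raises(InvalidInputError):
            phase_to_shift(0.1, 0, 256)


class TestFindCenterPhaseSymmetry:
    @pytest.mark.parametrize("t_prime", [-16.0, -7.25, -1.0, 0.0, 0.5, 5.3, 16.0])
    def test_noiseless_exact_recovery(self, shepp_pair_factory, t_prime):
        est = find_center_phase_symmetry(shepp_pair_factory(t_prime))
        assert est.t_prime == pytest.approx(t_prime, abs=0.05)
        assert est.cor_absolute == pytest.approx(127.5 + t_prime, abs=0.05)

    def test_polarity_invariance(self, shepp_pair_factory):
        pair = shepp_pair_factory(5.3)
        t_trans = find_center_phase_symmetry(pair).t_prime
        flipped = ReflectionPair(
            ProjectionImage(-pair.p1.data, 0.0, "emission"),
            ProjectionImage(-pair.p2.data, 180.0, "emission"),
        )
        assert find_center_phase_symmetry(flipped).t_prime == pytest.approx(
            t_trans, abs=1e-9
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        gain=st.floats(0.01, 100.0, allow_nan=False),
        offset=st.floats(-50.0, 50.0, allow_nan=False),
    )
    def test_gain_offset_invariance(self, shepp_pair_factory, gain, offset):
        pair = shepp_pair_factory(3.3)
        base = find_center_phase_symmetry(pair).t_prime
        scaled = ReflectionPair(
            ProjectionImage(gain * pair.p1.data + offset, 0.0),
            ProjectionImage(gain * pair.p2.data + offset, 180.0),
        )
        assert find_center_phase_symmetry(scaled).t_prime == pytest.approx(
            base, abs=1e-9
        )

    @pytest.mark.parametrize("t_prime", [-7.25, 0.0, 5.3])
    def test_agrees_with_brute_force_symmetry_search(
        self, shepp_pair_factory, t_prime
    ):
        pair = shepp_pair_factory(t_prime)
        est = find_center_phase_symmetry(pair).t_prime
        oracle = pair_symmetry_center(pair)
        assert est == pytest.approx(oracle, abs=0.25)

    def test_collapse_modes_are_equivalent(self):
        pair = make_reflection_pair(shepp_logan_3d(grid=64, cor_offset=2.2))
        flat = find_center_phase_symmetry(pair, collapse="flattened")
        rows = find_center_phase_symmetry(pair, collapse="rows_collapsed")
        assert flat.diagnostics["phi"] == pytest.approx(
            rows.diagnostics["phi"], abs=1e-12
        )
        assert flat.diagnostics["k_index"] == 64
        assert rows.diagnostics["k_index"] == 1

    def test_principal_branch_wraps_beyond_quarter_width(self):
        # Shifts are only identifiable within |t'| < n_t/4 = 64; a blob at
        # +70 px aliases to 70 - 128 = -58.
        t = np.arange(256.0)
        blob = np.exp(-((t - (127.5 + 70.0)) ** 2) / 50.0)[None, :]
        pair = ReflectionPair(ProjectionImage(blob), ProjectionImage(blob))
        est = find_center_phase_symmetry(pair).t_prime
        assert est == pytest.approx(70.0 - 128.0, abs=0.05)
        # just inside the branch: recovered faithfully
        blob = np.exp(-((t - (127.5 + 60.0)) ** 2) / 50.0)[None, :]
        pair = ReflectionPair(ProjectionImage(blob), ProjectionImage(blob))
        assert find_center_phase_symmetry(pair).t_prime == pytest.approx(60.0, abs=0.05)


class TestNormalizeBackgroundEdges:
    def test_identity_when_edges_match(self, shepp_pair_factory):
        p = shepp_pair_factory(2.0).p1
        out = normalize_background_edges(p, margin=12)
        assert np.abs(out.data - p.data).max() < 1e-12

    def test_linear_ramp_removed_from_flat_image(self):
        t = np.arange(128.0)
        ramped = (1.0 + 0.003 * (t - 63.5))[None, :] * np.ones((3, 1))
        out = normalize_background_edges(ProjectionImage(ramped), margin=6)
        assert abs(out.data[:, :6].mean() - out.data[:, -6:].mean()) < 1e-9
        assert out.data.mean() == pytest.approx(ramped.mean())

    def test_margin_too_wide_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize_background_edges(ProjectionImage(np.ones((1, 8))), margin=4)

    def test_recovers_cor_under_illumination_gradient(self, shepp_pair_factory):
        pair = shepp_pair_factory(2.0)
        base = find_center_phase_symmetry(pair).t_prime
        ramp = 1.0 + 0.001 * (np.arange(256) - 127.5)
        ramped = ReflectionPair(
            ProjectionImage(pair.p1.data * ramp, 0.0),
            ProjectionImage(pair.p2.data * ramp, 180.0),
        )
        biased = find_center_phase_symmetry(ramped).t_prime
        assert abs(biased - base) > 1.0
        fixed = ReflectionPair(
            normalize_background_edges(ramped.p1, 12),
            normalize_background_edges(ramped.p2, 12),
        )
        assert find_center_phase_symmetry(fixed).t_prime == pytest.approx(
            base, abs=0.2
        )
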