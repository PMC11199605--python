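"""Nonlocal interaction-redistribution model: kernels, feedbacks, dynamics."""

import numpy as np
import pytest

from fogbands.grids import Field2D
from fogbands.nonlocal_model import (
    NonlocalOperator,
    NonlocalParams,
    build_kernel,
    rhs_nonlocal,
    simulate_nonlocal,
    uniform_states_nonlocal,
)


def _uniform_field(value, nx=48, ny=48, dx=0.75, dy=0.75, bc_x="periodic"):
    return Field2D(np.full((nx, ny), float(value)), dx=dx, dy=dy,
                   bc_x=bc_x, bc_y="periodic")


class TestKernels:
    @pytest.mark.parametrize("which", ["facilitation", "competition"])
    def test_printed_width_sets_have_unit_mass(self, nonlocal_ref, which):
        # acceptance-scale grid: 60 x 36 box
        k = build_kernel(nonlocal_ref, which, (160, 96), 0.375, 0.375)
        assert abs(k.sum() * 0.375 * 0.375 - 1.0) < 1e-3

    def test_centered_kernel_peaks_at_zero_lag(self, nonlocal_ref):
        from dataclasses import replace

        p = replace(nonlocal_ref, x0f=0.0)
        k = build_kernel(p, "f", (64, 64), 0.3, 0.3)
        assert np.unravel_index(np.argmax(k), k.shape) == (0, 0)

    def test_offset_kernel_peaks_at_offset_lag(self, nonlocal_ref):
        # facilitation offset x0f = 0.5 on a dx = 0.25 grid -> lag index 2
        k = build_kernel(nonlocal_ref, "f", (64, 64), 0.25, 0.25)
        assert np.unravel_index(np.argmax(k), k.shape) == (2, 0)

    def test_offset_sign_flip_is_mirror_image(self, nonlocal_ref):
        from dataclasses import replace

        k_pos = build_kernel(nonlocal_ref, "f", (64, 64), 0.25, 0.25)
        k_neg = build_kernel(replace(nonlocal_ref, x0f=-0.5), "f", (64, 64), 0.25, 0.25)
        # mirror in x on the wrap grid: index i -> -i mod n
        mirrored = np.roll(k_pos[::-1, :], 1, axis=0)
        np.testing.assert_allclose(k_neg, mirrored, atol=1e-12)
        # nonreciprocity: with a nonzero offset the kernel is NOT symmetric
        assert not np.allclose(k_pos, mirrored)

    def test_too_small_grid_raises_naming_extent(self, nonlocal_ref):
        with pytest.raises(ValueError, match="extent"):
            build_kernel(nonlocal_ref, "c", (32, 32), 0.5, 0.5)  # 16 < 6 * 5


class TestFeedbacks:
    def test_zero_biomass_gives_unit_feedback(self, nonlocal_ref):
        op = NonlocalOperator(nonlocal_ref, _uniform_field(0.0))
        mf, mc = op.feedbacks(np.zeros((48, 48)))
        np.testing.assert_allclose(mf, 1.0)
        np.testing.assert_allclose(mc, 1.0)

    def test_uniform_biomass_periodic_box(self, nonlocal_ref):
        b0 = 0.12
        f = _uniform_field(b0)
        op = NonlocalOperator(nonlocal_ref, f)
        mf, mc = op.feedbacks(f.values)
        np.testing.assert_allclose(mf, np.exp(nonlocal_ref.chi_f * b0), rtol=1e-6)
        np.testing.assert_allclose(mc, np.exp(nonlocal_ref.chi_c * b0), rtol=1e-6)

    def test_zero_chi_gives_unit_feedback(self, nonlocal_ref):
        from dataclasses import replace

        p = replace(nonlocal_ref, chi_f=0.0, chi_c=0.0)
        f = _uniform_field(0.4)
        op = NonlocalOperator(p, f)
        mf, mc = op.feedbacks(f.values)
        np.testing.assert_allclose(mf, 1.0)
        np.testing.assert_allclose(mc, 1.0)

    def test_exponent_guard(self, nonlocal_ref):
        from dataclasses import replace

        p = replace(nonlocal_ref, chi_f=100.0)
        f = _uniform_field(1.0)
        op = NonlocalOperator(p, f)
        with pytest.raises(FloatingPointError, match="regime"):
            op.feedbacks(f.values)

    def test_fft_convolution_matches_direct_sum(self, nonlocal_ref):
        """Dirichlet-x convolution vs brute-force double sum on a small grid."""
        from dataclasses import replace

        p = replace(nonlocal_ref, lcx=1.2, lcy=1.0)  # narrow enough for a small box
        rng = np.random.default_rng(0)
        nx, ny, dx, dy = 16, 12, 0.8, 0.9
        b = rng.uniform(0.0, 0.3, (nx, ny))
        field = Field2D(b, dx=dx, dy=dy, bc_x="dirichlet", bc_y="periodic")
        op = NonlocalOperator(p, field)
        conv_f, conv_c = op.convolutions(b)

        def direct(x0, y0, lx, ly):
            # brute-force quadruple sum; x extended by bare ground (zeros),
            # y periodized by summing wrap images
            out = np.zeros((nx, ny))
            Ly = ny * dy
            for i in range(nx):
                for j in range(ny):
                    acc = 0.0
                    for ip in range(nx):
                        sx = (i - ip) * dx - x0
                        for jp in range(ny):
                            for q in (-1, 0, 1):
                                sy = (j - jp) * dy + q * Ly - y0
                                acc += np.exp(-sx**2 / (2 * lx**2)
                                              - sy**2 / (2 * ly**2)) * b[ip, jp]
                    out[i, j] = acc
            return out * dx * dy / (2 * np.pi * lx * ly)

        ref = direct(p.x0c, p.y0c, p.lcx, p.lcy)
        np.testing.assert_allclose(conv_c, ref, atol=1e-8)
        ref_f = direct(p.x0f, p.y0f, p.lfx, p.lfy)
        np.testing.assert_allclose(conv_f, ref_f, atol=1e-8)


class TestUniformStates:
    def test_printed_parameters_root(self, nonlocal_ref):
        # independent bisection oracle on (1 - b) e^{0.9 b} = 0.98
        g = lambda b: (1.0 - b) * np.exp(0.9 * b) - 0.98
        lo, hi = 0.0, 0.5
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if g(lo) * g(mid) <= 0:
                hi = mid
            else:
                lo = mid
        oracle = 0.5 * (lo + hi)
        states = uniform_states_nonlocal(nonlocal_ref)
        nontrivial = [s for s in states if s > 1e-9]
        assert len(nontrivial) == 1
        assert nontrivial[0] == pytest.approx(oracle, abs=1e-9)
        assert nontrivial[0] == pytest.approx(0.1215, abs=5e-4)

    def test_equal_intensities_reduce_to_logistic_root(self):
        p = NonlocalParams(mu=0.7, chi_f=1.5, chi_c=1.5)
        states = uniform_states_nonlocal(p)
        assert any(abs(s - 0.3) < 1e-10 for s in states)

    def test_excess_aridity_leaves_only_bare_ground(self):
        # mu above the max of (1-b)e^{dchi b} on (0, 1]
        dchi = 0.9
        bs = np.linspace(0, 1, 10001)
        mu_max = np.max((1 - bs) * np.exp(dchi * bs))
        p = NonlocalParams(mu=mu_max + 0.05, chi_f=2.1, chi_c=1.2)
        assert uniform_states_nonlocal(p) == [0.0]


class TestDynamics:
    def test_bare_state_is_fixed_point(self, nonlocal_ref):
        f = _uniform_field(0.0, bc_x="dirichlet")
        assert np.all(rhs_nonlocal(f, nonlocal_ref) == 0.0)

    def test_local_limit_is_logistic(self, nonlocal_ref):
        from dataclasses import replace

        p = replace(nonlocal_ref, chi_f=0.0, chi_c=0.0, D=0.0)
        f = _uniform_field(0.5)
        expected = 0.5 * (1 - 0.5) - p.mu * 0.5
        np.testing.assert_allclose(rhs_nonlocal(f, p), expected, atol=1e-12)
        f_eq = _uniform_field(1.0 - p.mu)
        np.testing.assert_allclose(rhs_nonlocal(f_eq, p), 0.0, atol=1e-12)

    def test_uniform_steady_state_has_tiny_rhs(self, nonlocal_ref):
        states = uniform_states_nonlocal(nonlocal_ref)
        b_star = max(states)
        f = _uniform_field(b_star)
        assert np.abs(rhs_nonlocal(f, nonlocal_ref)).max() < 1e-8

    def test_zero_ic_stays_zero(self, nonlocal_ref):
        f = _uniform_field(0.0, nx=40, ny=40, bc_x="dirichlet")
        traj = simulate_nonlocal(nonlocal_ref, f, dt=0.05, n_steps=20)
        assert np.all(traj.final.values == 0.0)

    def test_reflection_equivariance(self, nonlocal_ref):
        """Mirroring the IC and negating kernel offsets mirrors the trajectory."""
        from dataclasses import replace

        rng = np.random.default_rng(4)
        nx, ny = 44, 40
        v = 0.12 + 0.03 * rng.standard_normal((nx, ny))
        v[0] = v[-1] = 0.0
        f = Field2D(v, dx=0.75, dy=0.75, bc_x="dirichlet", bc_y="periodic")
        f_mirror = f.with_values(v[::-1, :].copy())
        p_mirror = replace(nonlocal_ref, x0f=-nonlocal_ref.x0f, x0c=-nonlocal_ref.x0c)
        a = simulate_nonlocal(nonlocal_ref, f, dt=0.05, n_steps=40).final.values
        b = simulate_nonlocal(p_mirror, f_mirror, dt=0.05, n_steps=40).final.values
        np.testing.assert_allclose(a, b[::-1, :], atol=1e-10)

    def test_high_aridity_drives_decay(self, nonlocal_ref):
        from dataclasses import replace

        p = replace(nonlocal_ref, mu=2.0)
        assert uniform_states_nonlocal(p) == [0.0]  # bare ground only
        f = _uniform_field(0.12, nx=40, ny=40, bc_x="dirichlet")
        f.values[0] = f.values[-1] = 0.0
        traj = simulate_nonlocal(p, f, dt=0.05, n_steps=200)
        assert traj.final.values.max() < 0.5 * 0.12
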