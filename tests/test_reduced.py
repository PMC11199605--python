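"""Reduced PDE: parameter mapping, homogeneous states, dynamics, classifier."""

import numpy as np
import pytest

from fogbands.grids import Field2D
from fogbands.linear_stability import dispersion
from fogbands.reduced_model import (
    MappingInputs,
    ReducedParams,
    classify_pattern,
    map_parameters,
    rhs_reduced,
    simulate_reduced,
    uniform_states_reduced,
)

REFERENCE_INPUTS = dict(mu=0.98, chi_f=2.1, chi_c=1.2, x0f=0.5, x0c=-0.2, lfx=0.9, lcx=5.0)


class TestParameterMapping:
    def test_printed_inputs_give_expected_coefficients(self):
        # independent arithmetic oracle, evaluated from the mapping formulas
        lf2, lc2 = 0.9**2, 5.0**2
        chi0 = lf2 / (lc2 - lf2)
        sigma = 3.0 * lf2 * lc2
        alpha_o = (-0.2 * chi0 - 0.5 * (1 + chi0)) / sigma**0.25
        gamma_o = (1.2 - chi0) * (lc2 - lf2) / sigma**0.5
        p = map_parameters(MappingInputs(**REFERENCE_INPUTS))
        assert p.kappa == pytest.approx(-0.1, abs=1e-12)
        assert p.eta == pytest.approx(-0.02, abs=1e-12)
        assert chi0 == pytest.approx(0.033485, abs=1e-5)
        assert sigma == pytest.approx(60.75, abs=1e-12)
        assert p.alpha == pytest.approx(alpha_o, abs=1e-12)
        assert p.alpha == pytest.approx(-0.18749, abs=1e-4)
        assert p.gamma == pytest.approx(gamma_o, abs=1e-12)
        assert p.gamma == pytest.approx(3.6204, abs=1e-3)

    def test_zero_offsets_give_reciprocal_limit(self):
        p = map_parameters(MappingInputs(**{**REFERENCE_INPUTS, "x0f": 0.0, "x0c": 0.0}))
        assert p.alpha == 0.0

    def test_unit_intensity_gap_sits_at_nascent_bistability(self):
        p = map_parameters(MappingInputs(**{**REFERENCE_INPUTS, "chi_f": 2.2}))
        assert p.kappa == pytest.approx(0.0, abs=1e-12)

    def test_range_ordering_enforced(self):
        with pytest.raises(ValueError, match="range"):
            MappingInputs(**{**REFERENCE_INPUTS, "lcx": 0.5})


class TestUniformStates:
    def test_vegetated_state_at_printed_parameters(self):
        us = uniform_states_reduced(-0.02, 0.3)
        assert us.b_plus == pytest.approx(0.3 + np.sqrt(0.09 + 0.04), abs=1e-12)
        assert us.b_plus == pytest.approx(0.66056, abs=1e-5)
        assert not us.b_minus_physical  # negative root flagged nonphysical

    def test_zero_aridity_limits(self):
        us = uniform_states_reduced(0.0, 0.4)
        assert us.b_plus == pytest.approx(0.8)
        assert us.b_minus == pytest.approx(0.0)

    def test_tipping_point(self):
        us = uniform_states_reduced(-0.02, 0.3)
        assert us.eta_tip == pytest.approx(0.0225)
        assert us.b_tip == pytest.approx(0.15)

    def test_bistable_window(self):
        assert uniform_states_reduced(0.01, 0.3).bistable
        assert not uniform_states_reduced(-0.01, 0.3).bistable
        assert not uniform_states_reduced(0.05, 0.3).bistable  # above the fold


def _periodic_uniform(value, nx=64, ny=8, dx=0.5, dy=0.5):
    return Field2D(np.full((nx, ny), float(value)), dx=dx, dy=dy,
                   bc_x="periodic", bc_y="periodic")


class TestRhs:
    def test_bare_state_fixed(self, reduced_ref):
        f = Field2D(np.zeros((32, 8)), dx=0.5, dy=0.5)
        assert np.all(rhs_reduced(f, reduced_ref) == 0.0)

    def test_uniform_vegetated_state_fixed_on_periodic_box(self, reduced_ref):
        us = uniform_states_reduced(reduced_ref.eta, reduced_ref.kappa)
        f = _periodic_uniform(us.b_plus)
        assert np.abs(rhs_reduced(f, reduced_ref)).max() < 1e-10

    def test_nonfinite_input_rejected(self, reduced_ref):
        v = np.zeros((32, 8))
        v[3, 3] = np.nan
        with pytest.raises(FloatingPointError):
            rhs_reduced(Field2D(v, dx=0.5, dy=0.5), reduced_ref)

    def test_seeded_mode_grows_at_closed_form_rate(self, reduced_ref):
        """Finite-difference growth matches the dispersion relation."""
        us = uniform_states_reduced(reduced_ref.eta, reduced_ref.kappa)
        nx, dx = 128, 0.2
        L = nx * dx
        m = 4  # k = 0.982, inside the unstable band
        k = 2 * np.pi * m / L
        x = np.arange(nx) * dx
        v = us.b_plus + 1e-5 * np.cos(k * x)[:, None] * np.ones((1, 4))
        f = Field2D(v, dx=dx, dy=0.5, bc_x="periodic", bc_y="periodic")
        T, dt = 1.5, 1e-4
        traj = simulate_reduced(reduced_ref, f, dt, int(T / dt))
        a0 = np.abs(np.fft.rfft(f.values.mean(axis=1))[m])
        a1 = np.abs(np.fft.rfft(traj.final.values.mean(axis=1))[m])
        rate = np.log(a1 / a0) / T
        theory = dispersion(reduced_ref, us.b_plus).re(k, 0.0)
        assert rate == pytest.approx(theory, rel=0.02)


class TestSimulate:
    def test_below_threshold_uniform_state_is_inert(self):
        p = ReducedParams(eta=-0.40, kappa=0.3, d=0.3, alpha=0.27, gamma=2.0)
        us = uniform_states_reduced(p.eta, p.kappa)
        f = _periodic_uniform(us.b_plus, nx=48)
        traj = simulate_reduced(p, f, dt=2.5e-3, n_steps=2000)
        assert np.abs(traj.final.values - us.b_plus).max() < 1e-6

    def test_mirror_equivariance_with_alpha_flip(self, reduced_ref):
        """x -> Lx - x together with alpha -> -alpha maps trajectories."""
        from dataclasses import replace

        rng = np.random.default_rng(2)
        v = 0.66 + 0.05 * rng.standard_normal((41, 16))
        v[0] = v[-1] = 0.0
        f = Field2D(v, dx=0.5, dy=0.5, bc_x="dirichlet", bc_y="periodic")
        f_m = f.with_values(v[::-1, :].copy())
        p_m = replace(reduced_ref, alpha=-reduced_ref.alpha)
        a = simulate_reduced(reduced_ref, f, 2e-3, 500).final.values
        b = simulate_reduced(p_m, f_m, 2e-3, 500).final.values
        np.testing.assert_allclose(a, b[::-1, :], atol=1e-10)

    def test_divergence_guard_reports_step(self, reduced_ref):
        from dataclasses import replace

        p = replace(reduced_ref, eta=-50.0)  # absurd forcing
        f = _periodic_uniform(1.0, nx=32)
        with pytest.raises(FloatingPointError, match="step"):
            simulate_reduced(p, f, dt=1.0, n_steps=50)

    def test_final_amplitude_insensitive_to_small_alpha(self, reduced_ref):
        """Nonreciprocity only advects the saturated pattern near onset."""
        from dataclasses import replace

        us = uniform_states_reduced(reduced_ref.eta, reduced_ref.kappa)
        amps = []
        for alpha in (0.0, 0.1):
            p = replace(reduced_ref, alpha=alpha)
            nx, dx = 64, 0.5
            k = 2 * np.pi * 5 / (nx * dx)  # m = 5 -> k = 0.98, unstable
            x = np.arange(nx) * dx
            v = us.b_plus + 0.1 * np.cos(k * x)[:, None] * np.ones((1, 4))
            f = Field2D(v, dx=dx, dy=0.5, bc_x="periodic", bc_y="periodic")
            traj = simulate_reduced(p, f, 2.5e-3, int(60 / 2.5e-3))
            prof = traj.final.values.mean(axis=1)
            amps.append(np.abs(np.fft.rfft(prof - prof.mean())[5]) * 2 / nx)
        assert amps[1] == pytest.approx(amps[0], rel=0.02)


class TestClassifier:
    def _field(self, v, bc_x="periodic"):
        return Field2D(v, dx=0.5, dy=0.5, bc_x=bc_x, bc_y="periodic")

    def test_pure_horizontal_mode(self):
        x = np.arange(64) * 0.5
        v = 0.1 * np.cos(2 * np.pi * 5 / 32 * x)[:, None] * np.ones((1, 32))
        cls = classify_pattern(self._field(v))
        assert cls.label == "H"
        assert cls.ky == 0.0

    @pytest.mark.parametrize("sign,label", [(1.0, "O_l"), (-1.0, "O_r")])
    def test_oblique_sign_convention(self, sign, label):
        x = np.arange(64) * 0.5
        y = np.arange(32) * 0.5
        X, Y = np.meshgrid(x, y, indexing="ij")
        kx, ky = 2 * np.pi * 5 / 32, sign * 2 * np.pi * 2 / 16
        cls = classify_pattern(self._field(0.1 * np.cos(kx * X + ky * Y)))
        assert cls.label == label

    def test_white_noise_is_none(self, rng):
        v = 0.1 * rng.standard_normal((64, 64))
        assert classify_pattern(self._field(v)).label == "none"

    def test_two_strong_modes_are_mixed(self):
        x = np.arange(64) * 0.5
        y = np.arange(32) * 0.5
        X, Y = np.meshgrid(x, y, indexing="ij")
        v = 0.1 * np.cos(2 * np.pi * 5 / 32 * X) + 0.09 * np.cos(
            2 * np.pi * 5 / 32 * X + 2 * np.pi * 2 / 16 * Y
        )
        assert classify_pattern(self._field(v)).label == "mixed"
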