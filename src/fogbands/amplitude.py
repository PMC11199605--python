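"""Ginzburg-Landau envelope and three-mode amplitude dynamics.

Near the pattern-forming threshold the band envelope A(r, t) obeys

    dA/dt = mu A - (1 + i beta) |A|^2 A + lap(A) - alpha_hat dA/dx,

with mu the critical-mode growth rate, beta a nonlinear dispersion, and
alpha_hat the group-velocity coefficient (it equals d Im(lambda)/d k_x of
the underlying dispersion and sets the band migration speed).  Projecting on
the three competing modes A = H + O_l e^{i dk y} + O_r e^{-i dk y} (dk the
oblique transverse offset, of order sqrt(mu)) and truncating higher modes
yields the coupled amplitude equations

    dH/dt   = mu H - (1+ib) H (|H|^2 + 2(|O_l|^2 + |O_r|^2))
              - 2 (1+ib) O_l O_r conj(H),
    dO_l/dt = (mu - dk^2) O_l - (1+ib) O_l (2|H|^2 + |O_l|^2 + 2|O_r|^2)
              - (1+ib) H^2 conj(O_r),
    dO_r/dt = (mu - dk^2) O_r - (1+ib) O_r (2(|H|^2 + |O_l|^2) + |O_r|^2)
              - (1+ib) H^2 conj(O_l).

At beta = 0 this is a gradient flow of the potential implemented in
:func:`potential`, so every trajectory relaxes.  The equilibrium branches
reproduce the bifurcation sequence of the full PDE: the horizontal pattern
appears supercritically at mu = 0 and is stable throughout; the single
oblique branch |O|^2 = mu - dk^2 appears at mu = dk^2 but is initially
unstable, and stabilizes at mu = 2 dk^2 where the mixed branch (all moduli
nonzero, a saddle) emerges, opening an H/O bistability window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import fsolve

NEUTRAL_TOL = 1e-7  # eigenvalues below this magnitude are global-phase modes


@dataclass
class AmplitudeParams:
    mu: float  # growth-rate (bifurcation) parameter
    beta: float = 0.0  # nonlinear dispersion
    alpha_hat: float = 0.0  # group-velocity coefficient
    dk: float = 0.3  # oblique transverse wavenumber offset

    def __post_init__(self) -> None:
        if self.dk < 0:
            raise ValueError("dk must be >= 0")
        for name in ("mu", "beta", "alpha_hat", "dk"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")


def params_from_linear(dispersion_result, beta: float = 0.0, dk: float | None = None) -> AmplitudeParams:
    """Convenience mapping from a linear-stability result.

    Sets mu = max_k Re lambda and alpha_hat = -b_s alpha (the group-velocity
    coefficient); dk defaults to sqrt(mu) to respect its near-onset scaling.
    The reduced model's normal-form coefficients are not derived here, so
    beta stays user-specified.
    """
    mu = dispersion_result.max_growth()
    alpha_hat = -dispersion_result.b_s * dispersion_result.params.alpha
    if dk is None:
        dk = float(np.sqrt(max(mu, 0.0)))
    return AmplitudeParams(mu=mu, beta=beta, alpha_hat=alpha_hat, dk=dk)


def amplitude_rhs(state, params: AmplitudeParams) -> np.ndarray:
    """Time derivatives of (H, O_l, O_r); supports batched state (..., 3)."""
    s = np.asarray(state, dtype=complex)
    H, Ol, Or = s[..., 0], s[..., 1], s[..., 2]
    c = 1.0 + 1j * params.beta
    mu, dk2 = params.mu, params.dk**2
    aH = np.abs(H) ** 2
    al = np.abs(Ol) ** 2
    ar = np.abs(Or) ** 2
    dH = mu * H - c * H * (aH + 2.0 * (al + ar)) - 2.0 * c * Ol * Or * np.conj(H)
    dOl = (mu - dk2) * Ol - c * Ol * (2.0 * aH + al + 2.0 * ar) - c * H**2 * np.conj(Or)
    dOr = (mu - dk2) * Or - c * Or * (2.0 * (aH + al) + ar) - c * H**2 * np.conj(Ol)
    return np.stack([dH, dOl, dOr], axis=-1)


def potential(state, params: AmplitudeParams) -> np.ndarray:
    """Lyapunov potential of the beta = 0 truncation (non-increasing)."""
    s = np.asarray(state, dtype=complex)
    H, Ol, Or = s[..., 0], s[..., 1], s[..., 2]
    aH = np.abs(H) ** 2
    al = np.abs(Ol) ** 2
    ar = np.abs(Or) ** 2
    mu, dk2 = params.mu, params.dk**2
    V = (
        -mu * aH
        - (mu - dk2) * (al + ar)
        + 0.5 * (aH**2 + al**2 + ar**2)
        + 2.0 * (aH * al + aH * ar + al * ar)
        + 2.0 * np.real(H**2 * np.conj(Ol) * np.conj(Or))
    )
    return np.real(V)


def integrate_amplitudes(
    state0,
    params: AmplitudeParams,
    dt: float = 0.02,
    T: float = 100.0,
    record_stride: int = 10,
):
    """RK4 trajectory of the three complex amplitudes (state may be batched).

    Returns (times, states) with states.shape = (n_records, ..., 3).
    """
    if dt > 0.1 / max(abs(params.mu), 1.0):
        raise ValueError("dt too large for the amplitude dynamics")
    s = np.asarray(state0, dtype=complex)
    n_steps = int(round(T / dt))
    times = [0.0]
    states = [s.copy()]
    for step in range(1, n_steps + 1):
        k1 = amplitude_rhs(s, params)
        k2 = amplitude_rhs(s + 0.5 * dt * k1, params)
        k3 = amplitude_rhs(s + 0.5 * dt * k2, params)
        k4 = amplitude_rhs(s + dt * k3, params)
        s = s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(s)):
            raise FloatingPointError(f"amplitude integration diverged at step {step}")
        if step % record_stride == 0 or step == n_steps:
            times.append(step * dt)
            states.append(s.copy())
    return np.asarray(times), np.asarray(states)


def classify_attractor(state, params: AmplitudeParams, tol: float = 0.05) -> str:
    """Label the attractor reached by a trajectory endpoint."""
    h, ol, orr = np.abs(np.asarray(state, dtype=complex))
    scale = max(np.sqrt(abs(params.mu)), 1e-6)
    big = lambda v: v > tol * scale
    if not any(map(big, (h, ol, orr))):
        return "trivial"
    if big(h) and not big(ol) and not big(orr):
        return "H"
    if not big(h) and (big(ol) != big(orr)):
        return "O_single"
    if not big(h) and big(ol) and big(orr):
        return "O_pair"
    return "mixed"


@dataclass
class BranchPoint:
    branch: str  # trivial, H, O_single, O_pair, mixed
    mu: float
    moduli: tuple[float, float, float]  # (|H|, |O_l|, |O_r|)
    exists: bool
    stable: bool
    leading_re: float


def _cartesian_spectrum(state, params: AmplitudeParams) -> np.ndarray:
    """Eigenvalues of the 6-D real Jacobian at a stationary state (beta = 0)."""

    def F(v):
        s = v[:3] + 1j * v[3:]
        d = amplitude_rhs(s, params)
        return np.concatenate([d.real, d.imag])

    v0 = np.concatenate([np.real(state), np.imag(state)])
    h = 1e-7
    J = np.empty((6, 6))
    for i in range(6):
        e = np.zeros(6)
        e[i] = h
        J[:, i] = (F(v0 + e) - F(v0 - e)) / (2 * h)
    return np.linalg.eigvals(J)


def _nontrivial_leading(eigs: np.ndarray, n_neutral_max: int = 2) -> float:
    """Largest real part after discarding the (expected) global-phase zeros."""
    eigs = np.sort_complex(eigs)
    mags = np.abs(eigs)
    order = np.argsort(mags)
    drop = [i for i in order[:n_neutral_max] if mags[i] < NEUTRAL_TOL]
    keep = [i for i in range(len(eigs)) if i not in drop]
    return float(np.max(eigs[keep].real))


def _mixed_equilibrium(params: AmplitudeParams, guess=None):
    """Symmetric mixed state (h, q, q, Phi) by root-finding; None if absent.

    Works in the modulus-phase reduction (Phi = 2 theta_H - theta_l -
    theta_r), which stays autonomous for beta != 0.  At beta = 0 the closed
    form is h^2 = (mu - 2 dk^2)/5, q^2 = (2 mu + dk^2)/15, Phi = 0, used as
    the continuation guess.
    """
    mu, dk2, b = params.mu, params.dk**2, params.beta
    if guess is None:
        h2 = (mu - 2.0 * dk2) / 5.0
        q2 = (2.0 * mu + dk2) / 15.0
        if h2 <= 0 or q2 <= 0:
            return None
        guess = np.array([np.sqrt(h2), np.sqrt(q2), 0.0])

    def eqs(v):
        h, q, phi = v
        cb, sb = np.cos(phi), np.sin(phi)
        eq_h = mu - (h**2 + 4 * q**2) - 2 * q**2 * (cb + b * sb)
        eq_q = (mu - dk2) - (2 * h**2 + 3 * q**2) - h**2 * (cb - b * sb)
        eq_phi = (
            2 * b * (h**2 - q**2)
            + sb * (4 * q**2 + 2 * h**2)
            + b * cb * (2 * h**2 - 4 * q**2)
        )
        return [eq_h, eq_q, eq_phi]

    sol, info, ier, _ = fsolve(eqs, guess, full_output=True)
    if ier != 1 or sol[0] <= 1e-8 or sol[1] <= 1e-8:
        return None
    return sol


def equilibrium_branches(params: AmplitudeParams, mu_grid) -> list[BranchPoint]:
    """Equilibrium branches with stability across a mu grid.

    Closed forms: |H|^2 = mu (H branch), |O|^2 = mu - dk^2 (single oblique),
    |O_l| = |O_r|, |O|^2 = (mu - dk^2)/3 (symmetric pair); the mixed branch
    is continued numerically from its closed beta = 0 form.  Stability comes
    from the 6-D real Jacobian with the global-phase zero modes projected
    out (beta = 0), or from branch-wise reductions whose leading real parts
    are beta-independent (trivial, H, single oblique, pair).
    """
    from dataclasses import replace

    out = []
    dk2 = params.dk**2
    mixed_guess = None
    for mu in mu_grid:
        p = replace(params, mu=mu)
        # trivial
        lead = max(mu, mu - dk2)
        out.append(BranchPoint("trivial", mu, (0.0, 0.0, 0.0), True, bool(lead < 0), float(lead)))
        # H
        if mu > 0:
            h = np.sqrt(mu)
            lead = _branch_leading(p, "H", h=h)
            out.append(BranchPoint("H", mu, (float(h), 0.0, 0.0), True, bool(lead < 0), float(lead)))
        else:
            out.append(BranchPoint("H", mu, (0.0, 0.0, 0.0), False, False, np.nan))
        # single oblique
        if mu > dk2:
            q = np.sqrt(mu - dk2)
            lead = _branch_leading(p, "O_single", q=q)
            out.append(BranchPoint("O_single", mu, (0.0, float(q), 0.0), True, bool(lead < 0), float(lead)))
        else:
            out.append(BranchPoint("O_single", mu, (0.0, 0.0, 0.0), False, False, np.nan))
        # symmetric pair
        if mu > dk2:
            q = np.sqrt((mu - dk2) / 3.0)
            lead = _branch_leading(p, "O_pair", q=q)
            out.append(BranchPoint("O_pair", mu, (0.0, float(q), float(q)), True, bool(lead < 0), float(lead)))
        else:
            out.append(BranchPoint("O_pair", mu, (0.0, 0.0, 0.0), False, False, np.nan))
        # mixed
        sol = _mixed_equilibrium(p, mixed_guess)
        if sol is not None:
            mixed_guess = sol
            h, q, phi = sol
            if params.beta == 0.0:
                state = np.array([h, q * np.exp(-0.5j * phi), q * np.exp(-0.5j * phi)])
                lead = _nontrivial_leading(_cartesian_spectrum(state, p))
            else:
                lead = _reduced_mixed_leading(p, sol)
            out.append(BranchPoint("mixed", mu, (float(h), float(q), float(q)), True, bool(lead < 0), float(lead)))
        else:
            mixed_guess = None
            out.append(BranchPoint("mixed", mu, (0.0, 0.0, 0.0), False, False, np.nan))
    return out


def _branch_leading(params: AmplitudeParams, branch: str, h: float = 0.0, q: float = 0.0) -> float:
    """Leading non-neutral eigenvalue real part for the closed-form branches.

    Derived from the complex linearization; the real parts below are exact
    for every beta (the dispersion shifts only imaginary parts for these
    branches).
    """
    mu, dk2, beta = params.mu, params.dk**2, params.beta
    if branch == "H":
        # amplitude mode -2 mu; oblique pair modes -dk^2 and -2 mu - dk^2
        if params.beta == 0.0:
            state = np.array([h, 0.0, 0.0], dtype=complex)
            return _nontrivial_leading(_cartesian_spectrum(state, params))
        return max(-2.0 * mu, -dk2)
    if branch == "O_single":
        if params.beta == 0.0:
            state = np.array([0.0, q, 0.0], dtype=complex)
            return _nontrivial_leading(_cartesian_spectrum(state, params))
        # H perturbation grows at Re = mu - 2 q^2 = 2 dk^2 - mu
        return max(2.0 * dk2 - mu, -(mu - dk2))
    if branch == "O_pair":
        if params.beta == 0.0:
            state = np.array([0.0, q, q], dtype=complex)
            return _nontrivial_leading(_cartesian_spectrum(state, params))
        # asymmetry mode +2 q^2 is beta-independent and always unstable
        disc = 4.0 * q**4 * (1.0 - 3.0 * beta**2)
        lam_h = mu - 4.0 * q**2 + (np.sqrt(disc) if disc > 0 else 0.0)
        return max(2.0 * q**2, lam_h)
    raise ValueError(branch)


def _reduced_mixed_leading(params: AmplitudeParams, sol) -> float:
    """Numeric Jacobian of the (h, ol, or, Phi) reduction at the mixed state."""
    mu, dk2, b = params.mu, params.dk**2, params.beta

    def F(v):
        h, ol, orr, phi = v
        cb, sb = np.cos(phi), np.sin(phi)
        dh = mu * h - h * (h**2 + 2 * (ol**2 + orr**2)) - 2 * ol * orr * h * (cb + b * sb)
        dol = (mu - dk2) * ol - ol * (2 * h**2 + ol**2 + 2 * orr**2) - h**2 * orr * (cb - b * sb)
        dorr = (mu - dk2) * orr - orr * (2 * (h**2 + ol**2) + orr**2) - h**2 * ol * (cb - b * sb)
        th_H = -b * (h**2 + 2 * (ol**2 + orr**2)) - 2 * ol * orr * (b * cb - sb)
        th_l = -b * (2 * h**2 + ol**2 + 2 * orr**2) - h**2 * (orr / ol) * (sb + b * cb)
        th_r = -b * (2 * (h**2 + ol**2) + orr**2) - h**2 * (ol / orr) * (sb + b * cb)
        dphi = 2 * th_H - th_l - th_r
        return np.array([dh, dol, dorr, dphi])

    v0 = np.array([sol[0], sol[1], sol[1], sol[2]])
    eps = 1e-7
    J = np.empty((4, 4))
    for i in range(4):
        e = np.zeros(4)
        e[i] = eps
        J[:, i] = (F(v0 + e) - F(v0 - e)) / (2 * eps)
    return float(np.max(np.linalg.eigvals(J).real))


# ---------------------------------------------------------------------------
# Envelope PDE
# ---------------------------------------------------------------------------


@dataclass
class EnvelopeTrajectory:
    times: np.ndarray
    projections: np.ndarray  # (n_records, 3): H, O_l, O_r mode projections
    higher_mode_fraction: np.ndarray  # power fraction outside the three modes
    final: np.ndarray  # final complex field A(x, y)


def simulate_envelope(
    params: AmplitudeParams,
    A0: np.ndarray,
    dy: float,
    dx: float = 1.0,
    dt: float = 0.02,
    T: float = 50.0,
    record_stride: int = 10,
) -> EnvelopeTrajectory:
    """Pseudo-spectral RK4 integration of the Ginzburg-Landau envelope.

    The periodic box must resolve the oblique offset: L_y must be an integer
    multiple of 2 pi / dk (checked).  Projections onto {1, e^{+-i dk y}}
    (uniform in x) are recorded for comparison with the three-mode
    truncation.
    """
    A = np.asarray(A0, dtype=complex).copy()
    nx, ny = A.shape
    Ly = ny * dy
    if params.dk > 0:
        ratio = Ly * params.dk / (2.0 * np.pi)
        if abs(ratio - round(ratio)) > 1e-8:
            raise ValueError("L_y must be an integer multiple of 2 pi / dk")
        n_dk = int(round(ratio))
    else:
        n_dk = 0
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, dy)
    KX, KY = np.meshgrid(kx, ky, indexing="ij")
    lin = params.mu - (KX**2 + KY**2) - 1j * params.alpha_hat * KX
    c = 1.0 + 1j * params.beta

    def rhs(a):
        a_hat = np.fft.fft2(a)
        return np.fft.ifft2(lin * a_hat) - c * np.abs(a) ** 2 * a

    def project(a):
        col = a.mean(axis=0)  # average over x (modes are x-uniform)
        col_hat = np.fft.fft(col) / ny
        H = col_hat[0]
        Ol = col_hat[n_dk] if n_dk else 0.0
        Or = col_hat[-n_dk] if n_dk else 0.0
        total = np.sum(np.abs(col_hat) ** 2)
        inside = abs(H) ** 2 + abs(Ol) ** 2 + abs(Or) ** 2
        frac = 0.0 if total == 0 else max(0.0, 1.0 - inside / total)
        return np.array([H, Ol, Or]), frac

    n_steps = int(round(T / dt))
    times = [0.0]
    proj, frac = project(A)
    projections = [proj]
    fracs = [frac]
    for step in range(1, n_steps + 1):
        k1 = rhs(A)
        k2 = rhs(A + 0.5 * dt * k1)
        k3 = rhs(A + 0.5 * dt * k2)
        k4 = rhs(A + dt * k3)
        A = A + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(A)):
            raise FloatingPointError(f"envelope integration diverged at step {step}")
        if step % record_stride == 0 or step == n_steps:
            times.append(step * dt)
            proj, frac = project(A)
            projections.append(proj)
            fracs.append(frac)
    return EnvelopeTrajectory(
        times=np.asarray(times),
        projections=np.asarray(projections),
        higher_mode_fraction=np.asarray(fracs),
        final=A,
    )


def ansatz_field(
    H: complex, Ol: complex, Or: complex, dk: float, nx: int, ny: int, dy: float
) -> np.ndarray:
    """Three-mode initial field A = H + O_l e^{i dk y} + O_r e^{-i dk y}."""
    y = np.arange(ny) * dy
    col = H + Ol * np.exp(1j * dk * y) + Or * np.exp(-1j * dk * y)
    return np.broadcast_to(col, (nx, ny)).copy()
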