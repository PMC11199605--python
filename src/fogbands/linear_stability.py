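"""Linear stability of the vegetated uniform state of the reduced model.

Perturbing b = b_s + b_0 exp(lambda t + i k.r) in the reduced equation about
a homogeneous steady state b_s gives the closed-form growth rate

    Re lambda = b_s (kappa - b_s) - d (k_x^2 + k_y^2)
                + b_s (gamma k_x^2 - k_x^4),
    Im lambda = -b_s alpha k_x.

Only the advective (nonreciprocity) term contributes to Im lambda, so the
real spectrum is alpha-independent, even in both wavenumbers, while the
imaginary part is odd in k_x: the pattern drifts at phase speed b_s alpha.

In a finite box with Dirichlet walls in x and periodic wrap in y the
admissible wavevectors are discrete: sine modes k_x = pi m / L_x (m >= 1)
and Fourier modes k_y = 2 pi n / L_y.  Modes with n = 0 are horizontal (H)
bands; n > 0 / n < 0 are the oblique pair O_l / O_r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .reduced_model import ReducedParams, uniform_states_reduced

_STEADY_TOL = 1e-8


def _check_steady(params: ReducedParams, b_s: float) -> None:
    resid = abs(-params.eta * b_s + params.kappa * b_s**2 - 0.5 * b_s**3)
    if resid > _STEADY_TOL:
        raise ValueError(
            f"b_s = {b_s} is not a homogeneous steady state (residual {resid:.2e})"
        )


@dataclass
class DispersionResult:
    """Closed-form growth-rate surface lambda(k) about a uniform state."""

    params: ReducedParams
    b_s: float

    def re(self, kx, ky=0.0):
        kx = np.asarray(kx, dtype=float)
        ky = np.asarray(ky, dtype=float)
        p, b = self.params, self.b_s
        return (
            b * (p.kappa - b)
            - p.d * (kx**2 + ky**2)
            + b * (p.gamma * kx**2 - kx**4)
        )

    def im(self, kx, ky=0.0):
        return -self.b_s * self.params.alpha * np.asarray(kx, dtype=float)

    def __call__(self, kx, ky=0.0):
        return self.re(kx, ky) + 1j * self.im(kx, ky)

    def kmax(self) -> float:
        """Wavenumber of the most unstable mode (on the k_y = 0 axis)."""
        p, b = self.params, self.b_s
        k2 = (b * p.gamma - p.d) / (2.0 * b)
        return float(np.sqrt(k2)) if k2 > 0 else 0.0

    def max_growth(self) -> float:
        return float(self.re(self.kmax(), 0.0))


def dispersion(params: ReducedParams, b_s: float) -> DispersionResult:
    """Growth-rate record for perturbations about the steady state b_s."""
    _check_steady(params, b_s)
    return DispersionResult(params=params, b_s=b_s)


def critical_point(
    params: ReducedParams,
    eta_min: float | None = None,
    eta_max: float | None = None,
) -> tuple[float, float]:
    """Pattern-forming threshold (eta_c, k_c) for fixed kappa, d, gamma.

    Solves Re lambda(k_c) = 0 with d(Re lambda)/dk = 0, i.e.
    k_c^2 = (b_+ gamma - d) / (2 b_+), by a bracketed root-find of the band
    maximum over eta.  Raises when no sign change exists in the bracket
    (e.g. gamma too small: the destabilizing term never wins).
    """
    kappa = params.kappa

    def band_max(eta: float) -> float:
        us = uniform_states_reduced(eta, kappa)
        if not us.b_plus_physical:
            return -np.inf
        b = us.b_plus
        k2 = (b * params.gamma - params.d) / (2.0 * b)
        if k2 <= 0:
            return b * (kappa - b)  # maximum sits at k = 0
        return b * (kappa - b) - params.d * k2 + b * (params.gamma * k2 - k2**2)

    hi = kappa**2 / 2.0 - 1e-12 if eta_max is None else eta_max
    lo = hi - 10.0 if eta_min is None else eta_min
    etas = np.linspace(lo, hi, 400)
    vals = np.array([band_max(e) for e in etas])
    finite = np.isfinite(vals)
    sign_change = None
    for i in range(len(etas) - 1):
        if finite[i] and finite[i + 1] and vals[i] * vals[i + 1] < 0:
            sign_change = (etas[i], etas[i + 1])
    if sign_change is None:
        raise ValueError("no pattern-forming threshold in range")
    eta_c = brentq(band_max, *sign_change, xtol=1e-13)
    us = uniform_states_reduced(eta_c, kappa)
    b = us.b_plus
    k2 = (b * params.gamma - params.d) / (2.0 * b)
    k_c = float(np.sqrt(max(k2, 0.0)))
    return float(eta_c), k_c


@dataclass
class Mode:
    m: int
    n: int
    kx: float
    ky: float
    re_lambda: float
    im_lambda: float
    unstable: bool
    label: str  # H (n = 0), O_l (n > 0), O_r (n < 0)


@dataclass
class ModeSet:
    modes: list[Mode]

    @property
    def unstable(self) -> list[Mode]:
        return [m for m in self.modes if m.unstable]

    def count_unstable(self) -> dict[str, int]:
        out = {"H": 0, "O_l": 0, "O_r": 0}
        for m in self.unstable:
            out[m.label] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.modes])


def enumerate_modes(
    params: ReducedParams,
    b_s: float,
    Lx: float,
    Ly: float,
    m_max: int = 60,
    n_max: int = 10,
) -> ModeSet:
    """Evaluate lambda on the discrete (m, n) grid of a mixed-BC box.

    Dirichlet sine columns k_x = pi m / L_x (Re lambda is even in k_x, so
    evaluating at |k_x| is exact) and periodic rows k_y = 2 pi n / L_y.
    """
    if Lx <= 0 or Ly <= 0:
        raise ValueError("box sizes must be positive")
    disp = dispersion(params, b_s)
    modes = []
    for m in range(1, m_max + 1):
        kx = np.pi * m / Lx
        for n in range(-n_max, n_max + 1):
            ky = 2.0 * np.pi * n / Ly
            re = float(disp.re(kx, ky))
            im = float(disp.im(kx, ky))
            label = "H" if n == 0 else ("O_l" if n > 0 else "O_r")
            modes.append(Mode(m, n, kx, ky, re, im, re > 0, label))
    return ModeSet(modes)


def drift_speed(params: ReducedParams, b_s: float) -> tuple[float, float]:
    """(phase speed, group-velocity coefficient) of the migrating bands.

    d Im(lambda)/dk_x = -b_s alpha is constant in k, and the phase speed
    -Im lambda(k_c)/k_c = b_s alpha: bands move along +x (toward the
    incoming fog) for alpha > 0, are motionless in the reciprocal limit
    alpha = 0, and reverse with the sign of alpha.
    """
    return b_s * params.alpha, -b_s * params.alpha


def admissible_box_window(
    params: ReducedParams,
    b_s: float,
    target_m: int | None = None,
) -> dict:
    """Continuous unstable band limits, for choosing box sizes.

    Returns the k_x interval where Re lambda(k_x, 0) > 0 and the maximum
    |k_y| still unstable at the band centre; any (L_x, L_y) whose discrete
    grid places exactly one sine column and the n = +-1 rows inside these
    limits realizes the three-mode scenario.
    """
    disp = dispersion(params, b_s)
    kmax = disp.kmax()
    if disp.max_growth() <= 0:
        return {"kx_lo": np.nan, "kx_hi": np.nan, "ky_max": 0.0, "k_peak": kmax}
    f = lambda k: disp.re(k, 0.0)
    kx_lo = brentq(f, 1e-9, kmax)
    kx_hi = brentq(f, kmax, 10.0 * max(kmax, 1.0))
    ky_max = float(np.sqrt(disp.max_growth() / params.d))
    return {"kx_lo": float(kx_lo), "kx_hi": float(kx_hi), "ky_max": ky_max, "k_peak": kmax}
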