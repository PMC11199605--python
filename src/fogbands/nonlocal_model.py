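"""Interaction-redistribution model with nonreciprocal Gaussian kernels.

The biomass density b(r, t) obeys

    db/dt = b (1 - b) M_f[b] - mu b M_c[b] + D lap(b),

with nonlocal feedbacks M_i[b](r) = exp(chi_i * int phi_i(r, r') b(r') dr'),
i in {facilitation, competition}.  The influence kernels phi_i are shifted
anisotropic Gaussians

    phi_i(r, r') = exp[-(x - x' - x_i0)^2 / 2 l_ix^2
                       -(y - y' - y_i0)^2 / 2 l_iy^2] / (2 pi l_ix l_iy),

normalized to unit mass.  Non-zero offsets (x_i0, y_i0) make the kernels
nonreciprocal, phi(r, r') != phi(r', r): a plant's influence on its downwind
neighbour differs from the reverse, which is the fog-flow mechanism that
sets banded patterns in motion.

The convolution at a point r integrates b at r' with weight centered at
r' = r - (x_i0, y_i0) (the offset sits inside x - x' - x_i0).  Boundary
conditions are periodic wrap in y and bare ground (b = 0) beyond the
Dirichlet walls in x, implemented by zero-padding in x before an FFT
convolution; kernels are sampled on the wrap grid with periodic images so
their discrete mass is the full unit integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .grids import Field2D

EXP_GUARD = 50.0  # |chi * conv| above this aborts: parameters out of regime


@dataclass
class NonlocalParams:
    """Parameters of the integrodifferential model (dimensionless units)."""

    mu: float = 0.98  # aridity / mortality-to-birth ratio
    chi_f: float = 2.1  # facilitation intensity
    chi_c: float = 1.2  # competition intensity
    D: float = 0.2  # seed-dispersion diffusivity
    x0f: float = 0.5  # facilitation kernel offset along the fog direction
    x0c: float = -0.2  # competition kernel offset
    y0f: float = 0.0
    y0c: float = 0.0
    lfx: float = 0.9  # kernel widths
    lfy: float = 0.9
    lcx: float = 5.0
    lcy: float = 3.5

    def __post_init__(self) -> None:
        if min(self.lfx, self.lfy, self.lcx, self.lcy) <= 0:
            raise ValueError("kernel widths must be positive")
        if self.mu < 0 or self.D < 0 or self.chi_f < 0 or self.chi_c < 0:
            raise ValueError("mu, D, chi_f, chi_c must be non-negative")

    def kernel_spec(self, which: str) -> tuple[float, float, float, float, float]:
        if which in ("facilitation", "f"):
            return self.chi_f, self.x0f, self.y0f, self.lfx, self.lfy
        if which in ("competition", "c"):
            return self.chi_c, self.x0c, self.y0c, self.lcx, self.lcy
        raise ValueError("which must be 'facilitation' or 'competition'")


def _wrap_lags(n: int, d: float) -> np.ndarray:
    return ((np.arange(n) + n // 2) % n - n // 2) * d


def build_kernel(
    params: NonlocalParams,
    which: str,
    shape: tuple[int, int],
    dx: float,
    dy: float,
) -> np.ndarray:
    """Discrete influence kernel on an (nx, ny) wrap grid.

    Entry [i, j] is the kernel at lag (s_x, s_y) in fftshift order (lag 0 at
    [0, 0]).  Periodic images are summed so the discrete mass
    ``kernel.sum() * dx * dy`` equals the unit Gaussian integral to high
    accuracy.  The grid extent must be at least 6 kernel widths per axis.
    """
    _, x0, y0, lx, ly = params.kernel_spec(which)
    nx, ny = shape
    Lx, Ly = nx * dx, ny * dy
    if Lx < 6.0 * lx:
        raise ValueError(f"x extent {Lx:g} < 6 * kernel width {lx:g} ({which})")
    if Ly < 6.0 * ly:
        raise ValueError(f"y extent {Ly:g} < 6 * kernel width {ly:g} ({which})")
    sx = _wrap_lags(nx, dx)
    sy = _wrap_lags(ny, dy)
    gx = np.zeros(nx)
    gy = np.zeros(ny)
    for p in (-1, 0, 1):  # periodic images: tails wrap instead of truncating
        gx += np.exp(-((sx + p * Lx - x0) ** 2) / (2.0 * lx**2))
        gy += np.exp(-((sy + p * Ly - y0) ** 2) / (2.0 * ly**2))
    return np.outer(gx, gy) / (2.0 * np.pi * lx * ly)


class NonlocalOperator:
    """Precomputed FFT plans for the two feedback convolutions on a grid."""

    def __init__(self, params: NonlocalParams, template: Field2D):
        self.params = params
        self.nx, self.ny = template.nx, template.ny
        self.dx, self.dy = template.dx, template.dy
        self.bc_x = template.bc_x
        if self.bc_x == "dirichlet":
            reach = max(
                4.0 * params.lfx + abs(params.x0f), 4.0 * params.lcx + abs(params.x0c)
            )
            self.pad = int(np.ceil(reach / self.dx))
        else:
            self.pad = 0
        nxp = self.nx + 2 * self.pad
        self._shape_p = (nxp, self.ny)
        kf = build_kernel(params, "facilitation", self._shape_p, self.dx, self.dy)
        kc = build_kernel(params, "competition", self._shape_p, self.dx, self.dy)
        self._kf_hat = np.fft.rfft2(kf)
        self._kc_hat = np.fft.rfft2(kc)

    def _embed(self, b: np.ndarray) -> np.ndarray:
        if self.pad == 0:
            return b
        bp = np.zeros(self._shape_p)
        bp[self.pad : self.pad + self.nx, :] = b
        return bp

    def convolutions(self, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Kernel-weighted integrals of b for both kernels."""
        b_hat = np.fft.rfft2(self._embed(b))
        area = self.dx * self.dy
        sl = slice(self.pad, self.pad + self.nx)
        cf = np.fft.irfft2(b_hat * self._kf_hat, s=self._shape_p)[sl, :] * area
        cc = np.fft.irfft2(b_hat * self._kc_hat, s=self._shape_p)[sl, :] * area
        return cf, cc

    def feedbacks(self, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """M_f and M_c fields; guards against exponent overflow."""
        cf, cc = self.convolutions(b)
        ef = self.params.chi_f * cf
        ec = self.params.chi_c * cc
        m = max(np.abs(ef).max(initial=0.0), np.abs(ec).max(initial=0.0))
        if m > EXP_GUARD:
            raise FloatingPointError(
                f"feedback exponent magnitude {m:.1f} > {EXP_GUARD}: parameters "
                "outside the intended regime"
            )
        return np.exp(ef), np.exp(ec)


def nonlocal_feedback(b: Field2D, kernel: np.ndarray, chi: float, pad: int = 0) -> np.ndarray:
    """exp(chi * (kernel (*) b)) for a single prebuilt kernel.

    ``kernel`` must live on the (possibly padded) wrap grid; for Dirichlet
    fields ``pad`` is the number of zero rows added on each x side.
    """
    nxp = b.nx + 2 * pad
    if kernel.shape != (nxp, b.ny):
        raise ValueError(f"kernel shape {kernel.shape} does not match grid ({nxp}, {b.ny})")
    bp = np.zeros((nxp, b.ny))
    bp[pad : pad + b.nx, :] = b.values
    conv = np.fft.irfft2(np.fft.rfft2(bp) * np.fft.rfft2(kernel), s=(nxp, b.ny))
    conv = conv[pad : pad + b.nx, :] * b.dx * b.dy
    expo = chi * conv
    if np.abs(expo).max(initial=0.0) > EXP_GUARD:
        raise FloatingPointError("feedback exponent out of the intended regime")
    return np.exp(expo)


def _laplacian(b: np.ndarray, dx: float, dy: float, bc_x: str) -> np.ndarray:
    mode = "constant" if bc_x == "dirichlet" else "wrap"
    bp = np.pad(b, ((1, 1), (0, 0)), mode=mode)
    bp = np.pad(bp, ((0, 0), (1, 1)), mode="wrap")
    c = bp[1:-1, 1:-1]
    return (bp[2:, 1:-1] - 2 * c + bp[:-2, 1:-1]) / dx**2 + (
        bp[1:-1, 2:] - 2 * c + bp[1:-1, :-2]
    ) / dy**2


def rhs_nonlocal(
    b: Field2D, params: NonlocalParams, operator: NonlocalOperator | None = None
) -> np.ndarray:
    """Time derivative b(1-b)M_f - mu b M_c + D lap(b) on the grid of b."""
    if not np.all(np.isfinite(b.values)):
        raise FloatingPointError("non-finite biomass values")
    op = operator if operator is not None else NonlocalOperator(params, b)
    mf, mc = op.feedbacks(b.values)
    v = b.values
    out = v * (1.0 - v) * mf - params.mu * v * mc + params.D * _laplacian(v, b.dx, b.dy, b.bc_x)
    if b.bc_x == "dirichlet":
        out[0, :] = 0.0
        out[-1, :] = 0.0
    return out


def uniform_states_nonlocal(params: NonlocalParams, n_scan: int = 2000) -> list[float]:
    """Uniform steady states: b = 0 plus roots of (1-b) exp[(chi_f-chi_c) b] = mu.

    With normalized kernels a uniform field has M_i = exp(chi_i b), so the
    steady-state condition reduces to the scalar equation above.  Roots on
    (0, 1] are located by a sign-change scan and bracketed root-finding.
    """
    from scipy.optimize import brentq

    if params.mu <= 0:
        raise ValueError("mu must be positive")
    dchi = params.chi_f - params.chi_c

    def g(b: float) -> float:
        return (1.0 - b) * np.exp(dchi * b) - params.mu

    states = [0.0]
    bs = np.linspace(1e-12, 1.0, n_scan)
    vals = g(bs)
    for i in range(len(bs) - 1):
        if vals[i] == 0.0:
            states.append(float(bs[i]))
        elif vals[i] * vals[i + 1] < 0:
            states.append(float(brentq(g, bs[i], bs[i + 1], xtol=1e-14)))
    if vals[-1] == 0.0:
        states.append(1.0)
    return states


@dataclass
class Trajectory:
    """Snapshots of a simulation, including the final state."""

    times: list[float] = dc_field(default_factory=list)
    snapshots: list[Field2D] = dc_field(default_factory=list)

    @property
    def final(self) -> Field2D:
        return self.snapshots[-1]


def simulate_nonlocal(
    params: NonlocalParams,
    b0: Field2D,
    dt: float,
    n_steps: int,
    snapshot_stride: int | None = None,
) -> Trajectory:
    """RK4 integration of the nonlocal model with mixed boundary conditions.

    Dirichlet x-walls are held at zero throughout; divergence (max |b| >
    1e3) raises with the offending step index.
    """
    op = NonlocalOperator(params, b0)
    b = b0.values.copy()
    if b0.bc_x == "dirichlet":
        b[0, :] = 0.0
        b[-1, :] = 0.0
    stride = snapshot_stride or max(1, n_steps)
    traj = Trajectory()
    traj.times.append(0.0)
    traj.snapshots.append(b0.with_values(b.copy()))

    def f(v: np.ndarray) -> np.ndarray:
        return rhs_nonlocal(b0.with_values(v), params, op)

    for step in range(1, n_steps + 1):
        k1 = f(b)
        k2 = f(b + 0.5 * dt * k1)
        k3 = f(b + 0.5 * dt * k2)
        k4 = f(b + dt * k3)
        b = b + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.abs(b).max() > 1e3 or not np.all(np.isfinite(b)):
            raise FloatingPointError(f"simulation diverged at step {step}")
        if step % stride == 0 or step == n_steps:
            traj.times.append(step * dt)
            traj.snapshots.append(b0.with_values(b.copy()))
    return traj
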