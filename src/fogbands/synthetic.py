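"""Synthetic inputs: noisy initial conditions, striped scenes, and DEMs.

Everything the downstream stages consume can be generated here with known
ground truth: uniform-noise initial conditions for the simulators, grayscale
striped "satellite-like" scenes with one or several orientation domains, and
digital elevation models (DEMs) with a prescribed slope-gradient direction.
All generators are pure functions of their spec and seed.

The scenes emulate imagery of fog-fed *Tillandsia* bands: a dominant band
angle (the field value is around 120 deg CCW from east, i.e. roughly
perpendicular to the mean wind at 30 deg), orientation domains offset by a
few degrees from one another, a smooth illumination/topography background,
speckle noise, and optional dislocation defects.  Stripes are sinusoidal
rather than binary: near pattern-forming onset the biomass modulation is
harmonic, and a pure cosine gives a clean closed-form ground truth for the
structure-tensor pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .grids import Field2D, fold_180

DEFAULT_WIND_DEG = 30.0  # mean fog/wind direction, degrees CCW from east


@dataclass(frozen=True)
class DomainSpec:
    """An axis-aligned rectangular orientation domain of a scene.

    ``bbox`` is (x0, x1, y0, y1) in pixels, half-open, in the array/axis
    convention of :class:`~fogbands.grids.Field2D` (axis 0 = x).
    """

    bbox: tuple[int, int, int, int]
    angle_deg: float  # band orientation, CCW from east, taken mod 180
    phase: float = 0.0


@dataclass
class SceneSpec:
    """Ground-truth description of a striped grayscale scene."""

    shape: tuple[int, int] = (256, 256)  # (nx, ny) pixels
    wavelength: float = 16.0  # stripe wavelength, pixels
    domains: list[DomainSpec] = dc_field(default_factory=list)
    contrast: float = 1.0  # stripe amplitude, intensity units
    background_gradient: tuple[float, float] = (0.0, 0.0)  # intensity / pixel
    background_level: float = 0.0
    noise_std: float = 0.0  # Gaussian pixel noise, intensity units
    defect_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength < 4.0:
            raise ValueError("stripe wavelength must be >= 4 px to be resolvable")
        if self.noise_std < 0:
            raise ValueError("noise std must be >= 0")
        if min(self.shape) <= 0:
            raise ValueError("scene shape must be positive")
        for d in self.domains:
            x0, x1, y0, y1 = d.bbox
            if not (0 <= x0 < x1 <= self.shape[0] and 0 <= y0 < y1 <= self.shape[1]):
                raise ValueError(f"domain bbox {d.bbox} outside scene shape {self.shape}")
        for i, a in enumerate(self.domains):
            for b in self.domains[i + 1 :]:
                if _bbox_overlap(a.bbox, b.bbox):
                    raise ValueError(
                        f"overlapping domains {a.bbox} and {b.bbox}: ground truth ambiguous"
                    )


def _bbox_overlap(a, b) -> bool:
    ax0, ax1, ay0, ay1 = a
    bx0, bx1, by0, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


@dataclass
class DemSpec:
    """Ground truth for a synthetic DEM: planar ramp plus optional ridges."""

    shape: tuple[int, int] = (128, 128)  # (nx, ny) pixels
    slope_direction_deg: float = 0.0  # uphill gradient direction, CCW from east
    slope_magnitude: float = 1.0  # height units per pixel
    ridge_amplitude: float = 0.0  # height units
    ridge_wavelength: float = 32.0  # pixels, along the cross-slope direction

    def __post_init__(self) -> None:
        if min(self.shape) <= 0:
            raise ValueError("DEM shape must be positive")
        if self.ridge_wavelength <= 0:
            raise ValueError("ridge wavelength must be positive")


def make_noise_ic(
    shape: tuple[int, int],
    box_sizes: tuple[float, float] | None = None,
    mean: float = 0.1,
    amplitude: float = 0.1,
    seed: int = 0,
    bc_x: str = "dirichlet",
) -> Field2D:
    """Uniform-noise initial condition for the biomass simulators.

    Values are ``mean + U(-amplitude, amplitude)``, clipped at zero (biomass
    cannot be negative); for Dirichlet walls the first and last x-rows are
    zeroed.  The noise is uniform with a small default amplitude so the early
    evolution stays in the linear regime of the pattern-forming instability.
    """
    nx, ny = shape
    if nx <= 0 or ny <= 0:
        raise ValueError(f"grid shape must be positive, got {shape}")
    if amplitude < 0:
        raise ValueError("noise amplitude must be >= 0")
    if mean < 0:
        raise ValueError("mean biomass must be >= 0")
    rng = np.random.default_rng(seed)
    values = mean + rng.uniform(-amplitude, amplitude, size=(nx, ny))
    np.clip(values, 0.0, None, out=values)
    if bc_x == "dirichlet":
        values[0, :] = 0.0
        values[-1, :] = 0.0
    if box_sizes is None:
        dx = dy = 1.0
    else:
        Lx, Ly = box_sizes
        dx = Lx / (nx - 1) if bc_x == "dirichlet" else Lx / nx
        dy = Ly / ny  # y is always periodic here
    return Field2D(values, dx=dx, dy=dy, bc_x=bc_x, bc_y="periodic")


def make_banded_scene(spec: SceneSpec) -> Field2D:
    """Render a striped intensity raster with known orientation structure.

    Each domain holds ``contrast * cos(k . r + phase)`` with the wavevector
    perpendicular to the domain band angle; a linear background, Gaussian
    pixel noise, and seeded dislocation defects (phase jumps of pi along a
    cut) are added on top.
    """
    nx, ny = spec.shape
    X, Y = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float), indexing="ij")
    rng = np.random.default_rng(spec.seed)
    img = (
        spec.background_level
        + spec.background_gradient[0] * X
        + spec.background_gradient[1] * Y
    )
    k = 2.0 * np.pi / spec.wavelength
    for dom in spec.domains:
        x0, x1, y0, y1 = dom.bbox
        normal = np.deg2rad(fold_180(dom.angle_deg) + 90.0)
        xs, ys = X[x0:x1, y0:y1], Y[x0:x1, y0:y1]
        phase = k * (xs * np.cos(normal) + ys * np.sin(normal)) + dom.phase
        if spec.defect_count > 0:
            for _ in range(spec.defect_count):
                cx = rng.uniform(x0, x1)
                cy = rng.uniform(y0, y1)
                phase = phase + np.pi * ((xs > cx) & (ys > cy))
        img[x0:x1, y0:y1] += spec.contrast * np.cos(phase)
    if spec.noise_std > 0:
        img += rng.normal(0.0, spec.noise_std, size=img.shape)
    return Field2D(img, dx=1.0, dy=1.0, bc_x="periodic", bc_y="periodic")


def three_domain_scene(
    wind_deg: float = DEFAULT_WIND_DEG,
    oblique_offset_deg: float = 7.0,
    shape: tuple[int, int] = (256, 256),
    wavelength: float = 16.0,
    contrast: float = 1.0,
    noise_std: float = 0.0,
    seed: int = 0,
    background_gradient: tuple[float, float] = (0.0, 0.0),
) -> tuple[Field2D, SceneSpec]:
    """Scene with three y-strips at the wind-perpendicular angle and +-offset.

    This is the synthetic analogue of a patch hosting one horizontal (H) and
    two oblique (O_l, O_r) band populations: band angles ``wind + 90`` and
    ``wind + 90 -+ offset``, all mod 180.
    """
    nx, ny = shape
    base = fold_180(wind_deg + 90.0)
    thirds = [0, ny // 3, 2 * ny // 3, ny]
    angles = [base - oblique_offset_deg, base, base + oblique_offset_deg]
    domains = [
        DomainSpec(bbox=(0, nx, thirds[i], thirds[i + 1]), angle_deg=angles[i])
        for i in range(3)
    ]
    spec = SceneSpec(
        shape=shape,
        wavelength=wavelength,
        domains=domains,
        contrast=contrast,
        noise_std=noise_std,
        seed=seed,
        background_gradient=background_gradient,
    )
    return make_banded_scene(spec), spec


def make_dem(spec: DemSpec) -> Field2D:
    """Height raster: planar ramp with the given uphill direction.

    With ``ridge_amplitude > 0`` a sinusoidal modulation running along the
    cross-slope coordinate is added, so the local gradient direction swings
    around the nominal one (non-degenerate slope-angle histogram).
    """
    nx, ny = spec.shape
    X, Y = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float), indexing="ij")
    th = np.deg2rad(spec.slope_direction_deg)
    s = X * np.cos(th) + Y * np.sin(th)  # along-slope coordinate
    t = -X * np.sin(th) + Y * np.cos(th)  # cross-slope coordinate
    h = spec.slope_magnitude * s
    if spec.ridge_amplitude != 0.0:
        h = h + spec.ridge_amplitude * np.sin(2.0 * np.pi * t / spec.ridge_wavelength)
    return Field2D(h, dx=1.0, dy=1.0, bc_x="periodic", bc_y="periodic")
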