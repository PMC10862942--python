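"""Synthetic projection phantoms with analytic ground truth.

A phantom is described by two co-registered fine-grid fields sampled at
cell centers: the intensity transmission ``T(x, y)`` and the phase shift
``phi(x, y)`` (radians) accumulated by the beam through the object.  The
fine grid oversamples the detector pixel grid by an integer factor ``s``
so that per-pixel quantities can be formed by exact area averaging.

Sign convention: for X-rays the refractive index is n = 1 - delta, so a
projected thickness t produces a phase *retardation* phi = -k * delta * t.
Flipping this convention flips only the sign of the differential-phase
signal Dn downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Geometry",
    "Material",
    "ProjectedObject",
    "MATERIALS",
    "ModelAssumptionWarning",
    "make_cylinder_phantom",
    "make_tube_phantom",
    "make_gaussian_phantom",
    "phase_gradient",
    "phase_laplacian",
    "pixel_average",
]

#: hc in keV.nm, so lambda[nm] = HC_KEV_NM / E[keV]
HC_KEV_NM = 1.239841984


class ModelAssumptionWarning(UserWarning):
    """A modeling assumption (slow variation, TIE validity) is strained."""


@dataclass(frozen=True)
class Geometry:
    """Imaging geometry and sampling.

    Parameters
    ----------
    z : float
        Object-to-detector propagation distance in meters.
    p : float
        Detector pixel size in meters.
    nx, ny : int
        Detector pixel counts along x (mask modulation direction) and y.
    energy : float
        Design photon energy in keV (monochromatic stand-in for the
        polychromatic spectrum of a real tube).
    s : int
        Fine-grid oversampling factor; fine spacing is ``p / s``.
    magnification : float
        Optional cone-beam magnification M = (SOD+ODD)/SOD.  The default
        1.0 selects the parallel-beam model; when set, ``effective_z``
        returns z/M for use in propagation formulas.
    """

    z: float
    p: float
    nx: int
    ny: int
    energy: float = 20.0
    s: int = 16
    magnification: float = 1.0

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("propagation distance z must be >= 0")
        if self.p <= 0:
            raise ValueError("pixel size p must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("detector must have at least one pixel per axis")
        if self.energy <= 0:
            raise ValueError("design energy must be positive (keV)")
        if self.s < 8:
            raise ValueError("oversampling factor s must be >= 8")
        if self.magnification < 1.0:
            raise ValueError("magnification must be >= 1")

    @property
    def wavelength(self) -> float:
        """Wavelength in meters, lambda = hc / E."""
        return HC_KEV_NM / self.energy * 1e-9

    @property
    def k(self) -> float:
        """Wavenumber 2*pi/lambda in 1/m."""
        return 2.0 * np.pi / self.wavelength

    @property
    def fine_dx(self) -> float:
        return self.p / self.s

    @property
    def effective_z(self) -> float:
        """Propagation distance entering the TIE; z/M in cone beam."""
        return self.z / self.magnification

    def x_fine(self) -> np.ndarray:
        """Cell-centered fine-grid x coordinates, pixel n spans [n*p, (n+1)*p)."""
        return (np.arange(self.nx * self.s) + 0.5) * self.fine_dx

    def y_fine(self) -> np.ndarray:
        return (np.arange(self.ny * self.s) + 0.5) * self.fine_dx

    def x_pixel(self) -> np.ndarray:
        """Pixel-center x coordinates."""
        return (np.arange(self.nx) + 0.5) * self.p

    @property
    def fov_x(self) -> float:
        return self.nx * self.p


@dataclass(frozen=True)
class Material:
    """Optical constants of a material at the design energy.

    delta is the refractive-index decrement (n = 1 - delta), mu the
    linear intensity attenuation coefficient in 1/m.
    """

    name: str
    delta: float
    mu: float

    def __post_init__(self) -> None:
        if self.delta < 0 or self.mu < 0:
            raise ValueError("delta and mu must be non-negative")


# Built-in constants at the 20 keV design energy.  delta from
# r_e * lambda^2 * n_e / (2 pi) with tabulated electron densities; mu
# from standard mass-attenuation compilations.  Override via config for
# other energies.
MATERIALS: dict[str, Material] = {
    "pmma": Material("pmma", delta=6.66e-7, mu=68.0),
    "water": Material("water", delta=5.76e-7, mu=81.0),
    "polycarbonate": Material("polycarbonate", delta=6.56e-7, mu=64.0),
}


@dataclass
class ProjectedObject:
    """Fine-grid transmission and phase-shift fields of a projected object."""

    dx: float
    dy: float
    T: np.ndarray
    phi: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.T.shape != self.phi.shape:
            raise ValueError("T and phi must have identical shapes")
        if not (np.all(np.isfinite(self.T)) and np.all(np.isfinite(self.phi))):
            raise ValueError("phantom fields must be finite")
        if np.any(self.T <= 0) or np.any(self.T > 1 + 1e-12):
            raise ValueError("transmission must lie in (0, 1]")


def _chord(radius: float, x: np.ndarray) -> np.ndarray:
    """Projected chord length 2*sqrt(r^2 - x^2) of a cylinder, 0 outside."""
    arg = radius * radius - x * x
    return 2.0 * np.sqrt(np.clip(arg, 0.0, None))


def make_cylinder_phantom(
    radius: float,
    material: Material,
    geometry: Geometry,
    center_x: float | None = None,
) -> ProjectedObject:
    """Projection of a solid cylinder with axis along y (mask strips).

    The projected thickness is t(x) = 2*sqrt(R^2 - (x-c)^2) inside the
    rod and 0 outside, giving T = exp(-mu*t) and phi = -k*delta*t.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if center_x is None:
        center_x = geometry.fov_x / 2.0
    if 2 * radius > geometry.fov_x:
        raise ValueError("cylinder diameter exceeds the detector field of view")
    x = geometry.x_fine() - center_x
    t = _chord(radius, x)
    T_line = np.exp(-material.mu * t)
    phi_line = -geometry.k * material.delta * t
    ny_fine = geometry.ny * geometry.s
    return ProjectedObject(
        dx=geometry.fine_dx,
        dy=geometry.fine_dx,
        T=np.broadcast_to(T_line, (ny_fine, T_line.size)).copy(),
        phi=np.broadcast_to(phi_line, (ny_fine, phi_line.size)).copy(),
        meta={
            "kind": "cylinder",
            "radius": radius,
            "center_x": center_x,
            "material": material.name,
        },
    )


def make_tube_phantom(
    outer_r: float,
    wall_thickness: float,
    rod_r: float,
    wall_mat: Material,
    fill_mat: Material,
    rod_mat: Material,
    geometry: Geometry,
    center_x: float | None = None,
) -> ProjectedObject:
    """Nested tube phantom: a tube wall, a liquid fill, and a coaxial rod.

    Per-material projected thicknesses follow from nested-cylinder chord
    lengths; attenuations and phase shifts add along the ray.
    """
    inner_r = outer_r - wall_thickness
    if wall_thickness <= 0 or outer_r <= 0 or rod_r <= 0:
        raise ValueError("all radii/thicknesses must be positive")
    if rod_r >= inner_r:
        raise ValueError("rod must fit inside the tube bore (rod_r < outer_r - wall)")
    if center_x is None:
        center_x = geometry.fov_x / 2.0
    if 2 * outer_r > geometry.fov_x:
        raise ValueError("tube diameter exceeds the detector field of view")
    x = geometry.x_fine() - center_x
    t_outer = _chord(outer_r, x)
    t_inner = _chord(inner_r, x)
    t_rod = _chord(rod_r, x)
    t_wall = t_outer - t_inner
    t_fill = t_inner - t_rod
    mut = wall_mat.mu * t_wall + fill_mat.mu * t_fill + rod_mat.mu * t_rod
    deltat = (
        wall_mat.delta * t_wall + fill_mat.delta * t_fill + rod_mat.delta * t_rod
    )
    ny_fine = geometry.ny * geometry.s
    T_line = np.exp(-mut)
    phi_line = -geometry.k * deltat
    return ProjectedObject(
        dx=geometry.fine_dx,
        dy=geometry.fine_dx,
        T=np.broadcast_to(T_line, (ny_fine, T_line.size)).copy(),
        phi=np.broadcast_to(phi_line, (ny_fine, phi_line.size)).copy(),
        meta={
            "kind": "tube",
            "outer_r": outer_r,
            "wall_thickness": wall_thickness,
            "rod_r": rod_r,
            "center_x": center_x,
        },
    )


def make_gaussian_phantom(
    amplitude_phi: float,
    amplitude_att: float,
    sigma: float,
    geometry: Geometry,
    center: tuple[float, float] | None = None,
) -> ProjectedObject:
    """Band-limited smooth blob: phi = -A_phi*G, T = 1 - A_att*G.

    G is a unit-peak isotropic Gaussian of scale ``sigma``.  A blob with
    ``amplitude_att ~ 1e-3 * amplitude_phi`` mimics the phase-dominant
    optical response of soft matter (for PMMA at 20 keV,
    mu/(k*delta) ~ 1e-3 per radian).
    """
    if not 0 <= amplitude_att < 1:
        raise ValueError("amplitude_att must be in [0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if sigma < 4 * geometry.p:
        warnings.warn(
            "sigma < 4 pixels: the slow-variation assumption behind the "
            "pixel-integrated model is strained",
            ModelAssumptionWarning,
            stacklevel=2,
        )
    if center is None:
        center = (geometry.fov_x / 2.0, geometry.ny * geometry.p / 2.0)
    x = geometry.x_fine() - center[0]
    y = geometry.y_fine() - center[1]
    G = np.exp(-(x[None, :] ** 2 + y[:, None] ** 2) / (2.0 * sigma * sigma))
    return ProjectedObject(
        dx=geometry.fine_dx,
        dy=geometry.fine_dx,
        T=1.0 - amplitude_att * G,
        phi=-amplitude_phi * G,
        meta={
            "kind": "gaussian",
            "amplitude_phi": amplitude_phi,
            "amplitude_att": amplitude_att,
            "sigma": sigma,
        },
    )


def _deriv1(f: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Central first derivative, one-sided at the boundary (np.gradient)."""
    return np.gradient(f, h, axis=axis, edge_order=2)


def _deriv2(f: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Second derivative by a 3-point stencil; quadratic-exact everywhere."""
    f = np.moveaxis(f, axis, -1)
    d2 = np.empty_like(f)
    d2[..., 1:-1] = f[..., 2:] - 2.0 * f[..., 1:-1] + f[..., :-2]
    # one-sided second differences are also exact for quadratics
    d2[..., 0] = f[..., 0] - 2.0 * f[..., 1] + f[..., 2]
    d2[..., -1] = f[..., -1] - 2.0 * f[..., -2] + f[..., -3]
    return np.moveaxis(d2 / (h * h), -1, axis)


def phase_gradient(obj: ProjectedObject) -> np.ndarray:
    """d(phi)/dx on the fine grid (radians/m), central differences."""
    if obj.phi.shape[-1] < 3:
        raise ValueError("need at least 3 samples along x")
    return _deriv1(obj.phi, obj.dx, axis=-1)


def phase_laplacian(obj: ProjectedObject) -> np.ndarray:
    """Transverse Laplacian of phi (radians/m^2), 5-point stencil."""
    if obj.phi.shape[-1] < 3 or obj.phi.shape[0] < 3:
        raise ValueError("need at least 3 samples along each axis")
    return _deriv2(obj.phi, obj.dx, axis=-1) + _deriv2(obj.phi, obj.dy, axis=0)


def pixel_average(fine: np.ndarray, geometry: Geometry) -> np.ndarray:
    """Area-weighted mean of a fine-grid field over each pixel footprint."""
    fine = np.asarray(fine)
    s = geometry.s
    ny, nx = fine.shape
    if ny != geometry.ny * s or nx != geometry.nx * s:
        raise ValueError(
            f"fine grid {fine.shape} is not commensurate with "
            f"{geometry.ny}x{geometry.nx} pixels at oversampling {s}"
        )
    return fine.reshape(geometry.ny, s, geometry.nx, s).mean(axis=(1, 3))
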