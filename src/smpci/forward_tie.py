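"""Forward image formation for single-mask phase contrast imaging.

Three levels of model are provided:

* ``tie_propagate`` — the mask-free propagation-based (PB) intensity on
  the fine grid, I = I0 - (z/k)(grad I0 . grad phi + I0 lap phi), with
  the cross term optionally dropped for smooth objects.
* ``single_mask_image_integrated`` — direct numeric per-pixel
  integration of the three transport terms T*M, T*dM/dx*dphi/dx and
  T*M*lap(phi) on the fine grid.  Serves as the oracle for the closed
  form.
* ``single_mask_image_closed_form`` — the two-coefficient pixel model

      In = we * Tn * (1 - Ln) + alpha * (-1)^(n+parity) * Tn * Dn

  where Tn, Ln = (z/k)<lap phi> and Dn = (z/k)<dphi/dx> are per-pixel
  averages and (we, alpha) characterize the mask.  With the default
  parity (slit centers at even pixel boundaries) a positive beamlet
  displacement Dn brightens even columns.

Pre-flat-correction images carry units of length (the effective
aperture we), so that flat-field correction is exactly dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mask_model import (
    MaskCoefficients,
    MaskSpec,
    mask_transmission,
    mask_transmission_derivative,
    _require_aligned,
)
from .phantoms import (
    Geometry,
    ModelAssumptionWarning,
    ProjectedObject,
    phase_gradient,
    phase_laplacian,
    pixel_average,
)

__all__ = [
    "DetectorImage",
    "PixelFields",
    "tie_propagate",
    "compute_pixel_fields",
    "single_mask_image_closed_form",
    "single_mask_image_integrated",
    "flat_field_image",
    "add_poisson_noise",
    "parity_signs",
]


@dataclass
class DetectorImage:
    """Per-pixel intensities with provenance metadata."""

    values: np.ndarray
    p: float
    kind: str = "sample_mask"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("detector image must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PixelFields:
    """Per-pixel object descriptors entering the closed-form model.

    Tn: transmission; Ln: (z/k)*lap(phi) (dimensionless); Dn: (z/k)*
    d(phi)/dx, the beamlet displacement at the detector (meters).
    """

    Tn: np.ndarray
    Ln: np.ndarray
    Dn: np.ndarray

    def __post_init__(self) -> None:
        for name in ("Tn", "Ln", "Dn"):
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), float)))
        if not (self.Tn.shape == self.Ln.shape == self.Dn.shape):
            raise ValueError("Tn, Ln, Dn must share one shape")


def parity_signs(nx: int, parity: int = 0) -> np.ndarray:
    """The alternating fringe sign (-1)^(n+parity) for 0-based columns."""
    return np.where((np.arange(nx) + parity) % 2 == 0, 1.0, -1.0)


def tie_propagate(
    obj: ProjectedObject,
    geometry: Geometry,
    keep_cross_term: bool = True,
    clip_negative: bool = False,
) -> np.ndarray:
    """Mask-free TIE intensity on the fine grid; I0 = T at the object plane."""
    z_over_k = geometry.effective_z / geometry.k
    I0 = obj.T
    lap = phase_laplacian(obj)
    if keep_cross_term:
        gx = np.gradient(I0, obj.dx, axis=-1, edge_order=2)
        gy = np.gradient(I0, obj.dy, axis=0, edge_order=2)
        cross = gx * phase_gradient(obj) + gy * np.gradient(
            obj.phi, obj.dy, axis=0, edge_order=2
        )
        I = I0 - z_over_k * (cross + I0 * lap)
    else:
        I = I0 * (1.0 - z_over_k * lap)
    if np.any(I < 0):
        warnings.warn(
            "negative TIE intensities: the linearized transport model is "
            "outside its validity regime here",
            ModelAssumptionWarning,
            stacklevel=2,
        )
        if clip_negative:
            I = np.clip(I, 0.0, None)
    return I


def compute_pixel_fields(obj: ProjectedObject, geometry: Geometry) -> PixelFields:
    """Pixel-averaged Tn, Ln, Dn under the slow-variation assumption."""
    z_over_k = geometry.effective_z / geometry.k
    return PixelFields(
        Tn=pixel_average(obj.T, geometry),
        Ln=z_over_k * pixel_average(phase_laplacian(obj), geometry),
        Dn=z_over_k * pixel_average(phase_gradient(obj), geometry),
    )


def single_mask_image_closed_form(
    fields: PixelFields,
    coeffs: MaskCoefficients,
    parity: int = 0,
    geometry: Geometry | None = None,
) -> DetectorImage:
    """Two-coefficient closed-form image (units of length).

    In = we*Tn*(1-Ln) + alpha*(-1)^(n+parity)*Tn*Dn.  Negative values
    (strong refraction) are reported via a warning, not clipped.
    """
    if coeffs.we <= 0:
        raise ValueError("effective aperture we must be positive")
    signs = parity_signs(fields.Tn.shape[-1], parity)
    values = coeffs.we * fields.Tn * (1.0 - fields.Ln) + (
        coeffs.alpha * signs[None, :] * fields.Tn * fields.Dn
    )
    if np.any(values < 0):
        warnings.warn(
            "negative closed-form intensities (|alpha Tn Dn| exceeds the PB "
            "term): outside the model's validity regime",
            ModelAssumptionWarning,
            stacklevel=2,
        )
    p = geometry.p if geometry is not None else 0.0  # 0.0 = unspecified
    return DetectorImage(
        values=values,
        p=p,
        kind="sample_mask",
        meta={"model": "closed_form", "we": coeffs.we, "alpha": coeffs.alpha,
              "parity": parity},
    )


def single_mask_image_integrated(
    obj: ProjectedObject, spec: MaskSpec, geometry: Geometry
) -> DetectorImage:
    """Direct numeric pixel integration of the three transport terms.

    Cell-centered Riemann sums commensurate with the pixel grid are
    exact for every cosine harmonic of the mask, so an empty beam
    reproduces the flat level C0*p to rounding precision.
    """
    _require_aligned(spec)
    samples_per_period = 2 * geometry.s
    n_harm = spec.coeffs.size - 1
    if n_harm > 1 and samples_per_period < 64:
        warnings.warn(
            f"{samples_per_period} samples per mask period may not resolve "
            "the mask transitions (want >= 64 for multi-harmonic masks)",
            ModelAssumptionWarning,
            stacklevel=2,
        )
    x = geometry.x_fine()
    M = mask_transmission(spec, x)[None, :]
    dM = mask_transmission_derivative(spec, x)[None, :]
    z_over_k = geometry.effective_z / geometry.k
    gx = phase_gradient(obj)
    lap = phase_laplacian(obj)
    integrand = obj.T * M - z_over_k * (obj.T * dM * gx + obj.T * M * lap)
    s = geometry.s
    blocks = integrand.reshape(geometry.ny, s, geometry.nx, s)
    values = blocks.mean(axis=1).sum(axis=-1) * geometry.fine_dx
    return DetectorImage(
        values=values,
        p=geometry.p,
        kind="sample_mask",
        meta={"model": "integrated", "n_harmonics": n_harm},
    )


def flat_field_image(coeffs: MaskCoefficients, geometry: Geometry) -> DetectorImage:
    """Mask-only image: every pixel equals the effective aperture we."""
    if coeffs.we <= 0:
        raise ValueError("effective aperture we must be positive")
    return DetectorImage(
        values=np.full((geometry.ny, geometry.nx), coeffs.we),
        p=geometry.p,
        kind="flat",
        meta={"we": coeffs.we, "alpha": coeffs.alpha},
    )


def add_poisson_noise(
    image: DetectorImage,
    mean_counts_flat: float,
    seed: int,
    flat_value: float | None = None,
) -> DetectorImage:
    """Poisson photon noise scaled so the flat level maps to
    ``mean_counts_flat`` expected counts per pixel.

    Each pixel value v is replaced by Poisson(v * c / flat) * flat / c.
    ``flat_value`` defaults to the image's recorded effective aperture,
    falling back to the median pixel value.
    """
    if mean_counts_flat <= 0:
        raise ValueError("mean_counts_flat must be positive")
    if not np.all(np.isfinite(image.values)):
        raise ValueError("cannot add noise to non-finite intensities")
    if flat_value is None:
        flat_value = image.meta.get("we") or float(np.median(image.values))
    scale = mean_counts_flat / flat_value
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(np.clip(image.values, 0.0, None) * scale) / scale
    meta = dict(image.meta, noise_counts=mean_counts_flat, noise_seed=seed)
    return DetectorImage(values=noisy, p=image.p, kind=image.kind, meta=meta)
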