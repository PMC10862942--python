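"""Single-shot separation of propagation-based and differential-phase images.

One sample+mask exposure and one flat (mask-only) exposure suffice.
After flat-field correction the per-pixel signal is

    In_bar = Tn (1 - Ln) + s_n (alpha / we) Tn Dn,      s_n = (-1)^(n+parity)

so adding and subtracting neighboring columns separates the smooth
propagation-based (PB) part Tn(1 - Ln) from the alternating
differential-phase (DPC) part.  For each pair (n, n+1):

    pb  = (In_bar + In+1_bar) / 2
    dpc = s_n * (we / alpha) * (In_bar - In+1_bar) / (In_bar + In+1_bar)

Pairing modes
-------------
disjoint
    Non-overlapping pairs (2j, 2j+1): half-width output at pair centers.
    Any smooth transmission gradient leaks into dpc at first order in
    the pixel size (crosstalk ~ (we/2 alpha) * p * d(ln T)/dx).
sliding
    Every adjacent pair, averaged over the two pairs covering each
    pixel: full-width output with a triangular [1, 2, 1]/4 column
    kernel.  The alternating first-order attenuation-gradient crosstalk
    cancels, leaving an O(p^2) residual.  With
    ``pb_gradient_correction`` the smooth gradient estimated from the
    PB channel is subtracted from each pair difference before the
    ratio, suppressing the residual further; the effective column
    kernel then becomes [1, 0, 1]/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_tie import DetectorImage, parity_signs
from .mask_model import MaskCoefficients
from .phantoms import Geometry

__all__ = [
    "CorrectedImage",
    "RetrievedPair",
    "flat_correct",
    "retrieve_pb_dpc",
    "dpc_to_refraction",
]


@dataclass
class CorrectedImage:
    """Flat-corrected, dimensionless intensities with a validity mask."""

    values: np.ndarray
    parity: int = 0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask must match the image shape")


@dataclass
class RetrievedPair:
    """PB image Tn(1-Ln) (dimensionless) and DPC image Dn (meters)."""

    pb: np.ndarray
    dpc: np.ndarray
    x: np.ndarray
    pairing: str
    parity: int = 0
    meta: dict = field(default_factory=dict)


def flat_correct(
    sample: DetectorImage, flat: DetectorImage, epsilon: float = 1e-6, parity: int = 0
) -> CorrectedImage:
    """Elementwise sample/flat ratio (the dimensionless In_bar).

    Flat pixels at or below ``epsilon * median(flat)`` are flagged
    invalid and excluded from pairing.
    """
    if sample.shape != flat.shape:
        raise ValueError(f"shape mismatch: sample {sample.shape} vs flat {flat.shape}")
    floor = epsilon * float(np.median(flat.values))
    good = flat.values > floor
    if not good.any():
        raise ValueError("all flat-field pixels are at or below the guard floor")
    out = np.full(sample.shape, np.nan)
    np.divide(sample.values, flat.values, out=out, where=good)
    return CorrectedImage(values=out, parity=parity, valid=good)


def _pair_estimates(
    a: np.ndarray,
    b: np.ndarray,
    sign: np.ndarray,
    coeffs: MaskCoefficients,
    floor: float,
):
    """Eq.-style per-pair PB and DPC estimates; guarded division."""
    total = a + b
    ok = np.isfinite(total) & (np.abs(total) > floor)
    pb = 0.5 * total
    dpc = np.full_like(pb, np.nan)
    np.divide(a - b, total, out=dpc, where=ok)
    dpc *= sign * (coeffs.we / coeffs.alpha)
    pb = np.where(np.isfinite(a) & np.isfinite(b), pb, np.nan)
    return pb, dpc


def retrieve_pb_dpc(
    corrected: CorrectedImage,
    coeffs: MaskCoefficients,
    pairing: str = "disjoint",
    geometry: Geometry | None = None,
    positivity_floor: float = 1e-12,
    pb_gradient_correction: bool = False,
) -> RetrievedPair:
    """Separate PB and DPC channels from a flat-corrected image."""
    vals = np.where(corrected.valid, corrected.values, np.nan)
    ny, nx = vals.shape
    if nx < 2:
        raise ValueError("need at least two pixel columns to pair")
    if coeffs.alpha <= 0:
        raise ValueError("mask contrast alpha must be positive to retrieve dpc")
    p = geometry.p if geometry is not None else 1.0
    signs = parity_signs(nx, corrected.parity)

    if pairing == "disjoint":
        npair = nx // 2
        a = vals[:, 0 : 2 * npair : 2]
        b = vals[:, 1 : 2 * npair : 2]
        pb, dpc = _pair_estimates(a, b, signs[0:2 * npair:2][None, :], coeffs,
                                  positivity_floor)
        x = (2 * np.arange(npair) + 1.0) * p  # pair-center coordinate
        meta = {"kernel": [0.5, 0.5]}
    elif pairing == "sliding":
        a, b = vals[:, :-1], vals[:, 1:]
        sign_pair = signs[:-1][None, :]
        pair_pb, pair_dpc = _pair_estimates(a, b, sign_pair, coeffs, positivity_floor)
        if pb_gradient_correction:
            # subtract the smooth (PB) per-pair gradient, estimated from the
            # triangular-kernel PB channel, before forming the ratio
            pb_full = _two_pair_average(pair_pb)
            diff_pb = pb_full[:, :-1] - pb_full[:, 1:]
            corr = sign_pair * (coeffs.we / coeffs.alpha) * diff_pb / (
                pair_pb * 2.0
            )
            pair_dpc = pair_dpc - corr
            kernel = [0.5, 0.0, 0.5]
        else:
            kernel = [0.25, 0.5, 0.25]
        pb = _two_pair_average(pair_pb)
        dpc = _two_pair_average(pair_dpc)
        x = (np.arange(nx) + 0.5) * p
        meta = {"kernel": kernel, "correlated_neighbors": True,
                "pb_gradient_correction": pb_gradient_correction}
    else:
        raise ValueError(f"unknown pairing mode: {pairing!r}")

    if np.any(pb[np.isfinite(pb)] <= 0):
        meta["nonpositive_pb"] = True
    return RetrievedPair(
        pb=pb, dpc=dpc, x=x, pairing=pairing, parity=corrected.parity, meta=meta
    )


def _two_pair_average(pair_vals: np.ndarray) -> np.ndarray:
    """Average the two adjacent-pair estimates covering each pixel.

    Column n of the output combines pairs (n-1, n) and (n, n+1); edge
    columns keep their single available pair.
    """
    ny, npair = pair_vals.shape
    out = np.empty((ny, npair + 1))
    out[:, 0] = pair_vals[:, 0]
    out[:, -1] = pair_vals[:, -1]
    out[:, 1:-1] = 0.5 * (pair_vals[:, :-1] + pair_vals[:, 1:])
    return out


def dpc_to_refraction(pair: RetrievedPair, geometry: Geometry) -> np.ndarray:
    """Refraction angle theta = Dn / z (radians); Dn = z * theta."""
    if geometry.effective_z <= 0:
        raise ValueError("propagation distance must be positive")
    return pair.dpc / geometry.effective_z
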