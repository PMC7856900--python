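"""Multiscale Hessian vesselness (Frangi) enhancement.

The vessel-enhanced training target ("ground truth 3") is the
full-sampling 532 nm image passed through the standard 2-D Frangi
filter: at each Gaussian scale sigma the scale-normalized Hessian is
eigendecomposed per pixel (|lambda1| <= |lambda2|); bright tubular
structures have lambda2 strongly negative and |lambda1| small, so the
vesselness is

    V = 0                                         if lambda2 > 0
    V = exp(-R_B^2 / 2 beta^2) * (1 - exp(-S^2 / 2 c^2))   otherwise

with blobness R_B = lambda1/lambda2 and structureness
S = sqrt(lambda1^2 + lambda2^2).  The final response is the pixelwise
maximum over scales, min-max normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

__all__ = ["VesselnessParams", "hessian_eigenvalues", "frangi_response", "make_ground_truth3"]


@dataclass(frozen=True)
class VesselnessParams:
    """Frangi filter parameters.

    scales : Gaussian SDs (pixels) probing vessel calibers.
    beta : blobness sensitivity (dimensionless).
    c : structureness sensitivity on the image-amplitude scale, or
        "auto" = half the maximum structureness per scale.
    bright_on_dark : True for bright vessels on dark background.
    """

    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    beta: float = 0.5
    c: float | str = "auto"
    bright_on_dark: bool = True

    def __post_init__(self) -> None:
        if len(self.scales) == 0 or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be non-empty and strictly positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (self.c == "auto" or (isinstance(self.c, (int, float)) and self.c > 0)):
            raise ValueError("c must be positive or 'auto'")


def _gaussian_derivative_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled Gaussian and its first/second derivatives, moment-corrected.

    Plainly sampled derivative-of-Gaussian kernels keep a tiny residual DC
    component and slightly wrong low-order moments, which shows up as a
    spurious Hessian response on flat and polynomial image regions.  The
    corrections enforce: sum(g0)=1; sum(k g1)=1 (unit response to a unit
    ramp); sum(g2)=0 and sum(k^2 g2)=2 (zero response to constants, exact
    curvature of x^2).
    """
    radius = max(int(8.0 * sigma + 0.5), 4)
    k = np.arange(-radius, radius + 1, dtype=float)
    g0 = np.exp(-(k**2) / (2.0 * sigma**2))
    g0 /= g0.sum()
    g1 = -k / sigma**2 * g0
    g1 /= (k * g1).sum()
    g2 = (k**2 / sigma**2 - 1.0) / sigma**2 * g0
    g2 -= g0 * g2.sum()
    g2 *= 2.0 / (k**2 * g2).sum()
    return g0, g1, g2


def hessian_eigenvalues(image: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the scale-normalized Gaussian Hessian at scale sigma.

    Returns per-pixel eigenvalue fields ordered by magnitude,
    |lambda1| <= |lambda2|.  Scale normalization multiplies second
    derivatives by sigma^2 so responses are comparable across scales.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 5:
        raise ValueError("image must be 2-D and at least 5x5")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    s2 = sigma * sigma
    g0, g1, g2 = _gaussian_derivative_kernels(sigma)
    hrr = s2 * correlate1d(correlate1d(image, g2, axis=0), g0, axis=1)
    hcc = s2 * correlate1d(correlate1d(image, g0, axis=0), g2, axis=1)
    hrc = s2 * correlate1d(correlate1d(image, g1, axis=0), g1, axis=1)
    # closed-form symmetric 2x2 eigenvalues
    tr_half = 0.5 * (hrr + hcc)
    disc = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc**2, 0.0))
    e_lo, e_hi = tr_half - disc, tr_half + disc
    swap = np.abs(e_lo) > np.abs(e_hi)
    lam1 = np.where(swap, e_hi, e_lo)
    lam2 = np.where(swap, e_lo, e_hi)
    return lam1, lam2


def frangi_response(image: np.ndarray, params: VesselnessParams = VesselnessParams()) -> np.ndarray:
    """Multiscale vesselness response in [0, 1] (maximum over scales)."""
    image = np.asarray(image, dtype=float)
    response = np.zeros_like(image)
    for sigma in params.scales:
        lam1, lam2 = hessian_eigenvalues(image, sigma)
        if not params.bright_on_dark:
            lam1, lam2 = -lam1, -lam2
        structureness = np.hypot(lam1, lam2)
        if params.c == "auto":
            c = 0.5 * structureness.max()
            # numerically flat at this scale: no structure anywhere (the
            # floor keeps float noise from being rescaled into "vessels")
            if c < 1e-12:
                continue
        else:
            c = float(params.c)
        with np.errstate(divide="ignore", invalid="ignore"):
            blobness = np.where(lam2 != 0, lam1 / lam2, 0.0)
        v = np.exp(-(blobness**2) / (2.0 * params.beta**2)) * (
            1.0 - np.exp(-(structureness**2) / (2.0 * c * c))
        )
        v = np.where(lam2 > 0, 0.0, v)  # bright vessels need lambda2 < 0
        response = np.maximum(response, v)
    return response


def make_ground_truth3(gt1: np.ndarray, params: VesselnessParams = VesselnessParams()) -> np.ndarray:
    """Vessel-enhanced training target: normalized multiscale response of gt1."""
    gt1 = np.asarray(gt1, dtype=float)
    if gt1.min() < -1e-9 or gt1.max() > 1.0 + 1e-9:
        raise ValueError("gt1 must be normalized to [0, 1]")
    resp = frangi_response(gt1, params)
    lo, hi = resp.min(), resp.max()
    if hi - lo < 1e-15:
        return np.zeros_like(resp)
    return (resp - lo) / (hi - lo)
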