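"""Dual-wavelength linear unmixing to oxygen saturation (sO2) maps.

Per pixel the photoacoustic amplitudes at the two wavelengths are
modeled as a linear mix of oxy- and deoxy-hemoglobin:

    [pa532]   [eps_HbO2(532)  eps_Hb(532)] [C_HbO2]
    [pa560] = [eps_HbO2(560)  eps_Hb(560)] [C_Hb  ]

so solving the 2x2 system gives relative concentrations and
sO2 = C_HbO2 / (C_HbO2 + C_Hb).  Because sO2 is a per-pixel ratio it is
invariant to any single global scale applied to both channels — which is
why it survives the joint min-max normalization used throughout the
pipeline.  The map is then restricted to vessels by thresholding a mask
image (an original image, a vesselness-filtered image, or the fused
network reconstruction); masking only hides pixels, it never edits the
retained sO2 values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._constants import DEFAULT_EXTINCTION, ExtinctionTable

__all__ = ["SO2Map", "unmix_so2", "apply_mask", "ExtinctionTable"]


@dataclass
class SO2Map:
    """Per-pixel oxygen saturation with its vessel mask.

    ``so2`` is NaN wherever the mask is false or the unmixed total
    hemoglobin is non-positive; ``mask_source`` records what image the
    mask was thresholded from.
    """

    so2: np.ndarray
    mask: np.ndarray
    mask_source: str = "recon3"

    def __post_init__(self) -> None:
        if self.so2.shape != self.mask.shape:
            raise ValueError("so2 and mask must share one shape")


def unmix_so2(
    pa532: np.ndarray,
    pa560: np.ndarray,
    table: ExtinctionTable = DEFAULT_EXTINCTION,
) -> np.ndarray:
    """Per-pixel two-wavelength unmixing; NaN where total hemoglobin <= 0.

    Values are clipped to [0, 1].
    """
    pa532 = np.asarray(pa532, dtype=float)
    pa560 = np.asarray(pa560, dtype=float)
    if pa532.shape != pa560.shape:
        raise ValueError("the two wavelength images must share one shape")
    inv = np.linalg.inv(table.matrix)
    c_hbo2 = inv[0, 0] * pa532 + inv[0, 1] * pa560
    c_hb = inv[1, 0] * pa532 + inv[1, 1] * pa560
    total = c_hbo2 + c_hb
    with np.errstate(divide="ignore", invalid="ignore"):
        so2 = np.where(total > 0, c_hbo2 / np.where(total > 0, total, 1.0), np.nan)
    return np.clip(so2, 0.0, 1.0)


def apply_mask(
    so2: np.ndarray,
    mask_image: np.ndarray,
    threshold: float = 0.1,
    mask_source: str = "recon3",
) -> SO2Map:
    """Restrict an sO2 map to pixels where ``mask_image >= threshold``.

    Retained values pass through bit-identically (masking selects, it
    never rescales or edits); everything outside the mask is NaN.  An
    empty mask triggers a warning, not an error.
    """
    so2 = np.asarray(so2, dtype=float)
    mask_image = np.asarray(mask_image, dtype=float)
    if so2.shape != mask_image.shape:
        raise ValueError("so2 and mask image must share one shape")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    mask = mask_image >= threshold
    if not mask.any():
        warnings.warn("mask threshold excludes every pixel", stacklevel=2)
    out = np.where(mask, so2, np.nan)
    return SO2Map(so2=out, mask=mask, mask_source=mask_source)
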