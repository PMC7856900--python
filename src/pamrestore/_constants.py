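"""Shared physical constants and default spectral coefficients.

The default molar-extinction table is deliberately stylized: 532 nm is
treated as exactly isosbestic for oxy-/deoxy-hemoglobin (the real
isosbestic point sits at ~530 nm, close enough that OR-PAM practice uses
532 nm as the hemoglobin-concentration wavelength), while at 560 nm
deoxy-hemoglobin absorbs markedly more than oxy-hemoglobin.  Magnitudes
are on the cm^-1/M scale of the usual compiled hemoglobin spectra, but
only ratios matter anywhere in this package: images are normalized, and
sO2 is a per-pixel ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Nominal vacuum speed of light [m/s] used for fiber-delay arithmetic.
SPEED_OF_LIGHT = 3.0e8


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of hemoglobin at the two OR-PAM wavelengths.

    Units are arbitrary-but-consistent (relative coefficients are
    sufficient for unmixing and phantom rendering).
    """

    hbo2_532: float = 45000.0
    hb_532: float = 45000.0
    hbo2_560: float = 32600.0
    hb_560: float = 53400.0

    def __post_init__(self) -> None:
        vals = (self.hbo2_532, self.hb_532, self.hbo2_560, self.hb_560)
        if any(v <= 0 for v in vals):
            raise ValueError("extinction coefficients must be strictly positive")
        if abs(np.linalg.det(self.matrix)) < 1e-12 * max(vals) ** 2:
            raise ValueError("extinction table is singular; wavelengths are not spectrally distinct")

    @property
    def matrix(self) -> np.ndarray:
        """2x2 system matrix: rows = wavelengths (532, 560), cols = (HbO2, Hb)."""
        return np.array(
            [[self.hbo2_532, self.hb_532], [self.hbo2_560, self.hb_560]], dtype=float
        )

    def absorption(self, so2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel absorption factors at (532, 560) for oxygen saturation `so2`."""
        so2 = np.asarray(so2, dtype=float)
        a532 = self.hbo2_532 * so2 + self.hb_532 * (1.0 - so2)
        a560 = self.hbo2_560 * so2 + self.hb_560 * (1.0 - so2)
        return a532, a560


#: Default table used by the phantom renderer and the sO2 estimator.
DEFAULT_EXTINCTION = ExtinctionTable()
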