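"""Image-quality evaluation: PSNR, global SSIM, line-profile SNR, error maps.

PSNR is defined against the reference peak:

    PSNR = 20 log10( max(ref) * sqrt(N) / ||ref - rec||_2 )

which equals the familiar 20 log10(max(ref)/RMSE).  SSIM is the
three-term product of luminance, contrast and structure computed from
GLOBAL image statistics (means, SDs and covariance over the whole
image), not a sliding window; a windowed variant is available through
``windowed=True`` but the global form is canonical here because the
normalized test patches are small and statistically homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "SSIMConstants",
    "MetricsReport",
    "psnr",
    "ssim",
    "line_profile_snr",
    "error_map",
    "summarize_distribution",
    "evaluate_pairs",
    "DegenerateImageError",
]


class DegenerateImageError(ValueError):
    """Raised where a metric is formally infinite (zero error / zero noise)."""


@dataclass(frozen=True)
class SSIMConstants:
    """Regularization constants of the three SSIM terms.

    Defaults follow the usual convention c1 = (0.01 L)^2,
    c2 = (0.03 L)^2, c3 = c2/2 with dynamic range L = 1 (data normalized
    to (0, 1)).
    """

    c1: float = 1e-4
    c2: float = 9e-4
    c3: float = 4.5e-4

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0 or self.c3 < 0:
            raise ValueError("SSIM constants must be non-negative")
        if self.c1 == self.c2 == self.c3 == 0:
            raise ValueError("at least one SSIM constant must be positive")


@dataclass
class MetricsReport:
    """Per-item PSNR/SSIM lists with their distribution summaries."""

    psnr_values: list[float]
    ssim_values: list[float]

    @property
    def n(self) -> int:
        return len(self.psnr_values)

    def summary(self) -> dict:
        out = {"n": self.n}
        for name, vals in (("psnr", self.psnr_values), ("ssim", self.ssim_values)):
            if len(vals) >= 2:
                mean, sd, _ = summarize_distribution(vals)
            else:  # single-item report: mean is the value, spread undefined -> 0
                mean, sd = float(vals[0]), 0.0
            out[f"{name}_mean"] = mean
            out[f"{name}_sd"] = sd
        return out


def _check_pair(ref: np.ndarray, rec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    rec = np.asarray(rec, dtype=float)
    if ref.shape != rec.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {rec.shape}")
    return ref, rec


def psnr(ref: np.ndarray, rec: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, peak taken from the reference."""
    ref, rec = _check_pair(ref, rec)
    peak = ref.max()
    if peak <= 0:
        raise ValueError("reference peak must be positive")
    mse = np.mean((ref - rec) ** 2)
    if mse == 0:
        raise DegenerateImageError("identical images: PSNR is infinite")
    return float(20.0 * np.log10(peak / np.sqrt(mse)))


def ssim(
    ref: np.ndarray,
    rec: np.ndarray,
    consts: SSIMConstants = SSIMConstants(),
    windowed: bool = False,
    window: int = 8,
) -> float:
    """Structural similarity: luminance x contrast x structure.

    With global statistics (default) the three terms are

        l = (2 mu_r mu_c + c1) / (mu_r^2 + mu_c^2 + c1)
        s1 = (2 cov + c2) / (var_r + var_c + c2)
        s2 = (cov + c3) / (sd_r sd_c + c3)

    (cov is the covariance of the two images; variances use the
    population 1/N convention).  ``windowed=True`` averages the same
    product over non-overlapping square tiles instead.
    """
    ref, rec = _check_pair(ref, rec)
    if not windowed:
        return float(_ssim_global(ref, rec, consts))
    h, w = ref.shape
    vals = [
        _ssim_global(ref[i : i + window, j : j + window], rec[i : i + window, j : j + window], consts)
        for i in range(0, h - window + 1, window)
        for j in range(0, w - window + 1, window)
    ]
    if not vals:
        raise ValueError("image smaller than the SSIM window")
    return float(np.mean(vals))


def _ssim_global(ref: np.ndarray, rec: np.ndarray, k: SSIMConstants) -> float:
    mu_r, mu_c = ref.mean(), rec.mean()
    var_r, var_c = ref.var(), rec.var()
    cov = ((ref - mu_r) * (rec - mu_c)).mean()
    sd_r, sd_c = np.sqrt(var_r), np.sqrt(var_c)
    luminance = (2 * mu_r * mu_c + k.c1) / (mu_r**2 + mu_c**2 + k.c1)
    contrast = (2 * cov + k.c2) / (var_r + var_c + k.c2)
    if k.c3 == 0 and sd_r * sd_c == 0:
        structure = 1.0  # zero-variance convention
    else:
        structure = (cov + k.c3) / (sd_r * sd_c + k.c3)
    return luminance * contrast * structure


def line_profile_snr(
    image: np.ndarray,
    line: tuple[tuple[float, float], tuple[float, float]],
    background_region: tuple[int, int, int, int],
    n_samples: int = 200,
) -> float:
    """Peak of the interpolated intensity profile along a line over background SD.

    ``line`` is ((row0, col0), (row1, col1)); ``background_region`` is a
    (row0, row1, col0, col1) half-open box that must not intersect the
    line.
    """
    image = np.asarray(image, dtype=float)
    (r0, c0), (r1, c1) = line
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= image.shape[0] - 1 and 0 <= c <= image.shape[1] - 1):
            raise ValueError("line endpoints must lie inside the image")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = r0 + t * (r1 - r0)
    cols = c0 + t * (c1 - c0)
    profile = map_coordinates(image, np.stack([rows, cols]), order=1, mode="nearest")
    br0, br1, bc0, bc1 = background_region
    background = image[br0:br1, bc0:bc1]
    if background.size < 2:
        raise ValueError("background region is empty or degenerate")
    in_box = (rows >= br0) & (rows < br1) & (cols >= bc0) & (cols < bc1)
    if in_box.any():
        raise ValueError("background region must be disjoint from the line")
    sd = background.std(ddof=1)
    if sd == 0:
        raise DegenerateImageError("zero background SD: SNR is infinite")
    return float(profile.max() / sd)


def error_map(ref: np.ndarray, rec: np.ndarray) -> np.ndarray:
    """Pixelwise absolute residual |ref - rec| (the paper-style residual map)."""
    ref, rec = _check_pair(ref, rec)
    return np.abs(ref - rec)


def summarize_distribution(values, n_bins: int = 20):
    """Mean, sample SD (n-1 denominator) and fixed-width histogram of values."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to summarize")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    counts, edges = np.histogram(values, bins=n_bins)
    return mean, sd, (counts, edges)


def evaluate_pairs(refs, recs, consts: SSIMConstants = SSIMConstants()) -> MetricsReport:
    """PSNR/SSIM over matched (reference, reconstruction) image lists."""
    if len(refs) != len(recs):
        raise ValueError("reference and reconstruction lists must have equal length")
    return MetricsReport(
        psnr_values=[psnr(a, b) for a, b in zip(refs, recs)],
        ssim_values=[ssim(a, b, consts) for a, b in zip(refs, recs)],
    )
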