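"""Forward model of high-speed, low-dosage OR-PAM acquisition.

Raising the scan speed within the laser-safety fluence ceiling means
(a) lowering the per-pulse energy to a fraction ``f`` of the limit —
the photoacoustic amplitude scales with pulse energy while detector
noise does not, so SNR drops proportionally — and (b) firing only at
every ``s``-th scan position along both axes (s-fold undersampling),
which cuts the pulse count by s^2 at the price of spatial resolution.
The total laser dosage delivered therefore falls by ``s^2 / f``.

This module degrades rendered ground-truth scenes accordingly: linear
amplitude scaling by ``f``, additive zero-mean Gaussian detector noise,
clipping back to the normalized [0, 1] range, and per-axis decimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from ._constants import SPEED_OF_LIGHT
from .phantom import PhantomScene

__all__ = [
    "DegradationSpec",
    "AcquisitionPair",
    "apply_energy_scaling",
    "undersample",
    "compute_dosage_reduction",
    "degrade_scene",
    "fiber_delay",
]


@dataclass(frozen=True)
class DegradationSpec:
    """Acquisition degradation parameters.

    energy_fraction : per-pulse energy as a fraction of the safety-limit
        energy, in (0, 1].
    undersample_factor : decimation factor applied to both scan axes.
    noise_sigma : SD of the additive detector noise on the normalized
        amplitude scale.
    seed : RNG seed for the noise fields (the two wavelength channels
        receive decorrelated streams derived from it).
    """

    energy_fraction: float = 0.5
    undersample_factor: int = 2
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.energy_fraction <= 1.0):
            raise ValueError("energy_fraction must lie in (0, 1]")
        if self.undersample_factor not in (1, 2, 4):
            raise ValueError("undersample_factor must be one of {1, 2, 4}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class AcquisitionPair:
    """Degraded dual-wavelength input images plus how they were made."""

    input1: np.ndarray  # 532 nm channel
    input2: np.ndarray  # 560 nm channel
    spec: DegradationSpec
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.input1.shape != self.input2.shape:
            raise ValueError("the two channels must have identical shape")


def apply_energy_scaling(
    image: np.ndarray, f: float, noise_sigma: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Scale amplitudes by the pulse-energy fraction and add detector noise.

    Returns ``clip(f * image + N(0, noise_sigma), 0, 1)``; deterministic
    per seed.  Noise is energy-independent (detector-dominated), so the
    image SNR scales proportionally to ``f``.
    """
    if not (0.0 < f <= 1.0):
        raise ValueError("energy fraction f must lie in (0, 1]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    image = np.asarray(image, dtype=float)
    out = f * image
    if noise_sigma > 0:
        out = out + np.random.default_rng(seed).normal(0.0, noise_sigma, size=image.shape)
    return np.clip(out, 0.0, 1.0)


def undersample(image: np.ndarray, s: int) -> np.ndarray:
    """Keep every s-th row and column (pure decimation, no interpolation)."""
    s = int(s)
    if s < 1:
        raise ValueError("undersampling factor must be >= 1")
    image = np.asarray(image)
    if s > image.shape[0] or s > image.shape[1]:
        raise ValueError("undersampling factor exceeds image dimensions")
    return image[::s, ::s]


def compute_dosage_reduction(f, s: int):
    """Total laser-dosage reduction factor s^2 / f.

    Undersampling by ``s`` per axis cuts the pulse count s^2-fold and
    each remaining pulse carries a fraction ``f`` of the limit energy.
    Arithmetic is exact: the result is an ``int`` when whole, otherwise a
    ``Fraction`` (floats are first snapped to their nearest simple ratio).
    """
    if isinstance(f, Fraction):
        fr = f
    else:
        fr = Fraction(f).limit_denominator(10**6)
    if fr <= 0 or fr > 1:
        raise ValueError("energy fraction f must lie in (0, 1]")
    if int(s) < 1:
        raise ValueError("undersampling factor must be >= 1")
    result = Fraction(int(s) ** 2, 1) / fr
    return int(result) if result.denominator == 1 else result


def degrade_scene(scene: PhantomScene, spec: DegradationSpec) -> AcquisitionPair:
    """Degrade both ground-truth channels into a low-dosage acquisition pair.

    The two channels get decorrelated noise streams (independent child
    seeds spawned from ``spec.seed``).
    """
    child1, child2 = np.random.SeedSequence(spec.seed).generate_state(2, dtype=np.uint32)
    out1 = undersample(
        apply_energy_scaling(scene.gt532, spec.energy_fraction, spec.noise_sigma, int(child1)),
        spec.undersample_factor,
    )
    out2 = undersample(
        apply_energy_scaling(scene.gt560, spec.energy_fraction, spec.noise_sigma, int(child2)),
        spec.undersample_factor,
    )
    return AcquisitionPair(input1=out1, input2=out2, spec=spec)


def fiber_delay(length_m: float, group_index: float = 1.5) -> float:
    """Propagation delay [s] of a delay fiber: length x group index / c.

    A ~150 m multimode fiber with group index 1.5 delays its pulse by
    about 750 ns, which is how high- and low-energy pulse pairs are
    separated at the detector in a delay-line dual-dosage acquisition.
    """
    if length_m < 0 or group_index < 1.0:
        raise ValueError("length must be non-negative and group index >= 1")
    return length_m * group_index / SPEED_OF_LIGHT
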