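"""Synthetic dual-wavelength vascular phantoms.

OR-PAM maximum-amplitude-projection images of mouse brain or ear show
bright curvilinear vessels of many calibers on a dark background, with
the two excitation wavelengths (532 nm, 560 nm) giving slightly
different per-vessel contrast depending on hemoglobin oxygenation.  The
generator emulates exactly that: a random piecewise-linear branching
vessel tree is rasterized with an anti-aliased disk brush, given a
per-segment oxygen saturation, converted to two absorption images
through an extinction table, blurred by the system point-spread
function, and normalized.

The two channels are normalized JOINTLY (one min/max over both), so the
per-pixel spectral ratio — and therefore the ground-truth sO2 — survives
normalization exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ._constants import DEFAULT_EXTINCTION, ExtinctionTable

__all__ = [
    "Segment",
    "VesselTree",
    "PhantomScene",
    "generate_vessel_tree",
    "rasterize_scene",
    "split_scenes",
    "generate_scenes",
]

#: FWHM -> Gaussian sigma conversion factor, 2*sqrt(2 ln 2).
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class Segment:
    """One straight vessel segment: endpoints in (row, col) pixel coordinates."""

    start: tuple[float, float]
    end: tuple[float, float]
    radius: float
    so2: float
    depth: int


@dataclass(frozen=True)
class VesselTree:
    segments: list[Segment]
    field_size: tuple[int, int]

    def __post_init__(self) -> None:
        rows, cols = self.field_size
        if rows < 16 or cols < 16:
            raise ValueError("field_size must be at least 16x16 pixels")
        for seg in self.segments:
            if seg.radius <= 0:
                raise ValueError("segment radii must be positive")
            if not (0.0 <= seg.so2 <= 1.0):
                raise ValueError("segment so2 must lie in [0, 1]")
            for pt in (seg.start, seg.end):
                if not (0 <= pt[0] <= rows - 1 and 0 <= pt[1] <= cols - 1):
                    raise ValueError("segment endpoints must lie inside the field")


@dataclass
class PhantomScene:
    """Rendered two-channel ground truth plus the generating geometry.

    ``gt532``/``gt560`` play the roles of the full-sampling,
    full-pulse-energy ground-truth channels; ``so2_true`` is defined on
    vessel pixels (NaN elsewhere); ``vessel_mask`` is the unblurred
    vessel support.
    """

    tree: VesselTree
    gt532: np.ndarray
    gt560: np.ndarray
    so2_true: np.ndarray
    vessel_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.gt532.shape != self.gt560.shape:
            raise ValueError("channel images must share one shape")


def _clip_point(p: np.ndarray, rows: int, cols: int) -> np.ndarray:
    return np.minimum(np.maximum(p, 0.0), [rows - 1.0, cols - 1.0])


def generate_vessel_tree(
    seed: int,
    n_roots: int = 3,
    max_depth: int = 4,
    field_size: tuple[int, int] = (128, 128),
    branch_prob: float = 0.7,
    radius_range: tuple[float, float] = (1.5, 4.0),
) -> VesselTree:
    """Grow a random branching vessel tree, deterministic per seed.

    Each root starts on the field border heading inward.  Every segment
    spawns 0-2 children: two independent Bernoulli(branch_prob) trials,
    each child turning by a random angle of 15-50 degrees (random sign),
    with radius = parent x U(0.6, 0.9) and length = parent x U(0.7, 1.0),
    down to ``max_depth`` levels.  Oxygen saturation is drawn per root
    (arterial-or-venous mixture) and jittered slightly along branches.

    The draw order per segment is fixed and documented so the recursion
    can be independently replayed: [branch child A?, branch child B?]
    then, per spawned child: [turn angle, turn sign, radius factor,
    length factor, so2 jitter].
    """
    if n_roots < 0 or max_depth < 0:
        raise ValueError("n_roots and max_depth must be non-negative")
    rows, cols = int(field_size[0]), int(field_size[1])
    if rows < 16 or cols < 16:
        raise ValueError("field_size must be at least 16x16 pixels")
    if not (0.0 <= branch_prob <= 1.0):
        raise ValueError("branch_prob must be a probability")
    if radius_range[0] <= 0 or radius_range[1] < radius_range[0]:
        raise ValueError("radius_range must be positive and ordered")

    rng = np.random.default_rng(seed)
    segments: list[Segment] = []

    def grow(start: np.ndarray, angle: float, radius: float, length: float, so2: float, depth: int) -> None:
        end = start + length * np.array([math.sin(angle), math.cos(angle)])
        end = _clip_point(end, rows, cols)
        segments.append(Segment(tuple(start), tuple(end), radius, so2, depth))
        if depth >= max_depth:
            return
        spawn = [rng.random() < branch_prob, rng.random() < branch_prob]
        for do_spawn in spawn:
            if not do_spawn:
                continue
            turn = math.radians(rng.uniform(15.0, 50.0))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            child_radius = radius * rng.uniform(0.6, 0.9)
            child_length = length * rng.uniform(0.7, 1.0)
            child_so2 = float(np.clip(so2 + rng.normal(0.0, 0.02), 0.0, 1.0))
            grow(end, angle + sign * turn, child_radius, child_length, child_so2, depth + 1)

    for _ in range(n_roots):
        side = rng.integers(0, 4)  # 0 top, 1 bottom, 2 left, 3 right
        t = rng.uniform(0.1, 0.9)
        if side == 0:
            start, base_angle = np.array([0.0, t * (cols - 1)]), math.pi / 2
        elif side == 1:
            start, base_angle = np.array([rows - 1.0, t * (cols - 1)]), -math.pi / 2
        elif side == 2:
            start, base_angle = np.array([t * (rows - 1), 0.0]), 0.0
        else:
            start, base_angle = np.array([t * (rows - 1), cols - 1.0]), math.pi
        angle = base_angle + rng.uniform(-0.5, 0.5)
        radius = rng.uniform(*radius_range)
        length = rng.uniform(0.25, 0.45) * min(rows, cols)
        so2 = rng.uniform(0.85, 0.98) if rng.random() < 0.5 else rng.uniform(0.55, 0.75)
        grow(start, angle, radius, length, so2, 0)

    return VesselTree(segments=segments, field_size=(rows, cols))


def _segment_distance_field(seg: Segment, rows: int, cols: int):
    """Distance from each pixel in a bounding box to the segment (capsule metric)."""
    a = np.asarray(seg.start, dtype=float)
    b = np.asarray(seg.end, dtype=float)
    pad = seg.radius + 2.0
    r0 = max(int(math.floor(min(a[0], b[0]) - pad)), 0)
    r1 = min(int(math.ceil(max(a[0], b[0]) + pad)), rows - 1)
    c0 = max(int(math.floor(min(a[1], b[1]) - pad)), 0)
    c1 = min(int(math.ceil(max(a[1], b[1]) + pad)), cols - 1)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    p = np.stack([rr, cc], axis=-1).astype(float)
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        t = np.zeros(p.shape[:2])
    else:
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    dist = np.linalg.norm(p - closest, axis=-1)
    return (slice(r0, r1 + 1), slice(c0, c1 + 1)), dist


def rasterize_scene(
    tree: VesselTree,
    psf_fwhm: float = 2.5,
    extinction: ExtinctionTable = DEFAULT_EXTINCTION,
    background_level: float = 0.02,
) -> PhantomScene:
    """Render a tree into the two wavelength channels.

    Per pixel the pre-blur absorption at wavelength L is
    ``coverage * (eps_HbO2(L) * so2 + eps_Hb(L) * (1 - so2))`` where
    ``coverage`` is the anti-aliased disk-brush vessel amplitude; each
    channel is blurred by an isotropic Gaussian of the given FWHM, the
    background level is added, and both channels are jointly min-max
    normalized to [0, 1].  A constant scene normalizes to all-zero.
    """
    if psf_fwhm <= 0:
        raise ValueError("psf_fwhm must be positive")
    rows, cols = tree.field_size
    coverage = np.zeros((rows, cols))
    so2 = np.zeros((rows, cols))
    best_dist = np.full((rows, cols), np.inf)
    mask = np.zeros((rows, cols), dtype=bool)

    for seg in tree.segments:
        box, dist = _segment_distance_field(seg, rows, cols)
        amp = np.clip(seg.radius + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
        coverage[box] = np.maximum(coverage[box], amp)
        inside = dist <= seg.radius
        mask[box] |= inside
        closer = dist < best_dist[box]
        take = closer & (amp > 0)
        so2_box = so2[box]
        so2_box[take] = seg.so2
        so2[box] = so2_box
        best_dist[box] = np.where(closer, dist, best_dist[box])

    a532, a560 = extinction.absorption(so2)
    ref = max(extinction.hbo2_532, extinction.hb_532, extinction.hbo2_560, extinction.hb_560)
    sigma = psf_fwhm / _FWHM_TO_SIGMA
    ch532 = gaussian_filter(coverage * a532 / ref, sigma) + background_level
    ch560 = gaussian_filter(coverage * a560 / ref, sigma) + background_level

    lo = min(ch532.min(), ch560.min())
    hi = max(ch532.max(), ch560.max())
    if hi - lo < 1e-12:  # constant scene: define normalization as all-zero
        gt532 = np.zeros_like(ch532)
        gt560 = np.zeros_like(ch560)
    else:
        gt532 = (ch532 - lo) / (hi - lo)
        gt560 = (ch560 - lo) / (hi - lo)

    so2_true = np.where(mask, so2, np.nan)
    return PhantomScene(tree=tree, gt532=gt532, gt560=gt560, so2_true=so2_true, vessel_mask=mask)


def generate_scenes(
    n_scenes: int,
    seed: int,
    field_size: tuple[int, int] = (128, 128),
    **tree_kwargs,
) -> list[PhantomScene]:
    """Convenience: independent scenes from one master seed."""
    children = np.random.SeedSequence(seed).generate_state(n_scenes, dtype=np.uint32)
    return [
        rasterize_scene(generate_vessel_tree(int(s), field_size=field_size, **tree_kwargs))
        for s in children
    ]


def split_scenes(scenes, train_fraction: float, seed: int):
    """Disjoint, exhaustive train/test partition, deterministic per seed."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if len(scenes) < 2:
        raise ValueError("need at least two scenes to split")
    order = np.random.default_rng(seed).permutation(len(scenes))
    n_train = int(round(train_fraction * len(scenes)))
    n_train = min(max(n_train, 1), len(scenes) - 1)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return [scenes[i] for i in train_idx], [scenes[i] for i in test_idx]
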