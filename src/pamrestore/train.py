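"""Patch bookkeeping, the training loop, and full-image reconstruction.

Images are cut into square low-resolution patches (row-major tiling,
with the last tile along each axis shifted inward so coverage is
complete even when the patch size does not divide the image), batched
through the three-subnetwork model, and the outputs are stitched back —
averaging wherever shifted or strided tiles overlap — into the three
full-resolution reconstructions Recon 1/2/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from . import nn
from .degrade import AcquisitionPair
from .mtrdn import MTRDN

__all__ = [
    "PatchSet",
    "TrainState",
    "extract_patches",
    "stitch_patches",
    "build_patch_set",
    "train_model",
    "reconstruct",
    "save_patch_set",
    "load_patch_set",
]


def _tile_starts(size: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, size - patch + 1, stride))
    if starts[-1] + patch < size:  # shift the last tile inward for full coverage
        starts.append(size - patch)
    return starts


def extract_patches(image: np.ndarray, patch: int, stride: int | None = None):
    """Cut a 2-D image into square tiles; returns (patches, origins).

    ``origins`` are (row, col) pixel coordinates of each tile's top-left
    corner, row-major.  ``stride`` defaults to ``patch`` (no overlap).
    """
    image = np.asarray(image)
    patch = int(patch)
    stride = patch if stride is None else int(stride)
    if patch > image.shape[0] or patch > image.shape[1]:
        raise ValueError("patch size exceeds image dimensions")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    origins = [
        (r, c)
        for r in _tile_starts(image.shape[0], patch, stride)
        for c in _tile_starts(image.shape[1], patch, stride)
    ]
    patches = np.stack([image[r : r + patch, c : c + patch] for r, c in origins])
    return patches, origins


def stitch_patches(patches, origins, out_shape: tuple[int, int], scale: int = 1) -> np.ndarray:
    """Place (possibly overlapping) patches back into one image.

    Origins are low-resolution coordinates; each patch lands at
    ``origin * scale`` in the output.  Overlapping pixels are averaged;
    any uncovered output pixel is a consistency error.
    """
    patches = np.asarray(patches, dtype=float)
    out = np.zeros(out_shape)
    weight = np.zeros(out_shape)
    for p, (r, c) in zip(patches, origins):
        r, c = r * scale, c * scale
        h, w = p.shape
        if r + h > out_shape[0] or c + w > out_shape[1]:
            raise ValueError("patch origins inconsistent with output shape")
        out[r : r + h, c : c + w] += p
        weight[r : r + h, c : c + w] += 1.0
    if (weight == 0).any():
        raise ValueError("stitching leaves uncovered output pixels")
    return out / weight


@dataclass
class PatchSet:
    """Aligned training patches for the five image roles.

    Low-resolution inputs for the two wavelength channels and the three
    full-resolution supervision targets, paired by identical tile
    origins.
    """

    input1: np.ndarray  # (N, p, p)
    input2: np.ndarray
    gt1: np.ndarray  # (N, p*scale, p*scale)
    gt2: np.ndarray
    gt3: np.ndarray
    patch_size_lr: int
    scale: int
    origins: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.input1)
        if not (len(self.input2) == len(self.gt1) == len(self.gt2) == len(self.gt3) == n):
            raise ValueError("all five patch arrays must have equal length")
        hr = self.patch_size_lr * self.scale
        if self.gt1.shape[1:] != (hr, hr):
            raise ValueError("full-resolution patch size must be patch_size_lr * scale")

    def __len__(self) -> int:
        return len(self.input1)


def build_patch_set(
    pairs: list[AcquisitionPair],
    gt_triples: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    patch: int,
    stride: int | None = None,
) -> PatchSet:
    """Tile matched (acquisition, ground-truth-triple) scenes into one PatchSet."""
    if len(pairs) != len(gt_triples):
        raise ValueError("one ground-truth triple is required per acquisition pair")
    if not pairs:
        raise ValueError("need at least one scene")
    scale = pairs[0].spec.undersample_factor
    stride = patch if stride is None else stride
    rows: dict[str, list[np.ndarray]] = {k: [] for k in ("i1", "i2", "g1", "g2", "g3")}
    origins: list[tuple[int, int]] = []
    for pair, (g1, g2, g3) in zip(pairs, gt_triples):
        p1, orig = extract_patches(pair.input1, patch, stride)
        p2, _ = extract_patches(pair.input2, patch, stride)
        rows["i1"].append(p1)
        rows["i2"].append(p2)
        for key, img in (("g1", g1), ("g2", g2), ("g3", g3)):
            hp = np.stack(
                [
                    np.asarray(img)[r * scale : (r + patch) * scale, c * scale : (c + patch) * scale]
                    for r, c in orig
                ]
            )
            rows[key].append(hp)
        origins.extend(orig)
    return PatchSet(
        input1=np.concatenate(rows["i1"]),
        input2=np.concatenate(rows["i2"]),
        gt1=np.concatenate(rows["g1"]),
        gt2=np.concatenate(rows["g2"]),
        gt3=np.concatenate(rows["g3"]),
        patch_size_lr=patch,
        scale=scale,
        origins=origins,
    )


@dataclass
class TrainState:
    """Final model plus the full optimization trace."""

    model: MTRDN
    step: int
    loss_history: list[tuple[int, float]]
    lr: float
    batch: int
    seed: int


class TrainingDivergedError(RuntimeError):
    def __init__(self, step: int, loss: float):
        super().__init__(f"non-finite loss {loss} at step {step}")
        self.step = step


def train_model(
    patches: PatchSet,
    model: MTRDN,
    steps: int = 500,
    lr: float = 1e-3,
    batch: int = 4,
    seed: int = 0,
    callback=None,
) -> TrainState:
    """Minimize the weighted multisupervised loss with Adam over mini-batches.

    Patches are shuffled each epoch with a dedicated RNG, so the run is
    a pure function of (patches, initial model, steps, lr, batch, seed)
    on a fixed platform.
    """
    if len(patches) == 0:
        raise ValueError("empty patch set")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    history: list[tuple[int, float]] = []
    order = rng.permutation(len(patches))
    cursor = 0
    for step in range(1, steps + 1):
        if cursor + batch > len(order):
            order = rng.permutation(len(patches))
            cursor = 0
        idx = order[cursor : cursor + batch]
        cursor += batch
        t1 = nn.Tensor(patches.input1[idx][..., None].astype(np.float32))
        t2 = nn.Tensor(patches.input2[idx][..., None].astype(np.float32))
        outputs = model.forward_tensors(t1, t2)
        gts = (
            patches.gt1[idx][..., None].astype(np.float32),
            patches.gt2[idx][..., None].astype(np.float32),
            patches.gt3[idx][..., None].astype(np.float32),
        )
        loss = model.loss_tensor(outputs, gts)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise TrainingDivergedError(step, loss_val)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append((step, loss_val))
        if callback is not None:
            callback(step, loss_val)
    return TrainState(model=model, step=steps, loss_history=history, lr=lr, batch=batch, seed=seed)


def reconstruct(
    model: MTRDN,
    input1: np.ndarray,
    input2: np.ndarray,
    patch: int | None = None,
    stride: int | None = None,
    batch: int = 8,
):
    """Patch-wise forward pass and stitch: returns (recon1, recon2, recon3).

    ``patch=None`` feeds each whole image as a single tile.  Outputs are
    ``scale`` times the input size along each axis.
    """
    input1 = np.asarray(input1, dtype=float)
    input2 = np.asarray(input2, dtype=float)
    if input1.shape != input2.shape:
        raise ValueError("the two channels must have identical shape")
    scale = model.scale
    if patch is None:
        patch = min(input1.shape)
    p1, origins = extract_patches(input1, patch, stride)
    p2, _ = extract_patches(input2, patch, stride)
    outs: list[list[np.ndarray]] = [[], [], []]
    for i in range(0, len(p1), batch):
        t1 = nn.Tensor(p1[i : i + batch][..., None].astype(np.float32))
        t2 = nn.Tensor(p2[i : i + batch][..., None].astype(np.float32))
        o1, o2, o3 = model.forward_tensors(t1, t2)
        for sink, o in zip(outs, (o1, o2, o3)):
            sink.extend(o.data[..., 0].astype(float))
    out_shape = (input1.shape[0] * scale, input1.shape[1] * scale)
    return tuple(stitch_patches(np.stack(sink), origins, out_shape, scale) for sink in outs)


def save_patch_set(patches: PatchSet, path) -> None:
    """Cache a PatchSet to HDF5."""
    with h5py.File(path, "w") as fh:
        for name in ("input1", "input2", "gt1", "gt2", "gt3"):
            fh.create_dataset(name, data=getattr(patches, name))
        fh.create_dataset("origins", data=np.asarray(patches.origins, dtype=np.int64))
        fh.attrs["patch_size_lr"] = patches.patch_size_lr
        fh.attrs["scale"] = patches.scale


def load_patch_set(path) -> PatchSet:
    with h5py.File(path, "r") as fh:
        return PatchSet(
            input1=fh["input1"][:],
            input2=fh["input2"][:],
            gt1=fh["gt1"][:],
            gt2=fh["gt2"][:],
            gt3=fh["gt3"][:],
            patch_size_lr=int(fh.attrs["patch_size_lr"]),
            scale=int(fh.attrs["scale"]),
            origins=[tuple(int(v) for v in row) for row in fh["origins"][:]],
        )
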