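"""TIFF and sidecar-JSON interchange for scenes and reconstructions."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .phantom import PhantomScene, VesselTree, Segment

__all__ = ["write_scene", "read_scene", "write_image", "read_image", "write_sidecar", "read_sidecar"]

_SCENE_PAGES = ("gt532", "gt560", "so2_true", "vessel_mask")


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32), photometric="minisblack")


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_sidecar(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


def write_scene(path, scene: PhantomScene, params: dict | None = None) -> None:
    """Multi-page TIFF (gt532, gt560, so2_true, vessel_mask) + JSON sidecar."""
    pages = np.stack(
        [
            scene.gt532,
            scene.gt560,
            np.nan_to_num(scene.so2_true, nan=-1.0),
            scene.vessel_mask.astype(float),
        ]
    ).astype(np.float32)
    tifffile.imwrite(str(path), pages, photometric="minisblack")
    sidecar = {
        "pages": list(_SCENE_PAGES),
        "field_size": list(scene.tree.field_size),
        "segments": [
            {
                "start": [float(v) for v in seg.start],
                "end": [float(v) for v in seg.end],
                "radius": float(seg.radius),
                "so2": float(seg.so2),
                "depth": int(seg.depth),
            }
            for seg in scene.tree.segments
        ],
    }
    if params:
        sidecar["params"] = params
    write_sidecar(Path(path).with_suffix(".json"), sidecar)


def read_scene(path) -> PhantomScene:
    pages = tifffile.imread(str(path)).astype(float)
    meta = read_sidecar(Path(path).with_suffix(".json"))
    so2_true = pages[2].copy()
    so2_true[so2_true < 0] = np.nan
    tree = VesselTree(
        segments=[
            Segment(
                start=tuple(s["start"]),
                end=tuple(s["end"]),
                radius=s["radius"],
                so2=s["so2"],
                depth=s["depth"],
            )
            for s in meta["segments"]
        ],
        field_size=tuple(meta["field_size"]),
    )
    return PhantomScene(
        tree=tree,
        gt532=pages[0],
        gt560=pages[1],
        so2_true=so2_true,
        vessel_mask=pages[3] > 0.5,
    )
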