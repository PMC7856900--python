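"""End-to-end orchestration: simulate -> degrade -> enhance -> train ->
reconstruct -> evaluate -> sO2, with a reproducibility manifest.

Every stage writes its artifacts under the run directory; the manifest
records seeds, parameters, SHA-256 hashes of every written file, and
the metric summaries, which is sufficient to re-run the pipeline
bit-identically on the same platform.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .degrade import DegradationSpec, compute_dosage_reduction, degrade_scene
from .estimators import MTRDNRestorer
from .metrics import evaluate_pairs
from .mtrdn import save_checkpoint
from .phantom import generate_scenes, split_scenes
from .so2 import apply_mask, unmix_so2
from .vesselness import VesselnessParams, make_ground_truth3

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """One YAML-serializable configuration for the whole pipeline."""

    out_dir: str = "run"
    seed: int = 0
    n_scenes: int = 8
    field_size: tuple[int, int] = (64, 64)
    train_fraction: float = 0.8
    energy_fraction: float = 0.5
    undersample_factor: int = 2
    noise_sigma: float = 0.05
    vessel_scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    vessel_beta: float = 0.5
    n_blocks: int = 4
    convs_per_block: int = 4
    growth: int = 16
    base_channels: int = 32
    loss_weights: tuple[float, float, float] = (0.25, 0.25, 0.5)
    patch: int = 16
    steps: int = 100
    lr: float = 1e-3
    batch: int = 4
    so2_threshold: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("field_size", "vessel_scales", "loss_weights"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, log=None) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}

    def emit(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        if log is not None:
            log(json.dumps({"stage": stage, **{k: v for k, v in info.items() if np.isscalar(v)}}))

    def record(path: Path) -> str:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)
        return str(path)

    try:
        # 1. simulate
        scenes = generate_scenes(config.n_scenes, config.seed, field_size=config.field_size)
        for i, scene in enumerate(scenes):
            pio.write_scene(out / f"scene_{i:03d}.tif", scene, params={"seed": config.seed})
            record(out / f"scene_{i:03d}.tif")
            record(out / f"scene_{i:03d}.json")
        emit("simulate", n_scenes=len(scenes))

        # 2. degrade
        pairs = []
        for i, scene in enumerate(scenes):
            spec = DegradationSpec(
                energy_fraction=config.energy_fraction,
                undersample_factor=config.undersample_factor,
                noise_sigma=config.noise_sigma,
                seed=config.seed * 10007 + i,
            )
            pair = degrade_scene(scene, spec)
            pairs.append(pair)
            pio.write_image(out / f"input1_{i:03d}.tif", pair.input1)
            pio.write_image(out / f"input2_{i:03d}.tif", pair.input2)
            record(out / f"input1_{i:03d}.tif")
            record(out / f"input2_{i:03d}.tif")
        emit(
            "degrade",
            dosage_reduction=compute_dosage_reduction(
                config.energy_fraction, config.undersample_factor
            ),
        )

        # 3. enhancement target
        vparams = VesselnessParams(scales=tuple(config.vessel_scales), beta=config.vessel_beta)
        gt3s = [make_ground_truth3(s.gt532, vparams) for s in scenes]
        for i, g in enumerate(gt3s):
            pio.write_image(out / f"gt3_{i:03d}.tif", g)
            record(out / f"gt3_{i:03d}.tif")
        emit("enhance", n_images=len(gt3s))

        # 4. train
        idx = list(range(len(scenes)))
        train_idx, test_idx = split_scenes(idx, config.train_fraction, config.seed)
        restorer = MTRDNRestorer(
            scale=config.undersample_factor,
            n_blocks=config.n_blocks,
            convs_per_block=config.convs_per_block,
            growth=config.growth,
            base_channels=config.base_channels,
            loss_weights=tuple(config.loss_weights),
            patch=config.patch,
            steps=config.steps,
            lr=config.lr,
            batch=config.batch,
            seed=config.seed,
        )
        restorer.fit(
            [pairs[i] for i in train_idx],
            [(scenes[i].gt532, scenes[i].gt560, gt3s[i]) for i in train_idx],
        )
        if log is not None:  # line-delimited JSON loss trace, thinned
            thin = max(1, config.steps // 20)
            for step, loss in restorer.loss_history_[::thin]:
                log(json.dumps({"step": step, "loss": loss}))
        save_checkpoint(restorer.model_, out / "model.npz")
        record(out / "model.npz")
        emit(
            "train",
            steps=config.steps,
            final_loss=restorer.loss_history_[-1][1],
            n_parameters=restorer.n_parameters_,
        )

        # 5. reconstruct held-out scenes
        recons = restorer.predict([pairs[i] for i in test_idx])
        for j, (i, triple) in enumerate(zip(test_idx, recons)):
            for k, img in enumerate(triple, start=1):
                pio.write_image(out / f"recon{k}_{i:03d}.tif", img)
                record(out / f"recon{k}_{i:03d}.tif")
        emit("reconstruct", n_scenes=len(test_idx))

        # 6. evaluate
        metric_block = {}
        refs = {
            "recon1": [scenes[i].gt532 for i in test_idx],
            "recon2": [scenes[i].gt560 for i in test_idx],
            "recon3": [gt3s[i] for i in test_idx],
        }
        for k, name in enumerate(("recon1", "recon2", "recon3")):
            report = evaluate_pairs(refs[name], [triple[k] for triple in recons])
            metric_block[name] = report.summary()
        (out / "metrics.json").write_text(json.dumps(metric_block, indent=2))
        record(out / "metrics.json")
        emit("evaluate", **{f"{k}_psnr": v["psnr_mean"] for k, v in metric_block.items()})
        manifest["metrics"] = metric_block

        # 7. sO2
        i = test_idx[0]
        recon1, recon2, recon3 = recons[0]
        so2 = unmix_so2(recon1, recon2)
        so2_map = apply_mask(so2, recon3, config.so2_threshold)
        pio.write_image(out / "so2.tif", so2_map.so2)
        record(out / "so2.tif")
        emit("so2", defined_fraction=float(so2_map.mask.mean()))
    except Exception as exc:
        stage = len(manifest["stages"])
        manifest["error"] = {"after_stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
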