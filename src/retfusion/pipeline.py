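"""End-to-end study orchestration at configurable scale.

simulate -> preprocess -> train (both directions) -> select best
checkpoints by FID -> translate the test set -> evaluate, with one global
seed propagated to every stage and every stage reading only the previous
stage's declared outputs so any stage can be re-run in isolation.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import phantom, preprocess, selection, metrics
from .errors import ParameterError
from .image import RasterImage
from .translator import CheckpointSet, Pix2PixModel, TrainConfig, translate

log = logging.getLogger("retfusion")


@dataclasses.dataclass
class RunConfig:
    """One study: phantom, preprocessing, training, selection, metrics.

    The default profile is the desk-scale tiny run; ``paper_scale()``
    encodes the full-scale schedule (512 px, 200 epochs, interval 10,
    lambda 100).
    """

    seed: int = 0
    n_pairs: int = 40
    n_test: int = 10
    canvas_size: int = 128
    image_size: int = 32
    epochs: int = 4
    checkpoint_interval_epochs: int = 2
    lambda_l1: float = 100.0
    base_channels: int = 16
    disc_channels: int = 16
    magnification_scale: float = 1.0
    saturation_threshold: int = 30
    directions: tuple = ("fa_to_oct", "oct_to_fa")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "RunConfig":
        return cls(seed=seed, n_pairs=1195, n_test=110, canvas_size=1024,
                   image_size=512, epochs=200, checkpoint_interval_epochs=10,
                   base_channels=64, disc_channels=64)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "directions" in data:
            data["directions"] = tuple(data["directions"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["directions"] = list(data["directions"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def train_config(self, direction: str) -> TrainConfig:
        return TrainConfig(
            image_size=self.image_size, epochs=self.epochs,
            checkpoint_interval_epochs=self.checkpoint_interval_epochs,
            lambda_l1=self.lambda_l1, seed=self.seed, direction=direction,
            base_channels=self.base_channels, disc_channels=self.disc_channels)


def _stage(name, out_root):
    """Context helper logging config hash, wall time and counts per stage."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.time() - self.t0
            if exc_type is not None:
                log.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
            else:
                log.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Ctx()


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(dataclasses.asdict(cfg), sort_keys=True,
                                     default=str).encode()).hexdigest()[:12]


def simulate_stage(cfg: RunConfig, out: Path):
    pairs = phantom.generate_dataset(cfg.n_pairs, seed=cfg.seed,
                                     canvas_size=cfg.canvas_size)
    (out / "phantoms").mkdir(parents=True, exist_ok=True)
    phantom.write_dataset(pairs, out / "phantoms", fmt="png")
    return pairs


def preprocess_stage(cfg: RunConfig, pairs, out: Path):
    import pandas as pd

    pp_cfg = preprocess.PreprocessConfig(
        canvas_side=cfg.image_size,
        saturation_threshold=cfg.saturation_threshold,
        magnification_scale=cfg.magnification_scale)
    records = [(p.fa_report, p.oct_report, p.laterality, p.grade_label,
                f"{i:04d}") for i, p in enumerate(pairs)]
    samples, rows, manual = preprocess.preprocess_dataset(records, pp_cfg)
    train_set, test_set = preprocess.split_dataset(samples, cfg.n_test,
                                                   seed=cfg.seed)
    test_ids = {s.source_id for s in test_set}
    for row in rows:
        row["split"] = ("manual" if row["qc_status"].startswith("manual")
                        else "test" if row["id"] in test_ids else "train")
    pre_dir = out / "preprocessed"
    pre_dir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        s.composite.save(pre_dir / f"{s.source_id}.png")
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    log.info("preprocessed %d samples (%d manual)", len(samples), len(manual))
    return train_set, test_set


def train_stage(cfg: RunConfig, train_set, out: Path, direction: str):
    model = Pix2PixModel(train_set, cfg.train_config(direction))
    results = model.fit()
    ck_dir = out / "checkpoints"
    results.checkpoints.save(ck_dir)
    results.history.to_csv(ck_dir / f"history_{direction}.csv", index=False)
    return results


def select_stage(cfg: RunConfig, results, test_set, out: Path, direction: str):
    if direction == "fa_to_oct":
        sources = [s.fa_crop for s in test_set]
        targets = [s.oct_crop for s in test_set]
    else:
        sources = [s.oct_crop for s in test_set]
        targets = [s.fa_crop for s in test_set]
    curve = results.select_best(sources, targets)
    sel_dir = out / "selection"
    sel_dir.mkdir(parents=True, exist_ok=True)
    curve.to_frame().to_csv(sel_dir / f"curve_{direction}.csv", index=False)
    return curve, sources, targets


def translate_stage(results, sources, targets, out: Path, direction: str):
    tr_dir = out / "translations" / direction
    tr_dir.mkdir(parents=True, exist_ok=True)
    from .image import as_pixels

    synth = []
    for i, (src, tgt) in enumerate(zip(sources, targets)):
        s = results.translate(src)
        synth.append(s)
        panel = np.concatenate(
            [RasterImage.from_array(as_pixels(src)).to_rgb().pixels,
             RasterImage.from_array(as_pixels(tgt)).to_rgb().pixels,
             s.pixels], axis=1)
        RasterImage.from_array(panel).save(tr_dir / f"{i:04d}_panel.png")
    return synth


def evaluate_stage(targets, synth, out: Path, direction: str):
    rep_dir = out / "report"
    rep_dir.mkdir(parents=True, exist_ok=True)
    report = metrics.evaluate_pairs(list(zip(targets, synth)))
    report.to_csv(rep_dir / f"metrics_{direction}.csv")
    maps_dir = rep_dir / f"maps_{direction}"
    maps_dir.mkdir(exist_ok=True)
    for i, (t, s) in enumerate(list(zip(targets, synth))[:8]):
        _, dmap = metrics.feature_distance(t, s)
        metrics.distance_map_image(dmap).save(maps_dir / f"{i:04d}_dmap.png")
    return report


def virtual_fa_stage(cfg: RunConfig, results, out: Path):
    """Translate the three diagrammatic virtual-FA drawings (FA -> OCT)."""
    v_dir = out / "virtual"
    v_dir.mkdir(parents=True, exist_ok=True)
    scale = phantom.ThicknessColorScale()
    decoded = {}
    for mode in ("dots", "focal", "diffuse"):
        # rings confined to the region the fovea-centered crop keeps, so
        # the diagram matches the training-crop geometry
        diagram = phantom.generate_virtual_fa(
            mode, canvas_size=cfg.canvas_size,
            outer_radius=0.85 * (cfg.canvas_size // 8))
        crop = preprocess.crop_fovea_centered(
            diagram, (cfg.canvas_size / 2, cfg.canvas_size / 2),
            2 * (cfg.canvas_size // 8))
        crop = preprocess.finalize_crop(crop, cfg.image_size)
        synth = results.translate(crop)
        synth.save(v_dir / f"virtual_{mode}.png")
        decoded[mode] = float(scale.decode(synth.pixels).mean())
    (v_dir / "decoded_thickness_um.json").write_text(json.dumps(decoded, indent=2))
    return decoded


def run_study(cfg: RunConfig, out_dir, stages=None) -> Path:
    """Run the full study; ``stages`` restricts to a subset (resume mode).

    Emits phantoms, preprocessed composites + manifest, checkpoints + loss
    histories, FID curves, translated test panels, virtual-FA translations
    and the metric report under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("run config hash %s seed %d", _config_hash(cfg), cfg.seed)
    cfg.to_yaml(out / "config.yaml")
    stages = set(stages or {"simulate", "preprocess", "train", "select",
                            "translate", "evaluate"})
    try:
        with _stage("simulate", out):
            pairs = simulate_stage(cfg, out)
        with _stage("preprocess", out):
            train_set, test_set = preprocess_stage(cfg, pairs, out)
        for direction in cfg.directions:
            if "train" in stages:
                with _stage(f"train[{direction}]", out):
                    results = train_stage(cfg, train_set, out, direction)
            else:
                from .translator import Pix2PixResults
                checkpoints = CheckpointSet.load(out / "checkpoints", direction)
                model = Pix2PixModel(train_set, cfg.train_config(direction))
                import pandas as pd
                hist = pd.read_csv(out / "checkpoints" / f"history_{direction}.csv")
                results = Pix2PixResults(model, checkpoints, hist)
            with _stage(f"select[{direction}]", out):
                curve, sources, targets = select_stage(cfg, results, test_set,
                                                       out, direction)
            with _stage(f"translate[{direction}]", out):
                synth = translate_stage(results, sources, targets, out, direction)
            with _stage(f"evaluate[{direction}]", out):
                evaluate_stage(targets, synth, out, direction)
            if direction == "fa_to_oct":
                with _stage("virtual_fa", out):
                    virtual_fa_stage(cfg, results, out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
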