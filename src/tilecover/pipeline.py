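"""End-to-end synthetic experiment: Model 1 -> mining -> Model 2 -> transfer.

`run_experiment` reproduces the full study protocol on generated scenes,
once per simulated camera:

1. render positive (near-pure flower cover) and negative training scenes;
2. build the labeled tile dataset (purity rule, stratified split);
3. train Model 1;
4. run mining over distractor-bearing negative scenes and harvest the
   false positives;
5. retrain with the enlarged negative class (Model 2);
6. build per-camera pure-cover test sets and evaluate every model on
   every camera's test set (transferability matrices for both model
   generations);
7. render a coverage overlay for one held-out scene per camera.

Outputs land in a fresh versioned run directory (``run-001``, ``run-002``,
...) containing model checkpoints, history CSVs, the mining report, metric
and kappa CSVs, overlays, a coverage summary, a manifest of every file
written and a provenance record.  Identical configuration and seed yield
identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import AugmentationConfig, augment_stream, build_dataset
from .evaluation import build_test_set, evaluate_model, transferability
from .io import save_image
from .mining import harvest_false_positives, retrain_with_hard_negatives
from .model import TrainConfig, build_network
from .overlay import aggregate_cells, calibrate_cell_threshold, render_overlay
from .synth import CameraProfile, SceneSpec, make_corpus
from .tiling import ChopConfig, chop_image

__all__ = ["SynthesisConfig", "EvalConfig", "PipelineConfig", "run_experiment"]

# Strong enough to degrade cross-camera transfer, mild enough that the
# green-purity rule still tells foliage from flowers under either profile.
DEFAULT_CAMERAS = (
    CameraProfile(name="warm", gain=(1.08, 1.0, 0.9), offset=(5.0, 0.0, -5.0)),
    CameraProfile(name="cool", gain=(0.9, 1.0, 1.1), offset=(-5.0, 0.0, 5.0)),
)


@dataclass(frozen=True)
class SynthesisConfig:
    """Scene counts and distractor levels for the synthetic experiment."""

    scene_width: int = 200
    scene_height: int = 200
    n_train_positive_scenes: int = 12
    n_train_negative_scenes: int = 12
    n_mining_scenes: int = 8
    n_holdout_distractor_scenes: int = 6
    n_test_positive_scenes: int = 4
    n_test_negative_scenes: int = 4
    n_calibration_scenes: int = 6
    train_cover_range: tuple[float, float] = (0.88, 0.93)
    test_cover_range: tuple[float, float] = (0.9, 0.95)
    length_range: tuple[int, int] = (10, 300)
    sunlit_leaf_fraction: float = 0.08
    nontarget_yellow_flower_count: int = 5
    noise_sd: float = 4.0


@dataclass(frozen=True)
class EvalConfig:
    n_test_tiles: int = 500
    positive_fraction: float = 0.5


@dataclass(frozen=True)
class PipelineConfig:
    chop: ChopConfig = field(default_factory=ChopConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    synth: SynthesisConfig = field(default_factory=SynthesisConfig)
    cameras: tuple[CameraProfile, ...] = DEFAULT_CAMERAS
    use_augmentation: bool = False
    max_tiles_per_class: int = 1000
    purity_threshold: float = 0.2
    overlay_alpha: float = 0.4
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def tup(x):
            return tuple(x) if isinstance(x, (list, tuple)) else x
        kwargs = dict(data)
        if "chop" in kwargs:
            kwargs["chop"] = ChopConfig(**kwargs["chop"])
        if "augmentation" in kwargs:
            kwargs["augmentation"] = AugmentationConfig(**kwargs["augmentation"])
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        if "eval" in kwargs:
            kwargs["eval"] = EvalConfig(**kwargs["eval"])
        if "synth" in kwargs:
            s = dict(kwargs["synth"])
            for key in ("train_cover_range", "test_cover_range", "length_range"):
                if key in s:
                    s[key] = tup(s[key])
            kwargs["synth"] = SynthesisConfig(**s)
        if "cameras" in kwargs:
            kwargs["cameras"] = tuple(
                CameraProfile(name=c["name"], gain=tup(c["gain"]), offset=tup(c["offset"]))
                for c in kwargs["cameras"]
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _derive_seed(*parts) -> int:
    """Stable sub-seed from the global seed plus string/int tags."""
    ints = []
    for p in parts:
        if isinstance(p, str):
            ints.append(int.from_bytes(hashlib.sha256(p.encode()).digest()[:4], "big"))
        else:
            ints.append(int(p))
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31 - 1))


def _camera_corpora(config: PipelineConfig, camera: CameraProfile):
    """All scene corpora for one camera, keyed by role."""
    s = config.synth
    base = SceneSpec(width=s.scene_width, height=s.scene_height, noise_sd=s.noise_sd,
                     camera=camera)
    distract = dataclasses.replace(
        base, sunlit_leaf_fraction=s.sunlit_leaf_fraction,
        nontarget_yellow_flower_count=s.nontarget_yellow_flower_count)
    roles = {
        "train_pos": (s.n_train_positive_scenes, base, s.train_cover_range),
        "train_neg": (s.n_train_negative_scenes, base, (0.0, 0.0)),
        "mining_neg": (s.n_mining_scenes, distract, (0.0, 0.0)),
        "holdout_distractor": (s.n_holdout_distractor_scenes, distract, (0.0, 0.0)),
        "test_pos": (s.n_test_positive_scenes, base, s.test_cover_range),
        "test_neg": (s.n_test_negative_scenes, base, (0.0, 0.0)),
        "calibration": (s.n_calibration_scenes, base, (0.1, 0.9)),
    }
    out = {}
    for role, (n, template, cover) in roles.items():
        seed = _derive_seed(config.seed, camera.name, role)
        scenes, manifest = make_corpus(n, template, cover_range=cover,
                                       length_range=s.length_range, seed=seed)
        out[role] = ([sc.to_source(f"{camera.name}_{role}_{i}") for i, sc in enumerate(scenes)],
                     scenes, manifest)
    return out


def _next_run_dir(out_root: Path) -> Path:
    out_root.mkdir(parents=True, exist_ok=True)
    k = 1
    while (out_root / f"run-{k:03d}").exists():
        k += 1
    run_dir = out_root / f"run-{k:03d}"
    run_dir.mkdir()
    return run_dir


def run_experiment(config: PipelineConfig, out_root: str | Path) -> Path:
    """Run the full synthetic two-model protocol; returns the run directory."""
    run_dir = _next_run_dir(Path(out_root))
    written: list[str] = []

    def _record(path: Path) -> Path:
        written.append(str(path.relative_to(run_dir)))
        return path

    config.to_yaml(_record(run_dir / "config.yaml"))

    models1, models2 = {}, {}
    test_sets = {}
    mining_rows = []
    coverage_rows = []

    for camera in config.cameras:
        cam_dir = run_dir / camera.name
        cam_dir.mkdir()
        corpora = _camera_corpora(config, camera)

        ds = build_dataset(
            corpora["train_pos"][0], corpora["train_neg"][0], config.chop,
            purity_threshold=config.purity_threshold,
            seed=_derive_seed(config.seed, camera.name, "dataset"),
            max_tiles_per_class=config.max_tiles_per_class,
        )
        train_cfg = dataclasses.replace(
            config.train, seed=_derive_seed(config.seed, camera.name, "model1"))
        model1 = build_network(config.chop.tile_size_px, train_cfg)
        if config.use_augmentation:
            stream = augment_stream(ds.train, config.augmentation,
                                    seed=_derive_seed(config.seed, camera.name, "augment"))
            model1.fit(stream, ds.validation, n_train=len(ds.train))
        else:
            model1.fit(ds.train, ds.validation)
        model1.save(cam_dir / "model1")
        _record(cam_dir / "model1" / "history.csv")

        report, harvested, harvested_ids = harvest_false_positives(
            model1, corpora["mining_neg"][0], config.chop)
        (cam_dir / "mining_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        _record(cam_dir / "mining_report.json")
        mining_rows.append({"camera": camera.name, **report.to_dict(),
                            "per_source": json.dumps(report.to_dict()["per_source"])})

        train_cfg2 = dataclasses.replace(
            config.train, seed=_derive_seed(config.seed, camera.name, "model2"))
        model2, _ = retrain_with_hard_negatives(ds, harvested, train_cfg2,
                                                harvested_ids=harvested_ids)
        model2.save(cam_dir / "model2")
        _record(cam_dir / "model2" / "history.csv")

        # false positives of both model generations on held-out distractor scenes
        holdout_tiles = np.concatenate([
            np.stack([t.pixels for t in chop_image(src.image, config.chop)[1]])
            for src in corpora["holdout_distractor"][0]
        ])
        fp_model1 = int(model1.predict(holdout_tiles).sum())
        fp_model2 = int(model2.predict(holdout_tiles).sum())
        mining_rows[-1].update({
            "holdout_tiles": len(holdout_tiles),
            "holdout_fp_model1": fp_model1,
            "holdout_fp_model2": fp_model2,
        })

        test_sets[camera.name] = build_test_set(
            corpora["test_pos"][0], corpora["test_neg"][0], config.chop,
            n_tiles=config.eval.n_test_tiles,
            positive_fraction=config.eval.positive_fraction,
            seed=_derive_seed(config.seed, camera.name, "test"),
        )
        models1[camera.name] = model1
        models2[camera.name] = model2

        # coverage overlay of one held-out positive test scene, with the
        # cell threshold calibrated on this camera's calibration scenes
        cell_threshold = calibrate_cell_threshold(
            model2, corpora["calibration"][1], config.chop)
        scene = corpora["test_pos"][1][0]
        grid, tiles = chop_image(scene.image, config.chop, source_id="overlay")
        probs = model2.predict_proba(np.stack([t.pixels for t in tiles]))
        cov = aggregate_cells(grid, probs, threshold=cell_threshold)
        save_image(_record(cam_dir / "overlay.png"),
                   render_overlay(scene.image, cov, alpha=config.overlay_alpha))
        summary = cov.summary(source_id=f"{camera.name}_test_pos_0")
        summary["cell_threshold"] = cell_threshold
        summary["truth_cover_fraction"] = scene.cover_fraction
        coverage_rows.append({"camera": camera.name, **summary})

    pd.DataFrame(mining_rows).to_csv(_record(run_dir / "mining_summary.csv"), index=False)
    pd.DataFrame(coverage_rows).to_csv(_record(run_dir / "coverage_summary.csv"), index=False)

    for label, models in (("model1", models1), ("model2", models2)):
        matrix = transferability(models, test_sets)
        matrix.to_frame().to_csv(_record(run_dir / f"metrics_{label}.csv"), index=False)
        matrix.kappa_frame().to_csv(_record(run_dir / f"kappa_{label}.csv"))

    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    (run_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    _record(run_dir / "provenance.json")
    (run_dir / "manifest.json").write_text(json.dumps(sorted(written), indent=2))
    return run_dir
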