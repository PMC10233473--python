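"""Run configuration, seed derivation and the end-to-end experiment driver.

A run is described by one YAML file with nested sections mirroring the
stages (simulate / calibrate / dataset / model / metrics / smlm) plus a
global seed.  Defaults are the acquisition/analysis settings of the method
(157 nm pixels, 100-frame averaging, the published Adam parameters, the
published detection thresholds); unknown keys are rejected with their path.

One global seed expands into independent per-stage seeds through a fixed
counter scheme, so any stage can be re-run in isolation and reproduce its
stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dataset import DatasetConfig
from .mprenet import MPReNetConfig
from .optics import BlinkModel, CameraModel, DetectionModel, SheetGeometry
from .smlm import DetectionConfig

__all__ = [
    "ConfigError",
    "SimulateConfig",
    "CalibrateConfig",
    "MetricsConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "stage_seed",
    "run_experiment",
]

log = logging.getLogger("tiltsheet")

_STAGES = ("simulate", "calibrate", "dataset", "train", "predict", "smlm", "eval")


class ConfigError(ValueError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed."""
    if stage not in _STAGES:
        raise ConfigError(f"unknown stage {stage!r}; known: {_STAGES}")
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _build(cls, data: dict, path: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"{path}: {err}") from err


@dataclass
class SimulateConfig:
    phantom_kind: str = "shell"
    phantom_params: dict = field(default_factory=dict)
    n_frames: int = 100
    n_pairs: int = 8
    exposure: float = 1.0
    tilt_deg: float = 18.0
    waist_fwhm_um: float = 1.6
    rayleigh_um: float = 12.0
    focus_xy_um: float = 5.0


@dataclass
class CalibrateConfig:
    z_min_um: float = -10.0
    z_max_um: float = 10.0
    step_um: float = 0.5
    frames_per_z: int = 100
    peak_photons: float = 200.0
    # profile scans need a field wide enough to follow the stripe drift
    # (~z-range / tan(tilt)); None keeps the shared detection geometry
    fov_px: tuple[int, int] | None = None

    def detection_for(self, detection: DetectionModel) -> DetectionModel:
        if self.fov_px is None:
            return detection
        return dataclasses.replace(detection, fov_px=tuple(self.fov_px))


@dataclass
class MetricsConfig:
    camera_offset: float = 100.0


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "tiltsheet_run"
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    calibrate: CalibrateConfig = field(default_factory=CalibrateConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    model: MPReNetConfig = field(default_factory=MPReNetConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    smlm: DetectionConfig = field(default_factory=DetectionConfig)
    detection: DetectionModel = field(default_factory=DetectionModel)
    camera: CameraModel = field(default_factory=CameraModel)
    blink: BlinkModel = field(default_factory=BlinkModel)

    def geometry(self) -> SheetGeometry:
        sim = self.simulate
        return SheetGeometry(
            sim.tilt_deg, sim.waist_fwhm_um, sim.rayleigh_um, sim.focus_xy_um
        )


_SECTIONS = {
    "simulate": SimulateConfig,
    "calibrate": CalibrateConfig,
    "dataset": DatasetConfig,
    "model": MPReNetConfig,
    "metrics": MetricsConfig,
    "smlm": DetectionConfig,
    "detection": DetectionModel,
    "camera": CameraModel,
    "blink": BlinkModel,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys take the package defaults; an empty file is a valid,
    fully-defaulted configuration.  Violations are reported with their key
    path.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level must be a mapping")
    known = set(_SECTIONS) | {"seed", "out_dir", "log_level"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    kwargs = {}
    for key in ("seed", "out_dir", "log_level"):
        if key in data:
            kwargs[key] = data[key]
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data[name]
            if name in ("detection", "calibrate") and section and section.get("fov_px"):
                section["fov_px"] = tuple(section["fov_px"])
            kwargs[name] = _build(cls, section, name)
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    Path(path).write_text(yaml.safe_dump(clean(config), sort_keys=False))


# ---------------------------------------------------------------------------
# end-to-end driver


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Simulate -> calibrate -> prepare -> train -> predict -> localize -> evaluate.

    Writes every stage artifact plus ``manifest.json`` (inputs, seeds,
    outputs with checksums, metric summaries) into the output directory and
    returns its path.  Deterministic outputs reproduce bit-exactly under
    the same config and seed.
    """
    from . import io as tio
    from . import metrics as tmetrics
    from .calibration import calibrate_stack
    from .dataset import build_dataset
    from .mprenet import build_model, save_model, train
    from .optics import make_phantom, simulate_pair, simulate_profile_stack, simulate_smlm_movie
    from .smlm import evaluate_localizations, run_pipeline

    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    geometry = config.geometry()
    detection = config.detection
    camera = config.camera

    # 1. profile stack + calibration (beam redirected onto the camera:
    # focus centred in the -- typically wider -- calibration field)
    seed = stage_seed(config.seed, "calibrate")
    cal = config.calibrate
    cal_det = cal.detection_for(detection)
    cal_geom = dataclasses.replace(
        geometry, focus_xy_um=cal_det.fov_px[1] * cal_det.pixel_nm / 2e3
    )
    stack, z_um = simulate_profile_stack(
        cal_geom,
        cal.z_min_um,
        cal.z_max_um,
        cal.step_um,
        cal.frames_per_z,
        cal_det,
        camera,
        seed,
        cal.peak_photons,
    )
    tio.write_stack(out / "profile.tif", stack)
    calib = calibrate_stack(stack, z_um, cal_det.pixel_nm / 1e3)
    tio.write_calibration_yaml(out / "calibration.yaml", calib)
    manifest["stages"]["calibrate"] = {
        "seed": seed,
        "tilt_deg": calib.tilt_deg,
        "waist_fwhm_um": calib.waist_fwhm_um,
        "efov_um": calib.efov_um,
    }
    log.info("calibration: tilt %.2f deg, waist %.3f um", calib.tilt_deg, calib.waist_fwhm_um)

    # 2. paired acquisitions + dataset
    seed = stage_seed(config.seed, "simulate")
    sim = config.simulate
    pair_seeds = np.random.SeedSequence(seed).generate_state(2 * sim.n_pairs)
    pairs = []
    for i in range(sim.n_pairs):
        phantom = make_phantom(
            sim.phantom_kind, dict(sim.phantom_params), int(pair_seeds[2 * i] % 2**31)
        )
        pairs.append(
            simulate_pair(
                phantom,
                geometry,
                detection,
                camera,
                sim.n_frames,
                int(pair_seeds[2 * i + 1] % 2**31),
                sim.exposure,
            )
        )
    train_set, val_set, ds_manifest = build_dataset(
        pairs, config.dataset, stage_seed(config.seed, "dataset")
    )
    ds_manifest.to_csv(out / "dataset_manifest.csv", index=False)
    manifest["stages"]["dataset"] = {
        "n_train": len(train_set),
        "n_val": len(val_set),
        "seed": stage_seed(config.seed, "dataset"),
    }

    # 3. training
    model = build_model(config.model, stage_seed(config.seed, "train"))
    train(model, train_set, val_set, config.model)
    save_model(model, out / "model.ckpt.npz")
    manifest["stages"]["train"] = {
        "seed": stage_seed(config.seed, "train"),
        "final_train_loss": model.history["train_loss"][-1],
        "final_val_loss": model.history["val_loss"][-1] if model.history["val_loss"] else None,
    }

    # 4. prediction metrics on held-out patches
    ssim_in, ssim_pred, nrmse_in, nrmse_pred = [], [], [], []
    for patch in val_set:
        pred = model.forward(patch.input_img.astype(np.float32))
        ssim_in.append(tmetrics.ssim(patch.input_img, patch.target_img, data_range=1.0))
        ssim_pred.append(tmetrics.ssim(pred, patch.target_img, data_range=1.0))
        nrmse_in.append(tmetrics.nrmse(patch.input_img, patch.target_img))
        nrmse_pred.append(tmetrics.nrmse(pred, patch.target_img))
    manifest["stages"]["predict"] = {
        "mean_ssim_input": float(np.mean(ssim_in)),
        "mean_ssim_pred": float(np.mean(ssim_pred)),
        "mean_nrmse_input": float(np.mean(nrmse_in)),
        "mean_nrmse_pred": float(np.mean(nrmse_pred)),
    }

    # 5. SMLM movie + localization + evaluation
    seed = stage_seed(config.seed, "smlm")
    from .optics import field_center_um

    cx, cy = field_center_um(detection)
    phantom = make_phantom(
        "sparse_molecules",
        {
            "n": 30,
            "bounds_um": (0.8 * cx, 0.8 * cy, 0.3),
            "center_um": (cx, cy, 0.0),
        },
        seed,
    )
    movie = simulate_smlm_movie(
        phantom, config.blink, None, detection, camera, n_frames=30, seed=seed
    )
    tio.write_stack(out / "smlm_movie.tif", movie.frames)
    tio.write_truth_csv(out / "smlm_truth.csv", movie.truth)
    table = run_pipeline(movie, "none", config=config.smlm)
    tio.write_locs_csv(out / "locs.csv", table)
    result = evaluate_localizations(table, movie.truth, tol_nm=100.0)
    manifest["stages"]["smlm"] = {
        "seed": seed,
        "n_localizations": int(len(table)),
        "recall": result.recall,
        "precision": result.precision,
        "rmse_nm": result.rmse_nm,
    }

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
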