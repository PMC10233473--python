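"""Desk-scale reference experiments.

Self-contained, seeded experiments exercising the whole toolkit at sizes a
single CPU handles in minutes.  They define the package's standard study
conditions — phantom geometry, photon budgets, noise model, training
profile — in one place so the validation suite and reproduction scripts
run the same protocol.

Problem sizes: calibration scans use the full +/-10 um, 0.5 um, 100-frame
protocol; cross-modality training uses ~256 patch pairs (32 x 32 px for
the shell experiment, 64 x 64 px — the acquisition frame size — for the
spot-background model) and 300 optimizer steps of the T=3 / 16-channel
network profile; localization movies are 50 frames of a 64 x 64 px field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import calibrate_stack
from .dataset import (
    DatasetConfig,
    NormAffine,
    TrainingPatch,
    build_dataset,
    denormalize_patch,
    normalize_patch,
)
from .metrics import RoiSpec, annulus_mask, disk_mask, nrmse, sbr_structure, ssim
from .mprenet import MPReNet, MPReNetConfig, build_model, train
from .optics import (
    BlinkModel,
    CameraModel,
    DetectionModel,
    Phantom,
    SheetGeometry,
    add_camera_noise,
    field_center_um,
    make_phantom,
    render_frame,
    simulate_pair,
    simulate_profile_stack,
    simulate_smlm_movie,
)
from .smlm import DetectionConfig, drift_correct, evaluate_localizations, run_pipeline

__all__ = [
    "rayleigh_range_um",
    "calibration_recovery",
    "shell_training",
    "train_spot_background_model",
    "step_movie",
    "step_retention",
    "localization_fidelity",
    "drift_recovery",
]

_LAMBDA_UM = 0.56  # illumination wavelength used for physically consistent zR


def rayleigh_range_um(waist_fwhm_um: float, wavelength_um: float = _LAMBDA_UM) -> float:
    """Rayleigh range of a Gaussian beam with the given intensity-FWHM waist."""
    w0 = waist_fwhm_um / math.sqrt(2.0 * math.log(2.0))
    return math.pi * w0**2 / wavelength_um


# ---------------------------------------------------------------------------


def calibration_recovery(seed: int, n_truths: int = 10) -> list[dict]:
    """Round-trip sheet calibration over random geometries.

    Draws tilts in [10, 40] degrees and waists in [1, 3] um (Rayleigh range
    from the wavelength), simulates the standard z-scan (+/-10 um, 0.5 um
    steps, 100-frame camera averages) on a field wide enough to follow the
    stripe drift, and calibrates.  Returns per-truth records with the
    true/estimated tilt and waist.
    """
    rng = np.random.default_rng(seed)
    records = []
    for trial in range(n_truths):
        tilt = float(rng.uniform(10.0, 40.0))
        fwhm = float(rng.uniform(1.0, 3.0))
        drift = 22.0 / math.tan(math.radians(tilt))
        width = int(np.ceil((drift + 12.0) / 0.157 / 32)) * 32
        det = DetectionModel(fov_px=(16, width))
        geom = SheetGeometry(
            tilt, fwhm, rayleigh_range_um(fwhm), width * 0.157 / 2.0
        )
        stack, z_um = simulate_profile_stack(
            geom,
            detection=det,
            camera=CameraModel(),
            frames_per_z=100,
            seed=int(rng.integers(2**31)),
        )
        cal = calibrate_stack(stack, z_um, det.pixel_nm / 1e3)
        records.append(
            {
                "tilt_true": tilt,
                "tilt_est": cal.tilt_deg,
                "waist_true": fwhm,
                "waist_est": cal.waist_fwhm_um,
                "efov_um": cal.efov_um,
            }
        )
    return records


# ---------------------------------------------------------------------------


@dataclass
class TrainingOutcome:
    model: MPReNet
    mean_ssim_input: float
    mean_ssim_pred: float
    mean_nrmse_input: float
    mean_nrmse_pred: float
    mean_sbr_enhancement: float


def _shell_pairs(seed: int, n_pairs: int, det, cam, geom):
    """Nucleolar-shell fields: a bright surface shell plus a dim dense
    out-of-focus population filling the surrounding volume — the source of
    the epi-illumination haze that the sheet optically rejects."""
    cx, cy = field_center_um(det)
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        center = (
            cx + rng.uniform(-0.3, 0.3),
            cy + rng.uniform(-1.5, 1.5),
            0.0,
        )
        shell = make_phantom(
            "shell",
            {
                "n": 500,
                "r_inner_um": 1.5,
                "r_outer_um": 1.8,
                "center_um": center,
                "bounds_um": (cx, cy, 3.0),
                "photon_rate": 60.0,
            },
            seed=int(rng.integers(2**31)),
        )
        volume = make_phantom(
            "dense_volume",
            {
                "n": 2000,
                "radii_um": (0.95 * cx, 0.95 * cy, 3.5),
                "center_um": (cx, cy, 0.0),
                "bounds_um": (cx, cy, 3.5),
                "photon_rate": 15.0,
            },
            seed=int(rng.integers(2**31)),
        )
        phantom = Phantom(
            np.vstack([shell.emitters, volume.emitters]),
            kind="shell",
            bounds_um=(cx, cy, 3.5),
            center_um=(cx, cy, 0.0),
        )
        pairs.append(
            simulate_pair(
                phantom, geom, det, cam, n_frames=100, seed=int(rng.integers(2**31))
            )
        )
    return pairs


def shell_training(
    seed: int, n_pairs: int = 96, max_iterations: int = 300
) -> TrainingOutcome:
    """Cross-modality training on hollow-shell phantoms.

    Paired epi / light-sheet acquisitions of nucleolar-surface-like shells
    are averaged, strip-cropped and normalized; the desk-profile network is
    trained and evaluated on the held-out pairs: SSIM and NRMSE against the
    light-sheet target, and the structure-SBR enhancement of predictions
    over epi inputs on the shell mid-plane ring (central crops).
    """
    det = DetectionModel(fov_px=(96, 48))
    cam = CameraModel(em_gain=50.0)
    cx, _ = field_center_um(det)
    geom = SheetGeometry(18.0, 1.6, rayleigh_range_um(1.6), cx)
    pairs = _shell_pairs(seed + 1, n_pairs, det, cam, geom)
    ds_cfg = DatasetConfig(n_average=100, split_fraction=0.9)
    train_set, val_set, _ = build_dataset(pairs, ds_cfg, seed=seed + 2)

    cfg = MPReNetConfig.desk(n_epochs=1000, seed=seed + 3)
    model = build_model(cfg, seed=seed + 4)
    train(model, train_set[:256], val_set, cfg, max_iterations=max_iterations)

    ssim_in, ssim_pred, nr_in, nr_pred, enh = [], [], [], [], []
    for p in val_set:
        pred = np.clip(model.forward(p.input_img.astype(np.float32)), 0.0, 1.0)
        ssim_in.append(ssim(p.input_img, p.target_img, data_range=1.0))
        ssim_pred.append(ssim(pred, p.target_img, data_range=1.0))
        nr_in.append(nrmse(p.input_img, p.target_img))
        nr_pred.append(nrmse(pred, p.target_img))
        if p.crop_index == 1:  # central crop holds the shell mid-plane ring
            shape = p.input_img.shape
            c = (shape[0] / 2 - 0.5, shape[1] / 2 - 0.5)
            roi = RoiSpec(
                annulus_mask(shape, c, 1.5e3 / det.pixel_nm, 1.9e3 / det.pixel_nm),
                disk_mask(shape, c, 0.8e3 / det.pixel_nm),
            )
            inp_ph = np.clip(
                denormalize_patch(p.input_img, p.norm) - cam.offset, 1e-3, None
            )
            pred_ph = np.clip(
                denormalize_patch(pred, p.norm) - cam.offset, 1e-3, None
            )
            enh.append(sbr_structure(pred_ph, roi) / sbr_structure(inp_ph, roi))
    return TrainingOutcome(
        model,
        float(np.mean(ssim_in)),
        float(np.mean(ssim_pred)),
        float(np.mean(nr_in)),
        float(np.mean(nr_pred)),
        float(np.mean(enh)),
    )


# ---------------------------------------------------------------------------


def _spot_background_patch(seed: int, det, cam) -> TrainingPatch:
    """One (spots + structured background, spots only) training pair."""
    r = np.random.default_rng(seed)
    h, w = det.fov_px
    cx, cy = field_center_um(det)
    n_spots = int(r.integers(4, 13))
    pts = np.column_stack(
        [
            r.uniform(0.6, 2 * cx - 0.6, n_spots),
            r.uniform(0.6, 2 * cy - 0.6, n_spots),
            np.zeros(n_spots),
            r.uniform(700.0, 1600.0, n_spots),  # brightness variety
        ]
    )
    ph = Phantom(pts, "sparse_molecules", (cx, cy, 1.0), (cx, cy, 0.0))
    clean = render_frame(ph, None, det, 1.0, cam.qe)
    yy, xx = np.mgrid[0:h, 0:w]
    # step amplitudes up to the peak-pixel signal of a molecule: the regime
    # where a sharp background edge genuinely competes with detection
    hi = 240.0
    bg = r.uniform(3.0, 0.4 * hi) + r.uniform(0, 0.3 * hi) * np.sin(
        xx / r.uniform(8, 30) + r.uniform(0, 6)
    ) * np.cos(yy / r.uniform(8, 30) + r.uniform(0, 6))
    if r.random() < 0.8:  # sharp step along a random line (nucleolus edge regime)
        angle = r.uniform(0, np.pi)
        c = np.cos(angle) * (xx - r.uniform(0.25 * w, 0.75 * w)) + np.sin(angle) * (
            yy - r.uniform(0.25 * h, 0.75 * h)
        )
        bg = bg + r.uniform(0.4 * hi, hi) * (c > 0)
    bg = np.clip(bg, 0, None)
    inp = np.clip(
        cam.counts_to_photons(
            add_camera_noise(clean + bg, cam, int(r.integers(2**31)))
        ),
        0,
        None,
    )
    # target is the noiseless signal -- the analogue of the heavily
    # frame-averaged ground truth the cross-modality mapping is learned from
    inp_n, _ = normalize_patch(inp, affine=_SPOT_AFFINE)
    tgt_n, _ = normalize_patch(clean, affine=_SPOT_AFFINE)
    return TrainingPatch(inp_n, tgt_n, f"s{seed}", 0, _SPOT_AFFINE)


# fixed photon-unit normalization for spot models: unclipped, with the
# scale above the full signal range (spot peak + background) so neither
# spot peaks nor bright backgrounds saturate and fitted amplitudes survive
# the round trip exactly
_SPOT_AFFINE = NormAffine(0.0, 600.0, clip=False)


def train_spot_background_model(
    seed: int, n_patches: int = 288, max_iterations: int = 300
) -> MPReNet:
    """Desk-profile model mapping spot images with structured background
    (smooth + sharp steps) to background-free spot images.

    Normalization is a fixed photon-unit affine shared by training and
    inference (stored in the model), keeping molecule amplitudes faithful
    for the downstream photon filter.  Patches are the acquisition frame
    size (64 x 64) so inference sees the border statistics it was trained
    with — the network's receptive field spans such frames entirely."""
    det = DetectionModel(fov_px=(64, 64))
    cam = CameraModel()
    patches = [
        _spot_background_patch(seed * 10_000 + i, det, cam) for i in range(n_patches)
    ]
    cfg = MPReNetConfig.desk(
        n_epochs=1000,
        seed=seed + 1,
        norm_source="input",
        batch_size=8,
        global_residual=True,
    )
    model = build_model(cfg, seed=seed + 2)
    model.input_affine = _SPOT_AFFINE
    train(model, patches[:256], patches[256:], cfg, max_iterations=max_iterations)
    return model


def step_movie(seed: int, n_frames: int = 50):
    """Blinking-molecule movie over a sharp vertical background step (the
    nucleus/nucleolus-edge regime).  Returns (movie, step_x_nm)."""
    det = DetectionModel(fov_px=(64, 64))
    cam = CameraModel()
    cx, cy = field_center_um(det)
    yy, xx = np.mgrid[0 : det.fov_px[0], 0 : det.fov_px[1]]
    step_col = det.fov_px[1] // 2
    # step height comparable to a molecule's peak-pixel signal (~185
    # photoelectrons for 1000 photons): the nucleolus-edge regime
    bgmap = 8.0 + 180.0 * (xx >= step_col)
    phantom = make_phantom(
        "sparse_molecules",
        {
            "n": 100,
            "bounds_um": (0.75 * cx, 0.75 * cy, 0.01),
            "center_um": (cx, cy, 0.0),
            "photon_rate": 1000.0,
            "min_sep_um": 0.5,
        },
        seed=seed,
    )
    blink = BlinkModel(on_rate=0.12, off_rate=0.75)
    movie = simulate_smlm_movie(
        phantom, blink, bgmap, det, cam, n_frames=n_frames, seed=seed + 1
    )
    return movie, step_col * det.pixel_nm


def step_retention(model: MPReNet, seed: int, near_nm: float = 500.0) -> dict:
    """Count true localizations recovered near the background step under
    model-based vs rolling-ball background removal."""
    movie, step_x_nm = step_movie(seed)
    config = DetectionConfig()
    near = np.abs(movie.truth[:, 1] - step_x_nm) <= near_nm
    truth_near = movie.truth[near]
    out = {"n_truth_near": int(near.sum())}
    for mode, mdl in (("model", model), ("rolling_ball", None)):
        table = run_pipeline(movie, mode, mdl, config)
        res_all = evaluate_localizations(table, movie.truth, 100.0)
        res_near = evaluate_localizations(table, truth_near, 100.0)
        out[f"{mode}_matched_near"] = res_near.n_matched
        out[f"{mode}_recall"] = res_all.recall
    out["retention_ratio"] = out["model_matched_near"] / max(
        out["rolling_ball_matched_near"], 1
    )
    return out


# ---------------------------------------------------------------------------


def localization_fidelity(seed: int, n_frames: int = 50, n_emitters: int = 20) -> dict:
    """Localization accuracy on a flat-background movie of continuously
    emitting 1000-photon molecules; recall/precision/RMSE at 100 nm.

    Emitters are placed with a 0.8 um minimum lateral separation — the
    resolvable regime the single-emitter fitter is specified for (the
    multi-emitter extension is out of scope)."""
    det = DetectionModel(fov_px=(64, 64))
    cam = CameraModel()
    cx, cy = field_center_um(det)
    phantom = make_phantom(
        "sparse_molecules",
        {
            "n": n_emitters,
            "bounds_um": (0.75 * cx, 0.75 * cy, 0.05),
            "center_um": (cx, cy, 0.0),
            "photon_rate": 1000.0,
            "min_sep_um": 0.8,
        },
        seed=seed,
    )
    movie = simulate_smlm_movie(
        phantom,
        BlinkModel(on_rate=1.0, off_rate=0.0),
        None,
        det,
        cam,
        n_frames=n_frames,
        seed=seed + 1,
        start_on_prob=1.0,
    )
    table = run_pipeline(movie, "none", config=DetectionConfig())
    res = evaluate_localizations(table, movie.truth, 100.0)
    return {
        "recall": res.recall,
        "precision": res.precision,
        "rmse_nm": res.rmse_nm,
        "n_localizations": len(table),
    }


def drift_recovery(seed: int, total_drift_nm: float = 100.0, n_frames: int = 500) -> dict:
    """Inject a linear stage drift into a clustered localization table and
    measure the residual after cross-correlation correction."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = 4000
    frames = rng.integers(0, n_frames, n)
    cx = rng.uniform(500, 9500, 40)
    cy = rng.uniform(500, 9500, 40)
    pick = rng.integers(0, 40, n)
    x = cx[pick] + rng.normal(0, 50, n)
    y = cy[pick] + rng.normal(0, 50, n)
    rate = total_drift_nm / (n_frames - 1)
    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "frame": frames,
            "x_nm": x + frames * rate,
            "y_nm": y - 0.5 * frames * rate,
            "photons": 1000.0,
        }
    )
    corrected, trace = drift_correct(table, n_bins=5, magnification=5)
    # drift is estimated relative to the first temporal bin, so compare up
    # to the global registration constant
    res_x = corrected["x_nm"].to_numpy() - x
    res_y = corrected["y_nm"].to_numpy() - y
    res_x -= res_x.mean()
    res_y -= res_y.mean()
    return {
        "rms_x_nm": float(np.sqrt(np.mean(res_x**2))),
        "rms_y_nm": float(np.sqrt(np.mean(res_y**2))),
        "trace": trace,
    }
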