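"""Virtual tilted-light-sheet / epi-illumination microscope.

Generates the synthetic inputs used throughout the package: co-registered
epi and light-sheet image stacks of a phantom, direct-beam sheet-profile
z-stacks for calibration, and blinking single-molecule movies with ground
truth.

Coordinate conventions
----------------------
Right-handed axes with ``z = 0`` at the detection focal plane.  Images are
row-major and 0-based; the centre of pixel ``(row, col)`` sits at
``((col + 0.5) * pixel, (row + 0.5) * pixel)`` with columns along *x* and
rows along *y*.  Lateral distances are micrometres unless a name says
otherwise (``*_nm``).

The excitation sheet is a cylindrically focused Gaussian beam whose
mid-plane is inclined by ``tilt_deg`` to the focal plane and crosses it at
``focus_xy_um`` along *x*.  Its 1/e^2 half-thickness grows hyperbolically
with the in-plane distance from focus, the usual Gaussian-beam law
``w(s) = w0 * sqrt(1 + (s / zR)^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = [
    "SheetGeometry",
    "field_center_um",
    "Phantom",
    "DetectionModel",
    "CameraModel",
    "BlinkModel",
    "ImagePair",
    "SMLMMovie",
    "make_phantom",
    "sheet_excitation",
    "render_frame",
    "add_camera_noise",
    "simulate_pair",
    "simulate_profile_stack",
    "simulate_smlm_movie",
]

# intensity FWHM of a Gaussian beam = sqrt(2 ln 2) * w  (w = 1/e^2 radius)
_FWHM_PER_W = math.sqrt(2.0 * math.log(2.0))


class ConfigurationError(ValueError):
    """Raised for unknown modes/kinds or inconsistent option combinations."""


@dataclass(frozen=True)
class SheetGeometry:
    """Tilted Gaussian-beam light sheet.

    Parameters
    ----------
    tilt_deg:
        Angle between the sheet mid-plane and the focal plane, degrees,
        in (0, 90].
    waist_fwhm_um:
        Sheet thickness at focus as an intensity FWHM (what a profile
        measurement reports), micrometres.
    rayleigh_um:
        Rayleigh range of the thickness growth along propagation.
    focus_xy_um:
        Lateral *x* position where the sheet mid-plane crosses the focal
        plane.
    peak_intensity:
        Relative excitation irradiance at the focus (1.0 = reference).
    """

    tilt_deg: float
    waist_fwhm_um: float
    rayleigh_um: float
    focus_xy_um: float = 0.0
    peak_intensity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tilt_deg <= 90.0:
            raise ValueError(f"tilt_deg must be in (0, 90], got {self.tilt_deg}")
        if self.waist_fwhm_um <= 0:
            raise ValueError("waist_fwhm_um must be positive")
        if self.rayleigh_um <= 0:
            raise ValueError("rayleigh_um must be positive")
        if self.peak_intensity <= 0:
            raise ValueError("peak_intensity must be positive")

    @property
    def waist_w0_um(self) -> float:
        """1/e^2 half-thickness at focus."""
        return self.waist_fwhm_um / _FWHM_PER_W


@dataclass(frozen=True)
class Phantom:
    """A 3D set of point emitters consumed by the renderer.

    ``emitters`` is an (n, 4) float array of columns
    (x_um, y_um, z_um, photon_rate_per_frame).
    """

    emitters: np.ndarray
    kind: str
    bounds_um: tuple[float, float, float]
    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        emitters = np.asarray(self.emitters, dtype=float).reshape(-1, 4)
        object.__setattr__(self, "emitters", emitters)
        if emitters.size and emitters[:, 3].min() < 0:
            raise ValueError("photon rates must be non-negative")
        for axis, bound in enumerate(self.bounds_um):
            if emitters.size:
                off = np.abs(emitters[:, axis] - self.center_um[axis]).max()
                if off > bound + 1e-9:
                    raise ValueError("emitter outside simulation bounds")

    @property
    def n_emitters(self) -> int:
        return self.emitters.shape[0]


@dataclass(frozen=True)
class DetectionModel:
    """Detection-side PSF and sampling.

    The PSF is an isotropic Gaussian whose SD grows with defocus,
    ``sigma(z) = sqrt(sigma0^2 + (defocus_slope * z)^2)`` — the simplest
    model that produces out-of-focus haze.
    """

    sigma0_nm: float = 130.0
    defocus_slope: float = 200.0  # nm of extra SD per um of defocus
    pixel_nm: float = 157.0
    fov_px: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.sigma0_nm <= 0:
            raise ValueError("sigma0_nm must be positive")
        if self.defocus_slope < 0:
            raise ValueError("defocus_slope must be non-negative")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")

    def sigma_nm(self, z_um: float | np.ndarray) -> float | np.ndarray:
        return np.hypot(self.sigma0_nm, self.defocus_slope * np.asarray(z_um, float))


@dataclass(frozen=True)
class CameraModel:
    """EMCCD-style Poisson-Gaussian camera.

    ``excess_noise`` doubles the shot-noise variance via a gamma-distributed
    gain, the usual high-gain approximation of the EM register.
    """

    em_gain: float = 100.0
    offset: float = 100.0
    read_noise_counts: float = 10.0
    qe: float = 0.9
    excess_noise: bool = True

    def __post_init__(self) -> None:
        if self.em_gain <= 0:
            raise ValueError("em_gain must be positive")
        if not 0.0 < self.qe <= 1.0:
            raise ValueError("qe must be in (0, 1]")
        if self.read_noise_counts < 0:
            raise ValueError("read_noise_counts must be non-negative")

    def counts_to_photons(self, counts: np.ndarray) -> np.ndarray:
        """Invert the mean camera response (offset + gain)."""
        return (np.asarray(counts, float) - self.offset) / self.em_gain


@dataclass(frozen=True)
class BlinkModel:
    """Two-state (+ bleached) Markov photoswitching, probabilities per frame."""

    on_rate: float = 0.05
    off_rate: float = 0.5
    bleach_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("on_rate", "off_rate", "bleach_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def stationary_on(self) -> float:
        total = self.on_rate + self.off_rate
        return self.on_rate / total if total > 0 else 0.0


@dataclass
class ImagePair:
    """Co-registered epi and light-sheet stacks of one field of view."""

    epi_stack: np.ndarray
    sheet_stack: np.ndarray
    geometry: SheetGeometry
    truth_clean: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.epi_stack.shape != self.sheet_stack.shape:
            raise ValueError("epi and sheet stacks must share a shape")
        if self.epi_stack.ndim != 3 or self.epi_stack.shape[0] < 1:
            raise ValueError("stacks must be (frames, H, W) with frames >= 1")


@dataclass
class SMLMMovie:
    """Blinking single-molecule movie with per-frame ground truth."""

    frames: np.ndarray
    truth: "np.ndarray"  # structured-free (n, 4): frame, x_nm, y_nm, photons
    background_map: np.ndarray
    blink: BlinkModel
    detection: DetectionModel
    camera: CameraModel

    def __post_init__(self) -> None:
        if self.truth.size:
            if self.truth[:, 0].max() >= self.frames.shape[0]:
                raise ValueError("truth frame index beyond movie length")


# ---------------------------------------------------------------------------
# phantoms


def make_phantom(kind: str, params: dict | None = None, seed: int = 0) -> Phantom:
    """Draw a seeded random emitter set of the requested class.

    ``shell`` places emitters uniformly in a spherical annulus (hollow
    nucleolus-surface-like structures), ``dense_volume`` fills an ellipsoid
    (chromatin-like dense labelling), ``sparse_molecules`` scatters at most
    ``n`` emitters uniformly in the box (single-molecule regime).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    n = int(params.pop("n", 1000))
    bounds = tuple(params.pop("bounds_um", (5.0, 5.0, 5.0)))
    rate = float(params.pop("photon_rate", 1000.0))
    center = np.asarray(params.pop("center_um", (0.0, 0.0, 0.0)), float)

    if kind == "shell":
        r_inner = float(params.pop("r_inner_um", 1.5))
        r_outer = float(params.pop("r_outer_um", 1.8))
        if r_outer <= r_inner:
            raise ValueError("r_outer_um must exceed r_inner_um")
        if r_outer > min(bounds):
            raise ValueError("shell radius exceeds simulation bounds")
        u = rng.random(n)
        radii = (r_inner**3 + u * (r_outer**3 - r_inner**3)) ** (1.0 / 3.0)
        direc = rng.normal(size=(n, 3))
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        xyz = center + radii[:, None] * direc
    elif kind == "dense_volume":
        radii_ax = np.asarray(params.pop("radii_um", (2.0, 2.0, 2.0)), float)
        if np.any(radii_ax > np.asarray(bounds) + 1e-9):
            raise ValueError("ellipsoid radii exceed simulation bounds")
        pts = []
        while sum(len(p) for p in pts) < n:
            cand = rng.uniform(-1.0, 1.0, size=(max(64, 2 * n), 3))
            cand = cand[(cand**2).sum(axis=1) <= 1.0]
            pts.append(cand)
        xyz = center + np.concatenate(pts)[:n] * radii_ax
    elif kind == "sparse_molecules":
        half = np.asarray(bounds, float)
        min_sep = float(params.pop("min_sep_um", 0.0))
        if min_sep <= 0:
            xyz = center + rng.uniform(-half, half, size=(n, 3))
        else:
            # rejection sampling: lateral spacing for resolvable single spots
            placed: list[np.ndarray] = []
            attempts = 0
            while len(placed) < n:
                cand = center + rng.uniform(-half, half, size=3)
                if all(
                    np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep
                    for p in placed
                ):
                    placed.append(cand)
                attempts += 1
                if attempts > 10000 * max(n, 1):
                    raise ValueError(
                        "cannot place emitters at the requested separation"
                    )
            xyz = np.asarray(placed).reshape(n, 3)
    else:
        raise ConfigurationError(f"unknown phantom kind {kind!r}")

    if params:
        raise ConfigurationError(f"unknown phantom parameters: {sorted(params)}")
    emitters = np.column_stack([xyz, np.full(n, rate)]) if n else np.empty((0, 4))
    return Phantom(
        emitters=emitters, kind=kind, bounds_um=bounds, center_um=tuple(center)
    )


# ---------------------------------------------------------------------------
# excitation and image formation


def sheet_excitation(
    x_um: np.ndarray | float,
    y_um: np.ndarray | float,
    z_um: np.ndarray | float,
    geometry: SheetGeometry,
) -> np.ndarray | float:
    """Relative excitation irradiance of the tilted sheet at a point.

    ``I = peak * (w0 / w(s)) * exp(-2 d^2 / w(s)^2)`` with *d* the
    perpendicular distance to the tilted mid-plane and *s* the in-plane
    distance from the focus along propagation.  The sheet is uniform along
    *y* (the cylindrical axis).
    """
    theta = math.radians(geometry.tilt_deg)
    x = np.asarray(x_um, float) - geometry.focus_xy_um
    z = np.asarray(z_um, float)
    d = np.abs(z * math.cos(theta) - x * math.sin(theta))
    s = x * math.cos(theta) + z * math.sin(theta)
    w0 = geometry.waist_w0_um
    w = w0 * np.sqrt(1.0 + (s / geometry.rayleigh_um) ** 2)
    return geometry.peak_intensity * (w0 / w) * np.exp(-2.0 * d**2 / w**2)


def field_center_um(detection: DetectionModel) -> tuple[float, float]:
    """(x, y) of the image centre in micrometres — the natural phantom centre."""
    h, w = detection.fov_px
    return (w * detection.pixel_nm / 2e3, h * detection.pixel_nm / 2e3)


def _pixel_edges_nm(n: int, pixel_nm: float) -> np.ndarray:
    return np.arange(n + 1, dtype=float) * pixel_nm


def render_frame(
    phantom: Phantom,
    illumination: SheetGeometry | None,
    detection: DetectionModel,
    exposure: float = 1.0,
    qe: float = 1.0,
) -> np.ndarray:
    """Noiseless expected-photoelectron image of a phantom.

    Each emitter contributes an integrated 2D Gaussian (pixel-integrated via
    the error function) of SD ``sigma(z)`` and total expected photoelectrons
    ``qe * photon_rate * excitation * exposure``.  ``illumination=None``
    means epi mode (unit excitation everywhere).  Photons are conserved up
    to clipping at the field border.
    """
    h, w = detection.fov_px
    image = np.zeros((h, w), dtype=float)
    if phantom.n_emitters == 0:
        return image
    ex = np.asarray(phantom.emitters[:, 0], float)
    ey = np.asarray(phantom.emitters[:, 1], float)
    ez = np.asarray(phantom.emitters[:, 2], float)
    rate = phantom.emitters[:, 3]
    if illumination is None:
        exc = np.ones_like(rate)
    else:
        exc = np.asarray(sheet_excitation(ex, ey, ez, illumination), float)
    totals = qe * rate * exc * exposure
    sig = np.asarray(detection.sigma_nm(ez), float)
    xe = _pixel_edges_nm(w, detection.pixel_nm)
    ye = _pixel_edges_nm(h, detection.pixel_nm)
    for k in range(phantom.n_emitters):
        if totals[k] <= 0:
            continue
        s = sig[k] * math.sqrt(2.0)
        fx = 0.5 * (erf((xe - ex[k] * 1e3) / s))
        fy = 0.5 * (erf((ye - ey[k] * 1e3) / s))
        image += totals[k] * np.outer(np.diff(fy), np.diff(fx))
    return image


def add_camera_noise(clean: np.ndarray, camera: CameraModel, seed: int) -> np.ndarray:
    """Sample a camera-count image from expected photoelectrons.

    counts = offset + gain * S + N(0, read_noise); S ~ Poisson(clean).  With
    ``excess_noise`` the amplified signal is drawn Gamma(S, gain), doubling
    the shot-noise variance as in a high-gain EM register.
    """
    clean = np.asarray(clean, float)
    if clean.size and clean.min() < 0:
        raise ValueError("expected photoelectron image must be non-negative")
    rng = np.random.default_rng(seed)
    electrons = rng.poisson(clean).astype(float)
    if camera.excess_noise:
        amplified = np.where(
            electrons > 0, rng.gamma(np.maximum(electrons, 1e-12), camera.em_gain), 0.0
        )
    else:
        amplified = camera.em_gain * electrons
    counts = camera.offset + amplified
    if camera.read_noise_counts > 0:
        counts = counts + rng.normal(0.0, camera.read_noise_counts, clean.shape)
    return counts


def simulate_pair(
    phantom: Phantom,
    geometry: SheetGeometry,
    detection: DetectionModel,
    camera: CameraModel,
    n_frames: int = 100,
    seed: int = 0,
    exposure: float = 1.0,
) -> ImagePair:
    """Acquire the same field under epi and light-sheet illumination.

    Both stacks view the same phantom with independent noise realizations
    per frame; the noiseless sheet-mode image (the in-focus signal) is kept
    as ``truth_clean`` for evaluation.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    clean_epi = render_frame(phantom, None, detection, exposure, camera.qe)
    clean_sheet = render_frame(phantom, geometry, detection, exposure, camera.qe)
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 * n_frames, dtype=np.uint32)
    epi = np.stack(
        [add_camera_noise(clean_epi, camera, int(child[i])) for i in range(n_frames)]
    )
    sheet = np.stack(
        [
            add_camera_noise(clean_sheet, camera, int(child[n_frames + i]))
            for i in range(n_frames)
        ]
    )
    meta = {"seed": seed, "exposure": exposure, "em_gain": camera.em_gain}
    return ImagePair(epi, sheet, geometry, truth_clean=clean_sheet, meta=meta)


def simulate_profile_stack(
    geometry: SheetGeometry,
    z_min_um: float = -10.0,
    z_max_um: float = 10.0,
    step_um: float = 0.5,
    frames_per_z: int = 100,
    detection: DetectionModel | None = None,
    camera: CameraModel | None = None,
    seed: int = 0,
    peak_photons: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct-beam profile z-scan: image the sheet cross-section per focal plane.

    Mimics projecting the sheet straight onto the camera while scanning the
    detection focus from ``z_min`` to ``z_max``: per z the image is a stripe
    along *y* whose centre column shifts by ``dz / tan(tilt)`` and whose
    lateral width follows ``w(s) / sin(tilt)``.  Returns the per-z average
    of ``frames_per_z`` noisy frames (noiseless if ``camera`` is None) and
    the z positions.
    """
    if z_min_um >= z_max_um:
        raise ValueError("z_min_um must be below z_max_um")
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    if step_um > (z_max_um - z_min_um):
        raise ValueError("step_um larger than the z range")
    detection = detection or DetectionModel()
    h, w = detection.fov_px
    px_um = detection.pixel_nm / 1e3
    x = (np.arange(w) + 0.5) * px_um
    y = (np.arange(h) + 0.5) * px_um
    n_z = int(round((z_max_um - z_min_um) / step_um)) + 1
    z_list = z_min_um + step_um * np.arange(n_z)
    xg = np.broadcast_to(x[None, :], (h, w))
    yg = np.broadcast_to(y[:, None], (h, w))
    ss = np.random.SeedSequence(seed).generate_state(n_z, dtype=np.uint32)
    stack = np.empty((n_z, h, w), dtype=float)
    for i, z in enumerate(z_list):
        clean = peak_photons * sheet_excitation(xg, yg, float(z), geometry)
        if camera is None:
            stack[i] = clean
        else:
            frame_seeds = np.random.SeedSequence(int(ss[i])).generate_state(
                frames_per_z, dtype=np.uint32
            )
            acc = np.zeros_like(clean)
            for fs in frame_seeds:
                acc += add_camera_noise(clean, camera, int(fs))
            stack[i] = acc / frames_per_z
    return stack, z_list


def simulate_smlm_movie(
    phantom: Phantom,
    blink: BlinkModel,
    background_map: np.ndarray | None,
    detection: DetectionModel,
    camera: CameraModel,
    n_frames: int = 100,
    seed: int = 0,
    start_on_prob: float | None = None,
) -> SMLMMovie:
    """Blinking single-molecule movie over a static background.

    Each emitter follows a two-state Markov chain (on/off) with an optional
    absorbing bleached state; the truth table records every frame in which
    an emitter is on.  ``background_map`` (expected photoelectrons per
    pixel) is added to the clean signal before camera noise; sharp-edged
    maps reproduce the difficult nucleus/nucleolus-edge regime.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    h, w = detection.fov_px
    if background_map is None:
        background_map = np.zeros((h, w), dtype=float)
    background_map = np.asarray(background_map, float)
    if background_map.shape != (h, w):
        raise ValueError("background_map shape must match detection.fov_px")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noise_seeds = np.random.SeedSequence(seed + 1).generate_state(
        n_frames, dtype=np.uint32
    )
    n = phantom.n_emitters
    p_start = blink.stationary_on if start_on_prob is None else start_on_prob
    on = rng.random(n) < p_start
    bleached = np.zeros(n, dtype=bool)
    frames = np.empty((n_frames, h, w), dtype=float)
    truth_rows: list[tuple[int, float, float, float]] = []
    em = phantom.emitters
    for t in range(n_frames):
        active = on & ~bleached
        sub = Phantom(
            em[active],
            kind=phantom.kind,
            bounds_um=phantom.bounds_um,
            center_um=phantom.center_um,
        )
        clean = render_frame(sub, None, detection, exposure=1.0, qe=camera.qe)
        frames[t] = add_camera_noise(clean + background_map, camera, int(noise_seeds[t]))
        for idx in np.flatnonzero(active):
            truth_rows.append((t, em[idx, 0] * 1e3, em[idx, 1] * 1e3, em[idx, 3]))
        # state update for the next frame
        u = rng.random(n)
        bleach_draw = rng.random(n)
        next_on = np.where(on, u >= blink.off_rate, u < blink.on_rate)
        newly_bleached = on & (bleach_draw < blink.bleach_prob)
        bleached |= newly_bleached
        on = next_on & ~bleached
    truth = np.asarray(truth_rows, dtype=float).reshape(-1, 4)
    return SMLMMovie(frames, truth, background_map, blink, detection, camera)
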